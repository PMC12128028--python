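# Methods

## Scope and design

`cvsteer` implements a complete desk-scale pipeline for driving and
validating hinge-bending conformational transitions with low-dimensional
collective variables (CVs): CV geometry and gradients, seeded Langevin
dynamics, four-stage steered protocols with moving harmonic restraints,
temperature-accelerated dynamics (TAMD) with auxiliary variables, frame
ranking and relaxation validation, and the surrounding statistics and I/O.
Because all-atom trajectories of the real protein are not reproducible at
desk scale, the pipeline is exercised on a synthetic gated two-basin model
whose observable statistics emulate the closed/open reference table of T4
lysozyme. The model is first-class, tested code: its behavioural contract —
not any particular parameter value — is what the test suite enforces.

## The gated two-basin model

State vector θ = (d1, d2, d6, χ1, Lα3); lengths nm, χ1 in radians
internally (degrees at every API surface), energies kJ/mol.

U(θ) = U_basins + U_block + U_lock + U_sb + U_rot + U_helix, with:

* **U_basins** = −ε·ln(exp(−g_c) + exp(−g_o)), where
  g_s = Σ_i (Δ_i/(√2 σ_{s,i}))² runs over (d1, d2, d6, χ1) with the per-CV
  means and SDs of the closed/open reference table (angle differences
  wrapped), plus a shared folded-helix term in Lα3 (below). With
  ε = k_BT (2.494 kJ/mol at 300 K) each basin's equilibrium fluctuations
  reproduce the reference SDs. A much deeper ε would make basin walls so
  stiff that a 500 kJ/mol·nm² steering spring could never extract the
  tightest coordinate (d6, σ = 0.06 nm): the pulling force required would
  exceed κ·Δ for any reachable lag.
* The Lα3 contribution q/(1 + q/cap) with q = (Lα3 − L_fold)²/(2σ_L²),
  σ_L = 0.05 nm, cap = 4, is common to both basins: a broken helix excludes
  both states. The saturation matters: an unbounded quadratic would pull a
  broken helix back to the folded length with ~400 kJ/mol·nm, making
  breakage unobservable.
* **U_block** = A_block · sig((r_gate − d6)/w_gate) · G(χ1; χ_open, s_chi):
  while the salt bridge is intact (d6 below ~0.6 nm) the open rotamer
  pocket is inaccessible (A_block = 50 kJ/mol, s_chi = 30°). At the open
  rotamer the block makes (χ1 open, bridge intact) a saddle, so a rotamer
  forced into a blocked pocket is expelled once the bias is released.
* **U_rot** = A_rot · G(χ1; χ_mid, s_rot): an intrinsic rotamer ridge
  (50 kJ/mol at 135°, width 10°) between the two χ1 wells. Without it the
  log-sum-exp structure lets χ1 slide barrier-free to the open rotamer as
  soon as the distance CVs are held open, and steering sets that omit χ1
  would spuriously succeed.
* **U_lock** = A_lock · (1 − G(χ1; χ_open, s_chi)) · G(d2; μ_open,d2, 0.1):
  d2 cannot rest at its open value unless χ1 occupies the open rotamer
  (A_lock = 10 kJ/mol).
* **U_sb** = A_sb · G(d6; r_sb, s_sb): the salt-bridge rupture barrier
  (80 kJ/mol at 0.7 nm; width 0.08 nm on the approach side and 0.05 nm on
  the open side so the barrier decays before the open basin's thermal
  envelope). The height is set by a kinetic requirement: when a steering
  set rotates χ1 while leaving d6 unbiased, the stored block energy pushes
  d6 outward with up to ~250 kJ/mol·nm, and the barrier must hold against
  it for the length of a run.
* **U_helix**: a quartic double well in Lα3 with minima at L_fold = 2.05
  and L_broken = 2.45 nm, barrier 36 kJ/mol, broken well 3 kJ/mol above
  folded, continued as harmonic tails beyond the minima so the stiffness
  stays bounded for the integrator.

**Helix strain is a tension response, not a potential term.** When
external restraints pull d2 and d6 in opposite directions (their
generalized forces have opposite signs), the Lα3 coordinate feels a
stretching force λ·√|f_d2 · f_d6| (λ = 1.6, cut off at L_broken),
implemented in the protocol layer where the restraint forces are known. A
position-window formulation was tried first and rejected empirically: any
attractive window reachable from the closed basin either traps unbiased
trajectories or cannot distinguish driven transit from thermal excursions,
because the parked mid-transition values of d2/d6 lie only 1.5–2σ from the
closed means. Tension-based strain is zero in unbiased runs by
construction, matching the mechanistic picture (opposing pulls on the two
helix termini). TAMD coupling forces are excluded from the strain response:
they fluctuate around zero on the auxiliary-relaxation timescale and carry
no sustained tension.

**Stationary-mean calibration.** The gate terms and basin overlap shift
the model's stationary means slightly off the placed centres (e.g. the
rupture barrier truncates the open d6 basin's lower flank; the rotamer
ridge truncates the closed χ1 well's upper flank). Five small centre
offsets (`cal_*` parameters, solved by Boltzmann quadrature over the
conditional potential and refined against long sampled runs) put the
sampled means back on the reference values. The residual fidelity of all
stationary means is better than 0.05 of a basin SD, which is the floor the
equilibrium tests assert alongside their two-standard-error bounds.

A Cartesian bead embedding (18 beads; harmonic bonds keeping the dihedral
quadruple and the two Lα3 tetrahedra non-degenerate) composes the same
potential with explicit CV geometry, so Jacobian-projected biasing forces
are exercised end-to-end.

## Dynamics

Time is measured in reduced units with friction γ = 1; one *schedule unit*
(the analog of 1 ns of the all-atom protocol) is `steps_per_unit · dt`
with defaults 1000 × 2·10⁻⁴. Absolute timescales are out of scope; stage
proportions are preserved.

The production propagator for CV-space models is overdamped Langevin via
the Leimkuhler–Matthews splitting (drift step plus the average of two
consecutive Gaussian increments). Plain Euler–Maruyama at dt·k/γ ≈ 1.4 on
the stiffest coordinate (the folded-helix well, k ≈ 7500 kJ/mol·nm²)
inflates that coordinate's variance ~1.8× and produced spurious
helix-breaking; the LM scheme samples configurations with O(dt²) accuracy
at identical cost. A BAOAB integrator serves the Cartesian bead model and
the TAMD auxiliary variables. Runs are pure functions of
(model, x₀, parameters, seed); replica sets use seed = base_seed + index.
Blow-ups (non-finite energy or |x| > 10³) abort with the partial
trajectory attached.

## Steering protocol

Per-CV moving harmonic restraints follow four stages (defaults 25 units
each, the equal-stage schedule; five further schedules reweight ramp vs
steer time and every duration is configurable): κ rises linearly from 0
during ramp-up with centres at the start-state means; centres move
linearly (shortest wrapped arc for angles) during steer; κ falls to zero
during ramp-down with centres held at the targets; the free stage is
unbiased. Restrain-only terms (the Lα3 restraint, κ = 500 kJ/mol·nm² at
2.05 nm) keep their centre fixed throughout and ramp with everything else.
The 19 registered steering sets mirror the study table of CV
combinations, spring constants and schedules, including the desynchronized
variant compiled as per-CV stage lists. Success: every steered CV's mean
over the final half of the free stage within 2σ of the target-state mean
(boundary inclusive — "near" is not quantified in the source and 2σ of the
reference SD is adopted), and the helix analog inside its folded window
(|Lα3 − 2.05| < 0.2 nm, the folded/broken midpoint).

## Temperature-accelerated dynamics

Each coupled CV is tethered (κ = 500 kJ/mol·nm² distances, 100 kJ/mol·rad²
for χ1) to an auxiliary variable of mass m = κ(τ/2π)² evolved by BAOAB at
a fictitious temperature T_f with friction γ_z; the physical system feels
the spring force at 300 K, with the Lα3 restraint on by default. The mass
convention makes τ and γ_z independent knobs (the spec of a harmonic
auxiliary leaves their joint parameterization open; this matches common
extended-Lagrangian practice). Toy defaults γ_z = 25/time, τ = 0.05 time
preserve the relaxation-time ordering of the reference parameters;
T_f = 12000 K (40× physical, versus 10× in the all-atom setting) is the
calibration at which the synthetic landscape's basin separations — up to
10.5 closed-state SDs along d6 — become reachable within a desk-scale run,
reproducing the qualitative pattern: the full coupling set reaches the
open state in ≥ 8/10 seeds while reduced sets (d1/d2, with or without χ1)
never do. Frame extraction filters frames with every coupled CV inside the
open 2σ window, ranks by σ-scaled Euclidean distance (wrapped angles),
enforces a minimum index separation (0.5 % of the trajectory) so
snapshots are non-redundant, and breaks ties toward earlier time.

## Estimators

Rolling means are centred with symmetrically shrinking edge windows
(window 51 by default; circular averaging for angles). Series statistics
use circular mean/SD for periodic CVs. Densities: Freedman–Diaconis
histograms or Gaussian KDE with Silverman bandwidth; periodic series are
estimated on the wrapped circle by ±360° replication. The overlap
coefficient ∫min(p, q) is computed on the union grid. Closed-state
multimodality is reported descriptively (KDE modes above 10 % of the
maximum) and never used in decisions.

## Synthetic stand-in structures

The CV-table pipeline is designed for the closed/open crystal structures.
The repository carries no deposited coordinates; instead
`synthetic_structures` builds stand-in PDB files in which every registry
CV takes a prescribed value (by default the published crystal values).
The distance-constraint graph is a forest, so atoms are placed cluster by
cluster at exact constrained distances, the χ1 quadruple by torsion
construction (with elongated bonds so the 0.001 Å PDB grid resolves the
angle, plus a quantisation-compensation pass), and the α3 termini as CA
quadruplets at an exact COM separation. The stand-ins are labelled
synthetic in their REMARK records; they exercise parsing, altloc
resolution, chain selection and CV evaluation, but say nothing about real
crystal packing.

## What the synthetic model does and does not show

Passing tests demonstrate that the *protocol machinery* behaves correctly
on a landscape with the reference statistics and couplings: insufficient
CV sets fail, the gated mechanism (bridge → rotamer → lock) is required,
opposing pulls break the unprotected helix, and target-free acceleration
finds the open state only with the full CV set. They do not demonstrate
anything about explicit-solvent energetics, absolute timescales, the
multimodality of real closed-state distributions (basins here are single
Gaussians), or CVs beyond the registry. Problem sizes were chosen for a
single CPU: 100 schedule units per steered replica (10⁵ steps), 5–10
replicas per set, 10 seeds per TAMD set.

## Known limitations

* The closed-state multimodality of the real distance distributions is not
  modelled; only means/SDs are matched.
* d3–d5 and d7–d10 are carried in the registry and evaluated on structures
  but are not degrees of freedom of the synthetic model (the successful
  protocol never steers them).
* The gate amplitudes are not fitted to any measured free-energy surface;
  they are the smallest set of couplings that reproduces the qualitative
  outcome pattern, and the behavioural tests are the authority on them.
* Euler–Maruyama (`step`) remains available for single-step use; long
  runs should go through `run`, which applies the LM splitting.
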