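"""Synthetic gated two-basin model of the hinge-bending transition.

The model is a five-dimensional potential over the reduced coordinates
θ = (d1, d2, d6, χ1, Lα3) whose equilibrium statistics emulate the
closed/open reference table and whose couplings encode the mechanistic
features of the real protein's hinge transition:

* a log-sum-exp pair of Gaussian basins centred on the closed and open
  per-CV means (the Lα3 term is centred on the *folded* helix length in
  both basins, so a broken helix excludes both states);
* ``U_block`` — while the Arg8–Glu64 salt bridge is intact (d6 small), the
  hydrophobic pocket is inaccessible and the open χ1 rotamer is penalised;
* ``U_rot`` — an intrinsic rotameric ridge between the two χ1 wells, so the
  Phe4 analog does not rotate spontaneously on the run timescale even when
  the salt bridge has been forced open;
* ``U_lock`` — d2 cannot rest at its open value unless χ1 occupies the open
  rotamer (the "locking" mechanism);
* ``U_sb`` — a barrier along d6 representing salt-bridge rupture;
* ``U_helix`` — a double well in Lα3 (folded / broken α3);
* ``U_strain`` — transit through mid-transition with d2 and d6 both
  displaced tilts the helix toward breaking, reproducing the α3 fragility
  under simultaneous opposing pulls.

A Cartesian bead embedding (:func:`build_bead_model`) maps the same
potential through explicit CV geometry so that Jacobian-projected biasing
forces are exercised end to end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np

from . import cv as cvg
from .constants import KBT
from .errors import ConfigurationError
from .references import MODEL_CVS, StateReference, state_pair

__all__ = [
    "GatedModelParams",
    "SystemModel",
    "build_cv_space_model",
    "build_bead_model",
    "initial_condition",
]

TWO_PI = 2.0 * math.pi


def _wrap_rad(a: float) -> float:
    """Wrap a radian angle to (−π, π]."""
    w = a - TWO_PI * math.floor(a / TWO_PI + 0.5)
    return math.pi if w <= -math.pi else w


@dataclass(frozen=True)
class GatedModelParams:
    """Tunable parameters of the gated two-basin potential.

    Energies kJ/mol, lengths nm, angles degrees. The defaults are
    order-of-magnitude choices that satisfy the behavioural contract
    exercised by the test suite (closed-state metastability, salt-bridge
    gating of the rotamer, rotamer locking of d2, helix fragility under
    simultaneous d2/d6 pulls); the contract, not these particular numbers,
    is normative.
    """

    epsilon: float = KBT          # well-depth scale; kBT makes per-CV SDs match the table
    basin_offset_open: float = 0.0
    A_block: float = 50.0         # pocket-blocking amplitude while salt bridge intact
    A_lock: float = 10.0          # d2-at-open penalty while χ1 is closed
    A_sb: float = 80.0            # salt-bridge rupture barrier along d6
    A_rot: float = 50.0           # intrinsic χ1 rotamer ridge
    r_gate: float = 0.6           # d6 switching centre of the gate (nm)
    w_gate: float = 0.05          # gate switching width (nm)
    s_chi: float = 30.0           # open-rotamer window width (degrees)
    r_sb: float = 0.7             # salt-bridge barrier centre (nm)
    s_sb: float = 0.08            # salt-bridge barrier width, closed side (nm)
    s_sb_open: float = 0.05       # barrier width on the open side: decays
                                  # before the open basin's thermal envelope
    chi_mid: float = 135.0        # rotamer ridge position (degrees)
    s_rot: float = 10.0           # rotamer ridge width (degrees)
    L_fold: float = 2.05          # folded α3 end-to-end length (nm)
    L_broken: float = 2.45        # broken-helix well position (nm)
    helix_barrier: float = 36.0   # folded→broken barrier (kJ/mol)
    helix_depth_penalty: float = 3.0  # broken well lies this far above folded
    sigma_La3: float = 0.05       # width of the folded-Lα3 basin term (nm)
    la3_cap: float = 4.0          # saturation of the Lα3 basin term (dimensionless)
    # antagonistic-tension coupling: when external restraints pull d2 and d6
    # in opposite directions (their generalized forces have opposite sign),
    # the α3 analog feels a stretching force strain_coupling·√|f_d2·f_d6|
    # until it reaches the broken length. Unbiased dynamics carry no strain.
    strain_coupling: float = 1.6  # dimensionless
    strain_cv_a: str = "d2"
    strain_cv_b: str = "d6"
    strain_target: str = "La3"
    # basin-centre calibration (nm): the rupture-barrier tail and basin
    # overlap pull the stationary means slightly off the placed centres;
    # these offsets put the *sampled* means back on the reference values
    # (solved by 1-D Boltzmann quadrature over the conditional potential)
    cal_d6_closed: float = 0.0225
    cal_chi_closed: float = 10.73 # degrees
    cal_chi_open: float = -0.74   # degrees
    cal_d6_open: float = -0.077
    cal_d2_closed: float = -0.007

    def __post_init__(self):
        for name in ("A_block", "A_lock", "A_sb", "A_rot", "strain_coupling",
                     "helix_barrier", "helix_depth_penalty", "epsilon"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if not self.L_fold < self.L_broken:
            raise ConfigurationError("L_fold must be below L_broken")

    def with_(self, **kwargs) -> "GatedModelParams":
        return replace(self, **kwargs)


@dataclass
class SystemModel:
    """Contract for any simulatable system.

    ``energy``/``gradient`` act on the full coordinate vector ``x`` (the
    5-vector θ for the CV-space model, flattened 3N Cartesian for the bead
    model). ``cv_values`` reports CVs in user units (nm / degrees);
    ``cv_jacobian`` returns ∂θ_i/∂x_j in internal units (radians for
    angles). ``wrap_state`` re-wraps periodic coordinates after a step.
    """

    dimension: int
    cv_names: Sequence[str]
    periodic: np.ndarray
    energy: Callable[[np.ndarray], float]
    gradient: Callable[[np.ndarray], np.ndarray]
    cv_values: Callable[[np.ndarray], np.ndarray]
    cv_jacobian: Callable[[np.ndarray], np.ndarray]
    wrap_state: Callable[[np.ndarray], np.ndarray]
    masses: np.ndarray = None
    params: GatedModelParams = None
    refs: tuple = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.masses is None:
            self.masses = np.ones(self.dimension)
        self.periodic = np.asarray(self.periodic, dtype=bool)

    def energy_gradient(self, x):
        return self.energy(x), self.gradient(x)


def _check_refs(refs):
    closed, open_ = refs
    for ref, label in ((closed, "closed"), (open_, "open")):
        if ref.state != label:
            raise ConfigurationError(f"expected ({'closed'}, {'open'}) reference pair")
        for name in MODEL_CVS:
            ref.mean(name)  # raises ConfigurationError when missing
    return closed, open_


def _compile_energy(p: GatedModelParams, closed: StateReference, open_: StateReference):
    """Build a scalar energy/gradient pair over θ = (d1, d2, d6, χ1[rad], Lα3).

    Written in plain scalar arithmetic: the integrators call this tens of
    millions of times per protocol run.
    """
    names = MODEL_CVS
    mu_c = [closed.mean(n) for n in names]
    mu_o = [open_.mean(n) for n in names]
    sd_c = [closed.sd(n) for n in names]
    sd_o = [open_.sd(n) for n in names]
    # internal radians for χ1 (index 3); Lα3 (index 4) uses the folded length
    # with a common width in both basins
    mu_c[3] = math.radians(mu_c[3])
    mu_o[3] = math.radians(mu_o[3])
    sd_c[3] = math.radians(sd_c[3])
    sd_o[3] = math.radians(sd_o[3])
    mu_c[1] += p.cal_d2_closed
    mu_c[2] += p.cal_d6_closed
    mu_o[2] += p.cal_d6_open
    mu_c[3] += math.radians(p.cal_chi_closed)
    mu_o[3] += math.radians(p.cal_chi_open)
    inv2_c = [1.0 / (2.0 * s * s) for s in sd_c[:4]]
    inv2_o = [1.0 / (2.0 * s * s) for s in sd_o[:4]]
    inv_sL2 = 1.0 / (p.sigma_La3 * p.sigma_La3)
    la3_cap = p.la3_cap

    eps = p.epsilon
    off = p.basin_offset_open / eps if eps > 0 else 0.0
    chi_open = mu_o[3]
    chi_mid = math.radians(p.chi_mid)
    s_chi = math.radians(p.s_chi)
    s_rot = math.radians(p.s_rot)
    mu_o_d2 = mu_o[1]
    c_mid = 0.5 * (p.L_fold + p.L_broken)
    a_h = 0.5 * (p.L_broken - p.L_fold)
    inv_a4 = 1.0 / a_h ** 4

    def energy_gradient(x):
        d1, d2, d6, chi, La = float(x[0]), float(x[1]), float(x[2]), float(x[3]), float(x[4])
        # --- two-basin log-sum-exp over (d1, d2, d6, χ1) ------------------
        dc = [d1 - mu_c[0], d2 - mu_c[1], d6 - mu_c[2], _wrap_rad(chi - mu_c[3])]
        do = [d1 - mu_o[0], d2 - mu_o[1], d6 - mu_o[2], _wrap_rad(chi - mu_o[3])]
        g_c = sum(dc[i] * dc[i] * inv2_c[i] for i in range(4))
        g_o = sum(do[i] * do[i] * inv2_o[i] for i in range(4)) + off
        m = g_c if g_c < g_o else g_o
        ec = math.exp(-(g_c - m))
        eo = math.exp(-(g_o - m))
        z = ec + eo
        u = eps * (m - math.log(z))
        w_c = ec / z
        w_o = eo / z
        grad = [eps * (w_c * 2.0 * dc[i] * inv2_c[i] + w_o * 2.0 * do[i] * inv2_o[i])
                for i in range(4)]
        grad.append(0.0)
        # folded-Lα3 basin term, common to both basins (a broken helix
        # excludes both states); saturates at large deviations so a broken
        # helix is a genuine metastable trap rather than healing instantly
        dL = La - p.L_fold
        q = 0.5 * dL * dL * inv_sL2
        den = 1.0 + q / la3_cap
        u += eps * q / den
        grad[4] += eps * (dL * inv_sL2) / (den * den)
        # --- gates --------------------------------------------------------
        dchi_open = _wrap_rad(chi - chi_open)
        g_pocket = math.exp(-dchi_open * dchi_open / (2.0 * s_chi * s_chi))
        dg_pocket = -dchi_open / (s_chi * s_chi) * g_pocket
        sig = 1.0 / (1.0 + math.exp(-(p.r_gate - d6) / p.w_gate))
        u += p.A_block * sig * g_pocket
        grad[2] += p.A_block * g_pocket * sig * (1.0 - sig) * (-1.0 / p.w_gate)
        grad[3] += p.A_block * sig * dg_pocket

        dd2_o = d2 - mu_o_d2
        g_d2 = math.exp(-dd2_o * dd2_o / (2.0 * 0.10 * 0.10))
        u += p.A_lock * (1.0 - g_pocket) * g_d2
        grad[1] += p.A_lock * (1.0 - g_pocket) * (-dd2_o / 0.01) * g_d2
        grad[3] += -p.A_lock * dg_pocket * g_d2

        dd6_sb = d6 - p.r_sb
        s_side = p.s_sb if dd6_sb < 0.0 else p.s_sb_open
        g_sb = math.exp(-dd6_sb * dd6_sb / (2.0 * s_side * s_side))
        u += p.A_sb * g_sb
        grad[2] += p.A_sb * (-dd6_sb / (s_side * s_side)) * g_sb

        dchi_mid = _wrap_rad(chi - chi_mid)
        g_rot = math.exp(-dchi_mid * dchi_mid / (2.0 * s_rot * s_rot))
        u += p.A_rot * g_rot
        grad[3] += p.A_rot * (-dchi_mid / (s_rot * s_rot)) * g_rot

        # --- helix double well + strain tilt ------------------------------
        # quartic between the folded/broken minima, harmonic tails outside
        # (C2-continuous; keeps the stiffness bounded for the integrator)
        y = La - c_mid
        if y > a_h:
            du = 8.0 * p.helix_barrier / (a_h * a_h) * (y - a_h)
            u += 0.5 * du * (y - a_h)
            grad[4] += du
        elif y < -a_h:
            du = 8.0 * p.helix_barrier / (a_h * a_h) * (y + a_h)
            u += 0.5 * du * (y + a_h)
            grad[4] += du
        else:
            yy = y * y - a_h * a_h
            u += p.helix_barrier * yy * yy * inv_a4
            grad[4] += 4.0 * p.helix_barrier * yy * y * inv_a4
        sig_h = 1.0 / (1.0 + math.exp(-y / (0.5 * a_h)))
        u += p.helix_depth_penalty * sig_h
        grad[4] += p.helix_depth_penalty * sig_h * (1.0 - sig_h) / (0.5 * a_h)

        return u, grad

    return energy_gradient


def build_cv_space_model(params: Optional[GatedModelParams] = None,
                         refs=None) -> SystemModel:
    """Five-dimensional model with x ≡ θ = (d1, d2, d6, χ1, Lα3).

    χ1 is carried in radians internally and reported in degrees.
    """
    params = params or GatedModelParams()
    refs = _check_refs(refs or state_pair())
    eg = _compile_energy(params, *refs)

    def energy(x):
        return eg(x)[0]

    def gradient(x):
        return np.asarray(eg(x)[1])

    def cv_values(x):
        out = np.asarray(x, dtype=float).copy()
        out[3] = cvg.wrap_angle(math.degrees(out[3]))
        return out

    jac = np.eye(5)

    def cv_jacobian(x):
        return jac

    def wrap_state(x):
        x[3] = _wrap_rad(x[3])
        return x

    model = SystemModel(
        dimension=5, cv_names=list(MODEL_CVS),
        periodic=np.array([False, False, False, True, False]),
        energy=energy, gradient=gradient, cv_values=cv_values,
        cv_jacobian=cv_jacobian, wrap_state=wrap_state,
        params=params, refs=refs,
    )
    model.meta["energy_gradient"] = eg
    model.meta["kind"] = "cv_space"
    model.meta["strain"] = _strain_spec(params)
    return model


def _strain_spec(params: GatedModelParams):
    """Antagonistic-tension coupling descriptor consumed by the protocols."""
    if params.strain_coupling <= 0:
        return None
    return {
        "cv_a": params.strain_cv_a, "cv_b": params.strain_cv_b,
        "target": params.strain_target, "coupling": params.strain_coupling,
        "cutoff": params.L_broken,
    }


# ---------------------------------------------------------------------------
# Cartesian bead embedding
# ---------------------------------------------------------------------------

#: bead indices backing each model CV in the default topology
DEFAULT_BEAD_GROUPS = {
    "d1": ((0,), (1,)),
    "d2": ((2,), (3,)),
    "d6": ((4,), (5,)),
    "chi1": ((6,), (7,), (8,), (9,)),
    "La3": ((10, 11, 12, 13), (14, 15, 16, 17)),
}
N_BEADS = 18


def _default_topology():
    """Harmonic bonds that keep the embedding geometry non-degenerate."""
    bonds = []
    # χ1 backbone chain with 1–3 spacers fixing the bend angles
    for i, j, r0 in ((6, 7, 0.15), (7, 8, 0.15), (8, 9, 0.15),
                     (6, 8, 0.245), (7, 9, 0.245)):
        bonds.append((i, j, r0, 8000.0))
    # each Lα3 group is a near-rigid tetrahedron
    for base in (10, 14):
        grp = list(range(base, base + 4))
        for a in range(4):
            for b in range(a + 1, 4):
                bonds.append((grp[a], grp[b], 0.3, 8000.0))
    return bonds


def _place_fourth(a, b_, c, bond, angle, torsion):
    """NeRF placement of atom D with given |CD|, angle B-C-D and torsion A-B-C-D."""
    bc = c - b_
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b_ - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * (-math.cos(angle) * bc
                      + math.sin(angle) * (math.cos(torsion) * m + math.sin(torsion) * n))
    return c + d_local


def reference_pose(state: str, params: Optional[GatedModelParams] = None,
                   refs=None) -> np.ndarray:
    """Bead coordinates whose CV values equal a basin's per-CV means."""
    params = params or GatedModelParams()
    closed, open_ = _check_refs(refs or state_pair())
    ref = closed if state == "closed" else open_
    if state not in ("closed", "open"):
        raise ValueError(f"unknown state {state!r}")
    x = np.zeros((N_BEADS, 3))
    # distance pairs laid out on separated parallel lines
    for name, y in zip(("d1", "d2", "d6"), (0.0, 2.0, 4.0)):
        (i,), (j,) = DEFAULT_BEAD_GROUPS[name]
        x[i] = (0.0, y, 0.0)
        x[j] = (ref.mean(name), y, 0.0)
    # dihedral quadruple with the target torsion about the j→k bond
    chi_target = ref.mean("chi1")
    b = 0.15
    ang = math.radians(109.5)
    x[7] = (0.0, 6.0, 0.0)
    x[8] = (b, 6.0, 0.0)
    x[6] = (b * math.cos(ang), 6.0 + b * math.sin(ang), 0.0)
    x[9] = _place_fourth(x[6], x[7], x[8], b, ang, math.radians(chi_target))
    if abs(cvg.wrap_angle_diff(cvg.eval_dihedral(x, 6, 7, 8, 9), chi_target)) > 1e-6:
        x[9] = _place_fourth(x[6], x[7], x[8], b, ang, -math.radians(chi_target))
    # Lα3 tetrahedra separated along x by the folded length
    tet = np.array([(0.0, 0.0, 0.0), (0.3, 0.0, 0.0),
                    (0.15, 0.26, 0.0), (0.15, 0.087, 0.245)])
    centroid = tet.mean(axis=0)
    x[10:14] = tet - centroid + np.array([0.0, 9.0, 0.0])
    x[14:18] = tet - centroid + np.array([ref.mean("La3"), 9.0, 0.0])
    return x


def build_bead_model(params: Optional[GatedModelParams] = None, refs=None,
                     topology=None) -> SystemModel:
    """3N-dimensional Cartesian embedding of the gated potential.

    Energy = Σ harmonic bonds + U(θ(x)); forces flow through the CV
    Jacobian by the chain rule.
    """
    params = params or GatedModelParams()
    refs = _check_refs(refs or state_pair())
    bonds = _default_topology() if topology is None else list(topology)
    for i, j, _, _ in bonds:
        if not (0 <= i < N_BEADS and 0 <= j < N_BEADS):
            raise ConfigurationError(f"bond ({i},{j}) references undefined beads")
    eg = _compile_energy(params, *refs)
    specs = [
        cvg.CVSpec("d1", "pair_distance", DEFAULT_BEAD_GROUPS["d1"]),
        cvg.CVSpec("d2", "pair_distance", DEFAULT_BEAD_GROUPS["d2"]),
        cvg.CVSpec("d6", "pair_distance", DEFAULT_BEAD_GROUPS["d6"]),
        cvg.CVSpec("chi1", "dihedral", DEFAULT_BEAD_GROUPS["chi1"]),
        cvg.CVSpec("La3", "com_distance", DEFAULT_BEAD_GROUPS["La3"]),
    ]

    def theta_of(coords):
        th = np.array([cvg.eval_cv(s, coords) for s in specs])
        th[3] = math.radians(th[3])
        return th

    def bond_energy_grad(coords):
        u = 0.0
        g = np.zeros_like(coords)
        for i, j, r0, k in bonds:
            d = coords[i] - coords[j]
            r = np.linalg.norm(d)
            u += 0.5 * k * (r - r0) ** 2
            f = k * (r - r0) / max(r, 1e-12) * d
            g[i] += f
            g[j] -= f
        return u, g

    def energy(x):
        coords = np.asarray(x, dtype=float).reshape(-1, 3)
        ub, _ = bond_energy_grad(coords)
        return ub + eg(theta_of(coords))[0]

    def gradient(x):
        coords = np.asarray(x, dtype=float).reshape(-1, 3)
        ub, g = bond_energy_grad(coords)
        _, dth = eg(theta_of(coords))
        for s, dth_i in zip(specs, dth):
            # dihedral cv_gradient is already in rad/nm, matching dU/dχ[rad]
            g += dth_i * cvg.cv_gradient(s, coords)
        return g.reshape(-1)

    def cv_values(x):
        coords = np.asarray(x, dtype=float).reshape(-1, 3)
        return np.array([cvg.eval_cv(s, coords) for s in specs])

    def cv_jacobian(x):
        coords = np.asarray(x, dtype=float).reshape(-1, 3)
        return np.stack([cvg.cv_gradient(s, coords).reshape(-1) for s in specs])

    model = SystemModel(
        dimension=3 * N_BEADS, cv_names=[s.name for s in specs],
        periodic=np.array([s.periodic for s in specs]),
        energy=energy, gradient=gradient, cv_values=cv_values,
        cv_jacobian=cv_jacobian, wrap_state=lambda x: x,
        params=params, refs=refs,
    )
    model.meta["kind"] = "bead"
    model.meta["specs"] = specs
    model.meta["energy_gradient_theta"] = eg
    model.meta["strain"] = _strain_spec(params)
    return model


def initial_condition(model: SystemModel, state: str, seed,
                      jitter_scale: float = 0.25) -> np.ndarray:
    """Basin centre plus Gaussian jitter of ``jitter_scale``·σ per CV.

    Deterministic per seed. For the bead model the jitter is applied as a
    small Cartesian perturbation of the reference pose instead (per-CV
    jitter has no unique Cartesian preimage).
    """
    if state not in ("closed", "open"):
        raise ValueError(f"unknown state {state!r}; expected 'closed' or 'open'")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    closed, open_ = model.refs
    ref = closed if state == "closed" else open_
    if model.meta.get("kind") == "bead":
        pose = reference_pose(state, model.params, model.refs)
        pose += jitter_scale * 0.01 * rng.standard_normal(pose.shape)
        return pose.reshape(-1)
    x = np.array([ref.mean(n) for n in model.cv_names], dtype=float)
    sd = np.array([ref.sd(n) for n in model.cv_names], dtype=float)
    x[3] = math.radians(x[3])
    sd[3] = math.radians(sd[3])
    # the helix starts folded regardless of the basin
    x[4] = model.params.L_fold
    sd[4] = model.params.sigma_La3
    x = x + jitter_scale * sd * rng.standard_normal(5)
    return model.wrap_state(x)
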