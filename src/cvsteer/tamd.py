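"""Temperature-accelerated dynamics on a gated model.

Each selected CV θ_i is tethered by a harmonic spring κ_i to an auxiliary
variable z_i ("fictitious particle") of mass m_i = κ_i (τ/2π)², which
evolves by underdamped Langevin dynamics at an elevated fictitious
temperature T_f while the physical system stays at the physiological
temperature. Because the auxiliary variables feel the free-energy surface
scaled by T/T_f, they random-walk across barriers and drag the physical
CVs with them — accelerating conformational exploration without a target
bias. Validation proceeds by target-free sampling: frames near the target basin
are extracted, ranked by standardized CV-space distance, and relaxed by
unbiased dynamics to test metastability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from . import analysis, dynamics
from .constants import KB
from .cv import wrap_angle_diff
from .errors import ConfigurationError, IntegrationError
from .model import SystemModel, initial_condition
from .references import L_FOLD, StateReference, is_periodic

__all__ = [
    "TAMDParams", "FrameRank", "coupling_force", "step_aux", "run_tamd",
    "joint_open_visit", "rank_frames", "relax_from_frames",
]

TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class TAMDParams:
    """Auxiliary-variable coupling parameters (toy time units).

    ``kappas`` maps CV name → spring constant (kJ/mol·nm² for distances,
    kJ/mol·rad² for angles). ``tau`` sets the fictitious mass via
    m = κ(τ/2π)²; ``gamma`` is an independent friction. ``t_fict`` must be
    at least the physical temperature.
    """

    kappas: dict = field(default_factory=lambda: {
        "d1": 500.0, "d2": 500.0, "d6": 500.0, "chi1": 100.0})
    gamma: float = 25.0
    tau: float = 0.05
    t_fict: float = 12000.0
    t_phys: float = 300.0
    restrain_la3: bool = True
    la3_kappa: float = 500.0

    def __post_init__(self):
        if self.t_fict < self.t_phys:
            raise ConfigurationError("t_fict must be >= the physical temperature")
        if self.gamma <= 0 or self.tau <= 0:
            raise ConfigurationError("gamma and tau must be positive")
        if any(k <= 0 for k in self.kappas.values()):
            raise ConfigurationError("kappas must be positive")

    def mass(self, cv: str) -> float:
        return self.kappas[cv] * (self.tau / TWO_PI) ** 2

    def with_(self, **kw):
        return replace(self, **kw)


@dataclass(frozen=True)
class FrameRank:
    index: int
    time: float
    cv_values: dict
    distance: float

    def __post_init__(self):
        if self.distance < 0:
            raise ValueError("distance must be non-negative")


def coupling_force(theta, z, kappas, periodic=None):
    """Spring forces between physical CVs and auxiliary variables.

    Returns ``(force_on_theta, force_on_z)`` with
    force_on_z = −κ(z−θ) (wrapped for angles) and the equal-and-opposite
    generalized force on θ. Inputs are in internal units (radians).
    """
    theta = np.asarray(theta, dtype=float)
    z = np.asarray(z, dtype=float)
    kappas = np.asarray(kappas, dtype=float)
    if theta.shape != z.shape or theta.shape != kappas.shape:
        raise ValueError("theta, z and kappas must have matching lengths")
    d = z - theta
    if periodic is not None:
        p = np.asarray(periodic, dtype=bool)
        d[p] -= TWO_PI * np.round(d[p] / TWO_PI)
    f_z = -kappas * d
    return -f_z, f_z


def coupling_energy(theta, z, kappas, periodic=None):
    """½ Σ κ (z − θ)², wrapped for angles."""
    d = np.asarray(z, dtype=float) - np.asarray(theta, dtype=float)
    if periodic is not None:
        p = np.asarray(periodic, dtype=bool)
        d[p] -= TWO_PI * np.round(d[p] / TWO_PI)
    return float(0.5 * np.sum(np.asarray(kappas) * d * d))


def step_aux(z, theta, params: TAMDParams, rng, dt, v=None, cv_names=None,
             periodic=None):
    """One BAOAB step for the auxiliary variables around fixed θ.

    Returns ``(z', v')``. Angles are wrapped after each position update.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    z = np.asarray(z, dtype=float).copy()
    theta = np.asarray(theta, dtype=float)
    names = list(cv_names) if cv_names is not None else list(params.kappas)
    kap = np.array([params.kappas[n] for n in names])
    m = np.array([params.mass(n) for n in names])
    per = np.asarray(periodic, dtype=bool) if periodic is not None else \
        np.array([is_periodic(n) for n in names])
    if v is None:
        v = np.zeros_like(z)

    def force(zz):
        _, f_z = coupling_force(theta, zz, kap, per)
        return f_z

    v = v + 0.5 * dt * force(z) / m
    z = _wrap(z + 0.5 * dt * v, per)
    c1 = math.exp(-params.gamma * dt)
    c2 = np.sqrt((1.0 - c1 * c1) * KB * params.t_fict / m)
    v = c1 * v + c2 * rng.standard_normal(z.shape)
    z = _wrap(z + 0.5 * dt * v, per)
    v = v + 0.5 * dt * force(z) / m
    if not np.all(np.isfinite(z)):
        raise IntegrationError("non-finite auxiliary variable")
    return z, v


def _wrap(z, per):
    z[per] -= TWO_PI * np.floor(z[per] / TWO_PI + 0.5)
    return z


def run_tamd(model: SystemModel, params: TAMDParams, n_steps: int, seed: int,
             lp: Optional[dynamics.LangevinParams] = None,
             record_stride: int = 20, record_coords: bool = True,
             x0=None) -> dynamics.Trajectory:
    """Joint evolution of the physical system (physical T) and the hot
    auxiliary variables, with the optional static Lα3 restraint.

    The physical coordinates propagate by the overdamped
    Leimkuhler–Matthews scheme with the coupling spring forces added;
    z propagates by BAOAB at T_f. Records both θ(t) and z(t).
    """
    lp = lp or dynamics.LangevinParams()
    names = [n for n in model.cv_names if n in params.kappas]
    if not names:
        raise ConfigurationError("no coupled CV exists in the model")
    if model.meta.get("kind") != "cv_space":
        raise ConfigurationError("run_tamd drives CV-space models")
    idx = np.array([model.cv_names.index(n) for n in names])
    kap = np.array([params.kappas[n] for n in names])
    m_z = np.array([params.mass(n) for n in names])
    per = np.array([is_periodic(n) for n in names])
    la3_i = model.cv_names.index("La3") if "La3" in model.cv_names else None
    # Unlike steering springs, the coupling forces fluctuate around zero on
    # the z relaxation timescale, so no sustained antagonistic tension acts
    # on the helix analog here; the static restraint is the only Lα3 bias.

    rng = np.random.default_rng(seed)
    x = np.array(initial_condition(model, "closed", rng) if x0 is None else x0,
                 dtype=float)
    z = x[idx].copy()
    v = np.zeros_like(z)
    eg = model.meta["energy_gradient"]
    dt = lp.dt
    mob = dt / lp.friction
    sigma = math.sqrt(2.0 * KB * lp.temperature * dt / lp.friction)
    c1 = math.exp(-params.gamma * dt)
    c2 = np.sqrt((1.0 - c1 * c1) * KB * params.t_fict / m_z)
    prev = rng.standard_normal(x.shape[0])

    times, cvs, zs, biases, coords = [], [], [], [], []

    def record(i, xi, zi):
        times.append(i * dt)
        cvs.append(model.cv_values(xi))
        zrep = zi.copy()
        zrep[per] = np.degrees(zrep[per])
        zs.append(zrep)
        biases.append(coupling_energy(xi[idx], zi, kap, per))
        if record_coords:
            coords.append(xi.copy())

    record(0, x, z)
    for i in range(1, n_steps + 1):
        _, grad = eg(x)
        f = -np.asarray(grad)
        d = z - x[idx]
        d[per] -= TWO_PI * np.round(d[per] / TWO_PI)
        f_theta = kap * d          # spring force on the physical CVs
        f[idx] += f_theta
        if params.restrain_la3 and la3_i is not None:
            f[la3_i] += -params.la3_kappa * (x[la3_i] - L_FOLD)
        noise = rng.standard_normal(x.shape[0])
        x = x + mob * f + (0.5 * sigma) * (prev + noise)
        prev = noise
        x = model.wrap_state(x)
        # BAOAB for z around the updated θ
        fz = -kap * _wrapped_diff(z, x[idx], per)
        v = v + 0.5 * dt * fz / m_z
        z = _wrap(z + 0.5 * dt * v, per)
        v = c1 * v + c2 * rng.standard_normal(z.shape)
        z = _wrap(z + 0.5 * dt * v, per)
        v = v + 0.5 * dt * (-kap * _wrapped_diff(z, x[idx], per)) / m_z
        if i % record_stride == 0 or i == n_steps:
            if not (np.all(np.isfinite(x)) and np.all(np.isfinite(z))):
                raise IntegrationError(f"blow-up at step {i}", step=i)
            record(i, x, z)

    traj = dynamics.Trajectory(
        times=np.asarray(times), cv_names=list(model.cv_names),
        cvs=np.asarray(cvs), bias_energy=np.asarray(biases),
        aux=np.asarray(zs), stages=["tamd"] * len(times),
        coords=np.asarray(coords) if record_coords else None,
        meta={"seed": seed, "scheme": "tamd", "dt": dt,
              "aux_names": names, "params": params},
    )
    return traj


def _wrapped_diff(z, th, per):
    d = z - th
    d[per] -= TWO_PI * np.round(d[per] / TWO_PI)
    return d


def joint_open_visit(traj: dynamics.Trajectory, open_ref: StateReference,
                     cv_names: Sequence[str], n_sigma: float = 2.0) -> bool:
    """True when all listed CVs lie inside the open n·σ window simultaneously
    in at least one recorded frame."""
    ok = np.ones(len(traj), dtype=bool)
    for name in cv_names:
        dev = np.array([open_ref.deviation_sigmas(name, val, is_periodic(name))
                        for val in traj.series(name)])
        ok &= np.abs(dev) <= n_sigma
    return bool(ok.any())


def rank_frames(traj: dynamics.Trajectory, open_ref: StateReference,
                n: int = 10, min_separation: Optional[int] = None,
                cv_names: Optional[Sequence[str]] = None, n_sigma: float = 2.0):
    """Filter frames near the target state and rank by standardized distance.

    Frames qualify when every listed CV is within ``n_sigma``·σ of the
    open-state mean; qualifying frames are ranked by the σ-scaled Euclidean
    CV distance (wrapped angles), keeping at least ``min_separation`` frames
    between picks (default 1% of the trajectory). Ties break toward earlier
    time. Returns ``(ranked list, shortfall flag)``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if cv_names is None:
        cv_names = traj.meta.get("aux_names") or [c for c in traj.cv_names
                                                  if c != "La3"]
    if min_separation is None:
        min_separation = max(1, len(traj) // 200)
    devs = np.stack([
        [open_ref.deviation_sigmas(name, val, is_periodic(name))
         for val in traj.series(name)] for name in cv_names
    ])  # (n_cv, n_frames)
    qualify = np.all(np.abs(devs) <= n_sigma, axis=0)
    dist = np.sqrt(np.sum(devs ** 2, axis=0))
    order = sorted(np.flatnonzero(qualify), key=lambda i: (dist[i], traj.times[i]))
    picks = []
    for i in order:
        if len(picks) >= n:
            break
        if all(abs(i - j) >= min_separation for j in picks):
            picks.append(int(i))
    ranked = [FrameRank(i, float(traj.times[i]),
                        {c: float(traj.series(c)[i]) for c in traj.cv_names},
                        float(dist[i]))
              for i in picks]
    return ranked, len(ranked) < n


def relax_from_frames(model: SystemModel, traj: dynamics.Trajectory,
                      frames: Sequence[FrameRank], n_steps: int,
                      seeds: Sequence[int],
                      lp: Optional[dynamics.LangevinParams] = None,
                      open_ref: Optional[StateReference] = None,
                      record_stride: int = 20):
    """Unbiased relaxation runs started from ranked snapshots.

    Returns ``(trajectories, report)`` where the report lists, per replica,
    the per-CV density overlap with the open-state reference Gaussian and
    whether the replica's mean stayed inside the open 2σ window.
    """
    if traj.coords is None:
        raise ValueError("trajectory carries no coordinates to relax from")
    lp = lp or dynamics.LangevinParams()
    open_ref = open_ref or model.refs[1]
    cv_names = [c for c in model.cv_names if c != "La3"]
    out, report = [], []
    for frame, seed in zip(frames, seeds):
        x0 = traj.coords[frame.index]
        t = dynamics.run(model, x0, n_steps, lp.with_(seed=seed),
                         record_stride=record_stride)
        out.append(t)
        entry = {"seed": seed, "frame": frame.index, "overlap": {},
                 "stays_open": True}
        for name in cv_names:
            series = t.series(name)
            periodic = is_periodic(name)
            mean = analysis.series_stats(series, periodic).mean
            dev = open_ref.deviation_sigmas(name, mean, periodic)
            if abs(dev) > 2.0:
                entry["stays_open"] = False
            est = analysis.density(series, method="kde", periodic=periodic)
            ref = analysis.gaussian_density_on(est.grid, open_ref.mean(name),
                                               open_ref.sd(name), periodic)
            entry["overlap"][name] = analysis.density_overlap(est, ref)
        report.append(entry)
    return out, report
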