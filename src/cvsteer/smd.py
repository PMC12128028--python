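"""Steered-dynamics machinery: moving harmonic restraints on CVs driven by
four-stage schedules, replica execution and the free-stage success test.

A *schedule* divides a run into four stages measured in schedule units (the
analog of ns in the all-atom protocol):

* ``ramp_up``   — spring constants rise linearly 0 → κ_max while centres sit
  at the start-state characteristic values;
* ``steer``     — centres move linearly (shortest wrapped arc for angles)
  from start to target values at full stiffness;
* ``ramp_down`` — κ_max → 0 with centres held at the target values;
* ``free``      — no restraints; metastability of the reached state is
  judged here.

A replica is *successful* when, for every steered CV, the mean over the
final half of the free stage lies within 2σ (boundary inclusive) of the
target state's mean — wrapped for angles — and the helix-length analog, if
present, remains in its folded window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import dynamics
from .cv import wrap_angle_diff
from .errors import ConfigurationError, IntegrationError
from .model import SystemModel, initial_condition
from .references import L_FOLD, StateReference, is_periodic

__all__ = [
    "StageSchedule", "BiasTerm", "SMDRunSpec", "SuccessReport",
    "SCHEDULES", "SMD_SETS", "schedule_kappa", "schedule_center",
    "bias_energy_force", "make_run_spec", "run_smd", "classify_success",
    "build_composite_schedule",
]

STAGES = ("ramp_up", "steer", "ramp_down", "free")


@dataclass(frozen=True)
class StageSchedule:
    """Durations of the four stages, in schedule units."""

    id: str
    durations: tuple  # (ramp_up, steer, ramp_down, free)

    def __post_init__(self):
        if len(self.durations) != 4 or any(d < 0 for d in self.durations):
            raise ConfigurationError("schedule needs four non-negative durations")

    @property
    def total(self) -> float:
        return float(sum(self.durations))

    def boundaries(self):
        return tuple(np.cumsum((0.0,) + tuple(self.durations)))

    def stage_at(self, t: float) -> str:
        if not 0.0 <= t <= self.total:
            raise ValueError(f"t={t} outside schedule span [0, {self.total}]")
        b = self.boundaries()
        for name, hi in zip(STAGES, b[1:]):
            if t < hi:
                return name
        return STAGES[-1]


# Only Schedule I's stage durations are stated outright (25 units each).
# II–IV shorten ramps in favour of steering; V and VI lengthen ramp-up.
# All are config-overridable.
SCHEDULES = {
    "I": StageSchedule("I", (25, 25, 25, 25)),
    "II": StageSchedule("II", (10, 55, 10, 25)),
    "III": StageSchedule("III", (5, 65, 5, 25)),
    "IV": StageSchedule("IV", (2, 71, 2, 25)),
    "V": StageSchedule("V", (40, 25, 10, 25)),
    "VI": StageSchedule("VI", (40, 40, 10, 10)),
}


@dataclass(frozen=True)
class BiasTerm:
    """One harmonic restraint: κ in kJ/mol·nm² (distances) or kJ/mol·rad²
    (angles); values in nm or degrees. ``restrain_only`` keeps the centre at
    ``start_value`` through every stage (the helix-length restraint)."""

    cv: str
    kappa_max: float
    start_value: float
    target_value: float
    restrain_only: bool = False

    def __post_init__(self):
        if self.kappa_max < 0:
            raise ConfigurationError("kappa_max must be >= 0")
        if self.restrain_only and self.start_value != self.target_value:
            raise ConfigurationError("restrain_only requires start == target")


def schedule_kappa(schedule: StageSchedule, bias: BiasTerm, t: float) -> float:
    """Piecewise-linear spring constant at schedule time ``t`` (units)."""
    b = schedule.boundaries()
    if not 0.0 <= t <= schedule.total:
        raise ValueError(f"t={t} outside schedule span")
    ru, st, rd = schedule.durations[0], schedule.durations[1], schedule.durations[2]
    if t < b[1]:
        return bias.kappa_max * (t / ru if ru > 0 else 1.0)
    if t < b[2]:
        return bias.kappa_max
    if t < b[3]:
        return bias.kappa_max * (1.0 - (t - b[2]) / rd) if rd > 0 else 0.0
    return 0.0


def schedule_center(schedule: StageSchedule, bias: BiasTerm, t: float) -> float:
    """Moving restraint centre at schedule time ``t``.

    Angles interpolate along the shortest wrapped arc. During the free
    stage κ is zero; the centre is reported at the target value purely for
    plotting continuity.
    """
    if bias.restrain_only:
        if not 0.0 <= t <= schedule.total:
            raise ValueError(f"t={t} outside schedule span")
        return bias.start_value
    b = schedule.boundaries()
    if not 0.0 <= t <= schedule.total:
        raise ValueError(f"t={t} outside schedule span")
    if t <= b[1]:
        return bias.start_value
    if t < b[2]:
        frac = (t - b[1]) / schedule.durations[1]
        if is_periodic(bias.cv):
            arc = wrap_angle_diff(bias.target_value, bias.start_value)
            return wrap_angle_diff(bias.start_value + frac * arc, 0.0)
        return bias.start_value + frac * (bias.target_value - bias.start_value)
    return bias.target_value


def bias_energy_force(kappa: float, center: float, theta: float,
                      periodic: bool = False):
    """Harmonic restraint energy ½κΔ² and generalized force dU/dθ.

    For angles, ``center``/``theta`` are degrees but Δ enters in radians so
    κ in kJ/mol·rad² yields kJ/mol; the returned derivative is per radian.
    """
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    if periodic:
        delta = math.radians(wrap_angle_diff(theta, center))
    else:
        delta = theta - center
    return 0.5 * kappa * delta * delta, kappa * delta


# ---------------------------------------------------------------------------
# Named CV sets (the 18 steering sets of the study, ASCII keys)
# ---------------------------------------------------------------------------

_K = 500.0    # default distance spring, kJ/mol·nm²
_KA = 1000.0  # default angle spring, kJ/mol·rad²

SMD_SETS = {
    "1": {"cvs": {"d1": _K}, "schedule": "I"},
    "2": {"cvs": {"d2": _K}, "schedule": "I"},
    "12": {"cvs": {"d1": _K, "d2": _K}, "schedule": "I"},
    "12x": {"cvs": {"d1": _K, "d2": _K, "chi1": _KA}, "schedule": "I"},
    "126": {"cvs": {"d1": _K, "d2": _K, "d6": _K}, "schedule": "I"},
    "126x": {"cvs": {"d1": _K, "d2": _K, "d6": _K, "chi1": _KA}, "schedule": "I"},
    "186": {"cvs": {"d1": _K, "d8": _K, "d6": _K}, "schedule": "I"},
    "129x": {"cvs": {"d1": _K, "d2": _K, "d9": _K, "chi1": _KA}, "schedule": "I"},
    "129-10x": {"cvs": {"d1": _K, "d2": _K, "d9": _K, "d10": _K, "chi1": _KA},
                "schedule": "I"},
    "126x-F1": {"cvs": {"d1": 200.0, "d2": 100.0, "d6": 50.0, "chi1": _KA},
                "schedule": "I"},
    "126x-F2": {"cvs": {"d1": 20.0, "d2": 10.0, "d6": 5.0, "chi1": _KA},
                "schedule": "I"},
    "126x-S1": {"cvs": {"d1": _K, "d2": _K, "d6": _K, "chi1": _KA}, "schedule": "II"},
    "126x-S2": {"cvs": {"d1": _K, "d2": _K, "d6": _K, "chi1": _KA}, "schedule": "III"},
    "126x-S3": {"cvs": {"d1": _K, "d2": _K, "d6": _K, "chi1": _KA}, "schedule": "IV"},
    "6-12x": {"cvs": {"d1": _K, "d2": _K, "d6": _K, "chi1": _KA}, "schedule": "*"},
    "126a3x-a": {"cvs": {"d1": _K, "d2": _K, "d6": _K, "chi1": _KA},
                 "restrain": {"La3": _K}, "schedule": "V"},
    "126a3x-b": {"cvs": {"d1": _K, "d2": _K, "d6": _K, "chi1": _KA},
                 "restrain": {"La3": _K}, "schedule": "II"},
    "126a3x-c": {"cvs": {"d1": _K, "d2": _K, "d6": _K, "chi1": _KA},
                 "restrain": {"La3": _K}, "schedule": "VI"},
    "126a3x-d": {"cvs": {"d1": _K, "d2": _K, "d6": _K, "chi1": _KA},
                 "restrain": {"La3": _K}, "schedule": "I"},
}

DISPLAY_NAMES = {
    "12x": "12χ", "126x": "126χ", "129x": "129χ", "129-10x": "129-10χ",
    "126x-F1": "126χ-(F1)", "126x-F2": "126χ-(F2)", "126x-S1": "126χ-(S1)",
    "126x-S2": "126χ-(S2)", "126x-S3": "126χ-(S3)", "6-12x": "6-12χ",
    "126a3x-a": "126α3χ-(a)", "126a3x-b": "126α3χ-(b)",
    "126a3x-c": "126α3χ-(c)", "126a3x-d": "126α3χ-(d)",
}


@dataclass
class SMDRunSpec:
    """A named steering experiment: bias terms, schedule, direction, replicas."""

    set_name: str
    biases: Sequence[BiasTerm]
    schedule: StageSchedule
    direction: str = "closed_to_open"
    n_replicas: int = 5
    base_seed: int = 1

    def __post_init__(self):
        if self.direction not in ("closed_to_open", "open_to_closed"):
            raise ConfigurationError(f"unknown direction {self.direction!r}")
        if self.set_name in SMD_SETS:
            declared = set(SMD_SETS[self.set_name]["cvs"]) | set(
                SMD_SETS[self.set_name].get("restrain", {}))
            if {b.cv for b in self.biases} != declared:
                raise ConfigurationError(
                    f"bias CVs do not match registered set {self.set_name!r}")


@dataclass
class SuccessReport:
    set_name: str
    schedule_id: str
    direction: str
    replicas: list = field(default_factory=list)  # dicts per replica

    @property
    def n_success(self) -> int:
        return sum(1 for r in self.replicas if r["success"])

    @property
    def n_replicas(self) -> int:
        return len(self.replicas)


def make_run_spec(set_name: str, refs, direction: str = "closed_to_open",
                  n_replicas: int = 5, base_seed: int = 1,
                  schedule: Optional[StageSchedule] = None,
                  helix_restraint: Optional[bool] = None) -> SMDRunSpec:
    """Instantiate a registered steering set against a reference pair.

    ``helix_restraint`` overrides the set's registered Lα3 restraint (used
    by the helix-fragility controls).
    """
    try:
        entry = SMD_SETS[set_name]
    except KeyError:
        raise ConfigurationError(f"unknown SMD set {set_name!r}") from None
    closed, open_ = refs
    start_ref, target_ref = (closed, open_) if direction == "closed_to_open" \
        else (open_, closed)
    if schedule is None:
        sid = entry["schedule"]
        if sid == "*":
            raise ConfigurationError(
                f"set {set_name!r} uses a composite schedule; build it with "
                "build_composite_schedule and run stages explicitly")
        schedule = SCHEDULES[sid]
    biases = [
        BiasTerm(cvname, k, start_ref.mean(cvname), target_ref.mean(cvname))
        for cvname, k in entry["cvs"].items()
    ]
    restrain = dict(entry.get("restrain", {}))
    if helix_restraint is False:
        restrain.pop("La3", None)
    elif helix_restraint is True and "La3" not in restrain:
        restrain["La3"] = _K
    for cvname, k in restrain.items():
        biases.append(BiasTerm(cvname, k, L_FOLD, L_FOLD, restrain_only=True))
    return SMDRunSpec(set_name, biases, schedule, direction, n_replicas, base_seed)


def _compile_biases(model: SystemModel, biases, schedule, unit_time: float):
    """Precompile per-CV (κ, centre) lookups in toy time and model units."""
    idx_of = {n: i for i, n in enumerate(model.cv_names)}
    compiled = []
    for b in biases:
        if b.cv not in idx_of:
            raise ConfigurationError(
                f"CV {b.cv!r} is not a coordinate of this model")
        compiled.append((b, idx_of[b.cv], is_periodic(b.cv)))
    total_t = schedule.total * unit_time

    def eval_biases(t, theta_user):
        """Return (energy, list of (cv_index, periodic, dU/dθ internal))."""
        tu = min(max(t / unit_time, 0.0), schedule.total)
        energy = 0.0
        forces = []
        for b, i, per in compiled:
            kap = schedule_kappa(schedule, b, tu)
            if kap == 0.0:
                continue
            cen = schedule_center(schedule, b, tu)
            u, dU = bias_energy_force(kap, cen, theta_user[i], per)
            energy += u
            forces.append((i, dU))
        return energy, forces

    return eval_biases, total_t


def _bias_table(model: SystemModel, biases, schedule: StageSchedule,
                n_steps: int, unit_time: float) -> dynamics.HarmonicBiasTable:
    """Tabulate κ(t) and centre(t) per integrator step in internal units."""
    idx_of = {n: i for i, n in enumerate(model.cv_names)}
    t_units = np.minimum(np.arange(n_steps + 1) * (schedule.total / n_steps),
                         schedule.total)
    b = schedule.boundaries()
    idx, per, kap_cols, cen_cols = [], [], [], []
    for bias in biases:
        if bias.cv not in idx_of:
            raise ConfigurationError(f"CV {bias.cv!r} is not a coordinate of this model")
        idx.append(idx_of[bias.cv])
        periodic = is_periodic(bias.cv)
        per.append(periodic)
        kap_cols.append(np.interp(
            t_units, [0.0, b[1], b[2], b[3], b[4]],
            [0.0, bias.kappa_max, bias.kappa_max, 0.0, 0.0]))
        if bias.restrain_only:
            cen = np.full_like(t_units, bias.start_value)
        else:
            start, target = bias.start_value, bias.target_value
            if periodic:
                target = start + wrap_angle_diff(target, start)
            cen = np.interp(t_units, [0.0, b[1], b[2], b[3], b[4]],
                            [start, start, target, target, target])
        if periodic:
            cen = np.radians(cen)
        cen_cols.append(cen)
    table = dynamics.HarmonicBiasTable(
        idx=np.array(idx, dtype=int), periodic=np.array(per, dtype=bool),
        kappas=np.column_stack(kap_cols), centers=np.column_stack(cen_cols))
    strain = model.meta.get("strain")
    if strain is not None:
        names = [b.cv for b in biases]
        if (strain["cv_a"] in names and strain["cv_b"] in names
                and strain["target"] in idx_of):
            table.strain_cols = (names.index(strain["cv_a"]),
                                 names.index(strain["cv_b"]))
            table.strain_target = idx_of[strain["target"]]
            table.strain_lam = strain["coupling"]
            table.strain_cutoff = strain["cutoff"]
    return table


def run_smd(model: SystemModel, spec: SMDRunSpec,
            params: Optional[dynamics.LangevinParams] = None,
            steps_per_unit: int = 1000, record_stride: int = 20,
            record_coords: bool = False):
    """Execute a replica set of steered runs and classify each replica.

    Returns ``(trajectories, SuccessReport)``. Integration failures mark
    the replica unsuccessful but do not abort the set.
    """
    params = params or dynamics.LangevinParams()
    unit_time = steps_per_unit * params.dt
    n_steps = int(round(spec.schedule.total * steps_per_unit))
    closed, open_ = model.refs
    start_state = "closed" if spec.direction == "closed_to_open" else "open"
    target_ref = open_ if spec.direction == "closed_to_open" else closed
    steered = [b.cv for b in spec.biases if not b.restrain_only]
    extra_force = None
    table = None
    if model.meta.get("kind") == "cv_space":
        table = _bias_table(model, spec.biases, spec.schedule, n_steps, unit_time)
    else:
        eval_biases, _ = _compile_biases(model, spec.biases, spec.schedule,
                                         unit_time)
        strain = model.meta.get("strain")
        name_of = list(model.cv_names)

        def extra_force(t, x):
            theta = model.cv_values(x)
            _, forces = eval_biases(t, theta)
            out = np.zeros(model.dimension)
            if not forces:
                return out
            jac = model.cv_jacobian(np.asarray(x))
            cv_force = {}
            for i, dU in forces:
                out -= dU * jac[i]
                cv_force[name_of[i]] = -dU
            if strain is not None:
                fa = cv_force.get(strain["cv_a"], 0.0)
                fb = cv_force.get(strain["cv_b"], 0.0)
                i_t = name_of.index(strain["target"])
                if fa * fb < 0.0 and theta[i_t] < strain["cutoff"]:
                    out += strain["coupling"] * math.sqrt(-fa * fb) * jac[i_t]
            return out

    def bias_energy(t, x):
        theta = model.cv_values(x)
        return eval_biases(t, theta)[0]

    def stage_label(t):
        return spec.schedule.stage_at(min(t / unit_time, spec.schedule.total))

    trajectories = []
    report = SuccessReport(spec.set_name, spec.schedule.id, spec.direction)
    for r in range(spec.n_replicas):
        seed = spec.base_seed + r
        rp = params.with_(seed=seed)
        x0 = initial_condition(model, start_state, seed)
        try:
            traj = dynamics.run(model, x0, n_steps, rp, extra_force,
                                record_stride, record_coords,
                                bias_energy if table is None else None,
                                stage_label, bias_table=table)
        except IntegrationError as err:
            trajectories.append(err.partial)
            report.replicas.append({
                "seed": seed, "success": False, "failed": True,
                "error": str(err), "deviations": {},
            })
            continue
        traj.meta.update(set_name=spec.set_name, replica=r,
                         direction=spec.direction,
                         stage_boundaries=[b * unit_time
                                           for b in spec.schedule.boundaries()])
        trajectories.append(traj)
        verdict = classify_success(traj, target_ref, steered)
        verdict["seed"] = seed
        report.replicas.append(verdict)
    return trajectories, report


def classify_success(traj: dynamics.Trajectory, target_ref: StateReference,
                     steered_cvs: Sequence[str], n_sigma: float = 2.0) -> dict:
    """Judge one replica by the free-stage criterion.

    Success iff every steered CV's mean over the final half of the free
    stage lies within ``n_sigma``·σ of the target state's mean (boundary
    inclusive; wrapped for angles), and the helix-length analog, when
    recorded, stays in its folded window (below the folded/broken midpoint).
    """
    if traj.stages is None or "free" not in traj.stages:
        raise ValueError("trajectory has no free stage to classify")
    free = traj.stage_slice("free")
    lo = free.start + (free.stop - free.start) // 2
    window = slice(lo, free.stop)
    deviations, means = {}, {}
    ok = True
    for name in steered_cvs:
        series = traj.series(name)[window]
        if is_periodic(name):
            mean = _circular_mean(series)
        else:
            mean = float(np.mean(series))
        dev = target_ref.deviation_sigmas(name, mean, is_periodic(name))
        deviations[name] = dev
        means[name] = mean
        if abs(dev) > n_sigma:
            ok = False
    if "La3" in traj.cv_names:
        la3 = float(np.mean(traj.series("La3")[window]))
        means["La3"] = la3
        if abs(la3 - L_FOLD) >= 0.2:
            ok = False
            deviations["La3"] = (la3 - L_FOLD) / 0.05
    return {"success": ok, "deviations": deviations, "free_means": means,
            "failed": False}


def _circular_mean(deg):
    rad = np.radians(deg)
    return math.degrees(math.atan2(np.mean(np.sin(rad)), np.mean(np.cos(rad))))


# ---------------------------------------------------------------------------
# Composite (desynchronized) schedules
# ---------------------------------------------------------------------------

@dataclass
class CompositeSchedule:
    """Per-CV piecewise (κ, centre) segments covering a common span.

    Each segment is ``(t0, t1, k0, k1, c0, c1)`` in schedule units with κ
    and centre linear in t (centre along the shortest arc for angles).
    """

    id: str
    span: float
    segments: dict  # cv name -> list of segments

    def kappa(self, cvname, t):
        seg = self._find(cvname, t)
        if seg is None:
            return 0.0
        t0, t1, k0, k1, _, _ = seg
        f = 0.0 if t1 == t0 else (t - t0) / (t1 - t0)
        return k0 + f * (k1 - k0)

    def center(self, cvname, t):
        seg = self._find(cvname, t)
        if seg is None:
            return None
        t0, t1, _, _, c0, c1 = seg
        f = 0.0 if t1 == t0 else (t - t0) / (t1 - t0)
        if is_periodic(cvname):
            return wrap_angle_diff(c0 + f * wrap_angle_diff(c1, c0), 0.0)
        return c0 + f * (c1 - c0)

    def _find(self, cvname, t):
        if not 0.0 <= t <= self.span:
            raise ValueError(f"t={t} outside composite span [0, {self.span}]")
        for seg in self.segments.get(cvname, ()):
            if seg[0] <= t <= seg[1]:
                return seg
        return None


def build_composite_schedule(stage_lists: dict, span: Optional[float] = None,
                             id: str = "*") -> CompositeSchedule:
    """Compile per-CV stage lists into a :class:`CompositeSchedule`.

    ``stage_lists`` maps CV name to an ordered list of
    ``(kind, duration, kappa, start, target)`` with kind in
    {"ramp_up", "steer", "ramp_down", "hold", "free"}. Stages of one CV may
    not overlap; κ is continuous at the joints by construction and
    validated here.
    """
    segments = {}
    max_t = 0.0
    for cvname, stages in stage_lists.items():
        t = 0.0
        segs = []
        for kind, dur, kappa, start, target in stages:
            t1 = t + dur
            if kind == "ramp_up":
                segs.append((t, t1, 0.0, kappa, start, start))
            elif kind == "steer":
                segs.append((t, t1, kappa, kappa, start, target))
            elif kind == "ramp_down":
                segs.append((t, t1, kappa, 0.0, target, target))
            elif kind == "hold":
                segs.append((t, t1, kappa, kappa, start, start))
            elif kind == "free":
                segs.append((t, t1, 0.0, 0.0, target, target))
            else:
                raise ConfigurationError(f"unknown composite stage {kind!r}")
            t = t1
        for (a, b) in zip(segs, segs[1:]):
            if a[1] > b[0] + 1e-12:
                raise ConfigurationError(
                    f"overlapping stages for CV {cvname!r}")
            if abs(a[3] - b[2]) > 1e-9:
                raise ConfigurationError(
                    f"κ discontinuity at t={a[1]} for CV {cvname!r}")
        segments[cvname] = segs
        max_t = max(max_t, t)
    return CompositeSchedule(id, span if span is not None else max_t, segments)


def desynchronized_6_12x(refs) -> CompositeSchedule:
    """The quoted desynchronized protocol: open the salt bridge first, then
    hand over to the hinge/rotamer CVs while releasing d6."""
    closed, open_ = refs
    c, o = closed.mean, open_.mean
    stage_lists = {
        "d6": [("ramp_up", 25.0, _K, c("d6"), c("d6")),
               ("steer", 25.0, _K, c("d6"), o("d6")),
               ("ramp_down", 25.0, _K, o("d6"), o("d6")),
               ("free", 25.0, 0.0, o("d6"), o("d6"))],
    }
    for name, kap in (("d1", _K), ("d2", _K), ("chi1", _KA)):
        stage_lists[name] = [
            ("free", 50.0, 0.0, c(name), c(name)),
            ("ramp_up", 25.0, kap, c(name), c(name)),
            ("steer", 25.0, kap, c(name), o(name)),
        ]
    return build_composite_schedule(stage_lists, id="6-12x")
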