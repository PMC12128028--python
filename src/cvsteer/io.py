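"""Serialization: CV-series TSV, XYZ coordinates, run configuration.

Every file written here starts with comment headers recording the package
version, the seed and a hash of the active configuration, so identical
(config, seed) inputs give byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .dynamics import Trajectory
from .errors import ConfigurationError, FormatError
from .references import MODEL_CVS
from .smd import SCHEDULES, SMD_SETS

__all__ = [
    "write_cv_series", "read_cv_series", "write_xyz", "read_xyz",
    "default_config", "load_config", "dump_config", "config_hash",
]


def _header(seed=None, cfg_hash=None):
    lines = [f"# cvsteer {__version__}"]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    if cfg_hash is not None:
        lines.append(f"# config_hash: {cfg_hash}")
    return lines


def write_cv_series(traj: Trajectory, path, cfg_hash=None):
    """TSV with columns time, one per CV, z_* for auxiliary series,
    bias_energy and stage; full float precision round-trips."""
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    path = Path(path)
    cols = ["time"] + list(traj.cv_names)
    aux_names = traj.meta.get("aux_names") or []
    cols += [f"z_{n}" for n in aux_names] + ["bias_energy", "stage"]
    lines = _header(traj.meta.get("seed"), cfg_hash)
    lines.append("\t".join(cols))
    for i in range(len(traj)):
        row = [repr(float(traj.times[i]))]
        row += [repr(float(v)) for v in traj.cvs[i]]
        if aux_names:
            row += [repr(float(v)) for v in traj.aux[i]]
        row.append(repr(float(traj.bias_energy[i])) if traj.bias_energy is not None
                   else "0.0")
        row.append(traj.stages[i] if traj.stages else "run")
        lines.append("\t".join(row))
    path.write_text("\n".join(lines) + "\n")


def read_cv_series(path) -> Trajectory:
    """Inverse of :func:`write_cv_series` (CV part of the trajectory)."""
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    meta = {}
    body = []
    for ln in lines:
        if ln.startswith("#"):
            if ":" in ln:
                key, _, val = ln[1:].partition(":")
                meta[key.strip()] = val.strip()
            continue
        body.append(ln)
    if not body:
        raise FormatError(f"{path}: no data rows")
    header = body[0].split("\t")
    if header[0] != "time" or "stage" not in header:
        raise FormatError(f"{path}: unexpected header {header!r}")
    zcols = [h for h in header if h.startswith("z_")]
    cv_names = [h for h in header[1:] if not h.startswith("z_")
                and h not in ("bias_energy", "stage")]
    times, cvs, aux, bias, stages = [], [], [], [], []
    for ln in body[1:]:
        parts = ln.split("\t")
        if len(parts) != len(header):
            raise FormatError(f"{path}: row width mismatch: {ln[:40]!r}")
        rec = dict(zip(header, parts))
        times.append(float(rec["time"]))
        cvs.append([float(rec[c]) for c in cv_names])
        if zcols:
            aux.append([float(rec[c]) for c in zcols])
        bias.append(float(rec["bias_energy"]))
        stages.append(rec["stage"])
    traj = Trajectory(
        times=np.array(times), cv_names=cv_names, cvs=np.array(cvs),
        bias_energy=np.array(bias), aux=np.array(aux) if zcols else None,
        stages=stages,
        meta={"aux_names": [c[2:] for c in zcols],
              "seed": int(meta["seed"]) if "seed" in meta else None})
    return traj


def write_xyz(traj: Trajectory, path, elements=None, cfg_hash=None):
    """Standard multi-frame XYZ from recorded coordinates (nm)."""
    if traj.coords is None:
        raise ValueError("trajectory carries no coordinates")
    path = Path(path)
    coords = np.asarray(traj.coords)
    if coords.ndim == 2 and coords.shape[1] % 3 == 0:
        coords = coords.reshape(len(coords), -1, 3)
    elif coords.ndim == 2:
        # CV-space state: one pseudo-particle per coordinate on the x axis
        coords = np.stack([np.column_stack([c, np.zeros_like(c),
                                            np.zeros_like(c)])
                           for c in coords])
    n_at = coords.shape[1]
    elements = elements or ["C"] * n_at
    out = []
    for i in range(len(traj)):
        stage = traj.stages[i] if traj.stages else "run"
        out.append(str(n_at))
        out.append(f"t={traj.times[i]:.6f} stage={stage} "
                   f"seed={traj.meta.get('seed')} config={cfg_hash}")
        for e, (x, y, z) in zip(elements, coords[i]):
            out.append(f"{e} {x:.6f} {y:.6f} {z:.6f}")
    path.write_text("\n".join(out) + "\n")


def read_xyz(path):
    """Frames from an XYZ file → (list of (n,3) arrays, comments)."""
    lines = Path(path).read_text().splitlines()
    frames, comments = [], []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i])
        except ValueError:
            raise FormatError(f"bad XYZ count line {i + 1}: {lines[i]!r}") from None
        comments.append(lines[i + 1])
        block = lines[i + 2:i + 2 + n]
        if len(block) < n:
            raise FormatError(f"truncated XYZ frame at line {i + 1}")
        frames.append(np.array([[float(v) for v in ln.split()[1:4]]
                                for ln in block]))
        i += 2 + n
    return frames, comments


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

_ENGINE_DEFAULTS = {"temperature": 300.0, "friction": 1.0, "dt": 2e-4,
                    "scheme": "overdamped"}
_SMD_DEFAULTS = {"steps_per_unit": 1000, "record_stride": 20,
                 "n_replicas": 5, "base_seed": 1}
_TAMD_DEFAULTS = {"gamma": 25.0, "tau": 0.05, "t_fict": 12000.0,
                  "t_phys": 300.0, "restrain_la3": True, "la3_kappa": 500.0,
                  "n_units": 100,
                  "kappas": {"d1": 500.0, "d2": 500.0, "d6": 500.0,
                             "chi1": 100.0}}


def default_config() -> dict:
    """The full default run configuration, including the registered
    steering sets and schedules."""
    from .model import GatedModelParams
    import dataclasses
    return {
        "model": dataclasses.asdict(GatedModelParams()),
        "engine": dict(_ENGINE_DEFAULTS),
        "smd": {**_SMD_DEFAULTS,
                "sets": {k: {"cvs": dict(v["cvs"]),
                             **({"restrain": dict(v["restrain"])}
                                if "restrain" in v else {}),
                             "schedule": v["schedule"]}
                         for k, v in SMD_SETS.items()},
                "schedules": {k: list(v.durations) for k, v in SCHEDULES.items()}},
        "tamd": {**_TAMD_DEFAULTS},
    }


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:12]


def _merge_validate(base, override, path=""):
    out = dict(base)
    for key, val in (override or {}).items():
        if key not in base and path in ("model", "engine", "smd", "tamd", ""):
            if path == "" and key in ("model", "engine", "smd", "tamd"):
                pass
            else:
                raise ConfigurationError(f"unknown config key {path + '.' + key!r}")
        if isinstance(val, dict) and isinstance(base.get(key), dict) \
                and key not in ("sets", "schedules", "kappas", "cvs", "restrain"):
            out[key] = _merge_validate(base[key], val, f"{path}.{key}" if path else key)
        else:
            out[key] = val
    return out


def load_config(path=None) -> dict:
    """Load, merge with defaults and validate a YAML run configuration.

    Unknown keys are rejected; spring constants must be non-negative;
    schedule CV names must exist in the model CV registry.
    """
    cfg = default_config()
    if path is not None:
        try:
            user = yaml.safe_load(Path(path).read_text()) or {}
        except yaml.YAMLError as err:
            raise FormatError(f"{path}: invalid YAML ({err})") from None
        if not isinstance(user, dict):
            raise ConfigurationError(f"{path}: top level must be a mapping")
        for key in user:
            if key not in cfg:
                raise ConfigurationError(f"unknown config section {key!r}")
        cfg = _merge_validate(cfg, user)
    _validate(cfg)
    return cfg


def _validate(cfg):
    from .references import ATOM_REGISTRY
    known_cvs = set(ATOM_REGISTRY) | {"chi1", "La3"}
    for name, entry in cfg["smd"]["sets"].items():
        for cvname, kappa in {**entry.get("cvs", {}),
                              **entry.get("restrain", {})}.items():
            if cvname not in known_cvs:
                raise ConfigurationError(
                    f"set {name!r}: unknown CV {cvname!r}")
            if kappa < 0:
                raise ConfigurationError(
                    f"set {name!r}: negative spring constant for {cvname!r}")
    for sid, durs in cfg["smd"]["schedules"].items():
        if len(durs) != 4 or any(d < 0 for d in durs):
            raise ConfigurationError(f"schedule {sid!r}: need 4 non-negative durations")
    for cvname, kappa in cfg["tamd"]["kappas"].items():
        if cvname not in MODEL_CVS:
            raise ConfigurationError(f"tamd: unknown CV {cvname!r}")
        if kappa <= 0:
            raise ConfigurationError(f"tamd: kappa must be positive for {cvname!r}")
    if cfg["engine"]["dt"] <= 0:
        raise ConfigurationError("engine.dt must be positive")
    if cfg["engine"]["scheme"] not in ("overdamped", "baoab"):
        raise ConfigurationError(f"unknown engine scheme {cfg['engine']['scheme']!r}")


def dump_config(cfg: dict, path):
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=True))
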