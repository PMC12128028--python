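"""Trajectory statistics and reporting.

Per-CV summaries (mean ± SD tables), centred rolling means for plotting,
probability-density estimates (histogram or Gaussian KDE, with wrapped
estimation for angles), density-overlap coefficients, and tabular summaries
of steering outcomes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cv import wrap_angle
from .references import ATOM_REGISTRY, is_periodic

__all__ = [
    "SeriesStats", "DensityEstimate", "rolling_mean", "series_stats",
    "density", "gaussian_density_on", "density_overlap", "count_modes",
    "state_table", "success_summary",
]


@dataclass(frozen=True)
class SeriesStats:
    mean: float
    sd: float
    n: int
    circular: bool = False

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


@dataclass
class DensityEstimate:
    """Normalized 1-D density on a grid (trapezoidal integral 1)."""

    grid: np.ndarray
    values: np.ndarray
    method: str
    bandwidth: float = None
    bins: int = None
    periodic: bool = False
    degenerate: bool = False
    name: str = ""

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("density values must be non-negative")

    @property
    def integral(self) -> float:
        return float(np.trapezoid(self.values, self.grid))


def rolling_mean(series, window: int = 51, periodic: bool = False) -> np.ndarray:
    """Centred moving average with a symmetrically shrinking edge window.

    ``window`` must be odd. Output length equals input length. Periodic
    series average on the circle (vector mean of angles in degrees).
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    x = np.asarray(series, dtype=float)
    if window == 1:
        return x.copy()
    half = window // 2
    if periodic:
        rad = np.radians(x)
        cs, sn = np.cos(rad), np.sin(rad)
        c = rolling_mean(cs, window)
        s = rolling_mean(sn, window)
        return wrap_angle(np.degrees(np.arctan2(s, c)))
    out = np.empty_like(x)
    csum = np.concatenate([[0.0], np.cumsum(x)])
    n = len(x)
    for i in range(n):
        h = min(half, i, n - 1 - i)
        out[i] = (csum[i + h + 1] - csum[i - h]) / (2 * h + 1)
    return out


def series_stats(series, periodic: bool = False) -> SeriesStats:
    """Arithmetic mean/SD, or circular mean and circular SD (degrees)."""
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("empty series")
    if not periodic:
        return SeriesStats(float(np.mean(x)), float(np.std(x)), x.size, False)
    rad = np.radians(x)
    c, s = np.mean(np.cos(rad)), np.mean(np.sin(rad))
    mean = wrap_angle(math.degrees(math.atan2(s, c)))
    r = min(1.0, math.hypot(c, s))
    csd = math.degrees(math.sqrt(max(0.0, -2.0 * math.log(r)))) if r > 0 else 180.0
    return SeriesStats(mean, csd, x.size, True)


def _fd_bins(x):
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    if iqr <= 0:
        return 10
    width = 2 * iqr / len(x) ** (1 / 3)
    return max(1, int(np.ceil((x.max() - x.min()) / width)))


def density(series, method: str = "kde", bins=None, bandwidth=None,
            periodic: bool = False, grid_size: int = 512,
            name: str = "") -> DensityEstimate:
    """Normalized probability density of a scalar series.

    Histogram bins default to the Freedman–Diaconis rule; the KDE is
    Gaussian with Silverman bandwidth. Periodic series are estimated on the
    wrapped circle (−180, 180] by replicating the sample ±360°.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 10:
        raise ValueError("need at least 10 points for a density estimate")
    if np.std(x) == 0:
        grid = np.linspace(x[0] - 0.5, x[0] + 0.5, grid_size)
        vals = np.zeros(grid_size)
        vals[np.argmin(np.abs(grid - x[0]))] = 1.0
        vals /= np.trapezoid(vals, grid)
        return DensityEstimate(grid, vals, method, periodic=periodic,
                               degenerate=True, name=name)
    if periodic:
        x = wrap_angle(x)
        grid = np.linspace(-180.0, 180.0, grid_size)
        if method == "kde":
            sd = min(np.std(x), stats.circstd(np.radians(x)) * 180 / math.pi)
            bw = bandwidth or 1.06 * sd * x.size ** (-1 / 5)
            tiled = np.concatenate([x - 360.0, x, x + 360.0])
            kde = stats.gaussian_kde(tiled, bw_method=bw / np.std(tiled))
            vals = kde(grid) * 3.0
        else:
            nb = bins or _fd_bins(x)
            hist, edges = np.histogram(x, bins=nb, range=(-180.0, 180.0),
                                       density=True)
            grid = 0.5 * (edges[:-1] + edges[1:])
            vals = hist
    else:
        if method == "kde":
            kde = stats.gaussian_kde(
                x, bw_method=None if bandwidth is None else bandwidth / np.std(x))
            pad = 3 * np.std(x)
            grid = np.linspace(x.min() - pad, x.max() + pad, grid_size)
            vals = kde(grid)
        elif method == "histogram":
            nb = bins or _fd_bins(x)
            hist, edges = np.histogram(x, bins=nb, density=True)
            grid = 0.5 * (edges[:-1] + edges[1:])
            vals = hist
        else:
            raise ValueError(f"unknown density method {method!r}")
    est = DensityEstimate(grid, vals, method, bandwidth=bandwidth, bins=bins,
                          periodic=periodic, name=name)
    est.values = est.values / est.integral
    return est


def gaussian_density_on(grid, mean: float, sd: float,
                        periodic: bool = False) -> DensityEstimate:
    """Reference Gaussian (wrapped if periodic) evaluated on a given grid."""
    grid = np.asarray(grid, dtype=float)
    if periodic:
        vals = np.zeros_like(grid)
        for k in (-360.0, 0.0, 360.0):
            vals += stats.norm.pdf(grid, loc=mean + k, scale=sd)
    else:
        vals = stats.norm.pdf(grid, loc=mean, scale=sd)
    est = DensityEstimate(grid, vals, "analytic", periodic=periodic)
    est.values = est.values / est.integral
    return est


def density_overlap(a: DensityEstimate, b: DensityEstimate) -> float:
    """Overlap coefficient ∫ min(a, b) on the union support (symmetric)."""
    if a.name and b.name and a.name != b.name:
        raise ValueError(f"incompatible CV names {a.name!r} vs {b.name!r}")
    lo = min(a.grid.min(), b.grid.min())
    hi = max(a.grid.max(), b.grid.max())
    grid = np.linspace(lo, hi, 1024)
    av = np.interp(grid, a.grid, a.values, left=0.0, right=0.0)
    bv = np.interp(grid, b.grid, b.values, left=0.0, right=0.0)
    return float(np.clip(np.trapezoid(np.minimum(av, bv), grid), 0.0, 1.0))


def count_modes(est: DensityEstimate, rel_height: float = 0.1) -> int:
    """Local maxima above ``rel_height``·max — a descriptive multimodality
    measure (the closed-state distance distributions are multimodal)."""
    v = est.values
    peaks = [i for i in range(1, len(v) - 1)
             if v[i] >= v[i - 1] and v[i] > v[i + 1] and v[i] >= rel_height * v.max()]
    return max(1, len(peaks))


def state_table(state_trajs: dict, cv_names=None) -> pd.DataFrame:
    """Per-CV mean ± SD per state from equilibrium trajectory sets.

    ``state_trajs`` maps state label → list of trajectories. Missing CVs
    are reported as NA. Returns a tidy frame with one row per CV.
    """
    if not state_trajs or any(len(v) == 0 for v in state_trajs.values()):
        raise ValueError("need at least one trajectory per state")
    if cv_names is None:
        cv_names = []
        for trajs in state_trajs.values():
            for t in trajs:
                for c in t.cv_names:
                    if c not in cv_names:
                        cv_names.append(c)
    rows = []
    for cv in cv_names:
        atoms = ATOM_REGISTRY.get(cv)
        row = {
            "cv": cv,
            "atom1": f"{atoms[0][0]}{atoms[0][1]}" if atoms else "",
            "atom2": f"{atoms[1][0]}{atoms[1][1]}" if atoms else "",
        }
        for state, trajs in state_trajs.items():
            samples = [t.series(cv) for t in trajs if cv in t.cv_names]
            if not samples:
                row[f"{state}_mean"] = np.nan
                row[f"{state}_sd"] = np.nan
                continue
            st = series_stats(np.concatenate(samples), is_periodic(cv))
            row[f"{state}_mean"] = round(st.mean, 4)
            row[f"{state}_sd"] = round(st.sd, 4)
        rows.append(row)
    return pd.DataFrame(rows)


def success_summary(reports) -> pd.DataFrame:
    """One row per steering set: name, CV:κ list, schedule, success count."""
    if not reports:
        raise ValueError("no reports to summarise")
    from .smd import DISPLAY_NAMES, SMD_SETS
    rows = []
    for rep in reports:
        entry = SMD_SETS.get(rep.set_name, {})
        cvk = " ".join(f"{cv}:{int(k)}" for cv, k in entry.get("cvs", {}).items())
        cvk += "".join(f" {cv}:{int(k)}(restrain)"
                       for cv, k in entry.get("restrain", {}).items())
        rows.append({
            "set": DISPLAY_NAMES.get(rep.set_name, rep.set_name),
            "cv_kappa": cvk.strip(),
            "schedule": rep.schedule_id,
            "direction": rep.direction,
            "result": rep.n_success,
            "n_replicas": rep.n_replicas,
        })
    return pd.DataFrame(rows)
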