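"""Collective-variable geometry: definitions, values, Cartesian gradients.

Three CV kinds are supported, the ones a hinge-bending transition needs:

* ``pair_distance`` — Euclidean distance between two atoms (nm),
* ``com_distance`` — distance between mass-weighted centroids of two
  disjoint atom groups (nm), e.g. the end-to-end length of a helix,
* ``dihedral`` — signed proper torsion over four atoms (degrees), e.g. the
  χ1 rotamer angle of a side chain.

Angles follow the IUPAC sign convention (positive = clockwise looking down
the central bond) and are reported in degrees in (−180, 180]; internally,
gradients of dihedrals are in radians per nm so that harmonic spring
constants in kJ/mol·rad² act consistently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import DegenerateGeometryError

__all__ = [
    "CVSpec",
    "CVVector",
    "eval_pair_distance",
    "eval_com_distance",
    "eval_dihedral",
    "eval_cv",
    "cv_gradient",
    "wrap_angle",
    "wrap_angle_diff",
    "cv_space_distance",
]

CV_KINDS = ("pair_distance", "com_distance", "dihedral")

#: cross products with squared norm below this (nm^4) make a dihedral undefined
DEGENERATE_CROSS_SQ = (1e-10) ** 2


@dataclass(frozen=True)
class CVSpec:
    """Definition of one collective variable.

    Parameters
    ----------
    name : str
        Label, e.g. ``"d6"`` or ``"chi1"``.
    kind : {"pair_distance", "com_distance", "dihedral"}
    groups : tuple of tuple of int
        Ordered particle-index groups: two singletons for ``pair_distance``,
        two non-empty disjoint groups for ``com_distance``, four singletons
        for ``dihedral``.
    report_unit : str
        ``"nm"`` for distances, ``"degrees"`` for dihedrals.
    """

    name: str
    kind: str
    groups: tuple = ()
    report_unit: str = ""

    def __post_init__(self):
        groups = tuple(tuple(int(i) for i in g) for g in self.groups)
        object.__setattr__(self, "groups", groups)
        if self.kind not in CV_KINDS:
            raise ValueError(f"unknown CV kind {self.kind!r}")
        if self.kind == "pair_distance":
            if len(groups) != 2 or any(len(g) != 1 for g in groups):
                raise ValueError("pair_distance needs two singleton groups")
        elif self.kind == "dihedral":
            idx = [g[0] for g in groups]
            if len(groups) != 4 or any(len(g) != 1 for g in groups):
                raise ValueError("dihedral needs four singleton groups")
            if len(set(idx)) != 4:
                raise ValueError("dihedral indices must be distinct")
        else:
            if len(groups) != 2 or any(len(g) == 0 for g in groups):
                raise ValueError("com_distance needs two non-empty groups")
            if set(groups[0]) & set(groups[1]):
                raise ValueError("com_distance groups must be disjoint")
        if not self.report_unit:
            unit = "degrees" if self.kind == "dihedral" else "nm"
            object.__setattr__(self, "report_unit", unit)

    @property
    def periodic(self) -> bool:
        """True iff the CV is an angle living on the circle."""
        return self.kind == "dihedral"

    @property
    def indices(self) -> tuple:
        """All particle indices referenced by this CV (flattened)."""
        return tuple(i for g in self.groups for i in g)


@dataclass
class CVVector:
    """An ordered CV list together with evaluated values.

    Distances in nm; dihedrals in degrees, wrapped to (−180, 180].
    """

    specs: Sequence[CVSpec]
    values: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(self.specs) != self.values.shape[-1]:
            raise ValueError("specs and values length mismatch")
        for spec, v in zip(self.specs, self.values):
            if spec.periodic and not (-180.0 < v <= 180.0 + 1e-9):
                raise ValueError(f"dihedral {spec.name} out of (-180, 180]: {v}")

    @property
    def names(self):
        return [s.name for s in self.specs]

    def __getitem__(self, name):
        return float(self.values[self.names.index(name)])


def eval_pair_distance(coords: np.ndarray, i: int, j: int) -> float:
    """Euclidean distance (nm) between particles ``i`` and ``j``."""
    if i == j:
        raise ValueError("pair distance needs two distinct indices")
    coords = np.asarray(coords, dtype=float)
    return float(np.linalg.norm(coords[i] - coords[j]))


def eval_com_distance(coords, group_a, group_b, masses=None) -> float:
    """Distance (nm) between the mass-weighted centroids of two groups.

    ``masses`` defaults to unit masses (geometric centroid), the convention
    for bead models; real structures pass per-atom masses.
    """
    coords = np.asarray(coords, dtype=float)
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("com_distance groups must be non-empty")
    if masses is None:
        masses = np.ones(len(coords))
    masses = np.asarray(masses, dtype=float)
    if np.any(masses < 0):
        raise ValueError("masses must be non-negative")
    ca = _com(coords, masses, list(group_a))
    cb = _com(coords, masses, list(group_b))
    return float(np.linalg.norm(ca - cb))


def _com(coords, masses, idx):
    m = masses[idx]
    total = m.sum()
    if total <= 0:
        raise ValueError("zero total mass in COM group")
    return (coords[idx] * m[:, None]).sum(axis=0) / total


def eval_dihedral(coords, i, j, k, l) -> float:
    """Signed proper dihedral i–j–k–l in degrees, in (−180, 180].

    Positive angles are clockwise when sighting from ``j`` to ``k``
    (IUPAC convention). Raises :class:`DegenerateGeometryError` when either
    bonded plane is undefined (collinear atoms).
    """
    coords = np.asarray(coords, dtype=float)
    if len({i, j, k, l}) != 4:
        raise ValueError("dihedral needs four distinct indices")
    b1 = coords[j] - coords[i]
    b2 = coords[k] - coords[j]
    b3 = coords[l] - coords[k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if n1 @ n1 < DEGENERATE_CROSS_SQ or n2 @ n2 < DEGENERATE_CROSS_SQ:
        raise DegenerateGeometryError("collinear atoms: dihedral undefined")
    phi = np.arctan2(np.cross(n1, n2) @ b2 / np.linalg.norm(b2), n1 @ n2)
    return wrap_angle(np.degrees(phi))


def eval_cv(spec: CVSpec, coords, masses=None) -> float:
    """Evaluate one CV on a coordinate array (N, 3) in nm."""
    g = spec.groups
    if spec.kind == "pair_distance":
        return eval_pair_distance(coords, g[0][0], g[1][0])
    if spec.kind == "com_distance":
        return eval_com_distance(coords, g[0], g[1], masses)
    return eval_dihedral(coords, g[0][0], g[1][0], g[2][0], g[3][0])


def evaluate(specs, coords, masses=None) -> CVVector:
    """Evaluate a CV list into a :class:`CVVector`."""
    return CVVector(list(specs), [eval_cv(s, coords, masses) for s in specs])


def cv_gradient(spec: CVSpec, coords, masses=None) -> np.ndarray:
    """Gradient of the CV value w.r.t. every Cartesian coordinate.

    Returns an (N, 3) array; rows of particles outside the CV's groups are
    zero. Distances differentiate in nm/nm; dihedrals in *radians* per nm so
    that angular spring constants (kJ/mol·rad²) project to Cartesian forces
    without unit juggling.
    """
    coords = np.asarray(coords, dtype=float)
    grad = np.zeros_like(coords)
    g = spec.groups
    if spec.kind == "pair_distance":
        i, j = g[0][0], g[1][0]
        d = coords[i] - coords[j]
        r = np.linalg.norm(d)
        if r < 1e-12:
            raise DegenerateGeometryError("coincident atoms: distance gradient undefined")
        u = d / r
        grad[i] = u
        grad[j] = -u
    elif spec.kind == "com_distance":
        if masses is None:
            masses = np.ones(len(coords))
        masses = np.asarray(masses, dtype=float)
        ca = _com(coords, masses, list(g[0]))
        cb = _com(coords, masses, list(g[1]))
        d = ca - cb
        r = np.linalg.norm(d)
        if r < 1e-12:
            raise DegenerateGeometryError("coincident centroids: gradient undefined")
        u = d / r
        for sign, group in ((1.0, g[0]), (-1.0, g[1])):
            total = masses[list(group)].sum()
            for i in group:
                grad[i] = sign * (masses[i] / total) * u
    else:
        i, j, k, l = (grp[0] for grp in g)
        b1 = coords[j] - coords[i]
        b2 = coords[k] - coords[j]
        b3 = coords[l] - coords[k]
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        n1_sq = n1 @ n1
        n2_sq = n2 @ n2
        if n1_sq < DEGENERATE_CROSS_SQ or n2_sq < DEGENERATE_CROSS_SQ:
            raise DegenerateGeometryError("collinear atoms: dihedral gradient undefined")
        b2_len = np.linalg.norm(b2)
        f_i = -(b2_len / n1_sq) * n1
        f_l = (b2_len / n2_sq) * n2
        p = (b1 @ b2) / (b2_len * b2_len)
        q = (b3 @ b2) / (b2_len * b2_len)
        grad[i] = f_i
        grad[l] = f_l
        grad[j] = -(1.0 + p) * f_i + q * f_l
        grad[k] = p * f_i - (1.0 + q) * f_l
    return grad


def wrap_angle(a):
    """Wrap an angle in degrees to (−180, 180]."""
    w = -np.remainder(-np.asarray(a, dtype=float) + 180.0, 360.0) + 180.0
    return float(w) if np.ndim(a) == 0 else w


def wrap_angle_diff(a, b):
    """Minimal signed difference a ⊖ b in degrees, in (−180, 180]."""
    return wrap_angle(np.asarray(a, dtype=float) - np.asarray(b, dtype=float))


def cv_space_distance(v1: CVVector, v2: CVVector, scales) -> float:
    """Scaled Euclidean distance between two CV vectors.

    sqrt(Σ_i (Δ_i / scale_i)²), with periodic CVs differenced on the circle.
    Used to rank trajectory frames by proximity to a reference state.
    """
    if [s.name for s in v1.specs] != [s.name for s in v2.specs] or any(
        s1.kind != s2.kind for s1, s2 in zip(v1.specs, v2.specs)
    ):
        raise ValueError("CV vectors must share an identical spec list")
    scales = np.asarray(scales, dtype=float)
    if scales.shape != v1.values.shape or np.any(scales <= 0):
        raise ValueError("scales must be positive, one per CV")
    total = 0.0
    for spec, a, b, s in zip(v1.specs, v1.values, v2.values, scales):
        delta = wrap_angle_diff(a, b) if spec.periodic else a - b
        total += (delta / s) ** 2
    return float(np.sqrt(total))
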