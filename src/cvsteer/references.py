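"""Reference statistics and atom definitions for the T4 lysozyme CV set.

The hinge-bending transition of T4 lysozyme is described by ten interatomic
distances (d1–d10), the Phe4 χ1 side-chain torsion, and the α3-helix
end-to-end length Lα3. Each conformational state (closed / open) is
characterised by a per-CV mean and standard deviation estimated from
equilibrium sampling, plus the value observed in the corresponding crystal
structure (closed: PDB 2LZM; open: PDB 150L).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cv import wrap_angle_diff
from .errors import ConfigurationError

__all__ = [
    "CVStat",
    "StateReference",
    "ATOM_REGISTRY",
    "CLOSED_STATE",
    "OPEN_STATE",
    "XTAL_CLOSED",
    "XTAL_OPEN",
    "PERIODIC_CVS",
    "MODEL_CVS",
    "CHI1_QUADRUPLE",
    "ALPHA3_RANGE",
    "L_FOLD",
]


@dataclass(frozen=True)
class CVStat:
    name: str
    mean: float
    sd: float

    def __post_init__(self):
        if self.sd <= 0:
            raise ValueError(f"sd must be positive for {self.name}")


@dataclass
class StateReference:
    """Per-CV mean ± SD of one named conformational state."""

    state: str
    stats: dict = field(default_factory=dict)

    def __post_init__(self):
        for name, st in self.stats.items():
            if not isinstance(st, CVStat):
                self.stats[name] = CVStat(name, *st)

    def mean(self, name: str) -> float:
        return self._get(name).mean

    def sd(self, name: str) -> float:
        return self._get(name).sd

    def _get(self, name: str) -> CVStat:
        try:
            return self.stats[name]
        except KeyError:
            raise ConfigurationError(
                f"CV {name!r} has no reference entry in state {self.state!r}"
            ) from None

    def names(self):
        return list(self.stats)

    def deviation_sigmas(self, name: str, value: float, periodic: bool = False) -> float:
        """Signed deviation of ``value`` from this state's mean, in SD units."""
        st = self._get(name)
        delta = wrap_angle_diff(value, st.mean) if periodic else value - st.mean
        return float(delta / st.sd)

    def within(self, name: str, value: float, n_sigma: float = 2.0,
               periodic: bool = False) -> bool:
        """Boundary-inclusive n-sigma window test around this state's mean."""
        return abs(self.deviation_sigmas(name, value, periodic)) <= n_sigma


# Atom pairs defining each distance CV: (residue number, atom name) twice.
# chi1 is defined on the standard N–CA–CB–CG quadruple of Phe4; Lα3 is the
# distance between the centres of mass of the four N- and four C-terminal
# residues of the α3 helix (residue range configurable, default 60–80).
ATOM_REGISTRY = {
    "d1": ((22, "CA"), (141, "CA")),
    "d2": ((5, "CA"), (59, "CA")),
    "d3": ((35, "CA"), (109, "CA")),
    "d4": ((35, "CA"), (137, "CA")),
    "d5": ((45, "CA"), (109, "CA")),
    "d6": ((8, "CZ"), (64, "CD")),
    "d7": ((4, "CA"), (60, "CA")),
    "d8": ((4, "CZ"), (63, "CA")),
    "d9": ((8, "CZ"), (9, "CB")),
    "d10": ((64, "CD"), (65, "NZ")),
}

CHI1_QUADRUPLE = ((4, "N"), (4, "CA"), (4, "CB"), (4, "CG"))
ALPHA3_RANGE = (60, 80)  # author numbering; 4 residues from each end enter Lα3

PERIODIC_CVS = frozenset({"chi1"})

#: CVs that are degrees of freedom of the synthetic gated model
MODEL_CVS = ("d1", "d2", "d6", "chi1", "La3")

#: folded α3 end-to-end length (nm); also the restraint target during steering
L_FOLD = 2.05

# Equilibrium-sampling means ± SDs per state (distances nm, angles degrees).
_CLOSED = {
    "d1": (0.93, 0.23), "d2": (1.91, 0.11), "d3": (1.51, 0.19),
    "d4": (1.81, 0.16), "d5": (2.18, 0.17), "d6": (0.41, 0.06),
    "d7": (1.52, 0.10), "d8": (1.36, 0.17), "d9": (0.96, 0.09),
    "d10": (1.01, 0.13), "chi1": (66.40, 27.20), "La3": (L_FOLD, 0.05),
}
_OPEN = {
    "d1": (1.92, 0.29), "d2": (1.46, 0.08), "d3": (2.00, 0.22),
    "d4": (2.67, 0.24), "d5": (2.74, 0.19), "d6": (1.04, 0.18),
    "d7": (1.00, 0.06), "d8": (0.48, 0.05), "d9": (0.71, 0.15),
    "d10": (0.71, 0.22), "chi1": (176.10, 8.60), "La3": (L_FOLD, 0.05),
}

CLOSED_STATE = StateReference("closed", {k: CVStat(k, *v) for k, v in _CLOSED.items()})
OPEN_STATE = StateReference("open", {k: CVStat(k, *v) for k, v in _OPEN.items()})

# Crystal-structure CV values (closed: 2LZM; open: 150L).
XTAL_CLOSED = {
    "d1": 0.90, "d2": 1.87, "d3": 1.61, "d4": 1.82, "d5": 2.20,
    "d6": 1.02, "d7": 1.45, "d8": 1.22, "d9": 0.79, "d10": 0.96,
    "chi1": 65.67,
}
XTAL_OPEN = {
    "d1": 1.73, "d2": 1.48, "d3": 1.93, "d4": 2.66, "d5": 2.59,
    "d6": 1.08, "d7": 1.04, "d8": 0.49, "d9": 0.85, "d10": 0.72,
    "chi1": 175.80,
}


def state_pair():
    """The default (closed, open) reference pair."""
    return CLOSED_STATE, OPEN_STATE


def is_periodic(name: str) -> bool:
    return name in PERIODIC_CVS


def sigma_vector(ref: StateReference, names) -> np.ndarray:
    return np.array([ref.sd(n) for n in names], dtype=float)


def mean_vector(ref: StateReference, names) -> np.ndarray:
    return np.array([ref.mean(n) for n in names], dtype=float)
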