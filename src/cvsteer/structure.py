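"""PDB structure reading and CV evaluation on crystal structures.

Reads model 1 of a PDB file (via biotite), resolves altlocs by highest
occupancy, and evaluates the full CV registry — ten interatomic distances,
the Phe4 χ1 torsion (N–CA–CB–CG) and the α3 end-to-end length Lα3 — in nm
and degrees. Residues are addressed by author numbering (resSeq).
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import biotite.structure as struc
import biotite.structure.io.pdb as pdb

from . import cv as cvg
from .errors import FormatError
from .references import ALPHA3_RANGE, ATOM_REGISTRY, CHI1_QUADRUPLE

__all__ = ["AtomRecord", "Structure", "read_pdb", "compute_reference_cvs"]

ANGSTROM_TO_NM = 0.1

#: standard atomic masses (u) for COM weighting, by element
MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
          "P": 30.974}


def element_of(atom_name: str) -> str:
    name = atom_name.strip().lstrip("0123456789")
    if name[:2].upper() in ("SE",):
        return "S"
    return name[0].upper()


@dataclass(frozen=True)
class AtomRecord:
    serial: int
    name: str
    res_name: str
    res_seq: int
    chain_id: str
    element: str
    coords: tuple  # Å
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self):
        if not self.name:
            raise ValueError("atom name must be non-empty")
        if not all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")


@dataclass
class Structure:
    atoms: list
    model_id: int = 1
    source: str = ""
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        for a in self.atoms:
            self._index.setdefault((a.chain_id, a.res_seq, a.name), a)

    def atom(self, res_seq: int, name: str, chain_id=None):
        """Look up one atom by residue number and atom name (first chain
        containing it when ``chain_id`` is None)."""
        if chain_id is not None:
            return self._index.get((chain_id, res_seq, name))
        for a in self.atoms:
            if a.res_seq == res_seq and a.name == name:
                return a
        return None

    def chains(self):
        seen = []
        for a in self.atoms:
            if a.chain_id not in seen:
                seen.append(a.chain_id)
        return seen

    def select_chain(self, chain_id: str) -> "Structure":
        return Structure([a for a in self.atoms if a.chain_id == chain_id],
                         self.model_id, self.source)

    def residue_atoms(self, res_seq: int):
        return [a for a in self.atoms if a.res_seq == res_seq]

    def __len__(self):
        return len(self.atoms)


def read_pdb(path) -> Structure:
    """Parse model 1 of a PDB file into a :class:`Structure`.

    Altloc groups are resolved to the highest-occupancy conformer (label
    'A' wins ties, matching biotite's first-encountered rule for standard
    files). Raises :class:`FormatError` on malformed input.
    """
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as err:
        raise FormatError(f"cannot read {path}: {err}") from None
    return _parse_pdb_text(text, source=path.name)


def _parse_pdb_text(text: str, source: str = "") -> Structure:
    try:
        pf = pdb.PDBFile.read(_io.StringIO(text))
        n_models = pf.get_model_count()
        if n_models < 1:
            raise FormatError(f"{source}: no coordinate model found")
        arr = pf.get_structure(model=1, altloc="occupancy",
                               extra_fields=["occupancy", "atom_id"])
    except FormatError:
        raise
    except Exception as err:
        raise FormatError(f"{source}: malformed PDB ({err})") from None
    arr = arr[~arr.hetero]
    if arr.array_length() == 0:
        raise FormatError(f"{source}: model 1 contains no ATOM records")
    atoms = []
    for i in range(arr.array_length()):
        name = str(arr.atom_name[i])
        elem = str(arr.element[i]) or element_of(name)
        atoms.append(AtomRecord(
            serial=int(arr.atom_id[i]), name=name,
            res_name=str(arr.res_name[i]), res_seq=int(arr.res_id[i]),
            chain_id=str(arr.chain_id[i]), element=elem,
            coords=tuple(float(c) for c in arr.coord[i]),
            occupancy=float(arr.occupancy[i]),
        ))
    return Structure(atoms, model_id=1, source=source)


def _pick_chain(structure: Structure, chain=None) -> Structure:
    """Default chain rule: the first chain whose residue 4 is PHE."""
    if chain is not None:
        sub = structure.select_chain(chain)
        if len(sub) == 0:
            raise FormatError(f"chain {chain!r} not present")
        return sub
    for cid in structure.chains():
        sub = structure.select_chain(cid)
        a = sub.atom(4, "CA", cid)
        if a is not None and a.res_name == "PHE":
            return sub
    return structure


def compute_reference_cvs(structure: Structure, chain=None,
                          alpha3_range=ALPHA3_RANGE) -> pd.DataFrame:
    """Evaluate the 11 registry CVs plus Lα3 on a structure.

    Returns a frame with columns (cv, atoms, value, unit, note); rows whose
    atoms are missing get a NA value and an explanatory note while the
    remaining rows are still computed. Distances are nm, angles degrees,
    both reported at full precision (print at 2 d.p. for table comparison).
    """
    sub = _pick_chain(structure, chain)
    rows = []

    def coord_nm(res_seq, name):
        a = sub.atom(res_seq, name)
        return None if a is None else np.array(a.coords) * ANGSTROM_TO_NM

    for cvname, ((r1, a1), (r2, a2)) in ATOM_REGISTRY.items():
        p1, p2 = coord_nm(r1, a1), coord_nm(r2, a2)
        if p1 is None or p2 is None:
            missing = f"{r1}{a1}" if p1 is None else f"{r2}{a2}"
            rows.append((cvname, f"{r1}{a1}-{r2}{a2}", np.nan, "nm",
                         f"missing atom {missing}"))
            continue
        value = float(np.linalg.norm(p1 - p2))
        rows.append((cvname, f"{r1}{a1}-{r2}{a2}", value, "nm", ""))

    pts = [coord_nm(r, a) for r, a in CHI1_QUADRUPLE]
    if any(p is None for p in pts):
        rows.append(("chi1", "Phe4 N-CA-CB-CG", np.nan, "degrees",
                     "missing chi1 atoms"))
    else:
        coords = np.stack(pts)
        rows.append(("chi1", "Phe4 N-CA-CB-CG",
                     cvg.eval_dihedral(coords, 0, 1, 2, 3), "degrees", ""))

    lo, hi = alpha3_range
    n_term = [a for r in range(lo, lo + 4) for a in sub.residue_atoms(r)]
    c_term = [a for r in range(hi - 3, hi + 1) for a in sub.residue_atoms(r)]
    if not n_term or not c_term:
        rows.append(("La3", f"a3[{lo}-{hi}] termini COM", np.nan, "nm",
                     "missing a3 residues"))
    else:
        atoms = n_term + c_term
        coords = np.array([a.coords for a in atoms]) * ANGSTROM_TO_NM
        masses = np.array([MASSES.get(a.element, 12.011) for a in atoms])
        ga = list(range(len(n_term)))
        gb = list(range(len(n_term), len(atoms)))
        rows.append(("La3", f"a3[{lo}-{hi}] termini COM",
                     cvg.eval_com_distance(coords, ga, gb, masses), "nm", ""))
    return pd.DataFrame(rows, columns=["cv", "atoms", "value", "unit", "note"])
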