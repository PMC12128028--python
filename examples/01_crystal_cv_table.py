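"""Evaluate the hinge-transition CV registry on crystal-like structures.

Builds the synthetic stand-in structures for the closed and open states of
T4 lysozyme (coordinates constructed so each collective variable takes its
published crystal value), parses them through the PDB reader, and prints
the resulting CV table: ten interatomic distances (nm), the Phe4 χ1
torsion (degrees) and the α3 end-to-end length. To run the same evaluation
on a real structure, pass its path to ``read_pdb`` instead.
"""

import tempfile
from pathlib import Path

from cvsteer.structure import compute_reference_cvs, read_pdb
from cvsteer.synthetic_structures import standin_pdb_text

with tempfile.TemporaryDirectory() as td:
    for state in ("closed", "open"):
        path = Path(td) / f"{state}.pdb"
        path.write_text(standin_pdb_text(state))
        table = compute_reference_cvs(read_pdb(path))
        table["value"] = table["value"].round(2)
        print(f"\n=== {state} state ===")
        print(table[["cv", "atoms", "value", "unit"]].to_string(index=False))

print(
    "\nd6 is the Arg8-Glu64 salt-bridge distance: note it is ~1 nm in both"
    "\ncrystal forms, while equilibrium sampling of the closed state holds"
    "\nit at 0.41 nm - the bridge forms in solution and gates the transition."
)
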