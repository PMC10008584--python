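"""Inscribed-sphere pore-radius profile of a toy channel structure.

Builds a two-ring channel (a wide vestibule and a narrow constriction),
writes it as PDB, reads it back and profiles the pore. The constriction
diameter is known exactly: 2 * (ring radius - atom vdW radius).
"""

import tempfile
from pathlib import Path

import gjctools as gj
from gjctools.simulate import write_toy_pdb

atoms = gj.simulate_toy_pore([(0.0, 10.0, 24), (20.0, 6.0, 24)], atom_vdw=1.7)
pdb = Path(tempfile.mkdtemp()) / "toy_pore.pdb"
write_toy_pdb(atoms, pdb)
atoms = gj.load_structure(pdb)
print(f"loaded {len(atoms)} atoms from {pdb.name}")

prof = gj.pore_profile(atoms, z_range=(-2.0, 22.0), step=1.0)
print("\n   z     radius   centre x,y")
for z, r, (cx, cy) in zip(prof.z, prof.radius, prof.center_xy):
    print(f" {z:6.1f}  {r:6.2f}   ({cx:5.2f}, {cy:5.2f})")

d = gj.min_constriction_diameter(prof)
print(f"\nminimum solvent-accessible diameter: {d:.2f} A "
      f"(exact: 2*(6.0 - 1.7) = 8.60 A)")
print("This is the diameter of the widest sphere that can pass the "
      "constriction given atomic van der Waals radii.")
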