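"""Perceive a structure-based pharmacophore from a protein–ligand complex.

Builds a small synthetic complex with four designed interactions (an H-bond
accepted by the ligand, one donated, a hydrophobic contact and a
phosphate–lysine salt bridge), detects the contacts and turns them into a
pharmacophore with excluded volumes.
"""

import tempfile
from pathlib import Path

from polopharm import fixtures as fx
from polopharm import build_structure_pharmacophore, detect_all_contacts, read_complex

toy = fx.make_toy_complex(
    ["hbond_lig_acceptor", "hbond_lig_donor", "hydrophobic", "neg_ionizable"]
)
with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "toy.pdb"
    path.write_text(toy.pdb_text)
    complex_ = read_complex(path, "LIG", pdb_id="TOY1")

print("contacts (kind, residue, distance Å):")
for contact in detect_all_contacts(complex_):
    chain, resnum, resname, atom = contact.receptor_atom
    print(f"  {contact.kind.value:<20} {resname}{resnum}:{atom:<12} {contact.distance:.2f}")

model = build_structure_pharmacophore(complex_)
print(f"\npharmacophore features: {model.kind_counts()}")
print(f"excluded-volume spheres: {len(model.excluded_volumes)}")
# Each detected receptor-ligand interaction became one feature anchored on
# the ligand side; receptor atoms lining the site became steric spheres.
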