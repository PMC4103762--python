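"""Gate a compound library for drug-likeness: ADMET surrogate levels first,
then the Rule of 5 (MW < 500, logP < 5, HBD < 5, HBA < 10, all strict)."""

from rdkit import Chem

from polopharm import compute_descriptors, filter_library, rule_of_five
from polopharm.library_prep import AdmetRuleset
from polopharm.structures import Library, SmallMolecule

SMILES = {
    "aspirin": "CC(=O)Oc1ccccc1C(=O)O",
    "caffeine": "Cn1cnc2c1c(=O)n(C)c(=O)n2C",
    "phenol": "Oc1ccccc1",
    "octadecane": "CCCCCCCCCCCCCCCCCC",          # logP violation
    "polyamine": "NCCNCCNCCNCCNCCNCCN",          # HBD violation
    "bigalkane": "C" * 40,                        # MW + logP violations
}

molecules = []
for mol_id, smiles in SMILES.items():
    mol = Chem.MolFromSmiles(smiles)
    molecules.append(
        SmallMolecule(
            id=mol_id,
            elements=[a.GetSymbol() for a in mol.GetAtoms()],
            bonds=[(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), b.GetBondTypeAsDouble())
                   for b in mol.GetBonds()],
            rdkit_mol=mol,
        )
    )

print(f"{'compound':<12} {'MW':>7} {'logP':>6} {'HBD':>4} {'HBA':>4}  Ro5")
for m in molecules:
    d = compute_descriptors(m)
    ok, violations = rule_of_five(d)
    verdict = "pass" if ok else f"fail ({','.join(violations)})"
    print(f"{m.id:<12} {d.molecular_weight:7.1f} {d.logp:6.2f} "
          f"{d.hbd_count:4d} {d.hba_count:4d}  {verdict}")

kept, report = filter_library(
    Library(molecules), require_levels=(3, 3, 0),
    ruleset=AdmetRuleset.permissive((3, 3, 0)),
)
print(f"\npipeline counts: input {report.n_input} -> post-ADMET "
      f"{report.n_post_admet} -> post-Ro5 {report.n_post_ro5}")
# The per-stage counts mirror the sequential gate; only violation-free
# compounds advance to virtual screening.
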