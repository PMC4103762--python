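"""Feature typing and contact perception: designed-geometry truth, brute-force
oracle equivalence, rigid invariance, cutoff monotonicity."""

import dataclasses

import numpy as np
import pytest
from rdkit import Chem

from polopharm import fixtures as fx
from polopharm.chem import MolGraph
from polopharm.geometry import random_rigid_transform
from polopharm.pharmacophore import FeatureKind
from polopharm.perception import (
    PerceptionConfig,
    build_structure_pharmacophore,
    detect_all_contacts,
    detect_hbonds,
    detect_hydrophobic_contacts,
    detect_ionic_contacts,
    perceive_ligand_feature_atoms,
)
from polopharm.structures import AtomRecord, ComplexStructure

from conftest import complex_from_toy


# ---------------------------------------------------------------------------
# ligand feature typing


@pytest.mark.parametrize(
    "smiles, expectations",
    [
        # benzene: one 6-carbon hydrophobic group, no donors/acceptors
        ("c1ccccc1", {FeatureKind.HYDROPHOBIC: 1, FeatureKind.HBA: 0, FeatureKind.HBD: 0}),
        # ethane: apolar but below the 3-atom group size
        ("CC", {FeatureKind.HYDROPHOBIC: 0, FeatureKind.HBA: 0, FeatureKind.HBD: 0}),
        # phosphothreonine-like fragment: phosphate is negative-ionizable
        ("C[C@@H](OP(=O)(O)O)C(N)C(=O)O", {FeatureKind.NEG_ION: 2}),
        # guanidine: one positive-ionizable group
        ("NC(N)=N", {FeatureKind.POS_ION: 1}),
        # acetamide: amide N excluded as acceptor, carbonyl O accepts
        ("CC(=O)N", {FeatureKind.HBA: 1, FeatureKind.HBD: 1}),
    ],
)
def test_feature_typing_counts(smiles, expectations):
    graph = MolGraph.from_rdkit(Chem.MolFromSmiles(smiles))
    features = perceive_ligand_feature_atoms(graph)
    for kind, count in expectations.items():
        assert len(features[kind]) == count, kind


def test_benzene_hydrophobic_group_covers_ring():
    graph = MolGraph.from_rdkit(Chem.MolFromSmiles("c1ccccc1"))
    groups = perceive_ligand_feature_atoms(graph)[FeatureKind.HYDROPHOBIC]
    assert groups == [[0, 1, 2, 3, 4, 5]]


# ---------------------------------------------------------------------------
# contact detection vs designed truth


def _detected_as_tuples(complex_, config=None):
    return sorted(
        (c.kind.value, c.receptor_atom[1], c.receptor_atom[3], round(c.distance, 3))
        for c in detect_all_contacts(complex_, config)
    )


def _truth_as_tuples(truth):
    return sorted(
        (t["kind"], t["residue_number"], t["atom"], t["distance"]) for t in truth
    )


def test_detection_equals_designed_truth(toy_complex):
    complex_, truth = toy_complex
    assert _detected_as_tuples(complex_) == _truth_as_tuples(truth)


@pytest.mark.parametrize(
    "contacts",
    [
        [("hbond_lig_acceptor", 2.9)],
        [("hbond_lig_donor", 3.4)],
        [("hydrophobic", 4.5)],
        [("neg_ionizable", 4.8)],
        [("pos_ionizable", 4.0)],
        [("hbond_lig_acceptor", 2.6), ("hydrophobic", 3.5), ("neg_ionizable", 5.2)],
    ],
)
def test_detection_matches_truth_across_geometries(contacts, tmp_path):
    toy = fx.make_toy_complex(contacts)
    complex_ = complex_from_toy(toy, tmp_path)
    assert _detected_as_tuples(complex_) == _truth_as_tuples(toy.truth)


@pytest.mark.parametrize(
    "kind, distance, detector",
    [
        ("hbond_lig_acceptor", 4.2, detect_hbonds),
        ("hbond_lig_acceptor", 3.6, detect_hbonds),
        ("hydrophobic", 6.5, detect_hydrophobic_contacts),
        ("neg_ionizable", 6.0, detect_ionic_contacts),
    ],
)
def test_contacts_outside_cutoff_not_detected(kind, distance, detector, tmp_path):
    toy = fx.make_toy_complex([(kind, distance)])
    complex_ = complex_from_toy(toy, tmp_path)
    assert detector(complex_) == []
    assert toy.truth == []


def test_detection_invariant_under_rigid_transforms(toy_complex, rng):
    complex_, _ = toy_complex
    reference = [
        (c.kind.value, c.receptor_atom, c.distance)
        for c in detect_all_contacts(complex_)
    ]
    for _ in range(20):
        tf = random_rigid_transform(rng)
        moved = complex_.transformed(tf)
        transformed = [
            (c.kind.value, c.receptor_atom, c.distance)
            for c in detect_all_contacts(moved)
        ]
        assert len(transformed) == len(reference)
        for (ka, ra, da), (kb, rb, db) in zip(reference, transformed):
            assert ka == kb and ra == rb
            assert abs(da - db) < 1e-9


def test_tightening_cutoffs_never_adds_contacts(toy_complex):
    complex_, _ = toy_complex
    loose = PerceptionConfig()
    tight = PerceptionConfig(hbond_max=3.0, hydrophobic_max=4.0, ionic_max=4.0)
    assert len(detect_all_contacts(complex_, tight)) <= len(
        detect_all_contacts(complex_, loose)
    )


def test_brute_force_all_pairs_oracle(toy_complex):
    """Independent all-pairs scan over typed atoms reproduces detect_hbonds."""
    complex_, _ = toy_complex
    config = PerceptionConfig()
    graph = complex_.ligand_graph()
    heavy = graph.heavy_indices
    features = perceive_ligand_feature_atoms(graph)

    receptor_donor_names = {"N", "NZ", "NE1", "ND1", "OG", "OG1", "OH", "ND2", "NE2"}
    receptor_acceptor_names = {"O", "OXT", "OD1", "OD2", "OE1", "OE2", "OG", "OG1", "OH"}
    expected = set()
    for group in features[FeatureKind.HBD]:
        la = complex_.ligand_atoms[heavy[group[0]]]
        for r in complex_.receptor_atoms:
            if r.name not in receptor_acceptor_names or r.element == "C":
                continue
            if r.name == "NE2" and r.residue_name != "HIS":
                continue
            d = float(np.linalg.norm(la.coords - r.coords))
            if config.hbond_min <= d <= config.hbond_max:
                expected.add(("HBOND_LIG_DONOR", r.residue_number, r.name))
    for group in features[FeatureKind.HBA]:
        la = complex_.ligand_atoms[heavy[group[0]]]
        for r in complex_.receptor_atoms:
            if r.name not in receptor_donor_names or r.element != "N":
                continue
            d = float(np.linalg.norm(la.coords - r.coords))
            if config.hbond_min <= d <= config.hbond_max:
                expected.add(("HBOND_LIG_ACCEPTOR", r.residue_number, r.name))
    detected = {
        (c.kind.value, c.receptor_atom[1], c.receptor_atom[3])
        for c in detect_hbonds(complex_, config)
    }
    assert detected == expected


# ---------------------------------------------------------------------------
# pharmacophore construction


def test_model_feature_count_matches_contacts(tmp_path):
    toy = fx.make_toy_complex([("hbond_lig_acceptor", 2.9), ("hydrophobic", 4.0)])
    complex_ = complex_from_toy(toy, tmp_path)
    model = build_structure_pharmacophore(complex_)
    assert model.kind_counts() == {"HBA": 1, "HYDROPHOBIC": 1}
    assert len(model.excluded_volumes) > 0


def test_duplicate_contacts_merge_into_one_feature_with_two_directions():
    # one carbonyl O flanked by two backbone N-H donors at 3.0 Å
    receptor = []
    for k, x in enumerate((-3.0, 3.0)):
        receptor += [
            AtomRecord(10 * k + 1, "N", "N", "GLY", "A", 401 + k, (x, 0.0, 0.0)),
            AtomRecord(10 * k + 2, "CA", "C", "GLY", "A", 401 + k, (x, -1.5, 0.0)),
        ]
    ligand = [
        AtomRecord(100, "O1", "O", "LIG", "L", 900, (0.0, 0.0, 0.0), is_hetero=True),
        AtomRecord(101, "C1", "C", "LIG", "L", 900, (0.0, 1.21, 0.0), is_hetero=True),
    ]
    complex_ = ComplexStructure("MERGE", receptor, ligand)
    contacts = detect_hbonds(complex_)
    assert len(contacts) == 2
    model = build_structure_pharmacophore(complex_)
    hba = [f for f in model.features if f.kind == FeatureKind.HBA]
    assert len(hba) == 1
    assert len(hba[0].directions) == 2


def test_feature_centroids_inside_inflated_ligand_bbox(toy_complex, key_site):
    for complex_, _ in (toy_complex, key_site):
        model = build_structure_pharmacophore(complex_)
        xyz = complex_.ligand_coords
        lo, hi = xyz.min(axis=0) - 1.0, xyz.max(axis=0) + 1.0
        for f in model.features:
            assert np.all(f.centroid >= lo) and np.all(f.centroid <= hi)


def test_empty_contact_model_warns():
    receptor = [AtomRecord(1, "CA", "C", "GLY", "A", 401, (50.0, 0.0, 0.0))]
    ligand = [
        AtomRecord(2, "C1", "C", "LIG", "L", 900, (0.0, 0.0, 0.0), is_hetero=True),
        AtomRecord(3, "C2", "C", "LIG", "L", 900, (1.5, 0.0, 0.0), is_hetero=True),
    ]
    complex_ = ComplexStructure("EMPTY", receptor, ligand)
    with pytest.warns(UserWarning, match="no contacts"):
        model = build_structure_pharmacophore(complex_)
    assert model.features == []
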