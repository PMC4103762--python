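"""Pharmacophore matching: closed-form fit values, brute-force oracle
equivalence, pose invariance, omission monotonicity and the library driver."""

import itertools

import numpy as np
import pytest

from polopharm import fixtures as fx
from polopharm.geometry import kabsch, random_rigid_transform
from polopharm.pharmacophore import FeatureKind, Pharmacophore, PharmacophoreFeature
from polopharm.screening import (
    MatchAborted,
    best_match,
    find_assignments,
    ligand_feature_points,
    score_fit,
    screen_library,
)
from polopharm.structures import SmallMolecule


def hexagon_molecule(radius: float = 1.39) -> SmallMolecule:
    angles = np.arange(6) * np.pi / 3
    coords = np.stack(
        [radius * np.cos(angles), radius * np.sin(angles), np.zeros(6)], axis=1
    )
    bonds = [(i, (i + 1) % 6, 1.5) for i in range(6)]
    return SmallMolecule("benzene", ["C"] * 6, bonds, conformers=[coords])


# ---------------------------------------------------------------------------
# feature points


def test_pseudo_ligand_points_cover_model(consensus_model):
    mol, _ = fx.make_pseudo_ligand(consensus_model)
    points = ligand_feature_points(mol)
    for feature in consensus_model.features:
        assert any(
            p.kind == feature.kind
            and np.linalg.norm(p.position - feature.centroid) < 1e-9
            for p in points
        )


def test_benzene_single_hydrophobic_point_at_centroid():
    points = ligand_feature_points(hexagon_molecule())
    assert len(points) == 1
    assert points[0].kind == FeatureKind.HYDROPHOBIC
    assert np.allclose(points[0].position, 0.0, atol=1e-12)


def test_featureless_molecule_yields_no_points():
    ethane = SmallMolecule(
        "ethane", ["C", "C"], [(0, 1, 1.0)], conformers=[np.array([[0, 0, 0], [1.5, 0, 0]])]
    )
    assert ligand_feature_points(ethane) == []


# ---------------------------------------------------------------------------
# assignments


def test_exact_ligand_full_assignment(consensus_model):
    mol, _ = fx.make_pseudo_ligand(consensus_model)
    points = ligand_feature_points(mol)
    assignments = find_assignments(consensus_model, points, max_omitted=0)
    assert assignments
    assert max(len(a) for a in assignments) == 5


def test_partial_ligand_respects_max_omitted(consensus_model):
    mol, _ = fx.make_pseudo_ligand(consensus_model, omit=(0, 4))
    points = ligand_feature_points(mol)
    with_two = find_assignments(consensus_model, points, max_omitted=2)
    assert any(len(a) >= 3 for a in with_two)
    # the two omitted features (an HBA and the only hydrophobic) cannot be
    # matched at all, so allowing one omission leaves no valid assignment
    best = best_match(consensus_model, mol, max_omitted=1)
    assert best is None


def test_wrong_kind_points_never_assigned(consensus_model):
    from polopharm.screening import FeaturePoint

    mol, _ = fx.make_pseudo_ligand(consensus_model)
    flipped = [
        FeaturePoint(FeatureKind.NEG_ION, p.position, p.atoms)
        for p in ligand_feature_points(mol)
    ]
    assert find_assignments(consensus_model, flipped, max_omitted=2) == []


def test_combinatorial_guard_trips():
    features = [
        PharmacophoreFeature(FeatureKind.HBA, (i * 0.1, 0, 0), tolerance=50.0)
        for i in range(6)
    ]
    model = Pharmacophore("degenerate", features)
    from polopharm.screening import FeaturePoint

    points = [
        FeaturePoint(FeatureKind.HBA, np.array([0.1 * k, 0.1, 0]), (k,))
        for k in range(8)
    ]
    with pytest.raises(MatchAborted):
        find_assignments(model, points, max_omitted=2, max_expansions=50)


# ---------------------------------------------------------------------------
# fit values (closed forms hold in the in-place frame)


def test_perfect_match_fit_equals_feature_count(consensus_model):
    mol, truth = fx.make_pseudo_ligand(consensus_model)
    assert truth == 5.0
    result = best_match(consensus_model, mol, max_omitted=0, refit=False)
    assert result.fit_value == pytest.approx(5.0, abs=1e-9)
    assert result.n_matched == 5


def test_half_tolerance_displacement_closed_form(consensus_model):
    tol = consensus_model.features[1].tolerance
    mol, truth = fx.make_pseudo_ligand(consensus_model, displace={1: tol / 2})
    assert truth == pytest.approx(4.75)
    result = best_match(consensus_model, mol, max_omitted=2, refit=False)
    assert result.fit_value == pytest.approx(4.75, abs=1e-9)
    # re-alignment can only lower the residual sum, never the fit
    refit = best_match(consensus_model, mol, max_omitted=2, refit=True)
    assert refit.fit_value >= 4.75 - 1e-9


def test_displacement_at_tolerance_contributes_zero_and_omits(consensus_model):
    tol = consensus_model.features[2].tolerance
    mol, truth = fx.make_pseudo_ligand(consensus_model, displace={2: tol})
    assert truth == pytest.approx(4.0)
    result = best_match(consensus_model, mol, max_omitted=2, refit=False)
    assert result.fit_value == pytest.approx(4.0, abs=1e-9)
    assert result.n_matched == 4
    assert 2 in result.omitted


def test_fit_upper_bound_and_equality_condition(consensus_model, rng):
    for _ in range(5):
        displace = {int(rng.integers(5)): float(rng.uniform(0.1, 1.4))}
        mol, truth = fx.make_pseudo_ligand(consensus_model, displace=displace)
        result = best_match(consensus_model, mol, max_omitted=2, refit=False)
        assert result.fit_value <= consensus_model.n_features + 1e-12
        assert result.fit_value < consensus_model.n_features  # displaced ⇒ strict
    exact, _ = fx.make_pseudo_ligand(consensus_model)
    result = best_match(consensus_model, exact, max_omitted=0, refit=False)
    assert result.fit_value == pytest.approx(consensus_model.n_features, abs=1e-9)


def test_fit_invariant_under_rigid_conformer_transform(consensus_model, rng):
    mol, _ = fx.make_pseudo_ligand(consensus_model)
    reference = best_match(consensus_model, mol, max_omitted=0).fit_value
    for _ in range(10):
        tf = random_rigid_transform(rng)
        moved = SmallMolecule(
            mol.id, list(mol.elements), list(mol.bonds),
            conformers=[tf.apply(mol.conformers[0])],
        )
        fit = best_match(consensus_model, moved, max_omitted=0).fit_value
        assert fit == pytest.approx(reference, abs=1e-9)


def test_fit_monotone_in_max_omitted(consensus_model):
    mol, _ = fx.make_pseudo_ligand(consensus_model, omit=(0, 1))
    fits = []
    for k in (2, 3, 4):
        result = best_match(consensus_model, mol, max_omitted=k, refit=False)
        fits.append(result.fit_value if result else 0.0)
    assert all(a <= b + 1e-12 for a, b in zip(fits, fits[1:]))


def test_excluded_volume_clash_rejects_match(consensus_model):
    mol, _ = fx.make_pseudo_ligand(consensus_model)
    atom_pos = mol.conformers[0][0]
    clashing = Pharmacophore(
        "clash",
        consensus_model.features,
        excluded_volumes=[(atom_pos, 1.0)],
    )
    assert best_match(clashing, mol, max_omitted=0, refit=False) is None
    open_model = Pharmacophore("open", consensus_model.features)
    assert best_match(open_model, mol, max_omitted=0, refit=False) is not None


# ---------------------------------------------------------------------------
# brute-force oracle equivalence


def brute_force_best_fit(model, points, max_omitted):
    """Exhaustive best fit over every injective kind-compatible mapping of
    every feature subset, scored with its own alignment + omission rules."""
    n = len(model.features)
    min_size = n - max_omitted
    best = None
    feature_idx = list(range(n))
    for size in range(min_size, n + 1):
        for subset in itertools.combinations(feature_idx, size):
            candidates = [
                [pi for pi, p in enumerate(points) if p.kind == model.features[fi].kind]
                for fi in subset
            ]
            for chosen in itertools.product(*candidates):
                if len(set(chosen)) != len(chosen):
                    continue
                lig = np.array([points[pi].position for pi in chosen])
                ref = np.array([model.features[fi].centroid for fi in subset])
                tf, _ = kabsch(lig, ref, allow_translation_only=True)
                disp = np.linalg.norm(tf.apply(lig) - ref, axis=1)
                fit = 0.0
                matched = 0
                for fi, d in zip(subset, disp):
                    tol = model.features[fi].tolerance
                    if d <= tol:
                        fit += model.features[fi].weight * (1.0 - (d / tol) ** 2)
                        matched += 1
                if matched < min_size:
                    continue
                if best is None or fit > best:
                    best = fit
    return best


def random_matcher_case(seed):
    rng = np.random.default_rng(seed)
    kinds = list(FeatureKind)
    n_feat = int(rng.integers(3, 7))
    n_points = int(rng.integers(4, 9))
    features = [
        PharmacophoreFeature(
            kind=kinds[int(rng.integers(len(kinds)))],
            centroid=rng.uniform(-6, 6, size=3),
            tolerance=1.5,
        )
        for _ in range(n_feat)
    ]
    model = Pharmacophore(f"case_{seed}", features)
    from polopharm.screening import FeaturePoint

    points = []
    for k in range(n_points):
        if k < n_feat and rng.random() < 0.6:  # near-match with jitter
            base = features[k].centroid + rng.normal(0, 0.8, size=3)
            kind = features[k].kind
        else:
            base = rng.uniform(-8, 8, size=3)
            kind = kinds[int(rng.integers(len(kinds)))]
        points.append(FeaturePoint(kind, base, (k,)))
    return model, points


@pytest.mark.parametrize("seed", range(25))
def test_matcher_equals_exhaustive_enumeration(seed):
    model, points = random_matcher_case(seed)
    max_omitted = min(2, len(model.features) - 1)
    oracle = brute_force_best_fit(model, points, max_omitted)
    assignments = find_assignments(model, points, max_omitted)
    best = None
    for assignment in assignments:
        result = score_fit(model, points, assignment)
        if result.n_matched < len(model.features) - max_omitted:
            continue
        if best is None or result.fit_value > best:
            best = result.fit_value
    if oracle is None:
        assert best is None
    else:
        assert best == pytest.approx(oracle, abs=1e-9)


# ---------------------------------------------------------------------------
# screening driver


def test_screen_separates_matchers_from_decoys(consensus_model):
    library, truth = fx.make_library(consensus_model, n_match=5, n_decoy=10, seed=11)
    table, report = screen_library(consensus_model, library, max_omitted=2, min_fit=3.0)
    assert sorted(table.molecule_id) == truth["match_ids"]
    assert report["n_hits"] == 5
    assert report["aborted"] == []
    assert (table.fit_value >= 3.0).all()


def test_degenerate_thresholds_hit_everything(consensus_model):
    library, _ = fx.make_library(consensus_model, n_match=3, n_decoy=3, seed=5)
    table, _ = screen_library(
        consensus_model, library,
        max_omitted=consensus_model.n_features - 1, min_fit=0.0,
    )
    assert len(table) == len(library)  # every molecule has ≥1 compatible point


def test_empty_library_empty_table(consensus_model):
    table, report = screen_library(consensus_model, [], min_fit=3.0)
    assert table.empty
    assert report["n_hits"] == 0


def test_ranking_descends_with_id_tiebreak(consensus_model):
    library, _ = fx.make_library(consensus_model, n_match=4, n_decoy=0, seed=2)
    table, _ = screen_library(consensus_model, library, min_fit=0.0)
    fits = table.fit_value.to_numpy()
    assert (fits[:-1] >= fits[1:] - 1e-12).all()
    for _, group in table.groupby("fit_value"):
        ids = list(group.molecule_id)
        assert ids == sorted(ids)
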