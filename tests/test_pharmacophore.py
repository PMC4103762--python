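"""Consensus construction, serialization and geometry reporting."""

import numpy as np
import pytest

from polopharm import fixtures as fx
from polopharm.pharmacophore import (
    ConsensusError,
    FeatureKind,
    Pharmacophore,
    PharmacophoreFeature,
    build_consensus,
    deserialize,
    geometry_report,
    serialize,
)


def brute_force_common_features(models, cluster_radius):
    """Exact multiset-intersection oracle for well-separated clusters: a
    feature of the first model is common iff every model has a same-kind
    feature within the radius."""
    common = []
    for f in models[0].features:
        shared = all(
            any(
                g.kind == f.kind
                and np.linalg.norm(g.centroid - f.centroid) <= cluster_radius
                for g in m.features
            )
            for m in models[1:]
        )
        if shared:
            common.append(f.kind.value)
    return sorted(common)


def test_consensus_recovers_designed_core(feature_family):
    models = feature_family.models
    consensus = build_consensus(models, min_support=len(models))
    assert consensus.n_features == 5
    assert consensus.kind_counts() == {"HBA": 3, "HBD": 1, "HYDROPHOBIC": 1}
    oracle = brute_force_common_features(models, cluster_radius=2.0)
    assert sorted(f.kind.value for f in consensus.features) == oracle
    # centroids sit within the jitter envelope of the designed core
    designed = feature_family.core_centroids
    for f in consensus.features:
        assert min(np.linalg.norm(f.centroid - c) for c in designed) <= 0.3


def test_consensus_supports_recorded(feature_family):
    consensus = build_consensus(feature_family.models)
    assert all(f.support == len(feature_family.models) for f in consensus.features)


def test_consensus_permutation_invariant(feature_family, rng):
    models = list(feature_family.models)
    reference = build_consensus(models, min_support=9)
    for _ in range(5):
        shuffled = list(models)
        rng.shuffle(shuffled)
        other = build_consensus(shuffled, min_support=9)
        assert [f.kind for f in other.features] == [f.kind for f in reference.features]
        assert np.allclose(
            other.centroids(), reference.centroids(), atol=1e-12
        )


def test_consensus_monotone_in_min_support(feature_family):
    counts = [
        build_consensus(feature_family.models, min_support=s).n_features
        for s in range(1, 10)
    ]
    assert all(a >= b for a, b in zip(counts, counts[1:]))


def test_min_support_one_keeps_every_cluster():
    family = fx.make_feature_sets(n_models=4, jitter=0.0, n_extra_range=(0, 0), seed=1)
    consensus = build_consensus(family.models, min_support=1)
    assert consensus.n_features == 5
    assert np.allclose(
        np.sort(consensus.centroids(), axis=0),
        np.sort(family.core_centroids, axis=0),
    )


def test_consensus_of_identical_copies_is_the_model():
    family = fx.make_feature_sets(n_models=1, jitter=0.0, n_extra_range=(0, 0), seed=0)
    model = family.models[0]
    consensus = build_consensus([model, model, model], min_support=3)
    assert consensus.kind_counts() == model.kind_counts()
    assert np.allclose(
        np.sort(consensus.centroids(), axis=0),
        np.sort(model.centroids(), axis=0),
    )


def test_no_common_features_raises_with_histogram():
    a = Pharmacophore("a", [PharmacophoreFeature(FeatureKind.HBA, (0, 0, 0))])
    b = Pharmacophore("b", [PharmacophoreFeature(FeatureKind.HYDROPHOBIC, (0, 0, 0))])
    with pytest.raises(ConsensusError, match="no common features") as err:
        build_consensus([a, b], min_support=2)
    assert err.value.support_histogram == {1: 2}


def test_opposite_directions_never_merge():
    up = PharmacophoreFeature(FeatureKind.HBA, (0, 0, 0), directions=((0, 0, 1),))
    down = PharmacophoreFeature(FeatureKind.HBA, (0, 0, 0), directions=((0, 0, -1),))
    a = Pharmacophore("a", [up])
    b = Pharmacophore("b", [down])
    with pytest.raises(ConsensusError):
        build_consensus([a, b], min_support=2)


def test_consensus_distance_constraints_cover_all_pairs(consensus_model):
    n = consensus_model.n_features
    assert len(consensus_model.distance_constraints) == n * (n - 1) // 2
    for i, j, d, tol in consensus_model.distance_constraints:
        actual = np.linalg.norm(
            consensus_model.features[i].centroid - consensus_model.features[j].centroid
        )
        assert d == pytest.approx(actual, abs=1e-12)
        assert tol == pytest.approx(
            consensus_model.features[i].tolerance + consensus_model.features[j].tolerance
        )


# ---------------------------------------------------------------------------
# serialization


def test_serialization_round_trip(consensus_model):
    back = deserialize(serialize(consensus_model))
    assert back.name == consensus_model.name
    assert back.provenance == consensus_model.provenance
    assert len(back.features) == len(consensus_model.features)
    for f, g in zip(back.features, consensus_model.features):
        assert f.kind == g.kind
        assert np.array_equal(f.centroid, g.centroid)
        assert f.tolerance == g.tolerance
        assert f.support == g.support
        assert len(f.directions) == len(g.directions)
        for da, db in zip(f.directions, g.directions):
            assert np.array_equal(da, db)
    assert back.distance_constraints == consensus_model.distance_constraints
    assert len(back.excluded_volumes) == len(consensus_model.excluded_volumes)


def test_minimal_json_applies_tolerance_default():
    doc = """
    {"schema": "polopharm-pharmacophore/1", "name": "m",
     "features": [{"kind": "HBA", "centroid": [0, 0, 0]}]}
    """
    model = deserialize(doc)
    assert model.features[0].tolerance == 1.5


def test_corrupt_kind_names_feature_index():
    doc = """
    {"schema": "polopharm-pharmacophore/1", "name": "m",
     "features": [{"kind": "HBA", "centroid": [0, 0, 0]},
                  {"kind": "BOGUS", "centroid": [1, 0, 0]}]}
    """
    with pytest.raises(ValueError, match="index 1"):
        deserialize(doc)


def test_unknown_schema_version_rejected():
    with pytest.raises(ValueError, match="schema"):
        deserialize('{"schema": "something/9", "features": []}')


# ---------------------------------------------------------------------------
# geometry report


def test_two_feature_report_single_distance():
    model = Pharmacophore(
        "m",
        [
            PharmacophoreFeature(FeatureKind.HBA, (0, 0, 0)),
            PharmacophoreFeature(FeatureKind.HBD, (4.0, 0, 0)),
        ],
    )
    table = geometry_report(model)
    assert table.shape == (2, 2)
    assert table.iloc[0, 1] == pytest.approx(4.0)
    assert np.allclose(table.values, table.values.T)


def test_single_feature_report_is_empty():
    model = Pharmacophore("m", [PharmacophoreFeature(FeatureKind.HBA, (0, 0, 0))])
    assert geometry_report(model).empty


def test_consensus_report_reproduces_designed_geometry(feature_family, consensus_model):
    table = geometry_report(consensus_model)
    designed = feature_family.core_centroids
    designed_d = sorted(
        float(np.linalg.norm(designed[i] - designed[j]))
        for i in range(len(designed))
        for j in range(i + 1, len(designed))
    )
    observed = sorted(
        table.values[i, j]
        for i in range(len(table))
        for j in range(i + 1, len(table))
    )
    # jitter ≤ 0.3 Å per model moves a mean centroid by ≤ 0.3, pairs by ≤ 0.6
    assert np.allclose(observed, designed_d, atol=0.6)
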