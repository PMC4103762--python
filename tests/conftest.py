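"""Shared fixtures: parsed toy complexes, feature-set families, consensus models."""

from __future__ import annotations

import numpy as np
import pytest

from polopharm import fixtures as fx
from polopharm.pharmacophore import build_consensus
from polopharm.structures import read_complex


def complex_from_toy(toy: fx.ToyComplex, tmp_path):
    path = tmp_path / f"{toy.pdb_id}.pdb"
    path.write_text(toy.pdb_text)
    return read_complex(path, "LIG", pdb_id=toy.pdb_id)


@pytest.fixture()
def toy_complex(tmp_path):
    """Four designed contacts: acceptor H-bond, donor H-bond, hydrophobic, ionic."""
    toy = fx.make_toy_complex(
        ["hbond_lig_acceptor", "hbond_lig_donor", "hydrophobic", "neg_ionizable"]
    )
    return complex_from_toy(toy, tmp_path), toy.truth


@pytest.fixture()
def key_site(tmp_path):
    toy = fx.make_key_site_complex()
    return complex_from_toy(toy, tmp_path), toy.truth


@pytest.fixture(scope="session")
def feature_family():
    return fx.make_feature_sets(seed=7)


@pytest.fixture(scope="session")
def consensus_model(feature_family):
    return build_consensus(feature_family.models, min_support=len(feature_family.models))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20140718)
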