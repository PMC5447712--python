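"""Shared fixtures: one fitted default synthetic instance reused across tests."""

import numpy as np
import pytest

from cspattern import CSPModel, synth


@pytest.fixture(scope="session")
def default_instance():
    """Default desk-scale synthetic dataset with planted truth."""
    matrix, truth = synth.gen_state_matrix(seed=0)
    return matrix, truth


@pytest.fixture(scope="session")
def fitted(default_instance):
    """CSP model fitted once on the default instance (capacity 10 > truth 4)."""
    matrix, _ = default_instance
    return CSPModel(matrix, n_patterns=10, n_groups=5).fit(
        n_iter=100, train_fraction=0.5, seed=0
    )


@pytest.fixture(scope="session")
def clusters(default_instance):
    matrix, _ = default_instance
    return synth.default_clusters(matrix.epigenome_ids)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
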