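import numpy as np
import pandas as pd
import pytest

from funclink import (
    DistanceMatrix,
    IncidenceMatrix,
    TraitSpec,
    TraitTable,
    simulate_realm,
)
from funclink.tree import FunctionalTree


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_realm():
    """One modest realm reused by read-only tests."""
    return simulate_realm(n_regions=14, n_hosts=16, n_fleas=14, theta_match=0.7, theta_env=0.3, seed=11)


@pytest.fixture
def mixed_trait_table():
    species = ["s1", "s2", "s3", "s4", "s5"]
    data = pd.DataFrame(
        {
            "mass": [1.0, 2.0, 3.0, 4.0, 5.0],
            "range": [np.e**2, np.e**2, np.e**4, np.e**4, np.e**3],
            "size": ["small", "small", "medium", "large", "large"],
            "shelter": ["burrow", "hair", "none", "burrow", "hair"],
        },
        index=species,
    )
    schema = {
        "mass": TraitSpec("continuous"),
        "range": TraitSpec("continuous", ln_transform=True),
        "size": TraitSpec("ordinal", levels=("small", "medium", "large")),
        "shelter": TraitSpec("nominal"),
    }
    return TraitTable(species, data, schema)


def balanced_quartet() -> FunctionalTree:
    """Rooted 4-leaf tree: root -> (x -> A, B), (y -> C, D), unit branches."""
    children = {4: [(5, 0), (6, 1)], 5: [(0, 2), (1, 3)], 6: [(2, 4), (3, 5)]}
    edges = [(4, 5), (4, 6), (5, 0), (5, 1), (6, 2), (6, 3)]
    lengths = np.ones(6)
    leaf_name = {0: "A", 1: "B", 2: "C", 3: "D"}
    return FunctionalTree(4, children, edges, lengths, leaf_name)


@pytest.fixture
def quartet():
    return balanced_quartet()


def bm_sample(C: np.ndarray, sigma2: float, rng: np.random.Generator) -> np.ndarray:
    """Draw one Brownian-motion realization with covariance sigma2*C."""
    ev, Q = np.linalg.eigh(C)
    L = Q @ np.diag(np.sqrt(np.clip(ev, 0.0, None)))
    return np.sqrt(sigma2) * (L @ rng.standard_normal(C.shape[0]))


@pytest.fixture
def three_taxon_distance():
    return DistanceMatrix(
        ["A", "B", "C"], np.array([[0.0, 2.0, 4.0], [2.0, 0.0, 4.0], [4.0, 4.0, 0.0]])
    )


def make_incidence(regions, species, rows) -> IncidenceMatrix:
    return IncidenceMatrix(list(regions), list(species), np.asarray(rows))
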