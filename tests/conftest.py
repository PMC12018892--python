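"""Shared fixtures: small simulated datasets and toy genotype matrices."""

from __future__ import annotations

import numpy as np
import pytest

from nestkin.breeding_habits import nest_records_from_frame
from nestkin.genotype_io import GenotypeMatrix
from nestkin.synthetic_data import (
    SimulationConfig,
    simulate_dataset,
    two_family_scenario,
)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240601)


@pytest.fixture(scope="session")
def two_family_dataset():
    """Breeding-stock layout: 11 full sibs + a 5/5 half-sib nest, 2000 SNPs."""
    config = SimulationConfig(n_snps=2000, seed=11, plan=two_family_scenario())
    return simulate_dataset(config)


@pytest.fixture(scope="session")
def default_dataset():
    """The study-sized default scenario at desk scale (2000 SNPs)."""
    return simulate_dataset(SimulationConfig(n_snps=2000, seed=7))


@pytest.fixture(scope="session")
def default_nests(default_dataset):
    return nest_records_from_frame(default_dataset.nests_frame())


@pytest.fixture
def toy_matrix() -> GenotypeMatrix:
    """3 samples x 4 sites, fully called, with depths."""
    genos = np.array(
        [
            [0, 1, 2, 1],
            [0, 1, 2, 0],
            [2, 1, 0, 1],
        ],
        dtype=np.int8,
    )
    depths = np.full(genos.shape, 50, dtype=np.int64)
    sites = [("1", 100, "A", "G"), ("1", 200, "C", "T"),
             ("2", 100, "G", "A"), ("2", 250, "T", "C")]
    return GenotypeMatrix(samples=["s1", "s2", "s3"], sites=sites,
                          genotypes=genos, depths=depths)
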