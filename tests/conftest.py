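"""Shared fixtures: tiny deterministic datasets for the unit tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from ecgc.io_config import GenotypeMatrix
from ecgc.synthetic_data import SynthConfig, generate_dataset

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_gm() -> GenotypeMatrix:
    """3 varieties x 4 SNPs with hand-checkable doses (one monomorphic)."""
    doses = pd.DataFrame(
        [[0.0, 1.0, 2.0, 2.0],
         [1.0, 1.0, 0.0, 2.0],
         [2.0, 0.0, 1.0, 2.0]],
        index=["a", "b", "c"], columns=["s1", "s2", "s3", "s4"])
    snp_map = pd.DataFrame({"chrom": ["chr1"] * 4,
                            "bp": [100, 200, 300, 400]},
                           index=["s1", "s2", "s3", "s4"])
    return GenotypeMatrix(doses, snp_map)


SMALL_CFG = SynthConfig(n_varieties=80, n_snps=300, n_chrom=3, n_env=8,
                        years_per_env=2, rng_seed=11)


@pytest.fixture(scope="session")
def small_dataset():
    """One small synthetic dataset shared across the session (seed 11)."""
    return generate_dataset(SMALL_CFG)


@pytest.fixture(scope="session")
def small_cfg():
    return SMALL_CFG
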