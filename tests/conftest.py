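"""Shared fixtures: small synthetic datasets reused across test modules."""

import warnings

import numpy as np
import pytest

warnings.filterwarnings("ignore", category=FutureWarning)
warnings.filterwarnings("ignore", category=UserWarning, module="anndata")

from v1atlas import preprocess, qc
from v1atlas.simulate import (default_config, en1_experiment_config,
                              simulate_counts, simulate_reference)


@pytest.fixture(scope="session")
def atlas_small():
    """4,000-nucleus atlas-style dataset with 10% contaminants, 5% doublets."""
    cfg = default_config(n_nuclei=4_000, n_genes=2_000, seed=0)
    return simulate_counts(cfg)


@pytest.fixture(scope="session")
def atlas_qc(atlas_small):
    adata, truth = atlas_small
    return qc.apply_qc(adata), truth


@pytest.fixture(scope="session")
def atlas_norm(atlas_qc):
    """QC'd, normalized, clustered (resolution 0.24) atlas subset."""
    adata, truth = atlas_qc
    norm = preprocess.cluster_pipeline(adata, resolution=0.24, seed=0)
    return norm, truth


@pytest.fixture(scope="session")
def reference_small():
    """Synthetic embryonic-style reference with class labels incl. V1."""
    return simulate_reference(n_nuclei=3_000, n_genes=2_000, seed=7)


@pytest.fixture(scope="session")
def en1_small():
    """Genotype-comparison dataset: 4 samples, one cluster depleted 3-fold
    in KO."""
    cfg = en1_experiment_config(n_per_sample=1_000, n_genes=1_200, seed=3)
    return simulate_counts(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
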