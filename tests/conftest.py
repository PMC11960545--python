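import numpy as np
import pytest

from scmeth import (ClusterProfile, ModelConfig, SiteCatalog, SyntheticConfig,
                    cluster_cells, compute_bin_matrix, simulate)


@pytest.fixture(scope="session")
def small_dataset():
    """A quick synthetic dataset for unit tests (not the CI study scale)."""
    cfg = SyntheticConfig(
        n_cells=60, n_clusters=3,
        chrom_lengths={"s1": 60_000, "s2": 60_000, "s3": 60_000},
        split={"train": ["s1"], "val": ["s2"], "test": ["s3"]},
        cpg_density=0.01, motifs_per_chrom=15,
        n_dmr_per_cluster=6, coverage=0.25, seed=7,
    )
    return simulate(cfg)


@pytest.fixture(scope="session")
def small_profile(small_dataset):
    ds = small_dataset
    bm = compute_bin_matrix(ds.tables, ds.genome, bin_size=10_000)
    assignment = cluster_cells(bm, ds.config.n_clusters, seed=7)
    return assignment, ClusterProfile.from_states(ds.states, assignment,
                                                  ds.catalog)


@pytest.fixture
def tiny_model_config():
    """A seconds-scale model configuration for architecture tests."""
    return ModelConfig(
        n_cells=12, n_clusters=2, L=32, K=8, conv_layers=2, conv_kernels=8,
        kernel_size=5, pool_step=8, n_transformer_layers=1, n_heads=2,
        model_dim=16, ffn_dim=32, head_hidden=16, batch_size=16,
        max_epochs=2, patience=5, learning_rate=1e-3, seed=0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
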