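import pytest

from chiahub.sim import SimConfig, generate_dataset


@pytest.fixture(scope="session")
def small_cfg():
    """Fast generator config used by most integration-style tests."""
    return SimConfig(
        n_genes=800,
        n_tissues=12,
        loop_counts={"H3K4me3": 100, "RNAPII": 50, "H3K4me1": 50, "H3K27me3": 80, "H3K9me2": 80},
        n_hubs=15,
        n_cres=200,
        n_snps=100,
        n_coexpr_pairs=60,
        tf_configs=[("MYC2", 120, 0.7)],
        seed=7,
    )


@pytest.fixture(scope="session")
def small_ds(small_cfg):
    return generate_dataset(small_cfg)


@pytest.fixture(scope="session")
def default_ds():
    """The generator's default study conditions (2 x 20 Mb, 2,000 genes,
    43 tissues, 2x anchor boost, planted pair PCC 0.5)."""
    return generate_dataset(SimConfig(seed=11))
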