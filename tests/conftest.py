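import dataclasses

import pytest

from saconflict.effect_stats import annotate_snp_frame
from saconflict.synthetic_data import SyntheticConfig, generate_all, generate_snp_table


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    """A small, fast synthetic study (fixed seed)."""
    return SyntheticConfig(seed=42, n_genes=60)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_all(small_config)


@pytest.fixture(scope="session")
def annotated_snps(small_dataset):
    return annotate_snp_frame(small_dataset["snps"])


@pytest.fixture
def make_config():
    """Factory for configs derived from the session defaults."""

    def _make(**overrides) -> SyntheticConfig:
        return dataclasses.replace(SyntheticConfig(), **overrides)

    return _make


@pytest.fixture
def snp_frame_factory():
    def _make(cfg: SyntheticConfig):
        snps, genes, truth = generate_snp_table(cfg)
        return annotate_snp_frame(snps), genes, truth

    return _make
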