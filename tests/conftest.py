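import numpy as np
import pytest

from polymr import PolyMR, get_scenario, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """Base-settings generative model at a desk-scale size: n=8,000 samples,
    20 causal SNPs (per-SNP h² = 0.025, so instruments reach genome-wide
    significance)."""
    return simulate_dataset(
        get_scenario("base", n_samples=8_000, n_causal_snps=20, seed=42)
    )


@pytest.fixture(scope="session")
def small_fit(small_dataset):
    d = small_dataset
    model = PolyMR(
        d.outcome_raw,
        d.exposure,
        d.genotypes,
        instrument_p_threshold=5e-8,
        genotypes_standardized=True,
    )
    return model, model.fit()


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
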