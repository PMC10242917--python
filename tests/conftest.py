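import numpy as np
import pytest

from imputassoc import SimConfig, simulate_binary, simulate_imputed_variant, simulate_quantitative


@pytest.fixture(scope="session")
def mid_variant():
    """One mid-frequency variant with moderate imputation quality (n = 5,000)."""
    cfg = SimConfig(n=5000, maf_range=(0.2, 0.2), rsq_range=(0.7, 0.7))
    return simulate_imputed_variant(cfg, seed=42)


@pytest.fixture(scope="session")
def perfect_variant():
    """A variant with degenerate posteriors (Rsq = 1): dosage equals truth."""
    cfg = SimConfig(n=5000, maf_range=(0.2, 0.2), rsq_range=(1.0, 1.0))
    return simulate_imputed_variant(cfg, seed=43)


@pytest.fixture(scope="session")
def quant_pheno(mid_variant):
    return simulate_quantitative(mid_variant.g_true, beta=0.1, seed=7)


@pytest.fixture(scope="session")
def binary_pheno(mid_variant):
    return simulate_binary(mid_variant.g_true, beta=0.2, prevalence=0.3, seed=8)
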