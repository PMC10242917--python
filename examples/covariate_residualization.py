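"""Covariate adjustment by residualization before single-variant testing.

The four tests are covariate-free by design; real analyses (e.g. lipid traits
against age, sex and ancestry principal components) first regress the
phenotype on the covariates and test the residuals.
"""
import numpy as np

import imputassoc as ia
from imputassoc.types import PhenotypeSet, SimConfig

rng = np.random.default_rng(3)
n = 5000
cfg = SimConfig(n=n, maf_range=(0.05, 0.05), rsq_range=(0.8, 0.8))
v = ia.simulate_imputed_variant(cfg, seed=4)

age = rng.uniform(40, 70, n)
sex = rng.integers(0, 2, n).astype(float)
pcs = rng.standard_normal((n, 2))
covariates = np.column_stack([age, sex, pcs])
y = 0.02 * age + 0.3 * sex + 0.1 * v.g_true + rng.standard_normal(n)

raw = ia.test_dosage(PhenotypeSet(y, "quantitative"), v)
resid = ia.residualize(y, covariates)
adj = ia.test_dosage(PhenotypeSet(resid, "quantitative"), v)

print(f"unadjusted : beta={raw.beta_hat:.4f}  p={raw.p_value:.3e}")
print(f"adjusted   : beta={adj.beta_hat:.4f}  p={adj.p_value:.3e}")
print("\nResidualizing removes covariate variance from the phenotype, sharpening")
print("the genetic signal (smaller residual variance, smaller p) without")
print("changing the target of inference for covariate-independent genotypes.")
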