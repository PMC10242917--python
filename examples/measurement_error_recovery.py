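"""Regression-dilution correction by conditional multiple imputation.

Generates data under the classical measurement-error model the conditional MI
is built on: a latent Gaussian exposure G, two noisy replicates (playing the
roles of dosage and best-guess genotype), and an outcome y = 0.5 G + noise.
Naive regression on a replicate attenuates the slope by
var(G) / (var(G) + var(error)); the SMCFCS imputation recovers it.
"""
import numpy as np

import imputassoc as ia
from imputassoc.glm import ols_fit
from imputassoc.types import PhenotypeSet, SMCFCSConfig

rng = np.random.default_rng(1)
n = 5000
G = rng.normal(1.0, 1.0, n)
d = G + rng.normal(0, 0.3, n)
w = G + rng.normal(0, 0.3, n)
yv = 0.5 * G + rng.standard_normal(n)

naive = ols_fit(yv, d)
imps = ia.smcfcs_impute(PhenotypeSet(yv, "quantitative"), d, w, SMCFCSConfig(m=5, seed=2))
fits = [ols_fit(yv, g) for g in imps]
pooled = ia.rubin_pool([f.beta1 for f in fits], [f.se for f in fits])

print(f"generative slope          : 0.500")
print(f"naive slope on replicate  : {naive.beta1:.3f}  (attenuation ~ 1/(1+0.09) = {1/1.09:.3f})")
print(f"conditional-MI pooled slope: {pooled.q_bar:.3f} +/- {pooled.t_var**0.5:.3f}")
print("\nThe pooled estimate should sit within a few percent of 0.5, while the")
print("naive estimate is biased towards zero by the measurement error.")
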