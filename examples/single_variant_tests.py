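"""Run all four association tests on one simulated imputed variant.

Simulates a common variant (MAF 0.2) with moderate imputation quality
(true Rsq ~ 0.7), a quantitative trait with a real per-allele effect, and
prints the per-method estimate, standard error and p-value.  Dosage, MRM and
the conditional MI (SMCFCS) should agree closely; unconditional MI typically
reports a weaker, attenuated signal because its genotype draws ignore the
outcome.
"""
import imputassoc as ia
from imputassoc.types import SimConfig, SMCFCSConfig

cfg = SimConfig(n=20_000, maf_range=(0.2, 0.2), rsq_range=(0.7, 0.7))
v = ia.simulate_imputed_variant(cfg, seed=108)
y = ia.simulate_quantitative(v.g_true, beta=0.08, seed=208)

print(f"variant: MAF={v.maf:.3f}  true Rsq={v.rsq_true:.3f}  estimated Rsq={v.rsq_est:.3f}")
print(f"{'method':<8} {'beta':>8} {'se':>8} {'p':>12}")
results = [
    ia.test_dosage(y, v),
    ia.test_unconditional_mi(y, v, m=5, seed=308),
    ia.test_mrm(y, v),
    ia.test_smcfcs(y, v, SMCFCSConfig(seed=408)),
]
for r in results:
    print(f"{r.method:<8} {r.beta_hat:8.4f} {r.se:8.4f} {r.p_value:12.3e}")
print("\nThe generative slope is 0.08 per allele.  Dosage, MRM and the conditional")
print("MI estimate it without systematic bias (with calibrated posteriors,")
print("imputation costs precision, not bias), whereas unconditional MI is")
print("attenuated by roughly the Rsq (~0.7) AND carries inflated uncertainty -")
print("hence its visibly weaker p-value.")
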