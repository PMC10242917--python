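"""Desk-scale power comparison at genome-wide significance.

Each simulated variant receives its own effect size drawn from |N(0, 1)|
restricted to an odds-ratio bin; binary phenotypes are generated from the
*true* genotypes (prevalence 0.2) and the tests only see the imputed data.
Power is the fraction of variants with p < 5e-8.
"""
import imputassoc as ia
from imputassoc.types import BinSpec, SimConfig

cfg = SimConfig(n=20_000, maf_range=(0.01, 0.1), rsq_range=(0.6, 0.8),
                trait_type="binary", prevalence=0.2, n_variants=60, seed=9)
bins = [BinSpec((0.01, 0.1), (0.6, 0.8), (1.6, 1.8)),
        BinSpec((0.01, 0.1), (0.6, 0.8), (2.0, 3.0))]
res = ia.run_power_experiment(cfg, methods=["dosage", "umi", "smcfcs"], bins=bins, alpha=5e-8)
print(res.table[["bin", "method", "value", "mc_se", "n_used"]].to_string(index=False))
print("\n'value' is power at alpha = 5e-8.  Dosage and the conditional MI track each")
print("other closely; unconditional MI loses power in this poorly-imputed bin.")
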