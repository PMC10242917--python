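"""Tests for the regression backend, genotype draws, and Rubin pooling."""
import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st
from scipy import stats

import imputassoc as ia
from imputassoc.glm import logistic_fit, ols_fit
from imputassoc.types import DomainError, PhenotypeSet


class TestFitGLM:
    def test_noiseless_linear_fit_exact(self):
        rng = np.random.default_rng(0)
        x = rng.random(200)
        y = PhenotypeSet(2.0 * x + 1.0, "quantitative")
        fit = ia.fit_glm(y, x)
        assert fit.beta1 == pytest.approx(2.0, abs=1e-10)
        assert fit.p_value < 1e-10

    def test_constant_predictor_rejected(self):
        y = PhenotypeSet(np.random.default_rng(1).standard_normal(100), "quantitative")
        with pytest.raises(DomainError):
            ia.fit_glm(y, np.ones(100))

    @pytest.mark.parametrize("trait", ["quantitative", "binary"])
    def test_matches_statsmodels(self, trait):
        """The in-house OLS/Newton fits agree with statsmodels to high precision."""
        rng = np.random.default_rng(2)
        for rep in range(3):
            x = rng.choice([0.0, 1.0, 2.0], size=800, p=[0.5, 0.4, 0.1]) + 0.05 * rng.random(800)
            if trait == "quantitative":
                yv = 0.15 * x + rng.standard_normal(800)
                ours = ols_fit(yv, x)
                ref = sm.OLS(yv, sm.add_constant(x)).fit()
            else:
                pr = 1 / (1 + np.exp(-(-0.4 + 0.3 * x)))
                yv = (rng.random(800) < pr).astype(float)
                ours = logistic_fit(yv, x)
                ref = sm.Logit(yv, sm.add_constant(x)).fit(disp=0)
            assert ours.beta1 == pytest.approx(ref.params[1], rel=1e-6)
            assert ours.se == pytest.approx(ref.bse[1], rel=1e-5)
            assert ours.p_value == pytest.approx(ref.pvalues[1], rel=1e-4, abs=1e-12)

    @pytest.mark.parametrize("trait", ["quantitative", "binary"])
    def test_null_wald_p_uniform(self, trait):
        """Wald p-values are uniform under the null for both trait types."""
        rng = np.random.default_rng(3)
        pvals = []
        for _ in range(400):
            x = rng.choice([0.0, 1.0, 2.0], size=300, p=[0.64, 0.32, 0.04])
            if trait == "quantitative":
                fit = ols_fit(rng.standard_normal(300), x)
            else:
                fit = logistic_fit((rng.random(300) < 0.5).astype(float), x)
            if fit.converged:
                pvals.append(fit.p_value)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_separation_flagged_not_raised(self):
        y = np.array([0.0] * 50 + [1.0] * 50)
        x = np.array([0.0] * 50 + [1.0] * 50)
        fit = logistic_fit(y, x)
        assert not fit.converged
        assert np.isnan(fit.p_value)


class TestDosage:
    def test_equals_truth_fit_when_rsq_one(self, perfect_variant):
        y = ia.simulate_quantitative(perfect_variant.g_true, 0.05, seed=5)
        res = ia.test_dosage(y, perfect_variant)
        ref = ols_fit(y.y, perfect_variant.g_true.astype(float))
        assert res.p_value == ref.p_value
        assert res.beta_hat == ref.beta1
        assert res.statistic == pytest.approx(res.beta_hat / res.se, abs=1e-9)

    def test_worked_example_against_oracle(self):
        """A tiny frozen dataset: dosage test matches statsmodels to 1e-8."""
        rng = np.random.default_rng(1234)
        gp = rng.dirichlet([2.0, 3.0, 1.0], size=20)
        d = gp[:, 1] + 2 * gp[:, 2]
        yv = rng.standard_normal(20) + 0.3 * d
        v = ia.ImputedVariant("toy", gp, d, np.argmax(gp, 1), maf=0.3)
        res = ia.test_dosage(PhenotypeSet(yv, "quantitative"), v)
        ref = sm.OLS(yv, sm.add_constant(d)).fit()
        assert res.p_value == pytest.approx(ref.pvalues[1], abs=1e-8)

    def test_null_type1_error_calibrated(self):
        """Empirical type-I error of the dosage test at alpha = 0.05."""
        rng = np.random.default_rng(6)
        cfg = ia.SimConfig(n=2000, maf_range=(0.05, 0.05), rsq_range=(0.9, 0.9))
        v = ia.simulate_imputed_variant(cfg, seed=7)
        rejections = 0
        n_rep = 500
        for _ in range(n_rep):
            y = PhenotypeSet(rng.standard_normal(v.n), "quantitative")
            if ia.test_dosage(y, v).p_value < 0.05:
                rejections += 1
        assert abs(rejections / n_rep - 0.05) < 0.04  # ~4 MC SEs


class TestDrawGenotypes:
    def test_degenerate_rows_deterministic(self):
        gp = np.tile([0.0, 1.0, 0.0], (50, 1))
        assert np.all(ia.draw_genotypes(gp, seed=1) == 1)

    def test_categorical_frequencies(self):
        gp = np.tile([0.2, 0.5, 0.3], (100_000, 1))
        g = ia.draw_genotypes(gp, seed=2)
        for k, pk in enumerate([0.2, 0.5, 0.3]):
            assert abs(np.mean(g == k) - pk) < 0.006

    def test_seeded_reproducibility(self, mid_variant):
        a = ia.draw_genotypes(mid_variant.gp, seed=3)
        b = ia.draw_genotypes(mid_variant.gp, seed=3)
        assert np.array_equal(a, b)


class TestRubinPool:
    def test_hand_computed_example(self):
        """Pooling (0.10, 0.14, 0.12) with common se 0.05, frozen by hand."""
        pooled = ia.rubin_pool([0.10, 0.14, 0.12], [0.05, 0.05, 0.05])
        assert pooled.q_bar == pytest.approx(0.12, abs=1e-12)
        assert pooled.w_bar == pytest.approx(0.0025, abs=1e-12)
        assert pooled.b == pytest.approx(0.0004, abs=1e-12)
        assert pooled.t_var == pytest.approx(0.0025 + (4 / 3) * 0.0004, abs=1e-12)
        assert pooled.df == pytest.approx(64.6953125, abs=1e-8)
        assert pooled.p_value == pytest.approx(0.03299385734146285, abs=1e-10)

    def test_zero_between_variance_reduces_to_single_fit(self):
        pooled = ia.rubin_pool([0.1, 0.1, 0.1], [0.04, 0.04, 0.04])
        assert pooled.b == 0.0
        assert pooled.t_var == pooled.w_bar
        assert np.isinf(pooled.df)
        assert pooled.p_value == pytest.approx(2 * stats.norm.sf(0.1 / 0.04), abs=1e-12)

    def test_df_limit_large_between_variance(self):
        pooled = ia.rubin_pool([0.0, 10.0, -10.0], [1e-6, 1e-6, 1e-6])
        assert pooled.df == pytest.approx(2.0, rel=1e-6)

    def test_barnard_rubin_adjustment_caps_df(self):
        """The small-sample adjustment never exceeds the classic df and is
        bounded by the complete-data df."""
        classic = ia.rubin_pool([0.10, 0.14, 0.12], [0.05] * 3)
        adjusted = ia.rubin_pool([0.10, 0.14, 0.12], [0.05] * 3, n_obs=30)
        assert adjusted.df < classic.df
        assert adjusted.df < 30 - 2
        assert adjusted.p_value > classic.p_value  # heavier tails
        # b = 0 with finite n: df falls back to the complete-data df
        degenerate = ia.rubin_pool([0.1] * 3, [0.05] * 3, n_obs=30)
        assert degenerate.df == pytest.approx(28 * 29 / 31, rel=1e-12)

    def test_too_few_imputations(self):
        with pytest.raises(DomainError):
            ia.rubin_pool([0.1], [0.05])

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(
        q=st.lists(st.floats(-2, 2), min_size=2, max_size=10),
        s=st.floats(0.01, 1.0),
    )
    def test_total_variance_dominates_within(self, q, s):
        pooled = ia.rubin_pool(q, [s] * len(q))
        assert pooled.t_var >= pooled.w_bar - 1e-15
        assert pooled.b >= 0

    def test_p_monotone_in_between_variance(self):
        """Holding q_bar and w_bar fixed, more imputation disagreement can only
        weaken the evidence."""
        spreads = [0.0, 0.01, 0.05, 0.1]
        ps = []
        for d in spreads:
            pooled = ia.rubin_pool([0.2 - d, 0.2, 0.2 + d], [0.05] * 3)
            ps.append(pooled.p_value)
        assert all(p2 >= p1 - 1e-12 for p1, p2 in zip(ps, ps[1:]))


class TestUnconditionalMI:
    def test_degenerate_posteriors_reduce_to_truth_fit(self, perfect_variant):
        y = ia.simulate_quantitative(perfect_variant.g_true, 0.08, seed=9)
        res = ia.test_unconditional_mi(y, perfect_variant, m=5, seed=10)
        ref = ols_fit(y.y, perfect_variant.g_true.astype(float))
        # all M draws identical -> b = 0 -> z test on the single-fit estimate
        assert res.beta_hat == pytest.approx(ref.beta1, abs=1e-12)
        assert res.m_used == 5
        assert res.p_value == pytest.approx(2 * stats.norm.sf(abs(ref.statistic)), abs=1e-12)

    def test_seed_stability_for_moderate_signal(self, mid_variant):
        """Different seeds give different but broadly consistent evidence."""
        y = ia.simulate_quantitative(mid_variant.g_true, 0.1, seed=11)
        logs = [
            np.log10(ia.test_unconditional_mi(y, mid_variant, seed=s).p_value)
            for s in range(6)
        ]
        assert len(set(logs)) > 1  # stochastic method
        assert max(logs) - min(logs) < 1.5

    def test_monomorphic_draws_dropped(self):
        # near-certain all-reference posteriors: most draws are monomorphic
        gp = np.tile([0.9999, 0.0001, 0.0], (500, 1))
        d = gp[:, 1] + 2 * gp[:, 2]
        v = ia.ImputedVariant("rare", gp, d, np.zeros(500, dtype=int), maf=0.01)
        y = PhenotypeSet(np.random.default_rng(12).standard_normal(500), "quantitative")
        res = ia.test_unconditional_mi(y, v, m=5, seed=13)
        assert res.m_used is not None and res.m_used <= 5
        if res.m_used < 2:
            assert not res.converged
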