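"""Unit and property tests for the synthetic imputed-genotype generator."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import imputassoc as ia
from imputassoc.simdata import NoiseCalibrator, _rsq_given_noise, posterior_given_signal
from imputassoc.types import DomainError, UndefinedQualityError


class TestTrueGenotypes:
    def test_hwe_frequencies(self):
        g = ia.sample_true_genotypes(0.1, 100_000, seed=1)
        # heterozygote fraction 2p(1-p) = 0.18
        assert abs(np.mean(g == 1) - 0.18) < 0.01
        g5 = ia.sample_true_genotypes(0.5, 100_000, seed=2)
        assert abs(g5.mean() - 1.0) < 0.02

    def test_rare_limit_mostly_ref(self):
        g = ia.sample_true_genotypes(1e-9, 100, seed=3)
        assert np.all(g == 0)

    def test_invalid_maf(self):
        with pytest.raises(DomainError):
            ia.sample_true_genotypes(0.6, 10, seed=0)
        with pytest.raises(DomainError):
            ia.sample_true_genotypes(0.0, 10, seed=0)

    def test_seed_reproducibility(self):
        a = ia.sample_true_genotypes(0.2, 1000, seed=11)
        b = ia.sample_true_genotypes(0.2, 1000, seed=11)
        assert np.array_equal(a, b)


class TestPosteriors:
    def test_noiseless_degenerate(self):
        gp = ia.posteriors_from_signal(2, nu=0.0, maf=0.2, seed=0)
        assert np.allclose(gp, [[0.0, 0.0, 1.0]])

    def test_bayes_formula_at_fixed_signal(self):
        # HWE prior (0.64, 0.32, 0.04) at maf 0.2 combined with a Gaussian
        # likelihood of sd 0.5 centred at signal 1.0; triplet frozen from a
        # hand evaluation of prior_k * exp(-(1-k)^2 / (2 * 0.25)), normalised
        gp = posterior_given_signal(np.array([1.0]), nu=0.5, maf=0.2)[0]
        assert np.allclose(gp, [0.21021528, 0.77664626, 0.01313846], atol=1e-7)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        g=st.integers(0, 2),
        nu=st.floats(0.0, 3.0),
        maf=st.floats(0.01, 0.5),
        seed=st.integers(0, 2**20),
    )
    def test_normalization_and_dosage_identity(self, g, nu, maf, seed):
        gp = ia.posteriors_from_signal(g, nu, maf, seed=seed)
        assert abs(gp.sum() - 1.0) < 1e-12
        assert np.all(gp >= 0) and np.all(gp <= 1)
        d = gp[0, 1] + 2 * gp[0, 2]
        assert 0.0 <= d <= 2.0


class TestNoiseCalibration:
    def test_perfect_imputation_limit(self):
        assert ia.calibrate_noise(0.2, 1.0, seed=0) < 1e-3

    def test_round_trip(self):
        nu = ia.calibrate_noise(0.2, 0.7, tol=0.02, seed=1)
        rng = np.random.default_rng(99)
        g = ia.sample_true_genotypes(0.2, 100_000, rng)
        gp = ia.posteriors_from_signal(g, nu, 0.2, rng)
        d = gp[:, 1] + 2 * gp[:, 2]
        achieved = np.corrcoef(d, g)[0, 1] ** 2
        assert 0.66 <= achieved <= 0.74

    @pytest.mark.parametrize("maf", [0.05, 0.2, 0.4])
    @pytest.mark.parametrize("target", [0.4, 0.7, 0.95])
    def test_round_trip_grid(self, maf, target):
        nu = ia.calibrate_noise(maf, target, tol=0.005, seed=5)
        rng = np.random.default_rng(hash((maf, target)) % 2**31)
        g = ia.sample_true_genotypes(maf, 100_000, rng)
        gp = ia.posteriors_from_signal(g, nu, maf, rng)
        d = gp[:, 1] + 2 * gp[:, 2]
        assert abs(np.corrcoef(d, g)[0, 1] ** 2 - target) < 0.03

    def test_rsq_monotone_in_noise(self):
        rng = np.random.default_rng(3)
        g = ia.sample_true_genotypes(0.2, 50_000, rng)
        z = rng.standard_normal(50_000)
        rsqs = [_rsq_given_noise(g, z, nu, 0.2) for nu in np.linspace(0.05, 2.0, 10)]
        diffs = np.diff(rsqs)
        assert np.all(diffs <= 0.01)

    def test_interpolating_calibrator_matches_bisection(self):
        cal = NoiseCalibrator((0.05, 0.3), (0.5, 0.9), seed=0, n_maf=6, n_rsq=6, n_mc=20_000)
        rng = np.random.default_rng(17)
        g = ia.sample_true_genotypes(0.12, 100_000, rng)
        gp = ia.posteriors_from_signal(g, cal(0.12, 0.7), 0.12, rng)
        d = gp[:, 1] + 2 * gp[:, 2]
        assert abs(np.corrcoef(d, g)[0, 1] ** 2 - 0.7) < 0.03


class TestEstimatedRsq:
    def test_true_genotypes_give_unity(self):
        g = ia.sample_true_genotypes(0.3, 50_000, seed=21).astype(float)
        assert abs(ia.estimated_rsq(g) - 1.0) < 0.02

    def test_monomorphic_errors(self):
        with pytest.raises(UndefinedQualityError):
            ia.estimated_rsq(np.full(100, 0.4))

    def test_tracks_true_rsq(self):
        cfg = ia.SimConfig(n=100_000, maf_range=(0.2, 0.2), rsq_range=(0.6, 0.6))
        v = ia.simulate_imputed_variant(cfg, seed=31)
        assert abs(v.rsq_est - 0.6) < 0.1


class TestConcordanceFilter:
    @pytest.mark.parametrize(
        "est,true,expected",
        [
            (0.6, 0.6, True),
            (0.71, 0.6, True),   # 18.3% difference
            (0.73, 0.6, False),  # 21.7% difference
            (0.48, 0.6, False),  # exactly 20% is NOT < 20%
        ],
    )
    def test_boundary_semantics(self, est, true, expected):
        assert ia.rsq_concordance_filter(est, true) is expected


class TestSimulatedVariant:
    def test_perfect_rsq_degenerate(self, perfect_variant):
        v = perfect_variant
        assert np.all(np.isin(v.gp, (0.0, 1.0)))
        assert np.array_equal(v.dosage, v.g_true.astype(float))
        v.validate()

    def test_allele_frequency_matches_maf(self):
        cfg = ia.SimConfig(n=50_000, maf_range=(0.1, 0.1), rsq_range=(0.8, 0.8))
        v = ia.simulate_imputed_variant(cfg, seed=13)
        assert abs(v.g_true.mean() / 2 - 0.1) < 0.006

    def test_rsq_lands_near_target(self, mid_variant):
        assert abs(mid_variant.rsq_true - 0.7) < 0.04
        mid_variant.validate()


class TestPhenotypes:
    def test_null_quantitative_standard_normal(self):
        g = ia.sample_true_genotypes(0.2, 10_000, seed=41)
        y = ia.simulate_quantitative(g, 0.0, seed=42)
        assert abs(np.var(y.y) - 1.0) < 0.05
        assert abs(np.mean(y.y)) < 0.04

    def test_quantitative_slope_recovered(self):
        g = ia.sample_true_genotypes(0.2, 100_000, seed=43)
        y = ia.simulate_quantitative(g, 0.3, seed=44)
        slope = np.polyfit(g.astype(float), y.y, 1)[0]
        assert abs(slope - 0.3) < 0.02

    def test_quantitative_deterministic(self):
        g = ia.sample_true_genotypes(0.2, 1000, seed=45)
        y1 = ia.simulate_quantitative(g, 0.1, seed=46)
        y2 = ia.simulate_quantitative(g, 0.1, seed=46)
        assert np.array_equal(y1.y, y2.y)

    def test_null_binary_prevalence(self):
        g = ia.sample_true_genotypes(0.2, 50_000, seed=47)
        y = ia.simulate_binary(g, 0.0, prevalence=0.2, seed=48)
        assert abs(y.y.sum() - 10_000) < 360  # 4 binomial SEs

    def test_binary_all_ref_is_exact_prevalence(self):
        # with g = 0 everywhere the disease probability is the prevalence itself
        g = np.zeros(200_000, dtype=np.int8)
        y = ia.simulate_binary(g, beta=5.0, prevalence=0.3, seed=49)
        assert abs(y.y.mean() - 0.3) < 0.005

    def test_effect_sizes_half_normal(self):
        b = ia.draw_effect_size(seed=50, size=100_000)
        assert np.all(b >= 0)
        assert abs(b.mean() - np.sqrt(2 / np.pi)) < 0.008
        assert ia.draw_effect_size(seed=51) == ia.draw_effect_size(seed=51)

    def test_effect_size_in_range(self):
        b = ia.draw_effect_size_in_range(52, np.log(1.2), np.log(1.4), size=5000)
        assert np.all((b > np.log(1.2)) & (b <= np.log(1.4) + 1e-12))


def test_null_pvalues_uniform_over_many_variants():
    """Null phenotypes are independent of the posteriors: dosage-regression
    p-values over many simulated null variants follow a uniform law."""
    cal = NoiseCalibrator((0.1, 0.3), (0.5, 0.9), seed=60, n_maf=5, n_rsq=5, n_mc=20_000)
    from imputassoc.simdata import _materialize_variant
    from imputassoc.glm import ols_fit

    pvals = []
    root = np.random.SeedSequence(61)
    for ss in root.spawn(1000):
        rng = np.random.default_rng(ss)
        maf = np.exp(rng.uniform(np.log(0.1), np.log(0.3)))
        target = rng.uniform(0.5, 0.9)
        v = _materialize_variant(2000, maf, cal(maf, target), rng, "v")
        y = rng.standard_normal(2000)
        pvals.append(ols_fit(y, v.dosage).p_value)
    ks = stats.kstest(pvals, "uniform")
    assert ks.pvalue > 0.01
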