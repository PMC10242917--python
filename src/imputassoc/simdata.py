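"""Synthetic imputed-genotype datasets with controllable MAF and imputation quality.

The generator stands in for cohort data in which a sequencing-based "truth"
genotype exists alongside imputed posteriors.  True genotypes are drawn under
Hardy-Weinberg equilibrium at a chosen minor-allele frequency.  Imputation
error is emulated by a one-parameter Gaussian-signal model: each individual's
latent imputation signal is ``s = g + Normal(0, nu^2)`` and the reported
genotype posterior is the Bayes posterior over {0, 1, 2} combining a HWE prior
with a Gaussian likelihood of sd ``nu``.  The single noise parameter ``nu``
gives a monotone, calibratable dial for the true imputation Rsq
(cor^2 between dosage and truth) while producing realistically asymmetric
posteriors at low MAF.

Phenotypes follow the standard single-variant generative models: quantitative
``y = beta * g + Normal(0, 1)`` and binary via a logistic model whose
intercept is anchored at ``log(tau / (1 - tau))`` for disease prevalence
``tau``.
"""
from __future__ import annotations

from typing import Optional, Tuple, Union

import numpy as np

from .types import (
    CalibrationError,
    DomainError,
    GENOTYPE_LEVELS,
    ImputedVariant,
    PhenotypeSet,
    SimConfig,
    UndefinedQualityError,
)

RngLike = Union[int, np.random.Generator, np.random.SeedSequence]


def as_rng(seed: RngLike) -> np.random.Generator:
    """Coerce an int / SeedSequence / Generator into a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def hwe_probs(maf: float) -> np.ndarray:
    """Hardy-Weinberg genotype probabilities ((1-p)^2, 2p(1-p), p^2)."""
    if not (0.0 < maf <= 0.5):
        raise DomainError(f"maf must lie in (0, 0.5], got {maf}")
    q = 1.0 - maf
    return np.array([q * q, 2.0 * maf * q, maf * maf])


def sample_true_genotypes(maf: float, n: int, seed: RngLike) -> np.ndarray:
    """Draw n i.i.d. HWE genotypes (alt-allele counts 0/1/2) at the given MAF."""
    if n < 1:
        raise DomainError("n must be >= 1")
    probs = hwe_probs(maf)
    rng = as_rng(seed)
    # two Bernoulli(maf) allele draws per individual == HWE genotype
    return rng.choice(3, size=n, p=probs).astype(np.int8)


def posterior_given_signal(s: np.ndarray, nu: float, maf: float) -> np.ndarray:
    """Bayes posterior over genotypes given latent signal(s) ``s``.

    Combines the HWE prior at ``maf`` with a Gaussian likelihood centred at
    each genotype with sd ``nu``.  Deterministic; vectorised over ``s``.
    Returns an (n, 3) matrix of posteriors (rows sum to 1).
    """
    s = np.atleast_1d(np.asarray(s, dtype=float))
    prior = hwe_probs(maf)
    if nu < 1e-8:  # numerically degenerate likelihood
        # degenerate likelihood: posterior concentrates at the nearest genotype
        k = np.clip(np.rint(s), 0, 2).astype(int)
        out = np.zeros((len(s), 3))
        out[np.arange(len(s)), k] = 1.0
        return out
    # log posterior up to a constant; stabilise with per-row max subtraction
    logpost = np.log(prior)[None, :] - (s[:, None] - GENOTYPE_LEVELS[None, :]) ** 2 / (2.0 * nu * nu)
    logpost -= logpost.max(axis=1, keepdims=True)
    post = np.exp(logpost)
    post /= post.sum(axis=1, keepdims=True)
    return post


def posteriors_from_signal(
    g: Union[int, np.ndarray], nu: float, maf: float, seed: RngLike = 0
) -> np.ndarray:
    """Draw latent signals ``s = g + Normal(0, nu^2)`` and return Bayes posteriors.

    ``g`` may be a scalar genotype or a vector; the result is (n, 3).
    ``nu = 0`` returns degenerate triplets at the true genotypes.
    """
    if nu < 0:
        raise DomainError("nu must be >= 0")
    g = np.atleast_1d(np.asarray(g, dtype=float))
    if not np.all(np.isin(g, (0.0, 1.0, 2.0))):
        raise DomainError("genotypes must be in {0, 1, 2}")
    if nu < 1e-8:
        out = np.zeros((len(g), 3))
        out[np.arange(len(g)), g.astype(int)] = 1.0
        return out
    rng = as_rng(seed)
    s = g + nu * rng.standard_normal(len(g))
    return posterior_given_signal(s, nu, maf)


def _rsq_given_noise(g: np.ndarray, z: np.ndarray, nu: float, maf: float) -> float:
    """Achieved true Rsq for noise ``nu`` with frozen genotype/noise draws."""
    if nu == 0.0:
        return 1.0
    post = posterior_given_signal(g + nu * z, nu, maf)
    d = post[:, 1] + 2.0 * post[:, 2]
    if np.var(d) == 0.0:
        return 0.0
    return float(np.corrcoef(d, g)[0, 1] ** 2)


def calibrate_noise(
    maf: float,
    target_rsq: float,
    tol: float = 0.01,
    seed: RngLike = 0,
    n_mc: int = 50_000,
    nu_max: float = 32.0,
) -> float:
    """Find the signal-noise sd ``nu`` whose true Rsq matches ``target_rsq``.

    Uses bisection with common random numbers (the genotype vector and the
    standard-normal noise draws are frozen across ``nu`` evaluations), which
    makes the achieved Rsq a deterministic, monotone-decreasing function of
    ``nu`` for the given Monte-Carlo sample of ``n_mc`` individuals.
    """
    if not (0.0 < target_rsq <= 1.0):
        raise DomainError("target_rsq must lie in (0, 1]")
    rng = as_rng(seed)
    g = sample_true_genotypes(maf, n_mc, rng)
    z = rng.standard_normal(n_mc)
    if target_rsq >= 1.0 - 1e-12:
        return 0.0
    lo, hi = 0.0, 0.25
    r_hi = _rsq_given_noise(g, z, hi, maf)
    while r_hi > target_rsq:
        hi *= 2.0
        if hi > nu_max:
            raise CalibrationError(
                f"target_rsq={target_rsq} unreachable: achieved Rsq range "
                f"[{r_hi:.4f}, 1.0] within nu <= {nu_max}"
            )
        r_hi = _rsq_given_noise(g, z, hi, maf)
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        r_mid = _rsq_given_noise(g, z, mid, maf)
        if abs(r_mid - target_rsq) < tol:
            return mid
        if r_mid > target_rsq:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-6:
            break
    return 0.5 * (lo + hi)


class NoiseCalibrator:
    """Cache of calibrated noise levels on a (MAF, Rsq) grid.

    Experiment drivers simulate thousands of variants whose (MAF, target Rsq)
    pairs fall in a rectangle; re-running the bisection per variant would
    dominate runtime.  This helper calibrates ``nu`` on a small log-MAF x Rsq
    grid once and bilinearly interpolates, which keeps the achieved Rsq within
    about +/-0.02 of target across the bins used here.
    """

    def __init__(
        self,
        maf_range: Tuple[float, float],
        rsq_range: Tuple[float, float],
        seed: RngLike = 0,
        n_maf: int = 8,
        n_rsq: int = 8,
        n_mc: int = 50_000,
    ):
        self.maf_grid = np.exp(
            np.linspace(np.log(maf_range[0]), np.log(max(maf_range[1], maf_range[0] * (1 + 1e-9))), n_maf)
        )
        rlo, rhi = rsq_range
        rhi = max(rhi, rlo + 1e-9)
        self.rsq_grid = np.linspace(rlo, rhi, n_rsq)
        rng = as_rng(seed)
        self.nu = np.empty((n_maf, n_rsq))
        for i, maf in enumerate(self.maf_grid):
            for j, rsq in enumerate(self.rsq_grid):
                self.nu[i, j] = calibrate_noise(maf, rsq, tol=0.005, seed=rng, n_mc=n_mc)

    def __call__(self, maf: float, target_rsq: float) -> float:
        li = np.log(np.clip(maf, self.maf_grid[0], self.maf_grid[-1]))
        lg = np.log(self.maf_grid)
        i = np.clip(np.searchsorted(lg, li) - 1, 0, len(lg) - 2)
        ti = 0.0 if lg[i + 1] == lg[i] else (li - lg[i]) / (lg[i + 1] - lg[i])
        r = np.clip(target_rsq, self.rsq_grid[0], self.rsq_grid[-1])
        j = np.clip(np.searchsorted(self.rsq_grid, r) - 1, 0, len(self.rsq_grid) - 2)
        tj = (
            0.0
            if self.rsq_grid[j + 1] == self.rsq_grid[j]
            else (r - self.rsq_grid[j]) / (self.rsq_grid[j + 1] - self.rsq_grid[j])
        )
        return float(
            (1 - ti) * (1 - tj) * self.nu[i, j]
            + ti * (1 - tj) * self.nu[i + 1, j]
            + (1 - ti) * tj * self.nu[i, j + 1]
            + ti * tj * self.nu[i + 1, j + 1]
        )


def estimated_rsq(dosage: np.ndarray) -> float:
    """Dosage-only imputation quality: Var(D) / (2 p (1 - p)), p = mean(D)/2.

    This is the MaCH/minimac convention for the estimated Rsq reported by
    imputation software; it requires a polymorphic dosage vector.
    """
    d = np.asarray(dosage, dtype=float)
    if len(d) < 2:
        raise DomainError("need at least 2 dosages")
    if np.ptp(d) == 0.0:
        raise UndefinedQualityError("estimated Rsq undefined for monomorphic dosage")
    v = float(np.var(d))
    p = float(np.mean(d)) / 2.0
    denom = 2.0 * p * (1.0 - p)
    if denom <= 0.0:
        raise UndefinedQualityError("estimated Rsq undefined for monomorphic dosage")
    return max(v / denom, 0.0)


def rsq_concordance_filter(rsq_est: float, rsq_true: float, max_pct_diff: float = 0.2) -> bool:
    """True iff |rsq_est - rsq_true| / rsq_true is strictly below ``max_pct_diff``."""
    if rsq_true <= 0:
        raise DomainError("rsq_true must be > 0")
    return abs(rsq_est - rsq_true) / rsq_true < max_pct_diff


def _sample_maf(rng: np.random.Generator, maf_range: Tuple[float, float], how: str) -> float:
    lo, hi = maf_range
    if lo == hi:
        return lo
    if how == "log_uniform":
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    return float(rng.uniform(lo, hi))


#: cap on the sampled target Rsq in top bins, avoiding an atom at exactly 1
_RSQ_TOP_CAP = 0.97


def simulate_imputed_variant(cfg: SimConfig, seed: RngLike, variant_id: str = "sim") -> ImputedVariant:
    """Simulate one imputed variant under ``cfg``; deterministic under the seed.

    MAF is drawn per ``cfg.maf_sampling`` within ``maf_range``; the target true
    Rsq is drawn uniformly in ``[low, min(high, 0.97)]`` (exactly 1 only when
    the range is degenerate at 1, which yields noiseless posteriors).
    """
    cfg.validate()
    rng = as_rng(seed)
    maf = _sample_maf(rng, cfg.maf_range, cfg.maf_sampling)
    rlo, rhi = cfg.rsq_range
    rhi_eff = max(rlo, min(rhi, _RSQ_TOP_CAP))
    if rlo >= 1.0:
        target_rsq = 1.0
    elif rlo == rhi_eff:
        target_rsq = rlo
    else:
        target_rsq = float(rng.uniform(rlo, rhi_eff))
    nu = 0.0 if target_rsq >= 1.0 else calibrate_noise(maf, target_rsq, seed=rng)
    return _materialize_variant(cfg.n, maf, nu, rng, variant_id)


def _materialize_variant(
    n: int, maf: float, nu: float, rng: np.random.Generator, variant_id: str
) -> ImputedVariant:
    """Draw truth genotypes and posteriors at a fixed noise level."""
    g = sample_true_genotypes(maf, n, rng)
    gp = posteriors_from_signal(g, nu, maf, rng)
    dosage = gp[:, 1] + 2.0 * gp[:, 2]
    best_guess = np.argmax(gp, axis=1).astype(np.int8)
    if np.var(dosage) > 0 and np.var(g.astype(float)) > 0:
        rsq_true = float(np.corrcoef(dosage, g)[0, 1] ** 2)
    else:
        rsq_true = 1.0 if nu == 0.0 else 0.0
    try:
        rsq_est = estimated_rsq(dosage)
    except UndefinedQualityError:
        rsq_est = float("nan")
    return ImputedVariant(
        variant_id=variant_id,
        gp=gp,
        dosage=dosage,
        best_guess=best_guess,
        maf=maf,
        g_true=g,
        rsq_true=rsq_true,
        rsq_est=rsq_est,
    )


def simulate_quantitative(g_true: np.ndarray, beta: float, seed: RngLike) -> PhenotypeSet:
    """Quantitative trait ``y = beta * g + Normal(0, 1)``."""
    if not np.isfinite(beta):
        raise DomainError("beta must be finite")
    rng = as_rng(seed)
    g = np.asarray(g_true, dtype=float)
    y = beta * g + rng.standard_normal(len(g))
    return PhenotypeSet(y=y, trait_type="quantitative")


def simulate_binary(g_true: np.ndarray, beta: float, prevalence: float, seed: RngLike) -> PhenotypeSet:
    """Binary trait from a logistic model anchored at the disease prevalence.

    ``P(y=1 | g) = expit(beta0 + beta * g)`` with ``beta0 = log(tau/(1-tau))``,
    so a null effect reproduces case fraction ``tau``.
    """
    if not (0.0 < prevalence < 1.0):
        raise DomainError("prevalence must lie in (0, 1)")
    rng = as_rng(seed)
    g = np.asarray(g_true, dtype=float)
    beta0 = np.log(prevalence / (1.0 - prevalence))
    eta = beta0 + beta * g
    pi = 1.0 / (1.0 + np.exp(-eta))
    y = (rng.random(len(g)) < pi).astype(float)
    return PhenotypeSet(y=y, trait_type="binary", prevalence=prevalence)


def draw_effect_size(seed: RngLike, size: Optional[int] = None) -> Union[float, np.ndarray]:
    """Per-variant effect size |N(0, 1)| (half-normal; strictly positive a.s.)."""
    rng = as_rng(seed)
    draws = np.abs(rng.standard_normal(size if size is not None else 1))
    return draws if size is not None else float(draws[0])


def draw_effect_size_in_range(
    seed: RngLike, lo: float, hi: float, size: Optional[int] = None
) -> Union[float, np.ndarray]:
    """|N(0,1)| effect size conditioned on ``lo < beta <= hi`` (inverse-CDF).

    Used by the power experiment to populate an effect-size bin: the bin's
    betas follow the half-normal law restricted to the bin.
    """
    from scipy.stats import norm

    if not (0.0 <= lo < hi):
        raise DomainError("need 0 <= lo < hi")
    rng = as_rng(seed)
    # half-normal CDF: F(x) = 2*Phi(x) - 1
    flo, fhi = 2.0 * norm.cdf(lo) - 1.0, 2.0 * norm.cdf(hi) - 1.0
    u = rng.uniform(flo, fhi, size=size if size is not None else 1)
    draws = norm.ppf((u + 1.0) / 2.0)
    return draws if size is not None else float(draws[0])
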