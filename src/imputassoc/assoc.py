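"""Single-variant association tests for imputed genotypes.

Four tests are provided, sharing one regression backend:

* ``test_dosage`` — regress the phenotype on the posterior-mean dosage
  ``D = p1 + 2 p2`` (linear for quantitative traits, logistic for binary).
* ``test_unconditional_mi`` — draw genotypes from the posteriors M times,
  fit each completed dataset, and pool with Rubin's rules.  The draws do not
  condition on the outcome ("improper" imputation), which is exactly the
  behaviour the method comparison here is designed to expose.
* ``test_mrm`` — mixture-of-regression-models likelihood-ratio test
  (see :mod:`imputassoc.mrm`).
* ``test_smcfcs`` — substantive-model-compatible conditional multiple
  imputation treating dosage and best-guess genotype as two noisy
  measurements of the truth (see :mod:`imputassoc.smcfcs`).
"""
from __future__ import annotations

from typing import Union

import numpy as np
from scipy import stats

from .glm import GLMFit, logistic_fit, ols_fit
from .simdata import RngLike, as_rng
from .types import AssocResult, DomainError, ImputedVariant, PhenotypeSet, RubinPooled

__all__ = [
    "fit_glm",
    "test_dosage",
    "draw_genotypes",
    "rubin_pool",
    "test_unconditional_mi",
    "test_mrm",
    "test_smcfcs",
]


def fit_glm(y: PhenotypeSet, x: np.ndarray) -> GLMFit:
    """Intercept + slope GLM of the phenotype on ``x`` with a Wald slope test.

    Quantitative traits use OLS (t reference, n-2 df); binary traits use
    maximum-likelihood logistic regression (z reference).
    """
    if y.trait_type == "binary":
        return logistic_fit(y.y, x)
    return ols_fit(y.y, x)


def _as_result(method: str, fit: GLMFit) -> AssocResult:
    return AssocResult(
        method=method,
        beta_hat=fit.beta1,
        se=fit.se,
        statistic=fit.statistic,
        df=fit.df,
        p_value=fit.p_value,
        converged=fit.converged,
    )


def test_dosage(y: PhenotypeSet, v: ImputedVariant) -> AssocResult:
    """Wald test of the phenotype on the imputed dosage."""
    return _as_result("dosage", fit_glm(y, v.dosage))


def draw_genotypes(gp: np.ndarray, seed: RngLike) -> np.ndarray:
    """Independent categorical genotype draws, one per sample, P(g=k) = gp[i, k]."""
    gp = np.asarray(gp, dtype=float)
    rng = as_rng(seed)
    u = rng.random(gp.shape[0])
    cum = np.cumsum(gp, axis=1)
    return (u[:, None] > cum[:, :2]).sum(axis=1).astype(np.int8)


def rubin_pool(
    estimates: np.ndarray, ses: np.ndarray, n_obs: "int | None" = None
) -> RubinPooled:
    """Combine M imputation-specific estimates and standard errors.

    Classic pooling: q_bar is the mean estimate, W the mean squared standard
    error, B the between-imputation variance of the estimates, and the total
    variance T = W + (1 + 1/M) B.  The reference distribution is t with
    df = (M-1) (1 + W / ((1 + 1/M) B))^2, degenerating to a normal when B = 0.

    Passing ``n_obs`` (the analysed sample size) switches on the
    Barnard-Rubin small-sample adjustment, which caps the df by the
    complete-data df: 1/df = 1/df_classic + 1/df_obs with
    df_obs = nu (nu + 1) / (nu + 3) * (1 - gamma), nu = n_obs - 2 and
    gamma the fraction of missing information (1 + 1/M) B / T.  Off by
    default; immaterial at biobank-scale n.
    """
    q = np.asarray(estimates, dtype=float)
    s = np.asarray(ses, dtype=float)
    m = len(q)
    if m < 2 or len(s) != m:
        raise DomainError("Rubin pooling needs M >= 2 estimates with matching ses")
    if np.any(s <= 0):
        raise DomainError("standard errors must be positive")
    q_bar = float(q.mean())
    w_bar = float((s * s).mean())
    b = float(q.var(ddof=1))
    if b < 1e-14 * max(w_bar, q_bar * q_bar):
        b = 0.0  # numerically identical estimates across imputations
    t_var = w_bar + (1.0 + 1.0 / m) * b
    stat = q_bar / np.sqrt(t_var)
    df = np.inf if b == 0.0 else (m - 1) * (1.0 + w_bar / ((1.0 + 1.0 / m) * b)) ** 2
    if n_obs is not None:
        nu_com = n_obs - 2
        gamma = (1.0 + 1.0 / m) * b / t_var
        df_obs = nu_com * (nu_com + 1.0) / (nu_com + 3.0) * (1.0 - gamma)
        df = 1.0 / (1.0 / df + 1.0 / df_obs) if np.isfinite(df) else df_obs
    if np.isinf(df):
        p = 2.0 * stats.norm.sf(abs(stat))
    else:
        p = 2.0 * stats.t.sf(abs(stat), df)
    return RubinPooled(q_bar, w_bar, b, float(t_var), float(df), float(p), m)


def _pooled_result(method: str, pooled: RubinPooled, m_used: int) -> AssocResult:
    se = float(np.sqrt(pooled.t_var))
    return AssocResult(
        method=method,
        beta_hat=pooled.q_bar,
        se=se,
        statistic=pooled.q_bar / se,
        df=pooled.df,
        p_value=pooled.p_value,
        converged=True,
        m_used=m_used,
    )


def test_unconditional_mi(
    y: PhenotypeSet, v: ImputedVariant, m: int = 5, seed: RngLike = 0
) -> AssocResult:
    """Unconditional multiple imputation: draw-genotypes, fit, Rubin-pool.

    Repetitions whose drawn genotype vector is monomorphic or whose fit does
    not converge (e.g. perfect separation at very low MAF) are dropped and
    ``m_used`` reduced; fewer than 2 usable repetitions yields a flagged
    non-converged result.
    """
    rng = as_rng(seed)
    est, ses = [], []
    for _ in range(m):
        g = draw_genotypes(v.gp, rng)
        if np.ptp(g) == 0:
            continue
        fit = fit_glm(y, g.astype(float))
        if fit.converged:
            est.append(fit.beta1)
            ses.append(fit.se)
    if len(est) < 2:
        return AssocResult("umi", np.nan, np.nan, np.nan, np.nan, np.nan, False, m_used=len(est))
    pooled = rubin_pool(np.array(est), np.array(ses))
    res = _pooled_result("umi", pooled, len(est))
    return res


# re-exported here so the four tests share one import surface
from .mrm import test_mrm  # noqa: E402
from .smcfcs import test_smcfcs  # noqa: E402
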