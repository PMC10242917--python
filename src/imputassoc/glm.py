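"""Fast single-covariate GLM fits (OLS and Newton-scoring logistic).

The experiment drivers fit tens of thousands of two-parameter models
(intercept + one genotype predictor), so the fits are implemented directly on
the closed-form OLS solution and Fisher-scoring iterations rather than going
through a general modelling framework.  Agreement with statsmodels is enforced
in the test suite.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .types import DomainError


@dataclass
class GLMFit:
    beta0: float
    beta1: float
    se: float
    statistic: float
    df: float  # +inf means a normal (z) reference
    p_value: float
    converged: bool
    loglik: float = float("nan")


def _check_x(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0.0:
        raise DomainError("predictor is constant; association test undefined")
    return x


def ols_fit(y: np.ndarray, x: np.ndarray) -> GLMFit:
    """OLS of y on [1, x]; Wald t-test on the slope with n - 2 df."""
    x = _check_x(x)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 10 or len(x) != n:
        raise DomainError("need length-matched y and x with n >= 10")
    xm, ym = x.mean(), y.mean()
    xc = x - xm
    sxx = float(xc @ xc)
    beta1 = float(xc @ (y - ym)) / sxx
    beta0 = ym - beta1 * xm
    resid = y - beta0 - beta1 * x
    rss = float(resid @ resid)
    df = n - 2
    sigma2 = rss / df
    se = np.sqrt(sigma2 / sxx)
    tstat = beta1 / se
    p = 2.0 * stats.t.sf(abs(tstat), df)
    # Gaussian log-likelihood at the MLE (sigma2_mle = rss / n)
    s2_mle = rss / n
    ll = -0.5 * n * (np.log(2.0 * np.pi * s2_mle) + 1.0)
    return GLMFit(beta0, beta1, float(se), float(tstat), float(df), float(p), True, float(ll))


def logistic_fit(
    y: np.ndarray,
    x: np.ndarray,
    max_iter: int = 30,
    tol: float = 1e-10,
    start: "tuple[float, float] | None" = None,
) -> GLMFit:
    """ML logistic regression of y on [1, x] by Fisher scoring; Wald z-test.

    Perfect separation / non-convergence is flagged (``converged=False`` with
    NaN p-value) rather than raised, mirroring how per-variant genome scans
    must tolerate occasional degenerate variants.
    """
    x = _check_x(x)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 10 or len(x) != n:
        raise DomainError("need length-matched y and x with n >= 10")
    ybar = y.mean()
    if ybar <= 0.0 or ybar >= 1.0:
        return GLMFit(np.nan, np.nan, np.nan, np.nan, np.inf, np.nan, False)
    if start is not None:
        b0, b1 = float(start[0]), float(start[1])
    else:
        b0, b1 = float(np.log(ybar / (1.0 - ybar))), 0.0
    converged = False
    i00 = i01 = i11 = 0.0
    for _ in range(max_iter):
        eta = np.clip(b0 + b1 * x, -30.0, 30.0)
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p)
        r = y - p
        s0, s1 = float(r.sum()), float(r @ x)
        i00 = float(w.sum())
        i01 = float(w @ x)
        i11 = float(w @ (x * x))
        det = i00 * i11 - i01 * i01
        if det <= 0 or not np.isfinite(det):
            break
        d0 = (i11 * s0 - i01 * s1) / det
        d1 = (i00 * s1 - i01 * s0) / det
        b0 += d0
        b1 += d1
        if max(abs(d0), abs(d1)) < tol:
            converged = True
            break
    if not converged or abs(b1) > 15.0 or not np.isfinite(b1):
        return GLMFit(b0, b1, np.nan, np.nan, np.inf, np.nan, False)
    det = i00 * i11 - i01 * i01
    se = np.sqrt(i00 / det)
    z = b1 / se
    p_val = 2.0 * stats.norm.sf(abs(z))
    eta = np.clip(b0 + b1 * x, -30.0, 30.0)
    ll = float(y @ eta - np.logaddexp(0.0, eta).sum())
    return GLMFit(b0, b1, float(se), float(z), np.inf, float(p_val), True, ll)
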