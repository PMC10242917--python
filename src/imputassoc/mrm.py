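"""Mixture-of-regression-models (MRM) likelihood-ratio association test.

The marginal likelihood of the phenotype is a three-component mixture over
the unobserved genotype, weighted by each sample's imputation posteriors
(p0, p1, p2).  For a quantitative trait the components are
Normal(beta0 + beta1*k, sigma2) for k in {0, 1, 2}; for a binary trait they
are Bernoulli with logit(pi_k) = beta0 + beta1*k.  Association is assessed by
a 1-df likelihood-ratio test of beta1 = 0; under the null the mixture
collapses, so the null maximum likelihood is available in closed form.

Maximisation uses BFGS with analytic gradients (posterior-responsibility
form), sigma2 optimised on the log scale, starting values from the dosage
regression, and up to three jittered restarts on non-convergence.
"""
from __future__ import annotations

from typing import Tuple

import numpy as np
from scipy import optimize, stats
from statsmodels.tools.numdiff import approx_hess1

from .glm import logistic_fit, ols_fit
from .types import AssocResult, DomainError, ImputedVariant, MRMFit, PhenotypeSet

_K = np.array([0.0, 1.0, 2.0])
_LOG2PI = np.log(2.0 * np.pi)


def _log_gp(gp: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.where(gp > 0.0, np.log(np.clip(gp, 1e-300, None)), -np.inf)


def mrm_loglik(fit: MRMFit, y: PhenotypeSet, gp: np.ndarray) -> float:
    """Evaluate the mixture log-likelihood at the parameters held in ``fit``."""
    if y.trait_type == "quantitative":
        if fit.sigma2 is None or fit.sigma2 <= 0:
            raise DomainError("quantitative MRM requires sigma2 > 0")
        ll, _ = _quant_ll_grad(
            np.array([fit.beta0, fit.beta1, np.log(fit.sigma2)]), y.y, _log_gp(gp), grad=False
        )
    else:
        ll, _ = _binary_ll_grad(np.array([fit.beta0, fit.beta1]), y.y, gp, _log_gp(gp), grad=False)
    return float(ll)


def _quant_ll_grad(params: np.ndarray, y: np.ndarray, log_gp: np.ndarray, grad: bool = True):
    b0, b1, log_s2 = params
    s2 = np.exp(log_s2)
    resid = y[:, None] - b0 - b1 * _K[None, :]  # (n, 3)
    logcomp = log_gp - resid * resid / (2.0 * s2) - 0.5 * (_LOG2PI + log_s2)
    mx = logcomp.max(axis=1, keepdims=True)
    w = np.exp(logcomp - mx)
    sw = w.sum(axis=1)
    ll = float((mx[:, 0] + np.log(sw)).sum())
    if not grad:
        return ll, None
    r = w / sw[:, None]  # responsibilities
    g0 = float((r * resid).sum()) / s2
    g1 = float((r * resid * _K[None, :]).sum()) / s2
    g2 = float((r * (resid * resid / (2.0 * s2) - 0.5)).sum())
    return ll, np.array([g0, g1, g2])


def _binary_ll_grad(params: np.ndarray, y: np.ndarray, gp: np.ndarray, log_gp: np.ndarray, grad: bool = True):
    b0, b1 = params
    eta = np.clip(b0 + b1 * _K, -30.0, 30.0)  # (3,)
    pi = 1.0 / (1.0 + np.exp(-eta))
    # log Bernoulli(y; pi_k) per sample and component
    logbern = y[:, None] * np.log(pi)[None, :] + (1.0 - y[:, None]) * np.log1p(-pi)[None, :]
    logcomp = log_gp + logbern
    mx = logcomp.max(axis=1, keepdims=True)
    w = np.exp(logcomp - mx)
    sw = w.sum(axis=1)
    ll = float((mx[:, 0] + np.log(sw)).sum())
    if not grad:
        return ll, None
    r = w / sw[:, None]
    dtheta = r * (y[:, None] - pi[None, :])  # d ll_i / d eta_k
    g0 = float(dtheta.sum())
    g1 = float((dtheta * _K[None, :]).sum())
    return ll, np.array([g0, g1])


def _null_loglik(y: PhenotypeSet) -> Tuple[float, float, float]:
    """Closed-form null (beta1 = 0) fit: the mixture collapses to one component.

    Returns (loglik, beta0_hat, sigma2_hat-or-nan).
    """
    yy = np.asarray(y.y, dtype=float)
    n = len(yy)
    if y.trait_type == "quantitative":
        mu = yy.mean()
        s2 = float(np.var(yy))
        ll = -0.5 * n * (_LOG2PI + np.log(s2) + 1.0)
        return ll, float(mu), s2
    pbar = yy.mean()
    pbar = min(max(pbar, 1e-12), 1 - 1e-12)
    ll = n * (pbar * np.log(pbar) + (1 - pbar) * np.log(1 - pbar))
    return float(ll), float(np.log(pbar / (1 - pbar))), float("nan")


def fit_mrm(y: PhenotypeSet, gp: np.ndarray, n_restarts: int = 3, seed: int = 0) -> MRMFit:
    """Maximise the mixture likelihood over (beta0, beta1[, log sigma2])."""
    yy = np.asarray(y.y, dtype=float)
    log_gp = _log_gp(gp)
    dosage = gp[:, 1] + 2.0 * gp[:, 2]
    quant = y.trait_type == "quantitative"
    # starting values from the dosage regression
    try:
        start_fit = ols_fit(yy, dosage) if quant else logistic_fit(yy, dosage)
        b0s, b1s = start_fit.beta0, start_fit.beta1
        if not np.isfinite(b0s) or not np.isfinite(b1s):
            raise DomainError("dosage start failed")
    except DomainError:
        b0s, b1s = (yy.mean(), 0.0) if quant else (0.0, 0.0)
    if quant:
        resid = yy - b0s - b1s * dosage
        x0 = np.array([b0s, b1s, np.log(max(float(np.var(resid)), 1e-8))])

        def negll_grad(p):
            ll, g = _quant_ll_grad(p, yy, log_gp)
            return -ll, -g

    else:
        x0 = np.array([b0s, b1s])

        def negll_grad(p):
            ll, g = _binary_ll_grad(p, yy, gp, log_gp)
            return -ll, -g

    rng = np.random.default_rng(seed)
    # gradient tolerance scales with n: the log-likelihood (and its gradient
    # noise floor) grows linearly in the sample size
    gtol = max(1e-8, 1e-9 * len(yy))
    best = None
    x_start = x0.copy()
    for attempt in range(1 + n_restarts):
        res = optimize.minimize(
            negll_grad,
            x_start,
            jac=True,
            method="BFGS",
            options={"gtol": gtol, "maxiter": 500},
        )
        if best is None or -res.fun > -best.fun:
            best = res
        if res.success:
            break
        x_start = x0 + rng.normal(scale=0.1, size=len(x0))
    assert best is not None
    ll = float(-best.fun)
    ok = bool(best.success) or bool(np.linalg.norm(best.jac, np.inf) < 100 * gtol)
    if quant:
        b0, b1, log_s2 = best.x
        return MRMFit(float(b0), float(b1), float(np.exp(log_s2)), ll, ok)
    b0, b1 = best.x
    return MRMFit(float(b0), float(b1), None, ll, ok)


def test_mrm(y: PhenotypeSet, v: ImputedVariant, seed: int = 0) -> AssocResult:
    """1-df likelihood-ratio test of beta1 = 0 under the mixture model.

    The reported effect and standard error come from the alternative fit
    (observed information by numerical differentiation); the p-value is the
    chi-square(1) tail of the LRT statistic.
    """
    alt = fit_mrm(y, v.gp, seed=seed)
    ll_null, _, _ = _null_loglik(y)
    stat = max(2.0 * (alt.loglik - ll_null), 0.0)
    p = float(stats.chi2.sf(stat, 1))
    se = float("nan")
    if alt.converged:
        se = _observed_info_se(alt, y, v.gp)
    return AssocResult(
        method="mrm",
        beta_hat=alt.beta1,
        se=se,
        statistic=float(stat),
        df=1.0,
        p_value=p if alt.converged else float("nan"),
        converged=alt.converged,
    )


def _observed_info_se(fit: MRMFit, y: PhenotypeSet, gp: np.ndarray) -> float:
    yy = np.asarray(y.y, dtype=float)
    log_gp = _log_gp(gp)
    if y.trait_type == "quantitative":
        x = np.array([fit.beta0, fit.beta1, np.log(fit.sigma2)])
        f = lambda p: -_quant_ll_grad(p, yy, log_gp, grad=False)[0]
    else:
        x = np.array([fit.beta0, fit.beta1])
        f = lambda p: -_binary_ll_grad(p, yy, gp, log_gp, grad=False)[0]
    try:
        hess = approx_hess1(x, f)
        cov = np.linalg.inv(hess)
        var = cov[1, 1]
        return float(np.sqrt(var)) if var > 0 else float("nan")
    except np.linalg.LinAlgError:
        return float("nan")
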