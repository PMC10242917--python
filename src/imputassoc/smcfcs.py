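"""Measurement-error conditional multiple imputation (SMCFCS) association test.

Genotype imputation is recast as a measurement-error problem: the dosage D and
the best-guess genotype W are treated as two noisy replicates of the latent
true genotype G under classical measurement error (replicate = G + zero-mean
noise of shared variance var_u).  Each imputation chain alternates between

1. drawing substantive-model parameters theta* (slope/intercept and, for
   quantitative traits, the residual variance) from the asymptotic normal /
   scaled-inverse-chi-square approximation of their posterior given the
   current imputed G;
2. updating the latent-measurement model: mu_x and var_x from the moments of
   the imputed G, and var_u from the within-individual dispersion of (D, W)
   around the imputed G, each with an approximate posterior draw; and
3. proposing a new G per individual from the measurement-only conditional
   Normal (precision 1/var_x + 2/var_u, mean the precision-weighted
   combination of mu_x, D and W) and accepting it with probability
   proportional to the substantive likelihood f(y | G, theta*) — a rejection
   step that makes the imputation compatible with the analysis model.

The imputed G is continuous (not rounded to allele counts); the final cycle of
each chain is one completed dataset.  Fitting the substantive model on each of
the M chains and pooling with Rubin's rules yields the association test.
"""
from __future__ import annotations

from typing import List

import numpy as np
from scipy import stats

from .glm import logistic_fit, ols_fit
from .simdata import RngLike, as_rng
from .types import AssocResult, DomainError, ImputedVariant, PhenotypeSet, SMCFCSConfig

_VAR_U_FLOOR = 1e-8


def _mvn2_draw(mean0, mean1, cov, rng):
    """Draw from a bivariate normal via a hand-rolled 2x2 Cholesky."""
    a = np.sqrt(cov[0, 0])
    b = cov[0, 1] / a
    c = np.sqrt(max(cov[1, 1] - b * b, 0.0))
    z0, z1 = rng.standard_normal(2)
    return mean0 + a * z0, mean1 + b * z0 + c * z1


def _draw_theta_quant(y: np.ndarray, g: np.ndarray, rng: np.random.Generator):
    """Posterior-style draw of (beta0, beta1, sigma2) for the linear model y ~ g."""
    n = len(y)
    gm, ym = g.mean(), y.mean()
    gc = g - gm
    sxx = float(gc @ gc)
    b1 = float(gc @ (y - ym)) / sxx
    b0 = ym - b1 * gm
    resid = y - b0 - b1 * g
    rss = float(resid @ resid)
    sigma2 = rss / rng.chisquare(n - 2)
    # cov of (b0, b1) = sigma2 * inv([[n, sum g], [sum g, sum g^2]])
    sg = n * gm
    sgg = sxx + n * gm * gm
    det = n * sgg - sg * sg
    cov = sigma2 / det * np.array([[sgg, -sg], [-sg, n]])
    d0, d1 = _mvn2_draw(b0, b1, cov, rng)
    return d0, d1, float(sigma2)


def _draw_theta_binary(y, g, rng, start=None):
    """Posterior-style draw of (beta0, beta1) for the logistic model y ~ g."""
    fit = logistic_fit(y, g, start=start)
    if not fit.converged:
        raise DomainError("substantive logistic fit failed inside SMCFCS chain")
    # observed information at the MLE
    eta = np.clip(fit.beta0 + fit.beta1 * g, -30, 30)
    p = 1.0 / (1.0 + np.exp(-eta))
    w = p * (1 - p)
    i00, i01, i11 = float(w.sum()), float(w @ g), float(w @ (g * g))
    det = i00 * i11 - i01 * i01
    cov = np.array([[i11, -i01], [-i01, i00]]) / det
    d0, d1 = _mvn2_draw(fit.beta0, fit.beta1, cov, rng)
    return (d0, d1), (fit.beta0, fit.beta1)


def _acceptance_prob(yv, g, theta, trait_type):
    """f(y | g, theta) / sup_g f(y | g, theta): the rejection acceptance probability.

    For a quantitative trait the Gaussian likelihood peaks at 1/sqrt(2 pi s2),
    so the ratio is exp(-resid^2 / (2 s2)); for a binary trait the Bernoulli
    likelihood is bounded by 1 and ``yv`` carries the +/-1 coded outcome.
    """
    if trait_type == "quantitative":
        b0, b1, s2 = theta
        resid = yv - b0 - b1 * g
        return np.exp(-resid * resid / (2.0 * s2))
    b0, b1 = theta
    z = np.clip((b0 + b1 * g) * yv, -30, 30)  # yv in {-1, +1}
    return 1.0 / (1.0 + np.exp(-z))


def _substantive_loglik_ratio(y, g, theta, trait_type):
    """log f(y | g, theta) minus its supremum over g (log acceptance probability)."""
    yv = y if trait_type == "quantitative" else 2.0 * y - 1.0
    with np.errstate(divide="ignore"):
        return np.log(_acceptance_prob(yv, g, theta, trait_type))


def _one_chain(
    y: np.ndarray,
    trait_type: str,
    d: np.ndarray,
    w: np.ndarray,
    cfg: SMCFCSConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    n = len(y)
    g = 0.5 * (d + w)
    warm = None
    for _ in range(cfg.n_iter):
        # (a) substantive-model parameter draw
        if trait_type == "quantitative":
            theta = _draw_theta_quant(y, g, rng)
        else:
            theta, warm = _draw_theta_binary(y, g, rng, start=warm)
        # (b) latent-measurement model draws
        var_u_hat = float(((d - g) ** 2 + (w - g) ** 2).mean()) / 2.0
        var_u = max((2 * n) * var_u_hat / rng.chisquare(2 * n), _VAR_U_FLOOR)
        mu_hat = float(g.mean())
        var_x_hat = max(float(g.var(ddof=1)), 1e-10)
        var_x = max((n - 1) * var_x_hat / rng.chisquare(n - 1), 1e-10)
        mu_x = mu_hat + rng.standard_normal() * np.sqrt(var_x / n)
        # (c) measurement-only proposal + substantive rejection step
        prec = 1.0 / var_x + 2.0 / var_u
        mean = (mu_x / var_x + (d + w) / var_u) / prec
        sd = 1.0 / np.sqrt(prec)
        yv = y if trait_type == "quantitative" else 2.0 * y - 1.0
        g = _rejection_sample(yv, trait_type, theta, mean, sd, cfg.max_reject, rng)
        if not np.all(np.isfinite(g)):
            raise DomainError("non-finite imputed genotypes in SMCFCS chain")
    return g


def _rejection_sample(yv, trait_type, theta, mean, sd, max_reject, rng):
    """Per-individual rejection sampling from the measurement-only proposal.

    Attempts are drawn in geometrically growing batches so that even
    low-acceptance individuals exhaust their ``max_reject`` budget in a few
    vectorised rounds; individuals that never accept keep the proposal with
    the highest substantive likelihood seen.
    """
    n = len(yv)
    out = np.empty(n)
    best_g = mean.copy()  # degenerate fallback: the proposal mean
    best_p = np.full(n, -1.0)
    active = np.arange(n)
    attempts_left = max_reject
    batch = 1
    while attempts_left > 0 and len(active):
        k = min(batch, attempts_left)
        prop = mean[active][:, None] + sd * rng.standard_normal((len(active), k))
        pa = _acceptance_prob(yv[active][:, None], prop, theta, trait_type)
        accept = rng.random((len(active), k)) < pa
        any_acc = accept.any(axis=1)
        first = np.argmax(accept, axis=1)
        rows = np.arange(len(active))
        out[active[any_acc]] = prop[rows[any_acc], first[any_acc]]
        # the best-seen fallback only matters for individuals that might
        # exhaust the budget, so track it once the easy bulk has accepted
        if attempts_left < max_reject - 5:
            bidx = np.argmax(pa, axis=1)
            bp = pa[rows, bidx]
            better = bp > best_p[active]
            idx_b = active[better]
            best_p[idx_b] = bp[better]
            best_g[idx_b] = prop[rows[better], bidx[better]]
        active = active[~any_acc]
        attempts_left -= k
        batch = min(batch * 4, 512)
    if len(active):
        # attempt cap reached: keep the best-likelihood proposal seen
        out[active] = best_g[active]
    return out


def smcfcs_impute(
    y: PhenotypeSet, d: np.ndarray, w: np.ndarray, cfg: SMCFCSConfig
) -> List[np.ndarray]:
    """Run M independent SMCFCS chains; return the M imputed genotype vectors."""
    cfg.validate()
    d = np.asarray(d, dtype=float)
    w = np.asarray(w, dtype=float)
    yy = np.asarray(y.y, dtype=float)
    if not (len(d) == len(w) == len(yy)):
        raise DomainError("y, d and w must have matching lengths")
    if np.ptp(d) == 0.0:
        raise DomainError("dosage vector is constant; imputation model undefined")
    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.m)
    return [_one_chain(yy, y.trait_type, d, w, cfg, as_rng(s)) for s in seeds]


def test_smcfcs(y: PhenotypeSet, v: ImputedVariant, cfg: SMCFCSConfig | None = None) -> AssocResult:
    """SMCFCS conditional-MI association test: impute M times, fit, Rubin-pool."""
    from .assoc import rubin_pool, _pooled_result

    if cfg is None:
        cfg = SMCFCSConfig()
    imputations = smcfcs_impute(y, v.dosage, v.best_guess, cfg)
    est, ses = [], []
    for g in imputations:
        fit = ols_fit(y.y, g) if y.trait_type == "quantitative" else logistic_fit(y.y, g)
        if fit.converged:
            est.append(fit.beta1)
            ses.append(fit.se)
    if len(est) < 2:
        return AssocResult("smcfcs", np.nan, np.nan, np.nan, np.nan, np.nan, False, m_used=len(est))
    pooled = rubin_pool(np.array(est), np.array(ses))
    res = _pooled_result("smcfcs", pooled, len(est))
    res.method = "smcfcs"
    return res
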