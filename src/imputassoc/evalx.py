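"""Experiment drivers: null-calibration (type I error) and power studies.

The drivers simulate per-bin batches of imputed variants, run the requested
association tests, and summarise each (bin, method) cell either by the
genomic-control lambda of the null p-values or by power at a fixed
significance level.  Bins follow the MAF x Rsq (x odds-ratio) layout of
cohort-scale method comparisons; per-bin variant counts are configuration
knobs so the studies can be run at desk scale with Monte-Carlo error bars.
"""
from __future__ import annotations

import warnings
from typing import Iterable, List, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from . import assoc, simdata
from .types import (
    AssocResult,
    BinSpec,
    DomainError,
    ExperimentResult,
    ImputedVariant,
    PhenotypeSet,
    SimConfig,
    SMCFCSConfig,
)

#: median of the 1-df chi-square distribution
CHI2_1DF_MEDIAN = float(stats.chi2.ppf(0.5, 1))

METHODS = ("dosage", "umi", "mrm", "smcfcs")


class EmptyBinError(RuntimeError):
    """No simulated variant survived the Rsq-concordance filter in a bin."""


def gc_lambda(pvals: np.ndarray) -> float:
    """Genomic-control lambda: median association chi-square / 0.4549.

    1 indicates calibrated p-values; below 1, conservative; above 1, inflated.
    """
    p = np.asarray(pvals, dtype=float)
    if len(p) < 20:
        raise DomainError("need at least 20 p-values for a stable lambda")
    if np.any(p > 1.0) or np.any(p < 0.0):
        raise DomainError("p-values must lie in (0, 1]")
    if np.any(p == 0.0):
        warnings.warn("p-values of 0 clipped to the smallest positive float")
        p = np.clip(p, np.nextafter(0.0, 1.0), 1.0)
    chi = stats.chi2.isf(p, 1)
    return float(np.median(chi) / CHI2_1DF_MEDIAN)


def gc_lambda_se(n: int) -> float:
    """Asymptotic MC standard error of the lambda estimate from n null p-values."""
    f_med = stats.chi2.pdf(CHI2_1DF_MEDIAN, 1)
    return float(1.0 / (2.0 * f_med * np.sqrt(n)) / CHI2_1DF_MEDIAN)


def qq_points(pvals: np.ndarray) -> np.ndarray:
    """(expected, observed) -log10 p pairs for a quantile-quantile plot."""
    p = np.asarray(pvals, dtype=float)
    if len(p) < 1:
        raise DomainError("empty p-value vector")
    n = len(p)
    obs = -np.log10(np.sort(np.clip(p, np.nextafter(0.0, 1.0), 1.0)))[::-1]
    exp = -np.log10((np.arange(1, n + 1) - 0.5) / n)[::-1]
    return np.column_stack([exp[::-1], obs[::-1]])


def estimate_power(pvals: np.ndarray, alpha: float = 5e-8) -> float:
    """Fraction of p-values strictly below the significance level."""
    p = np.asarray(pvals, dtype=float)
    if len(p) == 0:
        raise DomainError("empty p-value vector")
    if not (0.0 < alpha < 1.0):
        raise DomainError("alpha must lie in (0, 1)")
    return float(np.mean(p < alpha))


def residualize(y: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """OLS residuals of y on covariates (with intercept); mean-zero by construction.

    Raises on rank deficiency, naming the collinear column indices.
    """
    y = np.asarray(y, dtype=float)
    C = np.atleast_2d(np.asarray(covariates, dtype=float))
    if C.shape[0] != len(y):
        C = C.T
    X = np.column_stack([np.ones(len(y)), C])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns via the QR diagonal
        _, R = np.linalg.qr(X)
        bad = [int(j) - 1 for j in np.where(np.abs(np.diag(R)) < 1e-10)[0]]
        raise DomainError(f"covariate matrix is rank deficient (collinear columns: {bad})")
    fit = sm.OLS(y, X).fit()
    return np.asarray(fit.resid)


def _run_method(
    method: str,
    y: PhenotypeSet,
    v: ImputedVariant,
    m: int,
    rng: np.random.Generator,
    smcfcs_cfg: SMCFCSConfig | None = None,
) -> AssocResult:
    if method == "dosage":
        return assoc.test_dosage(y, v)
    if method == "umi":
        return assoc.test_unconditional_mi(y, v, m=m, seed=rng)
    if method == "mrm":
        return assoc.test_mrm(y, v, seed=int(rng.integers(2**31)))
    if method == "smcfcs":
        cfg = smcfcs_cfg or SMCFCSConfig()
        cfg = SMCFCSConfig(m=cfg.m, n_iter=cfg.n_iter, max_reject=cfg.max_reject,
                           seed=int(rng.integers(2**31)))
        return assoc.test_smcfcs(y, v, cfg)
    raise DomainError(f"unknown method {method!r}; expected one of {METHODS}")


def _simulate_bin_variants(
    cfg: SimConfig, bin_: BinSpec, seeds: Sequence[np.random.SeedSequence]
) -> List[ImputedVariant]:
    """Simulate ``cfg.n_variants`` variants in a bin, applying the concordance filter.

    Noise calibration is cached on a (MAF, Rsq) grid shared by the bin.
    """
    calib = simdata.NoiseCalibrator(bin_.maf_range, bin_.rsq_range,
                                    seed=np.random.default_rng(seeds[0]))
    rlo, rhi = bin_.rsq_range
    rhi_eff = max(rlo, min(rhi, simdata._RSQ_TOP_CAP))
    out: List[ImputedVariant] = []
    for i, ss in enumerate(seeds):
        rng = simdata.as_rng(ss)
        maf = simdata._sample_maf(rng, bin_.maf_range, cfg.maf_sampling)
        if rlo >= 1.0:
            target, nu = 1.0, 0.0
        else:
            target = float(rng.uniform(rlo, rhi_eff)) if rlo < rhi_eff else rlo
            nu = calib(maf, target)
        v = simdata._materialize_variant(cfg.n, maf, nu, rng, f"bin_{bin_.label()}_{i}")
        if np.isfinite(v.rsq_est) and v.rsq_true > 0 and simdata.rsq_concordance_filter(
            v.rsq_est, v.rsq_true
        ):
            out.append(v)
    if not out:
        raise EmptyBinError(f"no variant survived the Rsq concordance filter in bin {bin_.label()}")
    return out


def run_type1_experiment(
    cfg: SimConfig,
    methods: Iterable[str] = ("dosage",),
    bins: Sequence[BinSpec] = (),
    m: int = 5,
    smcfcs_cfg: SMCFCSConfig | None = None,
) -> ExperimentResult:
    """Null-calibration study: phenotypes independent of the genotypes.

    For each bin, ``cfg.n_variants`` variants are simulated, filtered on
    Rsq concordance, and tested against a fresh null phenotype per variant
    (standard normal for quantitative traits; Bernoulli(prevalence) for
    binary).  Each (bin, method) cell reports the GC lambda with its MC
    standard error.
    """
    cfg.validate()
    methods = list(methods)
    rows, pvalues = [], {}
    for b, bin_ in enumerate(bins):
        bcfg = SimConfig(**{**cfg.__dict__, "maf_range": bin_.maf_range, "rsq_range": bin_.rsq_range})
        seeds = np.random.SeedSequence((cfg.seed, b)).spawn(cfg.n_variants)
        variants = _simulate_bin_variants(bcfg, bin_, seeds)
        pv = {meth: [] for meth in methods}
        for j, v in enumerate(variants):
            yrng = np.random.default_rng(np.random.SeedSequence((cfg.seed, b, j, 7)))
            if cfg.trait_type == "quantitative":
                y = PhenotypeSet(yrng.standard_normal(cfg.n), "quantitative")
            else:
                y = PhenotypeSet(
                    (yrng.random(cfg.n) < cfg.prevalence).astype(float), "binary",
                    prevalence=cfg.prevalence,
                )
            for meth in methods:
                mrng = np.random.default_rng(np.random.SeedSequence((cfg.seed, b, j, 100 + METHODS.index(meth))))
                res = _run_method(meth, y, v, m, mrng, smcfcs_cfg)
                if res.converged and np.isfinite(res.p_value):
                    pv[meth].append(res.p_value)
        for meth in methods:
            p = np.array(pv[meth])
            pvalues[(bin_.label(), meth)] = p
            lam = gc_lambda(p)
            rows.append(
                dict(bin=bin_.label(), method=meth, metric="lambda_gc", value=lam,
                     mc_se=gc_lambda_se(len(p)), n_used=len(p), alpha=np.nan)
            )
    return ExperimentResult(table=pd.DataFrame(rows), pvalues=pvalues)


def run_power_experiment(
    cfg: SimConfig,
    methods: Iterable[str] = ("dosage",),
    bins: Sequence[BinSpec] = (),
    alpha: float = 5e-8,
    m: int = 5,
    smcfcs_cfg: SMCFCSConfig | None = None,
) -> ExperimentResult:
    """Power study with per-variant effect sizes drawn from |N(0, 1)|.

    Each bin prescribes MAF and Rsq ranges plus an effect-size range: an
    odds-ratio interval for binary traits (beta = log OR) or the matching
    log-scale beta interval for quantitative traits.  Phenotypes are generated
    from the *true* genotypes; the tests only ever see the imputed data.
    Power is the fraction of converged tests with p < alpha.
    """
    cfg.validate()
    methods = list(methods)
    rows, pvalues = [], {}
    for b, bin_ in enumerate(bins):
        if bin_.or_range is None:
            raise DomainError("power bins require or_range (effect-size interval)")
        blo, bhi = np.log(bin_.or_range[0]), np.log(bin_.or_range[1])
        if blo < 0:
            raise DomainError("or_range must be >= 1")
        bcfg = SimConfig(**{**cfg.__dict__, "maf_range": bin_.maf_range, "rsq_range": bin_.rsq_range})
        seeds = np.random.SeedSequence((cfg.seed, b, 13)).spawn(cfg.n_variants)
        variants = _simulate_bin_variants(bcfg, bin_, seeds)
        pv = {meth: [] for meth in methods}
        for j, v in enumerate(variants):
            ss = np.random.SeedSequence((cfg.seed, b, j, 29))
            beta = simdata.draw_effect_size_in_range(np.random.default_rng(ss), blo, bhi)
            if cfg.trait_type == "quantitative":
                y = simdata.simulate_quantitative(v.g_true, beta, np.random.default_rng(ss.spawn(1)[0]))
            else:
                y = simdata.simulate_binary(
                    v.g_true, beta, cfg.prevalence, np.random.default_rng(ss.spawn(1)[0])
                )
            for meth in methods:
                mrng = np.random.default_rng(np.random.SeedSequence((cfg.seed, b, j, 31, 100 + METHODS.index(meth))))
                res = _run_method(meth, y, v, m, mrng, smcfcs_cfg)
                if res.converged and np.isfinite(res.p_value):
                    pv[meth].append(res.p_value)
        for meth in methods:
            p = np.array(pv[meth])
            pvalues[(bin_.label(), meth)] = p
            power = estimate_power(p, alpha)
            rows.append(
                dict(bin=bin_.label(), method=meth, metric="power", value=power,
                     mc_se=float(np.sqrt(max(power * (1 - power), 1e-12) / max(len(p), 1))),
                     n_used=len(p), alpha=alpha)
            )
    return ExperimentResult(table=pd.DataFrame(rows), pvalues=pvalues)


def qq_plot(pvalues: dict, path: str, title: str = "") -> None:
    """Write a QQ-plot panel (one curve per method) to ``path`` (PNG/SVG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for (label, meth), p in pvalues.items():
        pts = qq_points(p)
        ax.plot(pts[:, 0], pts[:, 1], marker=".", linestyle="none",
                label=f"{meth} (lambda={gc_lambda(p):.3f})")
    lim = ax.get_xlim()[1]
    ax.plot([0, lim], [0, lim], color="grey", linewidth=0.8)
    ax.set_xlabel("expected -log10 p")
    ax.set_ylabel("observed -log10 p")
    ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
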