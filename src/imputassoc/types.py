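"""Core data containers shared across the package.

The containers mirror the objects produced by genotype-imputation software
(per-sample genotype posteriors GP, dosages DS, best-guess genotypes) together
with the simulation metadata needed for method-comparison experiments.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Tuple

import numpy as np

#: allele counts of the three biallelic genotypes (ref-hom, het, alt-hom)
GENOTYPE_LEVELS = np.array([0.0, 1.0, 2.0])

TraitType = Literal["quantitative", "binary"]


class DomainError(ValueError):
    """A precondition on the scientific domain of an input was violated."""


class CalibrationError(RuntimeError):
    """The noise-calibration bisection could not reach the target Rsq."""


class UndefinedQualityError(ValueError):
    """Imputation quality is undefined (e.g. monomorphic dosage vector)."""


@dataclass
class ImputedVariant:
    """One biallelic variant as seen after genotype imputation.

    Attributes
    ----------
    variant_id : str
        Identifier (e.g. an rsID or ``chrom:pos``).
    gp : (n, 3) ndarray
        Posterior probabilities of the genotypes (ref-hom, het, alt-hom)
        per sample; rows sum to one.
    dosage : (n,) ndarray
        Expected alt-allele count ``gp[:, 1] + 2 * gp[:, 2]``, in [0, 2].
    best_guess : (n,) ndarray of int
        Genotype with maximal posterior probability per sample.
    maf : float
        Minor (alt) allele frequency used to generate / annotate the variant.
    g_true : (n,) ndarray of int, optional
        True genotypes when the variant is simulated (the sequencing "truth").
    rsq_true : float, optional
        Squared Pearson correlation between dosage and ``g_true``.
    rsq_est : float, optional
        Dosage-only imputation quality estimate Var(D) / (2 p (1 - p)).
    """

    variant_id: str
    gp: np.ndarray
    dosage: np.ndarray
    best_guess: np.ndarray
    maf: float
    g_true: Optional[np.ndarray] = None
    rsq_true: Optional[float] = None
    rsq_est: Optional[float] = None

    @property
    def n(self) -> int:
        return self.gp.shape[0]

    def validate(self, atol: float = 1e-9) -> None:
        """Check internal-consistency invariants; raise ``DomainError`` if violated."""
        gp = np.asarray(self.gp, dtype=float)
        if gp.ndim != 2 or gp.shape[1] != 3:
            raise DomainError("gp must be an (n, 3) matrix")
        if np.any(gp < -atol) or np.any(gp > 1 + atol):
            raise DomainError("gp entries must lie in [0, 1]")
        if np.any(np.abs(gp.sum(axis=1) - 1.0) > atol):
            raise DomainError("gp rows must sum to 1")
        if np.any(np.abs(self.dosage - (gp[:, 1] + 2.0 * gp[:, 2])) > atol):
            raise DomainError("dosage must equal gp[:,1] + 2*gp[:,2]")
        if np.any(self.best_guess != np.argmax(gp, axis=1)):
            raise DomainError("best_guess must be the argmax of each gp row")
        if not (0.0 < self.maf <= 0.5):
            raise DomainError("maf must lie in (0, 0.5]")
        if self.g_true is not None and self.rsq_true is not None:
            r = np.corrcoef(self.dosage, self.g_true)[0, 1] ** 2
            if abs(r - self.rsq_true) > 1e-6:
                raise DomainError("rsq_true inconsistent with cor^2(dosage, g_true)")


@dataclass
class PhenotypeSet:
    """Trait values (and optional covariates) for the analysed samples."""

    y: np.ndarray
    trait_type: TraitType
    covariates: Optional[np.ndarray] = None
    prevalence: Optional[float] = None

    @property
    def n(self) -> int:
        return len(self.y)

    def validate(self) -> None:
        y = np.asarray(self.y, dtype=float)
        if not np.all(np.isfinite(y)):
            raise DomainError("phenotype values must be finite")
        if self.trait_type == "binary" and not np.all(np.isin(y, (0.0, 1.0))):
            raise DomainError("binary phenotype must contain only 0/1")
        if self.prevalence is not None and not (0.0 < self.prevalence < 1.0):
            raise DomainError("prevalence must lie in (0, 1)")


@dataclass
class SimConfig:
    """Knobs of the synthetic imputed-genotype simulator.

    ``maf_range`` and ``rsq_range`` bound the per-variant minor-allele
    frequency and the target true imputation Rsq; ``effect_law`` selects the
    phenotype model (``null`` or per-variant |N(0,1)| effect sizes).
    """

    n: int
    maf_range: Tuple[float, float]
    rsq_range: Tuple[float, float]
    trait_type: TraitType = "quantitative"
    prevalence: float = 0.5
    effect_law: Literal["null", "abs_std_normal"] = "null"
    n_variants: int = 1
    seed: int = 0
    maf_sampling: Literal["uniform", "log_uniform"] = "log_uniform"

    def validate(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise DomainError("maf_range must satisfy 0 < low <= high <= 0.5")
        rlo, rhi = self.rsq_range
        if not (0.0 <= rlo <= rhi <= 1.0):
            raise DomainError("rsq_range must satisfy 0 <= low <= high <= 1")
        if self.n_variants < 1:
            raise DomainError("n_variants must be >= 1")
        if not (0.0 < self.prevalence < 1.0):
            raise DomainError("prevalence must lie in (0, 1)")


@dataclass
class AssocResult:
    """Outcome of one association test on one variant."""

    method: Literal["dosage", "umi", "mrm", "smcfcs"]
    beta_hat: float
    se: float
    statistic: float
    df: float
    p_value: float
    converged: bool
    m_used: Optional[int] = None


@dataclass
class RubinPooled:
    """Rubin's-rules pooling of M imputation-specific estimates."""

    q_bar: float
    w_bar: float
    b: float
    t_var: float
    df: float
    p_value: float
    m: int


@dataclass
class MRMFit:
    """Maximum-likelihood fit of the mixture-of-regression-models likelihood."""

    beta0: float
    beta1: float
    sigma2: Optional[float]
    loglik: float
    converged: bool


@dataclass
class SMCFCSConfig:
    """Settings of the measurement-error (SMCFCS) conditional imputation."""

    m: int = 5
    n_iter: int = 10
    max_reject: int = 1000
    seed: int = 0

    def validate(self) -> None:
        if self.m < 2:
            raise DomainError("SMCFCS requires m >= 2 imputations")
        if self.n_iter < 1 or self.max_reject < 1:
            raise DomainError("n_iter and max_reject must be >= 1")


@dataclass
class BinSpec:
    """One experiment cell: MAF range x Rsq range (x odds-ratio range for power)."""

    maf_range: Tuple[float, float]
    rsq_range: Tuple[float, float]
    or_range: Optional[Tuple[float, float]] = None

    def label(self) -> str:
        s = f"maf[{self.maf_range[0]:g},{self.maf_range[1]:g})_rsq[{self.rsq_range[0]:g},{self.rsq_range[1]:g})"
        if self.or_range is not None:
            s += f"_or({self.or_range[0]:g},{self.or_range[1]:g}]"
        return s


@dataclass
class ExperimentResult:
    """Tidy per-(bin, method) metrics plus the raw per-variant p-values."""

    table: "object"  # pandas.DataFrame: bin, method, metric, value, mc_se, n_used
    pvalues: dict = field(default_factory=dict)  # (bin_label, method) -> ndarray
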