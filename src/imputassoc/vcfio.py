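"""Reading and writing imputed-genotype VCFs and phenotype tables.

The on-disk formats follow the minimac/IMPUTE dialect: per-sample FORMAT
fields ``GP`` (posterior probabilities of ref-hom, het, alt-hom) and ``DS``
(expected alt-allele count), plus an ``INFO/R2`` imputation-quality estimate.
Phenotypes travel as a TSV whose first column is the sample id.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .types import DomainError, ImputedVariant, PhenotypeSet

log = logging.getLogger(__name__)


@dataclass
class VariantRecord:
    """One VCF record carrying imputed-genotype fields."""

    chrom: str
    pos: int  # 1-based, VCF convention
    id: str
    ref: str
    alt: str
    gp: Optional[np.ndarray] = None  # (n, 3)
    ds: Optional[np.ndarray] = None  # (n,)
    info_r2: Optional[float] = None
    missing: Optional[np.ndarray] = None  # bool mask of samples to drop

    def to_imputed_variant(self) -> Tuple[ImputedVariant, np.ndarray]:
        """Convert to an analysis-ready variant; returns (variant, kept-sample index).

        Requires GP (the posterior-based tests need the full triplet); samples
        with missing GP are dropped.
        """
        if self.gp is None:
            raise DomainError(
                f"variant {self.id}: GP absent; posterior-based methods (U-MI, MRM, "
                "SMCFCS) require genotype posteriors, not just dosages"
            )
        keep = ~self.missing if self.missing is not None else np.ones(len(self.gp), bool)
        gp = self.gp[keep]
        dosage = gp[:, 1] + 2.0 * gp[:, 2]
        p = float(dosage.mean()) / 2.0
        maf = min(max(p, 1e-12), 1 - 1e-12)
        maf = min(maf, 1 - maf)
        v = ImputedVariant(
            variant_id=self.id or f"{self.chrom}:{self.pos}",
            gp=gp,
            dosage=dosage,
            best_guess=np.argmax(gp, axis=1).astype(np.int8),
            maf=maf,
            rsq_est=self.info_r2,
        )
        return v, np.where(keep)[0]


def read_vcf(path: str, sample_subset: Optional[Sequence[str]] = None) -> Iterator[VariantRecord]:
    """Stream biallelic VariantRecords from a VCF with GP and/or DS FORMAT fields.

    GP rows whose sum falls in [0.98, 1.02] are renormalised (text-precision
    slack); sums outside that window are an error.  Records lacking both GP
    and DS are skipped with a logged reason, as are multi-allelic sites.
    Per-sample missing GP ('.') marks the sample for dropping at analysis time.
    """
    vcf = VCF(str(path), samples=list(sample_subset) if sample_subset is not None else None)
    for rec in vcf:
        if len(rec.ALT) != 1:
            log.warning("skipping multi-allelic site %s:%s", rec.CHROM, rec.POS)
            continue
        gp = ds = None
        try:
            raw = rec.format("GP")
        except KeyError:
            raw = None
        if raw is not None:
            gp = np.asarray(raw, dtype=float)
            if gp.ndim != 2 or gp.shape[1] != 3:
                raise DomainError(f"variant {rec.ID}: malformed GP arity {gp.shape}")
            missing = ~np.all(np.isfinite(gp), axis=1)
            sums = gp[~missing].sum(axis=1)
            if np.any((sums < 0.98) | (sums > 1.02)):
                raise DomainError(
                    f"variant {rec.ID}: GP rows sum outside [0.98, 1.02]; refusing to renormalise"
                )
            gp[~missing] /= gp[~missing].sum(axis=1, keepdims=True)
        else:
            missing = None
        try:
            raw_ds = rec.format("DS")
        except KeyError:
            raw_ds = None
        if raw_ds is not None:
            ds = np.asarray(raw_ds, dtype=float).reshape(-1)
        if gp is None and ds is None:
            log.warning("skipping %s:%s (%s): neither GP nor DS present", rec.CHROM, rec.POS, rec.ID)
            continue
        if gp is not None and ds is not None:
            d_from_gp = gp[:, 1] + 2.0 * gp[:, 2]
            ok = np.isfinite(ds) & ~missing if missing is not None else np.isfinite(ds)
            if np.any(np.abs(d_from_gp[ok] - ds[ok]) > 0.01):
                log.warning("variant %s: DS inconsistent with GP by > 0.01; preferring GP", rec.ID)
        info_r2 = rec.INFO.get("R2")
        yield VariantRecord(
            chrom=rec.CHROM,
            pos=rec.POS,
            id=rec.ID or f"{rec.CHROM}:{rec.POS}",
            ref=rec.REF,
            alt=rec.ALT[0],
            gp=gp,
            ds=ds,
            info_r2=float(info_r2) if info_r2 is not None else None,
            missing=missing,
        )


def vcf_samples(path: str) -> List[str]:
    return list(VCF(str(path)).samples)


def write_vcf(
    path: str,
    variants: Sequence[ImputedVariant],
    sample_ids: Sequence[str],
    chrom: str = "1",
    start_pos: int = 1000,
) -> None:
    """Write simulated variants as a VCF 4.2 with GP/DS FORMAT and INFO/R2.

    GP values carry 4 decimals (imputation-software convention); positions are
    synthetic and evenly spaced.
    """
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={chrom}>",
        '##INFO=<ID=R2,Number=1,Type=Float,Description="Estimated imputation Rsq from dosages">',
        '##FORMAT=<ID=GP,Number=G,Type=Float,Description="Genotype posterior probabilities (ref-hom, het, alt-hom)">',
        '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Expected alternate allele dosage">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT" + "".join(f"\t{s}" for s in sample_ids),
    ]
    for k, v in enumerate(variants):
        if v.n != len(sample_ids):
            raise DomainError("variant sample count does not match sample_ids")
        info = f"R2={v.rsq_est:.4f}" if v.rsq_est is not None and np.isfinite(v.rsq_est) else "."
        cells = [
            f"{v.gp[i,0]:.4f},{v.gp[i,1]:.4f},{v.gp[i,2]:.4f}:{v.dosage[i]:.4f}"
            for i in range(v.n)
        ]
        lines.append(
            f"{chrom}\t{start_pos + k}\t{v.variant_id}\tA\tG\t.\tPASS\t{info}\tGP:DS\t" + "\t".join(cells)
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_phenotypes(
    path: str,
    sample_ids: Sequence[str],
    pheno: PhenotypeSet,
    covariate_names: Optional[Sequence[str]] = None,
) -> None:
    """Write a phenotype (+ covariate) TSV: sample_id, phenotype, covariates..."""
    df = pd.DataFrame({"sample_id": list(sample_ids), "phenotype": np.asarray(pheno.y)})
    if pheno.covariates is not None:
        C = np.atleast_2d(pheno.covariates)
        if C.shape[0] != len(df):
            C = C.T
        names = covariate_names or [f"cov{i+1}" for i in range(C.shape[1])]
        for i, name in enumerate(names):
            df[name] = C[:, i]
    df.to_csv(path, sep="\t", index=False)


def read_phenotypes(
    path: str,
    trait_type: str = "quantitative",
    phenotype_col: Optional[str] = None,
    covariate_cols: Optional[Sequence[str]] = None,
) -> Tuple[pd.DataFrame, PhenotypeSet]:
    """Read a phenotype TSV (header; first column sample id).

    Returns the raw table (for sample alignment) and a PhenotypeSet over all
    rows.  Duplicate sample ids or non-numeric phenotypes raise with the
    offending row numbers.  Values confined to {0, 1} under a declared
    quantitative trait only warn.
    """
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise DomainError("phenotype table needs at least sample id and phenotype columns")
    id_col = df.columns[0]
    dup = df[id_col].duplicated()
    if dup.any():
        rows = (np.where(dup)[0] + 2).tolist()  # 1-based incl. header
        raise DomainError(f"duplicate sample ids at rows {rows}")
    pcol = phenotype_col or df.columns[1]
    vals = pd.to_numeric(df[pcol], errors="coerce")
    if vals.isna().any():
        rows = (np.where(vals.isna())[0] + 2).tolist()
        raise DomainError(f"non-numeric phenotype values at rows {rows}")
    y = vals.to_numpy(dtype=float)
    if trait_type == "quantitative" and set(np.unique(y)) <= {0.0, 1.0}:
        log.warning("phenotype looks binary (only 0/1) but trait declared quantitative; proceeding")
    if trait_type == "binary" and not set(np.unique(y)) <= {0.0, 1.0}:
        raise DomainError("binary trait declared but phenotype values are not all 0/1")
    cov = None
    if covariate_cols:
        missing = [c for c in covariate_cols if c not in df.columns]
        if missing:
            raise DomainError(f"covariate columns not found: {missing}")
        cov = df[list(covariate_cols)].to_numpy(dtype=float)
    ps = PhenotypeSet(y=y, trait_type=trait_type, covariates=cov)  # type: ignore[arg-type]
    ps.validate()
    return df, ps


def align_samples(
    vcf_sample_ids: Sequence[str], pheno_table: pd.DataFrame
) -> Tuple[np.ndarray, np.ndarray]:
    """Order-aligned index arrays (vcf_idx, pheno_idx) over the shared samples.

    Samples present in only one source are dropped with a logged count.
    """
    id_col = pheno_table.columns[0]
    pheno_ids = pheno_table[id_col].astype(str).tolist()
    pos = {s: i for i, s in enumerate(pheno_ids)}
    vcf_idx, ph_idx = [], []
    for i, s in enumerate(vcf_sample_ids):
        j = pos.get(str(s))
        if j is not None:
            vcf_idx.append(i)
            ph_idx.append(j)
    dropped = len(vcf_sample_ids) - len(vcf_idx) + len(pheno_ids) - len(ph_idx)
    if dropped:
        log.info("dropped %d samples absent from one of VCF/phenotype table", dropped)
    return np.array(vcf_idx, dtype=int), np.array(ph_idx, dtype=int)
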