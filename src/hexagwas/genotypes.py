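"""Allele-depth parsing and polysomic genotype calling.

Genotypes in an autohexaploid are represented three ways:

* quantitative genotype — the alt-allele read fraction in [0, 1], used
  directly as an additive predictor;
* hexaploid dosage — the nearest k/6 class, k = 0..6 (nulliplex..hexaplex);
* diploidized genotype — {0, 1, 2} copies of the *reference* allele, with
  heterozygosity called when the alt fraction lies in [5%, 95%].
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AlleleDepthMatrix",
    "QuantGenotypeMatrix",
    "DiploidizedMatrix",
    "read_allele_depths",
    "allele_ratio",
    "call_dosage",
    "diploidize",
    "filter_markers",
    "filter_correlation_set",
]


@dataclass
class AlleleDepthMatrix:
    """Per-marker x per-individual (ref, alt) read counts.

    ``missing`` marks genotypes whose total depth did not exceed the
    per-genotype coverage floor; raw counts are retained for coverage-based
    filters that use their own thresholds.
    """

    markers: pd.DataFrame  # chrom, pos, ref, alt
    individuals: list[str]
    ref_depth: np.ndarray
    alt_depth: np.ndarray
    missing: np.ndarray  # bool
    n_skipped_multiallelic: int = 0

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def total_depth(self) -> np.ndarray:
        return self.ref_depth + self.alt_depth

    def subset_individuals(self, ids: list[str]) -> "AlleleDepthMatrix":
        idx = [self.individuals.index(i) for i in ids]
        return AlleleDepthMatrix(
            markers=self.markers,
            individuals=list(ids),
            ref_depth=self.ref_depth[:, idx],
            alt_depth=self.alt_depth[:, idx],
            missing=self.missing[:, idx],
            n_skipped_multiallelic=self.n_skipped_multiallelic,
        )

    def subset_markers(self, index: np.ndarray) -> "AlleleDepthMatrix":
        return AlleleDepthMatrix(
            markers=self.markers.iloc[index].reset_index(drop=True),
            individuals=self.individuals,
            ref_depth=self.ref_depth[index],
            alt_depth=self.alt_depth[index],
            missing=self.missing[index],
            n_skipped_multiallelic=self.n_skipped_multiallelic,
        )


@dataclass
class QuantGenotypeMatrix:
    """Alt-allele read fractions and, optionally, called dosage classes."""

    markers: pd.DataFrame
    individuals: list[str]
    ratio: np.ndarray            # float, NaN = missing
    dosage: np.ndarray | None = None  # float with NaN, values 0..6


@dataclass
class DiploidizedMatrix:
    """{0,1,2} reference-allele copies (x_ij) with per-marker ref frequency p_i."""

    markers: pd.DataFrame
    individuals: list[str]
    geno: np.ndarray  # float, NaN = missing

    @property
    def m(self) -> int:
        return len(self.markers)

    @property
    def p(self) -> np.ndarray:
        """Reference-allele frequency per marker from non-missing genotypes."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.geno, axis=1) / 2.0


def read_allele_depths(vcf_path: str | Path, min_genotype_depth: int = 20) -> AlleleDepthMatrix:
    """Read per-genotype allele depths (AD) from a VCF.

    Genotypes are kept only when total coverage strictly exceeds
    ``min_genotype_depth`` (default 20); below-threshold entries are masked
    missing.  Multiallelic records are skipped and counted.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    individuals = list(vcf.samples)
    rows, refs, alts = [], [], []
    n_multi = 0
    last = {}
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        ad = var.format("AD")
        if ad is None:
            raise ValueError(f"VCF record {var.CHROM}:{var.POS} lacks the AD FORMAT field")
        if var.CHROM in last and var.POS < last[var.CHROM]:
            raise ValueError(f"VCF is not position-sorted at {var.CHROM}:{var.POS}")
        last[var.CHROM] = var.POS
        ad = np.asarray(ad)
        ad = np.where(ad < 0, 0, ad)  # cyvcf2 encodes missing as negative
        rows.append((var.CHROM, var.POS, var.REF, var.ALT[0]))
        refs.append(ad[:, 0])
        alts.append(ad[:, 1])
    if n_multi:
        logger.info("skipped %d multiallelic records", n_multi)
    if not rows:
        raise ValueError("no biallelic records found")
    markers = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    ref_depth = np.asarray(refs, dtype=np.int64)
    alt_depth = np.asarray(alts, dtype=np.int64)
    missing = (ref_depth + alt_depth) <= min_genotype_depth
    return AlleleDepthMatrix(
        markers=markers,
        individuals=individuals,
        ref_depth=ref_depth,
        alt_depth=alt_depth,
        missing=missing,
        n_skipped_multiallelic=n_multi,
    )


def allele_ratio(ad: AlleleDepthMatrix) -> QuantGenotypeMatrix:
    """Quantitative genotype: alt / (ref + alt); missingness propagates."""
    total = ad.total_depth.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = ad.alt_depth / total
    ratio[ad.missing | (total == 0)] = np.nan
    return QuantGenotypeMatrix(markers=ad.markers, individuals=ad.individuals, ratio=ratio)


def call_dosage(ratio: np.ndarray | float) -> np.ndarray | float:
    """Nearest-k/6 hexaploid dosage call; ties break toward the lower class.

    argmin_k |ratio - k/6| equals ceil(6*ratio - 1/2) on [0, 1], which puts
    midpoints such as 1/12 in the lower class.  NaN propagates.
    """
    r = np.asarray(ratio, dtype=float)
    valid = ~np.isnan(r)
    if np.any((r[valid] < 0) | (r[valid] > 1)):
        raise ValueError("ratios must lie in [0, 1]")
    d = np.ceil(6.0 * r - 0.5)
    d = np.clip(d, 0, 6)
    return float(d) if np.isscalar(ratio) else d


def diploidize(
    ratio: np.ndarray | float,
    het_low: float = 0.05,
    het_high: float = 0.95,
) -> np.ndarray | float:
    """Collapse alt-read fractions to reference-allele copies {0, 1, 2}.

    Below 5% alt reads the genotype is homozygous reference (2 ref copies);
    above 95% it is homozygous alternative (0); in between — boundaries
    included — it is heterozygous (1).  NaN propagates.
    """
    r = np.asarray(ratio, dtype=float)
    g = np.where(r < het_low, 2.0, np.where(r > het_high, 0.0, 1.0))
    g = np.where(np.isnan(r), np.nan, g)
    return float(g) if np.isscalar(ratio) else g


def filter_markers(
    dip: DiploidizedMatrix,
    maf_min: float = 0.05,
    max_missing_frac: float = 0.5,
) -> np.ndarray:
    """Marker mask: MAF strictly above ``maf_min`` and data for at least
    half the individuals (allele frequencies from diploidized codes)."""
    n = dip.geno.shape[1]
    n_obs = np.sum(~np.isnan(dip.geno), axis=1)
    with np.errstate(invalid="ignore"):
        p = np.where(n_obs > 0, np.nansum(dip.geno, axis=1) / (2 * np.maximum(n_obs, 1)), np.nan)
    maf = np.minimum(p, 1 - p)
    n_dropped_empty = int(np.sum(n_obs == 0))
    if n_dropped_empty:
        logger.info("dropped %d all-missing markers", n_dropped_empty)
    keep = (n_obs >= math.ceil((1 - max_missing_frac) * n)) & (maf > maf_min) & (n_obs > 0)
    return keep


def filter_correlation_set(
    dosage: np.ndarray,
    min_informative: int | None = None,
    reference: tuple[int, int] = (23, 83),
) -> np.ndarray:
    """Marker mask for the quantitative-genotype correlation scan.

    A marker is retained when enough individuals carry an intermediate
    (duplex..pentaplex) dosage — at least 23 of 83 in the reference design,
    scaled as ceil(n * 23/83) for other population sizes.
    """
    n = dosage.shape[1]
    if min_informative is None:
        k, d = reference
        min_informative = k if n == d else math.ceil(n * k / d)
    informative = np.sum((dosage >= 2) & (dosage <= 5), axis=1)
    return informative >= min_informative
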