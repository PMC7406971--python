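"""Transmission-ratio-distortion screening in an F1 population.

The statistic compares the alt-allele ratio in the progeny with the mean of
the two parental ratios on a log scale; genome-wide empirical
z-standardization of the log ratios gives per-marker P-values, with a
stringent default significance threshold of P < 1e-10.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import AlleleDepthMatrix, diploidize

logger = logging.getLogger(__name__)

__all__ = ["DistortionResult", "distortion_filter", "parent_mean_ratio", "distortion_scan"]


@dataclass
class DistortionResult:
    table: pd.DataFrame  # chrom, pos, f1_ratio, parent_ratio, log_ratio, z, p, significant
    p_threshold: float
    n_excluded_zero_ratio: int


def _progeny_columns(ad: AlleleDepthMatrix, parent_ids: tuple[str, str]) -> list[int]:
    for p in parent_ids:
        if p not in ad.individuals:
            raise ValueError(f"parent {p!r} absent from the depth matrix")
    return [j for j, s in enumerate(ad.individuals) if s not in parent_ids]


def distortion_filter(
    ad: AlleleDepthMatrix,
    parent_ids: tuple[str, str],
    mean_cov_range: tuple[float, float] = (60.0, 200.0),
    parent_cov_min: float = 60.0,
    maf_min: float = 0.01,
) -> np.ndarray:
    """Stringent marker mask for the distortion scan.

    Retains markers with mean progeny coverage inside ``mean_cov_range``
    (inclusive), both parents' coverage strictly above ``parent_cov_min``,
    MAF (diploidized progeny genotypes) strictly above ``maf_min``, and no
    missing genotype in any progeny (max-missing = 1).
    """
    prog = _progeny_columns(ad, parent_ids)
    par = [ad.individuals.index(p) for p in parent_ids]
    total = ad.total_depth
    prog_tot = total[:, prog]
    no_missing = np.all(prog_tot > 0, axis=1)
    mean_cov = prog_tot.mean(axis=1)
    cov_ok = (mean_cov >= mean_cov_range[0]) & (mean_cov <= mean_cov_range[1])
    parent_ok = np.all(total[:, par] > parent_cov_min, axis=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = ad.alt_depth[:, prog] / prog_tot
    geno = diploidize(ratio)
    with np.errstate(invalid="ignore"):
        p = np.nanmean(geno, axis=1) / 2.0
    maf = np.minimum(p, 1 - p)
    return no_missing & cov_ok & parent_ok & (maf > maf_min)


def parent_mean_ratio(ad: AlleleDepthMatrix, parent_ids: tuple[str, str]) -> np.ndarray:
    """Mean of the two per-parent alt ratios (each parent's ratio computed
    independently, then averaged — not pooled read counts)."""
    par = [ad.individuals.index(p) for p in parent_ids]
    total = ad.total_depth[:, par].astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = ad.alt_depth[:, par] / total
    return ratios.mean(axis=1)


def distortion_scan(
    ad: AlleleDepthMatrix,
    parent_ids: tuple[str, str],
    index: np.ndarray,
    p_threshold: float = 1e-10,
    log_base: float = 10.0,
    f1_mode: str = "mean",
    standardize: str = "weighted",
) -> DistortionResult:
    """Scan markers for transmission distortion.

    log_ratio = log(f1_ratio / parent_ratio); z-scores are the log ratios
    standardized genome-wide (empirical mean and SD), then tested against a
    two-sided normal.  ``f1_mode`` selects the F1 ratio definition: "mean"
    averages per-progeny alt fractions, "pooled" uses summed read counts.

    ``standardize="weighted"`` (default) first divides each log ratio by its
    own sampling SE (delta method: empirical progeny-ratio variance for the
    F1 term, binomial read sampling at the null ratio for the parental
    term) before the genome-wide standardization.  Without this, markers
    with a low parental ratio — whose parental read noise is large relative
    to the genome-wide spread — dominate the extreme tail and mimic
    distortion.  ``standardize="pooled"`` standardizes the raw log ratios.
    """
    if f1_mode not in ("mean", "pooled"):
        raise ValueError("f1_mode must be 'mean' or 'pooled'")
    if standardize not in ("weighted", "pooled"):
        raise ValueError("standardize must be 'weighted' or 'pooled'")
    sub = ad.subset_markers(np.flatnonzero(index) if index.dtype == bool else index)
    prog = _progeny_columns(sub, parent_ids)
    par = [sub.individuals.index(p) for p in parent_ids]
    total = sub.total_depth[:, prog].astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.where(total > 0, sub.alt_depth[:, prog] / total, np.nan)
    if f1_mode == "mean":
        f1 = np.nanmean(ratios, axis=1)
    else:
        f1 = sub.alt_depth[:, prog].sum(axis=1) / total.sum(axis=1)
    parents = parent_mean_ratio(sub, parent_ids)

    ok = (f1 > 0) & (parents > 0) & np.isfinite(f1) & np.isfinite(parents)
    n_excl = int(np.sum(~ok))
    if n_excl:
        logger.info("excluded %d markers with zero F1 or parental ratio", n_excl)
    log_ratio = np.full(len(f1), np.nan)
    log_ratio[ok] = np.log(f1[ok] / parents[ok]) / np.log(log_base)

    score = log_ratio
    if standardize == "weighted":
        # delta-method SE of the log ratio, with the parental binomial
        # variance evaluated at the null (the F1 ratio), so that a poorly
        # covered parent cannot masquerade as distortion
        n_prog = np.sum(~np.isnan(ratios), axis=1).astype(float)
        var_f1 = np.nanvar(ratios, axis=1, ddof=1) / np.maximum(n_prog, 1)
        par_depth = sub.total_depth[:, par].astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            var_par = f1 * (1 - f1) * (1.0 / par_depth).sum(axis=1) / 4.0
            se = np.sqrt(var_f1 / f1**2 + var_par / parents**2) / np.log(log_base)
            score = log_ratio / se
        score[~np.isfinite(score)] = np.nan

    mu = np.nanmean(score)
    sd = np.nanstd(score, ddof=1)
    if not np.isfinite(sd) or sd == 0:
        z = np.where(np.isnan(score), np.nan, 0.0)
    else:
        z = (score - mu) / sd
    p = 2 * stats.norm.sf(np.abs(z))

    table = pd.DataFrame(
        {
            "chrom": sub.markers["chrom"].values,
            "pos": sub.markers["pos"].values,
            "f1_ratio": f1,
            "parent_ratio": parents,
            "log_ratio": log_ratio,
            "z": z,
            "p": p,
            "significant": p < p_threshold,
        }
    )
    table = table[ok].reset_index(drop=True)
    return DistortionResult(table=table, p_threshold=p_threshold, n_excluded_zero_ratio=n_excl)
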