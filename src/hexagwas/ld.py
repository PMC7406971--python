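"""Pairwise linkage disequilibrium (genotype-count r^2) and haploblock spans.

Phasing is infeasible in hexaploids (more than two haplotypes per region),
so LD is the squared Pearson correlation of diploidized {0,1,2} genotype
codes — the convention of PLINK's --r2 on unphased data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import DiploidizedMatrix

__all__ = ["LDBlock", "ld_r2", "ld_window", "haploblock_span"]

MIN_PAIRWISE_N = 10


@dataclass
class LDBlock:
    focal_chrom: str
    focal_pos: int
    partners: pd.DataFrame  # chrom, pos, r2 (window markers)
    span_bp: int            # extent of markers with r2 > threshold (0 = summit only)
    span_start: int
    span_end: int
    threshold: float


def ld_r2(g1: np.ndarray, g2: np.ndarray) -> float:
    """Squared Pearson correlation of two diploidized genotype vectors.

    Pairwise-complete; returns NaN when fewer than 10 complete pairs remain
    or either vector is monomorphic on the complete pairs.
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    ok = np.isfinite(g1) & np.isfinite(g2)
    if ok.sum() < MIN_PAIRWISE_N:
        return float("nan")
    a, b = g1[ok], g2[ok]
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def ld_window(
    dip: DiploidizedMatrix,
    focal_chrom: str,
    focal_pos: int,
    window_bp: float = 5e6,
) -> pd.DataFrame:
    """r^2 of every same-chromosome marker within ``window_bp`` of the focal
    marker, computed against the focal genotypes."""
    chroms = dip.markers["chrom"].values
    pos = dip.markers["pos"].values
    f = np.flatnonzero((chroms == focal_chrom) & (pos == focal_pos))
    if f.size == 0:
        raise KeyError(f"no marker at {focal_chrom}:{focal_pos}")
    f = int(f[0])
    g_f = dip.geno[f]
    if np.nanstd(g_f) == 0:
        raise ValueError("focal marker is monomorphic")
    sel = np.flatnonzero((chroms == focal_chrom) & (np.abs(pos - focal_pos) <= window_bp))
    r2 = np.array([ld_r2(g_f, dip.geno[i]) for i in sel])
    return pd.DataFrame({"chrom": chroms[sel], "pos": pos[sel], "r2": r2})


def haploblock_span(
    dip: DiploidizedMatrix,
    focal_chrom: str,
    focal_pos: int,
    ld_threshold: float = 0.15,
    window_bp: float = 5e6,
) -> LDBlock:
    """Genomic extent of markers in LD (r^2 > threshold) with a peak summit.

    Contiguity is not required — in polyploids LD can be inconsistent with
    marker order — so the span is the min..max position of markers above the
    threshold within the window.
    """
    win = ld_window(dip, focal_chrom, focal_pos, window_bp)
    hits = win[win["r2"] > ld_threshold]
    if len(hits) <= 1:  # focal marker only (r2 = 1 with itself)
        start = end = int(focal_pos)
    else:
        start, end = int(hits["pos"].min()), int(hits["pos"].max())
    return LDBlock(
        focal_chrom=focal_chrom,
        focal_pos=int(focal_pos),
        partners=win,
        span_bp=end - start,
        span_start=start,
        span_end=end,
        threshold=ld_threshold,
    )
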