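"""Genome-wide association scans for polysomic genotypes.

Three scan models:

* additive correlation — Pearson r between the quantitative genotype (alt
  read fraction) and the phenotype, per marker;
* partial correlation — the same, compensated for the major (sex-locus)
  allele dosage O:
      r_partial = (r_by - r_ay r_ab) / sqrt[(1 - r_ay^2)(1 - r_ab^2)];
* mixed-model (LMM) scan on diploidized genotypes,
      y = b_o O + g + s tau + e,   Var[g] = K sg2,  Var[e] = I se2,
  with the kinship variance components fitted once under the null and
  reused per marker (P3D).

Correlation-type statistics get P-values by genome-wide empirical
z-standardization (Fisher-transform mode available); the LMM uses a Wald
t-test.  Genome-wide significance uses Bonferroni correction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import DiploidizedMatrix, QuantGenotypeMatrix
from .relatedness import KinshipMatrix, VarianceComponents, reml_fit

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationResult",
    "correlation_scan",
    "partial_correlation_scan",
    "lmm_null_fit",
    "lmm_scan",
    "bonferroni_threshold",
    "dosage_group_test",
    "multi_locus_r2",
]

MIN_PAIRWISE_N = 10


@dataclass
class AssociationResult:
    table: pd.DataFrame  # chrom, pos, model, stat, beta_o, p, neglog10p, pass_threshold
    model: str
    n_tests: int
    alpha: float
    neglog10_threshold: float
    null_components: VarianceComponents | None = None
    meta: dict = field(default_factory=dict)

    def top(self, k: int = 10) -> pd.DataFrame:
        return self.table.nlargest(k, "neglog10p")


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """-log10 of the Bonferroni-corrected per-test significance level."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be at least 1")
    return -math.log10(alpha / n_tests)


# ---------------------------------------------------------------------------
# masked, vectorized correlation machinery
# ---------------------------------------------------------------------------

def _masked_moments(G: np.ndarray, v: np.ndarray, M: np.ndarray):
    """Per-row pairwise-complete moments of rows of G against vector v.

    M is the validity mask (True = usable).  Returns (n, r) with NaN where
    n < MIN_PAIRWISE_N or a variance vanishes.
    """
    Gz = np.where(M, G, 0.0)
    vz = np.where(M, v[None, :], 0.0)
    n = M.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        mg = Gz.sum(axis=1) / n
        mv = vz.sum(axis=1) / n
        sgg = (Gz * Gz).sum(axis=1) / n - mg * mg
        svv = (vz * vz).sum(axis=1) / n - mv * mv
        sgv = (Gz * vz).sum(axis=1) / n - mg * mv
        r = sgv / np.sqrt(sgg * svv)
    bad = (n < MIN_PAIRWISE_N) | ~np.isfinite(r)
    r = np.where(bad, np.nan, np.clip(r, -1.0, 1.0))
    return n, r


def _coef_to_p(r: np.ndarray, n: np.ndarray, mode: str, center: str) -> np.ndarray:
    """Coefficient -> two-sided P: empirical genome-wide z or Fisher z."""
    if mode == "empirical":
        mu = 0.0 if center == "zero" else np.nanmean(r)
        sd = np.nanstd(r, ddof=1)
        if not np.isfinite(sd) or sd == 0:
            return np.where(np.isnan(r), np.nan, 1.0)
        z = (r - mu) / sd
    elif mode == "fisher":
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15)) * np.sqrt(np.maximum(n - 3, 0))
    else:
        raise ValueError("mode must be 'empirical' or 'fisher'")
    return 2 * stats.norm.sf(np.abs(z))


def _finish_scan(
    markers: pd.DataFrame,
    stat: np.ndarray,
    p: np.ndarray,
    model: str,
    alpha: float,
    beta_o: np.ndarray | None = None,
    null_components: VarianceComponents | None = None,
    meta: dict | None = None,
) -> AssociationResult:
    ok = np.isfinite(stat) & np.isfinite(p)
    n_tests = int(ok.sum())
    thr = bonferroni_threshold(alpha, max(n_tests, 1))
    with np.errstate(divide="ignore"):
        neglog = -np.log10(np.clip(p, 1e-300, None))
    table = pd.DataFrame(
        {
            "chrom": markers["chrom"].values,
            "pos": markers["pos"].values,
            "model": model,
            "stat": stat,
            "beta_o": beta_o if beta_o is not None else np.nan,
            "p": p,
            "neglog10p": neglog,
            "pass_threshold": neglog > thr,
        }
    )[ok].reset_index(drop=True)
    n_skipped = int(len(markers) - n_tests)
    if n_skipped:
        logger.info("%s scan skipped %d markers", model, n_skipped)
    return AssociationResult(
        table=table,
        model=model,
        n_tests=n_tests,
        alpha=alpha,
        neglog10_threshold=thr,
        null_components=null_components,
        meta=meta or {},
    )


def correlation_scan(
    quant: QuantGenotypeMatrix,
    y: np.ndarray,
    alpha: float = 0.1,
    mode: str = "empirical",
    center: str = "observed",
) -> AssociationResult:
    """Additive-model scan: Pearson r of alt-read fraction vs phenotype."""
    y = np.asarray(y, dtype=float)
    M = ~np.isnan(quant.ratio) & ~np.isnan(y)[None, :]
    n, r = _masked_moments(quant.ratio, y, M)
    p = _coef_to_p(r, n, mode, center)
    return _finish_scan(quant.markers, r, p, "correlation", alpha,
                        meta={"mode": mode, "center": center})


def partial_correlation_scan(
    quant: QuantGenotypeMatrix,
    y: np.ndarray,
    O: np.ndarray,
    alpha: float = 0.1,
    mode: str = "empirical",
    center: str = "observed",
) -> AssociationResult:
    """Major-locus-compensated scan via partial correlation.

    Per marker, on the individuals where the marker, the phenotype and the
    covariate O are all observed:
        r_partial = (r_by - r_ay r_ab) / sqrt[(1 - r_ay^2)(1 - r_ab^2)]
    with r_by genotype-phenotype, r_ay covariate-phenotype, r_ab
    covariate-genotype.  Markers collinear with O are skipped.
    """
    y = np.asarray(y, dtype=float)
    O = np.asarray(O, dtype=float)
    if np.any(np.isnan(O)):
        raise ValueError("covariate vector must be complete")
    M = ~np.isnan(quant.ratio) & ~np.isnan(y)[None, :] & ~np.isnan(O)[None, :]
    n, r_by = _masked_moments(quant.ratio, y, M)
    _, r_ab = _masked_moments(quant.ratio, O, M)
    # r_ay on each marker's own complete subset (constant rows of O vs y)
    Obc = np.broadcast_to(O[None, :], quant.ratio.shape)
    _, r_ay = _masked_moments(np.where(M, Obc, np.nan), y, M)
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = np.sqrt((1 - r_ay**2) * (1 - r_ab**2))
        pr = (r_by - r_ay * r_ab) / denom
    pr = np.where((np.abs(r_ay) >= 1 - 1e-12) | (np.abs(r_ab) >= 1 - 1e-12), np.nan, pr)
    p = _coef_to_p(pr, n, mode, center)
    return _finish_scan(quant.markers, pr, p, "partial-correlation", alpha,
                        meta={"mode": mode, "center": center})


# ---------------------------------------------------------------------------
# mixed model
# ---------------------------------------------------------------------------

def _design(n: int, O: np.ndarray | None) -> np.ndarray:
    X = [np.ones(n)]
    if O is not None:
        X.append(np.asarray(O, dtype=float))
    return np.column_stack(X)


def lmm_null_fit(
    y: np.ndarray,
    K: KinshipMatrix | np.ndarray,
    O: np.ndarray | None = None,
) -> VarianceComponents:
    """Null-model REML fit of y = b_o O + g + e with Var[g] = K sg2.

    Omitting O gives the plain kinship model.  The fitted components are
    reused for every marker in :func:`lmm_scan` (P3D).
    """
    y = np.asarray(y, dtype=float)
    X = _design(y.shape[0], O)
    return reml_fit(y, K, X=X)


def _gls_marker_block(
    yt: np.ndarray, Xt: np.ndarray, St: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-marker GLS t-tests in a whitened basis.

    yt (n,), Xt (n, q), St (n, m) are already whitened by the null
    covariance.  Returns (tau, t, p) per marker, re-estimating the residual
    scale per marker (t with n - q - 1 df).
    """
    n, q = Xt.shape
    Q, _ = np.linalg.qr(Xt)
    ry = yt - Q @ (Q.T @ yt)
    RS = St - Q @ (Q.T @ St)
    ss = np.einsum("ij,ij->j", RS, RS)
    sy = RS.T @ ry
    yy = float(ry @ ry)
    df = n - q - 1
    with np.errstate(invalid="ignore", divide="ignore"):
        tau = sy / ss
        rss = yy - sy * sy / ss
        se = np.sqrt(np.clip(rss, 0, None) / df / ss)
        t = tau / se
    p = 2 * stats.t.sf(np.abs(t), df)
    bad = ~np.isfinite(t) | (ss <= 1e-12)
    tau[bad], p[bad] = np.nan, np.nan
    return tau, t, p


def lmm_scan(
    dip: DiploidizedMatrix,
    y: np.ndarray,
    K: KinshipMatrix | np.ndarray,
    O: np.ndarray | None = None,
    alpha: float = 0.1,
    method: str = "p3d",
    null: VarianceComponents | None = None,
) -> AssociationResult:
    """Diploidized-genotype LMM GWAS with optional major-dosage covariate.

    ``method="p3d"`` fits the kinship variance components once under the
    null and applies generalized least squares per marker (Wald t-test for
    the SNP effect tau); ``method="exact"`` refits REML per marker and is
    meant for small oracle comparisons.  Missing genotypes are not imputed:
    markers with missingness are tested on their complete cases, grouped by
    missingness pattern.
    """
    y = np.asarray(y, dtype=float)
    A = K.A if isinstance(K, KinshipMatrix) else np.asarray(K, dtype=float)
    n = y.shape[0]
    S = dip.geno
    if S.shape[1] != n:
        raise ValueError("genotype and phenotype dimensions disagree")
    X = _design(n, O)

    if null is None:
        null = reml_fit(y, A, X=X)
    sg2, se2 = null.sigma_g2, null.sigma_e2

    m = S.shape[0]
    tau = np.full(m, np.nan)
    pvals = np.full(m, np.nan)

    if method == "exact":
        for i in range(m):
            s = S[i]
            ok = ~np.isnan(s)
            if ok.sum() < MIN_PAIRWISE_N or np.nanstd(s) == 0:
                continue
            Xi = np.column_stack([X[ok], s[ok]])
            if np.linalg.matrix_rank(Xi) < Xi.shape[1]:
                continue
            vc = reml_fit(y[ok], A[np.ix_(ok, ok)], X=Xi)
            tau[i] = vc.beta[-1]
            tstat = vc.beta[-1] / vc.beta_se[-1]
            pvals[i] = 2 * stats.t.sf(abs(tstat), ok.sum() - Xi.shape[1])
    elif method == "p3d":
        patterns: dict[bytes, np.ndarray] = {}
        rows: dict[bytes, list[int]] = {}
        miss = np.isnan(S)
        for i in range(m):
            key = miss[i].tobytes()
            rows.setdefault(key, []).append(i)
            patterns.setdefault(key, ~miss[i])
        for key, idxs in rows.items():
            ok = patterns[key]
            nn = int(ok.sum())
            if nn < MIN_PAIRWISE_N + X.shape[1]:
                continue
            V = sg2 * A[np.ix_(ok, ok)] + se2 * np.eye(nn)
            d, U = np.linalg.eigh(V)
            d = np.clip(d, 1e-12, None)
            W = U / np.sqrt(d)[None, :]  # V^{-1/2} action: W.T @ v
            yt = W.T @ y[ok]
            Xt = W.T @ X[ok]
            St = W.T @ np.nan_to_num(S[np.ix_(idxs, np.flatnonzero(ok))]).T
            tt, _, pp = _gls_marker_block(yt, Xt, St)
            tau[idxs] = tt
            pvals[idxs] = pp
    else:
        raise ValueError("method must be 'p3d' or 'exact'")

    beta_o = np.full(m, null.beta[1] if (O is not None and null.beta is not None) else np.nan)
    return _finish_scan(
        dip.markers, tau, pvals, "lmm", alpha,
        beta_o=beta_o, null_components=null,
        meta={"method": method, "covariate": O is not None},
    )


# ---------------------------------------------------------------------------
# dosage-effect and multi-locus summaries
# ---------------------------------------------------------------------------

def dosage_group_test(
    y: np.ndarray,
    O: np.ndarray,
    groups: tuple[int, int] = (1, 2),
) -> dict:
    """Welch t-test of the phenotype between two major-locus dosage classes.

    Individuals are assigned to the nearest integer dosage class; the
    default contrast is simplex (1) vs duplex (2).
    """
    y = np.asarray(y, dtype=float)
    cls = np.round(np.asarray(O, dtype=float)).astype(int)
    a = y[cls == groups[0]]
    b = y[cls == groups[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each dosage group needs at least 2 individuals")
    degenerate = a.std() == 0 and b.std() == 0
    if degenerate:
        t, p = np.nan, np.nan
    else:
        t, p = stats.ttest_ind(a, b, equal_var=False)
    return {
        "groups": groups,
        "n": (len(a), len(b)),
        "means": (float(a.mean()), float(b.mean())),
        "t": float(t) if np.isfinite(t) else np.nan,
        "p": float(p) if np.isfinite(p) else np.nan,
        "degenerate": degenerate,
    }


def multi_locus_r2(
    y: np.ndarray,
    loci: np.ndarray,
    O: np.ndarray | None = None,
    compensate: bool = False,
) -> dict:
    """OLS coefficient of determination of y on a handful of loci.

    ``loci`` is (n, k) with k <= 10 predictors (quantitative or diploidized
    genotypes); with ``compensate`` the major-locus dosage O is added as a
    predictor.  Complete cases only; rank deficiency falls back to the
    pseudo-inverse and is flagged.
    """
    y = np.asarray(y, dtype=float)
    loci = np.asarray(loci, dtype=float)
    if loci.ndim == 1:
        loci = loci[:, None]
    if loci.shape[1] > 10:
        raise ValueError("at most 10 predictor loci")
    cols = [np.ones(len(y)), *loci.T]
    if compensate:
        if O is None:
            raise ValueError("compensate=True requires the covariate O")
        cols.append(np.asarray(O, dtype=float))
    X = np.column_stack(cols)
    ok = np.all(np.isfinite(X), axis=1) & np.isfinite(y)
    X, yv = X[ok], y[ok]
    rank = np.linalg.matrix_rank(X)
    deficient = rank < X.shape[1]
    beta = np.linalg.pinv(X) @ yv
    resid = yv - X @ beta
    tss = float(np.sum((yv - yv.mean()) ** 2))
    r2 = 1.0 - float(resid @ resid) / tss if tss > 0 else np.nan
    return {"r2": r2, "n": int(ok.sum()), "k": X.shape[1] - 1, "rank_deficient": bool(deficient)}
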