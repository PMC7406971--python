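"""Genomic relationship matrix and REML variance components.

The additive relationship between individuals j and k is

    A_jk = sum_i (x_ij - 2 p_i)(x_ik - 2 p_i) / [2 p_i (1 - p_i)]

over diploidized genotypes x in {0, 1, 2} (reference-allele copies) with
reference-allele frequency p_i.  Narrow-sense heritability comes from the
variance components of y ~ N(X b, A sg2 + I se2), estimated by restricted
maximum likelihood via an eigendecomposition of A and a bounded 1-D search
over the variance ratio:

    h2 = sg2 / (sg2 + se2).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .genotypes import DiploidizedMatrix

logger = logging.getLogger(__name__)

__all__ = ["KinshipMatrix", "VarianceComponents", "grm", "reml_fit", "heritability"]

_LOG_RATIO_BOUNDS = (np.log(1e-5), np.log(1e5))


@dataclass
class KinshipMatrix:
    A: np.ndarray
    ids: list[str]

    def __post_init__(self) -> None:
        A = np.asarray(self.A, dtype=float)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("kinship matrix must be square")
        if not np.allclose(A, A.T):
            raise ValueError("kinship matrix must be symmetric")
        self.A = (A + A.T) / 2.0


@dataclass
class VarianceComponents:
    sigma_g2: float
    sigma_e2: float
    h2: float
    log_restricted_likelihood: float
    beta: np.ndarray | None = None
    beta_se: np.ndarray | None = None
    flags: list[str] = field(default_factory=list)


def grm(dip: DiploidizedMatrix, literal_sum: bool = False) -> KinshipMatrix:
    """Additive GRM from diploidized genotypes.

    Markers with p in {0, 1} must have been MAF-filtered beforehand; missing
    genotypes are mean-imputed at 2 p_i (the GRM needs complete columns).
    By default the per-marker sum is rescaled to a unit mean diagonal, so
    sigma_g2 is on the phenotypic-variance scale and heritability is
    well-defined; in a Hardy-Weinberg population this coincides with
    dividing by the marker count m, but in an F1 family — where genotype
    variance at a marker is below 2p(1-p) — it does not.  ``literal_sum``
    emits the raw per-marker sum instead.
    """
    X = np.array(dip.geno, dtype=float)
    p = dip.p
    if np.any((p <= 0) | (p >= 1) | ~np.isfinite(p)):
        raise ValueError("GRM requires 0 < p_i < 1 at every marker; apply the MAF filter first")
    center = 2.0 * p
    miss = np.isnan(X)
    if miss.any():
        X[miss] = np.broadcast_to(center[:, None], X.shape)[miss]
    Xc = (X - center[:, None]) / np.sqrt(2.0 * p * (1.0 - p))[:, None]
    A = Xc.T @ Xc
    if not literal_sum:
        mean_diag = np.trace(A) / A.shape[0]
        A /= mean_diag if mean_diag > 0 else dip.m
    return KinshipMatrix(A=A, ids=list(dip.individuals))


def _reml_profile(
    log_lambda: float,
    d: np.ndarray,
    yt: np.ndarray,
    Xt: np.ndarray,
) -> tuple[float, float, np.ndarray, np.ndarray]:
    """Profiled restricted log-likelihood at variance ratio lambda = sg2/se2.

    Works in the eigenbasis of A where V/se2 = diag(lambda d + 1).
    Returns (restricted loglik, sigma_e2, beta, cov_beta_unit).
    """
    lam = np.exp(log_lambda)
    h = lam * d + 1.0
    w = 1.0 / h
    XtW = Xt * w[:, None]
    G = Xt.T @ XtW  # X' V^-1 X (unit se2)
    Gi = np.linalg.inv(G)
    beta = Gi @ (XtW.T @ yt)
    r = yt - Xt @ beta
    n, q = Xt.shape
    rss = float(np.sum(w * r * r))
    se2 = rss / (n - q)
    sign, logdetG = np.linalg.slogdet(G)
    ll = -0.5 * (
        (n - q) * (np.log(2 * np.pi * se2) + 1.0)
        + float(np.sum(np.log(h)))
        + logdetG
    )
    return ll, se2, beta, Gi


def reml_fit(
    y: np.ndarray,
    K: KinshipMatrix | np.ndarray,
    X: np.ndarray | None = None,
    jitter: float = 1e-6,
) -> VarianceComponents:
    """REML estimation of (sigma_g2, sigma_e2) for y ~ N(X b, A sg2 + I se2).

    X defaults to the intercept.  The restricted likelihood is maximized by
    bounded scalar search on the log variance ratio in [1e-5, 1e5];
    boundary solutions are compared against the pure-noise (sg2 = 0) limit.
    """
    y = np.asarray(y, dtype=float).ravel()
    A = K.A if isinstance(K, KinshipMatrix) else np.asarray(K, dtype=float)
    n = y.shape[0]
    if n < 3:
        raise ValueError("REML needs at least 3 individuals")
    if A.shape != (n, n):
        raise ValueError("kinship dimension does not match the phenotype")
    if not np.all(np.isfinite(y)):
        raise ValueError("phenotype vector must be complete; drop missing individuals first")
    X = np.ones((n, 1)) if X is None else np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    q = X.shape[1]

    flags: list[str] = []
    if np.var(y) == 0:
        warnings.warn("constant phenotype: variance components are zero", stacklevel=2)
        return VarianceComponents(0.0, 0.0, 0.0, np.nan, flags=["constant-phenotype"])

    d, U = np.linalg.eigh((A + A.T) / 2.0)
    if d.min() < 0:
        d = d + jitter
        flags.append("jittered")
        if d.min() < -1e-8:
            raise np.linalg.LinAlgError("kinship matrix is not PSD beyond jitter tolerance")
    d = np.clip(d, 0.0, None)
    if d.max() - d.min() < 1e-10 * max(d.max(), 1.0):
        flags.append("unidentifiable")  # A proportional to I: flat in the ratio

    yt = U.T @ y
    Xt = U.T @ X

    res = minimize_scalar(
        lambda ll: -_reml_profile(ll, d, yt, Xt)[0],
        bounds=_LOG_RATIO_BOUNDS,
        method="bounded",
        options={"xatol": 1e-8},
    )
    ll_hat, se2, beta, Gi = _reml_profile(res.x, d, yt, Xt)
    lam = float(np.exp(res.x))

    # pure-noise limit: compare against lambda -> 0
    ll_lo, se2_lo, beta_lo, Gi_lo = _reml_profile(_LOG_RATIO_BOUNDS[0], d, yt, Xt)
    if ll_lo >= ll_hat - 1e-9 and "unidentifiable" not in flags:
        lam, ll_hat, se2, beta, Gi = np.exp(_LOG_RATIO_BOUNDS[0]), ll_lo, se2_lo, beta_lo, Gi_lo
        flags.append("boundary-low")

    sg2 = lam * se2
    h2 = sg2 / (sg2 + se2) if (sg2 + se2) > 0 else 0.0
    beta_se = np.sqrt(np.diag(Gi) * se2)
    return VarianceComponents(
        sigma_g2=float(sg2),
        sigma_e2=float(se2),
        h2=float(h2),
        log_restricted_likelihood=float(ll_hat),
        beta=beta,
        beta_se=beta_se,
        flags=flags,
    )


def heritability(vc: VarianceComponents) -> float:
    """Narrow-sense heritability sg2 / (sg2 + se2)."""
    if vc.sigma_g2 < 0 or vc.sigma_e2 < 0:
        raise ValueError("variance components must be non-negative")
    tot = vc.sigma_g2 + vc.sigma_e2
    if tot == 0:
        warnings.warn("both variance components are zero: h2 undefined, reporting 0", stacklevel=2)
        return 0.0
    return vc.sigma_g2 / tot
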