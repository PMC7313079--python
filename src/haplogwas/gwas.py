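"""Population-structure covariates and single-locus mixed-model GWAS.

The association model is the standard single-locus linear mixed model
y = X beta + g + e with g ~ N(0, sigma_g^2 K), K the standardized-
genotype relationship matrix Z Z^T / m. Following the factored-spectral
approach, K is eigendecomposed once; the noise/genetic variance ratio
delta = sigma_e^2 / sigma_g^2 is estimated per trait by maximizing the
rotated REML profile likelihood over log delta in [-10, 10]; each SNP is
then tested with a 1-df Wald statistic in the rotated (whitened) model,
with the candidate SNP added to the fixed effects. Residual inflation of
the test statistics is corrected by genomic control (median-based
lambda), and per-trait Benjamini-Hochberg q-values control the FDR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import minimize_scalar
from skbio import DistanceMatrix
from skbio.stats.ordination import pcoa as _skbio_pcoa
from statsmodels.stats.multitest import multipletests

CHI2_1_MEDIAN = sps.chi2.ppf(0.5, 1)  # 0.45494...

EARTH_RADIUS_KM = 6371.0


@dataclass
class CovariateSet:
    """Centered sample x k covariate matrix with per-axis variance shares."""

    matrix: np.ndarray
    source: str  # genotype_pca | geographic_pcoa | merged
    variance_explained: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if np.isnan(self.matrix).any():
            raise ValueError("covariates must not contain missing values")
        self.matrix = self.matrix - self.matrix.mean(axis=0, keepdims=True)

    @property
    def k(self) -> int:
        return self.matrix.shape[1]


def merge_covariates(a: CovariateSet, b: CovariateSet) -> CovariateSet:
    if a.matrix.shape[0] != b.matrix.shape[0]:
        raise ValueError("covariate sets have different sample counts")
    return CovariateSet(
        np.column_stack([a.matrix, b.matrix]),
        "merged",
        np.concatenate([a.variance_explained, b.variance_explained]),
    )


def _standardized_dosages(gm) -> tuple[np.ndarray, np.ndarray]:
    """Mean-imputed, centered, unit-variance dosages; drops monomorphic."""
    d = gm.dosages.copy()
    mean = np.nanmean(d, axis=0)
    r, c = np.nonzero(np.isnan(d))
    d[r, c] = mean[c]
    d -= d.mean(axis=0, keepdims=True)
    sd = d.std(axis=0)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all variants are monomorphic")
    return d[:, keep] / sd[keep], keep


def genotype_pca(gm, k: int = 8) -> CovariateSet:
    """Top-k principal components of the standardized genotype matrix."""
    if k >= min(gm.n_samples, gm.n_variants):
        raise ValueError("k must be smaller than both matrix dimensions")
    Z, _ = _standardized_dosages(gm)
    U, s, _vt = np.linalg.svd(Z, full_matrices=False)
    scores = U[:, :k] * s[:k]
    frac = (s**2) / np.sum(s**2)
    return CovariateSet(scores, "genotype_pca", frac[:k])


def haversine_matrix(lat: np.ndarray, lon: np.ndarray) -> np.ndarray:
    """Great-circle distance matrix (km) between lat/lon points (degrees)."""
    phi = np.radians(np.asarray(lat, float))
    lam = np.radians(np.asarray(lon, float))
    dphi = phi[:, None] - phi[None, :]
    dlam = lam[:, None] - lam[None, :]
    a = np.sin(dphi / 2) ** 2 + np.cos(phi)[:, None] * np.cos(phi)[None, :] * np.sin(dlam / 2) ** 2
    a = np.clip(a, 0.0, 1.0)
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))


def geographic_pcoa(coords: pd.DataFrame, k: int = 2) -> CovariateSet:
    """Classical metric scaling of great-circle distances between sites.

    Axes with non-positive eigenvalues are discarded; variance shares are
    eigenvalue fractions over the positive spectrum.
    """
    D = haversine_matrix(coords["lat"].to_numpy(), coords["lon"].to_numpy())
    if not (D > 0).any():
        raise ValueError("all coordinates identical: zero distance matrix")
    ids = [str(i) for i in range(D.shape[0])]
    ord_res = _skbio_pcoa(DistanceMatrix(D, ids), method="eigh",
                          number_of_dimensions=0)
    eig = ord_res.eigvals.to_numpy()
    pos = eig > 1e-9 * eig.max()
    n_pos = int(pos.sum())
    k_eff = min(k, n_pos)
    scores = ord_res.samples.to_numpy()[:, :k_eff]
    frac = eig[:k_eff] / eig[pos].sum()
    return CovariateSet(scores, "geographic_pcoa", frac)


@dataclass
class GWASResult:
    """Per-SNP association results for one trait."""

    trait: str
    table: pd.DataFrame = field(repr=False)  # chrom,pos,beta,se,stat,p_raw,p_gc,q
    lambda_gc: float = 1.0
    method: str = "lmm"
    delta: float | None = None  # REML noise/genetic variance ratio

    @property
    def n_hits(self) -> int:
        return int((self.table["q"] < 0.05).sum())


def genomic_control(statistics: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Median-based genomic-control correction of 1-df chi-square stats.

    lambda = median(stat) / median(chi2_1); statistics are deflated only
    when lambda > 1. Returns (lambda, adjusted stats, adjusted p).
    """
    stats_arr = np.asarray(statistics, dtype=float)
    if stats_arr.size == 0:
        raise ValueError("empty statistics")
    if (stats_arr < 0).any():
        raise ValueError("chi-square statistics must be non-negative")
    lam = float(np.median(stats_arr) / CHI2_1_MEDIAN)
    adj = stats_arr / lam if lam > 1.0 else stats_arr.copy()
    p = sps.chi2.sf(adj, df=1)
    return lam, adj, p


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _check_full_rank(X: np.ndarray) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _q, r = np.linalg.qr(X)
        diag = np.abs(np.diag(r))
        bad = np.flatnonzero(diag < 1e-8 * diag.max())
        raise ValueError(f"rank-deficient covariates: columns {bad.tolist()}")


def _reml_neg_loglik(log_delta: float, S: np.ndarray, Xr: np.ndarray,
                     yr: np.ndarray) -> float:
    delta = np.exp(log_delta)
    w = 1.0 / (S + delta)
    n, p = Xr.shape
    WX = Xr * w[:, None]
    A = Xr.T @ WX
    b = WX.T @ yr
    try:
        beta = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        return 1e30
    resid = yr - Xr @ beta
    rss = float(np.sum(w * resid**2))
    if rss <= 0:
        return 1e30
    sign, logdet_A = np.linalg.slogdet(A)
    if sign <= 0:
        return 1e30
    nf = n - p
    ll = -0.5 * (
        nf * np.log(2 * np.pi * rss / nf)
        + np.sum(np.log(S + delta))
        + logdet_A
        + nf
    )
    return -ll


def estimate_delta(S: np.ndarray, Xr: np.ndarray, yr: np.ndarray,
                   log_bounds: tuple[float, float] = (-10.0, 10.0),
                   n_grid: int = 41) -> float:
    """REML estimate of delta = sigma_e^2 / sigma_g^2 (grid + refinement)."""
    grid = np.linspace(log_bounds[0], log_bounds[1], n_grid)
    vals = [_reml_neg_loglik(g, S, Xr, yr) for g in grid]
    k = int(np.argmin(vals))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, n_grid - 1)]
    res = minimize_scalar(_reml_neg_loglik, bounds=(lo, hi), args=(S, Xr, yr),
                          method="bounded", options={"xatol": 1e-6})
    return float(np.exp(res.x))


def kinship_matrix(gm) -> np.ndarray:
    """Standardized-genotype relationship matrix K = Z Z^T / m."""
    Z, _ = _standardized_dosages(gm)
    return (Z @ Z.T) / Z.shape[1]


def gwas_scan(
    gm,
    trait: pd.Series | np.ndarray,
    covariates: CovariateSet | None = None,
    method: str = "lmm",
    trait_name: str = "trait",
    kinship_eig: tuple[np.ndarray, np.ndarray] | None = None,
) -> GWASResult:
    """Single-trait genome scan (LMM or OLS) with genomic control and FDR.

    Samples with a missing trait value are dropped; missing dosages are
    mean-imputed per variant. ``kinship_eig`` (eigenvalues, eigenvectors
    of K over all samples) can be precomputed and is reused whenever the
    trait is complete.
    """
    y_all = np.asarray(trait, dtype=float)
    if y_all.shape[0] != gm.n_samples:
        raise ValueError("trait length does not match sample count")
    keep = np.isfinite(y_all)
    if keep.sum() < 10:
        raise ValueError("fewer than 10 samples with a trait value")

    d = gm.dosages.copy()
    mean = np.nanmean(d, axis=0)
    r, c = np.nonzero(np.isnan(d))
    d[r, c] = mean[c]

    y = y_all[keep]
    G = d[keep]
    C = covariates.matrix[keep] if covariates is not None else np.empty((keep.sum(), 0))
    n = y.size
    X0 = np.column_stack([np.ones(n), C])
    _check_full_rank(X0)

    if method == "lmm":
        if keep.all() and kinship_eig is not None:
            S, U = kinship_eig
        else:
            Zs = G - G.mean(axis=0, keepdims=True)
            sd = Zs.std(axis=0)
            poly = sd > 0
            if not poly.any():
                raise ValueError("all variants are monomorphic")
            Zs = Zs[:, poly] / sd[poly]
            K = (Zs @ Zs.T) / Zs.shape[1]
            S, U = np.linalg.eigh(K)
            S = np.clip(S, 0.0, None)
        yr = U.T @ y
        Xr = U.T @ X0
        Gr = U.T @ G
        delta = estimate_delta(S, Xr, yr)
        w = 1.0 / (S + delta)
    elif method == "ols":
        yr, Xr, Gr = y, X0, G
        delta = None
        w = np.ones(n)
    else:
        raise ValueError(f"unknown method {method!r}")

    beta, se, stat = _wald_scan(yr, Xr, Gr, w)
    p_raw = sps.chi2.sf(stat, df=1)
    p_raw = np.clip(p_raw, 1e-300, 1.0)
    lam, _adj, p_gc = genomic_control(stat)
    p_gc = np.clip(p_gc, 1e-300, 1.0)
    q = bh_fdr(p_gc)

    table = gm.variants.copy()
    table["beta"] = beta
    table["se"] = se
    table["stat"] = stat
    table["p_raw"] = p_raw
    table["p_gc"] = p_gc
    table["q"] = q
    return GWASResult(trait_name, table, lam, method, delta)


def _wald_scan(yr: np.ndarray, Xr: np.ndarray, Gr: np.ndarray, w: np.ndarray):
    """Vectorized per-SNP GLS Wald tests with diagonal weights ``w``.

    Fits y ~ [X0, g] in the rotated model for every SNP column g using
    the Schur complement of the (fixed) covariate normal equations.
    """
    n, p = Xr.shape
    WX = Xr * w[:, None]
    A = Xr.T @ WX
    Ainv = np.linalg.inv(A)
    b = WX.T @ yr
    yWy = float(np.sum(w * yr * yr))
    base_rss_term = b @ Ainv @ b

    GW = Gr * w[:, None]
    gWg = np.einsum("ij,ij->j", Gr, GW)
    gWX = Gr.T @ WX          # m x p
    gWy = GW.T @ yr          # m

    u = gWX @ Ainv           # m x p
    denom = gWg - np.einsum("ij,ij->i", u, gWX)
    num = gWy - u @ b
    dof = n - p - 1
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = num / denom
        rss = yWy - base_rss_term - num * beta
        sigma2 = rss / dof
        se = np.sqrt(sigma2 / denom)
        stat = (beta / se) ** 2
    bad = ~np.isfinite(stat) | (denom <= 1e-12)
    beta[bad] = 0.0
    se[bad] = np.inf
    stat[bad] = 0.0
    return beta, se, stat


def gwas_many(
    gm,
    traits: pd.DataFrame,
    covariates: CovariateSet | None,
    method: str = "lmm",
) -> dict[str, GWASResult]:
    """Scan every trait column, reusing one kinship eigendecomposition."""
    eig = None
    if method == "lmm":
        K = kinship_matrix(gm)
        S, U = np.linalg.eigh(K)
        eig = (np.clip(S, 0.0, None), U)
    out = {}
    for name in traits.columns:
        out[name] = gwas_scan(
            gm, traits[name].to_numpy(), covariates, method=method,
            trait_name=name, kinship_eig=eig,
        )
    return out
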