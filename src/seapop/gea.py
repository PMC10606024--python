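"""Genotype-environment association scans and genome scans for selection.

Three per-locus scans share a calibration backbone (genomic inflation
factor + FDR q-values):

* ``rda_scan`` — individual-level (partial) redundancy analysis; loci are
  ranked by the Mahalanobis distance of their loadings on the significant
  constrained axes.
* ``lfmm_ridge_scan`` — latent factor mixed model: per-locus regression on
  environmental predictors with k latent factors (ridge-projected SVD)
  absorbing population structure.
* ``pca_scan`` — a principal-component differentiation scan: per-locus
  z-scores against the k leading genotype PCs, combined by Mahalanobis
  distance (the pcadapt-style statistic).

All scans impute-first (no missing genotypes allowed), calibrate their
chi-square-scale statistics by the median-based genomic inflation factor,
and call candidates at q < alpha (Benjamini-Hochberg by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datatypes import MISSING, DataError, GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class GeaConfig:
    """Shared scan settings."""

    alpha: float = 0.05
    gif: float | str = "auto"     # "auto" = median-based estimate, or a fixed value
    n_perm_axes: int = 999        # permutations for RDA axis significance
    seed: int | None = None
    ridge: float = 100.0          # latent-factor ridge penalty, x leading singular value^2

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise DataError("alpha must be in (0, 1)")


# ---------------------------------------------------------------------------
# calibration primitives


def genomic_inflation_factor(stats: np.ndarray, df: int):
    """Median-based genomic inflation factor and recalibrated p-values.

    lambda = median(stats) / median of chi-square(df); adjusted statistics
    are stats/lambda with p-values from chi-square(df).

    Returns (lambda, adjusted stats, p-values).
    """
    stats = np.asarray(stats, dtype=float)
    if df < 1:
        raise DataError("df must be >= 1")
    if (stats < 0).any() or not (stats > 0).any():
        raise DataError("statistics must be non-negative chi-square-scale values")
    if stats.size < 20:
        logger.warning("fewer than 20 statistics; inflation estimate is unstable")
    lam = float(np.median(stats) / sps.chi2.median(df))
    adj = stats / lam
    p = sps.chi2.sf(adj, df)
    return lam, adj, p


def qvalues(p: np.ndarray, method: str = "bh") -> np.ndarray:
    """FDR q-values: Benjamini-Hochberg step-up or Storey's pi0-scaled BH."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise DataError("p-values must be in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    q_bh = multipletests(p, method="fdr_bh")[1]
    if method == "bh":
        return q_bh
    if method == "storey":
        lam_grid = np.arange(0.05, 0.96, 0.05)
        m = p.size
        pi0_grid = np.array([(p > l).sum() / (m * (1.0 - l)) for l in lam_grid])
        # smooth with a cubic fit and evaluate at the largest lambda
        coef = np.polyfit(lam_grid, pi0_grid, 3)
        pi0 = float(np.clip(np.polyval(coef, lam_grid.max()), 0.0, 1.0))
        if pi0 <= 0:
            pi0 = 1.0
        return np.minimum(q_bh * pi0, 1.0)
    raise DataError(f"unknown q-value method {method!r}")


# ---------------------------------------------------------------------------
# shared regression machinery


def _check_imputed(g: GenotypeMatrix) -> np.ndarray:
    if (g.calls == MISSING).any():
        raise DataError("scan requires imputed genotypes (no missing calls)")
    return g.calls.astype(float)


def _multi_ols(Y: np.ndarray, D: np.ndarray):
    """Per-column OLS of Y (n x L) on a shared design D (n x p).

    Returns (coefficients p x L, standard errors p x L, residual df).
    """
    n, p = D.shape
    dtd_inv = np.linalg.inv(D.T @ D)
    B = dtd_inv @ (D.T @ Y)
    resid = Y - D @ B
    dof = n - p
    sigma2 = (resid ** 2).sum(axis=0) / dof
    se = np.sqrt(np.outer(np.diag(dtd_inv), sigma2))
    return B, se, dof


def _mahalanobis_sq(Z: np.ndarray) -> np.ndarray:
    """Classical-covariance squared Mahalanobis distance of each row."""
    mu = Z.mean(axis=0)
    cov = np.cov(Z, rowvar=False)
    cov = np.atleast_2d(cov)
    inv = np.linalg.inv(cov)
    Zc = Z - mu
    return np.einsum("ij,jk,ik->i", Zc, inv, Zc)


def _finalize(
    locus_index: np.ndarray,
    method: str,
    stat: np.ndarray,
    df: int,
    cfg: GeaConfig,
    predictor: np.ndarray | None = None,
    k_used: int = 0,
    q_method: str = "bh",
) -> pd.DataFrame:
    raw_p = sps.chi2.sf(stat, df)
    if cfg.gif == "auto":
        lam, _, gif_p = genomic_inflation_factor(stat, df)
    else:
        lam = float(cfg.gif)
        gif_p = sps.chi2.sf(stat / lam, df)
    q = qvalues(gif_p, method=q_method)
    out = pd.DataFrame({
        "locus": locus_index,
        "method": method,
        "statistic": stat,
        "raw_p": raw_p,
        "gif_p": gif_p,
        "q": q,
        "candidate": q < cfg.alpha,
        "predictor": predictor if predictor is not None else "",
        "k_used": k_used,
    })
    out.attrs["gif"] = lam
    return out


def _assign_predictors(G: np.ndarray, X: np.ndarray, names: list[str]) -> np.ndarray:
    """Per locus, the predictor with the largest |correlation| to the genotypes."""
    Gz = G - G.mean(axis=0)
    Xz = X - X.mean(axis=0)
    gs = Gz.std(axis=0)
    xs = Xz.std(axis=0)
    gs[gs == 0] = np.inf
    corr = (Xz.T @ Gz) / (len(G) * np.outer(xs, gs))
    best = np.abs(corr).argmax(axis=0)
    return np.asarray(names, dtype=object)[best]


# ---------------------------------------------------------------------------
# scans


def rda_scan(
    g_imputed: GenotypeMatrix,
    predictors: pd.DataFrame,
    cfg: GeaConfig | None = None,
    condition_on: pd.DataFrame | None = None,
    q_method: str = "bh",
):
    """Individual-level (partial) RDA scan.

    Genotypes are centred and regressed on the predictor matrix (optionally
    after partialling out ``condition_on`` from both sides — pRDA).  Axis
    significance is assessed by permutation; locus loadings on the
    significant axes are combined into a Mahalanobis distance with
    df = number of retained axes, recalibrated by the genomic inflation
    factor, and converted to q-values.

    Returns (ScanResult DataFrame, info dict with axis eigenvalues/p-values
    and the inflation factor).
    """
    cfg = cfg or GeaConfig()
    G = _check_imputed(g_imputed)
    X = predictors.to_numpy(dtype=float)
    names = list(predictors.columns)
    n, L = G.shape
    if X.shape[1] >= n:
        raise DataError("more predictors than individuals")

    Yc = G - G.mean(axis=0)
    Xc = X - X.mean(axis=0)
    if condition_on is not None:
        Z = condition_on.to_numpy(dtype=float)
        Zc = Z - Z.mean(axis=0)
        Qz, _ = np.linalg.qr(Zc)
        Yc = Yc - Qz @ (Qz.T @ Yc)
        Xc = Xc - Qz @ (Qz.T @ Xc)

    Qx, Rx = np.linalg.qr(Xc)
    rank = (np.abs(np.diag(Rx)) > np.abs(np.diag(Rx)).max() * 1e-10).sum()
    Qx = Qx[:, :rank]

    C = Qx.T @ Yc                                   # rank x L projection
    U, s, Vt = np.linalg.svd(C, full_matrices=False)
    eig = s ** 2 / (n - 1)

    rng = np.random.default_rng(cfg.seed)
    n_ax = len(eig)
    exceed = np.zeros(n_ax)
    for _ in range(cfg.n_perm_axes):
        perm = rng.permutation(n)
        sp = np.linalg.svd(Qx.T @ Yc[perm], compute_uv=False)
        lam_p = sp ** 2 / (n - 1)
        exceed += lam_p[:n_ax] >= eig
    axis_p = (1.0 + exceed) / (cfg.n_perm_axes + 1.0)

    # sequential retention: keep leading axes while significant
    K = 0
    for pk in axis_p:
        if pk <= cfg.alpha:
            K += 1
        else:
            break
    info = {"eigenvalues": eig, "axis_p": axis_p, "k_used": K}
    if K == 0:
        logger.info("no significant constrained axes; no candidates")
        empty = _empty_scan(L, "rda")
        info["gif"] = np.nan
        return empty, info

    loadings = Vt[:K].T * s[:K]                     # L x K locus scores
    d2 = _mahalanobis_sq(loadings)
    res = _finalize(np.arange(L), "rda", d2, K, cfg, k_used=K, q_method=q_method)
    res.loc[res["candidate"], "predictor"] = _assign_predictors(
        G[:, res["candidate"].to_numpy()], X, names
    )
    info["gif"] = res.attrs["gif"]
    return res, info


def _empty_scan(L: int, method: str) -> pd.DataFrame:
    return pd.DataFrame({
        "locus": np.arange(L), "method": method, "statistic": np.nan,
        "raw_p": 1.0, "gif_p": 1.0, "q": 1.0, "candidate": False,
        "predictor": "", "k_used": 0,
    })


def lfmm_ridge_scan(
    g_imputed: GenotypeMatrix,
    predictors: pd.DataFrame,
    k: int,
    cfg: GeaConfig | None = None,
    q_method: str = "bh",
):
    """Latent factor mixed model scan (ridge latent-factor estimation).

    Stage 1: latent factors = the top-k left singular vectors of the
    genotype matrix after a ridge-regularised projection removing the
    predictors.  The default penalty is large, which keeps the factor
    estimates close to the raw genotype SVD: confounded structure then
    stays in the factors rather than being attributed to the environment
    (the conservative, calibrated regime; a small penalty recovers the
    fully residualised factors).  Stage 2: per locus OLS of genotype on
    [intercept, predictors, factors]; the predictor t-statistics (squared)
    are calibrated per predictor with the genomic inflation factor (df=1)
    and converted to q-values.  A locus is a candidate when q < alpha for
    at least one predictor.

    Returns (long ScanResult DataFrame: one row per locus x predictor,
    info dict with per-predictor inflation factors).
    """
    cfg = cfg or GeaConfig()
    G = _check_imputed(g_imputed)
    X = predictors.to_numpy(dtype=float)
    names = list(predictors.columns)
    n, L = G.shape
    q_pred = X.shape[1]
    if k < 0 or k >= min(n, L):
        raise DataError("k must satisfy 0 <= k < min(n_samples, n_loci)")

    Gc = G - G.mean(axis=0)
    Xc = X - X.mean(axis=0)

    if k > 0:
        s_lead = np.linalg.svd(Xc, compute_uv=False)[0]
        lam = cfg.ridge * max(s_lead ** 2, 1.0)
        P = np.eye(n) - Xc @ np.linalg.solve(Xc.T @ Xc + lam * np.eye(q_pred), Xc.T)
        W = P @ Gc
        U, _, _ = np.linalg.svd(W, full_matrices=False)
        factors = U[:, :k]
        D = np.column_stack([np.ones(n), Xc, factors])
    else:
        D = np.column_stack([np.ones(n), Xc])

    B, se, dof = _multi_ols(Gc, D)
    var0 = Gc.var(axis=0) == 0           # monomorphic after imputation
    rows = []
    gifs = {}
    for j in range(q_pred):
        with np.errstate(invalid="ignore", divide="ignore"):
            t = B[1 + j] / se[1 + j]
        t[var0 | ~np.isfinite(t)] = 0.0
        raw_p = 2.0 * sps.t.sf(np.abs(t), dof)
        z2 = t ** 2
        if cfg.gif == "auto":
            lam_j, _, gif_p = genomic_inflation_factor(z2, 1)
        else:
            lam_j = float(cfg.gif)
            gif_p = sps.chi2.sf(z2 / lam_j, 1)
        qv = qvalues(gif_p, method=q_method)
        gifs[names[j]] = lam_j
        rows.append(pd.DataFrame({
            "locus": np.arange(L), "method": "lfmm", "statistic": z2,
            "raw_p": raw_p, "gif_p": gif_p, "q": qv,
            "candidate": qv < cfg.alpha, "predictor": names[j], "k_used": k,
        }))
    res = pd.concat(rows, ignore_index=True)
    info = {"gif": gifs, "k_used": k}
    return res, info


def pca_scan(
    g_imputed: GenotypeMatrix,
    k: int,
    cfg: GeaConfig | None = None,
    q_method: str = "bh",
):
    """PCA-based differentiation scan (pcadapt-style Mahalanobis statistic).

    Per locus, z-scores from regressing the genotype on the k leading
    genotype principal components; the z-vectors are combined across loci
    by a classical-covariance Mahalanobis distance with df=k, calibrated by
    the genomic inflation factor, and converted to q-values.
    """
    cfg = cfg or GeaConfig()
    G = _check_imputed(g_imputed)
    n, L = G.shape
    if k < 1 or k > min(n, L) - 1:
        raise DataError("k out of range for the available components")
    Gc = G - G.mean(axis=0)
    sd = Gc.std(axis=0)
    sd[sd == 0] = 1.0
    Gs = Gc / sd
    U, s, _ = np.linalg.svd(Gs, full_matrices=False)
    scores = U[:, :k] * s[:k]

    D = np.column_stack([np.ones(n), scores])
    B, se, dof = _multi_ols(Gs, D)
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = (B[1:] / se[1:]).T                       # L x k z-scores
    Z[~np.isfinite(Z)] = 0.0
    Z[Gc.var(axis=0) == 0] = 0.0
    d2 = _mahalanobis_sq(Z)
    res = _finalize(np.arange(L), "pca_scan", d2, k, cfg, k_used=k, q_method=q_method)
    info = {"gif": res.attrs["gif"], "k_used": k,
            "explained": (s[:k] ** 2) / (s ** 2).sum()}
    return res, info


# ---------------------------------------------------------------------------
# set operations on candidates


def derive_neutral_set(g: GenotypeMatrix, *scan_results: pd.DataFrame) -> GenotypeMatrix:
    """Remove the union of candidate loci over scans; return the complement."""
    if not scan_results:
        raise DataError("need at least one scan result")
    outliers: set[int] = set()
    for res in scan_results:
        outliers |= set(res.loc[res["candidate"], "locus"].astype(int))
    if len(outliers) >= g.n_loci:
        raise DataError("every locus flagged as an outlier; no neutral set remains")
    keep = np.ones(g.n_loci, dtype=bool)
    keep[sorted(outliers)] = False
    return g.take_loci(keep)


def candidate_overlap(
    scan_results: dict[str, pd.DataFrame],
    radlocus_of: pd.Series | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Method-membership table and intersection counts for candidate loci.

    ``radlocus_of`` (index = locus id, value = RAD locus) adds counting of
    unique environment-associated RAD loci per method and overall.
    """
    cand_sets = {
        name: set(res.loc[res["candidate"], "locus"].astype(int))
        for name, res in scan_results.items()
    }
    all_loci = sorted(set().union(*cand_sets.values())) if cand_sets else []
    members = pd.DataFrame(
        {name: [loc in s for loc in all_loci] for name, s in cand_sets.items()},
        index=pd.Index(all_loci, name="locus"),
    )
    inter = set.intersection(*cand_sets.values()) if cand_sets else set()
    union = set().union(*cand_sets.values())
    counts = {
        "per_method": {name: len(s) for name, s in cand_sets.items()},
        "union": len(union),
        "intersection": len(inter),
    }
    if radlocus_of is not None:
        counts["unique_rad_loci"] = {
            name: radlocus_of.loc[sorted(s)].nunique() for name, s in cand_sets.items()
        }
        counts["unique_rad_loci"]["union"] = (
            radlocus_of.loc[sorted(union)].nunique() if union else 0
        )
    return members, counts
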