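"""Spatial predictors and spatially explicit ordination.

Builds distance-based Moran eigenvector maps (dbMEMs) from a geographic
distance matrix, tests isolation by distance with the Mantel permutation
test, selects spatial predictors by forward selection with the
double-stopping rule, and fits site-level redundancy analysis (RDA) on
allele frequencies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree

from .datatypes import DataError

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0


def geo_to_cartesian(samples: pd.DataFrame) -> pd.DataFrame:
    """Local azimuthal-equidistant projection of lat/lon (degrees) to x,y km.

    Centred on the coordinate centroid; distances from the centroid are
    exact and pairwise distances stay within ~1% of great-circle for
    regional (sub-15-degree) spans.  Warns near the poles where a planar
    treatment stops making sense.
    """
    lat = np.asarray(samples["lat"], dtype=float)
    lon = np.asarray(samples["lon"], dtype=float)
    if (np.abs(lat) > 90).any() or (np.abs(lon) > 180).any():
        raise DataError("coordinates outside valid degree ranges")
    if (np.abs(lat) > 85).any():
        logger.warning("pole-adjacent sites; projection distortion will be large")
    phi = np.deg2rad(lat)
    lam = np.deg2rad(lon)
    phi0 = np.deg2rad(lat.mean())
    lam0 = np.deg2rad(lon.mean())
    cos_c = np.sin(phi0) * np.sin(phi) + np.cos(phi0) * np.cos(phi) * np.cos(lam - lam0)
    c = np.arccos(np.clip(cos_c, -1.0, 1.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        k = np.where(c > 1e-12, c / np.sin(c), 1.0)
    x = EARTH_RADIUS_KM * k * np.cos(phi) * np.sin(lam - lam0)
    y = EARTH_RADIUS_KM * k * (
        np.cos(phi0) * np.sin(phi) - np.sin(phi0) * np.cos(phi) * np.cos(lam - lam0)
    )
    out = pd.DataFrame({"x": x, "y": y})
    if "site" in samples.columns:
        out.insert(0, "site", samples["site"].to_numpy())
    elif "population" in samples.columns:
        out.insert(0, "site", samples["population"].to_numpy())
    return out


def euclidean_distance_matrix(xy: pd.DataFrame) -> np.ndarray:
    pts = xy[["x", "y"]].to_numpy(dtype=float)
    diff = pts[:, None, :] - pts[None, :, :]
    return np.sqrt((diff ** 2).sum(axis=-1))


@dataclass
class DbMemSet:
    """Orthonormal spatial eigenfunctions with positive eigenvalues."""

    vectors: pd.DataFrame       # sites x retained eigenvectors (orthonormal)
    eigenvalues: np.ndarray
    truncation: float           # t, the longest MST edge (same units as input)

    @property
    def names(self) -> list[str]:
        return list(self.vectors.columns)


def dbmem(dist: np.ndarray, labels=None) -> DbMemSet:
    """Distance-based Moran eigenvector maps.

    Truncation distance t = longest edge of the minimum spanning tree of
    the sites; distances beyond t are replaced by 4t; the truncated matrix
    is Gower-centred (-D^2/2) and eigendecomposed; eigenvectors with
    positive eigenvalue (positive spatial autocorrelation convention) are
    retained, orthonormal, ordered by decreasing eigenvalue.
    """
    D = np.asarray(dist, dtype=float)
    n = D.shape[0]
    if n < 3:
        raise DataError("need at least three sites")
    if not np.allclose(D, D.T, atol=1e-8):
        raise DataError("distance matrix must be symmetric")
    off = D[~np.eye(n, dtype=bool)]
    if (off == 0).any():
        logger.warning("duplicate coordinates (zero off-diagonal distance); "
                       "consider jittering")
    mst = minimum_spanning_tree(D).toarray()
    t = mst[mst > 0].max()
    Dt = np.where(D > t, 4.0 * t, D)
    np.fill_diagonal(Dt, 0.0)

    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (Dt ** 2) @ J
    evals, evecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = np.abs(evals).max() * 1e-9
    pos = evals > tol
    vecs = evecs[:, pos]
    names = [f"dbMEM{i+1}" for i in range(vecs.shape[1])]
    idx = labels if labels is not None else np.arange(n)
    return DbMemSet(
        vectors=pd.DataFrame(vecs, index=idx, columns=names),
        eigenvalues=evals[pos],
        truncation=float(t),
    )


def mantel_test(
    d1: np.ndarray,
    d2: np.ndarray,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Mantel correlation between two distance matrices.

    r is the Pearson correlation of the lower triangles; the one-sided p is
    (1 + #{r_perm >= r_obs}) / (n_perm + 1) under simultaneous row/column
    permutation of the second matrix.
    """
    A = np.asarray(d1, dtype=float)
    B = np.asarray(d2, dtype=float)
    if A.shape != B.shape or A.shape[0] != A.shape[1]:
        raise DataError("matrices must be square and of equal size")
    n = A.shape[0]
    tril = np.tril_indices(n, k=-1)
    a = A[tril]
    if a.std() == 0 or B[tril].std() == 0:
        raise DataError("constant distance matrix: r undefined")

    def corr_with(Bm):
        b = Bm[tril]
        return np.corrcoef(a, b)[0, 1]

    r_obs = corr_with(B)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if corr_with(B[np.ix_(perm, perm)]) >= r_obs:
            count += 1
    p = (1.0 + count) / (n_perm + 1.0)
    return float(r_obs), float(p)


# ---------------------------------------------------------------------------
# redundancy analysis machinery


def _center(M: np.ndarray) -> np.ndarray:
    return M - M.mean(axis=0)


def _fit_stats(Y: np.ndarray, X: np.ndarray):
    """R^2 of multivariate least squares of centred Y on centred X."""
    Yc = _center(Y)
    Xc = _center(X)
    coef, *_ = np.linalg.lstsq(Xc, Yc, rcond=None)
    fitted = Xc @ coef
    ss_tot = (Yc ** 2).sum()
    if ss_tot == 0:
        return 0.0, fitted
    return float((fitted ** 2).sum() / ss_tot), fitted


def adjusted_r2(r2: float, n: int, m: int) -> float:
    """Ezekiel correction: 1 - (1 - R^2)(n-1)/(n-m-1)."""
    if n - m - 1 <= 0:
        return np.nan
    return 1.0 - (1.0 - r2) * (n - 1.0) / (n - m - 1.0)


def hellinger(freqs: np.ndarray) -> np.ndarray:
    """Hellinger transform of a sites x loci frequency-like matrix."""
    F = np.asarray(freqs, dtype=float)
    rowsum = F.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.sqrt(np.where(rowsum > 0, F / rowsum, 0.0))


def site_rda(
    site_freqs: np.ndarray,
    predictors: pd.DataFrame | np.ndarray,
    n_perm: int = 999,
    seed: int | None = None,
    hellinger_transform: bool = False,
):
    """Site-level RDA of allele frequencies on spatial/environment predictors.

    Returns a dict with the constrained eigenvalues, site scores on the
    constrained axes, R^2 and Ezekiel-adjusted R^2, the global permutation
    p-value, and sequential per-axis permutation p-values.
    """
    X = predictors.to_numpy(dtype=float) if hasattr(predictors, "to_numpy") else np.asarray(predictors, float)
    Y = np.asarray(site_freqs, dtype=float)
    if hellinger_transform:
        Y = hellinger(Y)
    n, m = X.shape
    if Y.shape[0] != n:
        raise DataError("response and predictors have different site counts")
    if n < m + 2:
        raise DataError("need at least predictors + 2 sites")
    if np.linalg.matrix_rank(_center(X)) < m:
        raise DataError("rank-deficient predictors (collinear columns)")

    r2, fitted = _fit_stats(Y, X)
    adj = adjusted_r2(r2, n, m)

    # constrained axes: PCA of fitted values
    u, s, vt = np.linalg.svd(fitted, full_matrices=False)
    eig = (s ** 2) / (n - 1)
    keep = eig > (eig.max() * 1e-12 if eig.size and eig.max() > 0 else 0)
    eig = eig[keep]
    site_scores = (u * s)[:, keep]

    rng = np.random.default_rng(seed)
    Yc = _center(Y)
    # global test: permute response rows
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r2p, _ = _fit_stats(Yc[perm], X)
        if r2p >= r2:
            count += 1
    global_p = (1.0 + count) / (n_perm + 1.0)

    # sequential axis tests: axis k assessed against permutations of the
    # residuals from the previously accepted axes
    axis_p = []
    prev_scores = np.zeros((n, 0))
    for k in range(len(eig)):
        if prev_scores.shape[1]:
            Q, _ = np.linalg.qr(_center(prev_scores))
            resid = Yc - Q @ (Q.T @ Yc)
        else:
            resid = Yc
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            _, fit_p = _fit_stats(resid[perm], X)
            _, s_p, _ = np.linalg.svd(fit_p, full_matrices=False)
            lam1 = s_p[0] ** 2 / (n - 1)
            if lam1 >= eig[k]:
                count += 1
        axis_p.append((1.0 + count) / (n_perm + 1.0))
        prev_scores = np.column_stack([prev_scores, site_scores[:, k]])
    return {
        "eigenvalues": eig,
        "site_scores": site_scores,
        "r2": r2,
        "adj_r2": adj,
        "global_p": global_p,
        "axis_p": np.array(axis_p),
    }


def forward_select(
    response: np.ndarray,
    predictors: pd.DataFrame,
    alpha: float = 0.05,
    n_perm: int = 999,
    seed: int | None = None,
    use_adj_r2_stop: bool = True,
):
    """Forward selection of predictors with the double-stopping rule.

    The global model must pass a permutation test at ``alpha`` first.
    Predictors are then added greedily by added R^2; selection stops when a
    candidate's permutation p exceeds ``alpha`` or (when
    ``use_adj_r2_stop``) the cumulative adjusted R^2 exceeds the global
    model's adjusted R^2.  Returns (list of selected column names,
    per-step DataFrame).
    """
    X_all = predictors.to_numpy(dtype=float)
    names = list(predictors.columns)
    Y = np.asarray(response, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, m = X_all.shape
    rng = np.random.default_rng(seed)

    r2_global, _ = _fit_stats(Y, X_all)
    adj_global = adjusted_r2(r2_global, n, m)
    Yc = _center(Y)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r2p, _ = _fit_stats(Yc[perm], X_all)
        if r2p >= r2_global:
            count += 1
    global_p = (1.0 + count) / (n_perm + 1.0)
    if global_p > alpha:
        logger.info("global model not significant (p=%.4f); nothing selected", global_p)
        return [], pd.DataFrame(
            columns=["predictor", "r2_added", "r2_cum", "adj_r2_cum", "p"]
        )

    selected: list[int] = []
    steps = []
    r2_prev = 0.0
    max_select = min(m, n - 2)
    while len(selected) < max_select:
        best_j, best_r2 = None, -np.inf
        for j in range(m):
            if j in selected:
                continue
            r2j, _ = _fit_stats(Y, X_all[:, selected + [j]])
            if r2j > best_r2:
                best_j, best_r2 = j, r2j
        if best_j is None:
            break
        added = best_r2 - r2_prev
        # permutation test of the added predictor, conditioning on current set
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            Xp = X_all[:, selected + [best_j]].copy()
            Xp[:, -1] = Xp[perm, -1]
            r2p, _ = _fit_stats(Y, Xp)
            if r2p - r2_prev >= added:
                count += 1
        p = (1.0 + count) / (n_perm + 1.0)
        adj_cum = adjusted_r2(best_r2, n, len(selected) + 1)
        if p > alpha:
            break
        if use_adj_r2_stop and np.isfinite(adj_global) and adj_cum > adj_global:
            break
        selected.append(best_j)
        steps.append({
            "predictor": names[best_j], "r2_added": added, "r2_cum": best_r2,
            "adj_r2_cum": adj_cum, "p": p,
        })
        r2_prev = best_r2
    return [names[j] for j in selected], pd.DataFrame(steps)


def site_allele_frequencies(g, samples: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Per-population alternate allele frequencies (sites x loci)."""
    from .datatypes import population_indices, validate_sample_table

    samples = validate_sample_table(samples, g)
    pops = population_indices(samples)
    from .popgen import _pop_counts

    n, x, _ = _pop_counts(g, pops)
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = np.where(n > 0, x / (2 * n), np.nan)
    return freqs, list(pops)
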