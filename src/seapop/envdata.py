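"""Site-level environmental summaries and collinearity pruning.

Monthly time series of 16 raw oceanographic variables are reduced to 34
site-level summaries: the two sea-current velocity components are first
combined into an overall current speed (SCV), every one of the 15
resulting base variables gets an overall mean (OM) and standard deviation
(OSD) of its monthly values, and sea-surface temperature additionally gets
the mean and SD of the climatologically coldest and hottest months.
Collinear summaries are then pruned by an iterative |r|/VIF rule or
grouped by hierarchical clustering on 1 - |r|.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .datatypes import DataError

logger = logging.getLogger(__name__)


def scv_from_components(escv, nscv):
    """Overall sea-current velocity: Euclidean norm of the E/N components."""
    escv = np.asarray(escv, dtype=float)
    nscv = np.asarray(nscv, dtype=float)
    if escv.shape != nscv.shape:
        raise DataError("ESCV and NSCV series are misaligned")
    return np.sqrt(escv ** 2 + nscv ** 2)


def summarize_env(ts: pd.DataFrame) -> pd.DataFrame:
    """Reduce a long (site, year, month, variable, value) table to summaries.

    ESCV+NSCV are replaced by SCV per time step before any averaging.  The
    coldest and hottest months are identified from each site's own monthly
    SST climatology; their across-year mean and SD form the four seasonal
    SST summaries.  With all 16 raw variables supplied this yields exactly
    34 columns.
    """
    required = {"site", "year", "month", "variable", "value"}
    if not required.issubset(ts.columns):
        raise DataError(f"time series table needs columns {sorted(required)}")
    if ts.duplicated(["site", "year", "month", "variable"]).any():
        raise DataError("duplicate (site, year, month, variable) records")

    wide = ts.pivot_table(index=["site", "year", "month"], columns="variable",
                          values="value", observed=True)
    variables = list(wide.columns)
    if "ESCV" in variables and "NSCV" in variables:
        if wide["ESCV"].isna().any() or wide["NSCV"].isna().any():
            raise DataError("ESCV/NSCV series are misaligned across time steps")
        wide["SCV"] = scv_from_components(wide["ESCV"], wide["NSCV"])
        wide = wide.drop(columns=["ESCV", "NSCV"])

    out = {}
    grouped = wide.groupby(level="site", sort=False)
    for var in wide.columns:
        out[f"{var}_OM"] = grouped[var].mean()
        out[f"{var}_OSD"] = grouped[var].std(ddof=1)

    if "SST" in wide.columns:
        sst = wide["SST"].rename("value").reset_index().dropna(subset=["value"])
        # per-site climatology over months; all 12 months must be present
        for site, sub in sst.groupby("site", sort=False):
            months = set(sub["month"])
            gaps = sorted(set(range(1, 13)) - months)
            if gaps:
                raise DataError(f"site {site} is missing months {gaps} for the SST climatology")
        clim = sst.groupby(["site", "month"], sort=False)["value"].mean()
        cold, hot = {}, {}
        for site in clim.index.get_level_values("site").unique():
            c = clim.loc[site]
            cold[site] = int(c.idxmin())
            hot[site] = int(c.idxmax())
        for name, chosen in (("coldest", cold), ("hottest", hot)):
            means, sds = {}, {}
            for site, month in chosen.items():
                vals = sst[(sst["site"] == site) & (sst["month"] == month)]["value"]
                means[site] = vals.mean()
                sds[site] = vals.std(ddof=1)
            out[f"SST_{name}_mean"] = pd.Series(means)
            out[f"SST_{name}_sd"] = pd.Series(sds)

    summary = pd.DataFrame(out)
    summary.index.name = "site"
    # deterministic (sorted) site order, independent of record order
    return summary.sort_index()


def env_pca(env: pd.DataFrame):
    """PCA of the correlation matrix with broken-stick retention.

    Columns are z-scored first; constant columns are dropped with a
    warning.  Returns (scores, loadings, eigenvalues, n_retained).
    Component k is retained when its share of variance exceeds the
    broken-stick expectation b_k = (1/p) * sum_{i=k..p} 1/i.
    """
    if env.shape[0] < 2:
        raise DataError("need at least two sites")
    X = env.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    constant = sd == 0
    if constant.any():
        logger.warning("dropping constant columns: %s",
                       list(env.columns[constant]))
        env = env.loc[:, ~constant]
        X = X[:, ~constant]
        sd = sd[~constant]
    Z = (X - X.mean(axis=0)) / sd
    n, p = Z.shape
    u, s, vt = np.linalg.svd(Z, full_matrices=False)
    eig = s ** 2 / (n - 1)
    scores = u * s
    loadings = vt.T
    share = eig / eig.sum()
    bs = broken_stick(p)
    n_retained = 0
    for k in range(min(n - 1, p)):
        if share[k] > bs[k]:
            n_retained += 1
        else:
            break
    scores_df = pd.DataFrame(scores, index=env.index,
                             columns=[f"ePC{i+1}" for i in range(scores.shape[1])])
    loadings_df = pd.DataFrame(loadings, index=env.columns,
                               columns=scores_df.columns)
    return scores_df, loadings_df, eig, n_retained


def broken_stick(p: int) -> np.ndarray:
    """Expected eigenvalue shares under random partitioning of variance."""
    inv = 1.0 / np.arange(1, p + 1)
    return np.array([inv[k:].sum() for k in range(p)]) / p


def _vif(X: np.ndarray, j: int) -> float:
    """Variance inflation factor of column j against the other columns."""
    y = X[:, j]
    others = np.delete(X, j, axis=1)
    if others.shape[1] == 0:
        return 1.0
    A = np.column_stack([np.ones(len(y)), others])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    ss_tot = ((y - y.mean()) ** 2).sum()
    if ss_tot == 0:
        return np.inf
    r2 = 1.0 - (resid ** 2).sum() / ss_tot
    return np.inf if r2 >= 1.0 else 1.0 / (1.0 - r2)


def cor_select_vif(env: pd.DataFrame, r_threshold: float = 0.5):
    """Iteratively drop the higher-VIF member of each over-correlated pair.

    While any retained pair has |r| >= r_threshold, the most correlated
    pair is examined and the member with the higher VIF (against all other
    retained variables) is removed.  Deterministic given column order.
    Returns (retained column list, decision log DataFrame).
    """
    cols = list(env.columns)
    log_rows = []
    if len(cols) < 2:
        return cols, pd.DataFrame(columns=["dropped", "kept", "r", "vif_dropped", "vif_kept"])
    while True:
        sub = env[cols]
        corr = sub.corr().to_numpy()
        np.fill_diagonal(corr, 0.0)
        absr = np.abs(corr)
        if np.nanmax(absr) < r_threshold or len(cols) < 2:
            break
        i, j = np.unravel_index(np.nanargmax(absr), absr.shape)
        X = sub.to_numpy(dtype=float)
        Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
        vif_i, vif_j = _vif(Z, i), _vif(Z, j)
        drop, keep = (i, j) if vif_i >= vif_j else (j, i)
        log_rows.append({
            "dropped": cols[drop], "kept": cols[keep], "r": corr[i, j],
            "vif_dropped": vif_i if drop == i else vif_j,
            "vif_kept": vif_j if drop == i else vif_i,
        })
        cols.pop(drop)
    return cols, pd.DataFrame(log_rows)


def cluster_collinear(env: pd.DataFrame, r_threshold: float = 0.5, method: str = "complete"):
    """Group collinear variables by hierarchical clustering on 1 - |r|.

    Groups are cut at height 1 - r_threshold.  Returns (group labels as a
    Series over columns, scipy linkage matrix).
    """
    if env.shape[1] < 2:
        raise DataError("need at least two columns")
    corr = env.corr().to_numpy()
    dist = 1.0 - np.abs(corr)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)
    Z = linkage(squareform(dist, checks=False), method=method)
    labels = fcluster(Z, t=1.0 - r_threshold, criterion="distance")
    return pd.Series(labels, index=env.columns, name="group"), Z
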