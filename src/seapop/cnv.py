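"""CNV read-depth normalisation and population differentiation (V_ST).

Read depths at duplicated loci are normalised by the trimmed mean of
M-values (TMM) so that library-size and composition effects do not mimic
copy-number differences.  Population differentiation of the resulting
profiles is the variance-partition statistic

    V_ST = (V_T - V_S) / V_T,

with V_T the pooled two-population variance of normalised depths and V_S
the sample-size-weighted mean within-population variance; all variances
use the n-1 (sample) denominator.  Significance comes from a permutation
null and bootstrap-over-individuals confidence intervals.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datatypes import DataError

logger = logging.getLogger(__name__)

VST_MODERATE = 0.1
VST_STRONG = 0.3


def tmm_factors(
    counts: np.ndarray,
    logratio_trim: float = 0.3,
    abs_expr_trim: float = 0.05,
) -> np.ndarray:
    """TMM normalisation factors (geometric mean 1).

    The reference sample is the one whose 75th-percentile depth fraction is
    closest to the mean across samples.  Per sample, the factor is the
    precision-weighted mean of log2 depth ratios against the reference
    after trimming the most extreme 30% of log-ratios (each tail) and 5%
    of average log-expression (each tail); zero counts are excluded
    pairwise.
    """
    counts = np.asarray(counts, dtype=float)
    n, L = counts.shape
    lib = counts.sum(axis=1)
    if (lib <= 0).any():
        bad = int(np.flatnonzero(lib <= 0)[0])
        raise DataError(f"sample index {bad} has all-zero counts")

    frac = counts / lib[:, None]
    uq = np.array([np.percentile(frac[i][counts[i] > 0], 75) if (counts[i] > 0).any() else 0.0
                   for i in range(n)])
    ref = int(np.argmin(np.abs(uq - uq.mean())))

    log_factors = np.zeros(n)
    for s in range(n):
        if s == ref:
            continue
        both = (counts[s] > 0) & (counts[ref] > 0)
        if both.sum() < 2:
            continue
        ys, yr = counts[s, both], counts[ref, both]
        ls, lr = lib[s], lib[ref]
        m = np.log2((ys / ls) / (yr / lr))
        a = 0.5 * np.log2((ys / ls) * (yr / lr))
        w = (ls - ys) / (ls * ys) + (lr - yr) / (lr * yr)

        k = m.size
        lo_m, hi_m = np.floor(k * logratio_trim) + 1, k - np.floor(k * logratio_trim)
        lo_a, hi_a = np.floor(k * abs_expr_trim) + 1, k - np.floor(k * abs_expr_trim)
        rm = pd.Series(m).rank().to_numpy()
        ra = pd.Series(a).rank().to_numpy()
        keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        if not keep.any():
            keep = np.ones(k, dtype=bool)
        with np.errstate(divide="ignore"):
            inv_w = 1.0 / w[keep]
        log_factors[s] = (inv_w * m[keep]).sum() / inv_w.sum()

    factors = 2.0 ** log_factors
    factors = factors / np.exp(np.log(factors).mean())   # geometric mean 1
    return factors


def tmm_normalize(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Normalise a samples x loci depth matrix by effective library size.

    Returns (normalised matrix, per-sample TMM factors).  Depths are
    divided by library size x factor and rescaled by the mean effective
    library size so values stay on the raw-depth scale.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape[0] < 2:
        raise DataError("need at least two samples")
    factors = tmm_factors(counts)
    lib = counts.sum(axis=1)
    eff = lib * factors
    norm = counts / eff[:, None] * eff.mean()
    return norm, factors


def drop_zero_variance(nd: np.ndarray, loci: pd.DataFrame | None = None):
    """Remove loci whose normalised depth is constant across samples."""
    nd = np.asarray(nd, dtype=float)
    var = nd.var(axis=0)
    keep = var > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d zero-variance CNV loci", n_dropped)
    if not keep.any():
        logger.warning("all CNV loci have zero variance")
    if loci is not None:
        return nd[:, keep], loci.loc[keep].reset_index(drop=True), n_dropped
    return nd[:, keep], n_dropped


def _vst_from_groups(x_i: np.ndarray, x_j: np.ndarray) -> np.ndarray:
    """Vectorised V_ST per locus for two groups (rows = individuals)."""
    n_i, n_j = x_i.shape[0], x_j.shape[0]
    pooled = np.concatenate([x_i, x_j], axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        v_t = pooled.var(axis=0, ddof=1)
        v_i = x_i.var(axis=0, ddof=1)
        v_j = x_j.var(axis=0, ddof=1)
        v_s = (v_i * n_i + v_j * n_j) / (n_i + n_j)
        out = np.where(v_t > 0, (v_t - v_s) / v_t, np.nan)
    return out


def vst(
    nd: np.ndarray,
    samples: pd.DataFrame,
    pop_i: str,
    pop_j: str,
) -> np.ndarray:
    """Per-locus V_ST between two populations (NaN where V_T = 0)."""
    idx_i = np.flatnonzero((samples["population"] == pop_i).to_numpy())
    idx_j = np.flatnonzero((samples["population"] == pop_j).to_numpy())
    if len(idx_i) < 2 or len(idx_j) < 2:
        raise DataError("both populations need at least two individuals")
    nd = np.asarray(nd, dtype=float)
    return _vst_from_groups(nd[idx_i], nd[idx_j])


def vst_permutation(
    nd: np.ndarray,
    samples: pd.DataFrame,
    pop_i: str,
    pop_j: str,
    n_perm: int = 1000,
    seed: int | None = None,
    n_boot: int = 500,
) -> pd.DataFrame:
    """V_ST with permutation p-values, bootstrap CIs and outlier classes.

    p = (1 + #{permuted V_ST >= observed}) / (n_perm + 1) under random
    relabelling of the pooled individuals; the 95% CI comes from
    bootstrapping individuals within each population.  ``significant`` is
    True when the CI excludes zero.
    """
    if n_perm < 100:
        logger.warning("n_perm=%d is small; p-values will be coarse", n_perm)
    idx_i = np.flatnonzero((samples["population"] == pop_i).to_numpy())
    idx_j = np.flatnonzero((samples["population"] == pop_j).to_numpy())
    if len(idx_i) < 2 or len(idx_j) < 2:
        raise DataError("both populations need at least two individuals")
    nd = np.asarray(nd, dtype=float)
    x_i, x_j = nd[idx_i], nd[idx_j]
    n_i, n_j = len(idx_i), len(idx_j)
    obs = _vst_from_groups(x_i, x_j)

    rng = np.random.default_rng(seed)
    pooled = np.concatenate([x_i, x_j], axis=0)
    n_tot = n_i + n_j
    exceed = np.zeros(nd.shape[1])
    for _ in range(n_perm):
        perm = rng.permutation(n_tot)
        v = _vst_from_groups(pooled[perm[:n_i]], pooled[perm[n_i:]])
        exceed += np.where(np.isfinite(v) & np.isfinite(obs), v >= obs, 0)
    perm_p = (1.0 + exceed) / (n_perm + 1.0)

    if n_boot > 0:
        boots = np.empty((n_boot, nd.shape[1]))
        for b in range(n_boot):
            bi = rng.integers(0, n_i, size=n_i)
            bj = rng.integers(0, n_j, size=n_j)
            boots[b] = _vst_from_groups(x_i[bi], x_j[bj])
        ci_lo = np.nanpercentile(boots, 2.5, axis=0)
        ci_hi = np.nanpercentile(boots, 97.5, axis=0)
    else:
        ci_lo = ci_hi = np.full(nd.shape[1], np.nan)

    out = pd.DataFrame({
        "locus": np.arange(nd.shape[1]),
        "pop_i": pop_i,
        "pop_j": pop_j,
        "v_st": obs,
        "ci_lo": ci_lo,
        "ci_hi": ci_hi,
        "perm_p": perm_p,
        "significant": (ci_lo > 0) | (ci_hi < 0),
    })
    return classify_vst_outliers(out)


def classify_vst_outliers(results: pd.DataFrame) -> pd.DataFrame:
    """Attach genome-wide outlier classes: moderate (0.1, 0.3], strong (> 0.3)."""
    v = results["v_st"].to_numpy()
    cls = np.where(v > VST_STRONG, "strong",
                   np.where(v > VST_MODERATE, "moderate", "none"))
    cls = np.where(np.isfinite(v), cls, "none")
    results = results.copy()
    results["outlier_class"] = cls
    return results
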