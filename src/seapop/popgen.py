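"""Diversity and differentiation statistics.

Implements observed heterozygosity and Nei gene diversity with bootstrap
confidence intervals, the Weir–Cockerham (1984) variance-component F_ST
estimator (multi-locus ratio-of-sums), the allele-matching population-
specific differentiation index beta (Weir & Goudet-style), rarefied
allelic richness, private alleles, Nei's D_A genetic distance, and
principal coordinate analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .datatypes import (
    MISSING,
    DataError,
    GenotypeMatrix,
    population_indices,
    validate_sample_table,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# per-population sufficient statistics


def _pop_counts(g: GenotypeMatrix, pops: dict[str, np.ndarray]):
    """Per pop x locus: called individuals n, alt-allele copies x, het count."""
    calls = g.calls
    ok = calls != MISSING
    n = np.stack([ok[idx].sum(axis=0) for idx in pops.values()]).astype(float)
    x = np.stack([
        np.where(ok[idx], np.maximum(calls[idx], 0), 0).sum(axis=0)
        for idx in pops.values()
    ]).astype(float)
    het = np.stack([(calls[idx] == 1).sum(axis=0) for idx in pops.values()]).astype(float)
    return n, x, het


# ---------------------------------------------------------------------------
# Weir-Cockerham theta


def wc_variance_components(n: np.ndarray, p: np.ndarray, h: np.ndarray):
    """WC84 per-locus variance components a (among-pop), b, c.

    Parameters are pop x locus arrays: sample sizes (individuals), alt
    allele frequencies, and observed heterozygote fractions.  Loci where
    any population has no data, or with fewer than two populations, are
    returned as NaN components.
    """
    r = n.shape[0]
    if r < 2:
        raise DataError("need at least two populations")
    valid = (n >= 1).all(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = n.mean(axis=0)
        nc = (r * nbar - (n ** 2).sum(axis=0) / (r * nbar)) / (r - 1.0)
        pbar = (n * p).sum(axis=0) / (r * nbar)
        s2 = (n * (p - pbar) ** 2).sum(axis=0) / ((r - 1.0) * nbar)
        hbar = (n * h).sum(axis=0) / (r * nbar)

        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 * (r - 1.0) / r - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar) - s2 * (r - 1.0) / r - hbar * (2.0 * nbar - 1.0) / (4.0 * nbar)
        )
        c = hbar / 2.0
    bad = ~valid | (nbar <= 1) | (nc <= 0)
    for arr in (a, b, c):
        arr[bad] = np.nan
    # monomorphic loci across the included pops carry no information
    mono = (pbar <= 0) | (pbar >= 1)
    for arr in (a, b, c):
        arr[mono] = np.nan
    return a, b, c


def _theta_from_components(a, b, c):
    ok = np.isfinite(a) & np.isfinite(b) & np.isfinite(c)
    denom = (a[ok] + b[ok] + c[ok]).sum()
    if denom == 0 or not ok.any():
        return np.nan
    return a[ok].sum() / denom


def _pop_freq_stats(g: GenotypeMatrix, pops: dict[str, np.ndarray]):
    n, x, het = _pop_counts(g, pops)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, x / (2.0 * n), np.nan)
        h = np.where(n > 0, het / n, np.nan)
    return n, p, h


def multilocus_fst_wc(g: GenotypeMatrix, samples: pd.DataFrame) -> float:
    """Global multi-locus Weir-Cockerham theta over all populations."""
    samples = validate_sample_table(samples, g)
    pops = population_indices(samples)
    n, p, h = _pop_freq_stats(g, pops)
    a, b, c = wc_variance_components(n, p, h)
    return _theta_from_components(a, b, c)


def per_locus_fst_wc(g: GenotypeMatrix, samples: pd.DataFrame) -> np.ndarray:
    """Per-locus theta = a / (a+b+c) over all populations (NaN if undefined)."""
    samples = validate_sample_table(samples, g)
    pops = population_indices(samples)
    n, p, h = _pop_freq_stats(g, pops)
    a, b, c = wc_variance_components(n, p, h)
    with np.errstate(invalid="ignore", divide="ignore"):
        return a / (a + b + c)


@dataclass
class PairwiseMatrix:
    """Symmetric population-by-population statistic with optional CIs."""

    labels: list[str]
    values: np.ndarray
    ci_lo: np.ndarray | None = None
    ci_hi: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def formatted(self) -> pd.DataFrame:
        """Point estimates with "(lo-hi)" CI strings in the upper triangle."""
        out = self.to_frame().round(4).astype(object)
        if self.ci_lo is not None:
            k = len(self.labels)
            for i in range(k):
                for j in range(i + 1, k):
                    out.iat[i, j] = (
                        f"{self.values[i, j]:.4f} "
                        f"({self.ci_lo[i, j]:.4f}-{self.ci_hi[i, j]:.4f})"
                    )
        return out


def pairwise_fst_wc(
    g: GenotypeMatrix,
    samples: pd.DataFrame,
    n_boot: int = 1000,
    seed: int | None = None,
) -> PairwiseMatrix:
    """Pairwise multi-locus WC84 theta with bootstrap-over-loci 95% CIs."""
    samples = validate_sample_table(samples, g)
    pops = population_indices(samples)
    labels = list(pops)
    for lab, idx in pops.items():
        if len(idx) < 2:
            raise DataError(f"population {lab} has fewer than 2 samples")
    n, p, h = _pop_freq_stats(g, pops)
    k = len(labels)
    vals = np.full((k, k), np.nan)
    lo = np.full((k, k), np.nan)
    hi = np.full((k, k), np.nan)
    rng = np.random.default_rng(seed)
    for i in range(k):
        for j in range(i + 1, k):
            sel = np.array([i, j])
            a, b, c = wc_variance_components(n[sel], p[sel], h[sel])
            vals[i, j] = vals[j, i] = _theta_from_components(a, b, c)
            if n_boot > 0:
                ok = np.flatnonzero(np.isfinite(a))
                if len(ok) == 0:
                    continue
                draws = rng.integers(0, len(ok), size=(n_boot, len(ok)))
                asum = a[ok][draws].sum(axis=1)
                tsum = (a[ok] + b[ok] + c[ok])[draws].sum(axis=1)
                with np.errstate(invalid="ignore", divide="ignore"):
                    thetas = asum / tsum
                lo[i, j] = lo[j, i] = np.nanpercentile(thetas, 2.5)
                hi[i, j] = hi[j, i] = np.nanpercentile(thetas, 97.5)
    return PairwiseMatrix(labels, vals, lo if n_boot else None, hi if n_boot else None)


# ---------------------------------------------------------------------------
# diversity


def diversity_stats(
    g: GenotypeMatrix,
    samples: pd.DataFrame,
    n_boot: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-population H_O, H_S, multi-locus F_IS with bootstrap CIs.

    H_O is the mean over loci of the observed heterozygote fraction; H_S is
    Nei's unbiased gene diversity (n/(n-1) correction including the
    heterozygote term); F_IS = 1 - mean(H_O)/mean(H_S) as a ratio of
    averages, with percentile bootstrap over loci.
    """
    samples = validate_sample_table(samples, g)
    pops = population_indices(samples)
    if len(pops) < 2:
        raise DataError("need at least two populations")
    rng = np.random.default_rng(seed)
    rows = []
    for lab, idx in pops.items():
        n_ind = len(idx)
        sub = g.calls[idx]
        ok = sub != MISSING
        n = ok.sum(axis=0).astype(float)
        informative = n >= 2
        if n_ind < 2 or not informative.any():
            logger.warning("population %s too small for gene diversity", lab)
            rows.append({"population": lab, "n": n_ind, "h_o": np.nan, "h_s": np.nan,
                         "f_is": np.nan, "f_is_lo": np.nan, "f_is_hi": np.nan})
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n > 0, np.where(ok, np.maximum(sub, 0), 0).sum(axis=0) / (2 * n), np.nan)
            ho = np.where(n > 0, (sub == 1).sum(axis=0) / n, np.nan)
            hs = (n / (n - 1.0)) * (1.0 - p ** 2 - (1 - p) ** 2 - ho / (2.0 * n))
        ho_l = ho[informative]
        hs_l = hs[informative]
        h_o = float(np.nanmean(ho_l))
        h_s = float(np.nanmean(hs_l))
        if h_s <= 0:
            f_is, f_lo, f_hi = np.nan, np.nan, np.nan
        else:
            f_is = 1.0 - h_o / h_s
            if n_boot > 0:
                L = len(ho_l)
                draws = rng.integers(0, L, size=(n_boot, L))
                with np.errstate(invalid="ignore", divide="ignore"):
                    fb = 1.0 - np.nanmean(ho_l[draws], axis=1) / np.nanmean(hs_l[draws], axis=1)
                f_lo = float(np.nanpercentile(fb, 2.5))
                f_hi = float(np.nanpercentile(fb, 97.5))
            else:
                f_lo = f_hi = np.nan
        rows.append({"population": lab, "n": n_ind, "h_o": h_o, "h_s": h_s,
                     "f_is": f_is, "f_is_lo": f_lo, "f_is_hi": f_hi})
    return pd.DataFrame(rows)


def allelic_richness(
    g: GenotypeMatrix,
    samples: pd.DataFrame,
    rarefaction_size: int | None = None,
) -> pd.Series:
    """Rarefied allelic richness per population.

    Expected number of distinct alleles in a draw of ``g`` gene copies via
    the hypergeometric complement 1 - C(N - N_a, g)/C(N, g), averaged over
    loci.  The default rarefaction size is the smallest per-locus,
    per-population count of non-missing gene copies.
    """
    samples = validate_sample_table(samples, g)
    pops = population_indices(samples)
    n, x, _ = _pop_counts(g, pops)
    copies = 2.0 * n
    if rarefaction_size is None:
        positive = copies[copies > 0]
        if positive.size == 0:
            raise DataError("no called genotypes")
        rarefaction_size = int(positive.min())
    gsize = rarefaction_size
    if gsize < 2:
        raise DataError("rarefaction size must be >= 2")

    def log_choose(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    out = {}
    for pi, lab in enumerate(pops):
        N = copies[pi]
        Na = x[pi]
        usable = N >= gsize
        if not usable.any():
            out[lab] = np.nan
            continue
        ar = np.zeros(int(usable.sum()))
        for counts in (Na[usable], (N - Na)[usable]):
            Nu = N[usable]
            with np.errstate(invalid="ignore"):
                absent_ok = (Nu - counts) >= gsize
                term = np.where(
                    absent_ok,
                    np.exp(log_choose(Nu - counts, gsize) - log_choose(Nu, gsize)),
                    0.0,
                )
            term[counts == 0] = 1.0       # allele absent entirely: contributes 0
            ar += 1.0 - term
        out[lab] = float(ar.mean())
    return pd.Series(out, name="a_r")


def private_alleles(g: GenotypeMatrix, samples: pd.DataFrame) -> pd.Series:
    """Count of (locus, allele) pairs present in exactly one population."""
    samples = validate_sample_table(samples, g)
    pops = population_indices(samples)
    if len(pops) < 2:
        raise DataError("need at least two populations")
    n, x, _ = _pop_counts(g, pops)
    alt_present = x > 0
    ref_present = (2 * n - x) > 0
    counts = pd.Series(0, index=list(pops), name="a_p")
    for present in (alt_present, ref_present):
        only_one = present.sum(axis=0) == 1
        if only_one.any():
            owner = present[:, only_one].argmax(axis=0)
            for pi, lab in enumerate(pops):
                counts[lab] += int((owner == pi).sum())
    return counts


# ---------------------------------------------------------------------------
# population-specific differentiation (allele matching)


def _matching_sums(n: np.ndarray, x: np.ndarray):
    """Per-locus within-pop and mean-between-pop allele matching.

    Within-population matching uses unordered pairs of distinct gene
    copies (heterozygote matching enters through the pair counts); between
    uses the product of allele frequencies.
    """
    m = 2.0 * n
    with np.errstate(invalid="ignore", divide="ignore"):
        within = (x * (x - 1) + (m - x) * (m - x - 1)) / (m * (m - 1))
        p = x / m
    k = n.shape[0]
    pairsum = np.zeros(n.shape[1])
    npair = 0
    for i in range(k):
        for j in range(i + 1, k):
            pairsum += p[i] * p[j] + (1 - p[i]) * (1 - p[j])
            npair += 1
    between = pairsum / npair
    return within, between


def beta_wt(
    g: GenotypeMatrix,
    samples: pd.DataFrame,
    n_boot: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Population-specific F_ST via allele-matching proportions.

    beta_i = (sum_l M_i,l - sum_l M_B,l) / sum_l (1 - M_B,l), a ratio of
    sums over loci, with M_i the within-population matching proportion and
    M_B the mean between-population matching.  The overall index is the
    mean of the per-population values.  Percentile bootstrap over loci.
    Returns a DataFrame with one row per population plus an "overall" row.
    """
    samples = validate_sample_table(samples, g)
    pops = population_indices(samples)
    if len(pops) < 2:
        raise DataError("beta undefined for a single population")
    n, x, _ = _pop_counts(g, pops)
    within, between = _matching_sums(n, x)
    valid = np.isfinite(between) & np.isfinite(within).all(axis=0) if within.ndim > 1 else None
    valid = np.isfinite(between)
    for pi in range(n.shape[0]):
        valid &= np.isfinite(within[pi])
    w = within[:, valid]
    b = between[valid]
    L = b.size

    def betas(w_, b_):
        denom = (1.0 - b_).sum()
        return (w_.sum(axis=1) - b_.sum()) / denom

    point = betas(w, b)
    rng = np.random.default_rng(seed)
    rows = []
    if n_boot > 0 and L > 0:
        draws = rng.integers(0, L, size=(n_boot, L))
        boot = np.stack([betas(w[:, dr], b[dr]) for dr in draws])  # n_boot x pops
        lo = np.percentile(boot, 2.5, axis=0)
        hi = np.percentile(boot, 97.5, axis=0)
        overall_boot = boot.mean(axis=1)
        o_lo, o_hi = np.percentile(overall_boot, [2.5, 97.5])
    else:
        lo = hi = np.full(len(pops), np.nan)
        o_lo = o_hi = np.nan
    for pi, lab in enumerate(pops):
        rows.append({"population": lab, "beta_wt": point[pi],
                     "beta_lo": lo[pi], "beta_hi": hi[pi]})
    rows.append({"population": "overall", "beta_wt": float(point.mean()),
                 "beta_lo": o_lo, "beta_hi": o_hi})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# distances & ordination


def nei_da(g: GenotypeMatrix, samples: pd.DataFrame) -> PairwiseMatrix:
    """Nei's D_A genetic distance: 1 - mean over loci of sum_a sqrt(x_a y_a)."""
    samples = validate_sample_table(samples, g)
    pops = population_indices(samples)
    labels = list(pops)
    n, x, _ = _pop_counts(g, pops)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = x / (2.0 * n)
    k = len(labels)
    vals = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            both = (n[i] > 0) & (n[j] > 0)
            if not both.any():
                raise DataError(f"no shared loci between {labels[i]} and {labels[j]}")
            term = np.sqrt(p[i, both] * p[j, both]) + np.sqrt(
                (1 - p[i, both]) * (1 - p[j, both])
            )
            vals[i, j] = vals[j, i] = 1.0 - term.mean()
    return PairwiseMatrix(labels, vals)


def pcoa(dist: PairwiseMatrix | np.ndarray, k: int | None = None, cailliez: bool = False):
    """Principal coordinate analysis by Gower double-centering.

    Returns (coordinates, eigenvalues, variance fractions).  Coordinates
    are eigenvectors scaled by sqrt of the (positive) eigenvalues; negative
    eigenvalues are reported as-is unless ``cailliez`` adds the constant
    that renders the distances Euclidean.
    """
    if isinstance(dist, PairwiseMatrix):
        D = np.asarray(dist.values, dtype=float)
    else:
        D = np.asarray(dist, dtype=float)
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-10):
        raise DataError("distance matrix must be square and symmetric")
    n = D.shape[0]
    if cailliez:
        D = D + _cailliez_constant(D) * (1 - np.eye(n))
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    evals, evecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    pos = evals > max(evals.max(), 0) * 1e-12 if evals.size else evals > 0
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    if k is not None:
        coords = coords[:, :k]
    total = evals[evals > 0].sum()
    frac = np.where(evals > 0, evals / total, 0.0) if total > 0 else np.zeros_like(evals)
    return coords, evals, frac


def _cailliez_constant(D: np.ndarray) -> float:
    """Smallest additive constant making D (off-diagonal) Euclidean."""
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    d1 = -0.5 * J @ (D ** 2) @ J
    d2 = -0.5 * J @ D @ J
    upper = np.hstack([np.zeros((n, n)), 2 * d1])
    lower = np.hstack([-np.eye(n), -4 * d2])
    ev = np.linalg.eigvals(np.vstack([upper, lower]))
    return float(max(0.0, np.real(ev).max()))


def top_fst_subset(g: GenotypeMatrix, samples: pd.DataFrame, n_top: int = 150) -> GenotypeMatrix:
    """The n_top loci by per-locus WC theta, ties broken by genomic order."""
    theta = per_locus_fst_wc(g, samples)
    if n_top > g.n_loci:
        logger.warning("n_top exceeds locus count; returning all loci")
        n_top = g.n_loci
    key = np.where(np.isfinite(theta), theta, -np.inf)
    order = np.argsort(-key, kind="stable")[:n_top]
    order.sort()                           # preserve genomic order in output
    return g.take_loci(order)
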