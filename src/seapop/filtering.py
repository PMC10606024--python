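"""Locus- and individual-level quality filters for RADseq genotype matrices.

The filter chain mirrors standard reduced-representation practice: depth
masking, per-population call-rate and minor-allele-sample thresholds, then
individual missingness / heterozygosity / kinship pruning, and finally
within-RAD-locus thinning to unlinked SNPs.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datatypes import (
    MISSING,
    AlleleDepthMatrix,
    DataError,
    FilterReport,
    GenotypeMatrix,
    population_indices,
    validate_sample_table,
)

logger = logging.getLogger(__name__)


def filter_loci(
    g: GenotypeMatrix,
    d: AlleleDepthMatrix,
    samples: pd.DataFrame,
    min_depth: int = 4,
    min_call_rate_per_pop: float = 0.80,
    min_minor_allele_samples: int = 2,
) -> tuple[GenotypeMatrix, AlleleDepthMatrix, FilterReport]:
    """Mask low-depth calls, then drop loci failing call-rate or MAS rules.

    A genotype whose total read depth is below ``min_depth`` is set missing.
    A locus is retained iff its call rate is at least
    ``min_call_rate_per_pop`` in *every* population and at least
    ``min_minor_allele_samples`` samples carry the minor allele.
    """
    samples = validate_sample_table(samples, g)
    pops = population_indices(samples)
    for pop, idx in pops.items():
        if len(idx) == 0:
            raise DataError(f"population {pop} has no samples")

    calls = g.calls.copy()
    low = d.total() < min_depth
    calls[low] = MISSING

    ok = calls != MISSING
    keep = np.ones(g.n_loci, dtype=bool)
    for idx in pops.values():
        rate = ok[idx].mean(axis=0)
        keep &= rate >= min_call_rate_per_pop

    # minor-allele-sample count: samples carrying >= 1 copy of the rarer allele
    n_alt_carriers = ((calls == 1) | (calls == 2)).sum(axis=0)
    n_ref_carriers = ((calls == 0) | (calls == 1)).sum(axis=0)
    alt_copies = np.where(ok, np.maximum(calls, 0), 0).sum(axis=0)
    total_copies = 2 * ok.sum(axis=0)
    alt_is_minor = alt_copies * 2 <= total_copies
    mas = np.where(alt_is_minor, n_alt_carriers, n_ref_carriers)
    keep &= mas >= min_minor_allele_samples

    g2 = GenotypeMatrix(list(g.samples), g.loci, calls).take_loci(keep)
    d2 = d.take_loci(keep)
    report = FilterReport(
        stage="filter_loci",
        n_loci_before=g.n_loci, n_loci_after=g2.n_loci,
        n_samples_before=g.n_samples, n_samples_after=g2.n_samples,
        parameters={
            "min_depth": min_depth,
            "min_call_rate_per_pop": min_call_rate_per_pop,
            "min_minor_allele_samples": min_minor_allele_samples,
        },
    )
    return g2, d2, report


def individual_heterozygosity_F(g: GenotypeMatrix) -> pd.Series:
    """Method-of-moments inbreeding coefficient per individual.

    F = (O_hom - E_hom) / (n_sites - E_hom), with expected homozygosity from
    sample allele frequencies (unbiased 2n/(2n-1) correction) summed over
    that individual's non-missing sites.  Individuals with no called sites
    get NaN.
    """
    if g.n_samples < 2:
        raise DataError("need at least two samples")
    ok = g.calls != MISSING
    n = ok.sum(axis=0)                    # individuals called per locus
    p = g.alt_allele_freq()
    with np.errstate(invalid="ignore", divide="ignore"):
        e_het = 2.0 * p * (1.0 - p) * (2.0 * n) / (2.0 * n - 1.0)
    e_hom_site = 1.0 - e_het              # per-locus expected homozygosity

    obs_hom = ((g.calls == 0) | (g.calls == 2))
    f = np.full(g.n_samples, np.nan)
    for i in range(g.n_samples):
        sites = ok[i]
        n_sites = sites.sum()
        if n_sites == 0:
            logger.warning("individual %s has no called sites; F undefined", g.samples[i])
            continue
        e = np.nansum(e_hom_site[sites])
        o = obs_hom[i, sites].sum()
        denom = n_sites - e
        f[i] = (o - e) / denom if denom != 0 else np.nan
    return pd.Series(f, index=g.samples, name="F")


def pairwise_relatedness(g: GenotypeMatrix, method: str = "king") -> pd.DataFrame:
    """Pairwise kinship/relatedness matrix.

    ``king``: KING-robust kinship
        phi_ij = (N_het,het - 2 N_opposing_hom) / (N_het(i) + N_het(j))
    over sites non-missing in both members.  ``grm``: the standard
    frequency-standardised genomic relationship (Yang et al.) estimator
    averaged over loci.
    """
    if g.n_samples < 2:
        raise DataError("need at least two samples")
    if g.n_loci < 50:
        logger.warning("fewer than 50 loci; relatedness estimates will be noisy")
    n = g.n_samples
    out = np.full((n, n), np.nan)

    calls = g.calls
    ok = calls != MISSING
    if method == "king":
        het = (calls == 1) & ok
        hom_ref = (calls == 0)
        hom_alt = (calls == 2)
        for i in range(n):
            for j in range(i, n):
                both = ok[i] & ok[j]
                if not both.any():
                    logger.warning("samples %s/%s share no called loci",
                                   g.samples[i], g.samples[j])
                    continue
                n_hh = (het[i] & het[j] & both).sum()
                n_opp = ((hom_ref[i] & hom_alt[j]) | (hom_alt[i] & hom_ref[j]))[both].sum()
                denom = (het[i] & both).sum() + (het[j] & both).sum()
                if denom == 0:
                    continue
                out[i, j] = out[j, i] = (n_hh - 2.0 * n_opp) / denom
    elif method == "grm":
        p = g.alt_allele_freq()
        valid = (p > 0) & (p < 1)
        x = np.where(ok, calls, 0).astype(float)
        z = np.where(ok[:, valid],
                     (x[:, valid] - 2 * p[valid]) / np.sqrt(2 * p[valid] * (1 - p[valid])),
                     0.0)
        okv = ok[:, valid].astype(float)
        num = z @ z.T
        cnt = okv @ okv.T
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(cnt > 0, num / cnt, np.nan)
    else:
        raise DataError(f"unknown relatedness method {method!r}")
    return pd.DataFrame(out, index=g.samples, columns=g.samples)


def filter_individuals(
    g: GenotypeMatrix,
    d: AlleleDepthMatrix,
    samples: pd.DataFrame,
    max_missing: float = 0.20,
    min_F: float = -0.2,
    kinship_threshold: float = 0.25,
) -> tuple[GenotypeMatrix, AlleleDepthMatrix, pd.DataFrame, FilterReport]:
    """Drop high-missingness, excess-heterozygosity and related individuals.

    For each pair at or above ``kinship_threshold`` (KING-robust), the
    member with more missing data is removed (ties broken by dropping the
    lexicographically larger sample ID).
    """
    samples = validate_sample_table(samples, g)
    miss_frac = g.missing_mask().mean(axis=1)
    f = individual_heterozygosity_F(g).to_numpy()

    drop = np.zeros(g.n_samples, dtype=bool)
    drop |= miss_frac > max_missing
    with np.errstate(invalid="ignore"):
        drop |= np.nan_to_num(f, nan=0.0) < min_F

    kin = pairwise_relatedness(g, method="king").to_numpy()
    order = np.argsort([s for s in g.samples])
    for i in range(g.n_samples):
        for j in range(i + 1, g.n_samples):
            if drop[i] or drop[j]:
                continue
            if np.isnan(kin[i, j]) or kin[i, j] < kinship_threshold:
                continue
            if miss_frac[i] > miss_frac[j]:
                drop[i] = True
            elif miss_frac[j] > miss_frac[i]:
                drop[j] = True
            else:
                drop[i if g.samples[i] > g.samples[j] else j] = True

    keep = ~drop
    g2 = g.take_samples(keep)
    d2 = d.take_samples(keep)
    s2 = samples.loc[keep].reset_index(drop=True)
    lost_pops = set(samples["population"]) - set(s2["population"])
    if lost_pops:
        logger.warning("all samples removed from populations: %s", sorted(lost_pops))
    report = FilterReport(
        stage="filter_individuals",
        n_loci_before=g.n_loci, n_loci_after=g2.n_loci,
        n_samples_before=g.n_samples, n_samples_after=g2.n_samples,
        parameters={
            "max_missing": max_missing,
            "min_F": min_F,
            "kinship_threshold": kinship_threshold,
        },
    )
    return g2, d2, s2, report


def thin_unlinked(
    g: GenotypeMatrix,
    diff_threshold: float = 0.5,
    max_distance_bp: int = 600,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Keep only unlinked SNPs within each RAD locus.

    Scanning by position within each RAD locus, a SNP is kept iff against
    every already-kept SNP within ``max_distance_bp`` the fraction of
    pairwise-complete samples with differing genotype codes is at least
    ``diff_threshold``.  The first SNP of each RAD locus is always kept.
    """
    keep = np.zeros(g.n_loci, dtype=bool)
    calls = g.calls
    ok = calls != MISSING
    loci = g.loci
    for _, idx in loci.groupby("radlocus_id", sort=False).groups.items():
        idx = list(idx)
        idx.sort(key=lambda j: loci.at[j, "pos"])
        kept: list[int] = []
        for j in idx:
            admit = True
            for k in kept:
                if abs(int(loci.at[j, "pos"]) - int(loci.at[k, "pos"])) > max_distance_bp:
                    continue
                both = ok[:, j] & ok[:, k]
                nb = both.sum()
                if nb == 0:
                    continue
                diff = (calls[both, j] != calls[both, k]).mean()
                if diff < diff_threshold:
                    admit = False
                    break
            if admit or not kept:
                keep[j] = True
                kept.append(j)
    g2 = g.take_loci(keep)
    report = FilterReport(
        stage="thin_unlinked",
        n_loci_before=g.n_loci, n_loci_after=g2.n_loci,
        n_samples_before=g.n_samples, n_samples_after=g2.n_samples,
        parameters={"diff_threshold": diff_threshold, "max_distance_bp": max_distance_bp},
    )
    return g2, report


def impute_most_common(g: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing calls by the locus's modal genotype code.

    Ties between modes resolve to the lower genotype code.  A locus with no
    non-missing call raises an error naming the locus.
    """
    calls = g.calls.copy()
    counts = np.stack([(calls == c).sum(axis=0) for c in (0, 1, 2)])  # 3 x L
    empty = counts.sum(axis=0) == 0
    if empty.any():
        j = int(np.flatnonzero(empty)[0])
        raise DataError(
            f"locus {g.loci.at[j, 'chrom']}:{g.loci.at[j, 'pos']} is entirely missing"
        )
    mode = counts.argmax(axis=0).astype(np.int8)   # argmax takes lowest on ties
    miss = calls == MISSING
    calls[miss] = np.broadcast_to(mode, calls.shape)[miss]
    return GenotypeMatrix(list(g.samples), g.loci, calls)


def restrict_to_chromosomes(g: GenotypeMatrix, chrom_whitelist) -> GenotypeMatrix:
    """Keep only loci on whitelisted chromosomes (drops unplaced scaffolds)."""
    white = set(chrom_whitelist)
    keep = g.loci["chrom"].isin(white).to_numpy()
    if not keep.any():
        logger.warning("chromosome whitelist removed every locus")
    return g.take_loci(keep)
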