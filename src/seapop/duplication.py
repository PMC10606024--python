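"""Paralog/CNV detection from heterozygote allele-ratio statistics.

A SNP assembled from two merged genomic copies betrays itself through the
read ratios of its apparent heterozygotes (concentrated away from 1/2), an
inflated heterozygote fraction, and a strongly negative per-locus
inbreeding coefficient.  Four per-locus diagnostics are computed and loci
are split into a singleton-SNP dataset and a duplicated-locus (CNV) read
depth dataset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import MISSING, AlleleDepthMatrix, DataError, GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class ClassificationThresholds:
    """Cut-offs of the duplicate decision rule.

    A locus is called duplicated iff its heterozygote median allele ratio
    falls outside [med_ratio_low, med_ratio_high], or its heterozygote
    fraction exceeds max_prop_het, or its inbreeding coefficient is below
    min_f_is.  Defaults were fixed by calibration on synthetic paralog-merge
    data (the rare-homozygote fraction is reported but not used by default).
    """

    med_ratio_low: float = 0.35
    med_ratio_high: float = 0.65
    max_prop_het: float = 0.6
    min_f_is: float = -0.3

    def __post_init__(self) -> None:
        if not self.med_ratio_low < self.med_ratio_high:
            raise DataError("med_ratio_low must be below med_ratio_high")


def duplication_stats(g: GenotypeMatrix, d: AlleleDepthMatrix) -> pd.DataFrame:
    """Per-locus duplication diagnostics.

    Returns a DataFrame with columns ``med_ratio`` (median ref/(ref+alt)
    over heterozygous calls; NaN when no usable heterozygote), ``prop_het``,
    ``prop_hom_rare``, ``f_is`` (1 - H_O/H_S with H_S = 2p(1-p) * n/(n-1))
    and ``n_het``.
    """
    calls = g.calls
    ok = calls != MISSING
    n_called = ok.sum(axis=0).astype(float)
    het = (calls == 1)
    n_het = het.sum(axis=0)

    total = d.total().astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(total > 0, d.ref_depth / total, np.nan)
    usable = het & (total > 0)
    n_zero_depth_het = int((het & (total == 0)).sum())
    if n_zero_depth_het:
        logger.info("excluded %d zero-depth heterozygotes from MedRatio", n_zero_depth_het)

    med_ratio = np.full(g.n_loci, np.nan)
    any_het = usable.any(axis=0)
    for j in np.flatnonzero(any_het):
        med_ratio[j] = np.median(ratio[usable[:, j], j])

    with np.errstate(invalid="ignore", divide="ignore"):
        prop_het = np.where(n_called > 0, n_het / n_called, np.nan)
        p = g.alt_allele_freq()
        alt_is_minor = p <= 0.5
        hom_rare = np.where(alt_is_minor, (calls == 2).sum(axis=0), (calls == 0).sum(axis=0))
        prop_hom_rare = np.where(n_called > 0, hom_rare / n_called, np.nan)
        h_s = 2.0 * p * (1.0 - p) * n_called / np.maximum(n_called - 1.0, 1.0)
        f_is = np.where(h_s > 0, 1.0 - prop_het / h_s, np.nan)

    return pd.DataFrame({
        "med_ratio": med_ratio,
        "prop_het": prop_het,
        "prop_hom_rare": prop_hom_rare,
        "f_is": np.clip(f_is, -1.0, 1.0),
        "n_het": n_het,
    }, index=g.loci.index)


def classify_loci(
    stats: pd.DataFrame,
    thresholds: ClassificationThresholds | None = None,
    use_prop_hom_rare: float | None = None,
) -> np.ndarray:
    """Label each locus ``singleton`` or ``duplicated``.

    An undefined median ratio counts as inside the accepted band (no
    heterozygote evidence either way).  ``use_prop_hom_rare`` optionally
    adds "prop_hom_rare > value" as a fourth criterion.
    """
    t = thresholds or ClassificationThresholds()
    mr = stats["med_ratio"].to_numpy()
    outside = ~np.isnan(mr) & ((mr < t.med_ratio_low) | (mr > t.med_ratio_high))
    dup = (
        outside
        | (stats["prop_het"].to_numpy() > t.max_prop_het)
        | (stats["f_is"].to_numpy() < t.min_f_is)
    )
    if use_prop_hom_rare is not None:
        dup |= stats["prop_hom_rare"].to_numpy() > use_prop_hom_rare
    return np.where(dup, "duplicated", "singleton").astype(object)


def split_datasets(
    g: GenotypeMatrix,
    d: AlleleDepthMatrix,
    labels: np.ndarray,
) -> tuple[GenotypeMatrix, AlleleDepthMatrix, pd.DataFrame, np.ndarray]:
    """Partition loci into the SNP dataset and the CNV depth dataset.

    Returns the singleton GenotypeMatrix with its aligned depths, the
    locus table of the duplicated loci, and their total read depth matrix
    (individuals x duplicated loci).
    """
    labels = np.asarray(labels, dtype=object)
    if labels.shape[0] != g.n_loci:
        raise DataError("labels not aligned to loci")
    singleton = labels == "singleton"
    duplicated = labels == "duplicated"
    if not duplicated.any():
        logger.warning("no duplicated loci; CNV dataset is empty")
    snp_g = g.take_loci(singleton)
    snp_d = d.take_loci(singleton)
    cnv_loci = g.loci.loc[duplicated].reset_index(drop=True)
    cnv_depth = d.total()[:, duplicated]
    return snp_g, snp_d, cnv_loci, cnv_depth


def plot_duplication_stats(stats: pd.DataFrame, labels=None, path=None):
    """Diagnostic scatter plots of each pair of duplication statistics."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cols = ["med_ratio", "prop_het", "prop_hom_rare", "f_is"]
    fig, axes = plt.subplots(2, 3, figsize=(12, 7))
    pairs = [(a, b) for i, a in enumerate(cols) for b in cols[i + 1:]]
    color = None
    if labels is not None:
        color = np.where(np.asarray(labels, dtype=object) == "duplicated", "crimson", "steelblue")
    for ax, (a, b) in zip(axes.ravel(), pairs):
        ax.scatter(stats[a], stats[b], s=6, alpha=0.5, c=color)
        ax.set_xlabel(a)
        ax.set_ylabel(b)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
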