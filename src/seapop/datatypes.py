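"""Core in-memory containers shared by every pipeline stage.

Genotypes are held as a dense ``int8`` matrix of alternate-allele counts
(0 = hom-ref, 1 = het, 2 = hom-alt, -1 = missing), samples in rows and loci
in columns; locus metadata travels alongside as a DataFrame.  Per-genotype
allele depths mirror the genotype shape.  These are deliberately plain
numpy/pandas structures so every statistic downstream can vectorise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

#: required columns of a locus table, in canonical order
LOCUS_COLUMNS = ["chrom", "pos", "radlocus_id", "ref", "alt"]

#: required columns of a sample table
SAMPLE_COLUMNS = ["sample", "population", "lat", "lon"]


class DataError(ValueError):
    """Inconsistent or invalid input data."""


@dataclass
class GenotypeMatrix:
    """Individuals x biallelic loci genotype calls.

    Parameters
    ----------
    samples : list of str
        Ordered sample identifiers (rows of ``calls``).
    loci : pandas.DataFrame
        One row per locus with columns ``chrom, pos, radlocus_id, ref, alt``
        (``pos`` is 1-based).
    calls : ndarray of int8, shape (n_samples, n_loci)
        Alternate-allele dosage; ``-1`` encodes a missing call.
    """

    samples: list[str]
    loci: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.loci = self.loci.reset_index(drop=True)
        if self.calls.shape != (len(self.samples), len(self.loci)):
            raise DataError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.loci)} loci"
            )
        missing_cols = [c for c in LOCUS_COLUMNS if c not in self.loci.columns]
        if missing_cols:
            raise DataError(f"locus table lacks columns {missing_cols}")
        if len(self.loci) and (self.loci["pos"] < 1).any():
            raise DataError("locus positions must be 1-based (>= 1)")
        if len(set(self.samples)) != len(self.samples):
            raise DataError("duplicate sample IDs")
        bad = ~np.isin(self.calls, (MISSING, 0, 1, 2))
        if bad.any():
            raise DataError("genotype codes must be in {-1, 0, 1, 2}")

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def missing_mask(self) -> np.ndarray:
        return self.calls == MISSING

    # -- derived quantities ---------------------------------------------
    def alt_allele_freq(self) -> np.ndarray:
        """Per-locus alternate allele frequency over non-missing calls."""
        ok = self.calls != MISSING
        n = ok.sum(axis=0)
        alt = np.where(ok, self.calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, alt / (2.0 * n), np.nan)

    # -- subsetting ------------------------------------------------------
    def take_loci(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            samples=list(self.samples),
            loci=self.loci.iloc[idx],
            calls=self.calls[:, idx],
        )

    def take_samples(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in idx],
            loci=self.loci,
            calls=self.calls[idx, :],
        )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(list(self.samples), self.loci.copy(), self.calls.copy())


@dataclass
class AlleleDepthMatrix:
    """Per-genotype (ref, alt) read depths aligned to a GenotypeMatrix."""

    ref_depth: np.ndarray
    alt_depth: np.ndarray

    def __post_init__(self) -> None:
        self.ref_depth = np.asarray(self.ref_depth, dtype=np.int32)
        self.alt_depth = np.asarray(self.alt_depth, dtype=np.int32)
        if self.ref_depth.shape != self.alt_depth.shape:
            raise DataError("ref/alt depth shapes differ")
        if (self.ref_depth < 0).any() or (self.alt_depth < 0).any():
            raise DataError("depths must be non-negative")

    @property
    def shape(self):
        return self.ref_depth.shape

    def total(self) -> np.ndarray:
        return self.ref_depth + self.alt_depth

    def take_loci(self, idx) -> "AlleleDepthMatrix":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return AlleleDepthMatrix(self.ref_depth[:, idx], self.alt_depth[:, idx])

    def take_samples(self, idx) -> "AlleleDepthMatrix":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return AlleleDepthMatrix(self.ref_depth[idx, :], self.alt_depth[idx, :])


def validate_sample_table(samples: pd.DataFrame, genotypes: GenotypeMatrix | None = None) -> pd.DataFrame:
    """Check a sample->population/coordinates table and return it re-indexed.

    Every genotyped sample must appear exactly once; coordinates must be
    valid decimal degrees.
    """
    missing_cols = [c for c in SAMPLE_COLUMNS if c not in samples.columns]
    if missing_cols:
        raise DataError(f"sample table lacks columns {missing_cols}")
    if samples["sample"].duplicated().any():
        raise DataError("duplicate rows in sample table")
    if (samples["lat"].abs() > 90).any() or (samples["lon"].abs() > 180).any():
        raise DataError("coordinates outside valid degree ranges")
    samples = samples.reset_index(drop=True)
    if genotypes is not None:
        tabled = set(samples["sample"])
        absent = [s for s in genotypes.samples if s not in tabled]
        if absent:
            raise DataError(f"samples missing from table: {absent[:5]}")
        # align row order to the genotype matrix
        samples = (
            samples.set_index("sample").loc[genotypes.samples].reset_index()
        )
    return samples


def population_indices(samples: pd.DataFrame) -> dict[str, np.ndarray]:
    """Map population label -> row indices, preserving first-seen order."""
    out: dict[str, np.ndarray] = {}
    for pop in samples["population"].drop_duplicates():
        out[pop] = np.flatnonzero((samples["population"] == pop).to_numpy())
    return out


@dataclass
class FilterReport:
    """Record of one filtering stage: what went in, what came out."""

    stage: str
    n_loci_before: int
    n_loci_after: int
    n_samples_before: int
    n_samples_after: int
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_loci_after > self.n_loci_before or self.n_samples_after > self.n_samples_before:
            raise DataError("filter cannot increase counts")

    def to_row(self) -> dict:
        row = {
            "stage": self.stage,
            "n_loci_before": self.n_loci_before,
            "n_loci_after": self.n_loci_after,
            "n_samples_before": self.n_samples_before,
            "n_samples_after": self.n_samples_after,
        }
        row.update({f"param_{k}": v for k, v in self.parameters.items()})
        return row
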