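"""Synthetic metapopulation generator.

Emulates the statistical structure of a coastal RADseq study system: two
strongly diverged ocean-basin groups of populations arranged along a 1-D
coastline, weak structure within each basin, isolation-by-distance at the
between-basin scale only, a single extra-drifted ("divergent") population,
loci whose allele frequencies track environmental gradients, paralog-merged
loci with distorted heterozygote allele ratios, and CNV loci with
population-structured read depth.

Population allele frequencies follow a hierarchical Balding–Nichols model:
for ancestral frequency p and differentiation parameter F, population
frequencies are Beta(p(1-F)/F, (1-p)(1-F)/F), whose expected Weir–Cockerham
F_ST equals F.  The between-group level uses ``fst_between_groups`` and the
within-group level ``fst_within_group``.

Paralog-merged ("duplicated") loci follow the minimal HDplot model: one
polymorphic copy plus one copy fixed for the reference allele mapped on top
of each other.  The apparent genotype collapses hom-alt to het, apparent
heterozygotes have read ratios near 0.75 (true het) or 0.5 (hidden hom-alt),
and heterozygosity is inflated.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import MISSING, AlleleDepthMatrix, DataError, GenotypeMatrix

#: raw environmental variables tracked monthly (sea-surface and biogeochemical)
ENV_VARIABLES = [
    "SST", "SSS", "ESCV", "NSCV", "CHLa", "CHLm", "PHYC", "PP",
    "SPM", "DO", "NO3", "PO4", "SI", "FE", "SPCO2", "PH",
]

LOCUS_CLASSES = ("neutral", "adaptive", "duplicated", "cnv")


@dataclass
class SimConfig:
    """Parameters of the synthetic metapopulation.

    Defaults are the package's reference "global" scenario: 12 populations in
    two basin groups along a coastline, basin-level divergence 0.10 (which
    realises a global multi-locus F_ST near 0.07 across the 12 populations)
    and within-basin differentiation 0.01, one extra-drifted divergent
    population, ~18-20x sequencing depth and a few percent missing data.
    """

    n_pops: int = 12
    n_per_pop: int = 10
    n_loci: int = 5000
    frac_adaptive: float = 0.02
    frac_duplicated: float = 0.05
    frac_cnv: float = 0.03
    fst_between_groups: float = 0.10
    fst_within_group: float = 0.01
    env_effect_size: float = 1.0
    mean_depth: float = 20.0
    missing_rate: float = 0.03
    seed: int = 0
    # structural knobs beyond the minimal parameter list
    n_groups: int = 2
    divergent_pop: int | None = 1
    fst_divergent: float = 0.05
    adaptive_predictors: tuple[str, ...] = ("SST", "FE")

    def __post_init__(self) -> None:
        fracs = {
            "frac_adaptive": self.frac_adaptive,
            "frac_duplicated": self.frac_duplicated,
            "frac_cnv": self.frac_cnv,
            "missing_rate": self.missing_rate,
        }
        for name, val in fracs.items():
            if not 0.0 <= val <= 1.0:
                raise DataError(f"{name} must be in [0, 1], got {val}")
        if self.frac_adaptive + self.frac_duplicated + self.frac_cnv > 1.0:
            raise DataError("locus class fractions exceed 1")
        if not 0.0 <= self.fst_between_groups < 1.0:
            raise DataError("fst_between_groups must be in [0, 1)")
        if not 0.0 <= self.fst_within_group < 1.0:
            raise DataError("fst_within_group must be in [0, 1)")
        if self.n_pops < 1 or self.n_loci < 1:
            raise DataError("need at least one population and one locus")
        if self.n_per_pop < 2:
            raise DataError("n_per_pop must be >= 2")
        if self.n_groups < 1 or self.n_groups > self.n_pops:
            raise DataError("n_groups must be in [1, n_pops]")
        if self.divergent_pop is not None and not 0 <= self.divergent_pop < self.n_pops:
            raise DataError("divergent_pop out of range")


@dataclass
class SimTruth:
    """Ground-truth labels for a simulated dataset."""

    locus_class: np.ndarray            # per locus, one of LOCUS_CLASSES
    adaptive_predictor: dict           # locus index -> driving env variable
    pop_membership: pd.DataFrame       # sample, population, group
    true_copy_number: np.ndarray       # n_samples x n_cnv_loci ints
    cnv_locus_index: np.ndarray        # column indices of cnv loci
    paralog_genotypes: np.ndarray      # n_samples x n_dup underlying variable-copy calls
    duplicated_locus_index: np.ndarray

    def class_indices(self, cls: str) -> np.ndarray:
        return np.flatnonzero(self.locus_class == cls)


def _balding_nichols(rng: np.random.Generator, p: np.ndarray, f: float, size) -> np.ndarray:
    """Draw descendant frequencies with E[freq]=p and Var=f*p*(1-p)."""
    if f <= 0:
        return np.broadcast_to(p, size).copy()
    a = p * (1.0 - f) / f
    b = (1.0 - p) * (1.0 - f) / f
    return rng.beta(np.broadcast_to(a, size), np.broadcast_to(b, size))


def site_positions(n_pops: int) -> np.ndarray:
    """Evenly spaced positions of the populations on the unit coastline."""
    return np.linspace(0.0, 1.0, n_pops)


def latent_gradients(n_pops: int) -> tuple[np.ndarray, np.ndarray]:
    """Two standardised spatial patterns driving the environment.

    ``u`` is the linear coastline gradient; ``w`` is a full-period cosine
    (e.g. a mid-coast upwelling pattern), orthogonal both to ``u`` and to a
    half-split of the coastline into two basins.
    """
    s = site_positions(n_pops)
    u = (s - s.mean()) / s.std()
    w_raw = np.cos(2.0 * np.pi * s)
    sd = w_raw.std()
    w = (w_raw - w_raw.mean()) / sd if sd > 0 else np.zeros_like(w_raw)
    return u, w


def _assign_classes(rng: np.random.Generator, cfg: SimConfig) -> np.ndarray:
    n = cfg.n_loci
    n_ad = int(round(cfg.frac_adaptive * n))
    n_dup = int(round(cfg.frac_duplicated * n))
    n_cnv = int(round(cfg.frac_cnv * n))
    labels = np.array(["neutral"] * n, dtype=object)
    special = rng.choice(n, size=n_ad + n_dup + n_cnv, replace=False)
    labels[special[:n_ad]] = "adaptive"
    labels[special[n_ad:n_ad + n_dup]] = "duplicated"
    labels[special[n_ad + n_dup:]] = "cnv"
    return labels


def simulate_metapopulation(config: SimConfig) -> tuple[GenotypeMatrix, pd.DataFrame, SimTruth]:
    """Simulate genotypes, a sample table and ground truth.

    Returns
    -------
    genotypes : GenotypeMatrix
        Apparent genotype calls (paralog-merged loci already collapsed to
        their apparent codes; the underlying calls live in the truth).
    samples : pandas.DataFrame
        sample, population, group, lat, lon — populations on a 1-D coastline
        embedded along a coastal arc in lat/lon.
    truth : SimTruth
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    n_pops, n_per, L = cfg.n_pops, cfg.n_per_pop, cfg.n_loci
    n_ind = n_pops * n_per
    pop_of_sample = np.repeat(np.arange(n_pops), n_per)
    group_of_pop = (np.arange(n_pops) * cfg.n_groups) // n_pops

    labels = _assign_classes(rng, cfg)
    u, w = latent_gradients(n_pops)

    # hierarchical Balding-Nichols frequencies; clinal (adaptive) loci are
    # held at intermediate ancestral frequency, as migration-selection
    # balance maintains polymorphism there
    p_anc = rng.uniform(0.05, 0.95, size=L)
    adaptive_mask = labels == "adaptive"
    p_anc[adaptive_mask] = rng.uniform(0.25, 0.75, size=int(adaptive_mask.sum()))
    p_group = _balding_nichols(rng, p_anc[None, :], cfg.fst_between_groups,
                               (cfg.n_groups, L))
    p_pop = np.empty((n_pops, L))
    for k in range(n_pops):
        f = cfg.fst_within_group
        if cfg.divergent_pop is not None and k == cfg.divergent_pop:
            f = cfg.fst_within_group + cfg.fst_divergent
        p_pop[k] = _balding_nichols(rng, p_group[group_of_pop[k]], f, (L,))

    # adaptive loci: logit-scale shift along the predictor's site gradient
    adaptive_idx = np.flatnonzero(labels == "adaptive")
    adaptive_predictor: dict[int, str] = {}
    gradients = {"SST": u, "FE": w}
    for j, locus in enumerate(adaptive_idx):
        var = cfg.adaptive_predictors[j % len(cfg.adaptive_predictors)]
        adaptive_predictor[int(locus)] = var
        z = gradients.get(var, u)
        base = np.clip(p_pop[:, locus], 1e-6, 1 - 1e-6)
        logit = np.log(base / (1 - base)) + cfg.env_effect_size * z
        p_pop[:, locus] = 1.0 / (1.0 + np.exp(-logit))

    # genotypes
    p_ind = p_pop[pop_of_sample, :]
    calls = rng.binomial(2, p_ind).astype(np.int8)

    # paralog-merged loci: keep the underlying variable-copy genotype, then
    # collapse hom-alt to apparent het (the fixed-ref copy always contributes
    # reference reads, so both alleles are observed)
    dup_idx = np.flatnonzero(labels == "duplicated")
    paralog_genotypes = calls[:, dup_idx].copy()
    apparent = paralog_genotypes.copy()
    apparent[apparent == 2] = 1
    calls[:, dup_idx] = apparent

    # CNV loci: per-locus population-structured copy number 2 + Binomial(2, q_pop)
    cnv_idx = np.flatnonzero(labels == "cnv")
    q_pop = rng.uniform(0.0, 1.0, size=(n_pops, len(cnv_idx)))
    extra = rng.binomial(2, q_pop[pop_of_sample, :])
    true_copy_number = 2 + extra

    # completely-at-random missingness
    miss = rng.random(calls.shape) < cfg.missing_rate
    calls[miss] = MISSING

    # metadata
    loci = pd.DataFrame({
        "chrom": ["chr%d" % (1 + i % 25) for i in range(L)],
        "pos": np.arange(L) * 1000 + 1,
        "radlocus_id": ["RAD%05d" % (i // 3) for i in range(L)],
        "ref": ["A"] * L,
        "alt": ["T"] * L,
    })
    # sort by chrom/pos within chrom for realism; keep simple deterministic order
    sample_ids = ["P%02d_I%02d" % (pop_of_sample[i], i % n_per) for i in range(n_ind)]
    s = site_positions(n_pops)
    lat = 58.0 + 12.0 * s               # a Norway-scale coastal arc
    lon = 5.0 + 17.0 * s
    samples = pd.DataFrame({
        "sample": sample_ids,
        "population": ["pop%02d" % k for k in pop_of_sample],
        "group": ["basin%d" % group_of_pop[k] for k in pop_of_sample],
        "lat": lat[pop_of_sample],
        "lon": lon[pop_of_sample],
    })

    genotypes = GenotypeMatrix(samples=sample_ids, loci=loci, calls=calls)
    truth = SimTruth(
        locus_class=labels,
        adaptive_predictor=adaptive_predictor,
        pop_membership=samples[["sample", "population", "group"]].copy(),
        true_copy_number=true_copy_number,
        cnv_locus_index=cnv_idx,
        paralog_genotypes=paralog_genotypes,
        duplicated_locus_index=dup_idx,
    )
    return genotypes, samples, truth


def simulate_read_depths(
    genotypes: GenotypeMatrix, truth: SimTruth, config: SimConfig
) -> tuple[AlleleDepthMatrix, np.ndarray]:
    """Draw per-genotype allele depths consistent with the locus classes.

    Singleton loci: total depth ~ Poisson(mean_depth); heterozygote reference
    reads ~ Binomial(depth, 1/2).  Paralog-merged loci: two independent
    copies each at Poisson(mean_depth); the fixed copy contributes only
    reference reads.  CNV loci: depth ~ Poisson(mean_depth * copy_number / 2).

    Returns the allele-depth matrix and the total-depth matrix (ref+alt).
    """
    cfg = config
    if truth.locus_class.shape[0] != genotypes.n_loci:
        raise DataError("truth labels not aligned to genotype loci")
    rng = np.random.default_rng(cfg.seed + 1)
    n, L = genotypes.calls.shape

    depth = rng.poisson(cfg.mean_depth, size=(n, L))

    # CNV loci scale with copy number
    if len(truth.cnv_locus_index):
        lam = cfg.mean_depth * truth.true_copy_number / 2.0
        depth[:, truth.cnv_locus_index] = rng.poisson(lam)

    calls = genotypes.calls
    ref = np.where(calls == 0, depth, 0)
    het = calls == 1
    ref = ref + np.where(het, rng.binomial(depth, 0.5), 0)
    # hom-alt contributes zero reference reads

    # paralog-merged loci: re-draw from the two-copy model using the
    # underlying variable-copy genotype
    dup = truth.duplicated_locus_index
    if len(dup):
        d_var = rng.poisson(cfg.mean_depth, size=(n, len(dup)))
        d_fix = rng.poisson(cfg.mean_depth, size=(n, len(dup)))
        g_var = truth.paralog_genotypes
        ref_var = np.where(g_var == 0, d_var, 0)
        ref_var = ref_var + np.where(g_var == 1, rng.binomial(d_var, 0.5), 0)
        depth[:, dup] = d_var + d_fix
        ref[:, dup] = ref_var + d_fix    # fixed copy is all-reference

    # missing genotypes carry no reads
    miss = genotypes.missing_mask()
    depth = np.where(miss, 0, depth)
    ref = np.where(miss, 0, ref)
    alt = depth - ref
    ad = AlleleDepthMatrix(ref_depth=ref, alt_depth=alt)
    return ad, depth


def simulate_environment(
    sites: pd.DataFrame,
    config: SimConfig,
    n_years: int = 22,
    first_year: int = 1993,
    noise_sd: float = 0.25,
    loadings: dict[str, tuple[float, float]] | None = None,
    seasonal_amplitude: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Monthly environmental time series for each site.

    Each variable's site-level mean is a linear combination of the two
    latent spatial gradients (``u``: coastline, ``w``: second smooth
    pattern), plus a seasonal sinusoid and iid noise.  Shared gradient
    loadings create realistic collinearity between variables so that
    pruning has something to do.

    Parameters
    ----------
    sites : DataFrame
        One row per site with at least a ``population`` column; sites are
        taken in order of first appearance.
    loadings : mapping variable -> (load_u, load_w), optional
        Overrides the default gradient loadings.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed + 2)

    pops = list(sites["population"].drop_duplicates())
    n_sites = len(pops)
    u, w = latent_gradients(n_sites)

    default_loadings = {
        # dominant coastline-gradient block (temperature/salinity/carbonate)
        "SST": (1.0, 0.0), "SSS": (0.9, 0.1), "SPCO2": (0.8, 0.1),
        "PH": (-0.8, 0.1), "DO": (-0.7, -0.2),
        # nutrients also track the coastline, with some secondary pattern
        "NO3": (-0.6, 0.3), "PO4": (-0.6, 0.3), "SI": (-0.55, 0.25),
        # productivity block, collinear with each other
        "CHLa": (0.5, 0.4), "CHLm": (0.5, 0.4), "PHYC": (0.5, 0.4),
        "PP": (0.45, 0.35),
        # secondary (upwelling/riverine) pattern
        "FE": (0.1, 0.9), "SPM": (0.15, 0.7),
        # currents: weak spatial structure
        "ESCV": (0.2, 0.0), "NSCV": (0.0, 0.2),
    }
    if loadings:
        default_loadings.update(loadings)
    amp = {v: 0.3 for v in ENV_VARIABLES}
    amp["SST"] = 1.0                     # strong seasonality in temperature
    if seasonal_amplitude:
        amp.update(seasonal_amplitude)

    years = np.arange(first_year, first_year + n_years)
    months = np.arange(1, 13)

    records = []
    month_angle = 2.0 * np.pi * (months - 1) / 12.0
    for var in ENV_VARIABLES:
        lu, lw = default_loadings.get(var, (0.0, 0.0))
        site_mean = lu * u + lw * w
        seasonal = amp[var] * np.cos(month_angle - np.pi)  # coldest in January
        noise = rng.normal(0.0, noise_sd, size=(n_sites, n_years, 12))
        vals = site_mean[:, None, None] + seasonal[None, None, :] + noise
        for si, pop in enumerate(pops):
            for yi, year in enumerate(years):
                for mi, month in enumerate(months):
                    records.append((pop, int(year), int(month), var, vals[si, yi, mi]))
    env = pd.DataFrame.from_records(
        records, columns=["site", "year", "month", "variable", "value"]
    )
    return env


# ---------------------------------------------------------------------------
# fixture I/O


def write_fixture(
    genotypes: GenotypeMatrix,
    depths: AlleleDepthMatrix,
    samples: pd.DataFrame,
    env: pd.DataFrame,
    truth: SimTruth,
    out_dir,
) -> dict[str, str]:
    """Write VCF + TSV fixtures that round-trip through the io module."""
    import os

    from .io import write_vcf

    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "vcf": os.path.join(out_dir, "genotypes.vcf"),
        "samples": os.path.join(out_dir, "samples.tsv"),
        "env": os.path.join(out_dir, "environment.tsv"),
        "truth": os.path.join(out_dir, "truth.tsv"),
    }
    write_vcf(paths["vcf"], genotypes, depths)
    samples.to_csv(paths["samples"], sep="\t", index=False)
    env.to_csv(paths["env"], sep="\t", index=False)

    truth_rows = pd.DataFrame({
        "chrom": genotypes.loci["chrom"],
        "pos": genotypes.loci["pos"],
        "locus_class": truth.locus_class,
        "adaptive_predictor": [
            truth.adaptive_predictor.get(i, "") for i in range(genotypes.n_loci)
        ],
    })
    truth_rows.to_csv(paths["truth"], sep="\t", index=False)
    return paths


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=False)


def config_from_dict(d: dict) -> SimConfig:
    """Build a SimConfig from a plain mapping (e.g. parsed YAML)."""
    names = {f.name for f in dataclasses.fields(SimConfig)}
    unknown = set(d) - names
    if unknown:
        raise DataError(f"unknown simulation parameters: {sorted(unknown)}")
    d = dict(d)
    if "adaptive_predictors" in d:
        d["adaptive_predictors"] = tuple(d["adaptive_predictors"])
    return SimConfig(**d)
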