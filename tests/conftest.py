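"""Shared fixtures: small simulated datasets reused across test modules."""

import numpy as np
import pandas as pd
import pytest

import seapop as sp
from seapop.datatypes import GenotypeMatrix, AlleleDepthMatrix


def make_genotypes(calls, samples=None, chrom=None, pos=None, radlocus=None):
    """Build a GenotypeMatrix from a plain array with default metadata."""
    calls = np.asarray(calls, dtype=np.int8)
    n, L = calls.shape
    samples = samples or [f"s{i}" for i in range(n)]
    loci = pd.DataFrame({
        "chrom": chrom if chrom is not None else ["chr1"] * L,
        "pos": pos if pos is not None else np.arange(1, L + 1) * 1000,
        "radlocus_id": radlocus if radlocus is not None else [f"R{j}" for j in range(L)],
        "ref": ["A"] * L,
        "alt": ["T"] * L,
    })
    return GenotypeMatrix(samples=samples, loci=loci, calls=calls)


def make_samples(populations, lat=None, lon=None, sample_ids=None):
    populations = list(populations)
    n = len(populations)
    return pd.DataFrame({
        "sample": sample_ids or [f"s{i}" for i in range(n)],
        "population": populations,
        "lat": lat if lat is not None else np.linspace(58, 70, n),
        "lon": lon if lon is not None else np.linspace(5, 20, n),
    })


def hwe_genotypes(rng, n, L, p=None):
    """Panmictic Hardy-Weinberg genotypes."""
    if p is None:
        p = rng.uniform(0.1, 0.9, size=L)
    return rng.binomial(2, np.broadcast_to(p, (n, L))).astype(np.int8)


@pytest.fixture(scope="session")
def default_sim():
    """The reference global scenario: two basins, one divergent population."""
    cfg = sp.SimConfig(seed=1)
    g, samples, truth = sp.simulate_metapopulation(cfg)
    ad, depth = sp.simulate_read_depths(g, truth, cfg)
    return cfg, g, samples, truth, ad, depth


@pytest.fixture(scope="session")
def classified_sim():
    """Mid-size simulation for duplicate classification checks."""
    cfg = sp.SimConfig(n_pops=4, n_per_pop=25, n_loci=2000, frac_duplicated=0.05,
                       frac_adaptive=0.0, frac_cnv=0.03, divergent_pop=None,
                       mean_depth=20.0, seed=11)
    g, samples, truth = sp.simulate_metapopulation(cfg)
    ad, depth = sp.simulate_read_depths(g, truth, cfg)
    return cfg, g, samples, truth, ad, depth
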