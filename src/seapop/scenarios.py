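"""Reference study scenarios used for validation and reproduction runs.

Each scenario fixes every generator parameter except the seed, so the same
conditions can be recomputed end to end by the test-suite and the
reproduction script.

* ``global_scenario`` — the reference seascape: 12 populations in two ocean
  basins along a coastline (realised global multi-locus F_ST ~ 0.07,
  within-basin ~ 0.01), one extra-drifted divergent population, paralog-
  merged and CNV loci planted.
* ``classification_scenario`` — 100 individuals x 2000 loci with 5%
  paralog-merged loci at 20x depth, for duplicate-detection operating
  characteristics.
* ``gea_power_scenario`` — 200 individuals x 10,000 loci: two basins (one
  dominant structure axis), 100 loci under clinal selection on the
  secondary environmental gradient.
* ``gea_null_scenario`` — 200 individuals x 5000 loci: ten differentiated
  populations with the environment collinear with structure and *no* true
  associations (the latent-confounded null; its structure spans
  n_pops - 1 = 9 latent dimensions).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import (
    GeaConfig,
    SimConfig,
    env_pca,
    impute_most_common,
    simulate_environment,
    simulate_metapopulation,
    simulate_read_depths,
    summarize_env,
)


def global_scenario(seed: int = 1):
    cfg = SimConfig(seed=seed)
    g, samples, truth = simulate_metapopulation(cfg)
    ad, depth = simulate_read_depths(g, truth, cfg)
    return cfg, g, samples, truth, ad, depth


def classification_scenario(seed: int = 11):
    cfg = SimConfig(n_pops=4, n_per_pop=25, n_loci=2000, frac_adaptive=0.0,
                    frac_duplicated=0.05, frac_cnv=0.0, divergent_pop=None,
                    mean_depth=20.0, seed=seed)
    g, samples, truth = simulate_metapopulation(cfg)
    ad, depth = simulate_read_depths(g, truth, cfg)
    return cfg, g, samples, truth, ad, depth


def _env_pc_predictors(samples: pd.DataFrame, cfg: SimConfig, n_years: int = 5):
    summary = summarize_env(simulate_environment(samples, cfg, n_years=n_years))
    scores, _, _, n_ret = env_pca(summary)
    n_use = max(n_ret, 2)
    X = scores.iloc[:, :n_use].loc[
        samples["population"].to_numpy()].reset_index(drop=True)
    return X, summary


def gea_power_scenario(seed: int = 42):
    cfg = SimConfig(n_pops=10, n_per_pop=20, n_loci=10_000, frac_adaptive=0.01,
                    frac_duplicated=0.0, frac_cnv=0.0, fst_within_group=0.0,
                    divergent_pop=None, adaptive_predictors=("FE",), seed=seed)
    g, samples, truth = simulate_metapopulation(cfg)
    g_imp = impute_most_common(g)
    X, summary = _env_pc_predictors(samples, cfg)
    return cfg, g_imp, samples, truth, X, summary


def gea_null_scenario(seed: int = 9):
    cfg = SimConfig(n_pops=10, n_per_pop=20, n_loci=5000, frac_adaptive=0.0,
                    frac_duplicated=0.0, frac_cnv=0.0, divergent_pop=None,
                    seed=seed)
    g, samples, truth = simulate_metapopulation(cfg)
    g_imp = impute_most_common(g)
    X, summary = _env_pc_predictors(samples, cfg)
    k_true = cfg.n_pops - 1
    return cfg, g_imp, samples, X, k_true
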