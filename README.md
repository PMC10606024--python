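# seapop

Seascape population genomics from RADseq genotype + read-depth matrices.

Marine species with planktonic larvae often show near-panmixia over
thousands of kilometres of coastline, yet carry loci whose allele
frequencies track oceanographic gradients — local adaptation under high
gene flow. Detecting that signal from reduced-representation sequencing
takes a long chain of steps, each easy to get subtly wrong: separating
true single-copy SNPs from collapsed paralogs using heterozygote read
ratios, quantifying differentiation at SNPs (F_ST) and at copy-number
variants (V_ST on normalised read depths), building spatial predictors
that can absorb neutral structure, and running genotype–environment
association (GEA) scans whose p-values survive the confounding between
environment and ancestry. `seapop` packages that chain as a tested
Python library with a thin CLI, plus a synthetic metapopulation
generator so every stage can be validated end to end with known ground
truth.

## What it computes

| Stage | Statistics |
|---|---|
| `seapop.simulate` | hierarchical Balding–Nichols metapopulation with clinal selection, paralog-merged loci, population-structured CNVs, monthly environmental series |
| `seapop.filtering` | depth/call-rate/minor-allele-sample locus filters; individual missingness, heterozygosity-F and KING-robust kinship pruning; unlinked-SNP thinning; modal imputation |
| `seapop.duplication` | MedRatio / PropHet / PropHomRare / F_IS diagnostics; singleton vs duplicated split |
| `seapop.popgen` | Weir–Cockerham θ (multi-locus and pairwise, bootstrap CIs), population-specific β_WT, H_O/H_S/F_IS, rarefied allelic richness, private alleles, Nei's D_A, PCoA, top-F_ST subsets |
| `seapop.cnv` | TMM normalisation, V_ST with permutation p-values, bootstrap CIs and genome-wide outlier classes |
| `seapop.envdata` | 34 site-level summaries from 16 raw monthly variables, broken-stick PCA, |r|/VIF collinearity pruning, collinear-variable clustering |
| `seapop.spatial` | azimuthal-equidistant projection, dbMEM spatial eigenfunctions, Mantel IBD tests, double-stopping forward selection, site-level RDA |
| `seapop.gea` | individual-level RDA/pRDA scan, ridge-LFMM scan, PCA differentiation scan; genomic-inflation calibration, BH/Storey q-values, neutral-set derivation, candidate overlap |

The core estimators in brief: Weir–Cockerham
θ = Σa / Σ(a + b + c) over loci (variance components among/between/within
individuals); β_WT,i = (ΣM_i − ΣM_B)/Σ(1 − M_B) from allele-matching
proportions; V_ST = (V_T − V_S)/V_T on TMM-normalised depths with V_S
the size-weighted within-population variance; and GEA statistics
recalibrated by the genomic inflation factor
λ = median(stat)/median(χ²_df) before FDR control.

See `docs/methods.md` for the full model and parameter documentation.

## Worked example

Simulate the reference scenario — 12 populations in two ocean basins
along a coastline, one extra-drifted population (`pop01`), 5000 loci with
planted paralogs and CNVs — then split datasets and measure
differentiation:

```python
import seapop as sp
from seapop import scenarios

cfg, g, samples, truth, ad, depth = scenarios.global_scenario(seed=1)

labels = sp.classify_loci(sp.duplication_stats(g, ad))
snp_g, snp_d, cnv_loci, cnv_depth = sp.split_datasets(g, ad, labels)
print((labels == "singleton").sum(), (labels == "duplicated").sum())
# 4745 255

print(round(sp.multilocus_fst_wc(snp_g, samples), 4))
# 0.0744

beta = sp.beta_wt(snp_g, samples, n_boot=200, seed=1)
print(beta.round(3).to_string(index=False))
```

```
population  beta_wt  beta_lo  beta_hi
     pop00    0.072    0.062    0.082
     pop01    0.126    0.113    0.137
     ...
   overall    0.074    0.072    0.077
```

The global multi-locus F_ST (0.074) reflects the two-basin divergence;
the planted divergent population `pop01` stands out with the largest
population-specific β_WT (0.126 vs ~0.07 elsewhere), exactly the pattern
this index exists to reveal. The CNV side:

```python
norm, factors = sp.tmm_normalize(cnv_depth)
norm, n_dropped = sp.drop_zero_variance(norm)
res = sp.vst_permutation(norm, samples, "pop00", "pop11", n_perm=1000, seed=1)
print((res["outlier_class"] != "none").sum(), round(res["v_st"].max(), 3))
# 20 0.274
```

20 of the 255 duplicated loci show moderate V_ST differentiation between
the coastline's end populations — population-structured copy number that
the SNP genotypes alone would not reveal.

The same pipeline runs from the shell:

```bash
seapop simulate --out fixture --seed 5
seapop filter   --vcf fixture/genotypes.vcf --popmap fixture/samples.tsv --out filtered
seapop classify --vcf filtered/filtered.vcf --out classified
seapop popgen   --vcf classified/singletons.vcf --popmap filtered/samples.tsv --boot 1000 --out popgen
seapop cnv      --depths classified/cnv_depth.tsv --popmap filtered/samples.tsv --out cnv
seapop env      --in fixture/environment.tsv --out env
```

GEA scans are library calls (they combine matrices from several stages);
see `seapop.rda_scan`, `seapop.lfmm_ridge_scan`, `seapop.pca_scan` and
the scenarios in `seapop/scenarios.py`.

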