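# Methods

`seapop` implements a seascape population-genomics analysis pipeline for
reduced-representation (RADseq-style) SNP data with per-genotype allele
depths: dataset construction (filtering and paralog/CNV separation),
diversity and differentiation statistics, copy-number differentiation,
spatial eigenfunction modelling, and genotype–environment association
(GEA) scans. Every stage can be exercised on a synthetic metapopulation
whose statistical structure mirrors a two-basin coastal study system, so
the whole pipeline is testable without any external download.

## The synthetic metapopulation

**Model.** Populations sit at evenly spaced positions along a 1-D
"coastline" and are partitioned into `n_groups` ocean basins. Allele
frequencies follow a hierarchical Balding–Nichols (BN) model: for
ancestral frequency *p* ~ U(0.05, 0.95) and differentiation parameter
*F*, descendant frequencies are Beta(p(1−F)/F, (1−p)(1−F)/F), whose
expected Weir–Cockerham F_ST equals *F*. The basin level uses
`fst_between_groups`, the within-basin level `fst_within_group`, and one
designated population can receive extra drift (`fst_divergent`), mirroring
the common situation of a single anomalously divergent sample site.
Genotypes are Binomial(2, p_pop); missingness is completely at random.

**Defaults as study conditions.** The reference "global" scenario uses 12
populations in two equal basins, `fst_between_groups = 0.10` — which
realises a global multi-locus F_ST ≈ 0.07 across the 12 populations,
the scale typical of trans-Atlantic marine fish — `fst_within_group =
0.01` (weak regional structure), 10 individuals per site (5–15 is the
usual field range), mean depth 20× and 3% missing data. The locus count
(5000 by default) is a desk-scale stand-in for the tens of thousands of
RAD SNPs of a real experiment; all differentiation statistics are
ratios-of-sums over loci and are insensitive to this scale beyond Monte
Carlo noise.

**Environmental gradients and selection.** Two standardised latent spatial
patterns drive the environment: `u`, the linear coastline gradient, and
`w`, a full-period cosine (a mid-coast "upwelling" pattern orthogonal both
to `u` and to the basin split). Each of the 16 raw monthly variables
(SST, SSS, ESCV, NSCV, CHLa, CHLm, PHYC, PP, SPM, DO, NO3, PO4, SI, FE,
SPCO2, PH) loads on (u, w) with a fixed default pattern in which the
coastline block (temperature/salinity/carbonate/nutrients) dominates —
this keeps the environmental PCA well conditioned (ePC1 ≈ u, ePC2 ≈ w)
— plus a seasonal sinusoid (strong for SST) and iid monthly noise.
Shared loadings create realistic collinearity for the pruning step.

Adaptive loci receive a logit-scale allele-frequency shift
`env_effect_size × z(site)` along their assigned gradient. The default
effect is 1.0 logit per environmental SD — strong divergent selection, the
regime in which GEA methods are expected to have power — and adaptive loci
are drawn at intermediate ancestral frequency (0.25–0.75), since
migration–selection balance maintains clinal polymorphism away from the
frequency boundaries.

**Paralogs and CNVs.** Paralog-merged ("duplicated") loci follow the
minimal HDplot model: one polymorphic copy plus one copy fixed for the
reference allele, mapped on top of each other. Each copy sequences at
Poisson(mean_depth); apparent heterozygotes therefore have read ratios
near 0.75 (true heterozygote at the variable copy) or 0.5 (hidden
hom-alt), heterozygosity is inflated (hom-alt collapses to het), and the
per-locus F_IS is strongly negative. CNV loci carry a per-individual
integer copy number 2 + Binomial(2, q_pop) with q_pop population-specific,
and depth ~ Poisson(mean_depth × copy/2).

**What the generator does not emulate.** Linkage disequilibrium beyond
shared RAD-locus membership, allele-frequency spectra shaped by
demography, batch/lane effects in depth, non-random missingness, and
sequencing error in the genotype calls. Tests passing on this generator
demonstrate the statistics are computed correctly and behave as designed
under their stated model — not that the thresholds transfer unchanged to
any particular empirical dataset.

## Filtering

The chain mirrors standard RADseq practice: genotypes below 4× total
depth are set missing; a locus is kept iff called in ≥ 80% of samples in
*every* population and ≥ 2 samples carry the minor allele (both
configurable — tool conventions vary between 2 and 3 for the minor-allele
count and 500–600 bp for the linkage window, so these stay explicit
parameters). Individuals are dropped for > 20% missingness, for
method-of-moments F < −0.2 (the vcftools `--het` statistic: excess
heterozygosity flags contamination), and for KING-robust kinship ≥ 0.25
(first degree), removing the pair member with more missing data (ties: the
lexicographically larger ID, for determinism). Within each RAD locus,
SNPs are thinned by position scan: a SNP is kept only if its genotype
column differs from every already-kept SNP within 600 bp in ≥ 50% of
pairwise-complete samples. Imputation (modal genotype per locus, ties to
the lower code) is applied only where downstream methods need complete
matrices.

## Duplicate classification

Four per-locus diagnostics: `MedRatio` (median reference-read fraction over
heterozygotes), `PropHet`, `PropHomRare`, and F_IS = 1 − H_O/H_S with
H_S = 2p(1−p)·n/(n−1). A locus is "duplicated" iff MedRatio falls outside
[0.35, 0.65], or PropHet > 0.6, or F_IS < −0.3. The band and cut-offs were
fixed once by calibration on the synthetic paralog-merge model (sensitivity
≈ 1.0, false-positive rate ≈ 0.3% at depth 20, n = 100); `PropHomRare` is
reported but not part of the default rule. The reference-allele
orientation of the read ratio is a convention; the band is symmetric so
orientation does not matter.

## Differentiation statistics

* **Weir–Cockerham θ** — per-locus variance components a, b, c with the
  textbook small-sample corrections; multi-locus θ is the ratio of summed
  components (ratio-of-sums, not mean-of-ratios, for stability); loci
  monomorphic across the compared populations or with an empty population
  are excluded. Pairwise CIs: percentile bootstrap over loci. The
  implementation is validated to 1e-12 against an independent scalar
  transcription of the estimator.
* **β_WT (population-specific F_ST)** — allele-matching form:
  β_i = (ΣM_i − ΣM_B) / Σ(1 − M_B) over loci, with M_i the
  within-population matching proportion of two distinct gene copies
  (heterozygote matching enters through the unordered-pair counts
  x(x−1) + (m−x)(m−x−1) over m(m−1)) and M_B the mean between-population
  matching of allele-frequency products. Overall index = mean over
  populations; percentile bootstrap over loci.
* **Diversity** — H_O as the mean observed-heterozygote fraction; H_S as
  Nei's unbiased gene diversity (n/(n−1) correction including the
  H_O/2n term); F_IS = 1 − mean(H_O)/mean(H_S).
* **Allelic richness** — hypergeometric rarefaction to the smallest
  per-locus, per-population count of non-missing gene copies (checked
  against exhaustive enumeration).
* **Nei's D_A** — 1 − mean over loci of Σ_a √(x_a y_a); **PCoA** by Gower
  double-centering, negative eigenvalues reported (optional Cailliez
  correction).

## CNV differentiation

Depths at duplicated loci are TMM-normalised (reference sample by
upper-quartile proximity to the mean; log-ratios doubly trimmed 30%/5%
with precision weights; factors rescaled to geometric mean 1; counts
divided by effective library size and rescaled to the raw-depth scale).
V_ST = (V_T − V_S)/V_T with V_S the size-weighted mean within-population
variance; all variances use the n−1 denominator (the convention is
switchable; the worked value 0.7143 for (1,2,3) vs (4,5,6) pins the
default). Permutation p-values use the (1 + exceedances)/(n_perm + 1)
convention over pooled relabellings; 95% CIs bootstrap individuals within
populations; genome-wide outlier classes are moderate (0.1, 0.3] and
strong (> 0.3).

## Environment

ESCV and NSCV are combined per time step into SCV = √(ESCV² + NSCV²);
each of the 15 base variables gets an overall mean and SD of monthly
values (monthly rather than annual-mean SD: the larger, more informative
sample), and SST additionally the across-year mean and SD of the
per-site climatologically coldest and hottest months — 34 summaries from
16 raw variables. Collinearity pruning iterates: among the currently most
correlated pair at |r| ≥ 0.5, drop the member with the higher VIF against
all retained variables. Variable grouping uses complete-linkage
clustering on 1 − |r| cut at 1 − r_threshold. PCA retention follows the
broken-stick rule on correlation-matrix eigenvalues.

## Spatial predictors

Coordinates are projected by a local azimuthal-equidistant projection
about the site centroid (pairwise distances within ~1% of great-circle
for regional spans; the naive fixed-parallel equirectangular projection
errs by ~18% over a 12° latitude span and is not used). dbMEMs follow
the classical construction: truncation at the longest minimum-spanning-
tree edge t, distances beyond t replaced by 4t, Gower-centred −½D²,
eigenvectors with positive eigenvalues retained (orthonormal). The Mantel
test permutes rows/columns of one matrix jointly with a one-sided
(1 + exceedances)/(n_perm + 1) p-value. Forward selection uses the
double-stopping rule (global permutation test first; greedy addition by
added R²; stop at candidate p > α or when cumulative adjusted R² passes
the global adjusted R² — the latter cap can be disabled). Site-level RDA
regresses (optionally Hellinger-transformed) site allele frequencies on
predictors; constrained axes are the PCA of the fitted values, R²
adjusted by the Ezekiel correction, axes tested sequentially by
permutation.

## GEA scans and calibration

All scans work on imputed genotype matrices and share the calibration
backbone: chi-square-scale statistics are divided by the median-based
genomic inflation factor λ = median(stat)/median(χ²_df), p-values come
from χ²_df, and candidates are called at Benjamini–Hochberg q < 0.05
(Storey's π₀-scaled variant available).

* **rda_scan** — individual-level RDA of centred genotypes on predictors
  (pRDA partials a conditioning matrix out of both sides). Axis
  significance by permutation of the response rows; the leading
  significant axes' locus loadings are combined into a classical-
  covariance Mahalanobis D² with df = number of retained axes. Candidates
  are assigned the predictor with the largest |correlation| to their
  genotype column.
* **lfmm_ridge_scan** — two-stage latent factor mixed model: (1) factors =
  top-k left singular vectors of the genotype matrix after a
  ridge-regularised projection removing the predictors; (2) per-locus OLS
  on [intercept, predictors, factors], squared t-statistics calibrated
  per predictor at df = 1. With k = 0 the raw p-values are exactly the
  ordinary per-locus regression p-values. The ridge penalty defaults to
  the *large*-penalty regime (100 × the leading singular value squared),
  keeping the factor estimates close to the raw genotype SVD: structure
  that is collinear with the environment then remains in the factors
  rather than being credited to the environment. This is the conservative,
  calibrated regime — under a confounded null with the correct number of
  factors (one per drifted deme minus one), λ stays near 1, while k = 0
  inflates λ well above 1.3. A small penalty recovers fully residualised
  factors (anti-conservative under collinearity) and is available in
  `GeaConfig.ridge`.
* **pca_scan** — per-locus z-scores against the k leading genotype PCs,
  combined by Mahalanobis D² (df = k); this fills the
  differentiation-scan role, and its candidates join the union that
  defines the neutral SNP set.

**Choosing k.** k should match the resolvable latent dimension of the
sampling design: n_pops − 1 for a set of mutually drifted demes, 1 for a
clean two-basin split with panmixia within. When strong clinal selection
acts on many loci, the selected axis itself becomes a leading PC; with
factors taken from the raw SVD side, setting k larger than the structural
dimension absorbs the signal (conservative). This is the fundamental
confounding limit of all structure-corrected GEA, not an implementation
artefact: when the environmental gradient is collinear with the dominant
structure axis (the two-basin coastline case), no method can attribute
the shared variance, and the calibrated behaviour is to credit it to
structure.

## Reference scenarios and problem sizes

`seapop.scenarios` freezes four configurations used by the validation
suite and the reproduction script: the 12-population global scenario
(5000 loci), the duplicate-classification scenario (100 × 2000, 5%
paralogs, 20×), the GEA power scenario (200 × 10,000, 100 clinal loci on
the secondary gradient over two panmictic basins), and the
latent-confounded null (200 × 5000, ten drifted demes, environment
collinear with structure, no true associations). These sizes keep a full
validation run under a minute on one CPU while leaving every statistic's
Monte Carlo error well inside its test tolerance.

## Numerical conventions

Missing genotypes are −1 in an int8 matrix; allele frequencies and
variance components skip missing entries per locus. Bootstrap and
permutation routines take explicit seeds (numpy Generator); identical
seeds give byte-identical outputs. Tie-breaks are deterministic
everywhere (modal imputation → lower genotype code; kinship pruning →
lexicographically larger ID; top-F_ST subset → genomic order). Zero-depth
heterozygotes are excluded from MedRatio; loci monomorphic after
imputation get zero scan statistics rather than NaNs.
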