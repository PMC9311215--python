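# Methods

This note documents the statistical models implemented in `adaptscan`, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical conventions a user relying on the
results should know.

## Data model and filtering

Genotypes are diploid alt-allele dosages (0/1/2) in a dense individuals ×
loci matrix with an explicit missing sentinel; loci are unordered de-novo
GBS markers (rad-tags), so no genomic coordinates or linkage map are
assumed. Downstream statistics always consult the missing mask — nothing
imputes silently; the only imputations are the explicitly requested modal
within-clade imputation before RDA and per-locus mean imputation inside
PCA/SVD operations.

The filter cascade runs in a fixed order: (1) individuals with > 90%
missing calls, (2) loci with > 30% missingness, (3) one SNP per rad-tag
chosen at random under the run seed (SNPs on one ~90 bp tag are effectively
one linkage observation), (4) loci with minor-allele frequency < 0.05
computed over all non-missing calls pooled across populations. Individual
removal precedes the locus filters so that ghost missingness from bad
samples does not inflate locus missingness; MAF is recomputed after
individual removal, so removing an individual can change which loci pass.
A pooled (rather than per-population) MAF matches a single global 5%
cut-off. A separate filter removes any locus with zero calls in at least
one population; its report is broken down by how many populations a locus
was absent from.

## Diversity and differentiation

Per locus and population with *n* called diploids and alt frequency *p*:
Ho = heterozygote proportion, and gene diversity
h = 2p(1−p)·2n/(2n−1) — the unbiased correction uses the allele count 2n.
Ho and Hs are unweighted means over populations; Ht = 2p̄(1−p̄) from the
unweighted mean of population frequencies, deliberately uncorrected so that
two populations fixed for alternate alleles give exactly Hs = 0, Ht = 0.5,
Fst = 1. Multi-locus Fst = (Ht − Hs)/Ht and Fis = 1 − Ho/Hs are ratios of
per-locus averages (not averages of ratios), the convention of standard
hierarchical-F packages. A side effect of correcting Hs but not Ht is a
small negative bias of order −1/(2n−1) in Fst for identical populations;
tests account for it.

Pairwise differentiation is the Weir–Cockerham (1984) θ from the a/b/c
variance components with r = 2; loci monomorphic in the pair are excluded,
and the multi-locus value is Σa/Σ(a+b+c). Negative per-locus estimates are
reported as-is.

Allele-frequency spectra (folded or unfolded, per population, and 2-D per
group pair) use listwise exclusion: only loci fully called in the focal
population(s) contribute. This is exact rather than approximate and is the
right match for data that are nearly complete; it is biased for loci with
population-specific missingness, which the upstream filters remove.

## Directional relative migration

For each population pair a hypothetical pooled population is formed from the
unweighted mean of the pair's allele frequencies, and GST of each member
against the pool (ratio of per-locus averages) is converted to a Wright
island-model migrant estimate Nm = ((1/GST) − 1)/4. Direction convention:
the rate *from i to j* derives from the *recipient's* (j's) differentiation
from the pool — a population receiving many migrants is an admixture and so
both resembles the pool and carries elevated diversity. All entries are
scaled by the matrix maximum (max = 1); rates below a display threshold
(0.05 by default) can be masked. The migration–distance relationship is
summarised by a plain Pearson correlation with two-tailed t p-value over
ordered pairs; matrix entries are not independent, so this is a descriptive
test, kept deliberately simple rather than replaced by a Mantel
permutation.

## Outlier scan

Genotype columns are standardised binomially — centred at 2p̂ and scaled by
√(2p̂(1−p̂)) — with missing entries mean-imputed for the SVD only;
monomorphic loci are excluded from the scan. Each standardised column is
regressed on the k leading left singular vectors; because the axes are
orthonormal the coefficient vector is U_kᵀx, standardised by the residual
standard error into a k-vector of z-scores. The squared Mahalanobis
distance of each locus's z-vector is taken under a minimum-covariance-
determinant robust location/scatter (sample covariance when fewer than 10·k
loci; diagonal fallback if singular). The genomic inflation factor
λ = median(D²)/median(χ²_k) rescales the statistics, and p-values come from
the upper tail of χ²_k only (D² is a squared distance). q-values are
Storey–Tibshirani with the cubic-smoother π₀ estimate, falling back to
π₀ = 1 (exactly Benjamini–Hochberg step-up) below 100 p-values or on a
degenerate fit.

k is chosen as the axis before the largest drop in the scree of
explained-variance proportions — an automated stand-in for visual scree
inspection — with a fallback to k = 1 (and a warning) when the scree is
flat (max drop < 0.01); callers can always override k.

Two properties worth knowing. First, the scan is exactly invariant to
swapping reference/alternate alleles at a locus in its z magnitudes (column
outer products are sign-invariant, so the SVD basis does not move), but the
robust location/scatter re-estimate makes D² only approximately invariant.
Second, the median-based λ calibrates the centre of the null, not its tail:
under strong drift the per-locus drift variance is heterogeneous (Beta
mixing), the z distribution is genuinely heavy-tailed, and the scan reports
many tail outliers even on neutral data. That is the structure-driven
inflation the pipeline is designed to expose, not an implementation
artefact; the null-calibration experiment therefore uses a weakly
structured regime (pooled Fst ≈ 0.04, comparable to the weakest-structure
spatial scale of the motivating study) where the χ² reference is adequate,
and the inflation experiment measures the heavy-tail effect directly.

## Genotype–environment association

Environmental variables live at population resolution and are broadcast to
individuals. Preprocessing centres and scales each variable (sample sd) and
greedily prunes collinearity in a configurable priority order
(latitude-first by default): a variable is kept iff its squared correlation
with every already-kept variable is ≤ 0.7, threshold inclusive. The
pipeline additionally caps predictors at n_populations − 2 so the
constrained model keeps residual degrees of freedom.

RDA is the SVD of the fitted values of the least-squares regression of
centred genotypes on the individual-level design; all axes with positive
constrained eigenvalue are retained (no axis-selection rule is imposed),
and SNP loadings are scaled to unit variance per axis. The per-locus ×
variable score projects the locus's loading vector onto the environmental
direction of each axis:

    score(j, v) = Σ_k loading(j, k) · corr(v, site scores on axis k).

This aggregate projection was chosen because it reduces exactly to the
genotype–environment correlation when one variable is fitted alone, making
the univariate random-variable runs and the multivariate real-variable run
directly comparable. Scores are standardised per variable to z, two-tailed
normal p-values, and per-variable Storey q-values. The full model is tested
by permutation ANOVA: pseudo-F = (SS_fit/df_model)/(SS_res/df_resid) with
individuals' environment rows permuted, p = (1 + #{F_perm ≥ F_obs})/(n_perm
+ 1), 999 permutations by default (minimum attainable p = 0.001). Note the
permutation exchanges individuals, not populations: when populations are
strongly drifted, any population-level variable explains some between-
population variance and the full-model test is liberal — the random-
variable control downstream exists precisely to absorb this.

Missing genotypes are imputed with the modal genotype among called
individuals of the same clade, ties broken toward the lower dosage code;
loci for which a clade has no calls must be removed beforehand.

Random variables are drawn iid standard normal, one value per population
(the resolution of the real variables), 100 by default, and are *not*
collinearity-pruned. "Broad-sense" significance for an anchor variable
(latitude by default) combines, per locus, the q-values of the anchor and
every variable with r² > 0.7 to it, by the geometric mean.

## Combination and classification

The combined q of two methods is √(q_A·q_B), vectorised over loci and over
locus × variable grids. Loci absent from one method's table receive q = 1
there (with a warning) rather than being dropped: the geometric mean then
demands q_A < α² from the other method, preserving the principle that
strong support from one method can outweigh silence from the other. Exact
zeros combine to zero; log-domain paths floor q at the smallest positive
float. The significant set at α always satisfies intersection ⊆ combined ⊆
union.

On the GEA track, a locus × variable pair is significant iff combined
q < 0.05, and a significant locus is **high-confidence** iff it is
significant with fewer than 5 of the 100 random variables, applied per
locus (not per pair). On the outlier-scan track no random-variable control
exists, so significant loci are labelled low-confidence by construction.
Post-hoc checks flag candidates with pooled observed heterozygosity > 0.5
(possible paralog collapse) and remove candidates wholly missing from a
population. When only the in-house method of a track is available the
geometric mean degenerates to that method's q; external per-locus or
per-pair q-tables (e.g. from Bayesian scans, whose internals are out of
scope) plug in through TSV adapters and are combined identically.

## Synthetic data

The generator draws a hierarchical Balding–Nichols model: ancestral
frequency p₀ ~ U(0.05, 0.95) per locus; clade frequency ~ Beta with mean p₀
and variance f_group·p₀(1−p₀); population frequency ~ Beta around the clade
value with f_pop; genotypes Binomial(2, p). The composite neutral
differentiation has closed form E[Fst] ≈ 1 − (1−f_group)(1−f_pop); with G
clades the realised between-clade variance carries a finite-sample factor
(1 − 1/G), so calibration against the closed form uses many clades, while
regime-matching (below) targets the realised Nei Fst directly.

Populations occupy a latitude axis with clades in contiguous bands; real
environmental variables are c·z(latitude) + √(1−c²)·noise at population
level (default collinearity c = 0.8, six variables plus raw latitude and
longitude), so the r² ≤ 0.7 pruning path is exercised. A fraction of loci
(default 2%) is clinal instead of clade-drifted: logit(p_pop) = logit(p₀) ±
effect_b·z(latitude) plus population-level Beta noise. Missingness is
uniform by default (0.2%, the completeness of a stringently filtered GBS
matrix), with a population-biased mode that wipes whole populations at
random loci to exercise the per-population-missing filter. Default design:
3 clades × 3 populations, 5–20 individuals per population, 2 000 loci,
f_group = 0.75/f_pop = 0.15 (strong-structure regime, pooled Fst ≈ 0.7–0.8).

What it does *not* emulate: linkage (loci are independent; one SNP per tag
is the identity operation on simulated data), site-frequency-spectrum shape
of real demographies (Beta-Binomial, not coalescent — a coalescent backend
is a natural extension point), sequencing error, batch effects in
missingness, or spatially autocorrelated environmental noise. Passing the
simulation-based tests therefore demonstrates correctness of the statistics
and the designed behaviour of the controls under the assumed model, not
robustness to everything real GBS data can do.

## Evaluation regimes

Three experiment presets (module `evaluation`) fix the simulation regimes:

- **Null calibration**: 2 clades × 4 populations × 10 individuals, 2 000
  neutral loci, f_group = 0.03/f_pop = 0.01 (pooled Fst ≈ 0.04), k = 2,
  20 replicates — the corrected p-fraction at 0.05 and q < 0.05 discovery
  count measure calibration where the χ² null applies.
- **GEA recovery**: 9 populations of one clade, 10 individuals each, 5 000
  loci with 2% clinal at slope 2, f_pop = 0.15 (pooled Fst ≈ 0.15, the
  weakly structured southern-scale regime — the only regime in which the
  motivating study recovered high-confidence loci), 10 replicates —
  measures ranking recovery of planted loci and the high-confidence set's
  false-discovery proportion against the generator's truth.
- **Structure inflation**: seed-matched pairs at f_group = 0.82 vs 0.02
  (f_pop = 0.18), realising pooled Fst ≈ 0.79 vs ≈ 0.17 — the strong- and
  moderate-structure regimes — comparing outlier-scan discovery counts.

Replicate counts (10–20 seeds) and problem sizes (2 000–5 000 loci) are the
package's own choice of a scale at which the stochastic summaries are
stable to a few percent.

## Numerical conventions

- Missing sentinel −1; all proportions validated into [0, 1].
- Tag thinning, robust covariance, random variables and permutations are
  all seeded; the pipeline fans one global seed into per-stage seeds by
  fixed offsets, so stages are independently reproducible.
- Median of an even count is the mean of the central order statistics
  (numpy convention), used in λ.
- r² pruning compares with a 1e-12 tolerance so an exact 0.7 is kept.
- Degenerate inputs raise with the responsible stage named: constant
  matrices (PCA), monomorphic data (migration, scans), rank-deficient
  designs (RDA), populations with fewer than two called individuals
  (diversity), clades with zero calls at a locus (imputation).

## Known limitations

- The directional-migration asymmetry rests on the diversity contrast of
  recipient admixture; with two populations the pooled frequencies are the
  pair midpoint and the signal is weak.
- The migration–distance Pearson test ignores matrix non-independence.
- Storey's smoother π₀ can be unstable below a few hundred p-values; the
  BH fallback is conservative.
- The per-variable attribution from a multivariate RDA is one documented
  choice among several; per-axis attributions would differ when constrained
  axes mix variables strongly.
- Under strong hierarchical structure the GEA latitude axis is confounded
  with clade drift; the random-variable control demotes such candidates but
  also sacrifices true clinal loci (low power there is expected, and
  matches the motivating study's finding of no high-confidence loci at the
  strongly structured scale).
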