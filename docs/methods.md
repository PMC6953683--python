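# Methods

This note documents the models, estimators and numerical choices behind
`clinepop`, what the synthetic-data generator does and does not emulate, and
the limitations a user should keep in mind.

## The synthetic gradient design

The generator (`clinepop.simdata`) emulates a clinal sampling design: nine
populations along a precipitation gradient (BIO12 from 1,300 to 6,000 mm,
with correlated salinity values and coastal coordinates), genotyped sample
sizes of (5, 12, 3, 2, 13, 8, 9, 3, 13) and phenotyped sizes of
(15, 20, 5, 3, 19, 16, 14, 5, 18). Defaults: 15,000 neutral loci plus 50
clinal ones (a ~0.3% clinal fraction), differentiation F = 0.015 (the weak
neutral-structure regime of the study system), 5% per-call missingness, and
one trait with σ²_B = 0.04, σ²_W = 0.006 (the bill-height scale in mm²).

**Genetics.** Ancestral frequencies are Uniform(0.05, 0.95) so most simulated
loci survive the MAF filter and filter tests stay non-degenerate. Neutral
per-population frequencies follow the Balding–Nichols model,
`p_k ~ Beta(p(1−F)/F, (1−p)(1−F)/F)`, giving E[p_k] = p and
Var[p_k] = F·p(1−p); the realized multilocus Weir–Cockerham θ of a neutral
dataset therefore converges to F, which is the recovery property the
acceptance tests verify. Clinal loci have deterministic frequencies
`logistic(slope·(z − mid))` on the z-scored environment (default slope 3:
frequencies sweep ~0.05→0.95 across the gradient). Clinal loci are placed at
random positions and identified only in the truth record, so scans cannot
exploit positional cues. Genotypes are Binomial(2, p_k) — no inbreeding, no
linkage; loci get synthetic coordinates (200 per scaffold, 1 kb spacing)
purely so windowed operations have something to order by.

**Traits.** `y_ij = μ + β_env z_j + b_j + e_ij` with `b_j ~ N(0, σ²_B)` and
`e_ij ~ N(0, σ²_W)`. The deterministic environmental trend (β_env) and the
random between-population variance (σ²_B) are exposed separately because the
ratio of plastic to genetic divergence along a real gradient is unknowable
from field data; users pick the mixture. Traits are independent of the
genotypes and of each other — the package compares aggregate divergence
(P_ST vs F_ST), it does not simulate QTL architecture.

**What passing tests do not show.** The generator has no linkage
disequilibrium (the LD-pruning code is exercised on duplicated/correlated
loci constructed in tests), no genotyping-error model beyond missingness, no
spatial autocorrelation beyond the cline itself, and no plasticity; real
ddRAD data violate all four. Recovery results on simulated data bound the
statistical behavior of the estimators, not the sequencing pipeline upstream.

**Randomness.** One root seed; every component (frequencies, genotypes,
traits, each bootstrap/permutation) draws from its own `SeedSequence` child
stream keyed by a stable CRC of the component name, so outputs are
byte-identical across runs and insensitive to draw-count changes elsewhere.

## SNP QC

Five consecutive steps, each on the survivors of the previous one (order
changes the per-step counts, so it is fixed): (1) locus call rate ≥ 80% of
individuals *and* coverage in ≥ 80% of locations, a location covering a locus
when ≥ 50% of its members are called — the coverage sub-rule is exposed in
config because "genotyped at a location" is not otherwise well defined;
(2) observed heterozygosity ≤ 0.5 (paralog signal); (3) Hardy–Weinberg exact
test per population at α = 0.01, a locus failing when rejected in > 60% of
populations with ≥ 5 called individuals; (4) missingness ≤ 30% — note this is
per-locus and is largely redundant after step 1 (a >30%-missing locus has
<70% call rate), which is visible in reports as a zero-removal step;
(5) global MAF ≥ 5%, minor allele defined across all populations.

The HWE test is the conditional exact test (enumeration of the heterozygote
count given allele counts, two-sided by summing configurations no more
probable than observed). With 2–13 individuals per population the chi-square
approximation is useless; the exact test is valid at any n. Computed in log
space with an LRU cache since the same genotype counts recur across loci.

LD pruning uses the composite genotypic correlation (dosage Pearson r²,
pairwise-complete) — unphased dosages cannot give gametic r². Within a
sliding 50-locus window in (scaffold, position) order, any pair exceeding the
threshold (default r² > 0.5) loses its lower-MAF member; ties keep the
earlier locus. Deterministic given input order.

## Weir–Cockerham F_ST

Per locus, the a (among-population), b (among-individual-within) and c
(within-individual) components are computed from per-population sample sizes,
allele frequencies and observed heterozygote proportions (heterozygote =
dosage 1), with the unequal-sample-size weights (n̄, n_c). Multilocus and
pairwise θ are ratios of summed components; negative values are reported as
computed (truncation would bias the ratio of sums). Monomorphic loci and loci
seen in < 2 populations get undefined components and drop out of the sums.

Pairwise estimates are computed on each pair's samples only. Uncertainty is a
nonparametric bootstrap over loci (default 10,000 replicates), implemented
with multinomial locus weights in chunks so memory stays bounded; the CI is
the percentile interval and the p-value the bootstrap tail at zero (one-sided
against θ > 0; a two-sided option doubles the smaller tail). At very small
locus counts a percentile interval can exclude the point estimate; the
estimate object flags this rather than hiding it.

Genotype PCA centers loci at 2p̂, imputes missing calls to the locus mean,
and takes the SVD; variance fractions are relative to the total (centered)
variance. Mean imputation shrinks structure slightly — acceptable at the ≤5%
missingness this pipeline targets.

## Outlier and association scans

**Trimmed chi-square F_ST scan.** Per-locus *uncorrected* F_ST is defined as
s² / (p̄q̄ + s²/r) — the infinite-sample limit of the WC ratio, which is
non-negative and so amenable to a scaled chi-square model. Loci with expected
heterozygosity < 0.1 are excluded from the fit (their F_ST estimates are
erratic) but still receive p-values. After trimming 5% from each tail, the
(mean, df) of the scaled chi-square are fitted by maximum likelihood on the
doubly-truncated density (Nelder–Mead on log-parameters; truncation bounds at
the trim cut values; df initialized at r − 1). Right-tail p-values from the
fitted envelope apply to all loci; Benjamini–Hochberg q < 0.05 flags
outliers. BH is used wherever "FDR" appears in this package: it is
conservative and dependency-free compared with smoothed q-value estimators.
The reported `mean_fst` is the ratio-of-sums of *corrected* components over
the fit set (the interpretable neutral mean); `mean_fst_nocorr` is the fitted
location of the uncorrected distribution, which sits higher because sampling
noise inflates s² at small n.

**RDA scan.** Dosages are mean-imputed, centered and scaled to unit variance
per locus; predictors z-scored; the constrained axes are the principal axes
of the fitted values of the multivariate regression of dosages on predictors.
Locus scores are loadings scaled by the axis singular value. A locus is an
outlier when its score on any of the first three axes (fewer if there are
fewer predictors) lies > 3 SD from that axis's mean; the SD is the plain
empirical SD including would-be outliers (no iterative trimming). Unit
variance matters: with centered-only dosages the loading tails vary with MAF
and the 3-SD rule over-flags (~1.1% of null loci vs ~0.5% scaled, at
undiminished power on planted clines). Each outlier is assigned the predictor
with the largest |Pearson r| against its population allele frequencies.

**Latent-factor association scan.** A least-squares stand-in for latent-
factor mixed models (the MCMC machinery is out of scope; outputs are labeled
as this scan, never as LFMM). Per locus: OLS of mean-imputed dosage on the
predictor plus K latent factors (default K = 1), two-sided slope p, BH q. Two
constructions matter and both are deliberate:

1. *Factors are estimated net of the predictor* — the top-K principal axes of
   the dosage matrix **after** the predictor is regressed out. Naive genotype
   PCs fail catastrophically here: with a strong cline, PC1 *is* the cline
   (r ≈ 0.98 with the environment in simulation), and conditioning on it
   removes the entire signal being tested.
2. *Genomic-control calibration* (on by default): squared t-statistics are
   rescaled by the genomic inflation factor (median rule against the χ²₁
   median) before conversion to p-values. With few populations, drift aligned
   with the predictor cannot be absorbed by factors that are orthogonal to it,
   and the raw test is inflated genome-wide (~1.5% false flags at q < 0.05 in
   a drift-null simulation; ~0.05% after calibration). Under a predictor
   independent of the genotypes the GIF is ≈ 1 and p-values stay uniform.

With K = 0 and calibration off, the scan reduces exactly to ordinary
per-locus regression.

**Gene windows.** Candidate SNPs are matched to every gene whose GFF3
interval (1-based inclusive) intersects ±25 kb; distance 0 inside a gene,
otherwise the gap to the nearest edge, direction naming the side (upstream =
lower coordinate; strand is ignored because the question is linkage, not
regulation). Allele-frequency summaries exclude populations under 5 genotyped
individuals by default (a strict "> 5" variant is a flag, since either
reading of "more than five" is defensible) and can average linked SNPs per
gene.

## P_ST–F_ST

σ²_B and σ²_W come from REML of the one-way random-intercept model. For this
model the REML criterion profiles exactly to one dimension in
λ = σ²_B/σ²_W: with group sizes n_j, means ȳ_j, within-group sum of squares
SSW, and d_j = 1 + λn_j,

    μ̂(λ)  = Σ w_j ȳ_j / Σ w_j,            w_j = n_j / d_j
    Q(λ)  = SSW + Σ n_j (ȳ_j − μ̂)² / d_j
    −2l_R ∝ Σ log d_j + log Σ w_j + (N−1) log Q

minimized by bounded scalar search on log λ (λ ∈ [0, 1e8], boundary λ = 0
checked separately, σ̂²_W = Q/(N−1)). This is exact — it matches an
independent grid-plus-golden-section maximization of the same criterion to
1e−6 and statsmodels' MixedLM to its tolerance — and fast enough (~1 ms) for
the 1,000-replicate parametric bootstrap and for coverage experiments with
tens of thousands of refits. With zero within-group variance the criterion is
unbounded along σ²_W → 0; the bounded search then returns σ²_W ≈ 0 with a
large σ²_B and the decomposition is flagged degenerate. Populations
contributing a single observation are kept (they inform the mean) with a
warning.

The parametric bootstrap simulates the fitted model on the observed design
and refits; CIs are percentile intervals. P_ST confidence bands transform the
*paired* bootstrap draws of (σ²_B, σ²_W) through the P_ST formula — the
coherent percentile construction; combining the marginal CI endpoints (low
σ²_B with high σ²_W for the lower band) is available as `ci_method=
"endpoints"` for sensitivity analysis but ignores the positive dependence of
the two estimates and is conservative.

The c/h² grid is 100 evenly spaced values 0.02, 0.04, …, 2.00 — zero is
excluded because P_ST is identically 0 there. The critical c/h² is the
smallest grid value whose lower P_ST bound exceeds the F_ST reference,
infinite if none does. The reference defaults, in the pipeline, to the global
multilocus θ of the outlier-excluded locus set, so the comparison is against
*neutral* differentiation. Body mass is excluded from P_ST by default (mass
divergence conflates size and condition); configurable. h² and c are never
estimated — the sweep exists precisely because they are not estimable from
field data.

## Distances and MMRR

Great-circle distances use the haversine formula (km). Coastal distance
projects each site onto an ordered coastline polyline (per-segment projection
in a local equirectangular frame — accurate at the tens-of-km scale) and
takes absolute differences of along-path arclength; a site farther than the
snap tolerance (default 100 km) from the polyline is an error, not a silent
snap. Environmental distance is |Δvalue|.

MMRR z-scores the lower triangle of every matrix (diagonal excluded — the
structural zeros would distort the scaling), fits OLS, and assesses
significance by jointly permuting rows and columns of the response matrix
(node permutation), the appropriate exchangeability unit for distance
matrices. p-values use the add-one rule (1 + #{perm ≥ obs})/(1 + n_perm), so
the minimum attainable p is 1/(n_perm+1) and the test is slightly
conservative, with null rejection ≈ 4.5% at nominal 5% — within the
calibration band the acceptance tests check. Collinear or constant predictor
matrices are rejected up front. The default IBD/IBE model uses the coastal
(or great-circle, if no coastline is supplied) and environmental matrices as
predictors.

## Morphometrics

Trait–environment fits compare degree-1 and degree-2 polynomials by
small-sample-corrected AIC (the quadratic needs ≥ 4 points), reporting the
model F-test p and R². AICc is the selection rule because bill-type traits
plausibly saturate at gradient extremes while others stay linear, and no
fixed rule fits both. Allometric correction takes residuals of trait ~ mass
(OLS), which are mean-zero and mass-orthogonal by construction. Trait PCA
operates on the correlation matrix (traits mix mm and g), drops incomplete
cases with a reported count, and fixes signs so each component's largest-
magnitude loading is positive — loadings are then reproducible across
platforms.

## Pipeline

Stages run in dependency order with per-stage status; a failure marks
dependents skipped and the process exits nonzero. The consolidated JSON
report contains the filter table, envelope fit, outlier counts and overlaps,
neutral global/pairwise θ, PCA fractions, per-trait variance components and
critical c/h², MMRR statistics, and the config hash (output paths excluded
from the hash so identical analyses hash identically wherever they land).
Same config + seed ⇒ byte-identical report. Within the pipeline, the outlier
set excluded before neutral F_ST is the trimmed-chi-square scan's flags — a
single-scan approximation to a union of scans, chosen because it is the one
F_ST-based scan in scope.

## Problem sizes

Default statistical settings follow the scale of the study design: 10,000
bootstrap replicates for pairwise F_ST and 10,000 MMRR permutations at the
function level. The packaged acceptance run uses 1,000 bootstrap replicates
and 9,999 permutations with 15,050 simulated loci — sizes chosen so the whole
chain, including the per-trait 1,000-replicate parametric bootstrap, completes
in a few minutes on a single core while leaving Monte-Carlo error well below
the effect sizes of interest. Calibration experiments in the test suite use
2,000–5,000 loci and 20–500 replicates on the same reasoning.

## Known limitations

- The latent-factor scan is least-squares with GIF calibration, not a joint
  MCMC estimator; at K > 1 with highly confounded structure its power/FDR
  trade-off is untested.
- The envelope fit assumes a single neutral F_ST regime; hierarchical
  structure (e.g., two regional clusters) would violate the scaled
  chi-square and inflate flags.
- Coastal distance assumes the polyline is sampled finely relative to
  between-site spacing; a coarse polyline biases arclengths downward.
- P_ST inference inherits every caveat of P_ST itself: plasticity and
  non-additive variance load onto σ²_B, and only a common-garden Q_ST could
  separate them. The critical-c/h² sweep quantifies robustness to this,
  it does not remove it.
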