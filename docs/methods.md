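# Methods

This note documents the models, the synthetic-data generators, the numerical
choices, and the known limitations of the `sexdiet` pipeline. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Negative-binomial differential expression

Counts are modelled as NB(μ, φ) with Var = μ + φμ² and a log link. Library
offsets are ln(N_i f_i) with f_i the TMM factors: the reference library is
the one whose 75th-percentile count fraction is closest to the mean of those
fractions; per-library M (log2 ratio) and A (log2 abundance) values are
computed over genes nonzero in both libraries, doubly trimmed (30% per side
on M, 5% on A by rank), and combined as a precision-weighted mean with
delta-method weights; factors are rescaled to geometric mean one. Filtering
keeps genes with CPM above a threshold (default 1) in at least `min_samples`
libraries (default 3, the cell size of the 2×2×3 design).

**Dispersions.** The common dispersion maximises the summed Cox–Reid
adjusted profile likelihood (APL) over genes, APL_g(φ) = ℓ_g(β̂(φ)) −
½ log det(XᵀWX), found by bounded scalar optimisation of log₁₀φ on [−8, 1].
Gene-wise ("tagwise") estimates maximise APL_g + (prior_df / residual_df) ×
mean-over-genes APL on a log-spaced grid of 2^±6 around the common value,
then are clipped between the raw per-gene maximiser and the common value so
shrinkage can only move estimates toward the common dispersion. prior_df
defaults to 10; prior_df = ∞ collapses all genes to the common value. TMM
factors and the common dispersion agree with the Bioconductor reference
implementation on simulated data (cross-checked in the test suite).

**GLM fitting.** All genes share one design matrix, so IRLS is vectorised
across genes: per-iteration weighted normal equations are solved as a batch;
step-halving (up to 12 halvings per iteration) guards against likelihood
decreases; convergence is a relative log-likelihood change < 1e-8 within 50
iterations. The linear predictor is capped at ±50; a fit touching the cap is
flagged as a boundary case (e.g. an all-zero treatment cell) and excluded
from fold-change reporting. φ ≤ 1e-8 switches to the Poisson likelihood.

**Testing.** Each design term is tested by a likelihood-ratio test against
the design with that column removed, with dispersions held fixed;
LR = 2Δℓ clipped at 0, p from χ² with df equal to the rank difference.
Factor coding is deviation (±½) by default: the diet column then measures
the across-sex *average* carb→protein effect and the interaction column the
male-minus-female difference in diet response. Treatment coding
(reference female/carbohydrate) is available; note that drop-column
main-effect tests under the two codings test *different hypotheses*
(average effect vs reference-sex effect) — LR values agree only for nested
pairs spanning the same column spaces, which the suite verifies. Deviation
coding was chosen because the three headline categories (concordant D,
opposing D×S, sex-biased D+D×S) are defined in terms of the average effect
and the sex difference; under treatment coding a gene responding only in
males would be labelled "opposing", which contradicts the category's meaning.

**FDR.** Benjamini–Hochberg step-up adjustment, implemented directly and
tested against independent oracles. The working threshold is q < 0.05
(0.10 supported via `alpha`).

**Per-sex fold changes.** Diet-only NB GLMs are refit separately within each
sex's libraries, with normalization factors and dispersions recomputed in the
subset (the subset has its own composition); log2 fold changes are oriented
carbohydrate → protein; per-sex BH q-values produce the four-way flag
(female_only / male_only / both / neither).

**Sex-limited genes.** Detection is raw count ≥ 1 in at least one library
(CPM-based detection available). Genes detected in one sex only are analysed
within that sex's libraries with a diet-only model; BH is applied within the
sex-limited set only, since that is the family of hypotheses actually tested.

### Known limitation: far-tail liberality of the LRT

On all-null data the diet-term p-values are uniform in bulk (KS < 0.05), but
the extreme tail is inflated: genes whose chance diet-like pattern is
absorbed by the full model get a deflated tagwise dispersion and hence an
inflated LR. At 2000 genes × 3 replicates, the probability that BH at
q < 0.05 makes at least one (false) discovery is ~0.3 rather than the
nominal ≤ 0.05. This is a property of the method, not the implementation:
edgeR's `glmLRT` with `prior.df = 10` reproduces it on the same simulated
datasets (the quasi-likelihood F-test that addresses it is out of scope
here). Discovery *sets* at realistic effect sizes are essentially unaffected
(planted-category sensitivity and specificity are tested directly), but
single-gene significance near the BH boundary should be read with this in
mind.

## Classification

Shared genes are placed in the 8 cells of the (S, D, D×S) significance
pattern; the cells partition the shared set. Headline categories: D =
diet significant and interaction not; D×S = interaction significant and diet
not; D+D×S = both. Genes whose GLM did not converge are "untestable" and
excluded from category totals. Summaries report each category's share of the
diet-responsive total.

## Concordance and overlap

Cross-sex concordance of a gene set is the Pearson correlation (Spearman
optional) of male vs female carb→protein log2 fold changes over the set; all
genes of a set enter, not only per-sex-significant ones. The non-metabolic
baseline is the parent term's annotation minus the union of the excluded
branch (the excluded term plus all hierarchy descendants). The bootstrap
contrast resamples genes with replacement independently within target and
baseline (B ≥ 100, seeded), reports 95% percentile CIs and a two-sided
empirical p for the correlation difference floored at 1/B; zero-variance
resamples are redrawn and counted.

Overlap of two gene lists requires an explicit universe; the one-sided
over-enrichment p is the hypergeometric upper tail, reported with expected
overlap n_a·n_b/N, percent excess, and the sample odds ratio (Haldane 0.5
correction only on zero cells). Classification correspondence is Pearson χ²
on the R×C table without continuity correction (expected cells < 5 are
logged). Generic gene-set enrichment runs the overlap test against every
collection member with BH adjustment.

## Fitness landscapes

Fitness is Z-transformed within sex (the sexes' assays are on different
scales: egg counts vs paternity share). Gradients follow the standard
selection-analysis convention w = α + βᵀz + ½ zᵀγz: β from the linear-only
OLS model, γ from the full quadratic model with γ_PP = 2·coef(P²), γ_PC =
coef(P·C). Classical OLS standard errors accompany both. Surfaces are
exported as prediction grids; the analytic stationary point −γ⁻¹β is exposed
but is numerically unstable when curvature is weakly identified — for
"optimal diet" summaries prefer the argmax over the observed intake range or
over the design rails.

**Parametric bootstrap sex test.** Shared model: one quadratic surface and
one residual variance for both sexes. Sex-specific model: separate surfaces
and variances. PB-stat = 2(ℓ_sexspecific − ℓ_shared) with Gaussian profile
likelihoods at MLE variances. Null replicates are simulated from the fitted
shared model with Gaussian residuals, **re-standardized per sex**, and both
models refit (vectorised over replicates); p = (1 + #{PB* ≥ PB_obs})/(B+1).
The re-standardization step is essential: the per-sex Z-transformation makes
each sex's surface amplitude depend on its sample SD, and a null that omits
the step treats that sampling artifact as a real sex difference (type-I
error ~0.6 in simulation). With the step included the test is approximately
calibrated (about 0.06–0.09 at nominal 0.05 across simulation batches at the
default design) — a mild residual liberality, concentrated in datasets with
extreme between-sex SD ratios, that users should weigh for p-values near the
threshold. The statistic's construction (likelihood-ratio form, Gaussian
working likelihood on Z-scaled fitness) is this package's design choice; the
binomial male assay is handled only through the Z scale.

## Synthetic data

`simulate_counts` draws NB counts by a gamma–Poisson mixture with log-normal
library sizes (default mean 1.8e7, CV 0.1 — deep bulk libraries), gene
abundances uniform on log2 CPM (0.5, 10), and constant dispersion 0.1 by
default (a gamma distribution over genes is available). Planted categories
on log2 scale with effect size e (default 1.5): D = (e, e) in
(female, male); D×S = (e, −e); D+D×S = (2e, e/2) with the dominant sex
female for 80% of genes — a large response in one sex and a small
same-direction response in the other, making both the average-diet and the
interaction contrast of magnitude ≥ e. Sex-limited genes have true mean zero
in the silent sex (so detection recovers them exactly); 30% are
diet-responsive in the directions the biology predicts (female-limited up on
protein, male-limited up on carbohydrate). 80% of genes carry a sex effect
(log2 magnitude 1.0, random sign). Default planted sizes 600/50/120 in 9000
genes echo the magnitudes of the motivating study.

`simulate_landscape` places each observation on one of the eight P:C rails
(4:1 … 1:32) with log-normal total intake (CV 0.35), and quadratic fitness
with Gaussian noise (SD 0.5). Default surfaces put the female optimum on the
2:1 rail and the male optimum on 1:4 with γ = −2·I, which makes the
quadratic surface explain roughly half the fitness variance — inside the
range implied by real landscape assays (strong female, moderate male signal).
Stronger curvature produces implausible catastrophic fitness excursions at
high intakes whose leverage also breaks the Gaussian bootstrap null.
`n_per_sex` is the total number of observations per sex (default 120),
spread evenly over the rails.

What the generators do *not* emulate: gene–gene correlation, GC/length
biases, batch effects, isoform structure, read-level error, the pooling of
12 flies per library, vial effects in the fitness assay, or a mean–dispersion
trend. Passing tests therefore demonstrate correctness of the statistical
machinery under the stated generative model, not robustness to every
real-data pathology.

## Numerical and design details

- Deterministic seeding throughout; identical configuration ⇒ byte-identical
  output TSVs.
- TSV is the canonical tabular format (gene ids may contain commas); GMT for
  gene sets; two-column parent→child TSV for hierarchies; YAML config for
  the CLI.
- Degenerate inputs raise typed errors rather than coercing: zero-count
  libraries, constant fitness within a sex, rank-deficient designs (all
  observations on one rail), sets outside their stated universe, p-values
  outside [0, 1].
- The CLI (`sexdiet simulate|de|classify|concordance|overlap|landscape|all`)
  is a thin layer over the library; `--threads` is accepted for interface
  stability but results never depend on it.
- Problem sizes in the test suite (2000-gene null batches, one 9000-gene
  planted run, 200–300 simulation replicates for coverage/calibration,
  B = 199 bootstrap replicates) were chosen to give stable Monte-Carlo
  estimates at the study's own design sizes.
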