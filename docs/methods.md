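# Methods

`dogclock` reimplements, end to end and against synthetic data, an analysis
of epigenetic aging in companion dogs: per-feature age-association models
for chromatin-accessibility peaks (ATAC) and CpG methylation sites (RRBS),
chromatin-state enrichment among direction-classified peaks, and elastic-net
age clocks evaluated by a manual leave-one-out loop. This note records the
models, the parameters that matter, and the design choices made where the
procedure was genuinely open.

## The synthetic cohort

The raw study data live in public sequencing archives and are deliberately
not consumed here; instead `dogclock.simulate` generates the
post-quantification inputs with known ground truth, so every downstream
stage is testable for recovery and calibration.

**Cohort.** `n_samples` dogs (default 71) with integer ages uniform on
`age_range` (default 1–16 years, matching owner-reported whole-year
precision; the true age distribution is unknown beyond its range, so
uniform is an explicit assumption exposed in the config). Sex is balanced
Bernoulli; each dog belongs to one of 30 synthetic breeds whose mean adult
weights are log-uniform on 4–60 kg. Weight categories use configurable
thresholds (small < 10 kg ≤ medium < 25 kg ≤ large) — the category bounds
are a convention, stored with the run. Exercise has three levels whose
probabilities shift away from "vigorous" linearly in age on the log-odds
scale. Cell-type proportions are "percent of parent gate" values — each
type independently in [0, 100], *not* a simplex — mirroring flow-cytometry
gating output. Two designated memory-T-cell gates (`cell.CD8`, `cell.DN`)
gain `celltype_age_slope` percentage points per year of age (default 1.0,
noise SD 5: a clearly detectable but not overwhelming trend at n = 71); all
other types are age-independent.

**Methylation.** Per site, read depth is negative binomial with mean
`mean_depth_meth` (default 30) and a per-feature dispersion drawn from a
log-normal (one realistic overdispersion knob). Methylated counts are
binomial with logit(p) = baseline + slope × age. Baselines are N(0, 1.2) on
the logit scale, so most sites have intermediate median fractions; a
configurable minority (`frac_extreme_meth`, default 8%) is constitutively
hyper-/hypo-methylated (logit ±4) to exercise the 0.1–0.9 median filter.
Exactly `round(frac_age_assoc_meth · n_cpg_sites)` sites carry slopes drawn
N(0, `meth_age_slope_sd`); the defaults — 5% of sites, SD 0.15 logit/yr —
are the signal-recovery study condition.

**Accessibility.** Counts are negative binomial with
log E[count] = baseline + slope × age + library offset. Library offsets are
rescaled to span exactly [−log 1.5, log 1.5], so library sizes always vary
≥ 2-fold. 5% of peaks (default) carry slopes N(0, 0.05 log/yr). Planted
structure for the filters: a configurable fraction of low-coverage peaks
(median ≤ 20), decoy features on `chrM` and `scaffold_*` contigs, and one
pair of peaks with summits 400 bp apart to exercise summit merging.

**Annotation.** A toy genome (5 chromosomes sized to hold the peak
catalogue) is tiled end-to-end by non-overlapping chromatin-state intervals
labelled "1"–"13" (all labels guaranteed present) and sprinkled with
uniquely named genes of 1–10 kb.

**What the generator does not emulate.** Breed genetic structure, read-level
artifacts (mapping bias, bisulfite conversion failure), spatial correlation
between nearby features, compositional coupling between cell proportions,
and any real relationship between chromatin state and age effects. Passing
tests therefore certify the *pipeline's* statistical behaviour (calibration,
recovery, exactness), not biological conclusions about real dogs.

## Feature processing

ATAC: peaks whose summits lie strictly closer than 500 bp chain into single
features (single-linkage, per chromosome; count rows are summed). The merged
summit is the midpoint of the member-summit range — this choice keeps merged
summits at least the threshold apart, making the operation idempotent,
whereas a span midpoint can drift within the threshold of a neighbour.
Features then need an across-sample median count strictly greater than 20
and a canonical contig (exclusion regex configurable; default catches
chrM/MT, scaffold, chrUn, \*\_random, \*\_alt). Counts become RPKM —
count / (width/10³) / (library/10⁶) — with library size the per-sample total
of the input count matrix (the only notion of "total mapped reads" available
post-quantification), then log2(x + 1), then per-feature standardization
(mean 0, SD 1 with the n−1 denominator). Pseudocount and log base are
config-visible conventions.

Methylation: per-site fraction methylated/(methylated+unmethylated), with
depth-0 cells missing (never 0). Sites need mean depth ≥ 5 (inclusive),
across-sample median fraction within [0.1, 0.9] (inclusive), and a canonical
contig. Surviving missing cells are imputed with the site's across-sample
mean fraction — the elastic net needs complete data and the fraction of such
cells is small at the default depth. Fractions are standardized directly; no
log or M-value transform.

Zero-variance columns are centred to all-zeros and flagged rather than
dropped, so downstream shapes stay aligned with the catalogue.

## Age-association models

Each processed feature is fit by OLS:

    feature ~ age + weight + sex + exercise + cell.CD8 + cell.DN

with breed mean weight continuous, sex a single indicator, exercise
dummy-coded (unordered; the survey levels carry no stated order) and the two
age-correlated cell proportions as covariates. One shared design is solved
once via its pseudoinverse and applied to every feature column — numerically
identical to per-feature OLS and hundreds of times faster. p-values use the
t distribution with n − rank(X) degrees of freedom; zero-variance features
report β = 0, p = 1. Adjustment is plain Benjamini–Hochberg step-up by
default (the conservative Benjamini–Yekutieli variant is a flag); features
with q < 0.05 are classified increasing/decreasing by the sign of the age
coefficient. The metadata screen regresses each cell proportion on age and
runs one-way ANOVA of age across the levels of each categorical variable,
with BH across the whole screen.

## Annotation and enrichment

A feature spanning several chromatin-state intervals is assigned the state
covering it by the most bases (ties to the leftmost interval; a
midpoint-containment mode is available). CpG sites are width-1 intervals and
reduce to containment. Any additional interval track (CpG islands,
promoters) can be annotated by the same rule. Per state, a 2×2 table of
(in-state vs not) × (increasing vs decreasing) is tested with a two-sided
Fisher exact test implemented by hypergeometric-support summation: the
p-value sums the probabilities of all same-margin tables whose probability
does not exceed the observed one, with a 1e-7 relative guard against
floating-point ties. The odds ratio is (ad)/(bc), with a 0.5 continuity
correction only when a cell is zero; odds ratio > 1 means enrichment among
age-increasing peaks. Nearest genes use strand-agnostic gene-body distance
(0 on overlap, else interval gap), ties to the smaller gene start then the
lexicographically smaller name.

## The elastic-net clock

The solver minimizes the glmnet-form objective
(1/2N)·RSS + λ[(1−α)/2‖β‖₂² + α‖β‖₁] by cyclic coordinate descent with
soft-thresholding, organised as: sequential strong-rule screening (reusing
the previous λ's gradient), active-set iteration, then a full
Karush–Kuhn–Tucker check that repairs any screening miss. Every returned
fit is KKT-certified at `tol · sd(y)` with tol = 1e-7. The λ path is
log-spaced over `n_lambda` = 100 points from λ_max = max_j |x_jᵀ(y−ȳ)|/(Nα)
down to eps·λ_max (eps 1e-3 when N > p, else 1e-2). Inner cross-validation
fits the path per fold with warm starts at a loose tolerance (1e-4·sd(y)) in
single precision — those fits only trace the CV error curve, whose argmin is
insensitive at that scale (verified against tight double-precision fits) —
and λ\* takes the minimum mean CV MSE with ties to the larger λ (a
one-standard-error rule is available). α = 0 makes λ_max undefined; a capped
value (α floor 1e-3) stands in for path construction.

The clock design concatenates the epigenetic feature block(s) with the
"meta features": all cell-type proportions and breed weight category coded
ordinally 1/2/3, standardized like any column and penalized equally
(no exemption). Sex is not offered to the clock. The outer loop leaves out
one dog at a time: inner 10-fold CV (fold assignment derived
deterministically from the run seed and the fold index) picks λ, the final
model is refit tight along the path prefix, and the held-out dog is
predicted. By default standardization happens once on the full cohort
before the loop — replicating the published processing order, which leaks
distributional information — while `scaling="fold"` restandardizes from
training-fold statistics only and is the honest variant used for null
calibration.

## Evaluation

Accuracy is reported in two conventions. The regression convention — R² and
adjusted R² (one predictor df) from OLS of predicted on observed age — is
what the headline clock numbers use; RMSE is computed on the raw
prediction errors (the regression-residual RMSE is also emitted). The skill
convention — R² = 1 − SSE/SST on the raw pairs, with the analogous
adjustment — measures out-of-sample predictive skill. The distinction
matters for null calibration: when a leave-one-out fold selects the null
model, its held-out prediction is the training mean (Σy − y_i)/(N−1), an
*exact anti-correlate* of the held-out age, so the sign-agnostic regression
R² can be large on skill-free predictions as a pure artifact of manual
LOOCV. The skill R² is at or below zero in expectation for such predictions
and is therefore the measure used by the null-calibration check; both are
reported everywhere.

"Residual age" is the residual of the predicted-versus-observed OLS line
(predicted as response; the swapped orientation is a flag), regressed on
breed mean weight to ask whether bigger breeds age faster; residual-age
vectors from different clocks are compared by Pearson correlation.
Stratified evaluation repeats the scoring within small/medium/large breed
categories, skipping strata with fewer than 3 dogs.

## Orchestration and determinism

`run_pipeline` executes simulate → process → associate → annotate →
clock ×{atac, dnam, combined} → evaluate into one directory; each output
carries the package version and a hash of the fully resolved configuration
(excluding the output path), and the resolved config is written alongside.
One integer seeds everything; two runs with the same configuration are
byte-identical. Stage outputs are plain text (TSV/BED/JSON); per-fold
models serialize sparsely (selected coefficients only) as JSON lines.
Stages always recompute rather than reusing cached outputs — determinism
makes caching a pure optimization, and recomputation keeps a run directory
self-consistent with its config.

Enrichment is skipped with a logged message (not a failure) when no
direction-classified peaks exist in both directions, which is the expected
outcome on null cohorts.

## Problem sizes

Defaults were chosen so the full synthetic study — 71 dogs, 2000 CpG sites
and 2000 peaks plus decoys, three LOOCV clocks — runs in a few minutes on
one core, and the calibration studies (50 replicate null cohorts with
fold-wise-scaled clocks; 20 replicate enrichment simulations) complete
within a routine test run. Counts shown in the README's worked example come
from these sizes.

## Known limitations

The per-feature models assume independent features and homoscedastic
Gaussian noise on the processed scale; counts are actually overdispersed
and heteroscedastic, which the null-calibration test shows is adequately
absorbed at the default depths. Breed is not modelled as a random effect.
The paper-order (global) standardization leaks the held-out sample's
contribution to feature means and variances into training; it is the
default because the goal is replication, and the fold-wise mode quantifies
the honest alternative. Merged peaks keep the first member's name, so a
ground-truth id can disappear into a merged feature; recovery statistics
drop such ids (rare at default spacing).
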