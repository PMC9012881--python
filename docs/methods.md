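# Methods

This note documents the models, algorithms, defaults, and design choices in
`nfomics`, and what the synthetic-data tests do and do not establish about
real data.

## Study design being emulated

A longitudinal cohort of hospitalized chemotherapy patients. Serum and
stool are collected on a twice-weekly grid (Mon/Thu offsets, days 0..28)
with a ±1-day scheduling window, simulated as an independent uniform
{−1, 0, +1} shift per collection, clipped to the follow-up window. Each
patient either develops neutropenic fever on an integer day drawn uniformly
from −3..20 relative to chemotherapy start, or never does; the never-febrile
count is `round(frac_never_nf · n_patients)` (default 3/36, reproducing the
source cohort's shape at its size). A serum sample collected **on** the
onset day is labeled post-NF (fever is present that day); samples from
never-febrile patients are labeled pre-NF. Both conventions are declared
choices — the underlying study reports neither. A per-patient bloodstream
infection flag (default prevalence 17/36) supports the first sensitivity
analysis.

## Synthetic data generator

**Metabolome.** Concentrations are log-normal (`base_log_mean` 2.0,
`base_log_sd` 1.0 on the natural-log scale). Signature metabolites get a
post-NF shift of `shift_log2fc · ln 2` added to their log-mean. Values
below each metabolite's empirical `detection_floor_quantile` (default 0.10)
are censored to missing, emulating a detection floor. No distributional
information about real serum concentrations is available, so these are
declared assumptions, not estimates; the defaults produce Welch effect
sizes of roughly one standard deviation per signature metabolite at
`shift_log2fc = 1.5`.

**Microbiome.** Per-sample genus log-abundances are independent normals
with genus-specific means (default: a fixed geometric decay spanning ~2
decades, so a few genera dominate as in stool communities) and common
log-sd 1.0; exponentiating and closing gives the composition. Each genus is
split across `asv_per_genus` ASVs with Dirichlet weights drawn once per
cohort, and ASV counts are multinomial at a depth drawn uniformly from
`depth_range` (default 5 000-50 000, matching the order of magnitude of
real 16S libraries).

**Genus-metabolite links.** The generator uses the same model the analysis
fits: for each linked metabolite, the paired serum sample's log
concentration is augmented by `z·b + N(0, noise_sd)` where `z` is the true
log relative abundance vector of the stool sample chosen by the *same*
nearest-preceding-within-3-days rule the integration stage uses, and `b`
sums to zero exactly (default pattern +1, −0.5, −0.5; `noise_sd` 0.5). The
detection floor is applied after this augmentation in the end-to-end
generator, so the censoring fraction refers to final values.

**What passing tests show.** Recovery benchmarks demonstrate correctness of
the machinery under the generator's assumptions: independent log-normal
features, links that truly follow the log-contrast form, and missingness
from a pure detection floor. Real data add batch effects, correlated
metabolites, compositional interactions, covariate-driven missingness, and
repeated-measures correlation within patients, none of which the generator
emulates — recovery rates here are upper bounds, not forecasts.

## Metabolome preprocessing

Metabolites detected in fewer than half of the serum samples are dropped
(exactly half is kept). Remaining missing values are imputed as half the
metabolite's minimum observed value plus Gaussian noise with standard
deviation `noise_sd_fraction` (default 0.01) times that half-minimum,
truncated at zero. Downstream tests operate on natural-log concentrations
by default (`log_concentrations: true`); Bray-Curtis distances are computed
on the unlogged imputed concentrations, since the dissimilarity is defined
for non-negative profiles.

## PERMANOVA

One-factor partitioning of squared distances: `SS_total = Σ_{i<j} d²/N`,
`SS_within = Σ_g Σ_{i<j∈g} d²/n_g`, `R² = 1 − SS_within/SS_total`,
`pseudo-F = (SS_between/(a−1))/(SS_within/(N−a))`. The permutation p-value
counts permuted F values at least as large as the observed one, including
the observed statistic in numerator and denominator, so p ∈ [1/(n_perm+1), 1].
Labels are permuted freely by default — patient identity explains almost
none of the metabolome variance in this design, which the pipeline verifies
by also reporting the patient-factor R² — and a `strata` argument provides
patient-blocked permutations when wanted. Permutations are vectorized over
an indicator-matrix product, so 999 permutations on hundreds of samples
cost a few matrix multiplies. The implementation is checked against an
exhaustive-enumeration oracle at n = 6 and against scikit-bio's PERMANOVA
statistic.

## sPLS-DA

Two-class only. The class is dummy-coded and centered; per component the
feature loading is the dominant left singular vector of `X'Y`,
soft-thresholded so exactly `keepX` entries remain nonzero (threshold = the
largest excluded magnitude; index order breaks ties), renormalized to unit
norm, with the largest-magnitude loading forced positive. X is deflated by
regression on the component score; Y likewise. Columns of X are centered
and unit-variance scaled; constant columns are dropped with a warning. The
fit has no randomness.

*Prediction rule:* nearest class centroid in score space, with the signed
distance difference as a continuous score for ROC construction. *Tuning:*
stratified ten-fold CV (3 repeats) on balanced classification error; the
chosen `keepX` is the smallest value whose mean error is within one
standard error of the minimum. The error curve is flat once every
informative feature is included, so the plain CV minimum frequently lands
on oversized `keepX`, after which stability selection retains
chance-correlated features; the one-SE convention removes this failure mode
(verified over multiple generator seeds). *Stability:* the model is refit
on every CV training split (10 folds × 10 repeats = 100 fits) and a
feature's frequency is the fraction of fits selecting it on component 1;
the stable set uses strict `frequency > 0.90`. Component 1 carries the
reported signature. *Evaluation:* leave-one-out CV; the AUC is the
tie-corrected rank statistic of held-out scores, cross-checked against a
brute-force concordant-pair count.

## Microbiome preprocessing

ASVs present in fewer than 10% of samples are dropped, with prevalence
computed on the table as given (before sample removal — the order is
ambiguous in prose descriptions of such filters, so it is fixed and
configurable here). Samples under 5 000 reads, or under 1 000 16S
copies/mL when absolute quantification is supplied, are dropped; the copy
filter is skipped with a warning otherwise.

**SRS** (scaling with ranked subsampling) normalizes every sample to the
minimum depth: counts are scaled, integer parts kept, and the residual
counts distributed one each to taxa by descending fractional part, ties
broken by a seeded random order. Output depths equal the target exactly —
asserted on every call.

**CLR / Aitchison.** Counts are converted to zero-free proportions with a
pseudocount applied on the proportion scale, scaled so that a sample at the
reference depth (the median observed depth) receives exactly 0.5 per taxon.
This choice makes the transform *exactly* invariant to rescaling any single
sample's counts — the property the compositional analysis is meant to
guarantee — whereas adding 0.5 to raw counts is only approximately
invariant and couples results to sequencing depth. At the reference depth
the two coincide. The Aitchison distance is the Euclidean distance on CLR
rows.

## Integration: zero-sum sparse log-contrast regression

Each serum sample is paired with its nearest preceding same-patient stool
sample within 3 days; same-day stool is eligible (lag 0). Genera present in
fewer than 20% of stool samples are dropped before pairing. The design
matrix is the log of the zero-free proportions above, columns centered but
**not** unit-variance scaled: scaling would rescale coefficients
genus-by-genus and thereby change what the zero-sum constraint means (it
was also tested and did not improve false-association control). Responses
are rank-based inverse-normal transformed: Φ⁻¹((r − 0.5)/n) with average
ranks for ties.

**Solver.** The penalized problem with the equality constraint is solved by
ADMM — the smooth constrained quadratic step is a Cholesky solve with the
constraint eliminated via its KKT multiplier; the L1 step is a soft
threshold — followed by an exact polish: the stationarity system restricted
to the detected support is solved directly, sign-inconsistent coefficients
dropped and violated inactive coordinates added until the full KKT
conditions hold with residual ≤ 1e-7. Reported coefficients are therefore
exactly sparse and satisfy the zero-sum constraint to rounding error.
λ_max (the smallest penalty giving the null model) has the closed form
`(max g − min g)/2` for `g = Z'y/n` on centered data.

**Penalty selection.** Ten-fold CV over a 20-point log-spaced grid from
λ_max down to 0.01·λ_max. The default rule takes the *largest* λ whose mean
held-out MSE is within one standard error of the minimum. The plain CV
minimum sits deep in the flat part of the error curve whenever the signal
is strong; at such small penalties near-OLS fits mark many genera nonzero
in essentially every bootstrap (bootstraps resample the same dataset, so
dataset-level chance correlations recur), and spurious genera then pass the
90% stability bar. Under the recovery benchmark's conditions the CV-min
rule produced 3-4 false associations per run against ≤ 1 tolerated; the
one-SE rule produced none while retaining all planted associations.
`rule="min"` (ties toward the larger penalty) remains available.

**Stability selection.** 100 bootstrap resamples of paired rows, refit at
the full-data λ\* (re-tuning per bootstrap is deliberately not done: λ is
part of the model specification being stabilized); a genus is reported when
nonzero in strictly more than 90 of 100 resamples, with the sign of its
full-data coefficient. Degenerate resamples (constant response) are redrawn
and logged. The association table is the collection of stable
(genus, metabolite, sign, frequency) records across signature metabolites.

## Pipeline and reproducibility

One global seed is fanned out to per-stage seeds through a fixed
`SeedSequence` spawn order (simulate, impute, permanova, sPLS-DA,
microbiome, integration, sensitivity), so stages re-run in isolation
reproduce their in-pipeline results. Reports are byte-identical across
reruns at a fixed seed. All thresholds live in one validated config object;
unknown config keys raise.

Benchmark problem sizes (the acceptance script's and test suite's defaults)
were chosen so the full verification sweep completes in minutes on one CPU:
200 paired samples × 20 genera × 6 planted associations × 5 seeds for
association recovery; ~150 serum samples × 300 metabolites × 15 planted for
signature recovery; 200 replicates at n = 40 with 999 permutations for
PERMANOVA calibration; 100 random instances for the constrained-lasso
oracle sweep.

## Known limitations

* Two-class sPLS-DA only; the default pipeline uses one component for the
  signature (component 2 can be tuned but does not feed the stable set).
* The generator draws genus log-abundances independently; it cannot create
  genuine inter-genus interaction structure, so collinearity-driven
  selection failure modes are under-tested.
* Repeated measures within patients are ignored by the univariate tests and
  default PERMANOVA, mirroring the analysis being reproduced; the blocked
  permutation option exists but is off by default.
* The copy-number sample filter requires externally supplied absolute
  quantification; the generator does not simulate it.
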