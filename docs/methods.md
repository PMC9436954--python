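# Methods

This note documents the models, conventions and design choices behind
`pvsignal`, in the order data flows through the pipeline.

## Report model and counting conventions

An individual case safety report carries demographics (gender; seven age
bands plus unknown), provenance (report type: spontaneous / post-marketing
surveillance / literature / other; reporter occupation and affiliation), a
seriousness flag, one or more drugs each with a causality role (suspected,
concomitant, drug–drug interaction) and one or more coded AE terms, each
with a system-organ-class (SOC) code.

Three conventions matter everywhere downstream:

* **Exposure = suspected role only.** A report counts as exposed to a drug
  iff the drug is listed as *suspected*; concomitant/interaction listings
  are retained but never define exposure.
* **Report-level counting.** A report contributes exactly once to one cell
  of each pair's 2×2 table, however many drug/event rows it spans in a
  file. This prevents double counting when reports list several drugs or
  events. (Whether row-level or report-level counting is used in any given
  national database is rarely stated; report-level is the defensible
  default and is applied consistently.)
* **Follow-up deduplication.** Cases may be superseded by later versions;
  only the highest version per case id survives. Duplicate
  (case, version) keys are an error, not silently resolved.

Cumulative yearly datasets (`build_cumulative_sets`) are nested subsets by
`report_year`; a ten-year window yields ten datasets. All screening
computations for year *t* use only the ≤ *t* dataset — the no-lookahead
property is tested by truncation.

File dialects: `generic_csv` (one row per report–drug–event triple, exact
column names documented in `pvsignal.core`) is the canonical interchange
format and round-trips losslessly. The `faers_quarter` reader ingests the
`$`-delimited DEMO/DRUG/REAC quarterly ASCII layout but maps only the
fields of the report model; seriousness (OUTC files) and report type are
not derivable there, so those fields take residual values, and SOC codes
come from a caller-supplied term→SOC map.

## Reference standard (Y/N/U)

As of year *t*, an observed pair (study drug, AE) is

* **Y** — the study drug's label lists the AE with label year ≤ *t*;
* **N** — no label among {study drug} ∪ class drugs lists it by *t*;
* **U** — otherwise (typically: listed for a same-class drug only).

The boundary convention counts `label_year == t` as labeled, so "detected
before the label update" is the strict inequality
`first_detection_year < label_year`. Y status is monotone: once labeled,
always Y. Term matching is exact string equality after case-folding and
trimming; cross-dictionary mapping is treated as upstream curation. Label
histories are plain CSV inputs (drug_id, ae_term, label_year), never
scraped.

## Feature schema (35 features per pair)

Exactly 35 columns, schema-locked: the four contingency cells; the SOC
ordinal (raw codes 100…3200 mapped to 1…32, the mapping table
configurable); covariate proportions over the n₁₁ reports — gender (3),
age band (8), report type (4), occupation (7), affiliation (6) — the
serious proportion, and the pair's first report year min–max normalized
over the study window. Proportion blocks sum to 1 when n₁₁ > 0 and are
all-zero otherwise. The three published feature blocks do not pin a unique
35-column composition; this allocation reproduces the stated total, the
stated SOC encoding and every named covariate, and lives in one place
(`FEATURE_COLUMNS`) so alternates are a schema swap.

Pair-level aggregation uses proportions (not counts) because classifiers
train on pairs while covariates live on reports; proportions are
scale-free across years.

## Disproportionality statistics

* **Crude ROR** = (n₁₁n₀₀)/(n₁₀n₀₁) with Wald 95% CI on the log scale;
  the Haldane–Anscombe +0.5 correction is applied to *all four* cells only
  when some cell is zero. All-zero tables are undefined (error).
* **Adjusted ROR** fits a report-level logistic regression of the outcome
  ("report lists the AE") on the exposure indicator ("study drug
  suspected") plus categorical covariates; the exponentiated exposure
  coefficient is the ROR. With no covariates this equals the crude
  cross-product exactly (tested to 1e-6), which anchors the implementation.
  Complete separation and non-convergence raise errors carrying the 2×2
  cells; they are never returned as numbers.
* **Information component** IC = log₂(P̂ₓᵧ/(P̂ₓP̂ᵧ)) with plug-in
  proportions; exactly 0 at independence, scale-invariant, undefined at
  n₁₁ = 0.
* **IC credible bounds**: cell probabilities are sampled from the
  flat-prior posterior Dirichlet(n₁₁+1, n₁₀+1, n₀₁+1, n₀₀+1), the IC is
  computed per draw (default 20 000), and lower quantiles reported
  (IC₀₂₅ = 2.5th percentile, IC₀₅ = 5th). This makes the prior explicit
  and the bound oracle-testable. The classical BCPNN normal approximation
  (prior moments γ₁₁ = α₁ = β₁ = 1, α = β = 2, γ tuned for prior IC 0) is
  available as `backend="normal"`; it is mildly conservative relative to
  the Monte-Carlo posterior. Published usage alternates between IC₀₂₅ and
  IC₀₅; both are always computed and the screening bound level is a config
  key (default 0.025).
* **Flag rules** are strict: ROR₀₂₅ > 1; IC bound > 0.

## Classifiers

GBM and RF (scikit-learn implementations) with small documented grids
(100 trees; depth 2/3 for GBM at learning rate 0.1; depth 3/unbounded and
feature subsampling for RF — defaults sized for desk-scale pair counts).
Pipeline order is strictly leakage-free:

1. stratified 75/25 split of the Y/N gold standard;
2. SMOTE on training data only — synthetic minority rows are convex
   combinations x·(1−λ) + λ·x′ of a minority row and one of its k = 5
   nearest minority neighbors (k shrinks automatically when the minority
   is tiny); originals are preserved verbatim; balancing also runs inside
   each CV training fold during tuning;
3. fivefold stratified CV picks the grid configuration maximizing the mean
   balanced AUROC at the per-fold optimal threshold (the same metric used
   everywhere: max over thresholds of (sens+spec)/2);
4. the winner is refit on the full balanced training set, and the
   signaling threshold is selected on **out-of-fold** training scores by
   exhaustive scan over observed score values plus the {0, 1} sentinels,
   flag rule `score ≥ threshold`, ties to the smallest maximizer.

The out-of-fold choice is deliberate: tree ensembles memorize pair-level
training sets of a few dozen rows, so resubstitution scores are
near-separable and would push the "optimal" threshold to the extreme of
the score range, where no newly emerging signal can ever reach it.
Out-of-fold scores estimate the generalization operating point.

## Retrospective screen

Per cumulative year: classify pairs as of that year; train both
classifiers on the Y/N pairs (skipping the year with an explicit record if
either class has < 2 members before or after the split); score the U pairs
with all four methods; convert to standardized differences
d = (score − To)/SD with To = the classifier's threshold, 1 on the ROR₀₂₅
axis, 0 on the IC-bound axis, and SD = the dispersion of that method's
scores across the year's U pairs. d > 0 flags a signal and coincides with
each method's native rule whenever SD > 0; degenerate pools (SD = 0) fall
back to the native rule with a logged warning. Pairs with undefined scores
(IC at n₁₁ = 0) are never flagged and are excluded from the SD pool.

Targets may be term groups (clinically equivalent preferred terms); a
group is detected in a year iff any member is flagged, its first report
year is the minimum over members, and its label year the earliest member
label year. `early ⇔ first_detection_year < label_update_year`.

The screening ROR defaults to the unadjusted (crude) bound: the default
generator plants no confounding, so crude and adjusted agree in
expectation, and fitting hundreds of per-pair logistic models per screen
adds cost without information. The full covariate-adjusted ROR is a
configuration switch (`screening.ror_covariates`) for data where
confounding is plausible.

Evaluation follows clinical-test logic: sensitivity over Y pairs,
specificity over N pairs, summary AUROC = (sens+spec)/2. Classifiers are
evaluated on the held-out test split (configurable to the whole gold
standard; the choice is recorded in output metadata) and also report full
score-based ROC curves, whose trapezoidal area equals the Mann–Whitney
concordance probability (ties at ½) — property-tested. Conventional
methods enter as binary flags over all Y/N pairs.

## Synthetic data generator

The generator emulates a two-drug SRS extract. Per report: year and
covariates from configurable marginals (defaults re-derived from the
printed category counts of a published infliximab report series, n = 4482;
study-drug share 4482/11376); 1 + Poisson(1) events sampled without
replacement with weight ∝ baseline_rate × multiplier, where the multiplier
applies on the study drug from the signal's first report year; planted
terms have weight zero (both drugs) before that year. Report seriousness
is Bernoulli with p = max over its events of the per-term p_serious
(default 1255/4482). With probability p_followup = 0.1 a case also emits a
superseded version 1; the surviving version may add one extra event.

**What the multiplier means.** Sampling weights are renormalized within a
report, so the realized rate ratio equals the multiplier only when planted
terms hold a small share of total weight. In a sparse vocabulary (the
multiplier-recovery test uses 1 planted term among 200) the crude ROR's
95% CI covers the multiplier; in the default scenario (20 of 45 terms
planted at ×10) absolute RORs compress toward ~2 while the planted/null
contrast stays ~10-fold. Detection results are therefore about contrast,
not absolute ROR calibration.

**Default scenario** (the package's reference study; 2009–2018,
n = 20 000): 45 AE terms — 10 known associations (×10, labeled 2009),
10 emerging signals (×10, first reported 2011–2015, label three years
later, listed on a same-class drug's label from 2009 so they classify as U
while unlabeled — the class-effect situation), 20 null terms (two listed
only on a class drug's label), and 5 label-positive-but-null terms
(multiplier 1, labeled 2009). The last group reflects that real labels
list AEs that are not enriched in a given database; without them the gold
standard is perfectly separable and the AUROC-optimal threshold
degenerates. Planted terms carry p_serious 0.6 (label-worthy reactions
skew serious). The null calibration scenario keeps the frame with no
planted signals.

**What the generator does not model** — and hence what passing tests do
not show about real data: duplicate cases under different ids, reporting
delays and version churn beyond one follow-up, secular trends in coding
practice, term co-occurrence structure beyond weight competition,
covariate–exposure confounding (available only in hand-built test
streams), and free-text narratives. Parameter-recovery results say the
pipeline recovers what was planted under these idealized conditions, not
that the same operating characteristics hold in any national database.

## Problem sizes and numerical conventions

The reference experiments use five replicates at n = 20 000 reports for
classifier recovery and early detection, and twenty all-null replicates at
n = 4 000 for ROR calibration; unit tests run reduced streams (1 500–8 000
reports). IC Monte-Carlo uses 20 000 draws by default (warning below
1 000). All stochastic stages take explicit integer seeds; the pipeline
writes a manifest (config snapshot, per-stage seeds, output SHA-256
digests) and two runs from the same manifest produce byte-identical CSVs.
Ties at thresholds are resolved strictly (> for flag rules, smallest
maximizer for thresholds); proportions use population SD (ddof 0) for the
standardized-difference pool.

## Known limitations

* The adjusted-ROR logistic fit is per pair over the whole report
  universe; restrictions (e.g., within-SOC comparators) are not modeled.
* The FAERS dialect reads one quarter at a time and does no cross-quarter
  case reconciliation.
* Conventional-method ROC curves are single-point by construction; only
  classifiers produce full curves.
* PRR and empirical-Bayes shrinkage scores (GPS/MGPS) are out of scope.
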