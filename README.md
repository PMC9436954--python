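# pvsignal

Early safety-signal detection in spontaneous adverse-event reporting data.

Regulators monitor post-marketing drug safety through spontaneous reporting
systems (SRS) such as KAERS and FAERS: streams of individual case safety
reports, each listing suspected drug(s), coded adverse-event (AE) terms and
reporter covariates. `pvsignal` is a library for researchers who want to ask,
retrospectively, *how early* a detection method would have flagged a drug–AE
association relative to the year it entered the drug's label. It implements
the full screening pipeline — report ingestion and deduplication, a
drug-label reference standard, pair-level feature engineering, conventional
disproportionality statistics, supervised ensemble classifiers and a
cumulative-yearly retrospective screen — together with a synthetic report
generator that plants associations with known strength, onset year and label
year, so every stage is testable without access-restricted SRS extracts.

## Methods at a glance

For a drug *x* and AE *y*, reports form the 2×2 table
(n₁₁, n₁₀, n₀₁, n₀₀) with N = Σnᵢⱼ ("exposed" = the drug is listed as
*suspected*). The package scores each pair four ways:

* **Reporting odds ratio** — ROR = (n₁₁·n₀₀)/(n₁₀·n₀₁), optionally
  covariate-adjusted by report-level logistic regression
  logit P(y) = β₀ + β·1[x suspected] + γ′z with z = reporting year, gender,
  age band, report type, reporter occupation/affiliation, seriousness.
  Signal rule: **ROR₀₂₅ > 1** (lower 95% Wald bound, strict).
* **BCPNN information component** — IC = log₂ P(x,y) / (P(x)P(y)), with
  lower credible bounds (IC₀₂₅, IC₀₅) from a Monte-Carlo
  Dirichlet(n+1) posterior over the four cells (a closed-form normal
  approximation is an alternative backend). Signal rule: **lower bound > 0**.
* **Gradient boosting (GBM)** and **random forest (RF)** — trained on
  label-positive (Y) vs label-negative (N) pairs described by 35 features:
  the four contingency cells, the system-organ-class ordinal (1–32), and
  covariate proportions over the pair's exposed-case reports. Training uses
  a stratified 75/25 split, SMOTE balancing (applied only to training data,
  inside each CV fold), fivefold stratified CV tuning, and a signaling
  threshold chosen to maximize AUROC = (sensitivity + specificity)/2 over
  out-of-fold training scores.

The **reference standard** classifies each observed pair, as of a year:
Y if the study drug's label lists the AE by then, N if no label in the
therapeutic class lists it, U (unknown) otherwise; the U pool is screened
for new signals. The **retrospective screen** rebuilds everything per
cumulative yearly dataset (no lookahead), puts all four methods on the
common scale d = (score − threshold)/SD (SD over the year's unknown pairs;
d > 0 declares a signal), and calls a signal *early* when its first
detection year strictly precedes its label-update year.

## Worked example

`examples/02_disproportionality.py` scores one planted (×10) and one null
pair on a synthetic 8 000-report stream:

```
ae01 (planted x10): cells=(325, 2849, 239, 4587)
  ROR  2.19 [1.84, 2.60]  -> signal: True
  IC   0.54 (IC025 0.44)  -> signal: True
ae25 (null): cells=(38, 3136, 227, 4599)
  ROR  0.25 [0.17, 0.35]  -> signal: False
  IC  -1.47 (IC025 -1.90)  -> signal: False
```

The planted pair's lower bounds clear both cut-points; the null pair's do
not. (With half the vocabulary planted at ×10, weight renormalization
compresses absolute RORs below the raw multiplier while preserving the
planted/null contrast — see `docs/methods.md`.)

`examples/06_published_flag_rules.py` replays the strict flag rules on a
published screen of 27 unknown AEs of infliximab (KAERS 2009–2018):

```
rows: 27
GBM signals: 27
RF signals:  27
ROR signals: 2 -> melaena, temperature changed sensation
IC signals:  3 -> melaena, psoriasis, uveitis
flag agreement with the published calls: 100%
```

The other examples cover generation (`01`), the year-aware reference
standard (`03`), classifier training (`04`) and the full retrospective
screen (`05`). An end-to-end experiment is one command:

```bash
pvsignal run -o runs/demo --seed 1
```

which simulates, screens, evaluates and writes `timeline.csv`,
`summary.csv`, `metrics.json` and a manifest sufficient to re-run
bit-identically.

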