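# Methods

## Scope and data model

The package operates on single-patient observation records with seven
numeric features — hour of day *t* ∈ [0, 24], blood sugar *bs* (mg/dL),
systolic *bh* and diastolic *bl* blood pressure (mmHg), exercise calories
*ce*, meal calories *cm*, and the daily target calorie intake *c* (kcal) —
plus an optional treatment label in {1..5} (more exercise / eat more /
rest / take insulin / maintain).  Records travel as header-led CSV;
thousands separators are accepted on read (printed source tables use
them) and never written.  Time is stored as a real number of hours:
printed data uses whole hours, but the distance computation treats time
as an ordinary numeric coordinate, so nothing forces integrality.  Hour
distance is linear, not circular (23 → 1 is 22 h, not 2 h): the distance
formula treats time like every other coordinate, and the advisory rules
never compare two times.

## Daily calorie target

Standard weight is height² (m²) × a sex factor in kg/m²: 21 for women,
22 for men.  The female factor is the canonical constant of this
standard-weight formula; the male companion value 22 is the conventional
extrapolation (the reference worked example covers only women) and is
overridable via the `factors` argument.  The standard weight is rounded
**up** to a whole kilogram — the only rounding rule consistent with
57.1725 kg being treated as 58 kg — and multiplied by the activity band
(light 25–30, normal 30–35, hard 35–40 kcal/kg/day).  `band_point` ∈
[0, 1] interpolates inside the band; the default 0 (band lower bound)
reproduces the canonical example 58 × 25 = 1450 kcal/day.

## Rule engine

Rules are data: each has a tier (evaluation priority), a set of inclusive
hour windows, one strict threshold comparison on blood sugar, and an
action code.  The first firing rule in tier order wins; if none fires the
default is maintenance (5).  The packaged default set:

| tier | windows (h) | condition | action |
|------|-------------|-----------|--------|
| 1 | 0–24 | bs < 70 | 3 rest |
| 2 | 0–7, 9–12, 14–18, 20–23 (fasting) | bs > 126 | 1 exercise |
| 3 | 22–24 (before sleep) | bs < 120 | 2 eat |
| 4 | 9–12, 15–17, 20–23 (4 h post-meal) | bs > 140 | 1 exercise |
| 4 | same | bs < 100 | 2 eat |
| 5 | 0–24 | bs > 180 | 4 insulin |

Precedence choices, and why:

- **Emergency dominates.**  bs < 70 yields rest at every hour, whatever
  else would fire — it is the only emergency action.
- **Windowed rules outrank always-insulin.**  A fasting-window reading of
  199 mg/dL is labeled "more exercise" in the reference data even though
  199 > 180; that single labeled row fixes the order.  Consequently
  insulin is recommended only at hours no window covers (8, 13, 19 on the
  whole-hour grid) or at covered hours where no windowed predicate fires.
- **Inclusive window bounds, strict thresholds.**  "Over 126" and "below
  100" are read literally: bs = 100 at hour 23 does not trigger the
  post-meal below-100 rule and instead falls to the before-sleep rule
  (bs < 120 → eat), matching the reference labeling.
- The relative order of the before-sleep and post-meal tiers is not
  pinned down by any labeled example in which they conflict; before-sleep
  is evaluated first.  This is recorded as an open degree of freedom; the
  rule set being serializable YAML makes alternative orders testable
  without code changes.

Two labeled rows of the reference sample table (hours 8 and 13, labels 1)
are not generated by any rule at those hours under any precedence; they
appear to have been labeled independently of the rules and are excluded
from rule-agreement checks.  The diagnostic table (normal / abnormally
high / impaired glucose tolerance / impaired fasting glucose / low) is
implemented alongside; input combinations outside the table return an
explicit `UNCLASSIFIED` value rather than raising, since a monitoring
loop must not crash on unusual readings.

## KNN recommender

Distance is Euclidean over the seven features, √Σ(aᵣ(x) − aᵣ(y))².
Whether the square root is applied cannot change any recommendation (a
monotone transform preserves neighbor ranking); a test asserts this
vote-invariance explicitly.  Determinism conventions:

- Neighbors at exactly equal distance are taken in dataset order (stable
  argsort), so results are reproducible on data with repeated rows.
- A tied plurality vote (possible at k = 3 with three distinct labels and
  at k = 5) resolves to the tied label whose representative is nearest —
  a k = 3 three-way tie therefore degenerates to the k = 1 answer.

Min–max normalization maps each feature to (x − min)/(max − min) with
bounds fitted on the sample (training) set only; query values outside the
fitted bounds are clamped to [0, 1].  A degenerate feature (max = min)
maps to 0 and contributes nothing to any distance.  The treatment label
is never normalized.  Fitted bounds can be exported/imported as JSON for
audit.

The packaged raw fixture table and its printed normalized twin are tied
together by per-feature reference bounds (time 5–23, blood sugar 50–423,
systolic 100–180, diastolic 50–100, exercise 0–500, meal 0–680): applying
the normalization formula with these bounds reproduces the printed
normalized cells to three decimals, with two documented exceptions — one
blood-sugar cell (0.0199 where the bounds give 0.091, an apparent
misprint since the same bounds reproduce the other nine cells of that
column) and the target-calories column, whose source bounds cannot be
recovered self-consistently from the printed values; the generator's
150–2439 kcal span is the printed raw column's own range.

## Evaluation harness

`score` reduces a prediction/label pair to a per-record 0/1 match vector,
a match count and an accuracy fraction; the reference experiments report
raw counts out of 100, so both forms are kept.  `compare_methods` scores
the rule engine and KNN (raw and normalized, each requested k) on one
shared test set in a fixed row order with no hidden randomness.  The
reference experiment's own headline counts (rule-based 42/100; raw KNN
36/52/64 for k = 1/3/5; normalized KNN 61/65/61) depended on a
200-sample/100-test dataset that was never published; they are quoted
here as context only and are not asserted anywhere.  What the suite
asserts instead: exact agreement of the KNN path with an independent
exhaustive-search oracle, exact rule accuracy 1.0 on rule-consistent
labels, accuracy ≈ 1 − p under label noise p (binomial tolerance), and a
mean normalized-over-raw KNN advantage on scale-imbalanced data.

## Synthetic data generator

The generator emulates the *structure* of the reference records, not
their physiology.  Defaults: 200 sample / 100 test records; features
drawn uniformly and independently within the reference spans above
(target calories 150–2439 kcal); systolic forced above diastolic; each
record is in exactly one of three situations — normal, after exercise,
after a meal — chosen uniformly, so at most one of *ce*/*cm* is nonzero
(every printed reference row satisfies this).  Uniform marginals were
chosen because no distributional information about the source records
exists; they keep every region of the rule space populated.  Labels are
the rule engine's output; `noisy` mode then flips each label with
probability *p* to a uniformly random different code, emulating the
reference situation in which labels disagree with the rules often enough
to make method comparison meaningful.  Identical configuration (including
seed; numpy `default_rng`) yields byte-identical CSV output.

`generate_scale_imbalanced` is a second generator for the normalization
study: same feature draws, but the label is the nearest of five random
prototypes in min–max scaled space, so the label depends on *all*
features equally while raw distances are dominated by the kcal-scale
features.  This is the canonical setting where normalized KNN should beat
raw KNN, and the harness verifies that tendency as a ≥ 0 mean gap over
20 seeded replicates (not per run — individual seeds may go either way).

What passing these tests does **not** show: behavior on real glucose
dynamics.  The generator has no meal-response curves, no correlation
between blood sugar and time of day, no patient heterogeneity; conclusions
about the two recommenders transfer to real data only insofar as the rule
thresholds and the feature-scale argument do.

## Numerical and testing choices

- Problem sizes: oracle-equivalence checks use datasets of ≤ 50 records
  (exhaustive search stays trivially fast and every case is inspectable);
  noise-calibration checks use 1000 records (binomial 3σ ≈ 0.043 at
  p = 0.3); the totality sweep covers hours 0–24 × blood sugar 0–400 on a
  unit grid.
- Printed-cell comparisons use an absolute tolerance of 10⁻³ (the printed
  table mixes 3- and 4-decimal cells and at least one truncated-rather-
  than-rounded value).
- The scikit-learn cross-check skips queries with a tied plurality, where
  tie-break conventions legitimately differ between implementations, and
  asserts that enough untied queries remain for the check to be
  meaningful.

## Limitations

- The five-way action code is coarse: no insulin dose, meal composition
  or exercise prescription is modeled.
- The rule set encodes fixed meal times (7:00, 12:00, 18:00) and sleep at
  24:00 through its windows; patients with other schedules need a custom
  YAML rule set.
- Diagnosis and treatment rules are separate surfaces; the diagnostic
  categories do not feed the treatment decision.
- KNN search is exhaustive (O(n) per query) by design — datasets are
  hundreds of records; no tree index or distance weighting is provided.
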