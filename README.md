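# glucoguide

A blood-glucose monitoring and treatment-advisory toolkit for diabetes
self-management records.  Given a timestamped observation — hour of day,
blood sugar (mg/dL), systolic/diastolic blood pressure (mmHg), exercise and
meal calories, and the daily calorie target — the package recommends one of
five treatment actions:

| code | action |
|------|--------|
| 1 | more exercise |
| 2 | eat more (meal or snack) |
| 3 | emergency (rest) |
| 4 | take insulin |
| 5 | normal (maintenance) |

It is aimed at health-informatics practitioners who want a small, fully
tested reference implementation of two classic advisory approaches and a
harness to compare them:

- **Rule engine** — time-windowed threshold rules with explicit precedence:
  blood sugar below 70 mg/dL always means rest; fasting-window readings
  (hours 0–7, 9–12, 14–18, 20–23) over 126 mg/dL mean exercise; readings
  below 120 mg/dL before sleep (22–24) or below 100 mg/dL four hours after
  a meal (9–12, 15–17, 20–23) mean eat more; over 140 mg/dL post-meal means
  exercise; over 180 mg/dL at any uncovered hour means insulin; otherwise
  maintain.  The rule set is plain data (YAML), so alternative precedence
  orders are testable without code changes.
- **K-nearest-neighbor classifier** — a query record receives the plurality
  treatment label of its *k* closest labeled records (k ∈ {1, 3, 5}) under
  Euclidean distance
  d(x, y) = √Σᵣ (aᵣ(x) − aᵣ(y))² over the seven features, either raw or
  after min–max scaling each feature to [0, 1]
  (x′ = (x − min)/(max − min), clamped) with bounds fitted on the sample
  set.
- **Evaluation harness** — match counts and accuracies of rule-based, raw
  KNN and normalized KNN on one shared test set, plus a seeded synthetic
  generator of labeled record files so every experiment is reproducible
  from code alone.

Supporting utilities compute the daily calorie target from body
information: standard weight = height² × 21 (women; 22 for men), rounded up
to a whole kg and multiplied by the activity band (light 25–30, normal
30–35, hard 35–40 kcal/kg/day).

## Worked example

```python
>>> from glucoguide import standard_weight, round_standard_weight, daily_calories
>>> standard_weight(1.65, "female")
57.17249999999999
>>> round_standard_weight(57.1725)
58
>>> daily_calories(58, "light")
1450.0
```

A 1.65 m woman has a standard weight of 57.1725 kg ≈ 58 kg; under light
activity she should consume 58 × 25 = 1450 kcal/day.

```python
>>> from glucoguide import ObservationRecord, recommend, knn_recommend, load_table4
>>> rec = ObservationRecord(time=19, blood_sugar=300, systolic=164,
...                         diastolic=68, exercise=0, meal=0, target_calories=600)
>>> int(recommend(rec))
4
```

Hour 19 falls in no rule window, so the always-rule for blood sugar over
180 mg/dL fires: treatment 4, take insulin.

```python
>>> vote = knn_recommend(rec, load_table4(), k=3, normalized=True)
>>> int(vote.predicted), vote.tally
(4, {<TreatmentCode.TAKE_INSULIN: 4>: 1, <TreatmentCode.MAINTAIN: 5>: 1, <TreatmentCode.EAT_MORE: 2>: 1})
```

With a three-way vote tie the label of the single nearest neighbor wins.

The `examples/` directory holds one short script per capability
(calorie target, rule advice, KNN advice, method comparison, dataset
generation); each prints its numbers and a line on what they mean.  A thin
CLI wraps the same functions:

```sh
glucoguide calories --height 1.65 --sex female --activity light
glucoguide recommend-rules --record "19,300,164,68,0,0,600"
glucoguide generate --n-sample 200 --n-test 100 --seed 7 \
    --label-mode noisy --noise-p 0.3 --out-dir data/
glucoguide compare --sample data/sample.csv --test data/test.csv --k 1,3,5
```

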