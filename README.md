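# mhengage

Engagement analytics for anonymized mobile mental-health (mHealth) telemetry.

Mobile mindfulness-training apps are downloaded by hundreds of thousands of
people, but almost everything known about their effectiveness comes from
supervised trials. To understand *natural* use — how often people open an
app, how long they stay, where they navigate, whether heavier use goes with
better outcomes — one needs to turn raw, anonymized event logs into
population-level engagement statistics. `mhengage` is a pipeline for exactly
that, built for telemetry from a 14-level mindfulness-training app with an
embedded Five-Facet Mindfulness Questionnaire–Short Form (FFMQ-SF)
assessment, and usable for any app whose logs fit the same event schema.

It is aimed at digital-health researchers and data scientists who have
event-level logs (one JSON object per record: installation id, timestamp,
event name, screen label, duration) and want reproducible, well-tested
engagement and dose–response analyses.

## What it computes

* **Sessionization.** *Events* are records with nonzero duration, capped at
  30 minutes (unless the user configured a longer cap). *Visits* are maximal
  clusters of records less than 30 minutes apart (a gap of exactly 30
  minutes splits). A visit containing the license-acceptance event is a
  *first-time* session; later visits are *return* sessions.
* **Engagement profiles and categories.** Per installation: visits, events,
  active minutes, whole retention weeks, highest training-plan level.
  Users are banded as *exploratory* (1 visit), *limited* (2–3), *moderate*
  (4–7) or *committed* (≥8), and descriptive/percentile tables are produced
  per band. Grand means are two-stage (within-user means first), so each
  user contributes equally.
* **Retention.** Return use: the share of installations active more than
  1 day / 1 week / 1 month / 3 / 6 / 12 months after first use. Rolling
  retention: distinct active days, ISO weeks and calendar months per user.
  All percentages are printed as `pct% (n/d)` and re-derived from the counts
  by a self-consistency linter.
* **Navigation.** Per session type: the first key content area entered, all
  distinct areas entered, and the distribution of distinct-area counts, with
  a Pearson chi-square comparing first-time to returning sessions.
* **FFMQ-SF scoring.** 19 items over four facets — observing (Obs), acting
  with awareness (AA), nonjudging (NJIE), nonreactivity (NRIE) — on a 1–5
  scale, reverse-keyed items scored 6−r, totals in [19, 95]. Only occasions
  closed by a completion event are scored; abandoned runs are counted.
* **Dose–response models.** For each predictor x (weeks since install, total
  active minutes, visits, events, level achieved), a polynomial
  repeated-measures regression of an FFMQ-SF outcome y for user *i*,
  occasion *j*:

  y_ij = β₀ + β₁ x_ij + β₂ x_ij² + β₃ x_ij³ + u_i + ε_ij,  u_i ~ N(0, τ²),
  ε_ij ~ N(0, σ²)

  fitted by REML with a per-installation random intercept (one model per
  predictor, since the predictors are strongly collinear), reporting
  per-term tests and a marginal pseudo-R² (squared correlation between
  observed outcomes and the fixed-effects prediction).
* **Synthetic telemetry.** A generator with analytically known ground truth
  (category mixture, navigation frequencies, level progression, latent
  outcome model) so that every stage can be validated by
  analysis-inverts-generator checks and parameter-recovery simulation.

## Worked example

```bash
cat > run.yaml <<EOF
synthetic_n_users: 1000
seed: 7
outdir: demo_out
EOF
mhe run --config run.yaml
```

This generates a 1,000-user synthetic population, runs the full pipeline and
writes nine artifacts (`visits.csv`, `profiles.csv`, `table1.csv`,
`table2.csv`, `retention.csv`, `table3.csv`, `ffmq_scores.csv`,
`models.csv`, `report.md`). The report begins:

```
## Reach

- Unique installations analyzed: 1000
- Android share: 63.60% (636/1000); iOS share: 36.40% (364/1000)
- License accepted: 87.10% (871/1000)

## Use

- exploratory users (1 visits): 40.10% (401/1000)
- limited users (2-3 visits): 30.50% (305/1000)
- moderate users (4-7 visits): 18.50% (185/1000)
- committed users (>=8 visits): 10.90% (109/1000)

- Mean visits per user: 4.5 (SD 14.7)
- Mean active minutes per user: 24.4 (SD 78.9)

## Retention

- Returned after first day: 53.90% (539/1000)
- Returned after 1 week: 32.80% (328/1000)
```

Reading it: about 40% of installations were opened exactly once; roughly
half the users returned after the first day; the heavy right skew (mean 4.5
visits against a median near 2) is characteristic of natural app use.
Further down, the navigation section shows first-time sessions
overwhelmingly entering the training plan first (~63%) while returning
sessions split between the training plan and practice exercises, with the
between-group chi-square printed per panel; the models section lists one
marginal R² per fitted predictor. Rerunning with the same seed reproduces
every artifact byte for byte.

The same subcommands work on real logs: `mhe validate`, `mhe sessionize`,
`mhe profile`, `mhe retention`, `mhe navigation`, `mhe ffmq-score`,
`mhe model`, or `mhe run` with `input_path` pointing at a JSON-lines file.

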