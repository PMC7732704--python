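# Methods

This note documents the definitions, modelling assumptions, numerical
choices and limitations behind `mhengage`. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Event model

An event log is JSON-lines, UTF-8, one object per record, with integer UTC
epoch-millisecond timestamps (`ts`), an opaque installation id, an event
name from a fixed vocabulary (`launch`, `eula_accepted`, `screen_view`,
`exercise_started`, `level_completed`, `assessment_item`,
`assessment_completed`, `other`), an optional content-area label
(`training_plan`, `practice_now`, `build_expertise`, `track_progress`,
`badges`, `other`, `home`) and a nonnegative `duration_s`. Unknown event or
area labels map to `other` with a warning rather than invalidating
historical logs; true schema violations (missing id, negative duration,
missing assessment payload) are collected completely and either abort
(strict mode, with line number) or are skipped and counted. Streams are
sorted by `(install_id, ts)` with a stable sort, so equal timestamps keep
input order. Writing then reading a validated stream is the identity,
record for record.

The observation window `[window_start, window_end]` is a parameter, not a
constant; every retention quantity is right-censored at `window_end`.

## Sessionization

* **Events** are records with `duration_s > 0` — the unit of in-app
  interaction. Zero-duration records still anchor visit boundaries (they
  are clicks in time) but never count toward event totals or active
  minutes. This is configurable only in the sense that callers can filter
  the stream first.
* **Durations** are capped at 1800 s; a user-configured longer cap (a
  `duration_cap_s` settings payload) raises the cap, never lowers it.
* **Visits** partition one installation's records: a new visit starts when
  the start-to-start gap to the previous record is ≥ 1800 s. The comparison
  is strict — "less than 30 minutes apart" keeps records together, exactly
  30 minutes splits. Gaps are measured start-to-start; an end-to-start
  alternative would need durations inside the gap rule and is deliberately
  not the default (start-to-start is the common clickstream convention and
  is what the tests' brute-force oracle implements).
* **Session type.** The visit containing the license-acceptance event is
  `first_time`; other visits of that user are `return`. At most one
  acceptance event per installation is allowed. Installations that never
  accepted have no classifiable sessions (`session_type` None); they remain
  in every per-user denominator but are excluded from the session-type
  navigation comparison.

Two implementations exist: an object path (`cluster_visits`,
`build_timeline`) that is the reference semantics, and a vectorized
pandas path (`sessionize_frame`) used at population scale. Their
equivalence on randomized streams is asserted in the test suite, and the
object path is itself checked against an O(n²) union-find partitioner on
1,000 random event lists whose gaps straddle the 30-minute boundary.

## Engagement metrics

Per installation: `n_visits`, `n_events` (countable interactions),
`active_minutes` (sum of capped countable durations / 60),
`retention_weeks` = floor(days between first and last use / 7),
`level_achieved` = highest completed level (1 if none), mean visit minutes,
and the category band — exploratory (1 visit), limited (2–3), moderate
(4–7), committed (≥8), a total partition of positive visit counts.

Descriptive tables report n / mean / SD (ddof=1) / range per band;
percentile tables use nearest-rank (type-1) percentiles, chosen because it
is exact on small groups and matches "all percentiles equal the value" for
degenerate groups; other definitions differ only in interpolation and can
be swapped at the call site. Percentages are rounded half-up to 2 decimals
using exact decimal arithmetic (`proportion_pct`); means and SDs keep full
precision internally and are rounded only in rendered reports.

Return use after a window w: share of all installations whose last activity
is strictly later than first use + w. Window lengths default to 1, 7, 30,
91, 182 and 365 days (1/3/6/12 "months" as day counts — calendar-month
arithmetic would make the quantity depend on install date). Proportions are
necessarily non-increasing in w; the retention linter asserts this and also
re-derives every stated percentage from its own numerator/denominator —
which is how a transcription error such as a stated 17.40% against counts
10,108/104,067 (= 9.71%) is caught. The linter flags; it never repairs.

Rolling retention counts distinct UTC calendar days, ISO weeks and calendar
months containing a countable event. Days ≥ weeks and days ≥ months always
hold; weeks ≥ months does **not** hold universally, because one ISO week
can straddle two calendar months (2018-W44 spans Oct 29–Nov 4: a user
active on 4 of those days has 4 days, 1 week, 2 months). We keep the honest
calendar definitions rather than forcing a hierarchy.

## Navigation

`home` is a hub, never a key content area. Three panels per session type:

* **first area** — label of the first non-home `screen_view` per session;
  sessions with none are excluded from this panel's denominator;
* **any area** — each distinct area a session entered, counted once per
  session (so denominators exceed session counts but stay close to them,
  matching the arithmetic of distinct-count distributions);
* **distinct-area count** — distribution of the number of distinct areas,
  over all sessions (home-only sessions appear as 0).

Stored percentages always recompute exactly from stored counts. The
between-group test is a Pearson chi-square on the 2×k table without
continuity correction; labels with zero total are collapsed (configurable
to an error), df = k−1.

## FFMQ-SF scoring

The in-app assessment uses 4 of the short form's 5 facets (describing is
omitted): observing (4 items), acting with awareness (5), nonjudging (5),
nonreactivity (5); 19 items, 1–5 Likert. Reverse-keyed items score 6−r;
facets are item sums; the total is the facet sum, bounded in [19, 95].
The shipped key reverse-keys all AA and NJ items, following the published
short-form assignment with describing removed; because deployed apps may
key differently, the key (items, facet map, reverse set, scale bounds) is
loadable from YAML. Missing-item occasions are rejected rather than
prorated — with 4–5 items per facet, proration trades transparency for
little gain, and the generator never produces partial *completed* runs.

Occasions are extracted per visit: item events accumulate until a
completion event closes the occasion; runs left open at visit end are
abandoned (counted, not scored); duplicate items keep the last response
with a warning.

## Outcome models

One model per predictor (weeks since install, total active minutes, visits,
events, level achieved — strongly collinear, hence separate models):
a linear mixed model with fixed effects polynomial in the predictor
(degree 1–3) and a per-installation random intercept (compound symmetry),
estimated by REML via `statsmodels.MixedLM`. The replication default uses
end-of-study totals as predictors; cumulative-to-occasion dose is what the
generator's latent model uses and is the causally cleaner covariate, and
the attenuation induced by fitting totals against outcomes produced by
cumulative dose is visible in (and explains) the modest marginal R² values
of the pipeline's model battery on synthetic data.

Numerics: the polynomial is fitted on an orthonormal basis (QR of the
increasing-power Vandermonde matrix, signs normalized), which conditions
the heavy-tailed predictors and makes per-term z-tests independent;
coefficients and their covariance are mapped back to the raw power basis
through R⁻¹. Fits with fewer than two installations contributing repeated
occasions fall back to OLS with a warning (the random intercept is not
identifiable); with degree+2 distinct predictor values required up front.
Reported R² is the squared correlation between observed outcomes and the
fixed-effects prediction (marginal pseudo-R²; with mixed models "R²" has no
unique definition, so a variance-decomposition alternative,
`variance_r_squared`, is provided). It is invariant to affine predictor
rescaling and equals classical R² for the OLS path.

## Synthetic data generator

The generator's defaults are the study conditions the pipeline targets:
category mix 0.39/0.32/0.18/0.11 (exploratory/limited/moderate/committed),
Android share 0.629, license acceptance 0.878, an Aug 2018 – Apr 2019
observation window. Visit counts: exploratory exactly 1; limited 2 w.p.
0.6 else 3; moderate on {4..7} with mean ≈ 5.1; committed 8 + negative
binomial (r = 0.26, mean 11.3) capped at 506 — parameters chosen so the
committed band shows the heavy skew (mean ≈ 19, SD ≈ 22) typical of
engaged-user tails. Inter-visit gaps are log-normal in days (median 2,
σ = 1.1) floored at 1830 s; within-visit gaps are exponential (mean 40 s)
capped at 1500 s; record counts per visit are log-normal (median ≈ 9);
15% of records have zero duration; durations are log-normal (median 15 s,
σ = 1.2). First-area choices per session type follow fixed mixtures
(including a "no content area" mass of ≈ 0.30 first-time / 0.38 return);
additional distinct areas continue geometrically (p = 0.3). Levels advance
with probability 0.1 per visit; assessments are prompted at levels 1, 7
and 14 with compliance 0.5 each, and declined prompts leave a partial
(abandoned) item run with probability 0.08. Real inter-visit gap and
duration distributions for such apps are unpublished; these are stylized
choices, and every one is a config field.

Two guarantees make the generator invertible by the analysis: within-visit
start-to-start gaps are always < 30 min and inter-visit gaps always
≥ 30.5 min, so sessionization recovers the intended visit count exactly;
and item-level FFMQ responses are an exact integer decomposition of the
occasion's realized total (reverse-keyed items stored un-reversed), so
scoring the emitted events reproduces the recorded ground-truth totals.
Long-tenure users are fitted into the window by sampling the install time
uniformly over the feasible range and, when necessary, proportionally
shrinking inter-visit gaps (never below the 30.5-minute floor) — the gap
distribution is therefore mildly truncated for the heaviest users.

The latent outcome model is
`total = β₀ + β₁·g(cumulative active minutes) + u + ε` with defaults
β₀ = 55, β₁ = 3, g = log1p, τ = 6, σ = 5, occasion totals rounded and
clipped to [19, 95]; or, in `time_cubic` mode, a cubic in weeks with
coefficients (52, 1.172, −0.072, 0.0015), whose derivative
0.0045·(w−16)² + 0.02 is strictly positive and nearly zero over weeks
~8–24 — a rise–plateau–rise trajectory over 0–32 weeks.

For estimator studies (slope bias, CI coverage, curve shape),
`generate_outcome_table` draws occasion-level rows directly from the same
latent model without materializing event streams, sampling per-user
engagement totals from stylized per-category distributions. This keeps
hundreds of 2,000-user replicates tractable; the event-level path is
exercised end-to-end by the pipeline and determinism tests. Replicate
sizes in the shipped tests (200 replicates × 2,000 users for coverage;
1,500 users for the shape check; 10,000 users for the determinism run) are
the package's chosen simulation scales.

All randomness flows from a single `numpy.random.default_rng` seed;
identical seeds give byte-identical logs and artifacts.

## What passing tests do and do not show

The generator reproduces the *structure* real telemetry is assumed to have
— mixture skew, boundary-respecting gaps, navigation frequencies, prompted
assessments, a latent dose–response. It does not reproduce circadian or
weekly usage rhythms, device switching, app-version drift, informative
missingness (responders who complete assessments are likelier to be engaged
— in the generator, compliance is independent of the latent trait), or the
true gap/duration distributions. Passing tests therefore demonstrate that
the pipeline's definitions are implemented correctly and that the
estimators recover known parameters under the stated model — not that any
particular real population behaves like the synthetic one.

## Known limitations

* Session typing depends on a recorded license-acceptance event; logs
  lacking it leave all of a user's sessions unclassified.
* Retention "months" are day-count conventions; calendar-month variants
  change the numbers slightly.
* The marginal pseudo-R² is one of several defensible definitions; mixed-
  model R² values are not comparable across definitions.
* The totals-as-predictor replication mode induces attenuation relative to
  the cumulative-dose data-generating process, and neither mode supports
  causal claims (no randomization, engagement is self-selected).
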