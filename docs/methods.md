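# Methods

## Setting and data model

The package compares two objects. The *simulated pool* holds one exact
predicted time-to-event per virtual patient; because the generating model
is deterministic and observed continuously, every pool record is an event.
The *observed cohort* holds reported times-to-event with right-censoring
indicators. All times are months from the time origin; records are
`(time, event)` pairs, non-negative times required.

## Kaplan–Meier estimation

The product-limit estimate is computed by lifelines and re-exposed as
arrays (event times, survival values, at-risk and event counts). Three
conventions, fixed here because published descriptions of this workflow
rarely state them:

* **Ties**: events precede censorings at identical times (both count as
  at risk at that time) — the standard convention.
* **Right-continuity**: the drop occurs at the event time, S(t) = P(T > t);
  grids can therefore be evaluated by a single `searchsorted`.
* **Extrapolation**: beyond the largest follow-up time the last value is
  carried forward but flagged, and all metric grids are truncated to
  `[0, min(observed max follow-up, max simulated time)]` so extrapolated
  values never enter a metric.

## Prediction interval

At each of `n_iter` iterations a cohort-sized subsample is drawn from the
pool **without replacement** (a sample "taken from" a finite set of model
runs; a with-replacement flag exists and is indistinguishable when the
pool dwarfs the sample), its KM curve is evaluated on the common grid, and
the pointwise empirical 2.5%/97.5% quantiles across iterations form the
band. Pointwise quantiles of non-increasing step functions are
non-increasing; an accumulate-guard removes floating-point jitter only.

The grid is uniform with 1000 intervals by default. The coverage-style
metrics are grid-point counts, and on a uniform grid the count ratio
converges to the length ratio of the covered time intervals, which is how
such figures are usually read; a grid at the pool's distinct event times
is available (`TimeGrid.from_event_times`) for fidelity to workflows that
evaluate at simulated event times, at the cost of weighting event-dense
regions more heavily.

## Raw coverage and juncture

Raw coverage counts grid points where `lo ≤ S_obs ≤ hi` (closed
comparisons: touching counts). Juncture replaces the observed curve by
the *observation variability band* — the region between the reported
curve and the curve with every event shifted one full inter-visit delay Δ
earlier — and counts grid points where that band and the prediction
interval share at least one value (`band.lo ≤ pi.hi` and
`pi.lo ≤ band.hi`).

Because the reported curve is always one edge of the observation band,
juncture ≥ raw coverage on any shared grid, and as Δ → 0 juncture
collapses to raw coverage exactly; both facts are property-tested.

A subtlety: shifting events earlier lowers the curve **only when there is
no censoring**. An event moved past a censoring time lands in a larger
risk set and takes a smaller relative drop, so the shifted curve can lie
*above* the reported one at late times. The band is therefore built as
pointwise min/max of the two curves rather than assuming an ordering.

## Observation-time uncertainty

Two distinct devices, deliberately asymmetric:

* `shift_events_full` moves **events only** (censoring is an
  administrative timestamp, not a detected event) by exactly Δ, clipped
  at 0 — this bounds the band used by juncture.
* `sample_otu_shift` perturbs **every record** by an independent
  U(−Δ, 0) draw — the uncertainty is assigned to each real patient, and
  a fresh draw is taken at every bootstrap iteration.

## Bootstrapped tests

Each iteration subsamples the pool down to the cohort size and runs
either the plain log-rank or the MaxCombo combination against the cohort
(OTU-shifted afresh when requested). The output is the ratio of
non-significant tests at α = 0.05 over evaluable iterations; iterations
whose test errors are excluded from the denominator (counting them as
non-significant would inflate the metric) and reported. The ratio is
compared to the acceptance threshold with a **closed** boundary (exactly
80% validates). A running-ratio convergence trace supports choosing
`n_iter`; 5000 is the default at which the trace is stable to well under
a percentage point.

The weighted log-rank uses the Fleming–Harrington weights
S(t⁻)^ρ(1−S(t⁻))^γ evaluated from the pooled KM at the left limit of each
event time (the standard definition), a hypergeometric variance with the
n=1 term set to zero, and two-sided normal p-values. MaxCombo runs
FH(0,0), FH(1,0), FH(1,1), FH(0,1), selects the largest |z| (ties break
to the first in that order, deterministically) and multiplies the
selected p-value by 4 (Bonferroni) — the literal correction, conservative
given the four statistics are positively correlated. The implementation
is verified against a brute-force per-risk-set tabulation and against
lifelines' Fleming–Harrington log-rank.

The proportional-hazards diagnostic fits a one-covariate Cox regression
on the group indicator and applies the scaled-Schoenfeld-residual score
test (rank time transform) at α = 0.05, via lifelines. Degenerate fits
(a group without events, non-convergence) are recorded as not evaluable
rather than as violations.

## Synthetic data

`simulate_model_pool` draws exponential predicted times (default rate
0.08/month, median ≈ 8.7 months — commensurate with progression endpoints
in advanced-cancer cohorts), optionally with mean-one log-normal
per-patient rate multipliers to widen the virtual population.

`simulate_trial` draws latent true times from a piecewise-exponential
arm, censors administratively on the true timescale (exponential
censoring rated to hit the target censoring probability; censored times
are reported unrounded), and reports each event at the next scheduled
visit — grid anchored at 0, spacing `visit_interval` — so
RTTE − TTE ∈ [0, Δ) holds for every simulated event, a contract tested
across all presets.

The five presets share 74 patients, 2-month visits and 10% censoring:
`null` (cohort hazard = pool hazard 0.08), `shifted` (+3 months),
`early_difference` (hazard ×2 before month 6), `late_difference`
(hazard ×0.5 after month 6) and `crossing` (0.05 → 0.20 at month 8, the
curve crossing verified on a large draw).

What the generator does **not** emulate: patient covariates and subgroup
structure, informative censoring, irregular per-patient visit calendars,
digitisation noise of published curves. Passing tests therefore show the
metrics behave as designed under their own observation model, not that
any particular disease model is valid.

### A discretisation finding

Visit-schedule rounding adds ≈ +Δ/2 to every reported event time. Against
an exactly-observed pool this acts as a global location shift: the no-OTU
metrics degrade even for a hazard-matching cohort (which is precisely the
motivation for the OTU-aware variants), and a late-only hazard difference
stops being "late-only" — plain log-rank then beats MaxCombo on reported
times, while on exact times MaxCombo wins as designed. The power
comparison in the acceptance suite therefore uses the scenario's latent
exact times and draws a fresh cohort per paired replicate, because a
single fixed cohort's conditional power can favour either test by luck of
the draw.

## Preprocessing (PFS/OS → TTP)

Censored PFS records are dropped first; remaining PFS events are matched
one-to-one, in ascending time order, to the nearest unused OS event
within tolerance (default 2 days = 2/30.4375 months; ties resolve to the
earliest OS event), and matched events are removed as deaths before
progression. The matching is deterministic and order-insensitive; PFS
events with several in-tolerance OS candidates are reported as ambiguous
instead of being resolved silently. The accounting identity
`input = censored + deaths + TTP` always holds. Note that removing events
renormalises the curve, so the derived TTP curve is *not* guaranteed to
lie left of the PFS curve pointwise — only the multiset-containment and
accounting properties are invariant.

## Numerical and design choices

* Significance level α = 0.05, threshold 80%, 5000 iterations, Δ = 2
  months as defaults; all configurable.
* One master seed drives every stochastic step through spawned
  `SeedSequence` streams; identical seed + config gives a bit-identical
  report (timestamp aside).
* `verdict` treats metric = threshold as validated.
* Zero pooled variance in a log-rank risk set yields z = 0, p = 1 with a
  warning instead of NaN.
* Problem sizes in the acceptance script — 10⁵-patient pool, 74-patient
  cohorts, 100×50 calibration tests, 2000 power replicates, 1000
  iterations per six-metric report — were chosen so the whole
  recomputation finishes in minutes on a single CPU while keeping
  Monte-Carlo error well inside the effects being measured.

## Known limitations

* Two groups only; no stratification, left truncation or
  interval-censored likelihoods (the OTU band is a bounding device, not a
  Turnbull estimator).
* The Bonferroni ×4 in MaxCombo ignores the correlation between the four
  statistics; a multivariate-normal combination would be sharper.
* The juncture metric validates a time point on *any* overlap, so a wide
  prediction interval or a wide OTU band makes it generous; it should be
  read alongside raw coverage and the test-based ratios, never alone.
* With a single observed cohort, the ratio of (non-)significant tests is
  a conditional quantity: its Monte-Carlo error across seeds is dominated
  by the cohort draw, not by the number of bootstrap iterations.
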