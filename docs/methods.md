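# Methods

## The data model

The unit of analysis is a participants × weeks response matrix. Cell (i, w)
holds participant i's answer to a weekly diary question — the number of days
(an integer 0–7) with bothersome low-back pain in the preceding week — or is
missing when no answer arrived. Week indexing is 1-based throughout the
public API ("week 1" is the first study week); the default horizon is 52
weeks and is configurable, since "one year" of weekly prompts can reasonably
be 52 or 53 messages. Cells outside 0–7 or non-numeric are coerced to
missing at parse time and counted in a validation report: the protocol only
admits 0–7, so anything else is an entry error, not a pain report, and
treating it as pain would bias the episode statistics.

## Episode definitions

A **zero-week** is a week with a reported value of 0; values 1–7 are pain
weeks. A **non-episode** is a run of at least `window` consecutive
zero-weeks; `window` defaults to 4 (the "one month pain-free" demarcation)
but is a parameter so that shorter or longer pain-free definitions can be
explored as a sensitivity analysis.

Two missing-data policies are implemented:

- **STRICT**: a week is a zero-week iff a response exists and equals 0.
  Missing weeks count as pain, so zero-weeks are never overestimated. This
  is the primary analysis.
- **LENIENT**: starting from STRICT, an unanswered week is imputed as a
  zero-week when its absolute distance to some *responded* zero-week is at
  most `window` weeks, in either direction. Imputed weeks never anchor
  further imputation — the rule is a single pass over the matrix of
  (missing week, responded zero-week) distances, which makes it idempotent
  by construction. Two readings of "within 4 weeks" are possible (distance
  ≤ 4, or membership in a candidate 4-week window); the distance reading is
  implemented because it is the one a manual inspection of a printed
  spreadsheet would apply, and the anchor-distance check is isolated in
  `classify` so the alternative is a local change.

Per participant, three statistics are derived under a single policy:
`max_zero_run` (the longest zero-week run, 0 if none), `has_non_episode`
(max run ≥ window), and `non_episode_at_end`. End-of-study status counts
backwards from the last study week if it was answered, otherwise from the
second-last week. No further fallback exists: when both tail weeks are
unanswered the start stays at the second-last week, which under STRICT is a
pain week (result False) while under LENIENT imputation may still produce a
qualifying run. A run of exactly `window` zeros qualifies ("at least 4").

## Cohort summaries and intervals

Participants answering fewer than 50% of scheduled weeks (the
`min_response_fraction` parameter, boundary inclusive: 26 of 52 is retained)
are excluded before any statistic is computed; excluded ids are carried into
the report. The summary bins maximum zero-runs into categories 0..8 and
"9+", bins missing-week counts into {0, 1–5, 6–10, 11–26, 27+} (the last
bin is necessarily empty after filtering at a 52-week horizon), and
attaches a proportion estimate to each run category and to the two
non-episode prevalences.

Proportions are reported as percentages with 95% confidence intervals from
the Wald (normal-approximation) interval with z = 1.96, clipped to
[0, 100] and rounded to integer percent. Rounding is half-away-from-zero by
default; an "outward" variant (floor the lower bound, ceil the upper) is
provided because published tables are found with either convention and the
two variants differ visibly at this granularity (e.g. 52/80 gives 55–75
nearest but 54–76 outward). The Wald interval is a deliberate choice over
Wilson or Clopper–Pearson: at integer-percent reporting granularity it is
the interval that matches how such cohort tables are conventionally
printed, and its closed form keeps the estimate auditable by hand. Its
known weakness — degenerate zero-width intervals at p̂ ∈ {0, 1} and
undercoverage at small n·p̂ — is accepted and documented rather than
patched. A zero denominator yields an explicit undefined marker (never NaN
propagation), and comparing an undefined estimate is an error.

Interval non-overlap is the only inferential device: two estimates are
called significantly different iff their integer CI bounds are disjoint. No
multiple-testing correction is applied, matching the descriptive character
of the analysis.

`missing_context_stat` quantifies a data-quality observation used to justify
the strict missing-as-pain rule: for each missing cell, the nearest
responded week on each side (where one exists) is inspected, and the
statistic is the fraction of such cells whose nearest neighbours are all
pain weeks. Values near 1 mean non-response clusters inside pain periods,
so imputing missingness as pain is conservative in the right direction.

## The synthetic cohort generator

No patient-level diary data are publicly available, so the generator is the
package's test bed. It emulates the qualitative features such cohorts
show — a majority with unbroken pain, a minority with genuine pain-free
runs, and non-response concentrated in pain weeks — with the simplest
mechanism that produces them:

- With probability `persistent_fraction` a participant is **persistent**:
  latently in pain every week.
- Otherwise the participant is **episodic** and follows a two-state Markov
  chain over {PAIN, FREE} with weekly transition probabilities
  `p_pain_to_free` and `p_free_to_pain`, started from the chain's
  stationary distribution π_FREE = p_pain_to_free / (p_pain_to_free +
  p_free_to_pain). (If both transition probabilities are zero the chain has
  no unique stationary law; the pain state is used, making such episodic
  participants behave like persistent ones.)
- Pain weeks emit a day-count drawn from `pain_days_distribution` over 1..7
  (default uniform — no empirical within-week distribution is available, so
  this is an explicitly free parameter); pain-free weeks emit 0.
- Each week is masked missing with probability `p_missing_base` in free
  weeks and `min(1, p_missing_base · missing_pain_multiplier)` in pain
  weeks. Missingness depends only on the current week's latent state; that
  single parameter is enough to reproduce the "missing cells are surrounded
  by pain weeks" pattern without modelling neighbour effects.

Each participant draws from an RNG stream keyed by `(seed, participant
index)` (NumPy `default_rng([seed, i])`), so a cohort is reproducible
independently of generation order or cohort size.

### Defaults

`persistent_fraction = 0.55`, `p_pain_to_free = 0.02`,
`p_free_to_pain = 0.15`, `p_missing_base = 0.01`,
`missing_pain_multiplier = 3`, 52 weeks. These were set from the exact
chain computation (below), not by trial against simulations: they give an
any-non-episode probability of 0.215, a no-zero-week fraction near 0.69,
and an end-of-study non-episode probability near 0.03 — the shape reported
for secondary-care LBP cohorts, where roughly 56–65% of participants show
no zero-week at all, about 20% have at least one non-episode, and about
4–5% end the year in one. Episodic participants average about one pain-free
spell per year of mean length ≈ 1/0.15 ≈ 6.7 weeks.

What the generator does **not** model: covariates (age, sex, imaging
findings), treatment arms, participant-level heterogeneity in response
behaviour (real cohorts show a heavy tail of poor responders that a single
per-week missingness probability cannot produce — the generated missingness
table is thinner-tailed than a real one), within-episode day-count dynamics,
and any fitting to real data. Passing tests therefore demonstrate that the
pipeline implements its stated definitions and that the estimator behaves
correctly under a known truth; they do not validate the generative model
against real diaries.

### Exact validation oracle

`exact_any_non_episode_probability` computes, by dynamic programming over
the state (latent state, current observed-zero run length capped at
`window`), the exact probability that a simulated participant shows an
observed pain-free run of at least `window` weeks under the strict rule.
An observed zero-week occurs only when the participant is latently FREE and
the week is not masked (probability 1 − p_missing_base); persistent
participants contribute zero. The test suite checks the simulated
prevalence against this value within 3 Monte-Carlo standard errors at
n = 1000 — a dual-route check of the generator and the run-detection code
at once.

## Numerical and testing choices

- Run detection is vectorized over boolean masks; brute-force quadratic
  scans (every start index, extend while zero) and a pairwise
  distance-check reimplementation of the lenient rule live in the test
  suite as independent oracles, exercised on 10,000 random series of length
  up to 60 plus derandomized hypothesis cases.
- Interval coverage is validated by simulation: 500 cohorts of n = 200 with
  true prevalence 0.2, asserting empirical coverage in [0.93, 0.97]. The
  exact coverage of the rounded Wald interval at these settings is 0.961,
  so the band leaves room for binomial noise in the 500 replicates.
- Simulation sizes in tests (≤ 1000 participants) keep the full suite under
  ten seconds while leaving Monte-Carlo standard errors an order of
  magnitude below every asserted tolerance.
- Degenerate inputs are explicit: an empty cohort filters to an empty
  cohort; a fully-excluded cohort yields undefined estimate markers; a
  series shorter than `window + 1` weeks rejects end-of-study evaluation
  (the fallback week must exist).

## Known limitations

- The Wald interval undercovers for small n·p̂; the package reports it
  because it is the convention this kind of cohort table uses, not because
  it is optimal. Wilson or exact intervals would be a one-line change but
  would no longer reproduce conventionally printed tables.
- The lenient rule's "within `window` weeks" reading is one of two
  defensible interpretations (see above).
- Episode *onset/offset* segmentation is out of scope: the package
  operationalizes non-episodes (pain-free runs) only.
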