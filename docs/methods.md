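# Methods

## The proxy and its validation design

Dispensing databases observe drug supply, not clinical events. The proxy
under study reads a *change in the prescription pattern* of an ACE-inhibitor
(ACEI) new user as a signal of an adverse drug reaction (ADR): guidelines
replace an ACEI by an angiotensin receptor blocker (ARB) when an ADR such as
cough or angioedema occurs, so an ACEI→ARB switch is the candidate marker,
with switching to another antihypertensive and stopping as weaker
alternatives. Validation compares each pattern against an adjudicated
chart-review outcome and reports PPV, NPV, sensitivity and specificity.

### Episodes and patterns

A prescription dispensed on day *d* for *u* units at a prescribed daily
number *q* covers `round_half_up(u/q)` days (minimum 1); its theoretical end
is the first uncovered day. Episode chaining accepts the next ACEI
dispensing while it falls no more than `gap_days` after the current episode
end, which is the running **maximum** of chained theoretical ends —
overlapping supply (stockpiling) extends coverage but is not appended
end-to-end, because the gap criterion is defined against the theoretical end
of supply, not against cumulative quantity.

Classification is exhaustive and mutually exclusive. A patient whose
follow-up exit falls within `gap_days` of the episode end is a *continuer*
(we cannot observe a failure to renew that never had time to happen);
continuers are subdivided by exit reason. Everyone else has an index date —
the episode's theoretical end — and the switch scan over
`(index, index + switch_window_days]` assigns switch-to-ARB over
switch-to-other when both drug classes appear, making the groups exclusive
with ARB priority (the guideline replacement is the primary marker).
Dispensings dated after the exit never count. By default
`switch_window_days = gap_days`, so the 180-day sensitivity setting widens
both the renewal tolerance and the switch window together; setting
`switch_window_days` explicitly pins the window (e.g. at 90 days) while the
gap varies.

New users are patients whose first-ever ACEI dispensing falls on/after the
study start with at least `lookback_days = 182` of observed history before
it and no ACEI inside that lookback. "Observed history" is database
coverage only — we do not additionally require a dispensing of some other
drug in the lookback, since pharmacy data capture in the source setting is
essentially complete for registered patients.

Months are fixed day counts (3 months = 90 days, 6 months = 180 days)
throughout. Calendar-month arithmetic was deliberately not implemented: the
day convention matches how refill tolerances are defined in this literature,
and a second arithmetic would double the test surface without changing any
conclusion.

### Adjudication

Chart review is represented by coded events; the package does no free-text
interpretation. A patient's class over a window is the highest-precedence
code present: definite ADR ≻ definite non-ADR ≻ probable ADR ≻ non-probable
health problem, with *nothing mentioned* for an empty window. The order
encodes two judgements: a documented ADR should dominate anything else, and
an explicit physician reason for the change should dominate speculative
mentions. Ties within a code resolve by earliest event date so the result
is independent of input order.

Windows are closed at both ends: cases `[index − 180, index + 90]` days;
matched controls `[ACEI start, start + matched duration]`; continuers
outside the matched subsample are reviewed over their whole episode
(truncated at exit). The whole-episode choice for continuers is the
package's own: some review period must be defined for the NPV denominators,
and the full episode is the only one that does not depend on an arbitrary
anchor.

The three ascertainment levels nest: *definite*; *at-least-probable* adds
probable ADRs; *at-least-possible* adds the nothing-mentioned patients — in
an incomplete chart, silence does not rule an ADR out. Definite non-ADR and
non-probable health problems belong to no level; this is what makes the
published at-least-possible proportions (e.g. 163/180) reproduce from the
contingency table.

### Accuracy metrics

PPVs divide the level count by the group size; NPVs deduct definite (and,
at the stricter level, probable) ADRs from the continuation subgroup; a
definite-only NPV is undefined because probable/possible classes have no
meaning without a switch/stop date. The cough-specific PPV counts definite
ADRs whose recorded term is "cough".

Sensitivity and specificity use the duration-matched design: cases are
processed in descending ACEI-duration order and matched uniformly at random
(seeded) to an unused continuer with at least the case's duration; greedy
descending order maximises the number of feasible matches under the
without-replacement constraint, and the random choice among eligible
controls avoids systematic pairing. Unmatched cases are reported, not
imputed. Only definite ADRs count in the 2×2 table.

Confidence intervals are two-sided Wilson score intervals (the score-test
inversion; well-behaved near 0 and 1), computed via statsmodels and
cross-checked in the tests against a bisection root-finder for the score
equation. Wilson was chosen because it reproduces the published intervals
(101/180 → 48.8–63.2); Clopper–Pearson and Wald are available behind
`ci_method`. Reports round to one decimal; the published tables appear
truncated rather than rounded in places (35.47 printed as 35.4), so tests
compare at ±0.1 percentage point.

## The synthetic cohort

The generator (`adrproxy.simulate`) states one world and keeps it fixed:

| parameter | default | why |
|---|---|---|
| `n_patients` | 1132 | size of the reference starter cohort |
| study window | 2000-01-01 – 2011-01-01 | reference follow-up window |
| prescription lengths | 30 d (0.4) / 90 d (0.6) | 90 days is the legal maximum supply in the source setting; a 30-day mix for titration/first fills |
| refill gap | exp(mean 7 d) capped at 90, plus a 3 % tail uniform on 91–180 d | renewals are mostly prompt; the long tail exercises the 3-vs-6-month reclassification |
| `adr_prob` | 0.30 | latent ADR prevalence consistent with a ~20 % definite-ADR rate after imperfect recording |
| `event_time_mean_days` | 180 (exposure days) | ADRs occur from weeks to years after start |
| `action_given_adr` | ARB 0.55 / other 0.12 / stop 0.18 / continue 0.15 | most ADR patients follow the guideline switch |
| `nonadr_discontinue_prob`, `action_given_no_adr` | 0.38; ARB 0.069 / other 0.233 / stop 0.698 | calibrated once so the 180-day category mix lands near the reference marginals (~16 % ARB, ~9 % other, ~21 % stop, ~54 % continuation) |
| recording | definite 0.62 / probable 0.20 / nothing 0.18 given ADR; 0.20 for non-ADR reasons | charts are incomplete; yields ≈0.55 definite PPV for ARB switchers |
| background events | probable 0.05 /yr, non-probable 0.02 /yr | chart noise (bronchitis, malaise, …) unrelated to the ACEI |
| censoring | death 0.04 /yr, move 0.06 /yr | produces death/moved continuer shares near the reference cohort |

Two design choices make a closed-form oracle possible. First, the intended
stop/switch event occurs after an exponential number of **covered**
(drug-exposed) days, identically distributed for ADR and non-ADR causes: a
drug-induced event should happen while the drug is taken, the chart note
therefore always falls inside the −180/+90 review window, and censoring
pre-emption cancels out of the Bayes ratio between causes. Second,
background chart events are homogeneous Poisson processes in time, so the
probability that one lands in a fixed-width window depends only on the
width. `expected_ppv` then enumerates (ADR yes/no → intended action →
index-event recording → background presence) and applies the precedence
rule, giving the exact conditional probability that a patient classified
into a group carries a class in a level.

The oracle is exact when the classification gap covers the refill-gap long
tail (gap ≥ 180 days here). Two residual mechanisms it ignores are
deliberately tiny: a case censored between the index date and the planned
switch dispensing is classified stop instead of switch (≈1 % of switchers,
shifting the stop-group ADR share by well under a standard error at the
tested sizes), and exit can truncate the switch window identically for both
causes. At a 90-day gap the long-tail renewals additionally split episodes
of true continuers — that is the stressor for the reclassification
behaviour, not an oracle setting.

What a green parameter-recovery test establishes: the episode builder,
classifier, adjudicator and tabulation compose to the generative
conditional probabilities at n = 20,000 within 3 binomial standard errors.
What it does not establish: realism of the world — real cohorts have
seasonal prescribing, dose changes, partial adherence, correlated
comorbidity and recording that depends on severity; none of that is
modelled, and age/sex are cosmetic covariates with no effect on the
mechanism.

The published contingency table (`table2_fixture`) is typed in verbatim,
including the cough/angioedema/other split of the definite ADRs, and is the
basis for the exact reproduction tests of the predictive-value tables; the
cohort-dependent published numbers (N = 1132 itself, sensitivity 91.8 %,
the 96 reclassified patients) are functions of the unavailable patient-level
data and are covered instead by the property-based checks above.

## Numerical and degenerate-input choices

- Supply duration rounds half-up with a 1-day minimum; a same-day renewal
  is always chained.
- Episode chaining, window membership and matching run on int64 day
  numbers; dates serialize as ISO-8601.
- Zero-denominator proportions raise (`UndefinedEstimateError`) rather than
  return NaN; empty groups are skipped in reports, so an empty dispensing
  file yields an empty (not failing) report bundle.
- A zero-duration matched control window still includes an event on the
  start day (closed window).
- `match_controls` ties (equal durations) break by patient id before the
  seeded random draw, so results are reproducible across platforms.
- Wilson bounds are clamped to exactly 0/1 at numerator 0/n (statsmodels
  returns ±1e-18-scale noise there).

## Known limitations

- The adjudication codes are inputs; disagreement between human reviewers,
  and the mapping from raw diagnoses to probable/non-probable, are outside
  the package.
- Dose changes and partial adherence are not modelled; supply duration is
  taken at face value.
- The matched design leaves long-duration cases unmatched when the
  continuer pool is exhausted; they are excluded from sensitivity/
  specificity, mirroring the reference design's "where possible" matching.
- Calendar-month gap arithmetic is intentionally unsupported (see above).
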