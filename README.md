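# adrproxy

Prescription databases record what was dispensed, not why treatment changed.
When a patient on an ACE inhibitor (ACEI) develops a cough or angioedema,
the chart may say so — the dispensing history only shows that the ACEI was
stopped or replaced. `adrproxy` implements and validates the
*prescription-pattern proxy* for ACEI-induced adverse drug reactions (ADRs):
it reconstructs ACEI treatment episodes from pharmacy dispensing records,
classifies every new user as continuing, stopping, switching to an
angiotensin receptor blocker (ARB) or switching to another antihypertensive,
and quantifies how well each pattern predicts an ADR documented in the
primary-care record. It is aimed at pharmacoepidemiologists who want to use
switching/stopping as an outcome (for example in pharmacogenetic studies of
ACEI intolerance) and need its operating characteristics.

## What it computes

**Treatment episodes.** Each prescription covers
`units_dispensed / daily_number` days (rounded half-up, minimum 1); the
*theoretical end date* is the first uncovered day. Prescriptions chain into
an episode while each renewal falls within a gap `g` (90 or 180 days by
default) of the running episode end; overlapping supply extends the episode
end as a running maximum.

**Patterns.** For a new user (first-ever ACEI on/after the study start, with
at least 182 days of prior observation), follow-up ending within `g` of the
episode end means *continuation*, subdivided by exit reason (end of study /
moved out / death). Otherwise the episode end is the *index date* and the
dispensings in the window `(index, index + g]` decide: ARB (ATC C09C/C09D)
→ switch-to-ARB; any beta blocker, calcium-channel blocker, diuretic or
other antihypertensive (C07/C08/C03/C02) → switch-to-other; nothing → stop.

**Adjudication.** Coded chart events in `[index − 180 d, index + 90 d]`
(continuers: the whole episode) give each patient one class by precedence:
definite ADR ≻ definite non-ADR ≻ probable ADR ≻ non-probable health
problem; no event ⇒ nothing mentioned (an ADR is then still possible).

**Accuracy.** With group size `N` and class counts `k`:

- PPV at level *definite* / *at-least-probable* / *at-least-possible* is
  `k_def / N`, `(k_def + k_prob) / N`, `(k_def + k_prob + k_nothing) / N`
  for each test-positive group; a cough-only PPV counts definite ADRs with
  the term "cough".
- NPV for a continuation subgroup is `(N − k_def) / N` (at-least-possible)
  or `(N − k_def − k_prob) / N` (at-least-probable).
- Sensitivity/specificity use a duration-matched design: each test-positive
  case is matched to an unused continuer who used the ACEI at least as long,
  the control is adjudicated from ACEI start over the case's duration, and
  only definite ADRs count: `sens = TP/(TP+FN)`, `spec = TN/(TN+FP)`.
- All proportions carry two-sided 95 % Wilson score intervals
  (Clopper–Pearson and Wald are available).

A synthetic-cohort generator (`adrproxy.simulate`) emulates the structure of
such data — renewal gaps with a long 90–180-day tail, latent ADRs that drive
switching, incomplete GP recording, censoring by death or moving — with
known ground truth and a closed-form expectation (`expected_ppv`) for the
pipeline PPVs, so every stage is testable end to end without any real data.

## Worked example

The published 6-month contingency table ships as a fixture, so the
predictive values can be recomputed directly from counts:

```python
from adrproxy import ppv, npv, table2_fixture
from adrproxy import AscertainmentLevel as L, PatternCategory as C

t = table2_fixture()                       # 1132 ACEI starters
print(ppv(t, C.SWITCH_ARB, L.DEFINITE))            # 56.1 % (48.8-63.2)
print(ppv(t, C.SWITCH_ARB, L.AT_LEAST_PROBABLE))   # 68.3 % (61.2-74.7)
print(ppv(t, C.SWITCH_ARB, L.AT_LEAST_POSSIBLE))   # 90.6 % (85.4-94.0)
print(ppv(t, C.SWITCH_ARB, L.DEFINITE, term_filter="cough"))  # 46.1 % (39.0-53.4)
print(npv(t, "CONTINUATION_TOTAL", L.AT_LEAST_POSSIBLE))      # 95.2 % (93.2-96.7)
```

Reading: 56.1 % of patients who switched from an ACEI to an ARB had a
definite ADR documented in their chart — the strongest proxy of all the
patterns — and 95.2 % of continuers had no definite ADR, so switching to an
ARB is a usable outcome definition while stopping alone (PPV 19.5 %) is not.

The same numbers come out of the command line, end to end on synthetic
data:

```bash
adrproxy simulate --seed 1 --out cohort/
adrproxy report --config config.yaml          # counts/metrics/durations/reclassification CSVs
adrproxy validate --counts counts.csv --out out/   # counts mode, no patient data needed
```

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
re-runs both entry modes from scratch: the counts-mode reproduction of the
predictive-value tables from the published contingency counts, and a
seeded synthetic cohort through starter identification, both gap settings,
adjudication, tabulation and the matched sensitivity/specificity design,
writing its JSON result to `--out`.

## Layout

- `adrproxy.episodes` — ATC classing, theoretical end dates, episode
  chaining, starter inclusion, pattern classification, gap reclassification
- `adrproxy.adjudication` — chart-event precedence, review windows,
  ascertainment levels
- `adrproxy.metrics` — contingency table, PPV/NPV, Wilson intervals,
  duration matching, sensitivity/specificity
- `adrproxy.simulate` — synthetic cohorts, closed-form PPV oracle, the
  published-table fixture
- `adrproxy.io`, `adrproxy.pipeline`, `adrproxy.cli` — CSV dialects, the
  report bundle, the `adrproxy` command

See `docs/methods.md` for the model, its assumptions and the numerical
choices.
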