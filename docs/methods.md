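# Methods

## Medication-history generation (era merging)

The exposure model treats prescription orders for one patient and one
medicine as dispensations into a single stock of medicine consumed at a
constant rate. The unused-medicine index `u ≥ 1` (`umi`, default 1.4) is
the ratio of the period a patient actually takes a prescription to its
nominal period; equivalently the patient consumes `1/u` doses per calendar
day, so missing 2 doses in 7 gives `u = 1/(1 − 2/7) = 1.4`.

All dates are calendar dates; a prescription of `n` days starting on day
`s` nominally covers the closed interval `[s, s + n − 1]` (a 1-day supply
covers exactly its start day). Orders are processed chronologically while
tracking the exact stock balance

```
remaining = dispensed − era_span / u
```

where `era_span` counts every day from the era start through the nominal
end of the last merged order, bridged gap days included. A following order
at gap `G = next_start − current_end − 1`:

- merges unconditionally when `G ≤ 0` (overlap or contiguity); overlapping
  coverage automatically accrues as stock because dispensed supply grows
  while the span does not;
- merges when `G ≥ 1` and `remaining × u ≥ G` ("the stock on hand covers
  the gap's consumption"), with the comparison inclusive;
- otherwise closes the era, recording `remaining` as `surplus_days`, and
  opens a new era at the next order. Surplus never carries across a closed
  era and never extends an era's end date: era boundaries always coincide
  with nominal order dates.

The balance is kept in exact rational arithmetic (`fractions.Fraction`), so
boundary ties such as `remaining × u = G` are decided exactly rather than
by floating-point accident. This span-based bookkeeping is provably
identical to a day-by-day simulation that dispenses `days_supply` doses at
each order start and consumes `1/u` per day (`mhg.stock_oracle`, kept in
the package purely as an independent cross-check); the test suite asserts
equality of merge decisions on randomized streams. A per-increment
formulation that credits overlap days and per-order missed-dose surplus
separately double-counts the missed-dose fraction over overlap days, which
is why the span form is used.

Same-day orders are treated as contiguous with supplies summed. Output is
invariant to input permutation (orders are sorted internally, ties broken
deterministically).

## Detection criteria

For one patient × era, with `ULN_ALT = 40 IU/L` by default:

1. **Elevation** — peak ALT in `[start, min(start + 90 d, end)]` strictly
   `> ULN` and `≥ 2 ×` baseline, where baseline is the value on the latest
   date strictly before the era start (unbounded look-back; if several
   values share that date the largest is used). The 90-day peak window is
   clipped at the era end so that elevation is always an on-drug finding;
   the window length is configurable (`peak_window_days`).
2. **Dechallenge** — minimum ALT in `(end, end + 30 d]` either `< 0.5 ×`
   the on-drug maximum or `< ULN`.
3. **Exclusion: on-drug resolution** — minimum ALT in `(peak_date, end]`
   either `< 0.25 × peak` or `< ULN`. The window is deliberately restricted
   to the medication period: extending it past the era end would overlap
   the dechallenge window and make criteria 2 and 3 contradict each other
   for every recovering patient. Vacuously not excluded when no post-peak
   on-drug ALT exists.
4. **Exclusion: non-drug causes** — any ICD-10 diagnosis with prefix F10,
   K70–K77 or K80–K87 (patient-level, any date), any positive viral
   serology (HAV IgM, HBsAg, HCV core antigen, CMV, EBV; patient-level,
   any date), or a surgery dated in `[peak − 14 d, peak]`.

Strict vs. inclusive inequalities follow the criterion statements exactly
(`>` strict, `≥` inclusive); an ALT dated on the era end counts as
"during", not "after". Eligibility requires at least one ALT in each of
the before/during/after windows; ineligible eras contribute to neither
numerator nor denominator. A patient with several eras of one medicine is
assessed per era and counted once — eligible if any era is, event-positive
if any era is, banded by the worst positive era. Severity uses the on-drug
maximum: mild `> ULN`, moderate `≥ 80`, severe `≥ 200 IU/L`; the mild
boundary is exclusive (a maximum exactly at ULN is no event) while the
moderate/severe cut points are inclusive.

## Hepatocellular screen

`R = (ALT/ULN_ALT) / (ALP/ULN_ALP)` with the maximum ALT within 90 days of
the era start; the screen passes when `ALT > 200 IU/L` and `R > 5`. The
standard direction of the ratio (ALT term in the numerator) is
implemented. ALT and ALP are paired by taking the ALP measurement nearest
in time to the maximal ALT within the same window (ties toward the earlier
ALP); with no in-window ALP the screen cannot pass and the era is flagged
untested, which is why the ALP-coverage statistic (`alp_testing_rate`)
accompanies screen output. An ALP of 0 makes the ratio undefined; the
result is flagged degenerate and not passed. Full RUCAM scoring is out of
scope: it requires chart-review items (concomitant drugs, rechallenge,
alcohol history) that have no structured representation in the schema.

## Statistics

`rate` keeps the exact proportion (`fractions.Fraction`) and renders
percentages with decimal half-up rounding at 2 decimals, so printed rates
are reproducible without binary-float drift for denominators up to 10^7.

The two-sided Fisher exact p-value is the point-probability definition —
the sum of hypergeometric probabilities of all same-margin tables whose
point probability does not exceed the observed table's (scipy's
implementation stands behind the module surface). Degenerate margins give
p = 1 with a warning. The test suite validates it against a brute-force
enumeration oracle in exact rational arithmetic over every 2×2 table with
total ≤ 60 (via symmetry-class representatives plus verified row/column
swap invariance).

The Ryan step-down procedure for k proportions orders groups by observed
rate and tests the pair spanning `r` ordered positions at
`α′(r) = 2α / (k(r − 1))`, so the extreme pair runs at the
Bonferroni-over-all-pairs level `α/(k(k−1)/2)` and adjacent pairs at
`2α/k`. Coherence is enforced: an inner pair is tested only when every
enclosing pair was significant; skipped pairs are reported as untested and
non-significant. With k = 2 the procedure reduces to a single Fisher test
at α. Both raw p-values and adjusted levels appear in output, since
significance marks may be read against either.

## Synthetic cohort generator

The generator emulates the intermediate-database tables a hospital EMR
would yield, with a per-exposure ground-truth table the pipeline never
sees. Defaults (all overridable on `SimulationConfig`):

- 500 patients; exposure probabilities 0.55/0.25/0.20 for three
  antiplatelet-like medicines; 1–3 courses per exposure separated by
  cessation gaps of 90–210 days; orders per course geometric with mean 6
  (capped at 15); days of supply 7/14/28/30 with weights .2/.3/.3/.2.
- Daily missed-dose probability `p_miss = 2/7`, so the true UMI is 1.4.
  Refills arrive when the stretched supply (`ceil(n × u_true)` days) is
  nearly exhausted, 1–4 days early — patients reorder shortly before
  running out. This makes era reconstruction a genuine inverse problem:
  the configured `umi` must match the generator's adherence for gap
  bridging to recover course boundaries, and reconstruction degrades both
  when `umi` is set too low (courses fragment) and too high (cessation
  gaps are bridged).
- Baseline ALT log-normal (median 20 IU/L, σ = 0.3) clipped to a healthy
  8–35 IU/L; ALP log-normal (median 150 IU/L, σ = 0.2); multiplicative
  measurement noise σ = 0.08; draws before start (day −45…−5), on-drug
  every ~14 days, and at 10/20/30 days post-cessation, each missed with
  probability 0.15; ALP accompanies a draw with probability 0.75.
- Injury episodes injected per course with probability 0.05 (courses
  shorter than ~34 days cannot host one): onset uniform on days 14–60,
  peak 1.5–15 × ULN reached over a 10-day rise, an on-drug plateau of
  0.5–0.9 × peak (never below ULN), and post-cessation exponential decay
  toward baseline with a 7-day half-life. Variants: on-drug-resolving
  (ALT back to baseline 10 days after the peak while still exposed;
  suppressed by criterion 3) and confounded (the same trajectory plus a
  liver/alcohol ICD-10 code, a positive serology, or a surgery within 14
  days before the peak; suppressed by criterion 4). Background confounders
  (liver codes 2%, positive serologies 2%, surgeries 3%, benign diagnoses
  30%) attach to random patients.
- `expected_detection` in the truth table is computed from the generator's
  own trajectory values and confounder assignments in plain arithmetic,
  independent of the rule-engine code, so recall measured against it is a
  genuine two-implementation cross-check.
- `ideal_sampling=True` switches to the noiseless verification regime: one
  exposure of one medicine per patient, contiguous refills, exact
  trajectory values, and guaranteed draws in every eligibility window
  (baseline at day −7, era start, peak day, post-peak trough, era end,
  end + 14). Under this regime detection recall is exactly 1.0 with zero
  false positives, and era reconstruction is exact.

What the generator does **not** emulate: real demographic structure or
absolute per-medicine event rates (these depend on unavailable EMR data),
concomitant-medicine confusion (ideal mode isolates exposures; the method
cannot attribute causality among co-prescribed drugs in any case),
cholestatic or delayed injury, dose titration, or within-day dosing.
Passing tests therefore demonstrate internal correctness of the era
algebra, the windowing and the rule logic — not clinical accuracy on real
records.

Determinism: a single `numpy` generator seeded from `SimulationConfig.seed`
drives everything; identical configs produce byte-identical CSV output.

## Numerical and degenerate-input choices

- Stock arithmetic and proportions in exact rationals; no tolerance knobs.
- Peak date ties resolve to the earliest date attaining the maximum;
  nearest-ALP ties resolve to the earlier measurement.
- Empty lab windows yield absent features and ineligibility, never errors;
  empty era lists and zero denominators are errors.
- Problem sizes in the test and acceptance runs (500-patient ideal cohort,
  300-patient adherence cohort, 200 random order streams, Fisher
  enumeration to total 60, 5000-day adherence trace) were chosen so each
  suite exercises its property at convincing scale while the whole run
  stays comfortably fast.

## Known limitations

- The UMI is global; the original calibration of 1.4 against chart review
  is not reproducible from structured data and is not re-derived here.
- Criterion 3's window is a design resolution of an ambiguity (see above);
  it is configurable only through the window primitives, not as an
  alternative rule.
- The screen pairs each era's single maximal ALT with one ALP; scanning
  all qualifying ALT–ALP pairs in the window is a possible alternative
  reading and would only ever pass more eras.
- Reported per-medicine rates are upper bounds on causal rates: every
  qualifying chronology is attributed to the medicine under assessment.
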