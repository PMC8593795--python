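# dilidetect

Rule-based detection of adverse drug events (ADEs) with serum ALT elevation
from electronic-medical-record data, built on a reconstructed *medication
history*: per-patient, per-medicine exposure eras merged from raw
computer-physician-order-entry (CPOE) prescription records.

The package is for pharmacoepidemiologists and medical informaticians who
have flat extracts of prescription orders, laboratory results, ICD-10
diagnoses and surgery dates, and want to (1) determine when each patient was
actually on each medicine, (2) flag hepatocellular-injury-type events from
the chronological relationship between the exposure era and the ALT
trajectory, and (3) compare event rates between medicines.

## The model

**Medication history generation.** A CPOE system records one row per
prescription, not the exposure span. Overlapping refills leave surplus
medicine, and missed doses stretch a prescription over more days than it
nominally covers. The *unused-medicine index* (UMI, default 1.4) models
adherence as a constant ratio of actual consumption period to nominal
prescription period: a patient consumes one dose per `u` days, so an
`n`-day supply leaves `n(u-1)/u` doses unconsumed at its nominal end. Two
consecutive orders separated by a gap of `G` uncovered days merge into one
era when the estimated remaining medicine covers the gap's consumption:

```
remaining × u ≥ G        (remaining = dispensed − era_span/u)
```

Overlapping or contiguous orders always merge. Era boundaries come from
nominal order dates only; surplus is bookkept but never extends an era.

**Detection criteria.** For each patient × era, with ULN the upper limit of
normal (ALT 40 IU/L, ALP 200 IU/L):

1. *Elevation*: peak ALT within 90 days of era start `> ULN` and
   `≥ 2 ×` the last pre-exposure ALT.
2. *Dechallenge*: lowest ALT within 30 days after the era `< 0.5 × max
   on-drug ALT` or `< ULN`.
3. *Exclusion — on-drug resolution*: an ALT after the peak but still
   on-drug `< 0.25 × peak` or `< ULN`.
4. *Exclusion — non-drug causes*: ICD-10 F10 / K70–K77 / K80–K87 at any
   date, a positive viral serology (HAV IgM, HBsAg, HCV core antigen, CMV,
   EBV), or surgery within 14 days before the peak.

A patient is *eligible* only if ALT was tested before, during and after the
era; severity is banded on the on-drug maximum (mild > ULN, moderate
≥ 80 IU/L, severe ≥ 200 IU/L). Per-medicine rates are compared with the
two-sided Fisher exact test under the Ryan step-down procedure
(`α′(r) = 2α / (k(r−1))`). A RUCAM-style hepatocellular screen
(`ALT > 200 IU/L` and `R = (ALT/ULN_ALT)/(ALP/ULN_ALP) > 5` within 90 days
of era start) is included for cross-method comparison.

Because real EMR extracts cannot be redistributed, the package ships a
synthetic cohort generator (`dilidetect.synth_cohort`) that emulates refill
streams, ALT/ALP sampling and injected injury episodes with a ground-truth
table, so the whole pipeline is testable end to end.

## Worked example

```
dilidetect simulate --seed 5 --n-patients 300 --outdir data/
dilidetect generate-history --orders data/orders.csv --out out/history.csv
dilidetect detect-ade --history out/history.csv --labs data/labs.csv \
    --diagnoses data/diagnoses.csv --surgeries data/surgeries.csv \
    --out out/assessments.csv --counts out/counts.csv
dilidetect report --counts out/counts.csv --out out/report.txt
```

`out/report.txt` then contains:

```
ADE with ALT elevation: per-medicine rates

medicine          eligible     ADE      rate    >=80   >=200
M_ASA                  149       8     5.37%       8       7
M_CLO                   75       1     1.33%       1       1
M_TIC                   55       4     7.27%       4       3

Ryan step-down multiple comparisons (alpha=0.05):
  M_CLO vs M_TIC: p=0.1618 (alpha'=0.01667)
  M_CLO vs M_ASA: skipped (coherence) (alpha'=0.03333)
  M_ASA vs M_TIC: skipped (coherence) (alpha'=0.03333)
```

Reading: of the 149 patients with an aspirin-like exposure era and ALT
tested before/during/after it, 8 met all four criteria (5.37%), 7 of them
with a maximum on-drug ALT ≥ 200 IU/L. With these small counts no pairwise
difference is significant — the extreme pair (lowest vs highest observed
rate) is tested first at `α′ = 2α/(k(r−1)) = 0.0167` and, being
non-significant, the inner pairs are skipped by step-down coherence.

The same operations are available as a library:

```python
from dilidetect import StudyConfig, generate_history, rate
cfg = StudyConfig()                  # UMI 1.4, ULN 40/200, windows 90/30/14
eras = generate_history(orders, cfg)
print(rate(868, 26059))              # 3.33%
```

## Layout

- `dilidetect.io_schema` — record types, CSV I/O, config validation
- `dilidetect.mhg` — medication-history generation (era merging) + stock oracle
- `dilidetect.ade_rules` — the four-criterion rule engine and cohort counts
- `dilidetect.rucam_screen` — hepatocellular screen and ALP coverage
- `dilidetect.stats` — rates, Fisher exact, Ryan step-down
- `dilidetect.synth_cohort` — synthetic EMR generator with ground truth
- `dilidetect.cli` — the `dilidetect` command
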