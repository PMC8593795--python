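"""Rule engine for adverse drug events with ALT elevation.

A medication era is judged against four criteria based on the chronological
relationship between the era and the patient's serum ALT values:

1. *Elevation after initiation* — the peak ALT within 90 days of the era
   start exceeds the upper limit of normal (ULN) and is at least twice the
   last pre-medication ALT.
2. *Decrease after cessation (dechallenge)* — the lowest ALT within 30 days
   after the era ends falls below half the on-drug maximum or below ULN.
3. *Exclusion: on-drug resolution* — the ALT already fell below a quarter
   of the peak (or below ULN) while still on the medicine, so the medicine
   is unlikely causative.
4. *Exclusion: non-drug causes* — prior alcohol/liver/biliary diagnoses
   (ICD-10 F10, K70-K77, K80-K87), positive viral serologies (HAV IgM,
   HBsAg, HCV core antigen, CMV, EBV), or surgery within 14 days before
   the peak.

A patient is eligible for assessment only if ALT was tested before, during,
and after the medication period. Severity is banded on the on-drug maximum
ALT: mild (> ULN), moderate (>= 80 IU/L), severe (>= 200 IU/L).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .io_schema import (
    DiagnosisRecord,
    LabResult,
    MedicationHistoryRecord,
    StudyConfig,
    SurgeryRecord,
)

__all__ = [
    "AltFeatures",
    "ADEAssessment",
    "CohortCounts",
    "extract_alt_features",
    "criterion1_elevation",
    "criterion2_recovery",
    "criterion3_decrease_during",
    "criterion4_nondrug_causes",
    "classify_severity",
    "assess_patient",
    "assess_cohort",
    "compute_cohort_counts",
]

SEVERITY_LEVELS = ("none", "mild", "moderate", "severe")


@dataclass(frozen=True)
class AltFeatures:
    """ALT landmarks extracted from one era's lab trajectory.

    All windows are closed on stated endpoints; an ALT dated exactly on the
    era end counts as "during", not "after".
    """

    baseline_alt: Optional[float]  # latest ALT strictly before era start
    peak_alt: Optional[float]  # max ALT in [start, min(start+90d, end)]
    peak_date: Optional[dt.date]
    max_alt: Optional[float]  # max ALT in [start, end]
    alt_after: Optional[float]  # min ALT in (end, end+30d]
    alt_during_post_peak: Optional[float]  # min ALT in (peak_date, end]
    tested_before: bool
    tested_during: bool
    tested_after: bool

    @property
    def eligible(self) -> bool:
        return self.tested_before and self.tested_during and self.tested_after


@dataclass(frozen=True)
class ADEAssessment:
    patient_id: str
    medicine_code: str
    era: MedicationHistoryRecord
    features: AltFeatures
    eligible: bool
    criterion1: bool
    criterion2: bool
    criterion3_excluded: bool
    criterion4_excluded: bool
    criterion4_reasons: Tuple[str, ...]
    is_ade: bool
    severity: str

    def __post_init__(self):
        if self.severity not in SEVERITY_LEVELS:
            raise ValueError(f"unknown severity {self.severity!r}")


def extract_alt_features(
    era: MedicationHistoryRecord,
    alt_results: Sequence[LabResult],
    config: StudyConfig,
) -> AltFeatures:
    """Locate the baseline, peak, on-drug maximum and recovery ALT values.

    ``alt_results`` must all belong to the era's patient; only ALT rows are
    considered. Absent windows yield absent features (and ineligibility)
    rather than errors.
    """
    start, end = era.start_date, era.end_date
    peak_end = min(start + dt.timedelta(days=config.peak_window_days), end)
    after_end = end + dt.timedelta(days=config.post_cessation_window_days)

    alts = sorted(
        ((r.date, r.value) for r in alt_results if r.test_code == "ALT"),
        key=lambda t: t[0],
    )

    before = [(d, v) for d, v in alts if d < start]
    during = [(d, v) for d, v in alts if start <= d <= end]
    after = [(d, v) for d, v in alts if end < d <= after_end]
    peak_window = [(d, v) for d, v in during if d <= peak_end]

    baseline = None
    if before:
        last_day = before[-1][0]
        baseline = max(v for d, v in before if d == last_day)

    peak_alt = peak_date = None
    if peak_window:
        peak_alt = max(v for _, v in peak_window)
        peak_date = min(d for d, v in peak_window if v == peak_alt)

    max_alt = max((v for _, v in during), default=None)
    alt_after = min((v for _, v in after), default=None)
    alt_during_post_peak = None
    if peak_date is not None:
        post_peak = [v for d, v in during if d > peak_date]
        alt_during_post_peak = min(post_peak, default=None)

    return AltFeatures(
        baseline_alt=baseline,
        peak_alt=peak_alt,
        peak_date=peak_date,
        max_alt=max_alt,
        alt_after=alt_after,
        alt_during_post_peak=alt_during_post_peak,
        tested_before=bool(before),
        tested_during=bool(during),
        tested_after=bool(after),
    )


def criterion1_elevation(
    baseline_alt: Optional[float], peak_alt: Optional[float], config: StudyConfig
) -> bool:
    """Peak ALT > ULN and peak ALT >= baseline x 2 (strict/inclusive as stated)."""
    if baseline_alt is None or peak_alt is None:
        return False
    return peak_alt > config.uln_alt and peak_alt >= baseline_alt * config.baseline_multiplier


def criterion2_recovery(
    max_alt: Optional[float], alt_after: Optional[float], config: StudyConfig
) -> bool:
    """Post-cessation ALT < max ALT x 0.5, or below ULN (dechallenge)."""
    if max_alt is None or alt_after is None:
        return False
    return (
        alt_after < max_alt * config.recovery_fraction_after
        or alt_after < config.uln_alt
    )


def criterion3_decrease_during(
    peak_alt: Optional[float],
    alt_during_post_peak: Optional[float],
    config: StudyConfig,
) -> bool:
    """Excluded if ALT fell below peak x 0.25 or below ULN while still on drug.

    Vacuously not excluded when no ALT exists between the peak and the era
    end.
    """
    if peak_alt is None or alt_during_post_peak is None:
        return False
    return (
        alt_during_post_peak < peak_alt * config.recovery_fraction_during
        or alt_during_post_peak < config.uln_alt
    )


def criterion4_nondrug_causes(
    diagnoses: Sequence[DiagnosisRecord],
    serologies: Sequence[LabResult],
    surgeries: Sequence[SurgeryRecord],
    peak_date: Optional[dt.date],
    config: StudyConfig,
) -> Tuple[bool, Tuple[str, ...]]:
    """Excluded for prior liver diagnoses, positive serologies, or recent surgery.

    Diagnosis and serology exclusions apply patient-level at any date; the
    surgery exclusion applies within ``surgery_lookback_days`` before the
    peak ALT date (inclusive on both ends).
    """
    reasons: List[str] = []
    prefixes = tuple(config.exclusion_icd10_prefixes)
    if any(d.icd10_code.startswith(prefixes) for d in diagnoses):
        reasons.append("prior-liver-disease")
    if any(
        r.test_code in config.serology_codes and r.is_positive for r in serologies
    ):
        reasons.append("viral-hepatitis")
    if peak_date is not None:
        lo = peak_date - dt.timedelta(days=config.surgery_lookback_days)
        if any(lo <= s.date <= peak_date for s in surgeries):
            reasons.append("recent-surgery")
    return bool(reasons), tuple(reasons)


def classify_severity(max_alt: Optional[float], config: StudyConfig) -> str:
    """Band the on-drug maximum ALT: severe >= 200, moderate >= 80, mild > ULN."""
    if max_alt is None:
        return "none"
    if max_alt >= config.severe_threshold:
        return "severe"
    if max_alt >= config.moderate_threshold:
        return "moderate"
    if max_alt > config.uln_alt:
        return "mild"
    return "none"


def assess_patient(
    era: MedicationHistoryRecord,
    labs: Sequence[LabResult],
    diagnoses: Sequence[DiagnosisRecord],
    surgeries: Sequence[SurgeryRecord],
    config: StudyConfig,
) -> ADEAssessment:
    """Apply all four criteria to one patient x medication era.

    ``labs``, ``diagnoses`` and ``surgeries`` must all belong to the era's
    patient. Deterministic: identical inputs give identical assessments.
    """
    pid = era.patient_id
    for recs in (labs, diagnoses, surgeries):
        for r in recs:
            if r.patient_id != pid:
                raise ValueError(
                    f"record for patient {r.patient_id!r} passed to assessment of {pid!r}"
                )
    feats = extract_alt_features(era, labs, config)
    c1 = criterion1_elevation(feats.baseline_alt, feats.peak_alt, config)
    c2 = criterion2_recovery(feats.max_alt, feats.alt_after, config)
    c3 = criterion3_decrease_during(feats.peak_alt, feats.alt_during_post_peak, config)
    c4, reasons = criterion4_nondrug_causes(
        diagnoses, labs, surgeries, feats.peak_date, config
    )
    is_ade = feats.eligible and c1 and c2 and not c3 and not c4
    severity = classify_severity(feats.max_alt, config) if is_ade else "none"
    return ADEAssessment(
        patient_id=pid,
        medicine_code=era.medicine_code,
        era=era,
        features=feats,
        eligible=feats.eligible,
        criterion1=c1,
        criterion2=c2,
        criterion3_excluded=c3,
        criterion4_excluded=c4,
        criterion4_reasons=reasons,
        is_ade=is_ade,
        severity=severity,
    )


def assess_cohort(
    histories: Sequence[MedicationHistoryRecord],
    labs: Sequence[LabResult],
    diagnoses: Sequence[DiagnosisRecord],
    surgeries: Sequence[SurgeryRecord],
    config: StudyConfig,
) -> List[ADEAssessment]:
    """Assess every medication era, grouping the patient-level records once."""
    by_pat_labs: Dict[str, List[LabResult]] = {}
    for r in labs:
        by_pat_labs.setdefault(r.patient_id, []).append(r)
    by_pat_dx: Dict[str, List[DiagnosisRecord]] = {}
    for d in diagnoses:
        by_pat_dx.setdefault(d.patient_id, []).append(d)
    by_pat_surg: Dict[str, List[SurgeryRecord]] = {}
    for s in surgeries:
        by_pat_surg.setdefault(s.patient_id, []).append(s)
    return [
        assess_patient(
            era,
            by_pat_labs.get(era.patient_id, ()),
            by_pat_dx.get(era.patient_id, ()),
            by_pat_surg.get(era.patient_id, ()),
            config,
        )
        for era in histories
    ]


@dataclass(frozen=True)
class CohortCounts:
    medicine_code: str
    n_eligible: int
    n_ade: int
    n_ade_moderate_or_worse: int
    n_ade_severe: int

    def __post_init__(self):
        if not (
            self.n_ade_severe
            <= self.n_ade_moderate_or_worse
            <= self.n_ade
            <= self.n_eligible
        ):
            raise ValueError("severity counts must be nested within eligible count")


def compute_cohort_counts(
    assessments: Sequence[ADEAssessment], config: StudyConfig
) -> Dict[str, CohortCounts]:
    """Per-medicine eligible denominators and severity-stratified ADE counts.

    A patient with multiple eras of the same medicine counts once: eligible
    if any era is eligible, ADE-positive if any era is positive, banded by
    the worst positive era.
    """
    per_patient: Dict[Tuple[str, str], Dict[str, bool | str]] = {}
    sev_rank = {s: i for i, s in enumerate(SEVERITY_LEVELS)}
    for a in assessments:
        key = (a.medicine_code, a.patient_id)
        slot = per_patient.setdefault(
            key, {"eligible": False, "ade": False, "severity": "none"}
        )
        slot["eligible"] = slot["eligible"] or a.eligible
        if a.is_ade:
            slot["ade"] = True
            if sev_rank[a.severity] > sev_rank[slot["severity"]]:
                slot["severity"] = a.severity
    out: Dict[str, CohortCounts] = {}
    for med in sorted({m for m, _ in per_patient}):
        slots = [v for (m, _), v in per_patient.items() if m == med]
        eligible = [s for s in slots if s["eligible"]]
        ades = [s for s in eligible if s["ade"]]
        out[med] = CohortCounts(
            medicine_code=med,
            n_eligible=len(eligible),
            n_ade=len(ades),
            n_ade_moderate_or_worse=sum(
                1 for s in ades if s["severity"] in ("moderate", "severe")
            ),
            n_ade_severe=sum(1 for s in ades if s["severity"] == "severe"),
        )
    return out
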