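"""Primary screening for hepatocellular-pattern liver injury (RUCAM-style).

The hepatocellular pattern is defined by the R ratio
``R = (ALT / ULN_ALT) / (ALP / ULN_ALP)``; a candidate passes the screen
when the maximum ALT within 90 days of the era start exceeds 200 IU/L and
R > 5 for that ALT paired with the nearest-in-time ALP in the same window.
Full RUCAM scoring (concomitant drugs, rechallenge, alcohol history) needs
chart data outside the structured schema and is out of scope; only this
screening criterion and the ALP-testing-coverage statistic are provided.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

from .io_schema import LabResult, MedicationHistoryRecord, StudyConfig

__all__ = ["ScreenResult", "screen_hepatocellular", "alp_testing_rate"]


@dataclass(frozen=True)
class ScreenResult:
    patient_id: str
    medicine_code: str
    passed: bool
    alt_value: Optional[float]
    alt_date: Optional[dt.date]
    alp_value: Optional[float]
    r_ratio: Optional[float]
    alp_tested_in_window: bool
    degenerate: bool = False  # ALP of 0 makes the ratio undefined

    def __post_init__(self):
        if self.passed and (self.r_ratio is None or self.alt_value is None):
            raise ValueError("a passing screen requires ALT and R values")


def _window(era: MedicationHistoryRecord, config: StudyConfig) -> Tuple[dt.date, dt.date]:
    return era.start_date, era.start_date + dt.timedelta(days=config.peak_window_days)


def screen_hepatocellular(
    era: MedicationHistoryRecord,
    labs: Sequence[LabResult],
    config: StudyConfig,
) -> ScreenResult:
    """Screen one era: max in-window ALT > 200 IU/L and R ratio > 5.

    The R ratio pairs the maximum ALT with the ALP measurement nearest in
    time within the same 90-day window. With no in-window ALP the screen
    cannot pass and ``alp_tested_in_window`` is False.
    """
    lo, hi = _window(era, config)
    alts = [
        (r.date, r.value)
        for r in labs
        if r.test_code == "ALT" and lo <= r.date <= hi
    ]
    alps = [
        (r.date, r.value)
        for r in labs
        if r.test_code == "ALP" and lo <= r.date <= hi
    ]
    if not alts:
        return ScreenResult(
            era.patient_id, era.medicine_code, False, None, None, None, None, bool(alps)
        )
    alt_value = max(v for _, v in alts)
    alt_date = min(d for d, v in alts if v == alt_value)
    if not alps:
        return ScreenResult(
            era.patient_id, era.medicine_code, False, alt_value, alt_date, None, None, False
        )
    # nearest-in-time ALP; ties broken toward the earlier measurement
    alp_date, alp_value = min(
        alps, key=lambda t: (abs((t[0] - alt_date).days), t[0])
    )
    if alp_value == 0:
        return ScreenResult(
            era.patient_id,
            era.medicine_code,
            False,
            alt_value,
            alt_date,
            alp_value,
            None,
            True,
            degenerate=True,
        )
    r_ratio = (alt_value / config.uln_alt) / (alp_value / config.uln_alp)
    passed = alt_value > config.rucam_alt_threshold and r_ratio > config.rucam_r_threshold
    return ScreenResult(
        era.patient_id,
        era.medicine_code,
        passed,
        alt_value,
        alt_date,
        alp_value,
        r_ratio,
        True,
    )


def alp_testing_rate(
    eras: Sequence[MedicationHistoryRecord],
    labs: Sequence[LabResult],
    config: StudyConfig,
) -> Tuple[int, int, float]:
    """Fraction of eras with at least one ALP test within 90 days of start.

    Returns ``(n_with_alp, n_total, percentage)`` with the percentage
    rounded half-up to 2 decimals. Low ALP coverage starves the R ratio and
    blinds the hepatocellular screen, so this statistic qualifies screen
    results per site.
    """
    if not eras:
        raise ValueError("era list must be non-empty")
    from .stats import rate

    alp_by_patient: dict[str, list[dt.date]] = {}
    for r in labs:
        if r.test_code == "ALP":
            alp_by_patient.setdefault(r.patient_id, []).append(r.date)
    n_with = 0
    for era in eras:
        lo, hi = _window(era, config)
        if any(lo <= d <= hi for d in alp_by_patient.get(era.patient_id, ())):
            n_with += 1
    return n_with, len(eras), rate(n_with, len(eras)).percent
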