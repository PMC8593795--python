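"""Medication-history generation: merging prescription orders into eras.

CPOE systems record one row per prescription, so the true span of drug
exposure has to be reconstructed: overlapping refills leave surplus
medicine on hand, and patients who skip doses stretch a prescription over
more calendar days than it nominally covers. The unused-medicine index
(UMI) models the second effect as a constant ratio of actual consumption
period to nominal prescription period — a patient with UMI ``u`` consumes
one dose every ``u`` days on average, so an ``n``-day supply leaves
``n*(u-1)/u`` doses unconsumed at its nominal end.

Two consecutive orders separated by a gap of ``G`` uncovered days are
combined into one era when the estimated remaining medicine is at least
what the gap would consume, ``remaining >= G/u`` (equivalently
``remaining * u >= G``). Overlapping or contiguous orders always combine.
Era boundaries come from nominal order dates only: surplus never extends
an era's end date, and surplus does not carry across a closed era.

The stock model is kept in exact rational arithmetic so merge decisions
have no floating-point ties; :func:`stock_oracle` re-derives the same
decisions by brute-force day-by-day simulation and exists purely as an
independent cross-check.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from fractions import Fraction
from typing import Dict, Iterable, List, Sequence, Tuple

from .io_schema import MedicationHistoryRecord, PrescriptionOrder, StudyConfig

__all__ = [
    "generate_history",
    "generate_all_histories",
    "summarize_histories",
    "HistorySummary",
    "stock_oracle",
]

_ONE_DAY = dt.timedelta(days=1)


def _sorted_orders(orders: Sequence[PrescriptionOrder]) -> List[PrescriptionOrder]:
    # Deterministic under input permutation: ties on start_date broken by
    # supply then name; same-start orders merge as contiguous either way.
    return sorted(orders, key=lambda o: (o.start_date, o.days_supply, o.medicine_name))


def _check_single_stream(orders: Sequence[PrescriptionOrder]) -> None:
    if not orders:
        raise ValueError("orders must be non-empty")
    patients = {o.patient_id for o in orders}
    medicines = {o.medicine_code for o in orders}
    if len(patients) > 1 or len(medicines) > 1:
        raise ValueError(
            f"generate_history expects one patient and one medicine, got "
            f"patients={sorted(patients)} medicines={sorted(medicines)}"
        )


def generate_history(
    orders: Sequence[PrescriptionOrder], config: StudyConfig
) -> List[MedicationHistoryRecord]:
    """Merge one patient's orders for one medicine into medication eras.

    Orders are processed in chronological order while tracking the exact
    stock balance ``dispensed - era_span/umi`` (doses dispensed minus doses
    consumed at rate ``1/umi`` per day over the era's span so far, bridged
    gap days included). A gap of ``G >= 1`` uncovered days is bridged iff
    the balance at the current era end covers ``G/umi``; otherwise the era
    closes with the balance recorded as ``surplus_days`` and a new era
    opens at the next order.
    """
    _check_single_stream(orders)
    umi = Fraction(config.umi)
    ordered = _sorted_orders(orders)

    eras: List[MedicationHistoryRecord] = []
    first = ordered[0]
    era_start = first.start_date
    cur_end = first.nominal_end
    dispensed = first.days_supply
    n_orders = 1

    def _remaining() -> Fraction:
        span = (cur_end - era_start).days + 1
        return Fraction(dispensed) - Fraction(span) / umi

    def _close() -> None:
        eras.append(
            MedicationHistoryRecord(
                patient_id=first.patient_id,
                medicine_code=first.medicine_code,
                start_date=era_start,
                end_date=cur_end,
                n_orders_combined=n_orders,
                total_days_supply=dispensed,
                surplus_days=float(max(_remaining(), Fraction(0))),
            )
        )

    for o in ordered[1:]:
        gap = (o.start_date - cur_end).days - 1
        if gap <= 0 or _remaining() * umi >= gap:
            dispensed += o.days_supply
            cur_end = max(cur_end, o.nominal_end)
            n_orders += 1
        else:
            _close()
            era_start = o.start_date
            cur_end = o.nominal_end
            dispensed = o.days_supply
            n_orders = 1
    _close()
    return eras


def generate_all_histories(
    orders: Iterable[PrescriptionOrder],
    config: StudyConfig,
    medicine: str | None = None,
) -> List[MedicationHistoryRecord]:
    """Group orders by (patient, medicine) and merge each stream.

    Optionally restrict to a single medicine code. Output is sorted by
    patient, medicine, then era start date.
    """
    streams: Dict[Tuple[str, str], List[PrescriptionOrder]] = {}
    for o in orders:
        if medicine is not None and o.medicine_code != medicine:
            continue
        streams.setdefault((o.patient_id, o.medicine_code), []).append(o)
    out: List[MedicationHistoryRecord] = []
    for key in sorted(streams):
        out.extend(generate_history(streams[key], config))
    return out


@dataclass(frozen=True)
class HistorySummary:
    n_patients: int
    n_cpoe: int
    cpoe_per_patient: float  # mean, 1 decimal
    n_history_records: int
    history_per_patient: float  # mean, 1 decimal
    combination_ratio_pct: float  # history records / CPOE records, percent, 2 decimals


def summarize_histories(
    n_cpoe: int, n_patients: int, histories: Sequence[MedicationHistoryRecord] | int
) -> HistorySummary:
    """Cohort-level summary: orders per patient and the combination ratio.

    ``histories`` may be the list of era records or their count. The
    combination ratio (era records as a fraction of CPOE records) measures
    how aggressively orders were merged.
    """
    if n_patients <= 0:
        raise ValueError("patient count must be positive")
    if n_cpoe <= 0:
        raise ValueError("CPOE record count must be positive")
    n_hist = histories if isinstance(histories, int) else len(histories)
    from .stats import rate, round_half_up

    return HistorySummary(
        n_patients=n_patients,
        n_cpoe=n_cpoe,
        cpoe_per_patient=round_half_up(n_cpoe / n_patients, 1),
        n_history_records=n_hist,
        history_per_patient=round_half_up(n_hist / n_patients, 1),
        combination_ratio_pct=rate(n_hist, n_cpoe).percent,
    )


def stock_oracle(
    orders: Sequence[PrescriptionOrder], umi: float
) -> List[Tuple[dt.date, dt.date]]:
    """Day-by-day stock simulation; returns (start, end) era boundaries.

    Reference implementation used to validate :func:`generate_history`:
    walk the calendar one day at a time, dispensing ``days_supply`` doses
    at each order start and consuming ``1/umi`` doses per day; a break is
    declared on the first gap day whose consumption the stock cannot cover
    before the next order arrives. Era ends are the nominal last day of
    the last merged order.
    """
    _check_single_stream(orders)
    u = Fraction(umi)
    dose = 1 / u
    ordered = _sorted_orders(orders)
    eras: List[Tuple[dt.date, dt.date]] = []

    i = 0
    n = len(ordered)
    while i < n:
        era_start = ordered[i].start_date
        stock = Fraction(0)
        nominal_end = era_start - _ONE_DAY
        day = era_start
        j = i
        while True:
            while j < n and ordered[j].start_date == day:
                stock += ordered[j].days_supply
                nominal_end = max(nominal_end, ordered[j].nominal_end)
                j += 1
            if stock < dose:
                # Cannot take today's dose: the era lapsed yesterday at the
                # latest; its recorded end is the last nominal day.
                break
            stock -= dose
            if j >= n and day >= nominal_end:
                break
            day += _ONE_DAY
        eras.append((era_start, nominal_end))
        i = j
    return eras
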