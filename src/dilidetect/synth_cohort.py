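"""Synthetic EMR generator with ground truth for end-to-end validation.

Real CPOE and laboratory extracts cannot be redistributed, so every
pipeline stage is exercised on simulated intermediate-database tables. The
generator writes what the EMR would record — prescription orders with
refill overlaps and gaps, scheduled (and sometimes missed) ALT/ALP draws,
ICD-10 diagnoses, surgeries — and, separately, what truly happened (the
truth table). The detection pipeline only ever sees the former.

A patient exposed to a medicine receives one or more *courses* of therapy,
each a run of refill orders separated from the next course by a long
cessation gap. Within a course the patient misses a dose with daily
probability ``p_miss``, so an ``n``-day supply stretches over about
``n / (1 - p_miss)`` calendar days and refills arrive late relative to the
nominal coverage — exactly the behaviour the unused-medicine index models
(true UMI = ``1/(1 - p_miss)``).

Hepatocellular injury episodes are injected per course with probability
``p_dili``: serum ALT rises to a peak within the first 90 days, stays
elevated on-drug, and decays exponentially toward baseline after
cessation. Variants exercise the exclusion criteria: an on-drug-resolving
episode (ALT returns to baseline while still on the medicine) and a
confounded episode (the same trajectory plus a liver/alcohol ICD-10 code,
a positive viral serology, or a surgery shortly before the peak).

``ideal_sampling`` produces the noiseless, fully-sampled regime: one
course of contiguous orders per patient, exact trajectory values, and a
guaranteed ALT draw in each eligibility window — under which every
injected detectable episode must be flagged and nothing else.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .io_schema import (
    DiagnosisRecord,
    LabResult,
    PrescriptionOrder,
    StudyConfig,
    SurgeryRecord,
    write_table,
)

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "SimulatedCohort",
    "simulate_cohort",
    "adherence_trace",
    "AdherenceTrace",
]

EVENT_TYPES = ("none", "dili", "dili_on_drug_resolving", "confounded_dili")

_BENIGN_DX = ("I10", "E11.9", "J45", "M54.5")  # outside every exclusion range


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic cohort; defaults are the study conditions.

    ``p_miss`` defaults to 2/7 so the true unused-medicine index is
    1/(1 - 2/7) = 1.4, the value the detection pipeline assumes.
    """

    seed: int = 0
    n_patients: int = 500
    start_date: dt.date = dt.date(2020, 1, 1)
    enrollment_span_days: int = 365
    # (code, name, exposure probability)
    medicines: Tuple[Tuple[str, str, float], ...] = (
        ("M_ASA", "aspirin", 0.55),
        ("M_CLO", "clopidogrel", 0.25),
        ("M_TIC", "ticlopidine", 0.20),
    )
    orders_per_course_mean: float = 6.0  # geometric, support >= 1
    extra_course_prob: float = 0.3  # chance of each additional course
    max_courses: int = 3
    days_supply_choices: Tuple[int, ...] = (7, 14, 28, 30)
    days_supply_weights: Tuple[float, ...] = (0.2, 0.3, 0.3, 0.2)
    p_miss: float = 2.0 / 7.0  # daily missed-dose probability
    refill_delay_min: int = -4  # days relative to actual supply exhaustion
    refill_delay_max: int = -1  # patients refill shortly before running out
    cessation_gap_range: Tuple[int, int] = (90, 210)
    # lab model
    alt_baseline_median: float = 20.0
    alt_baseline_sigma: float = 0.3
    alt_baseline_clip: Tuple[float, float] = (8.0, 35.0)  # healthy range
    alp_baseline_median: float = 150.0
    alp_baseline_sigma: float = 0.2
    alt_noise_sigma: float = 0.08
    pre_start_draw_range: Tuple[int, int] = (5, 45)
    on_drug_interval_days: int = 14
    post_cessation_draw_days: Tuple[int, ...] = (10, 20, 30)
    p_lab_miss: float = 0.15
    alp_test_prob: float = 0.75
    # injury injection
    p_dili: float = 0.05
    onset_day_range: Tuple[int, int] = (14, 60)
    peak_fold_range: Tuple[float, float] = (1.5, 15.0)  # x ULN(ALT)
    plateau_fraction_range: Tuple[float, float] = (0.5, 0.9)
    recovery_half_life_days: float = 7.0
    resolver_fraction: float = 0.15  # of injected events
    confounded_fraction: float = 0.2  # of injected events
    # background confounders on anyone
    p_background_liver_dx: float = 0.02
    p_background_serology: float = 0.02
    p_background_surgery: float = 0.03
    p_benign_dx: float = 0.3
    ideal_sampling: bool = False
    uln_alt: float = 40.0  # trajectory construction only; mirrors StudyConfig

    def __post_init__(self):
        probs = [
            self.extra_course_prob,
            self.p_miss,
            self.p_lab_miss,
            self.alp_test_prob,
            self.p_dili,
            self.resolver_fraction,
            self.confounded_fraction,
            self.p_background_liver_dx,
            self.p_background_serology,
            self.p_background_surgery,
            self.p_benign_dx,
        ] + [p for _, _, p in self.medicines]
        for p in probs:
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probability out of [0, 1]: {p}")
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        if self.orders_per_course_mean < 1:
            raise ValueError("orders_per_course_mean must be >= 1")
        if len(self.days_supply_choices) != len(self.days_supply_weights):
            raise ValueError("days_supply choices and weights differ in length")

    @property
    def true_umi(self) -> float:
        return 1.0 / (1.0 - self.p_miss)


@dataclass(frozen=True)
class TruthRecord:
    """What actually happened in one exposure (course) — never shown to the pipeline."""

    patient_id: str
    medicine_code: str
    era_start: dt.date  # first order start
    era_end: dt.date  # last order's nominal end (surplus never extends an era)
    injected_event: str
    expected_detection: bool

    def __post_init__(self):
        if self.injected_event not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.injected_event!r}")


@dataclass
class SimulatedCohort:
    orders: List[PrescriptionOrder]
    labs: List[LabResult]
    diagnoses: List[DiagnosisRecord]
    surgeries: List[SurgeryRecord]
    truth: List[TruthRecord]
    config: SimulationConfig

    def write(self, outdir: Path | str) -> Dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for kind, records in (
            ("orders", self.orders),
            ("labs", self.labs),
            ("diagnoses", self.diagnoses),
            ("surgeries", self.surgeries),
        ):
            paths[kind] = outdir / f"{kind}.csv"
            write_table(records, paths[kind], table_kind=kind)
        truth_path = outdir / "truth.csv"
        pd.DataFrame(
            [
                {
                    "patient_id": t.patient_id,
                    "medicine_code": t.medicine_code,
                    "era_start": t.era_start.isoformat(),
                    "era_end": t.era_end.isoformat(),
                    "injected_event": t.injected_event,
                    "expected_detection": t.expected_detection,
                }
                for t in self.truth
            ],
            columns=[
                "patient_id",
                "medicine_code",
                "era_start",
                "era_end",
                "injected_event",
                "expected_detection",
            ],
        ).to_csv(truth_path, index=False)
        paths["truth"] = truth_path
        return paths


@dataclass(frozen=True)
class _Trajectory:
    """Piecewise serum-ALT course for one exposure (days relative to era start)."""

    baseline: float
    event: str
    onset_day: Optional[int] = None
    peak: Optional[float] = None
    plateau: Optional[float] = None
    era_len: int = 0  # days, inclusive
    half_life: float = 7.0
    resolve_day: Optional[int] = None  # resolver: back to baseline from here

    def value(self, day: int) -> float:
        """ALT on ``day`` (0 = era start); valid for any day incl. after cessation."""
        b = self.baseline
        if self.event == "none" or self.onset_day is None:
            return b
        rise_start = self.onset_day - 10
        if day < rise_start:
            return b
        if day <= self.onset_day:
            frac = (day - rise_start) / (self.onset_day - rise_start)
            return b + (self.peak - b) * frac
        if self.event == "dili_on_drug_resolving":
            if day >= self.resolve_day:
                return b
            frac = (day - self.onset_day) / (self.resolve_day - self.onset_day)
            return self.peak + (b - self.peak) * frac
        # plain / confounded: plateau on drug, exponential decay after end
        last = self.era_len - 1
        if day <= last:
            return self.plateau
        t = day - last
        return b + (self.plateau - b) * 2.0 ** (-t / self.half_life)


def _geometric_n(rng: np.random.Generator, mean: float, cap: int = 15) -> int:
    # capped so one patient cannot stockpile an unrealistically long stream
    if mean <= 1.0:
        return 1
    return min(int(rng.geometric(1.0 / mean)), cap)


def _expected_detection(
    traj: _Trajectory,
    after_day: int,
    trough_day: int,
    confounded: bool,
    uln_alt: float,
) -> bool:
    """Evaluate the four criteria on the generator's own trajectory values.

    Deliberately written out in plain arithmetic, independent of the rule
    engine, so pipeline recall against this flag is a genuine cross-check.
    """
    if traj.event == "none":
        return False
    peak = traj.peak
    baseline = traj.baseline
    c1 = peak > uln_alt and peak >= 2.0 * baseline
    trough = traj.value(trough_day)
    c3_excluded = trough < 0.25 * peak or trough < uln_alt
    max_alt = peak
    after = traj.value(after_day)
    c2 = after < 0.5 * max_alt or after < uln_alt
    return c1 and c2 and (not c3_excluded) and (not confounded)


def simulate_cohort(sim_config: SimulationConfig) -> SimulatedCohort:
    """Generate the four intermediate-database tables plus the truth table.

    Deterministic given ``sim_config.seed``: the same config yields
    byte-identical CSV files. Every emitted table passes schema validation.
    """
    cfg = sim_config
    rng = np.random.default_rng(cfg.seed)
    supply_weights = np.asarray(cfg.days_supply_weights, dtype=float)
    supply_weights = supply_weights / supply_weights.sum()

    orders: List[PrescriptionOrder] = []
    labs: List[LabResult] = []
    diagnoses: List[DiagnosisRecord] = []
    surgeries: List[SurgeryRecord] = []
    truth: List[TruthRecord] = []

    med_names = {code: name for code, name, _ in cfg.medicines}

    for i in range(cfg.n_patients):
        pid = f"P{i:06d}"
        enroll = cfg.start_date + dt.timedelta(
            days=int(rng.integers(0, cfg.enrollment_span_days + 1))
        )
        alt_b = float(
            np.clip(
                cfg.alt_baseline_median
                * math.exp(rng.normal(0.0, cfg.alt_baseline_sigma)),
                *cfg.alt_baseline_clip,
            )
        )
        alp_b = float(
            cfg.alp_baseline_median * math.exp(rng.normal(0.0, cfg.alp_baseline_sigma))
        )

        # background records (patient-level)
        has_bg_liver_dx = rng.random() < cfg.p_background_liver_dx
        if has_bg_liver_dx:
            code = str(rng.choice(["K70.3", "K71.1", "K76.0", "F10.2", "K80.2"]))
            diagnoses.append(
                DiagnosisRecord(pid, code, enroll - dt.timedelta(days=int(rng.integers(30, 400))))
            )
        if rng.random() < cfg.p_benign_dx:
            diagnoses.append(
                DiagnosisRecord(
                    pid,
                    str(rng.choice(_BENIGN_DX)),
                    enroll - dt.timedelta(days=int(rng.integers(0, 200))),
                )
            )
        has_bg_serology = rng.random() < cfg.p_background_serology
        if has_bg_serology:
            code = str(rng.choice(["HBS_AG", "HCV_CORE_AG", "HAV_IGM", "CMV", "EBV"]))
            labs.append(
                LabResult(
                    pid,
                    code,
                    enroll - dt.timedelta(days=int(rng.integers(0, 300))),
                    qualitative="positive",
                )
            )
        elif rng.random() < 0.1:  # occasional documented negative serology
            labs.append(
                LabResult(
                    pid,
                    str(rng.choice(["HBS_AG", "HCV_CORE_AG"])),
                    enroll - dt.timedelta(days=int(rng.integers(0, 300))),
                    qualitative="negative",
                )
            )
        bg_surgery_dates: List[dt.date] = []
        if rng.random() < cfg.p_background_surgery:
            d = enroll + dt.timedelta(days=int(rng.integers(0, 500)))
            bg_surgery_dates.append(d)
            surgeries.append(SurgeryRecord(pid, d))

        exposed = [
            (code, name) for code, name, p in cfg.medicines if rng.random() < p
        ]
        if cfg.ideal_sampling:
            exposed = exposed[:1]  # isolate trajectories: one exposure per patient

        cursor = enroll
        for med_code, med_name in exposed:
            n_courses = 1
            while (
                not cfg.ideal_sampling
                and n_courses < cfg.max_courses
                and rng.random() < cfg.extra_course_prob
            ):
                n_courses += 1
            for _course in range(n_courses):
                course_start = cursor
                n_orders = _geometric_n(rng, cfg.orders_per_course_mean)
                start = course_start
                course_orders: List[PrescriptionOrder] = []
                for _k in range(n_orders):
                    supply = int(
                        rng.choice(np.asarray(cfg.days_supply_choices), p=supply_weights)
                    )
                    course_orders.append(
                        PrescriptionOrder(pid, med_code, med_name, start, supply)
                    )
                    if cfg.ideal_sampling:
                        nxt = supply  # contiguous refills
                    else:
                        stretch = int(math.ceil(supply * cfg.true_umi))
                        delay = int(
                            rng.integers(cfg.refill_delay_min, cfg.refill_delay_max + 1)
                        )
                        nxt = max(1, stretch + delay)
                    start = start + dt.timedelta(days=nxt)
                orders.extend(course_orders)
                era_start = course_orders[0].start_date
                era_end = max(o.nominal_end for o in course_orders)
                era_len = (era_end - era_start).days + 1

                traj, event, confounder_kind = _inject_event(
                    rng, cfg, alt_b, era_len
                )

                # confounder records tied to this course
                conf_surgery_date: Optional[dt.date] = None
                if confounder_kind == "diagnosis":
                    diagnoses.append(
                        DiagnosisRecord(
                            pid,
                            str(rng.choice(["K70", "K71.9", "K75.2", "F10.1"])),
                            era_start + dt.timedelta(days=int(rng.integers(0, 30))),
                        )
                    )
                elif confounder_kind == "serology":
                    labs.append(
                        LabResult(
                            pid,
                            str(rng.choice(["HBS_AG", "HCV_CORE_AG", "EBV"])),
                            era_start + dt.timedelta(days=int(rng.integers(0, 60))),
                            qualitative="positive",
                        )
                    )
                elif confounder_kind == "surgery":
                    peak_date = era_start + dt.timedelta(days=int(traj.onset_day))
                    conf_surgery_date = peak_date - dt.timedelta(
                        days=int(rng.integers(0, 15))
                    )
                    surgeries.append(SurgeryRecord(pid, conf_surgery_date))

                labs.extend(
                    _sample_labs(rng, cfg, pid, era_start, era_len, traj, alp_b)
                )

                # ground-truth detectability, accounting for every patient-level
                # confounder (injected or background) visible to criterion 4
                peak_date = (
                    era_start + dt.timedelta(days=int(traj.onset_day))
                    if traj.onset_day is not None
                    else None
                )
                confounded = confounder_kind is not None or has_bg_liver_dx or has_bg_serology
                if peak_date is not None and not confounded:
                    lo = peak_date - dt.timedelta(days=14)
                    confounded = any(lo <= d <= peak_date for d in bg_surgery_dates)
                after_day = era_len - 1 + 14 if cfg.ideal_sampling else era_len - 1 + 10
                trough_day = (
                    min(int(traj.onset_day) + 10, era_len - 1)
                    if traj.onset_day is not None
                    else 0
                )
                expected = _expected_detection(
                    traj, after_day, trough_day, confounded, cfg.uln_alt
                )
                if event != "none" and confounder_kind is not None:
                    event = "confounded_dili"
                truth.append(
                    TruthRecord(pid, med_code, era_start, era_end, event, expected)
                )

                gap = int(rng.integers(*cfg.cessation_gap_range))
                cursor = era_end + dt.timedelta(days=gap)
            cursor = cursor + dt.timedelta(days=int(rng.integers(120, 240)))

    return SimulatedCohort(orders, labs, diagnoses, surgeries, truth, cfg)


def _inject_event(
    rng: np.random.Generator, cfg: SimulationConfig, alt_b: float, era_len: int
) -> Tuple[_Trajectory, str, Optional[str]]:
    """Draw the injury event (if any) and build its ALT trajectory."""
    onset_max = min(cfg.onset_day_range[1], era_len - 20)
    can_host = onset_max >= cfg.onset_day_range[0] and rng.random() < cfg.p_dili
    if not can_host:
        return (
            _Trajectory(baseline=alt_b, event="none", era_len=era_len),
            "none",
            None,
        )
    onset = int(rng.integers(cfg.onset_day_range[0], onset_max + 1))
    fold = float(rng.uniform(*cfg.peak_fold_range))
    peak = fold * cfg.uln_alt
    u = rng.random()
    if u < cfg.resolver_fraction:
        event = "dili_on_drug_resolving"
        resolve = min(onset + 10, era_len - 1)
        traj = _Trajectory(
            baseline=alt_b,
            event=event,
            onset_day=onset,
            peak=peak,
            era_len=era_len,
            half_life=cfg.recovery_half_life_days,
            resolve_day=resolve,
        )
        return traj, event, None
    confounder_kind = None
    if u < cfg.resolver_fraction + cfg.confounded_fraction:
        confounder_kind = str(rng.choice(["diagnosis", "serology", "surgery"]))
    plateau = max(
        float(rng.uniform(*cfg.plateau_fraction_range)) * peak, cfg.uln_alt
    )
    traj = _Trajectory(
        baseline=alt_b,
        event="dili",
        onset_day=onset,
        peak=peak,
        plateau=plateau,
        era_len=era_len,
        half_life=cfg.recovery_half_life_days,
    )
    return traj, "dili", confounder_kind


def _sample_labs(
    rng: np.random.Generator,
    cfg: SimulationConfig,
    pid: str,
    era_start: dt.date,
    era_len: int,
    traj: _Trajectory,
    alp_b: float,
) -> List[LabResult]:
    """Draw the ALT/ALP measurement schedule for one exposure."""
    out: List[LabResult] = []
    last = era_len - 1

    def _alt(day: int, noisy: bool) -> float:
        v = traj.value(day)
        if noisy and cfg.alt_noise_sigma > 0:
            v *= math.exp(rng.normal(0.0, cfg.alt_noise_sigma))
        return round(max(v, 1.0), 1)

    def _alp(noisy: bool) -> float:
        v = alp_b
        if noisy and cfg.alt_noise_sigma > 0:
            v *= math.exp(rng.normal(0.0, cfg.alt_noise_sigma))
        return round(max(v, 1.0), 1)

    def _emit(day: int, with_alp: bool, noisy: bool) -> None:
        date = era_start + dt.timedelta(days=day)
        out.append(LabResult(pid, "ALT", date, value=_alt(day, noisy)))
        if with_alp:
            out.append(LabResult(pid, "ALP", date, value=_alp(noisy)))

    if cfg.ideal_sampling:
        _emit(-7, with_alp=True, noisy=False)
        _emit(0, with_alp=False, noisy=False)
        if traj.onset_day is not None:
            _emit(int(traj.onset_day), with_alp=True, noisy=False)
            trough_day = min(int(traj.onset_day) + 10, last)
            if trough_day > traj.onset_day:
                _emit(trough_day, with_alp=False, noisy=False)
        if last > 0:
            _emit(last, with_alp=False, noisy=False)
        _emit(last + 14, with_alp=False, noisy=False)
        return out

    # pre-start draws
    if rng.random() > cfg.p_lab_miss:
        day = -int(rng.integers(cfg.pre_start_draw_range[0], cfg.pre_start_draw_range[1] + 1))
        _emit(day, with_alp=rng.random() < cfg.alp_test_prob, noisy=True)
    # on-drug draws at a regular interval with jitter
    day = 0
    while day <= last:
        if rng.random() > cfg.p_lab_miss:
            _emit(day, with_alp=rng.random() < cfg.alp_test_prob, noisy=True)
        day += int(cfg.on_drug_interval_days + rng.integers(-3, 4))
        day = max(day, 1) if day <= 0 else day
    # post-cessation draws
    for offset in cfg.post_cessation_draw_days:
        if rng.random() > cfg.p_lab_miss:
            _emit(last + int(offset), with_alp=rng.random() < cfg.alp_test_prob, noisy=True)
    return out


@dataclass(frozen=True)
class AdherenceTrace:
    """Realized day-by-day consumption for one order stream."""

    first_day: dt.date
    took_dose: Tuple[bool, ...]  # indexed from first_day
    nominal_days: int  # total days of supply dispensed
    actual_span_days: int  # first dose through last dose, inclusive
    empirical_umi: float  # actual span / nominal span


def adherence_trace(
    orders: Sequence[PrescriptionOrder], p_miss: float, seed: int
) -> AdherenceTrace:
    """Simulate a patient consuming the dispensed supply with missed doses.

    Each day with stock on hand the patient takes a dose with probability
    ``1 - p_miss``; a missed dose leaves the stock for later, stretching
    consumption. The empirical unused-medicine index is the realized
    consumption span divided by the nominal days of supply, converging to
    ``1/(1 - p_miss)`` on long horizons.
    """
    if not orders:
        raise ValueError("orders must be non-empty")
    if not (0.0 <= p_miss < 1.0):
        raise ValueError("p_miss must be in [0, 1)")
    rng = np.random.default_rng(seed)
    ordered = sorted(orders, key=lambda o: o.start_date)
    first = ordered[0].start_date
    total = sum(o.days_supply for o in ordered)
    dispense: Dict[int, int] = {}
    for o in ordered:
        k = (o.start_date - first).days
        dispense[k] = dispense.get(k, 0) + o.days_supply
    last_order_day = max(dispense)

    took: List[bool] = []
    stock = 0
    consumed = 0
    last_take = -1
    day = 0
    while consumed < total:
        stock += dispense.get(day, 0)
        take = stock > 0 and rng.random() >= p_miss
        if take:
            stock -= 1
            consumed += 1
            last_take = day
        took.append(take)
        day += 1
        if day > last_order_day and stock == 0 and consumed < total:
            break  # unreachable with positive supplies; defensive
    span = last_take + 1
    return AdherenceTrace(
        first_day=first,
        took_dose=tuple(took[:span]),
        nominal_days=total,
        actual_span_days=span,
        empirical_umi=span / total,
    )
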