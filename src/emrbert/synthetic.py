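"""Synthetic EMR cohorts with the statistical structure the method assumes.

The generator emulates an administrative claims cohort in which two kinds of
diagnoses coexist:

* *noise* diagnoses (influenza-like illnesses) — short episodes whose
  revisit intervals are unimodal with a mode near 10 days;
* *chronic* trigger/target/filler diagnoses — recurring conditions whose
  revisit intervals follow a multi-peak mixture (roughly monthly, quarterly,
  half-yearly and yearly follow-ups).

A trigger->target causal rule is planted: a patient whose trigger disease
has occurred ``k`` times develops a target disease within the horizon with
probability ``rule_strength``. Ground truth (per-position noise flags and
per-patient labels) is emitted alongside the records so every downstream
stage is testable without restricted data.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import yaml

from .comorbidity import TriggerSpec
from .sequences import PatientRecord, Visit

__all__ = [
    "CohortConfig", "GroundTruth", "generate_cohort", "worked_example",
    "toy_graph_example", "default_noise_codes", "default_trigger_spec",
]

#: chronic but unrelated conditions used as background panel members
FILLER_CODES = (
    "530.8", "715.9", "724.2", "493.9", "296.3", "311", "300.4", "571.8",
    "585.9", "443.9", "427.3", "496", "327.2", "733.0", "268.9", "272.0",
    "781.2", "599.0", "564.0", "729.1",
)


def default_noise_codes() -> list[str]:
    """The packaged influenza-like noise-disease list (one code per line)."""
    text = (resources.files("emrbert.data") / "noise_codes.txt").read_text()
    return [line.strip() for line in text.splitlines()
            if line.strip() and not line.startswith("#")]


def default_trigger_spec() -> TriggerSpec:
    """Packaged default: hypertension trigger with its six related targets."""
    text = (resources.files("emrbert.data") / "trigger_targets.yaml").read_text()
    cfg = yaml.safe_load(text)
    return TriggerSpec(trigger=str(cfg["trigger"]), k=int(cfg["k"]),
                       targets=frozenset(str(t) for t in cfg["targets"]))


def default_horizon_days() -> int:
    text = (resources.files("emrbert.data") / "trigger_targets.yaml").read_text()
    return int(yaml.safe_load(text)["horizon_days"])


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort.

    Defaults follow the emulated claims cohort: ~20.5% of diagnosis
    positions are influenza-like noise, visits per patient average 27.34
    (sd 20.93), noise revisit intervals are log-normal with median 10 days,
    and chronic revisit intervals mix four peaks.
    """

    n_patients: int = 500
    start_date: dt.date = dt.date(2013, 1, 1)
    end_date: dt.date = dt.date(2016, 12, 31)
    noise_codes: tuple[str, ...] = field(
        default_factory=lambda: tuple(default_noise_codes()))
    trigger_spec: TriggerSpec = field(default_factory=default_trigger_spec)
    horizon_days: int = 365
    noise_prevalence: float = 0.205
    noise_interval_median: float = 10.0
    noise_interval_sigma: float = 0.3
    chronic_peaks: tuple[float, ...] = (28.0, 91.0, 182.0, 364.0)
    chronic_sds: tuple[float, ...] = (7.0, 14.0, 21.0, 30.0)
    chronic_weights: tuple[float, ...] = (0.35, 0.30, 0.20, 0.15)
    rule_strength: float = 0.7
    trigger_patient_fraction: float = 0.5
    target_background_rate: float = 0.08
    visits_mean: float = 27.34
    visits_sd: float = 20.93
    codes_per_visit: float = 1.9
    visit_merge_days: int = 2
    #: chance a chronic disease is co-managed on another panel member's
    #: follow-up schedule, and the per-visit chance it is then recorded
    co_schedule_prob: float = 0.5
    co_inclusion: float = 0.8
    filler_codes: tuple[str, ...] = FILLER_CODES

    def __post_init__(self):
        for p in (self.noise_prevalence, self.rule_strength,
                  self.trigger_patient_fraction, self.target_background_rate):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")
        if abs(sum(self.chronic_weights) - 1.0) > 1e-9:
            raise ValueError("chronic mixture weights must sum to 1")


@dataclass
class GroundTruth:
    """Per-position noise flags and per-patient labels (None = excluded)."""

    noise_flags: dict[str, list[bool]]
    nsp_labels: dict[str, int | None]
    seed: int


def _chronic_event_dates(rng: np.random.Generator, cfg: CohortConfig
                         ) -> list[dt.date]:
    span = (cfg.end_date - cfg.start_date).days
    first = int(rng.integers(0, span))  # onset anywhere in the window
    dates = [cfg.start_date + dt.timedelta(days=first)]
    while True:
        comp = rng.choice(len(cfg.chronic_weights), p=cfg.chronic_weights)
        gap = max(1, int(round(rng.normal(cfg.chronic_peaks[comp],
                                          cfg.chronic_sds[comp]))))
        nxt = dates[-1] + dt.timedelta(days=gap)
        if nxt > cfg.end_date:
            return dates
        dates.append(nxt)


def _noise_events(rng: np.random.Generator, cfg: CohortConfig,
                  n_target: int) -> list[tuple[dt.date, str]]:
    span = (cfg.end_date - cfg.start_date).days
    mu = np.log(cfg.noise_interval_median)
    events: list[tuple[dt.date, str]] = []
    guard = 0
    while len(events) < n_target and guard < 100:
        guard += 1
        code = cfg.noise_codes[rng.integers(len(cfg.noise_codes))]
        length = 1 + int(rng.poisson(1.2))
        date = cfg.start_date + dt.timedelta(days=int(rng.integers(0, span)))
        for _ in range(length):
            if date <= cfg.end_date and len(events) < n_target:
                events.append((date, code))
            gap = max(1, int(round(np.exp(
                rng.normal(mu, cfg.noise_interval_sigma)))))
            date = date + dt.timedelta(days=gap)
    return events


def _patient(rng: np.random.Generator, cfg: CohortConfig, pid: str
             ) -> tuple[PatientRecord, list[bool], int | None]:
    spec = cfg.trigger_spec
    target_visits = float(np.clip(rng.normal(cfg.visits_mean, cfg.visits_sd),
                                  2, 120))
    # expected chronic events per disease over the span
    mean_gap = float(np.dot(cfg.chronic_weights, cfg.chronic_peaks))
    span = (cfg.end_date - cfg.start_date).days
    per_disease = max(2.0, 1.0 + span * 0.5 / mean_gap)
    n_chronic = max(1, int(round(target_visits * cfg.codes_per_visit
                                 * (1 - cfg.noise_prevalence) / per_disease)))

    panel: list[str] = []
    if rng.random() < cfg.trigger_patient_fraction:
        panel.append(spec.trigger)
    for t in sorted(spec.targets):
        if rng.random() < cfg.target_background_rate:
            panel.append(t)
    fillers = [c for c in cfg.filler_codes if c not in panel]
    order = rng.permutation(len(fillers))
    while len(panel) < n_chronic and len(order):
        panel.append(fillers[order[0]])
        order = order[1:]
    if not panel:
        panel.append(fillers[int(rng.integers(len(fillers)))])

    events: list[tuple[dt.date, str, bool]] = []
    schedules: list[list[dt.date]] = []
    for code in panel:
        if schedules and rng.random() < cfg.co_schedule_prob:
            buddy = schedules[int(rng.integers(len(schedules)))]
            dates = [d for d in buddy if rng.random() < cfg.co_inclusion]
            if not dates:
                dates = _chronic_event_dates(rng, cfg)
        else:
            dates = _chronic_event_dates(rng, cfg)
            schedules.append(dates)
        for d in dates:
            events.append((d, code, False))

    # planted trigger -> target rule
    trigger_dates = sorted(d for d, c, _ in events if c == spec.trigger)
    if len(trigger_dates) >= spec.k:
        sep_date = trigger_dates[spec.k - 1]
        limit = sep_date + dt.timedelta(days=cfg.horizon_days)
        if rng.random() < cfg.rule_strength:
            target = sorted(spec.targets)[int(rng.integers(len(spec.targets)))]
            lo, hi = 30, max(31, cfg.horizon_days - 30)
            when = sep_date + dt.timedelta(days=int(rng.integers(lo, hi)))
            # clamp into the window but stay strictly after the trigger
            # point, outside the visit-consolidation window
            when = max(min(when, cfg.end_date),
                       sep_date + dt.timedelta(days=cfg.visit_merge_days + 1))
            events.append((when, target, False))
        else:
            events = [(d, c, f) for d, c, f in events
                      if not (c in spec.targets and sep_date < d <= limit)]

    n_c = len(events)
    x = n_c * cfg.noise_prevalence / max(1e-9, 1 - cfg.noise_prevalence)
    n_noise = int(np.floor(x)) + int(rng.random() < (x - np.floor(x)))
    for d, c in _noise_events(rng, cfg, n_noise):
        events.append((d, c, True))

    # consolidate events into visits: diagnoses landing within the merge
    # window of an open encounter share that visit (multi-code encounters);
    # the same code twice in one visit collapses to one slot
    visits_acc: list[tuple[dt.date, list[tuple[str, bool]]]] = []
    for d, c, f in sorted(events, key=lambda e: e[0]):
        if (visits_acc
                and (d - visits_acc[-1][0]).days <= cfg.visit_merge_days):
            slot = visits_acc[-1][1]
        else:
            visits_acc.append((d, []))
            slot = visits_acc[-1][1]
        if all(c != c2 for c2, _ in slot):
            slot.append((c, f))
    visits, flags = [], []
    for d, slot in visits_acc:
        visits.append(Visit(date=d, codes=tuple(c for c, _ in slot)))
        flags.extend(f for _, f in slot)
    record = PatientRecord(patient_id=pid, visits=visits)

    label = _nsp_label(record, spec, cfg.horizon_days)
    return record, flags, label


def _nsp_label(record: PatientRecord, spec: TriggerSpec,
               horizon_days: int) -> int | None:
    """Label by direct scan of the record (mirrors the separator rules)."""
    D = record.disease_positions()
    n_trigger = D.count(spec.trigger)
    if n_trigger >= spec.k:
        seen = 0
        sep_date = None
        for visit in record.visits:
            seen += sum(1 for c in visit.codes if c == spec.trigger)
            if seen >= spec.k:
                sep_date = visit.date
                break
        limit = sep_date + dt.timedelta(days=horizon_days)
        return int(any(v.date > sep_date and v.date <= limit
                       and any(c in spec.targets for c in v.codes)
                       for v in record.visits))
    if spec.trigger in D or (set(D) & spec.targets):
        return 0
    return None


def generate_cohort(config: CohortConfig | None = None, seed: int = 0
                    ) -> tuple[list[PatientRecord], GroundTruth]:
    """Generate a cohort and its ground truth; deterministic under seed."""
    cfg = config or CohortConfig()
    rng = np.random.default_rng(seed)
    records: list[PatientRecord] = []
    noise_flags: dict[str, list[bool]] = {}
    labels: dict[str, int | None] = {}
    for i in range(cfg.n_patients):
        pid = f"P{i:05d}"
        rec, flags, label = _patient(rng, cfg, pid)
        records.append(rec)
        noise_flags[pid] = flags
        labels[pid] = label
    return records, GroundTruth(noise_flags=noise_flags, nsp_labels=labels,
                                seed=seed)


def worked_example() -> PatientRecord:
    """The four-visit single-patient record used as the worked example."""
    return PatientRecord(patient_id="example", visits=[
        Visit(date=dt.date(2013, 11, 11), codes=("250.0",)),
        Visit(date=dt.date(2013, 11, 21), codes=("726.0", "438.5", "847.0")),
        Visit(date=dt.date(2013, 12, 5), codes=("250.0",)),
        Visit(date=dt.date(2013, 12, 9), codes=("414.0", "401.9", "250.0")),
    ])


def toy_graph_example() -> dict[str, set[str]]:
    """Three triggers and their target sets for the toy comorbidity graph."""
    return {
        "250.0": {"401.9", "272.4"},
        "401.9": {"414.9", "437.0"},
        "272.4": {"437.0"},
    }
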