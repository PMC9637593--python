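"""Breath classification from ground-truth patient and ventilator timing.

A breath is described by two delays:

* start-inspiration delay = trigger time - patient effort start,
* end-inspiration delay   = cycle time - patient effort end.

The taxonomy uses strict exceedances of the timing margins: a breath is
normal when the start delay is below 250 ms and the end delay lies strictly
between -100 ms and +300 ms.  Crossing one margin yields
delayed_inspiration (start delay > 250 ms), early_cycling (end delay
< -100 ms) or late_cycling (end delay > 300 ms); crossing a start and an
end margin in the same breath yields the two combination classes.  An
effort with no ventilator pressurization at all is an ineffective_effort,
whose delays are undefined.  Delays exactly equal to a margin count as
normal-side.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Tuple

__all__ = [
    "START_DELAY_MARGIN",
    "EARLY_CYCLING_MARGIN",
    "LATE_CYCLING_MARGIN",
    "LABEL_CLASSES",
    "BreathTiming",
    "BreathLabel",
    "BreathAnnotation",
    "compute_delays",
    "classify_breath",
    "annotate_record",
]

START_DELAY_MARGIN = 0.25    # s; start delay above this = delayed inspiration
EARLY_CYCLING_MARGIN = -0.10  # s; end delay below this = early cycling
LATE_CYCLING_MARGIN = 0.30   # s; end delay above this = late cycling

LABEL_CLASSES = (
    "normal",
    "early_cycling",
    "late_cycling",
    "delayed_inspiration",
    "ineffective_effort",
    "delayed_inspiration+early_cycling",
    "delayed_inspiration+late_cycling",
)


@dataclass(frozen=True)
class BreathTiming:
    """Event times (s) of one patient effort and its ventilator response."""

    patient_start: float
    patient_end: float
    patient_max: float
    trigger_time: Optional[float] = None
    cycle_time: Optional[float] = None

    def __post_init__(self) -> None:
        if not (self.patient_start < self.patient_max < self.patient_end):
            raise ValueError("require patient_start < patient_max < patient_end")
        if (self.trigger_time is None) != (self.cycle_time is None):
            raise ValueError("trigger and cycle must be present together")


@dataclass(frozen=True)
class BreathLabel:
    """Realised class and delays of one breath.

    Delays are ``None`` exactly when the class is ineffective_effort (no
    trigger, so neither delay is defined).
    """

    label: str
    start_delay: Optional[float]
    end_delay: Optional[float]

    def __post_init__(self) -> None:
        if self.label not in LABEL_CLASSES:
            raise ValueError(f"unknown label {self.label!r}")
        undefined = self.start_delay is None and self.end_delay is None
        if (self.label == "ineffective_effort") != undefined:
            raise ValueError("delays undefined iff ineffective_effort")


@dataclass(frozen=True)
class BreathAnnotation:
    """One annotated breath: timing, label and the five marker times."""

    timing: BreathTiming
    label: BreathLabel
    markers: dict  # name -> (time s, sample index or None)


def compute_delays(timing: BreathTiming) -> Tuple[Optional[float], Optional[float]]:
    """Start and end inspiration delays, or ``(None, None)`` without a trigger."""
    if timing.trigger_time is None:
        return None, None
    return (
        timing.trigger_time - timing.patient_start,
        timing.cycle_time - timing.patient_end,
    )


def classify_breath(timing: BreathTiming) -> BreathLabel:
    """Apply the timing-margin rules to one breath."""
    start_delay, end_delay = compute_delays(timing)
    if start_delay is None:
        return BreathLabel("ineffective_effort", None, None)
    delayed = start_delay > START_DELAY_MARGIN
    early = end_delay < EARLY_CYCLING_MARGIN
    late = end_delay > LATE_CYCLING_MARGIN
    if delayed and early:
        label = "delayed_inspiration+early_cycling"
    elif delayed and late:
        label = "delayed_inspiration+late_cycling"
    elif delayed:
        label = "delayed_inspiration"
    elif early:
        label = "early_cycling"
    elif late:
        label = "late_cycling"
    else:
        label = "normal"
    return BreathLabel(label, start_delay, end_delay)


def _sample_index(t: Optional[float], fs: float, n: int) -> Optional[int]:
    if t is None:
        return None
    i = int(round(t * fs))
    return min(max(i, 0), n - 1)


def annotate_record(record, schedule=None) -> Tuple[List[BreathAnnotation], List[float]]:
    """Annotate every scheduled effort of a simulated record.

    Each ventilator trigger is assigned to the latest effort that started
    before it, provided the gap is within one breath period; the paired
    cycle is the first cycle after that trigger.  Efforts left without a
    trigger are ineffective.  Triggers matching no effort are flagged as
    auto-trigger anomalies and returned separately (they are excluded from
    class counts).

    Returns ``(annotations, anomalies)`` where ``annotations`` has one
    entry per scheduled effort with the five markers (trigger, cycle,
    patient start/end/max) as (time, sample index) pairs.
    """
    sched = schedule if schedule is not None else record.schedule
    if sched is None:
        raise ValueError("a breath schedule is required for annotation")
    triggers = sorted(record.events.get("trigger", []))
    cycles = sorted(record.events.get("cycle", []))
    period = 60.0 / sched.rate
    n = len(record.t)
    fs = record.fs

    starts = [b.profile.effort_start for b in sched.breaths]
    assigned: dict = {}
    anomalies: List[float] = []
    for tr in triggers:
        k = None
        for i, st in enumerate(starts):
            if st <= tr:
                k = i
            else:
                break
        if k is None or tr - starts[k] > period or k in assigned:
            anomalies.append(tr)
            continue
        cyc = next((c for c in cycles if c > tr), None)
        if cyc is None:
            anomalies.append(tr)  # record ended mid-inspiration
            continue
        assigned[k] = (tr, cyc)

    annotations: List[BreathAnnotation] = []
    for i, b in enumerate(sched.breaths):
        pr = b.profile
        tr, cyc = assigned.get(i, (None, None))
        timing = BreathTiming(
            patient_start=pr.effort_start,
            patient_end=pr.effort_end,
            patient_max=pr.effort_max,
            trigger_time=tr,
            cycle_time=cyc,
        )
        label = classify_breath(timing)
        markers = {
            "trigger": (tr, _sample_index(tr, fs, n)),
            "cycle": (cyc, _sample_index(cyc, fs, n)),
            "patient_start": (pr.effort_start, _sample_index(pr.effort_start, fs, n)),
            "patient_end": (pr.effort_end, _sample_index(pr.effort_end, fs, n)),
            "patient_max": (pr.effort_max, _sample_index(pr.effort_max, fs, n)),
        }
        annotations.append(BreathAnnotation(timing=timing, label=label, markers=markers))
    return annotations, anomalies
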