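"""Respiratory muscle pressure (Pmus) generation and breath scheduling.

Each breath is a rounded trapezoid: a smooth ramp of duration ``rise_time``
down to ``-amplitude`` (inspiratory effort lowers pleural pressure; the
amplitude is reported positive, clinical convention), a plateau, and a
smooth ramp of duration ``fall_time`` back to baseline.  Corners are
blended with a raised-cosine slope profile of width ``rounding`` (default
10 % of the shorter ramp, brisk enough for realistic effort onset) so the
waveform is C1-continuous for the stiff solver.  A cardiac sine
(0.25-1 cmH2O, 1-2 Hz) rides on top of the whole record.

The per-class parameter ranges used to create asynchronies:

========================  ===============  ===========  ===========
class                     amplitude cmH2O  fall time s  rise time s
========================  ===============  ===========  ===========
normal                    5 - 10           0.25 - 0.35  0.5 - 0.7
early_cycling             5 - 10           0.25 - 0.35  0.7 - 0.9
late_cycling              5 - 10           0.25 - 0.35  0.5 - 0.7
delayed_inspiration       3.5 - 4.5        0.25 - 0.35  0.7 - 0.9
ineffective_effort        1.7 - 2.2        0.4 - 0.6    0.4 - 0.6
========================  ===============  ===========  ===========

A breath *intended* as a given class also carries per-breath ventilator
threshold overrides (trigger drop, cycling fraction); those induction
settings are explicit, logged generator settings.  The realised class is
always re-derived from realised timings by :mod:`psvsim.labeling`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "EFFORT_CLASSES",
    "PMUS_CLASS_RANGES",
    "CARDIAC_AMPLITUDE_RANGE",
    "CARDIAC_FREQUENCY_RANGE",
    "MuscleProfile",
    "ScheduledBreath",
    "BreathSchedule",
    "sample_profile",
    "pmus_envelope",
    "pmus_waveform",
    "schedule_breaths",
]

#: amplitude (cmH2O), fall time (s), rise time (s) ranges per intended class
PMUS_CLASS_RANGES = {
    "normal": ((5.0, 10.0), (0.25, 0.35), (0.5, 0.7)),
    "early_cycling": ((5.0, 10.0), (0.25, 0.35), (0.7, 0.9)),
    "late_cycling": ((5.0, 10.0), (0.25, 0.35), (0.5, 0.7)),
    "delayed_inspiration": ((3.5, 4.5), (0.25, 0.35), (0.7, 0.9)),
    "ineffective_effort": ((1.7, 2.2), (0.4, 0.6), (0.4, 0.6)),
}

#: the five base effort classes (table rows above)
EFFORT_CLASSES = tuple(PMUS_CLASS_RANGES)

CARDIAC_AMPLITUDE_RANGE = (0.25, 1.0)
CARDIAC_FREQUENCY_RANGE = (1.0, 2.0)

#: combination classes reuse the delayed-inspiration effort shape
_PROFILE_CLASS_FOR = {
    "delayed_inspiration+early_cycling": "delayed_inspiration",
    "delayed_inspiration+late_cycling": "delayed_inspiration",
}


@dataclass(frozen=True)
class MuscleProfile:
    """Shape of one breath's muscle effort.

    ``effort_end`` equals ``effort_start + rise_time + plateau + fall_time``
    where the plateau duration is implicit.  ``rounding`` is the corner
    blending width in seconds (default 10 % of the shorter ramp).
    """

    amplitude: float
    rise_time: float
    fall_time: float
    effort_start: float
    effort_end: float
    intended_class: str = "normal"
    cardiac_amplitude: float = 0.5
    cardiac_frequency: float = 1.2
    rounding: float = field(default=0.0)

    def __post_init__(self) -> None:
        if self.rise_time <= 0 or self.fall_time <= 0:
            raise ValueError("rise_time and fall_time must be positive")
        if self.effort_end <= self.effort_start:
            raise ValueError("effort_end must exceed effort_start")
        if self.effort_end - self.effort_start < self.rise_time + self.fall_time:
            raise ValueError("effort duration shorter than rise + fall")
        base = _PROFILE_CLASS_FOR.get(self.intended_class, self.intended_class)
        if base in PMUS_CLASS_RANGES and self.amplitude > 0:
            (alo, ahi), _, _ = PMUS_CLASS_RANGES[base]
            if not (alo - 1e-9 <= self.amplitude <= ahi + 1e-9):
                raise ValueError(
                    f"amplitude {self.amplitude} outside the "
                    f"{base} range {alo}-{ahi}"
                )
        clo, chi = CARDIAC_AMPLITUDE_RANGE
        if not (clo <= self.cardiac_amplitude <= chi):
            raise ValueError("cardiac amplitude outside 0.25-1 cmH2O")
        flo, fhi = CARDIAC_FREQUENCY_RANGE
        if not (flo <= self.cardiac_frequency <= fhi):
            raise ValueError("cardiac frequency outside 1-2 Hz")
        if self.rounding == 0.0:
            object.__setattr__(
                self, "rounding", 0.1 * min(self.rise_time, self.fall_time)
            )
        if self.rounding < 0 or self.rounding > 0.5 * min(self.rise_time, self.fall_time):
            raise ValueError("rounding must be in [0, min(rise, fall)/2]")

    @property
    def plateau(self) -> float:
        return self.effort_end - self.effort_start - self.rise_time - self.fall_time

    @property
    def effort_max(self) -> float:
        """Time of maximum |envelope|, defined as the plateau midpoint."""
        t0 = self.effort_start + self.rise_time
        return t0 + 0.5 * self.plateau

    def with_(self, **kwargs) -> "MuscleProfile":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class ScheduledBreath:
    """One scheduled effort plus its induction settings.

    ``trigger_drop`` / ``cycle_fraction`` override the ventilator defaults
    for the breath this effort is meant to produce (``None`` = use the
    ventilator configuration).  They are how asynchronies are induced and
    are logged verbatim into the ground-truth sidecar.
    """

    profile: MuscleProfile
    trigger_drop: Optional[float] = None
    cycle_fraction: Optional[float] = None

    @property
    def start(self) -> float:
        return self.profile.effort_start


@dataclass(frozen=True)
class BreathSchedule:
    """Ordered, non-overlapping efforts for one simulated record."""

    breaths: tuple
    rate: float
    duration: float

    def __post_init__(self) -> None:
        prev_end = -math.inf
        for b in self.breaths:
            if b.profile.effort_start < prev_end:
                raise ValueError("scheduled efforts overlap")
            prev_end = b.profile.effort_end

    @property
    def profiles(self):
        return [b.profile for b in self.breaths]

    def class_counts(self) -> dict:
        counts: dict = {}
        for b in self.breaths:
            c = b.profile.intended_class
            counts[c] = counts.get(c, 0) + 1
        return counts


# ---------------------------------------------------------------------------


def sample_profile(
    effort_class: str,
    rng: np.random.Generator,
    effort_start: float = 0.0,
    plateau_range=(0.1, 0.4),
    cardiac_amplitude: Optional[float] = None,
    cardiac_frequency: Optional[float] = None,
) -> MuscleProfile:
    """Draw one effort profile for the given class.

    Amplitude, fall time and rise time are uniform over the class row of
    the table above; the plateau duration is uniform over
    ``plateau_range`` (a free choice, giving inspiratory times consistent
    with 12-18 breaths/min).  Cardiac parameters are drawn uniformly from
    their stated ranges unless fixed by the caller (a record shares one
    cardiac oscillation across breaths).
    """
    base = _PROFILE_CLASS_FOR.get(effort_class, effort_class)
    if base not in PMUS_CLASS_RANGES:
        raise ValueError(f"unknown effort class {effort_class!r}")
    (alo, ahi), (flo, fhi), (rlo, rhi) = PMUS_CLASS_RANGES[base]
    amplitude = rng.uniform(alo, ahi)
    fall = rng.uniform(flo, fhi)
    rise = rng.uniform(rlo, rhi)
    plateau = rng.uniform(*plateau_range)
    if cardiac_amplitude is None:
        cardiac_amplitude = rng.uniform(*CARDIAC_AMPLITUDE_RANGE)
    if cardiac_frequency is None:
        cardiac_frequency = rng.uniform(*CARDIAC_FREQUENCY_RANGE)
    return MuscleProfile(
        amplitude=amplitude,
        rise_time=rise,
        fall_time=fall,
        effort_start=effort_start,
        effort_end=effort_start + rise + plateau + fall,
        intended_class=effort_class,
        cardiac_amplitude=cardiac_amplitude,
        cardiac_frequency=cardiac_frequency,
    )


def _ramp_shape(tau, T, r):
    """Normalised 0->1 ramp over [0, T] with raised-cosine slope corners.

    The slope profile rises from 0 to s over [0, r], holds s over
    [r, T-r], and falls back over [T-r, T]; integrating gives a C1 ramp
    with peak slope s = 1/(T - r).
    """
    tau = np.asarray(tau, dtype=float)
    if r <= 0:
        return np.clip(tau / T, 0.0, 1.0)
    s = 1.0 / (T - r)
    out = np.zeros_like(tau)
    # entry corner
    m = (tau > 0) & (tau < r)
    tm = tau[m]
    out[m] = 0.5 * s * (tm - (r / math.pi) * np.sin(math.pi * tm / r))
    # linear mid-section
    m = (tau >= r) & (tau <= T - r)
    out[m] = 0.5 * s * r + s * (tau[m] - r)
    # exit corner
    m = (tau > T - r) & (tau < T)
    tm = tau[m] - (T - r)
    out[m] = (
        0.5 * s * r
        + s * (T - 2 * r)
        + 0.5 * s * (tm + (r / math.pi) * np.sin(math.pi * tm / r))
    )
    out[tau >= T] = 1.0
    return out


def pmus_envelope(profile: MuscleProfile, t):
    """Rounded-trapezoid envelope (cmH2O, <= 0) without the cardiac sine.

    Zero outside ``[effort_start, effort_end]``, ``-amplitude`` on the
    plateau.  Accepts scalars or arrays.
    """
    t = np.asarray(t, dtype=float)
    a = profile.amplitude
    rel = t - profile.effort_start
    up = _ramp_shape(rel, profile.rise_time, profile.rounding)
    down = _ramp_shape(
        t - (profile.effort_end - profile.fall_time),
        profile.fall_time,
        profile.rounding,
    )
    return -a * (up - down)


def cardiac_wave(profile: MuscleProfile, t):
    """Cardiac oscillation component (absolute-time sine)."""
    t = np.asarray(t, dtype=float)
    return profile.cardiac_amplitude * np.sin(
        2.0 * math.pi * profile.cardiac_frequency * t
    )


def pmus_waveform(profile: MuscleProfile, t):
    """Sampled Pmus for one breath: envelope plus cardiac sine.

    ``t`` must be a uniform grid fine enough to resolve the corner
    rounding (spacing <= rounding/2), otherwise the rounded corners would
    alias away.
    """
    t = np.asarray(t, dtype=float)
    if t.ndim != 1 or t.size < 2:
        raise ValueError("t must be a 1-d grid with at least two samples")
    dt = float(np.max(np.diff(t)))
    if profile.rounding > 0 and dt > 0.5 * profile.rounding + 1e-12:
        raise ValueError(
            f"grid spacing {dt:.4f} s too coarse for rounding "
            f"{profile.rounding:.4f} s (need <= rounding/2)"
        )
    return pmus_envelope(profile, t) + cardiac_wave(profile, t)


def schedule_breaths(
    rate: float,
    duration: float,
    class_sequence: Sequence[str],
    rng: np.random.Generator,
    jitter: float = 0.0,
    induction: Optional[dict] = None,
    shared_cardiac: bool = True,
    cardiac_range=None,
    trigger_floor_gain: float = 0.0,
) -> BreathSchedule:
    """Place efforts at the breathing rate and assign the requested classes.

    Breath starts are spaced ``60/rate`` s apart (optional uniform jitter
    of +-``jitter`` s).  ``class_sequence`` gives the intended class of
    each breath in order; the schedule holds exactly those classes.
    ``induction`` maps class -> dict of per-breath ventilator overrides
    (``trigger_drop`` / ``cycle_fraction``, each a value or (lo, hi) range
    to draw from); see :data:`psvsim.dataset.DEFAULT_INDUCTION`.

    Raises
    ------
    ValueError
        If the rate is outside 12-18 breaths/min or efforts would overlap.
    """
    if not (12.0 <= rate <= 18.0):
        raise ValueError("breathing rate must be within 12-18 breaths/min")
    period = 60.0 / rate
    n = len(class_sequence)
    if duration < n * period:
        raise ValueError(f"duration {duration} s too short for {n} breaths at {rate}/min")
    if cardiac_range is None:
        cardiac_range = CARDIAC_AMPLITUDE_RANGE
    card_amp = rng.uniform(*cardiac_range) if shared_cardiac else None
    card_f = rng.uniform(*CARDIAC_FREQUENCY_RANGE) if shared_cardiac else None
    # a real operator sets the trigger sensitivity above the cardiac noise
    # floor; the gain is the patient's measured cardiac-to-sensor pressure
    # transmission
    drop_floor = trigger_floor_gain * (card_amp or 0.0) + 0.15
    breaths = []
    for i, cls in enumerate(class_sequence):
        start = (i + 0.25) * period
        if jitter > 0:
            start += rng.uniform(-jitter, jitter)
        overrides = dict((induction or {}).get(cls, {}))
        offs = overrides.get("start_offset")
        if offs is not None:
            start = (i + float(offs)) * period
            if jitter > 0:
                start += rng.uniform(-jitter, jitter)
        prof = sample_profile(
            cls,
            rng,
            effort_start=start,
            plateau_range=overrides.get("plateau_range", (0.1, 0.4)),
            cardiac_amplitude=card_amp,
            cardiac_frequency=card_f,
        )
        drawn = {}
        for key in ("trigger_drop", "cycle_fraction"):
            val = overrides.get(key)
            if val is None:
                drawn[key] = None
            elif isinstance(val, (tuple, list)):
                drawn[key] = float(rng.uniform(val[0], val[1]))
            else:
                drawn[key] = float(val)
        if drawn["trigger_drop"] is not None and drawn["trigger_drop"] < drop_floor:
            drawn["trigger_drop"] = drop_floor
        model = overrides.get("cycle_fraction_model")
        if model is not None:
            # amplitude-compensated cycling threshold: place this breath's
            # predicted end-inspiration delay at the model target
            a0, b0, g0 = model["coef"]
            lo, hi = model.get("clip", (0.02, 0.8))
            if abs(b0) > 1e-9:
                frac = math.exp((model["target"] - a0 - g0 * prof.amplitude) / b0)
            else:
                frac = drawn["cycle_fraction"] or 0.2
            frac *= float(rng.uniform(0.92, 1.08))
            drawn["cycle_fraction"] = float(min(max(frac, lo), hi))
        breaths.append(ScheduledBreath(profile=prof, **drawn))
    return BreathSchedule(breaths=tuple(breaths), rate=rate, duration=duration)
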