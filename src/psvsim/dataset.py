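"""End-to-end generation of the labeled synthetic dataset.

Orchestrates archetype calibration, pressure auto-setting (PEEP/Pinsp such
that a normal breath delivers 0.4-0.6 L), balanced asynchrony induction,
simulation, ground-truth annotation, noise injection and file output.

Noise model: zero-mean white noise low-pass filtered to 15 Hz is added to
the sensor pressure at an SNR drawn uniformly in 15-16 dB and to the flow
at 30-31 dB (SNR on total mean-square power).  Labels are always computed
from the noiseless internal signals before noise is injected, and always
from *realised* timings: a breath intended as an asynchrony but realised
normal is labeled normal.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
from scipy.signal import butter, lfilter

from .archetypes import ARCHETYPE_NAMES, archetype_spec, tune_archetype
from .circuit import CircuitParameters, VentilatorConfig
from .io import write_record
from .labeling import annotate_record
from .lung import LungParameters
from .muscle import schedule_breaths
from .solver import SimulationConfig, simulate

__all__ = [
    "DATASET_CLASSES",
    "DEFAULT_INDUCTION",
    "NoiseConfig",
    "DatasetConfig",
    "add_noise",
    "autoset_pressures",
    "generate_dataset",
    "audit_manifest",
]

#: the six intended classes balanced by default (five base classes plus the
#: delayed-inspiration + late-cycling combination, which the induction
#: mechanics produce reliably)
DATASET_CLASSES = (
    "normal",
    "early_cycling",
    "late_cycling",
    "delayed_inspiration",
    "ineffective_effort",
    "delayed_inspiration+late_cycling",
)

#: per-class ventilator-threshold manipulations used to induce asynchronies.
#: Ranges are drawn per breath; trigger drops outside the nominal 1-2 cmH2O
#: band are deliberate ("thresholds set slightly too high or too low"), and
#: cycling fractions lean on the extremes of the 10-80 % band.  The
#: ``plateau_range`` entries shape the effort-plateau draw (the plateau
#: duration is a free generator parameter, not a printed table value).
DEFAULT_INDUCTION = {
    "normal": {"trigger_drop": (0.6, 0.9), "cycle_fraction": (0.15, 0.25),
               "plateau_range": (0.1, 0.2)},
    "early_cycling": {"trigger_drop": (0.5, 0.7), "cycle_fraction": (0.65, 0.80)},
    "late_cycling": {"trigger_drop": (0.4, 0.7), "cycle_fraction": (0.05, 0.09),
                     "plateau_range": (0.1, 0.15)},
    "delayed_inspiration": {"trigger_drop": (2.0, 2.5), "cycle_fraction": (0.2, 0.3),
                            "plateau_range": (0.1, 0.2)},
    "ineffective_effort": {"trigger_drop": (3.2, 4.5), "cycle_fraction": (0.25, 0.35)},
    "delayed_inspiration+late_cycling": {
        "trigger_drop": (1.6, 2.0),
        "cycle_fraction": (0.08, 0.12),
        "plateau_range": (0.1, 0.15),
    },
}

#: archetype-specific refinements of the induction settings, reflecting the
#: very different time constants (a long-time-constant lung cycles late at a
#: given fraction, a stiff lung cycles early)
ARCHETYPE_INDUCTION = {
    "obese": {
        "normal": {"cycle_fraction": (0.28, 0.35)},
        "delayed_inspiration+late_cycling": {"trigger_drop": (1.4, 1.8)},
    },
    "ards": {
        "delayed_inspiration": {"cycle_fraction": (0.08, 0.15)},
    },
    "copd": {
        "normal": {"cycle_fraction": (0.05, 0.10)},
        "delayed_inspiration+late_cycling": {"trigger_drop": (1.7, 2.2),
                                             "cycle_fraction": (0.03, 0.06)},
    },
    "healthy": {
        "delayed_inspiration": {"trigger_drop": (2.3, 3.0),
                                "cycle_fraction": (0.08, 0.15)},
    },
}

#: archetype sampling weights (record level); obstructive archetypes carry
#: the late-cycling classes, so they appear more often
DEFAULT_ARCHETYPE_WEIGHTS = {
    "healthy": 0.20, "obese": 0.30, "ards": 0.19, "copd": 0.21, "fibrosis": 0.10,
}

#: breathing-rate draw per archetype (within the global 12-18 range);
#: obstructive patients are ventilated at the slow end to allow exhalation
ARCHETYPE_RATE_RANGES = {
    "obese": (12.0, 12.8),
    "copd": (12.0, 14.0),
}


def induction_for(archetype: str) -> dict:
    """Class->override induction table for one archetype (static defaults)."""
    merged = {}
    for cls, base in DEFAULT_INDUCTION.items():
        entry = dict(base)
        entry.update(ARCHETYPE_INDUCTION.get(archetype, {}).get(cls, {}))
        merged[cls] = entry
    return merged


# ---------------------------------------------------------------------------
# closed-loop induction calibration
#
# The end-inspiration delay realised at a given cycling fraction depends
# strongly on the archetype's time constant and on the calibrated Pinsp, so
# fixed threshold tables induce unreliably.  Before generating records the
# generator therefore probes each virtual patient: it simulates a few
# breaths across a grid of cycling fractions (for both the normal and the
# weak delayed-inspiration effort shapes), measures the realised delays,
# and places each class's thresholds on the measured delay-vs-fraction
# curve.  Classes whose target delay window is unreachable on an archetype
# (e.g. late cycling on a stiff, fast-emptying lung) get a near-zero
# affinity instead of doomed induction attempts.

_PROBE_FRACS = (0.03, 0.10, 0.22, 0.45)


def _probe_delays(lung, circuit, vent, cls, drop, seed, per_frac=3, rate=12.5):
    """Probe rows ``(frac, amplitude, start_delay, end_delay)`` for one shape."""
    from .muscle import BreathSchedule, ScheduledBreath, sample_profile

    rng = np.random.default_rng(seed)
    period = 60.0 / rate
    breaths = []
    fracs = []
    for i in range(per_frac):
        for frac in _PROBE_FRACS:
            start = (len(breaths) + 0.25) * period
            prof = sample_profile(cls, rng, effort_start=start,
                                  plateau_range=(0.1, 0.2),
                                  cardiac_amplitude=0.6, cardiac_frequency=1.4)
            breaths.append(ScheduledBreath(profile=prof, trigger_drop=drop,
                                           cycle_fraction=frac))
            fracs.append(frac)
    duration = (len(breaths) + 0.7) * period
    sched = BreathSchedule(breaths=tuple(breaths), rate=rate, duration=duration)
    rec = simulate(lung, circuit, vent, sched, SimulationConfig(duration=duration))
    anns, _ = annotate_record(rec)
    return [
        (f, b.profile.amplitude, ann.label.start_delay, ann.label.end_delay)
        for f, b, ann in zip(fracs, sched.breaths, anns)
    ]


def _cardiac_gain(lung, circuit, vent):
    """Cardiac-to-sensor pressure transmission gain (dip per cmH2O of
    cardiac Pmus amplitude), measured on an effort-free record."""
    from .muscle import BreathSchedule, MuscleProfile, ScheduledBreath

    prof = MuscleProfile(amplitude=0.0, rise_time=0.5, fall_time=0.3,
                         effort_start=0.5, effort_end=1.5,
                         intended_class="quiet", cardiac_amplitude=1.0,
                         cardiac_frequency=1.4)
    sched = BreathSchedule(breaths=(ScheduledBreath(profile=prof,
                                                    trigger_drop=25.0),),
                           rate=12.0, duration=8.0)
    rec = simulate(lung, circuit, vent, sched, SimulationConfig(duration=8.0))
    tail = rec.pao[rec.t > 3.0]
    return max(float(vent.PEEP - tail.min()), 0.0)


def _fit_ed_model(rows):
    """Least-squares fit of end delay ~ a + b*log(frac) + g*amplitude.

    Returns ``(coef, spread, n)`` where ``spread`` is the residual standard
    deviation (a knife-edge indicator), or ``(None, inf, n)`` when too few
    probed breaths triggered.
    """
    pts = [(f, a, e) for f, a, e, in
           ((f, a, e) for f, a, _, e in rows) if e is not None]
    if len(pts) < 5:
        return None, float("inf"), len(pts)
    X = np.array([[1.0, math.log(f), a] for f, a, _ in pts])
    y = np.array([e for _, _, e in pts])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    spread = float(np.std(resid))
    return tuple(float(c) for c in coef), spread, len(pts)


def _ed_range(coef, amp=7.5):
    """Predicted end-delay range over the usable fraction span [0.02, 0.8]."""
    a0, b0, g0 = coef
    lo = a0 + b0 * math.log(0.8) + g0 * amp
    hi = a0 + b0 * math.log(0.02) + g0 * amp
    return (min(lo, hi), max(lo, hi))


def _model_entry(coef, target, base_frac=(0.1, 0.2)):
    return {"cycle_fraction": base_frac,
            "cycle_fraction_model": {"coef": coef, "target": target,
                                     "clip": (0.02, 0.8)}}


def calibrate_induction(lung, circuit, vent, seed: int = 0):
    """Per-patient induction settings and class-affinity weights.

    Probes the patient with two short records (normal-shaped and weak
    delayed-shaped efforts over a grid of cycling fractions), fits an
    end-delay model ``ed ~ a + b*log(cycle_fraction) + g*amplitude`` per
    effort shape, and places every class's per-breath cycling threshold on
    that model (amplitude-compensated).  Classes whose target delay window
    is unreachable, or whose model residual marks a knife edge, get low
    affinity so the breath allocation avoids this patient for them.

    Returns ``(induction, affinity)``.
    """
    rows_n = _probe_delays(lung, circuit, vent, "normal", 0.6, seed)
    rows_d = _probe_delays(lung, circuit, vent, "delayed_inspiration", 2.2,
                           seed + 1, rate=14.0)
    gain = _cardiac_gain(lung, circuit, vent)
    coef_n, spread_n, _ = _fit_ed_model(rows_n)
    coef_d, spread_d, n_trig_d = _fit_ed_model(rows_d)
    sd_n = [s for _, _, s, _ in rows_n if s is not None]
    sd_d = [s for _, _, s, _ in rows_d if s is not None]
    sd_n_mean = float(np.mean(sd_n)) if sd_n else 1.0
    sd_d_mean = float(np.mean(sd_d)) if sd_d else float("nan")

    induction = {}
    affinity = {}

    def _window_overlap(coef, spread, k, amp=7.5, wlo=-0.1, whi=0.3):
        """Intersection of the achievable end-delay range with the class
        window shrunk by ``k`` residual standard deviations, or None.

        The spread estimate is floored at 0.05 s: the probe record cannot
        see all the breath-to-breath context variation of a full dataset.
        """
        if coef is None:
            return None
        spread = max(spread, 0.05)
        rlo, rhi = _ed_range(coef, amp=amp)
        lo = max(rlo, wlo + k * spread)
        hi = min(rhi, whi - k * spread)
        return (lo, hi) if lo <= hi else None

    # --- normal: place the end delay inside the normal window, as far from
    # both margins as this patient's spread allows
    ov1 = _window_overlap(coef_n, spread_n, 1.0)
    ov05 = _window_overlap(coef_n, spread_n, 0.5)
    tgt_n = 0.10
    if ov1:
        tgt_n = min(max(0.10, ov1[0]), ov1[1])
    elif ov05:
        tgt_n = 0.5 * (ov05[0] + ov05[1])
    induction["normal"] = {"trigger_drop": (0.4, 0.6),
                           "plateau_range": (0.1, 0.2),
                           **_model_entry(coef_n or (0.1, 0.0, 0.0), tgt_n)}
    if ov1 and sd_n_mean < 0.21:
        affinity["normal"] = 1.0
    elif ov05:
        affinity["normal"] = 0.35
    else:
        affinity["normal"] = 0.02

    # --- early cycling: aim far below the -0.1 margin; needs fast
    # triggering despite the slow-rise effort shape
    induction["early_cycling"] = {"trigger_drop": (0.4, 0.6),
                                  **_model_entry(coef_n or (-0.4, 0.0, 0.0),
                                                 -0.45, (0.65, 0.8))}
    if coef_n is not None:
        affinity["early_cycling"] = (1.0 if sd_n_mean < 0.14
                                     else 0.6 if sd_n_mean < 0.165 else 0.05)
    else:
        affinity["early_cycling"] = 0.05

    # --- late cycling: drive the end delay far above the +0.3 margin
    induction["late_cycling"] = {"trigger_drop": (0.4, 0.6),
                                 "plateau_range": (0.1, 0.15),
                                 **_model_entry(coef_n or (1.1, 0.0, 0.0), 1.10,
                                                (0.04, 0.08))}
    ed_max_n = _ed_range(coef_n)[1] if coef_n else -1.0
    if ed_max_n > 0.80 and sd_n_mean < 0.22:
        affinity["late_cycling"] = 1.0
    elif ed_max_n > 0.55:
        affinity["late_cycling"] = 0.3
    else:
        affinity["late_cycling"] = 0.005

    # --- delayed inspiration: raised threshold; end delay in the normal
    # window (weak-effort shape, so the model is evaluated at its amplitude)
    if n_trig_d < 8:
        di_drop = (1.6, 2.0)
    elif sd_d_mean < 0.3:
        di_drop = (2.4, 3.0)
    else:
        di_drop = (2.0, 2.5)
    ov1d = _window_overlap(coef_d, spread_d, 1.0, amp=4.0)
    ov05d = _window_overlap(coef_d, spread_d, 0.5, amp=4.0)
    tgt_d = 0.10
    if ov1d:
        tgt_d = min(max(0.10, ov1d[0]), ov1d[1])
    elif ov05d:
        tgt_d = 0.5 * (ov05d[0] + ov05d[1])
    induction["delayed_inspiration"] = {"trigger_drop": di_drop,
                                        "plateau_range": (0.1, 0.2),
                                        **_model_entry(coef_d or (0.1, 0.0, 0.0),
                                                       tgt_d)}
    if ov1d and n_trig_d >= 8:
        affinity["delayed_inspiration"] = 1.0
    elif ov05d:
        affinity["delayed_inspiration"] = 0.3
    else:
        affinity["delayed_inspiration"] = 0.02

    # --- ineffective effort: threshold far below any weak-effort dip
    induction["ineffective_effort"] = {"trigger_drop": (3.2, 4.5),
                                       "cycle_fraction": (0.25, 0.35)}
    affinity["ineffective_effort"] = 1.0

    # --- delayed inspiration + late cycling
    induction["delayed_inspiration+late_cycling"] = {
        "trigger_drop": (di_drop[0] - 0.3, di_drop[1] - 0.3),
        "plateau_range": (0.1, 0.15),
        **_model_entry(coef_d or (1.1, 0.0, 0.0), 1.10, (0.04, 0.08)),
    }
    ed_max_d = _ed_range(coef_d, amp=4.0)[1] if coef_d else -1.0
    if ed_max_d > 0.80:
        affinity["delayed_inspiration+late_cycling"] = 1.0
    elif ed_max_d > 0.55:
        affinity["delayed_inspiration+late_cycling"] = 0.25
    else:
        affinity["delayed_inspiration+late_cycling"] = 0.005

    for cls in induction:
        induction[cls]["trigger_floor_gain"] = gain
    return induction, affinity


@dataclass(frozen=True)
class NoiseConfig:
    """Sensor-noise settings: SNR ranges in dB, low-pass bandwidth in Hz."""

    pressure_snr_db: Tuple[float, float] = (15.0, 16.0)
    flow_snr_db: Tuple[float, float] = (30.0, 31.0)
    bandwidth: float = 15.0

    def __post_init__(self) -> None:
        for lo, hi in (self.pressure_snr_db, self.flow_snr_db):
            if hi < lo:
                raise ValueError("SNR range must be non-empty")
        if self.bandwidth <= 0:
            raise ValueError("bandwidth must be positive")


@dataclass(frozen=True)
class DatasetConfig:
    """Everything needed to (re)generate one dataset deterministically."""

    n_breaths: int
    out_dir: str
    master_seed: int = 0
    balanced: bool = True
    classes: Tuple[str, ...] = DATASET_CLASSES
    archetypes: Tuple[str, ...] = ARCHETYPE_NAMES
    breaths_per_record: int = 12
    peep: float = 5.0
    fs: float = 100.0
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    rate_range: Tuple[float, float] = (12.0, 18.0)
    tidal_band: Tuple[float, float] = (0.4, 0.6)

    def __post_init__(self) -> None:
        if self.balanced and self.n_breaths < len(self.classes):
            raise ValueError("balanced mode needs at least one breath per class")
        if self.breaths_per_record < 1:
            raise ValueError("breaths_per_record must be >= 1")


# ---------------------------------------------------------------------------
# noise


def add_noise(signal, snr_range, bandwidth, sample_rate, rng):
    """Add low-pass-filtered white noise at an SNR drawn from ``snr_range``.

    The noise is scaled so the realised SNR (total signal power over noise
    power, in dB) equals the drawn value exactly.  Returns
    ``(noisy_signal, realised_snr_db)``.

    Raises
    ------
    ValueError
        For an all-zero signal (SNR undefined) or a bandwidth at/above
        Nyquist.
    """
    signal = np.asarray(signal, dtype=float)
    p_sig = float(np.mean(signal**2))
    if p_sig == 0.0:
        raise ValueError("SNR undefined for an all-zero signal")
    if bandwidth >= sample_rate / 2.0:
        raise ValueError("noise bandwidth must be below Nyquist")
    snr_db = float(rng.uniform(*snr_range))
    white = rng.standard_normal(signal.shape[0])
    b, a = butter(5, bandwidth / (sample_rate / 2.0))
    shaped = lfilter(b, a, white)
    p_noise = float(np.mean(shaped**2))
    scale = math.sqrt(p_sig / (p_noise * 10.0 ** (snr_db / 10.0)))
    return signal + scale * shaped, snr_db


# ---------------------------------------------------------------------------
# pressure auto-calibration


def _calibration_schedule(n_breaths: int, rate: float, duration: float):
    """Deterministic normal-breath schedule used for pressure calibration.

    A fixed representative effort (amplitude 6 cmH2O, from the lower
    middle of the normal 5-10 band so that weak-but-normal efforts still
    reach the band after calibration) with minimal cardiac ripple.
    """
    from .muscle import BreathSchedule, MuscleProfile, ScheduledBreath

    period = 60.0 / rate
    breaths = []
    for i in range(n_breaths):
        start = (i + 0.25) * period
        prof = MuscleProfile(
            amplitude=6.0, rise_time=0.6, fall_time=0.3,
            effort_start=start, effort_end=start + 0.6 + 0.25 + 0.3,
            intended_class="normal", cardiac_amplitude=0.25,
            cardiac_frequency=1.5,
        )
        breaths.append(ScheduledBreath(profile=prof, trigger_drop=1.0,
                                       cycle_fraction=0.3))
    return BreathSchedule(breaths=tuple(breaths), rate=rate, duration=duration)


def _measure_tidal(lung, circuit, vent, seed: int = 0, n_breaths: int = 3):
    """Tidal volume (L) of the last of ``n_breaths`` calibration breaths."""
    rate = 15.0
    duration = (n_breaths + 0.6) * 60.0 / rate
    sched = _calibration_schedule(n_breaths, rate, duration)
    sim = SimulationConfig(duration=duration)
    rec = simulate(lung, circuit, vent, sched, sim)
    pairs = list(zip(rec.events["trigger"], rec.events["cycle"]))
    if not pairs:
        return 0.0
    tr, cy = pairs[-1]
    m = (rec.t >= tr) & (rec.t <= cy)
    return float(np.trapezoid(rec.flow[m], rec.t[m]))


def autoset_pressures(
    lung: LungParameters,
    template: VentilatorConfig,
    circuit: Optional[CircuitParameters] = None,
    tidal_band: Tuple[float, float] = (0.4, 0.6),
    seed: int = 0,
    max_iter: int = 12,
) -> VentilatorConfig:
    """Calibrate Pinsp (PEEP fixed) so a normal breath delivers 0.4-0.6 L.

    Bisection on the simulated tidal volume of a short normal-breath run;
    deterministic for a fixed seed.  Raises ``ValueError`` when the band
    is unreachable within the pressure bounds.
    """
    from .lung import AirwayCollapseError
    from .solver import SolverError

    circuit = circuit or CircuitParameters()
    lo = template.PEEP + 0.2
    hi = template.PEEP + 30.0
    v_lo = _measure_tidal(lung, circuit, template.with_(Pinsp=lo), seed)
    if v_lo > tidal_band[1]:
        raise ValueError("tidal volume above band even at minimal support")
    try:
        v_hi = _measure_tidal(lung, circuit, template.with_(Pinsp=hi), seed)
    except (SolverError, AirwayCollapseError):
        v_hi = math.inf  # over-inflated past the curve range: above the band
    if v_hi < tidal_band[0]:
        raise ValueError("tidal volume below band even at maximal support")
    # aim the representative effort at the upper middle of the band: the
    # admissible normal-effort amplitudes span 5-10 cmH2O, so the weakest
    # draws deliver ~0.1 L less than the representative breath and must
    # still clear the lower bound
    target = tidal_band[0] + 0.8 * (tidal_band[1] - tidal_band[0])
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        v = _measure_tidal(lung, circuit, template.with_(Pinsp=mid), seed)
        if abs(v - target) <= 0.025:
            return template.with_(Pinsp=round(mid, 2))
        if v < target:
            lo = mid
        else:
            hi = mid
    mid = 0.5 * (lo + hi)
    v = _measure_tidal(lung, circuit, template.with_(Pinsp=mid), seed)
    if tidal_band[0] <= v <= tidal_band[1]:
        return template.with_(Pinsp=round(mid, 2))
    raise ValueError(f"could not reach the tidal band; last tidal {v:.3f} L")


# ---------------------------------------------------------------------------
# dataset orchestration


def _class_pool(cfg: DatasetConfig, rng: np.random.Generator) -> dict:
    """Remaining breath count per intended class for the whole dataset."""
    classes = list(cfg.classes)
    if cfg.balanced:
        n_per, rem = divmod(cfg.n_breaths, len(classes))
        pool = {c: n_per for c in classes}
        for c in classes[:rem]:
            pool[c] += 1
    else:
        pool = {c: 0 for c in classes}
        for i in rng.integers(0, len(classes), cfg.n_breaths):
            pool[classes[i]] += 1
    return pool


def _allocate_breaths(pool: dict, affinities: dict, names, base_weights,
                      rng: np.random.Generator) -> dict:
    """Split the class pool across archetypes by measured affinity.

    Each breath of a class is hosted by an archetype drawn with probability
    proportional to (affinity x archetype weight), restricted to archetypes
    whose measured affinity is solid (>= 0.2) whenever any exist.  This
    guarantees e.g. that late-cycling breaths land on long-time-constant
    patients; the global class balance is exact by construction.
    """
    alloc = {a: {} for a in names}
    for cls, count in pool.items():
        w = np.array([affinities[a].get(cls, 1.0) * base_weights[a] for a in names])
        solid = np.array([affinities[a].get(cls, 1.0) >= 0.5 for a in names])
        if solid.any():
            w = w * solid
        if w.sum() <= 0:
            w = np.ones(len(names))
        w = w / w.sum()
        hosts = rng.choice(len(names), size=count, p=w)
        for h in hosts:
            a = names[h]
            alloc[a][cls] = alloc[a].get(cls, 0) + 1
    return alloc


#: how much expiration time a breath of this class leaves to its successor
#: (higher = longer expiration = fast next trigger)
_PRED_QUALITY = {"ineffective_effort": 2, "early_cycling": 2, "normal": 1,
                 "delayed_inspiration": 1, "late_cycling": 0,
                 "delayed_inspiration+late_cycling": 0}
#: how badly a class needs a long preceding expiration (negative = it
#: benefits from residual auto-PEEP, which delays its trigger as intended)
_NEED_PRED = {"late_cycling": 2, "normal": 1, "early_cycling": 1,
              "ineffective_effort": 0, "delayed_inspiration": 1,
              "delayed_inspiration+late_cycling": -1}


def _order_chunk(chunk):
    """Order one record's classes for favourable breath-to-breath context."""
    remaining = list(chunk)
    out = []
    q = 2  # the record starts after a long undisturbed expiration
    while remaining:
        if q >= 1:
            best = max(remaining, key=lambda c: _NEED_PRED.get(c, 0))
        else:
            best = min(remaining, key=lambda c: _NEED_PRED.get(c, 0))
        remaining.remove(best)
        out.append(best)
        q = _PRED_QUALITY.get(best, 1)
    return out


def _simulate_one_record(
    lung, circuit, vent, record_seed: int, record_classes, cfg: DatasetConfig,
    archetype: str, induction: Optional[dict] = None,
):
    rng = np.random.default_rng(record_seed)
    rate_range = ARCHETYPE_RATE_RANGES.get(archetype, cfg.rate_range)
    # records hosting trigger-delay-sensitive classes breathe at the slow
    # end of their range: a longer expiration empties the lung, so the next
    # effort pulls the airway pressure down without fighting residual
    # expiratory flow
    sensitive = {"early_cycling", "late_cycling", "normal"}
    has_sensitive = any(c in sensitive for c in record_classes)
    if has_sensitive:
        rate_range = (rate_range[0], min(rate_range[0] + 1.5, rate_range[1]))
    else:
        rate_range = (max(rate_range[0], 13.0), min(rate_range[1], 16.0))
        if rate_range[0] >= rate_range[1]:
            rate_range = (rate_range[0], rate_range[0] + 0.5)
    rate = float(rng.uniform(*rate_range))
    duration = (len(record_classes) + 0.7) * 60.0 / rate
    ind = induction or induction_for(archetype)
    gain = next(iter(ind.values())).get("trigger_floor_gain", 0.0) if ind else 0.0
    # records hosting trigger-delay-sensitive classes draw the calmer end
    # of the cardiac-amplitude range (the full 0.25-1 range is still
    # covered across the dataset)
    cardiac_range = (0.25, 0.55) if has_sensitive else (0.45, 1.0)
    sched = schedule_breaths(rate, duration, record_classes, rng,
                             induction=ind, cardiac_range=cardiac_range,
                             trigger_floor_gain=gain)
    sim = SimulationConfig(duration=duration, fs=cfg.fs)
    rec = simulate(lung, circuit, vent, sched, sim)
    annotations, anomalies = annotate_record(rec)
    noisy_pao, snr_p = add_noise(rec.pao, cfg.noise.pressure_snr_db,
                                 cfg.noise.bandwidth, cfg.fs, rng)
    noisy_flow, snr_q = add_noise(rec.flow, cfg.noise.flow_snr_db,
                                  cfg.noise.bandwidth, cfg.fs, rng)
    from scipy.integrate import cumulative_trapezoid

    noisy_volume = np.concatenate(([0.0], cumulative_trapezoid(noisy_flow, rec.t)))
    return rec, annotations, anomalies, noisy_pao, noisy_flow, noisy_volume, {
        "rate": rate,
        "pressure_snr_db": snr_p,
        "flow_snr_db": snr_q,
    }


def generate_dataset(cfg: DatasetConfig) -> dict:
    """Generate the full labeled dataset and write it under ``cfg.out_dir``.

    Breath classes are balanced across the whole dataset, chunked into
    records of ``breaths_per_record`` contiguous breaths sharing one
    archetype and one ventilator configuration (Pinsp auto-calibrated per
    archetype for a 0.4-0.6 L normal-breath tidal volume).  Every record
    gets its own seed derived from the master seed, so any record -- or
    the whole dataset -- can be regenerated byte-identically from the
    manifest.  Record failures are logged in the manifest, never hidden.

    Returns the manifest (also written as ``manifest.json``).
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    master = np.random.default_rng(cfg.master_seed)
    circuit = CircuitParameters()

    # per-archetype calibration (deterministic in the master seed)
    lungs = {}
    vents = {}
    inductions = {}
    affinities = {}
    for name in cfg.archetypes:
        spec = archetype_spec(name, peep=cfg.peep)
        lungs[name] = tune_archetype(spec, seed=cfg.master_seed)
        template = VentilatorConfig(PEEP=cfg.peep, Pinsp=cfg.peep + 10.0)
        vents[name] = autoset_pressures(
            lungs[name], template, circuit, cfg.tidal_band, seed=cfg.master_seed
        )
        inductions[name], affinities[name] = calibrate_induction(
            lungs[name], circuit, vents[name], seed=cfg.master_seed
        )

    pool = _class_pool(cfg, master)
    names = list(cfg.archetypes)
    base_w = {a: DEFAULT_ARCHETYPE_WEIGHTS.get(a, 1.0) for a in names}
    alloc = _allocate_breaths(pool, affinities, names, base_w, master)

    # expand each archetype's share into per-record chunks; within a record
    # the breath order is arranged so that trigger-delay-sensitive classes
    # follow short-inspiration breaths (an ineffective effort or an early
    # cycled breath leaves a long expiration, minimising residual
    # auto-PEEP at the next effort), while the delayed classes follow
    # long-inspiration breaths
    jobs = []
    for a in names:
        seq = [c for c, k in sorted(alloc[a].items()) for _ in range(k)]
        master.shuffle(seq)
        for j in range(0, len(seq), cfg.breaths_per_record):
            jobs.append((a, _order_chunk(seq[j : j + cfg.breaths_per_record])))
    master.shuffle(jobs)

    entries = []
    intended_totals: dict = {}
    realized_totals: dict = {}
    failures = []
    for i, (archetype, chunk) in enumerate(jobs):
        record_seed = int(master.integers(0, 2**31 - 1))
        base = out / f"record_{i:04d}"
        try:
            rec, anns, anomalies, npao, nflow, nvol, meta = _simulate_one_record(
                lungs[archetype], circuit, vents[archetype], record_seed, chunk,
                cfg, archetype, induction=inductions[archetype]
            )
        except Exception as exc:  # noqa: BLE001 - report, do not hide
            failures.append({"record": base.name, "error": str(exc)})
            continue
        meta.update({"record_seed": record_seed, "archetype": archetype})
        write_record(rec, base, annotations=anns, anomalies=anomalies,
                     pao=npao, flow=nflow, volume=nvol, meta=meta)
        intended = {}
        realized = {}
        for b, ann in zip(rec.schedule.breaths, anns):
            c = b.profile.intended_class
            intended[c] = intended.get(c, 0) + 1
            intended_totals[c] = intended_totals.get(c, 0) + 1
            r = ann.label.label
            realized[r] = realized.get(r, 0) + 1
            realized_totals[r] = realized_totals.get(r, 0) + 1
        entries.append(
            {
                "file": base.name,
                "seed": record_seed,
                "archetype": archetype,
                "n_breaths": len(chunk),
                "rate": meta["rate"],
                "PEEP": vents[archetype].PEEP,
                "Pinsp": vents[archetype].Pinsp,
                "pressure_snr_db": meta["pressure_snr_db"],
                "flow_snr_db": meta["flow_snr_db"],
                "intended_classes": intended,
                "realized_classes": realized,
                "anomalies": len(anomalies),
            }
        )
    manifest = {
        "config": {
            **dataclasses.asdict(cfg),
        },
        "records": entries,
        "failures": failures,
        "intended_class_counts": intended_totals,
        "realized_class_counts": realized_totals,
        "n_breaths_written": sum(e["n_breaths"] for e in entries),
        "partial": bool(failures),
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True), encoding="utf-8"
    )
    return manifest


def audit_manifest(out_dir) -> dict:
    """Recount classes from the sidecars and compare with the manifest.

    Returns match flags and the induction success rate (fraction of
    breaths whose realised label equals the intended class).
    """
    out = Path(out_dir)
    manifest = json.loads((out / "manifest.json").read_text(encoding="utf-8"))
    recount: dict = {}
    n_match = 0
    n_total = 0
    for entry in manifest["records"]:
        sidecar = json.loads(
            (out / f"{entry['file']}.json").read_text(encoding="utf-8")
        )
        for row in sidecar.get("breaths", []):
            recount[row["label"]] = recount.get(row["label"], 0) + 1
            n_total += 1
            if row["label"] == row["intended_class"]:
                n_match += 1
    return {
        "counts_match": recount == manifest["realized_class_counts"],
        "recount": recount,
        "manifest_counts": manifest["realized_class_counts"],
        "induction_success": (n_match / n_total) if n_total else float("nan"),
        "n_breaths": n_total,
    }
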