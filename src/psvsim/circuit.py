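"""Ventilator, breathing circuit and trigger/cycle logic.

The breathing set is split into an inspiratory and an expiratory limb, each
modeled by a Rohrer resistance (turbulence matters at clinical flow rates),
an inertance and a tubing compliance.  Two pressure sources (PEEP and
Pinsp) feed the limbs through unidirectional, diode-like valves that are
switched by the trigger/cycle state machine; the expiratory valve also
blocks inspiration from the contaminated expiratory connection.  The
proximal sensor sits at the Y-piece, upstream of the endotracheal tube,
which is itself a Rohrer resistance in series with the patient's upper
airway.

The numeric constants for the 9 mm endotracheal tube and the tubing ship
as editable defaults of realistic magnitude (total circuit resistance at
1 L/s of the same order as the airway resistance); they are not
authoritative measurements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "LimbParameters",
    "CircuitParameters",
    "VentilatorConfig",
    "VentilatorState",
    "rohrer_resistance",
    "rohrer_drop",
    "rohrer_flow",
    "et_tube_resistance",
    "source_pressure",
    "check_trigger",
    "check_cycle",
    "valve_flow",
]


@dataclass(frozen=True)
class LimbParameters:
    """One tubing limb: Rohrer resistance + inertance + compliance."""

    TubeA: float = 0.4   # cmH2O.s/L
    TubeK: float = 0.8   # cmH2O.s^2/L^2
    L: float = 0.02      # cmH2O.s^2/L
    C: float = 0.002     # L/cmH2O

    def __post_init__(self) -> None:
        for name in ("TubeA", "TubeK", "L", "C"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.L == 0 or self.C == 0:
            raise ValueError("limb inertance and compliance must be positive")


@dataclass(frozen=True)
class CircuitParameters:
    """Endotracheal tube, tubing limbs and valve conductances."""

    EtA: float = 1.9     # 9 mm ET tube Rohrer, cmH2O.s/L
    EtK: float = 3.3     # cmH2O.s^2/L^2
    insp: LimbParameters = field(default_factory=LimbParameters)
    exp: LimbParameters = field(default_factory=LimbParameters)
    g_forward: float = 10.0    # open-valve conductance, L/s per cmH2O
    g_blocking: float = 1.0e-6  # closed/reverse leakage conductance
    knee: float = 0.05   # diode smoothing knee, cmH2O

    def __post_init__(self) -> None:
        if self.EtA < 0 or self.EtK < 0:
            raise ValueError("ET tube Rohrer coefficients must be non-negative")
        if self.g_forward <= 0 or self.g_blocking < 0:
            raise ValueError("valve conductances must be positive/non-negative")
        if self.g_blocking > 1.0e-6 * self.g_forward:
            raise ValueError("blocking conductance must be <= 1e-6 x forward")
        if self.knee <= 0:
            raise ValueError("knee must be positive")

    def with_(self, **kwargs) -> "CircuitParameters":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class VentilatorConfig:
    """Pressure-support settings and switching thresholds.

    ``trigger_drop`` defaults to the 1-2 cmH2O-below-PEEP band and
    ``cycle_fraction`` to the 10-80 % of peak-flow band; both may be set
    outside those bands deliberately (that is how asynchronies are
    induced) via per-breath overrides, in which case ``strict=False``
    skips the range check.
    """

    PEEP: float = 5.0
    Pinsp: float = 12.0
    trigger_drop: float = 1.5
    cycle_fraction: float = 0.3
    pressurization: str = "trapezoid"   # "block" | "trapezoid"
    rise_time: float = 0.08             # s, trapezoid ramp
    breath_rate: float = 15.0           # breaths/min context
    trigger_mode: str = "pressure"      # "pressure" | "flow"
    flow_trigger: float = 0.1           # L/s, used when trigger_mode == "flow"
    min_insp_time: float = 0.1          # s before cycling is permitted
    refractory: float = 0.1             # s after cycling before re-triggering
    strict: bool = True

    def __post_init__(self) -> None:
        if not (self.Pinsp > self.PEEP >= 0):
            raise ValueError("require Pinsp > PEEP >= 0")
        if self.pressurization not in ("block", "trapezoid"):
            raise ValueError("pressurization must be 'block' or 'trapezoid'")
        if self.trigger_mode not in ("pressure", "flow"):
            raise ValueError("trigger_mode must be 'pressure' or 'flow'")
        if not (0.0 < self.cycle_fraction < 1.0):
            raise ValueError("cycle_fraction must be in (0, 1)")
        if self.strict:
            if not (0.10 <= self.cycle_fraction <= 0.80):
                raise ValueError("cycle_fraction outside the 10-80 % band")
            if not (1.0 <= self.trigger_drop <= 2.0):
                raise ValueError("trigger_drop outside the 1-2 cmH2O band")
        elif self.trigger_drop <= 0:
            raise ValueError("trigger_drop must be positive")
        if self.min_insp_time < 0 or self.refractory < 0 or self.rise_time < 0:
            raise ValueError("times must be non-negative")

    def with_(self, **kwargs) -> "VentilatorConfig":
        return replace(self, **kwargs)


@dataclass
class VentilatorState:
    """Trigger/cycle state machine state."""

    phase: str = "expiratory"           # "expiratory" | "inspiratory"
    t_trigger: float = -math.inf
    t_cycle: float = -math.inf
    peak_flow: float = 0.0
    insp_valve_open: bool = False
    exp_valve_open: bool = True


# ---------------------------------------------------------------------------
# Rohrer helpers


def rohrer_resistance(A, K, flow):
    """Flow-dependent Rohrer resistance ``A + K*|flow|`` (even in flow)."""
    return A + K * np.abs(flow)


def et_tube_resistance(EtA, EtK, flow):
    """Endotracheal-tube resistance; same Rohrer contract as the upper airway."""
    return rohrer_resistance(EtA, EtK, flow)


def rohrer_drop(A, K, flow):
    """Pressure drop ``(A + K*|q|) * q`` across a Rohrer resistor."""
    return (A + K * np.abs(flow)) * flow


def rohrer_flow(A, K, dp):
    """Flow through a Rohrer resistor for a given pressure drop.

    Inverts ``dp = (A + K*|q|) q`` (the positive root of the quadratic);
    reduces to ``dp/A`` when K = 0.
    """
    if K == 0.0:
        return dp / A
    mag = (math.sqrt(A * A + 4.0 * K * abs(dp)) - A) / (2.0 * K)
    return math.copysign(mag, dp)


# ---------------------------------------------------------------------------
# sources and valves


def source_pressure(phase: str, config: VentilatorConfig, t_since_trigger: float = 0.0):
    """Ventilator source pressure for the given phase.

    Expiratory phase: PEEP.  Inspiratory phase: Pinsp immediately (block)
    or a linear ramp from PEEP to Pinsp over ``rise_time`` (trapezoid).
    """
    if phase == "expiratory":
        return config.PEEP
    if phase != "inspiratory":
        raise ValueError(f"unknown phase {phase!r}")
    if config.pressurization == "block" or config.rise_time == 0.0:
        return config.Pinsp
    frac = min(1.0, max(0.0, t_since_trigger / config.rise_time))
    return config.PEEP + (config.Pinsp - config.PEEP) * frac


def valve_flow(dp, open_, g_forward, g_blocking, knee=0.05):
    """Flow through a (smoothed) unidirectional valve.

    When commanded open, the conductance blends from ``g_blocking``
    (reverse bias) to ``g_forward`` (forward bias) over a logistic knee of
    width ``knee`` cmH2O, keeping the ODE right-hand side continuous; the
    ideal diode is recovered as ``knee -> 0``.  When commanded closed only
    the blocking leakage remains.
    """
    if not open_:
        return g_blocking * dp
    x = dp / knee
    if x > 40.0:
        sig = 1.0
    elif x < -40.0:
        sig = 0.0
    else:
        sig = 1.0 / (1.0 + math.exp(-x))
    return (g_blocking + (g_forward - g_blocking) * sig) * dp


# ---------------------------------------------------------------------------
# trigger / cycle state machine (sample-by-sample form; the solver locates
# the same crossings in continuous time via event functions)


def check_trigger(
    sensor_pressure: float,
    config: VentilatorConfig,
    state: VentilatorState,
    t: float = 0.0,
    sensor_flow: float = 0.0,
    trigger_drop: Optional[float] = None,
) -> Optional[str]:
    """Fire a trigger if the sensor signal crosses the trigger threshold.

    Pressure triggering (default): sensor pressure < PEEP - trigger_drop.
    Flow triggering (optional mode): sensor flow > flow_trigger.
    On firing, switches to the inspiratory phase, opens the inspiratory
    valve, closes the expiratory valve and resets the running peak flow.
    """
    if state.phase != "expiratory":
        raise ValueError("trigger checks run in the expiratory phase only")
    if t - state.t_cycle < config.refractory:
        return None
    drop = config.trigger_drop if trigger_drop is None else trigger_drop
    if config.trigger_mode == "pressure":
        fired = sensor_pressure < config.PEEP - drop
    else:
        fired = sensor_flow > config.flow_trigger
    if not fired:
        return None
    state.phase = "inspiratory"
    state.t_trigger = t
    state.peak_flow = 0.0
    state.insp_valve_open = True
    state.exp_valve_open = False
    return "trigger"


def check_cycle(
    insp_flow: float,
    config: VentilatorConfig,
    state: VentilatorState,
    t: float = 0.0,
    cycle_fraction: Optional[float] = None,
) -> Optional[str]:
    """Fire a cycle when flow falls to the set fraction of its peak.

    The running peak resets at each trigger and is updated here; a sample
    at (or above) the current peak can never cycle, and cycling is
    suppressed for ``min_insp_time`` after the trigger to avoid cycling on
    the trigger transient.
    """
    if state.phase != "inspiratory":
        raise ValueError("cycle checks run in the inspiratory phase only")
    frac = config.cycle_fraction if cycle_fraction is None else cycle_fraction
    if insp_flow >= state.peak_flow:
        state.peak_flow = insp_flow
        return None
    if t - state.t_trigger < config.min_insp_time:
        return None
    if insp_flow > frac * state.peak_flow:
        return None
    state.phase = "expiratory"
    state.t_cycle = t
    state.insp_valve_open = False
    state.exp_valve_open = True
    return "cycle"
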