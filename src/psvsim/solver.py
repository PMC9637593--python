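"""Coupled patient-ventilator simulation.

The patient network (:mod:`psvsim.lung`) and breathing circuit
(:mod:`psvsim.circuit`) are assembled into a seven-state stiff ODE system

    y = [Vc, VA, Vve, Qi, Qe, Pai, Pae]

with the three stored patient volumes (collapsible segment, alveolar,
visco-elastic), the two limb inertance flows and the two tubing-compliance
pressures.  All node pressures are derived from the stored volumes through
the closed-form curve inversions, which makes "lung volume equals
chest-wall volume" hold by construction: the chest-wall curve is always
evaluated at the summed gas volume ``Vc + VA``.

Triggering and cycling are located in continuous time with terminal event
functions (pressure-threshold crossing for the trigger; running-peak
tracking plus a fractional-peak crossing for the cycle), never on the
sample grid.  Initial conditions come from an exact algebraic equilibrium
solve; the source network's PipPEEP/Rd initialisation construction is
thereby replaced without its slow artificial transient.

Flow is positive into the patient.  The sensor sits at the Y-piece:
``flow`` is the common flow through ET tube and upper airway, ``pao`` the
pressure just upstream of the ET tube.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import List, Optional

import numpy as np
from scipy.integrate import cumulative_trapezoid, solve_ivp
from scipy.signal import resample_poly

from .circuit import CircuitParameters, VentilatorConfig
from .lung import AirwayCollapseError, LungParameters, LungState, static_equilibrium
from .muscle import BreathSchedule

__all__ = [
    "SimulationConfig",
    "WaveformRecord",
    "SolverError",
    "equilibrium_init",
    "simulate",
    "resample_record",
]


class SolverError(RuntimeError):
    """Integration failed or produced a non-finite state."""


@dataclass(frozen=True)
class SimulationConfig:
    """Numerical settings for one run.

    ``max_step`` applies on smooth stretches; ``transition_max_step``
    (default 5 ms) bounds the step during the first 100 ms after each
    phase transition where the valve knees make the system stiffest.
    ``collapse_fraction``: integration aborts loudly if the collapsible
    volume falls below this fraction of Vcmax.  ``max_insp_time`` is a
    safety guard that forces cycling (logged) if the flow criterion is
    never met.
    """

    duration: float = 60.0
    fs: float = 100.0
    rtol: float = 1.0e-6
    atol: float = 1.0e-8
    max_step: float = 0.05
    transition_max_step: float = 0.005
    transition_window: float = 0.1
    collapse_fraction: float = 0.005
    max_insp_time: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs < 50.0:
            raise ValueError("sample rate must be >= 50 Hz")
        if self.rtol <= 0 or self.atol <= 0:
            raise ValueError("solver tolerances must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")


@dataclass
class WaveformRecord:
    """Sampled sensor signals plus ground-truth channels and event times.

    ``volume`` is the running integral of sensor flow (volume above the
    initialisation volume, clinical convention); ``v_lung`` is the
    absolute lung gas volume ground truth.  ``events`` holds every
    ventilator trigger/cycle and every patient effort start/end/max, in
    seconds.
    """

    t: np.ndarray
    pao: np.ndarray
    flow: np.ndarray
    volume: np.ndarray
    pmus: np.ndarray
    p_alv: np.ndarray
    ppl: np.ndarray
    v_lung: np.ndarray
    vc: np.ndarray
    phase: np.ndarray          # 0 = expiratory, 1 = inspiratory
    fs: float
    events: dict
    schedule: Optional[BreathSchedule] = None
    lung: Optional[LungParameters] = None
    circuit: Optional[CircuitParameters] = None
    vent: Optional[VentilatorConfig] = None
    sim: Optional[SimulationConfig] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.t)
        for name in ("pao", "flow", "volume", "pmus", "p_alv", "ppl", "v_lung", "vc", "phase"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"channel {name} length mismatch")

    @property
    def duration(self) -> float:
        return float(self.t[-1]) + 1.0 / self.fs if len(self.t) else 0.0

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time": self.t,
                "pao": self.pao,
                "flow": self.flow,
                "volume": self.volume,
                "pmus": self.pmus,
                "p_alv": self.p_alv,
                "ppl": self.ppl,
                "v_lung": self.v_lung,
                "phase": self.phase,
            }
        )


# ---------------------------------------------------------------------------


def equilibrium_init(
    lung: LungParameters, circuit: CircuitParameters, peep: float
) -> LungState:
    """Static state with zero flows at applied pressure ``peep``.

    Every airway and circuit node sits at ``peep``, the Kelvin capacitor
    is relaxed and the pleural pressure balances the chest wall at the
    common lung volume.  The residual of the static network equations is
    verified to < 1e-8.
    """
    ppl, vc, va = static_equilibrium(lung, peep)
    state = LungState(
        Vc=vc,
        VA=va,
        Vve=0.0,
        Vcw=vc + va,
        Pc=peep - ppl,
        Pt=peep - ppl,
        Pcw=ppl,
        Pmus=0.0,
        Qcw=0.0,
        PipPEEP=peep,
    )
    from .lung import chest_wall_pressure

    resid = abs(float(chest_wall_pressure(lung.TLC, lung.RV, lung.Acw, lung.Bcw, vc + va)) - ppl)
    if resid > 1e-8:
        raise SolverError(f"equilibrium residual {resid:.2e} exceeds 1e-8")
    return state


def _ramp_scalar(tau: float, T: float, r: float) -> float:
    """Scalar twin of muscle._ramp_shape for the ODE right-hand side."""
    if tau <= 0.0:
        return 0.0
    if tau >= T:
        return 1.0
    if r <= 0.0:
        return tau / T
    s = 1.0 / (T - r)
    if tau < r:
        return 0.5 * s * (tau - (r / math.pi) * math.sin(math.pi * tau / r))
    if tau <= T - r:
        return 0.5 * s * r + s * (tau - r)
    tm = tau - (T - r)
    return (
        0.5 * s * r
        + s * (T - 2.0 * r)
        + 0.5 * s * (tm + (r / math.pi) * math.sin(math.pi * tm / r))
    )


class _Model:
    """Closure bundle: constants, Pmus lookup, RHS and channel algebra."""

    def __init__(self, lung, circuit, vent, schedule):
        p, c, v = lung, circuit, vent
        self.lung, self.circuit, self.vent = p, c, v
        # patient constants
        self.Vcmax, self.Kc = p.Vcmax, p.Kc
        self.invDc = 1.0 / p.Dc
        self.Ac, self.Bc = p.Ac, p.Bc
        self.As, self.Ks, self.Bs = p.As, p.Ks, p.Bs
        self.RV = p.RV
        self.invVsr = 1.0 / (p.Vstar - p.RV)
        self.S = p.TLC - p.RV
        self.Acw, self.Bcw = p.Acw, p.Bcw
        self.Al, self.Bl, self.Dl = p.Al, p.Bl, p.Dl
        if p.Cve > 0 and p.Rve > 0:
            self.inv_Cve = 1.0 / p.Cve
            self.inv_RveCve = 1.0 / (p.Rve * p.Cve)
        else:  # Kelvin body disabled
            self.inv_Cve = 0.0
            self.inv_RveCve = 0.0
        # series Rohrer: ET tube + upper airway share the sensor flow
        self.SerA = c.EtA + p.Au
        self.SerK = c.EtK + p.Ku
        self.TAi, self.TKi = c.insp.TubeA, c.insp.TubeK
        self.TAe, self.TKe = c.exp.TubeA, c.exp.TubeK
        self.invLi, self.invLe = 1.0 / c.insp.L, 1.0 / c.exp.L
        self.invCi, self.invCe = 1.0 / c.insp.C, 1.0 / c.exp.C
        self.gf, self.gb, self.knee = c.g_forward, c.g_blocking, c.knee
        self.PEEP, self.Pinsp = v.PEEP, v.Pinsp
        self.block = v.pressurization == "block" or v.rise_time == 0.0
        self.inv_rise = 0.0 if self.block else 1.0 / v.rise_time
        # phase context (mutated by the segment loop)
        self.insp = False
        self.t_trig = -math.inf
        # Pmus tables
        profs = schedule.profiles if schedule is not None else []
        self._starts = [pr.effort_start for pr in profs]
        self._ptab = [
            (
                pr.effort_start,
                pr.effort_end,
                pr.amplitude,
                pr.rise_time,
                pr.fall_time,
                pr.rounding,
                pr.effort_end - pr.fall_time,
            )
            for pr in profs
        ]
        if profs:
            self.camp = profs[0].cardiac_amplitude
            self.cw = 2.0 * math.pi * profs[0].cardiac_frequency
        else:
            self.camp = 0.0
            self.cw = 0.0

    # -- muscle pressure ---------------------------------------------------
    def pmus(self, t: float) -> float:
        v = self.camp * math.sin(self.cw * t) if self.camp else 0.0
        i = bisect.bisect_right(self._starts, t) - 1
        if i >= 0:
            st, en, amp, rise, fall, rnd, fstart = self._ptab[i]
            if t < en:
                v -= amp * (
                    _ramp_scalar(t - st, rise, rnd)
                    - _ramp_scalar(t - fstart, fall, rnd)
                )
        return v

    def pmus_vec(self, t: np.ndarray) -> np.ndarray:
        from .muscle import _ramp_shape

        out = self.camp * np.sin(self.cw * t) if self.camp else np.zeros_like(t)
        if self._ptab:
            env = np.zeros_like(t)
            for st, en, amp, rise, fall, rnd, fstart in self._ptab:
                m = (t > st) & (t < en)
                if not m.any():
                    continue
                tm = t[m]
                env[m] -= amp * (
                    _ramp_shape(tm - st, rise, rnd) - _ramp_shape(tm - fstart, fall, rnd)
                )
            out = out + env
        return out

    # -- valves ------------------------------------------------------------
    def _valve(self, dp: float, open_: bool) -> float:
        if not open_:
            return self.gb * dp
        x = dp / self.knee
        if x > 40.0:
            sig = 1.0
        elif x < -40.0:
            sig = 0.0
        else:
            sig = 1.0 / (1.0 + math.exp(-x))
        return (self.gb + (self.gf - self.gb) * sig) * dp

    # -- core algebra ------------------------------------------------------
    def _nodes(self, t, Vc, VA, Vve, Qu):
        """Return (Ppl, Pmid, PA, Pao, Rc, Rs) at one state point."""
        ratio = (self.Vcmax / Vc) ** self.invDc - 1.0
        if ratio < 1e-12:
            ratio = 1e-12
        Pc = self.Bc - math.log(ratio) / self.Ac
        V = Vc + VA
        dv = V - self.RV
        if dv < 1e-9:
            dv = 1e-9
        acw = self.S / dv - 0.99
        if acw < 1e-12:
            acw = 1e-12
        Pcw = self.Acw - self.Bcw * math.log(acw)
        Ppl = Pcw + self.pmus(t)
        aA = self.Al / VA - 1.0
        if aA < 1e-12:
            aA = 1e-12
        Pt = self.Dl - math.log(aA) / self.Bl
        PA = Ppl + Pt + Vve * self.inv_Cve
        Pmid = Ppl + Pc
        Rc = self.Kc * (self.Vcmax / Vc) ** 2
        Rs = self.As * math.exp(self.Ks * (VA - self.RV) * self.invVsr) + self.Bs
        Pao = Pmid + (self.SerA + self.SerK * abs(Qu)) * Qu
        return Ppl, Pmid, PA, Pao, Rc, Rs

    def sensor_pressure(self, t: float, y) -> float:
        Qu = y[3] - y[4]
        return self._nodes(t, y[0], y[1], y[2], Qu)[3]

    def rhs(self, t, y):
        Vc, VA, Vve, Qi, Qe, Pai, Pae = y
        if Vc < 1e-6:
            Vc = 1e-6
        Qu = Qi - Qe
        Ppl, Pmid, PA, Pao, Rc, Rs = self._nodes(t, Vc, VA, Vve, Qu)
        QA = (Pmid - PA) / (Rc + Rs)
        dVc = Qu - QA
        dVA = QA
        dVve = QA - Vve * self.inv_RveCve
        if self.insp:
            if self.block:
                Psrc = self.Pinsp
            else:
                f = (t - self.t_trig) * self.inv_rise
                if f > 1.0:
                    f = 1.0
                Psrc = self.PEEP + (self.Pinsp - self.PEEP) * f
            # the inspiratory valve is a switched connection to the
            # pressure source (bidirectional when open); only the
            # expiratory port carries the contamination-blocking diode
            qvi = self.gf * (Psrc - Pai)
            qve = self.gb * (Pae - self.PEEP)
        else:
            qvi = self.gb * (self.PEEP - Pai)
            qve = self._valve(Pae - self.PEEP, True)
        dQi = (Pai - Pao - (self.TAi + self.TKi * abs(Qi)) * Qi) * self.invLi
        dQe = (Pao - Pae - (self.TAe + self.TKe * abs(Qe)) * Qe) * self.invLe
        dPai = (qvi - Qi) * self.invCi
        dPae = (Qe - qve) * self.invCe
        return (dVc, dVA, dVve, dQi, dQe, dPai, dPae)

    # -- vectorised channel reconstruction ---------------------------------
    def channels(self, t: np.ndarray, Y: np.ndarray):
        """Derived channels for sampled states Y of shape (n, 7)."""
        Vc, VA, Vve = Y[:, 0], Y[:, 1], Y[:, 2]
        Qu = Y[:, 3] - Y[:, 4]
        ratio = np.maximum((self.Vcmax / Vc) ** self.invDc - 1.0, 1e-12)
        Pc = self.Bc - np.log(ratio) / self.Ac
        V = Vc + VA
        acw = np.maximum(self.S / np.maximum(V - self.RV, 1e-9) - 0.99, 1e-12)
        Pcw = self.Acw - self.Bcw * np.log(acw)
        pmus = self.pmus_vec(t)
        Ppl = Pcw + pmus
        aA = np.maximum(self.Al / VA - 1.0, 1e-12)
        Pt = self.Dl - np.log(aA) / self.Bl
        PA = Ppl + Pt + Vve * self.inv_Cve
        Pao = Ppl + Pc + (self.SerA + self.SerK * np.abs(Qu)) * Qu
        return Pao, Qu, pmus, PA, Ppl, V


def _make_event(fn, terminal=True, direction=0):
    fn.terminal = terminal
    fn.direction = direction
    return fn


def simulate(
    lung: LungParameters,
    circuit: CircuitParameters,
    vent: VentilatorConfig,
    schedule: BreathSchedule,
    sim: SimulationConfig,
) -> WaveformRecord:
    """Integrate the coupled network and sample the proximal sensor.

    Returns a complete :class:`WaveformRecord`; bitwise reproducible for
    fixed configuration (the solver itself is deterministic, all
    randomness lives in the schedule).

    Raises
    ------
    AirwayCollapseError
        If the collapse guard fires (Vc below the configured fraction of
        Vcmax), with the simulation time in the message.
    SolverError
        On integrator failure or non-finite states.
    """
    m = _Model(lung, circuit, vent, schedule)
    duration = sim.duration
    n = int(round(duration * sim.fs))
    grid = np.arange(n) / sim.fs
    Y = np.empty((n, 7))
    phase_arr = np.zeros(n, dtype=np.int8)
    next_idx = 0

    state0 = equilibrium_init(lung, circuit, vent.PEEP)
    y = np.array([state0.Vc, state0.VA, 0.0, 0.0, 0.0, vent.PEEP, vent.PEEP])
    t = 0.0

    triggers: List[float] = []
    cycles: List[float] = []
    forced_cycles: List[float] = []
    nfev = 0

    vc_floor = sim.collapse_fraction * lung.Vcmax

    def collapse_event(tt, yy):
        return yy[0] - vc_floor

    collapse_event.terminal = True
    collapse_event.direction = -1

    def integrate(t0, y0, t1, events, max_step):
        nonlocal nfev
        if t1 - t0 < 1e-12:
            return None
        sol = solve_ivp(
            m.rhs,
            (t0, t1),
            y0,
            method="LSODA",
            dense_output=True,
            events=events,
            rtol=sim.rtol,
            atol=sim.atol,
            max_step=max_step,
        )
        if not sol.success:
            raise SolverError(f"integration failed at t={sol.t[-1]:.3f} s: {sol.message}")
        if not np.all(np.isfinite(sol.y[:, -1])):
            raise SolverError(f"non-finite state at t={sol.t[-1]:.3f} s")
        nfev += sol.nfev
        return sol

    def store(sol, t_end):
        nonlocal next_idx
        i = next_idx
        while i < n and grid[i] <= t_end + 1e-12:
            i += 1
        if i > next_idx:
            ts = np.clip(grid[next_idx:i], sol.t[0], sol.t[-1])
            Y[next_idx:i] = sol.sol(ts).T
            phase_arr[next_idx:i] = 1 if m.insp else 0
            next_idx = i

    def check_collapse(sol):
        if sol.t_events is not None and len(sol.t_events[0]):
            tc = sol.t_events[0][0]
            store(sol, tc)
            raise AirwayCollapseError(
                f"collapsible airway volume fell below "
                f"{sim.collapse_fraction:.1%} of Vcmax at t={tc:.3f} s"
            )

    starts = [b.start for b in schedule.breaths]
    n_breaths = len(starts)

    def effort_pointer(now: float) -> int:
        """First effort that could still own the next trigger."""
        k = bisect.bisect_right(starts, now)
        # an effort that has started but not ended may still trigger
        if k > 0 and now < schedule.breaths[k - 1].profile.effort_end and (
            not triggers or triggers[-1] < starts[k - 1]
        ):
            return k - 1
        return k

    while t < duration - 1e-9:
        if not m.insp:
            # ----------------------------------------------------- expiration
            # refractory window right after a cycle: no trigger checks
            if cycles and t == cycles[-1]:
                t1 = min(duration, t + vent.refractory)
                sol = integrate(t, y, t1, [collapse_event], sim.transition_max_step)
                if sol is not None:
                    check_collapse(sol)
                    store(sol, sol.t[-1])
                    t, y = sol.t[-1], sol.y[:, -1]
                if t >= duration - 1e-9:
                    break
            k = effort_pointer(t)
            drop = vent.trigger_drop
            if k < n_breaths and schedule.breaths[k].trigger_drop is not None:
                drop = schedule.breaths[k].trigger_drop
            # threshold may change at the next effort boundary
            t_boundary = starts[k + 1] if k + 1 < n_breaths else duration
            t1 = min(duration, max(t_boundary, t + 1e-6))
            thresh = vent.PEEP - drop

            if vent.trigger_mode == "pressure":
                def trig_event(tt, yy, _th=thresh):
                    return m.sensor_pressure(tt, yy) - _th

                trig_event.direction = -1
            else:
                def trig_event(tt, yy, _th=vent.flow_trigger):
                    return (yy[3] - yy[4]) - _th

                trig_event.direction = 1
            trig_event.terminal = True

            sol = integrate(t, y, t1, [collapse_event, trig_event], sim.max_step)
            if sol is None:
                t = t1
                continue
            check_collapse(sol)
            if len(sol.t_events[1]):
                t_ev = sol.t_events[1][0]
                store(sol, t_ev)
                t = t_ev
                y = sol.sol(t_ev)
                triggers.append(float(t))
                m.insp = True
                m.t_trig = t
            else:
                store(sol, sol.t[-1])
                t, y = sol.t[-1], sol.y[:, -1]
        else:
            # ---------------------------------------------------- inspiration
            t_trig = m.t_trig
            frac = vent.cycle_fraction
            kk = bisect.bisect_right(starts, t_trig) - 1
            if 0 <= kk < n_breaths and schedule.breaths[kk].cycle_fraction is not None:
                frac = schedule.breaths[kk].cycle_fraction
            t_forced = min(duration, t_trig + sim.max_insp_time)

            # minimum inspiratory time: no cycling, track the peak densely
            t1 = min(t_trig + vent.min_insp_time, t_forced)
            peak = 0.0
            sol = integrate(t, y, t1, [collapse_event], sim.transition_max_step)
            if sol is not None:
                check_collapse(sol)
                ts = np.linspace(sol.t[0], sol.t[-1], max(8, int((sol.t[-1] - sol.t[0]) / 0.002)))
                qs = sol.sol(ts)
                peak = max(peak, float(np.max(qs[3] - qs[4])))
                store(sol, sol.t[-1])
                t, y = sol.t[-1], sol.y[:, -1]

            cycled = False
            while not cycled and t < duration - 1e-9:
                dydt = m.rhs(t, y)
                rising = (dydt[3] - dydt[4]) > 0.0
                qu_now = y[3] - y[4]
                if rising or qu_now > peak:
                    # flow still climbing: run to the (next) peak
                    def peak_event(tt, yy):
                        d = m.rhs(tt, yy)
                        return d[3] - d[4]

                    peak_event.terminal = True
                    peak_event.direction = -1
                    sol = integrate(t, y, min(t_forced, duration), [collapse_event, peak_event], sim.max_step)
                    if sol is None:
                        break
                    check_collapse(sol)
                    if len(sol.t_events[1]):
                        t_ev = sol.t_events[1][0]
                        store(sol, t_ev)
                        t = t_ev
                        y = sol.sol(t_ev)
                        peak = max(peak, float(y[3] - y[4]))
                        # fall through to the decay stage below
                    else:
                        store(sol, sol.t[-1])
                        t, y = sol.t[-1], sol.y[:, -1]
                        if t >= t_forced - 1e-9:
                            cycles.append(float(t))
                            forced_cycles.append(float(t))
                            m.insp = False
                            cycled = True
                        continue
                # decay stage: cycle when flow falls to frac * peak, or
                # return to peak-tracking if it overtakes the running peak
                thresh_q = frac * peak

                def cycle_event(tt, yy, _q=thresh_q):
                    return (yy[3] - yy[4]) - _q

                cycle_event.terminal = True
                cycle_event.direction = -1

                def repeak_event(tt, yy, _p=peak * (1.0 + 1e-9) + 1e-12):
                    return (yy[3] - yy[4]) - _p

                repeak_event.terminal = True
                repeak_event.direction = 1

                sol = integrate(
                    t, y, min(t_forced, duration), [collapse_event, cycle_event, repeak_event], sim.max_step
                )
                if sol is None:
                    break
                check_collapse(sol)
                if len(sol.t_events[1]):
                    t_ev = sol.t_events[1][0]
                    store(sol, t_ev)
                    t = t_ev
                    y = sol.sol(t_ev)
                    cycles.append(float(t))
                    m.insp = False
                    cycled = True
                elif len(sol.t_events[2]):
                    t_ev = sol.t_events[2][0]
                    store(sol, t_ev)
                    t = t_ev
                    y = sol.sol(t_ev)
                    peak = float(y[3] - y[4])
                else:
                    store(sol, sol.t[-1])
                    t, y = sol.t[-1], sol.y[:, -1]
                    if t >= t_forced - 1e-9 and not cycled:
                        cycles.append(float(t))
                        forced_cycles.append(float(t))
                        m.insp = False
                        cycled = True
            if not cycled and t >= duration - 1e-9 and m.insp:
                m.insp = False  # record ends mid-inspiration

    # ------------------------------------------------------------- assemble
    if next_idx < n:
        # pad any trailing samples (can happen for a zero-length tail)
        Y[next_idx:] = Y[max(next_idx - 1, 0)]
    pao, flow, pmus, p_alv, ppl, v_lung = m.channels(grid, Y)
    volume = np.concatenate(([0.0], cumulative_trapezoid(flow, grid)))
    events = {
        "trigger": list(triggers),
        "cycle": list(cycles),
        "effort_start": [b.profile.effort_start for b in schedule.breaths],
        "effort_end": [b.profile.effort_end for b in schedule.breaths],
        "effort_max": [b.profile.effort_max for b in schedule.breaths],
    }
    return WaveformRecord(
        t=grid,
        pao=pao,
        flow=flow,
        volume=volume,
        pmus=pmus,
        p_alv=p_alv,
        ppl=ppl,
        v_lung=v_lung,
        vc=Y[:, 0].copy(),
        phase=phase_arr,
        fs=sim.fs,
        events=events,
        schedule=schedule,
        lung=lung,
        circuit=circuit,
        vent=vent,
        sim=sim,
        meta={"nfev": int(nfev), "forced_cycles": forced_cycles},
    )


def resample_record(record: WaveformRecord, target_rate: float) -> WaveformRecord:
    """Anti-aliased decimation of all channels to ``target_rate``.

    Event times are continuous quantities and remain unchanged.  Upsampling
    is refused.
    """
    if target_rate > record.fs + 1e-9:
        raise ValueError("resample_record only decimates (target <= native rate)")
    if abs(target_rate - record.fs) < 1e-12:
        return record
    ratio = Fraction(target_rate / record.fs).limit_denominator(1000)
    up, down = ratio.numerator, ratio.denominator
    n_new = int(len(record.t) * up / down)
    t_new = np.arange(n_new) / target_rate

    def dec(x):
        return resample_poly(np.asarray(x, dtype=float), up, down)[:n_new]

    return WaveformRecord(
        t=t_new,
        pao=dec(record.pao),
        flow=dec(record.flow),
        volume=dec(record.volume),
        pmus=dec(record.pmus),
        p_alv=dec(record.p_alv),
        ppl=dec(record.ppl),
        v_lung=dec(record.v_lung),
        vc=dec(record.vc),
        phase=record.phase[:: max(1, down // up)][:n_new]
        if down % up == 0
        else np.round(dec(record.phase.astype(float))).astype(np.int8),
        fs=target_rate,
        events=record.events,
        schedule=record.schedule,
        lung=record.lung,
        circuit=record.circuit,
        vent=record.vent,
        sim=record.sim,
        meta=dict(record.meta),
    )
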