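import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.signal import StateSpace, lsim

from psvsim.circuit import (
    CircuitParameters,
    VentilatorConfig,
    VentilatorState,
    check_cycle,
    check_trigger,
    et_tube_resistance,
    rohrer_drop,
    rohrer_flow,
    source_pressure,
    valve_flow,
)


class TestRohrer:
    @pytest.mark.parametrize("flow, expected", [(0.0, 5.0), (0.5, 9.0), (-0.5, 9.0)])
    def test_et_tube(self, flow, expected):
        assert et_tube_resistance(5.0, 8.0, flow) == pytest.approx(expected)

    def test_flow_inverts_drop(self):
        for dp in (-8.0, -0.3, 0.0, 0.3, 8.0):
            q = rohrer_flow(1.5, 2.0, dp)
            assert rohrer_drop(1.5, 2.0, q) == pytest.approx(dp, abs=1e-12)
        assert rohrer_flow(2.0, 0.0, 3.0) == pytest.approx(1.5)  # K = 0 limit


class TestSource:
    def test_expiratory_holds_peep(self):
        cfg = VentilatorConfig(PEEP=5, Pinsp=15)
        assert source_pressure("expiratory", cfg) == 5.0

    def test_block_steps_immediately(self):
        cfg = VentilatorConfig(PEEP=5, Pinsp=15, pressurization="block")
        assert source_pressure("inspiratory", cfg, 1e-6) == 15.0

    def test_trapezoid_linear_midpoint(self):
        cfg = VentilatorConfig(PEEP=5, Pinsp=15, rise_time=0.1)
        assert source_pressure("inspiratory", cfg, 0.05) == pytest.approx(10.0)
        assert source_pressure("inspiratory", cfg, 0.5) == pytest.approx(15.0)


class TestTriggerCycle:
    def test_trigger_fires_below_threshold(self):
        state = VentilatorState()
        cfg = VentilatorConfig(PEEP=5, Pinsp=15, trigger_drop=1.5)
        assert check_trigger(3.4, cfg, state, t=1.0) == "trigger"
        assert state.phase == "inspiratory"
        assert state.insp_valve_open and not state.exp_valve_open
        assert state.peak_flow == 0.0

    def test_no_trigger_above_threshold(self):
        state = VentilatorState()
        cfg = VentilatorConfig(PEEP=5, Pinsp=15, trigger_drop=1.5)
        assert check_trigger(3.6, cfg, state, t=1.0) is None
        assert state.phase == "expiratory"

    def test_weak_dip_never_triggers(self):
        """Pressure staying above threshold over a whole effort: no trigger
        (the upstream label for such an effort is ineffective)."""
        state = VentilatorState()
        cfg = VentilatorConfig(PEEP=5, Pinsp=15, trigger_drop=2.0, strict=True)
        dips = 5.0 - 1.2 * np.sin(np.linspace(0, np.pi, 50))
        for t, pao in enumerate(dips):
            assert check_trigger(float(pao), cfg, state, t=1.0 + t * 0.01) is None
        assert state.phase == "expiratory"

    def test_cycle_at_fraction_of_peak(self):
        state = VentilatorState(phase="inspiratory", t_trigger=0.0, peak_flow=1.0)
        cfg = VentilatorConfig(PEEP=5, Pinsp=15, cycle_fraction=0.3)
        assert check_cycle(0.31, cfg, state, t=0.5) is None
        assert check_cycle(0.29, cfg, state, t=0.5) == "cycle"
        assert state.phase == "expiratory"

    def test_cannot_cycle_at_the_peak_sample(self):
        state = VentilatorState(phase="inspiratory", t_trigger=0.0, peak_flow=0.8)
        cfg = VentilatorConfig(PEEP=5, Pinsp=15, cycle_fraction=0.3)
        assert check_cycle(0.9, cfg, state, t=0.5) is None  # still rising
        assert state.peak_flow == 0.9

    def test_min_insp_time_suppresses_cycling(self):
        state = VentilatorState(phase="inspiratory", t_trigger=0.0, peak_flow=1.0)
        cfg = VentilatorConfig(PEEP=5, Pinsp=15, cycle_fraction=0.3, min_insp_time=0.1)
        assert check_cycle(0.1, cfg, state, t=0.05) is None
        assert check_cycle(0.1, cfg, state, t=0.15) == "cycle"

    def test_alternating_event_sequence(self):
        """Trigger and cycle strictly alternate through a synthetic run."""
        state = VentilatorState()
        cfg = VentilatorConfig(PEEP=5, Pinsp=15, trigger_drop=1.5,
                               cycle_fraction=0.3, min_insp_time=0.0,
                               refractory=0.0)
        events = []
        t = 0.0
        for _ in range(4):
            for pao in (4.8, 4.0, 3.0):
                t += 0.01
                if state.phase == "expiratory" and check_trigger(pao, cfg, state, t=t):
                    events.append("trigger")
            for q in (0.2, 1.0, 0.5, 0.2):
                t += 0.01
                if state.phase == "inspiratory" and check_cycle(q, cfg, state, t=t):
                    events.append("cycle")
        assert events == ["trigger", "cycle"] * 4


class TestValve:
    def test_closed_valve_blocking_bound(self):
        g_f, g_b = 10.0, 1e-6
        for dp in (-30.0, -1.0, 1.0, 30.0):
            q = valve_flow(dp, False, g_f, g_b)
            assert abs(q) <= g_b * abs(dp) + 1e-15

    def test_open_forward_conductance(self):
        assert valve_flow(2.0, True, 10.0, 1e-6, knee=0.05) == pytest.approx(20.0, rel=1e-6)

    def test_zero_drop_zero_flow(self):
        assert valve_flow(0.0, True, 10.0, 1e-6) == 0.0

    def test_reverse_bias_blocks_when_open(self):
        q = valve_flow(-5.0, True, 10.0, 1e-6, knee=0.05)
        assert abs(q) <= 1e-5 * 5.0 * 10  # essentially the blocking leakage

    def test_sharp_knee_approaches_ideal_diode(self):
        dp = 0.5
        ideal = 10.0 * dp
        for knee in (0.05, 0.01, 0.001):
            q = valve_flow(dp, True, 10.0, 1e-6, knee=knee)
            assert abs(q - ideal) < abs(valve_flow(dp, True, 10.0, 1e-6, knee=0.2) - ideal) + 1e-12
        assert valve_flow(dp, True, 10.0, 1e-6, knee=1e-4) == pytest.approx(ideal, rel=1e-4)


class TestLinearLimitRLC:
    def test_step_response_matches_state_space_oracle(self):
        """With Rohrer K-terms zero and a sharp valve knee, the charging of
        the expiratory tubing compliance through both limbs is a linear
        R-L-C network; its simulated step response must match the
        closed-form linear-system solution."""
        from psvsim.lung import LungParameters
        from psvsim.muscle import BreathSchedule
        from psvsim.solver import _Model

        lung = LungParameters(
            Au=2.0, Ku=0.0, Kc=1.0, Vcmax=0.2, As=1.0, Ks=-2.5, Bs=0.5,
            Vstar=5.8, RV=1.2, TLC=6.0, Ac=0.5, Bc=2.0, Dc=1.0, Acw=-1.0,
            Bcw=6.0, Al=5.8, Bl=0.15, Dl=6.0, Cve=0.0, Rve=0.0,
        )
        from psvsim.circuit import LimbParameters

        # ET tube resistance made enormous: the patient branch draws a
        # negligible share of the limb currents
        limb = LimbParameters(TubeA=0.4, TubeK=0.0, L=0.02, C=0.002)
        circ = CircuitParameters(
            EtA=5000.0, EtK=0.0, insp=limb, exp=limb,
            g_forward=10.0, g_blocking=1e-8, knee=1e-3,
        )
        vent = VentilatorConfig(PEEP=5.0, Pinsp=15.0, pressurization="block")
        sched = BreathSchedule(breaths=(), rate=15.0, duration=2.0)
        m = _Model(lung, circ, vent, sched)
        m.insp = True
        m.t_trig = 0.0

        from psvsim.lung import static_equilibrium

        ppl, vc, va = static_equilibrium(lung, vent.PEEP)
        y0 = [vc, va, 0.0, 0.0, 0.0, vent.PEEP, vent.PEEP]
        sol = solve_ivp(m.rhs, (0.0, 0.6), y0, method="LSODA", rtol=1e-8,
                        atol=1e-10, dense_output=True, max_step=0.002)
        t = np.linspace(0.0, 0.6, 400)
        pae_sim = sol.sol(t)[6]

        # independent linear oracle: source -g_v- Pai(C_i) -R_i,L_i- Y
        # -R_e,L_e- Pae(C_e); the Y node has no storage, so one loop current
        Ri = circ.insp.TubeA + circ.exp.TubeA
        L = circ.insp.L + circ.exp.L
        Ci, Ce, gv = circ.insp.C, circ.exp.C, circ.g_forward
        A = np.array(
            [
                [-Ri / L, 1.0 / L, -1.0 / L],
                [-1.0 / Ci, -gv / Ci, 0.0],
                [1.0 / Ce, 0.0, 0.0],
            ]
        )
        B = np.array([[0.0], [gv / Ci], [0.0]])
        C = np.array([[0.0, 0.0, 1.0]])
        sys = StateSpace(A, B, C, [[0.0]])
        u = np.full_like(t, vent.Pinsp - vent.PEEP)
        _, pae_lin, _ = lsim(sys, u, t)
        pae_oracle = vent.PEEP + pae_lin
        err = np.max(np.abs(pae_sim - pae_oracle)) / (vent.Pinsp - vent.PEEP)
        assert err < 0.01
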