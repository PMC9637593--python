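import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from psvsim.lung import (
    AirwayCollapseError,
    CurveDomainError,
    LungParameters,
    alveolar_volume,
    chest_wall_volume,
    collapsible_resistance,
    collapsible_volume,
    invert_volume_curve,
    small_airway_resistance,
    static_equilibrium,
    upper_airway_resistance,
)

PARAMS = LungParameters(
    Au=2.0, Ku=0.5, Kc=3.0, Vcmax=0.2, As=1.5, Ks=-2.5, Bs=0.5, Vstar=5.8,
    RV=1.2, TLC=6.0, Ac=0.5, Bc=2.0, Dc=1.0, Acw=-1.0, Bcw=6.0,
    Al=5.8, Bl=0.15, Dl=6.0, Cve=0.5, Rve=1.5,
)


class TestResistances:
    @pytest.mark.parametrize(
        "Au, Ku, flow, expected",
        [(2.0, 0.5, 0.0, 2.0), (2.0, 0.5, -1.0, 2.5), (0.0, 1.0, 2.0, 2.0)],
    )
    def test_upper_airway_rohrer(self, Au, Ku, flow, expected):
        assert upper_airway_resistance(Au, Ku, flow) == pytest.approx(expected)

    def test_upper_airway_even_in_flow(self):
        q = np.linspace(-2, 2, 41)
        r = upper_airway_resistance(1.3, 0.7, q)
        assert np.allclose(r, r[::-1])
        assert np.all(np.diff(r[q >= 0]) >= 0)  # non-decreasing in |flow|

    @pytest.mark.parametrize(
        "Vc, expected", [(0.2, 3.0), (0.1, 12.0)],
    )
    def test_collapsible_quadratic_in_inverse_volume(self, Vc, expected):
        assert collapsible_resistance(3.0, 0.2, Vc) == pytest.approx(expected)

    def test_collapsible_rejects_collapsed_segment(self):
        with pytest.raises(AirwayCollapseError):
            collapsible_resistance(3.0, 0.2, 0.0)

    def test_collapsible_strictly_decreasing_in_volume(self):
        vc = np.linspace(0.01, 0.2, 100)
        r = collapsible_resistance(3.0, 0.2, vc)
        assert np.all(np.diff(r) < 0)

    def test_small_airway_exponential(self):
        # at VA = RV the exponent vanishes
        assert small_airway_resistance(1.5, -5, 0.5, 6, 1, 1) == pytest.approx(2.0)
        # direct evaluation at VA = Vstar
        expected = 1.5 * math.exp(-5.0) + 0.5
        assert small_airway_resistance(1.5, -5, 0.5, 6, 1, 6) == pytest.approx(expected)
        # constant limit with As = 0
        assert small_airway_resistance(0.0, -5, 0.7, 6, 1, 3.3) == pytest.approx(0.7)

    def test_small_airway_degenerate_vstar(self):
        with pytest.raises(ValueError):
            small_airway_resistance(1.5, -5, 0.5, 1.0, 1.0, 2.0)


class TestVolumeCurves:
    def test_collapsible_sigmoid_midpoint_and_exponent(self):
        assert collapsible_volume(1, 0, 1, 0.2, 0.0) == pytest.approx(0.1)
        assert collapsible_volume(1, 0, 2, 0.2, 0.0) == pytest.approx(0.05)
        assert collapsible_volume(1, 0, 1, 0.2, 60.0) == pytest.approx(0.2, abs=1e-9)

    def test_chest_wall_asymptotes_and_shift_point(self):
        assert chest_wall_volume(6, 1.2, -1, 6, -300.0) == pytest.approx(1.2, abs=1e-9)
        # at Pcw = Acw the exponential term equals one
        assert chest_wall_volume(6, 1.2, -1, 6, -1.0) == pytest.approx(
            4.8 / 1.99 + 1.2
        )
        hi = 1.2 + 4.8 / 0.99  # the 0.99 constant puts the ceiling ~1 % over TLC
        assert chest_wall_volume(6, 1.2, -1, 6, 400.0) == pytest.approx(hi, abs=1e-9)
        assert hi > 6.0

    def test_alveolar_midpoint_and_asymptote(self):
        assert alveolar_volume(6, 0.1, 5, 5.0) == pytest.approx(3.0)
        assert alveolar_volume(6, 0.1, 5, 500.0) == pytest.approx(6.0, abs=1e-9)
        assert alveolar_volume(6, 0.1, 5, 15.0) == pytest.approx(6.0 / (1 + math.exp(-1)))

    @pytest.mark.parametrize("curve", ["collapsible", "chest_wall", "alveolar"])
    def test_monotone_increasing_in_pressure(self, curve):
        p = np.linspace(-40, 40, 400)
        if curve == "collapsible":
            v = collapsible_volume(PARAMS.Ac, PARAMS.Bc, PARAMS.Dc, PARAMS.Vcmax, p)
        elif curve == "chest_wall":
            v = chest_wall_volume(PARAMS.TLC, PARAMS.RV, PARAMS.Acw, PARAMS.Bcw, p)
        else:
            v = alveolar_volume(PARAMS.Al, PARAMS.Bl, PARAMS.Dl, p)
        assert np.all(np.diff(v) > 0)


class TestInversion:
    def test_midpoint_inversion(self):
        p = LungParameters(**{**PARAMS.__dict__, "Al": 6.0, "Bl": 0.1, "Dl": 5.0})
        assert invert_volume_curve("alveolar", p, 3.0) == pytest.approx(5.0)

    def test_asymptote_rejected(self):
        with pytest.raises(CurveDomainError):
            invert_volume_curve("alveolar", PARAMS, PARAMS.Al)
        with pytest.raises(CurveDomainError):
            invert_volume_curve("chest_wall", PARAMS, PARAMS.RV)

    @settings(derandomize=True, max_examples=100)
    @given(frac=st.floats(min_value=1e-4, max_value=1 - 1e-4))
    def test_round_trip_all_curves(self, frac):
        """curve(invert(V)) = V to < 1e-9 L across the open range."""
        for curve, lo, hi in [
            ("collapsible", 0.0, PARAMS.Vcmax),
            ("chest_wall", PARAMS.RV, PARAMS.RV + (PARAMS.TLC - PARAMS.RV) / 0.99),
            ("alveolar", 0.0, PARAMS.Al),
        ]:
            v = lo + frac * (hi - lo)
            if v <= lo or v >= hi:
                continue
            p = invert_volume_curve(curve, PARAMS, v)
            if curve == "collapsible":
                back = collapsible_volume(PARAMS.Ac, PARAMS.Bc, PARAMS.Dc, PARAMS.Vcmax, p)
            elif curve == "chest_wall":
                back = chest_wall_volume(PARAMS.TLC, PARAMS.RV, PARAMS.Acw, PARAMS.Bcw, p)
            else:
                back = alveolar_volume(PARAMS.Al, PARAMS.Bl, PARAMS.Dl, p)
            assert abs(float(back) - v) < 1e-9


class TestParameters:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            LungParameters(**{**PARAMS.__dict__, "TLC": 1.0})  # TLC < RV
        with pytest.raises(ValueError):
            LungParameters(**{**PARAMS.__dict__, "Vcmax": -0.1})
        with pytest.raises(ValueError):
            LungParameters(**{**PARAMS.__dict__, "Rd": 10.0})  # not >> airway R

    def test_static_equilibrium_increases_with_pressure(self):
        vols = []
        for p in (0.0, 5.0, 10.0):
            _, vc, va = static_equilibrium(PARAMS, p)
            vols.append(vc + va)
        assert vols[0] < vols[1] < vols[2]
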