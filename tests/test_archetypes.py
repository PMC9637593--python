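import math

import numpy as np
import pytest

from psvsim.archetypes import (
    ACCEPTABLE_RANGES,
    ARCHETYPE_NAMES,
    TuningError,
    archetype_spec,
    compute_ctot,
    compute_frc,
    compute_resistances,
    derive_mechanics,
    load_archetype,
    pelosi_compliance,
    predicted_rv,
    tune_archetype,
    validate_archetype,
)
from psvsim.lung import LungParameters


class TestSpecs:
    def test_copd_rv_is_1p7_times_predicted(self):
        spec = archetype_spec("copd")
        assert spec.RV == pytest.approx(1.7 * predicted_rv())
        assert spec.TLC == pytest.approx(2.0 * spec.RV)

    def test_obese_ctot_follows_pelosi_relation(self):
        spec = archetype_spec("obese", bmi=30.0)
        assert spec.Ctot == pytest.approx((233.3 * math.exp(-0.086 * 30.0) + 40.0) / 1000)

    def test_copd_evaluated_at_peep(self):
        spec = archetype_spec("copd", peep=5.0, pinsp=15.0)
        assert spec.baseline_pressure == 5.0
        assert spec.inflation_pressure == 15.0


class TestFRC:
    def test_matches_hand_algebra_on_wide_curves(self):
        """On sigmoids operated near their midpoints the static balance is
        nearly linear; FRC then satisfies the hand-derived balance
        C_lc (P - Ppl) shifted through the chest-wall curve.  Verified by
        checking the defining equation directly."""
        lung = load_archetype("healthy")
        frc = compute_frc(lung, 0.0)
        from psvsim.lung import (
            alveolar_pressure,
            chest_wall_pressure,
            collapsible_pressure,
        )

        ppl = float(chest_wall_pressure(lung.TLC, lung.RV, lung.Acw, lung.Bcw, frc))
        # transmural pressures of both lung elements equal -Ppl at ZEEP
        from psvsim.lung import alveolar_volume, collapsible_volume

        va = float(alveolar_volume(lung.Al, lung.Bl, lung.Dl, -ppl))
        vc = float(collapsible_volume(lung.Ac, lung.Bc, lung.Dc, lung.Vcmax, -ppl))
        assert va + vc == pytest.approx(frc, abs=1e-8)

    def test_healthy_frc_in_reported_band(self, tuned):
        assert compute_frc(tuned["healthy"], 0.0) == pytest.approx(3.2, abs=1.2)

    def test_frc_increases_with_applied_pressure(self, tuned):
        f = [compute_frc(tuned["obese"], p) for p in (0.0, 3.0, 6.0)]
        assert f[0] < f[1] < f[2]


class TestCtot:
    def test_series_compliance_identity(self, tuned):
        """The combined slope equals the series combination of the lung
        (alveolar + collapsible) and chest-wall slopes evaluated
        analytically at the same operating point."""
        lung = tuned["ards"]
        frc = compute_frc(lung, 0.0)
        from psvsim.lung import chest_wall_pressure

        ppl = float(chest_wall_pressure(lung.TLC, lung.RV, lung.Acw, lung.Bcw, frc))
        trans = -ppl
        w = math.exp(-lung.Bl * (trans - lung.Dl))
        cl = lung.Al * lung.Bl * w / (1 + w) ** 2
        e = math.exp(-lung.Ac * (trans - lung.Bc))
        cc = lung.Vcmax * lung.Dc * lung.Ac * e * (1 + e) ** (-lung.Dc - 1)
        u = math.exp(-(ppl - lung.Acw) / lung.Bcw)
        ccw = (lung.TLC - lung.RV) * u / lung.Bcw / (0.99 + u) ** 2
        series = (cl + cc) * ccw / (cl + cc + ccw)
        assert compute_ctot(lung, frc) == pytest.approx(series, rel=1e-3)

    def test_step_halving_converges(self, tuned):
        lung = tuned["fibrosis"]
        frc = compute_frc(lung, 0.0)
        c1 = compute_ctot(lung, frc, step=0.05)
        c2 = compute_ctot(lung, frc, step=0.025)
        assert abs(c1 - c2) / c2 < 1e-3

    def test_obese_meets_pelosi_target(self, tuned):
        spec = archetype_spec("obese")
        frc = compute_frc(tuned["obese"], 0.0)
        assert compute_ctot(tuned["obese"], frc) == pytest.approx(spec.Ctot, abs=0.01)


class TestResistances:
    def test_linear_limit_flow_independent(self):
        """With Rohrer K-terms zero the three-resistance sum is the same
        at any low flow and in both directions at the same volumes."""
        lung = load_archetype("healthy").with_(Ku=0.0)
        r1 = compute_resistances(lung, "insp", low_flow=0.05)
        r2 = compute_resistances(lung, "insp", low_flow=0.2)
        assert r1 == pytest.approx(r2)

    def test_copd_rexp_in_reported_band(self, tuned):
        spec = archetype_spec("copd")
        rexp = compute_resistances(tuned["copd"], "exp",
                                   baseline_pressure=spec.baseline_pressure,
                                   inflation_pressure=spec.inflation_pressure)
        assert rexp == pytest.approx(14.0, abs=6.0)

    def test_copd_expiration_exceeds_inspiration(self, tuned):
        spec = archetype_spec("copd")
        kw = dict(baseline_pressure=spec.baseline_pressure,
                  inflation_pressure=spec.inflation_pressure)
        assert (compute_resistances(tuned["copd"], "exp", **kw)
                > compute_resistances(tuned["copd"], "insp", **kw))

    def test_unknown_direction_rejected(self, tuned):
        with pytest.raises(ValueError):
            compute_resistances(tuned["healthy"], "sideways")


class TestValidation:
    @pytest.mark.parametrize("name", ARCHETYPE_NAMES)
    def test_tuned_sets_pass_their_specs(self, tuned, name):
        report = validate_archetype(tuned[name], archetype_spec(name))
        assert report.all_pass, str(report)

    @pytest.mark.parametrize("name", ARCHETYPE_NAMES)
    def test_shipped_files_match_tuned_sets(self, tuned, name):
        assert load_archetype(name) == tuned[name]

    def test_out_of_tolerance_resistance_fails(self, tuned):
        """An Rinsp 2.0 cmH2O/L/s off its target must fail (tolerance 1.5)."""
        lung = tuned["healthy"]
        bad = lung.with_(Au=lung.Au + 2.0)
        report = validate_archetype(bad, archetype_spec("healthy"))
        rows = {q: ok for q, v, tgt, tol, ok in report.rows}
        assert not rows["Rinsp"]

    def test_report_is_deterministic(self, tuned):
        a = validate_archetype(tuned["copd"], archetype_spec("copd"))
        b = validate_archetype(tuned["copd"], archetype_spec("copd"))
        assert a == b

    def test_cross_archetype_orderings(self, tuned):
        mech = {}
        for name in ARCHETYPE_NAMES:
            spec = archetype_spec(name)
            mech[name] = derive_mechanics(tuned[name], spec.baseline_pressure,
                                          spec.inflation_pressure)
        assert mech["fibrosis"].Ctot < mech["ards"].Ctot < mech["healthy"].Ctot
        assert mech["copd"].Rexp > mech["healthy"].Rexp
        assert mech["copd"].TLC > mech["healthy"].TLC > mech["fibrosis"].TLC
        assert mech["obese"].FRC < mech["healthy"].FRC


class TestTuning:
    def test_two_seeds_give_distinct_passing_sets(self):
        spec = archetype_spec("ards")
        a = tune_archetype(spec, seed=1)
        b = tune_archetype(spec, seed=2)
        assert validate_archetype(a, spec).all_pass
        assert validate_archetype(b, spec).all_pass
        differing = [f for f in ("Au", "Ku", "Kc", "Vcmax", "As", "Ks", "Ac",
                                 "Bc", "Acw", "Bcw", "Bl", "Dl")
                     if getattr(a, f) != getattr(b, f)]
        assert len(differing) >= 3

    def test_infeasible_spec_raises(self):
        from psvsim.archetypes import ArchetypeSpec

        # FRC below the collapsible-segment volume: no room for alveolar gas
        bad = ArchetypeSpec("healthy", RV=0.05, FRC=0.1, TLC=6.0,
                            Rinsp=2.0, Rexp=2.0, Ctot=0.15)
        with pytest.raises((TuningError, ValueError)):
            tune_archetype(bad, seed=0)
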