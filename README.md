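# psvsim

Synthetic, automatically annotated pressure-support-ventilation (PSV)
waveforms for training and validating patient–ventilator asynchrony
detectors.

Machine-learning detectors of patient–ventilator asynchronies need large,
diverse, *labeled* datasets, but clinical labels require esophageal
manometry or expert annotation and some asynchrony types are rare. `psvsim`
generates airway pressure, flow and volume waveforms from a physiological
simulation in which every patient effort and every ventilator action is
known exactly, so the asynchrony labels are ground truth by construction.

## The model

**Patient.** A nonlinear one-compartment lung–airway network: three airway
resistances in series,

- upper airway: Rohrer resistor `Ru = Au + Ku·|V̇|` (turbulence),
- collapsible segment: `Rc = Kc·(Vcmax/Vc)²` (dynamic compression →
  expiratory flow limitation),
- small airways: `Rs = As·exp(Ks·(VA−RV)/(V*−RV)) + Bs` (recoil tethering),

with sigmoidal pressure–volume curves for the collapsible segment
`Vc(Pc) = Vcmax/(1+e^{−Ac(Pc−Bc)})^{Dc}`, the alveolar compartment
`VA(Pt) = Al/(1+e^{−Bl(Pt−Dl)})` (Venegas form) and the chest wall
`Vcw(Pcw) = (TLC−RV)/(0.99+e^{−(Pcw−Acw)/Bcw}) + RV`, plus a linear Kelvin
body (`Cve`, `Rve`) for tissue visco-elasticity. Respiratory muscle
pressure `Pmus` is a rounded trapezoid per breath with a superimposed
cardiac sine (0.25–1 cmH2O, 1–2 Hz).

**Ventilator.** A 9 mm endotracheal tube (Rohrer), inspiratory and
expiratory tubing limbs (Rohrer resistance + inertance + compliance), two
pressure sources (PEEP, Pinsp), switched valves with a diode-like
expiratory port, and the proximal sensor at the Y-piece. Pressure
triggering (threshold 1–2 cmH2O below PEEP) and fractional-peak-flow
cycling (10–80 %) form the PSV state machine.

**Archetypes.** Five virtual patients — healthy, obese, ARDS, COPD,
idiopathic fibrosis — are calibrated so that RV, FRC, TLC, `Rinsp`,
`Rexp` (sum of the three airway resistances at 0.1 L/s) and `Ctot` (slope
of the combined static pressure–volume curve at FRC) hit their
physiological targets, e.g. COPD: `Rinsp` 7.5, `Rexp` 15 cmH2O/L/s,
`Ctot` 0.075 L/cmH2O, evaluated at PEEP/Pinsp.

**Labels.** Each breath is classified from the realised start-inspiration
delay (trigger − effort start) and end-inspiration delay (cycle − effort
end): normal (start delay < 250 ms, end delay in (−100, 300) ms), early
cycling, late cycling, delayed inspiration, ineffective effort (no
trigger), and the delayed-inspiration combinations. Asynchronies are
*induced* by per-breath trigger/cycling-threshold manipulation, but labels
always reflect realised timing.

## Worked example

```python
import numpy as np
from psvsim import (archetype_spec, tune_archetype, validate_archetype,
                    CircuitParameters, VentilatorConfig, autoset_pressures,
                    schedule_breaths, SimulationConfig, simulate,
                    annotate_record)

lung = tune_archetype(archetype_spec("copd"), seed=0)
print(validate_archetype(lung, archetype_spec("copd")))
```

```
archetype: copd
  RV        3.3022  target    3.3022 +- 0.5000  pass
  FRC       4.6000  target    4.6000 +- 1.0000  pass
  TLC       6.6045  target    6.6045 +- 1.0000  pass
  Rinsp     7.5000  target    7.5000 +- 1.5000  pass
  Rexp     15.0000  target   15.0000 +- 1.5000  pass
  Ctot      0.0750  target    0.0750 +- 0.0100  pass
```

The report compares each derived quantity (L, cmH2O/L/s, L/cmH2O) with
its requirement target at the printed acceptable ranges. Next, calibrate
the support pressure and simulate four breaths, one of them a deliberately
ineffective effort:

```python
circ = CircuitParameters()
vent = autoset_pressures(lung, VentilatorConfig(PEEP=5.0, Pinsp=15.0), circ, seed=0)
rng = np.random.default_rng(4)
sched = schedule_breaths(
    13.0, 20.0, ["normal", "normal", "ineffective_effort", "normal"], rng,
    induction={"normal": {"trigger_drop": (1.0, 1.5), "cycle_fraction": (0.05, 0.08)},
               "ineffective_effort": {"trigger_drop": (3.5, 4.0)}})
rec = simulate(lung, circ, vent, sched, SimulationConfig(duration=20.0))
for i, ann in enumerate(annotate_record(rec)[0]):
    print(i, ann.label)
```

```
breath 0: normal               start_delay +0.119 s  end_delay -0.062 s
breath 1: normal               start_delay +0.137 s  end_delay -0.082 s
breath 2: ineffective_effort   start_delay   --   s  end_delay   --   s
breath 3: normal               start_delay +0.105 s  end_delay -0.078 s
```

The weak (1.7–2.2 cmH2O) third effort never reaches the raised trigger
threshold, so its delays are undefined and it is labeled ineffective. The
record holds the sensor channels (`pao`, `flow`, `volume`) plus
ground-truth channels (`pmus`, alveolar pressure, lung volume) and all
event times.

Datasets are generated end-to-end (calibration, balanced induction,
simulation, labeling, 15 Hz band-limited sensor noise at 15–16 dB SNR on
pressure and 30–31 dB on flow, delimited-text output with JSON sidecars)
from the command line:

```
psvsim generate --out data/run1 --seed 1 --n-breaths 120
psvsim validate-archetypes
psvsim inspect data/run1/record_0000
```

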