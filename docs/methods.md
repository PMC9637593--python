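# Methods

This note documents the model, its assumptions, the calibration
procedures and the numerical choices behind `psvsim`. It states design
rationale only; every empirical number quoted here is computed by the test
suite or by `scripts/acceptance.py`, not asserted independently.

## Patient model

The patient is a lumped pneumatic network with a single alveolar
compartment. Airflow passes through three series resistances — upper
airway (Rohrer, flow-dependent), collapsible segment (volume-dependent)
and small airways (alveolar-volume-dependent) — into the alveolar
compartment. Three logistic pressure–volume curves describe the storage
elements (collapsible segment, alveolar compartment, chest wall); all
three are strictly increasing, twice differentiable, and are inverted in
closed form (logit), so the simulator's state variables of record are the
stored volumes, the conserved quantities of the capacitors. A linear
Kelvin body in series with the lung recoil adds visco-elastic stress
relaxation: its state `Vve` obeys `dVve/dt = Q_A − Vve/(Rve·Cve)` and
contributes `Vve/Cve` to the alveolar pressure.

Two structural conventions matter:

- **Volume identity.** The chest-wall curve is always evaluated at the
  summed gas volume `Vc + VA`, so lung volume and chest-wall volume are
  identical by construction throughout a simulation (this is the purpose
  of placing the Kelvin body between lung recoil and chest wall rather
  than across them).
- **The 0.99 constant.** The chest-wall sigmoid divides by
  `0.99 + exp(...)`, so its supremum is `RV + (TLC−RV)/0.99`, about 1 %
  above TLC. The constant is kept exactly as specified rather than
  rounded to 1; TLC remains the nominal capacity parameter.

Sign conventions: flow positive into the patient; muscle pressure applied
as a negative (sub-atmospheric) pleural swing during inspiration while its
amplitude is reported positive; volumes reported relative to the
initialisation volume, with absolute lung volume available as a
ground-truth channel.

The small-airway exponent `Ks` is negative in every archetype: resistance
falls as the lung inflates, because elastic recoil tethers the small
airways open. This is what makes low lung volumes (and loss of recoil in
COPD) raise the small-airway resistance.

Degenerate inputs are rejected loudly: a collapsible volume at or below
zero is a collapse error, volumes at a curve asymptote are domain errors,
and the simulator aborts (with a timestamp) if the collapsible volume
falls below 0.5 % of `Vcmax` rather than clamping silently.

## Muscle model

Each effort is a rounded trapezoid: a ramp of duration `rise_time` to
`−amplitude`, a plateau, and a ramp of duration `fall_time` back to zero.
Corners are blended with a raised-cosine slope profile of width
`rounding`, giving a C1 (in fact piecewise-C2) waveform whose peak ramp
slope is `amplitude/(ramp − rounding)`. The default rounding is 10 % of
the shorter ramp: wide enough to keep the stiff solver comfortable and the
shape visibly rounded, brisk enough that effort onset is not artificially
sluggish (with 20 % rounding the first ~0.15 s of a slow effort produce
almost no pressure, which inflates trigger delays unrealistically).

The per-class amplitude/fall/rise ranges are the study conditions (normal
5–10 cmH2O, 0.25–0.35 s, 0.5–0.7 s; early cycling with slow 0.7–0.9 s
rise; delayed inspiration weak and slow at 3.5–4.5 cmH2O; ineffective
efforts 1.7–2.2 cmH2O). The plateau duration is not part of those
conditions; it defaults to a uniform 0.1–0.4 s draw (0.1–0.2 s in the
dataset generator), keeping inspiratory times consistent with breathing
rates of 12–18/min. The fall/rise column semantics (fall faster than rise
for a normal breath) are implemented exactly as printed. A cardiac sine
(0.25–1 cmH2O, 1–2 Hz) is shared by all breaths of a record. The time of
maximum effort, one of the five annotation markers, is defined as the
plateau midpoint of the envelope (before cardiac addition). No expiratory
muscle activity is modeled.

## Ventilator model

Each tubing limb is a Rohrer resistance, an inertance and a compliance;
the endotracheal tube (9 mm) is a Rohrer resistance in series with the
upper airway, and the proximal sensor sits at the Y-piece upstream of the
tube. The shipped circuit constants (`EtA` 1.9, `EtK` 3.3; per-limb
`TubeA` 0.4, `TubeK` 0.8 cmH2O·s²/L², `L` 0.02 cmH2O·s²/L, `C` 0.002
L/cmH2O) are editable defaults of realistic magnitude — total circuit
resistance at 1 L/s of the same order as the airway resistance — not
authoritative measurements.

The inspiratory valve is a switched connection to the pressure source:
bidirectional when open, leakage-only when closed. Only the expiratory
port carries the diode (blocking inspiration from the contaminated
expiratory connection); it is smoothed with a logistic conductance knee
(default 0.05 cmH2O) so the ODE right-hand side stays continuous, and the
ideal diode is recovered as the knee width goes to zero. An early design
used a diode on the inspiratory port too; that traps the inertance
overshoot above the source pressure and was abandoned.

Triggering is by pressure (sensor below PEEP − drop); flow triggering is
available as an optional mode but has no printed threshold values and is
not the default. Cycling fires at the first crossing below
`fraction × running peak flow` after the peak, never at the peak sample
itself, with a 100 ms minimum inspiratory time so the trigger transient
cannot cycle the breath, and a 100 ms refractory period after cycling. A
5 s safety limit forces cycling (and is logged) if the flow criterion is
never met. Pressurization is a block wave or a trapezoid with a
configurable rise time (default 80 ms).

## Solver

The coupled system has seven states: the three patient volumes, the two
limb inertance flows and the two tubing-compliance pressures. Integration
uses a stiff implicit method (LSODA) with rtol 1e-6, atol 1e-8, a 50 ms
step bound on smooth stretches and a 5 ms bound during the 100 ms after
each phase transition. Trigger and cycle crossings are located as
terminal solver events in continuous time (the running flow peak is
tracked by a peak event on the flow derivative, with a re-peak event if a
second effort pushes flow above the recorded maximum), never on the
sample grid. Channels are sampled at 100 Hz — a typical ventilator data
rate, comfortably above the 15 Hz noise bandwidth.

Initial conditions come from an exact algebraic equilibrium: with zero
flow every airway node sits at the applied pressure, and the pleural
pressure is the root of `Pcw(VA(P−Ppl) + Vc(P−Ppl)) = Ppl`, solved by
bracketed bisection to machine tolerance. This replaces the source
network's high-resistance initialisation construction (a very large
resistor feeding the pleural node) and removes its slow artificial
transient; the resistor remains available as a parameter for fidelity
experiments. The same static solve defines the FRC (at zero applied
pressure), the combined pressure–volume curve whose slope at FRC is
`Ctot` (central difference, 0.05 cmH2O step, truncation verified below
0.1 % by step halving), and the resistance operating points: inspiration
at the relaxed equilibrium of the baseline pressure, expiration at the
end-inspiratory alveolar volume with the airway back at baseline — the
configuration in which elevated chest-wall recoil compresses the
collapsible segment, which is exactly the COPD expiratory-resistance
mechanism. Low flow is fixed at 0.1 L/s, small enough that the Rohrer
terms contribute under 10 %.

## Archetype calibration

RV and TLC are direct parameters. The remaining targets are met
constructively rather than by black-box search: given a chosen pleural
pressure at FRC (≈ −5 cmH2O), a lung/chest-wall compliance split (≈ 1:1)
and a resistance allocation across the three airway elements, the
chest-wall and alveolar sigmoids are fitted in closed form through the
FRC operating point with the required slopes, and the collapsible sigmoid
is fitted through the inspiratory and expiratory operating points so the
three-resistance sums hit `Rinsp` and `Rexp`. A damped fixed-point loop
(≤ 40 iterations) reconciles the expiratory operating point with the
curves it depends on. Seeded jitter on the free choices (`Vcmax`, `Ks`,
pleural pressure, compliance split, allocation) yields distinct passing
parameter sets per seed. All six derived quantities land on their targets
to solver precision, well inside the printed acceptable ranges (±0.5 L
RV, ±1 L FRC/TLC, ±1.5 cmH2O/L/s resistances, ±0.01 L/cmH2O compliance).

Reference values used where the requirement is a formula: the obese
compliance target follows `233.3·exp(−0.086·BMI) + 40` mL/cmH2O at a
default BMI of 30 kg/m² (the clinical obesity threshold, consistent with
the reported obese compliance of 0.06 L/cmH2O); the COPD residual volume
is 1.7 × the predicted healthy RV from the standard ECSC/ERS reference
equation `1.31·H + 0.022·A − 1.23` (defaults 1.75 m, 40 yr → 1.94 L,
COPD RV 3.30 L), with TLC = 2 × RV. COPD quantities are evaluated at
PEEP = 5 / Pinsp = 15 cmH2O; all other archetypes at ZEEP with a +10
cmH2O inflation context for the expiratory operating point. The COPD
compliance target is 0.075 L/cmH2O as listed in the requirement table;
with that value total compliance does not order COPD above healthy, so
the cross-archetype ordering checks cover the fibrosis < ARDS < healthy
compliance ordering, the COPD resistance and capacity orderings, and the
obese FRC reduction.

## Dataset generation

Each record is a contiguous run of ~12 breaths on one archetype with one
ventilator configuration. Pinsp is auto-calibrated per archetype by
bisection on the simulated tidal volume of a fixed representative normal
effort (amplitude 6 cmH2O, rise 0.6 s, fall 0.3 s), aiming at 0.55 L —
the upper middle of the 0.4–0.6 L band — so that the weakest admissible
normal efforts (5 cmH2O) still deliver at least 0.4 L. PEEP defaults to
5 cmH2O.

Asynchronies are induced by per-breath threshold manipulation, and the
induction is calibrated closed-loop per virtual patient: two short probe
records (normal-shaped and weak delayed-shaped efforts across a grid of
cycling fractions) yield a fitted end-delay model
`ed ≈ a + b·log(cycle_fraction) + g·amplitude` per effort shape, plus the
start-delay statistics and the cardiac-to-sensor pressure transmission
gain (measured on an effort-free record). Every breath's cycling fraction
is then placed on the model, compensated for its drawn effort amplitude,
targeting +0.10 s end delay for normal/delayed breaths, −0.45 s for early
cycling and +1.1 s for the late-cycling classes; trigger drops sit at
0.4–0.6 cmH2O for delay-sensitive classes (floored at the measured
cardiac noise level plus margin, as an operator would set trigger
sensitivity), 2–3 cmH2O for delayed inspiration and 3.2–4.5 cmH2O for
ineffective efforts.

Because the achievable delay windows depend on the patient's time
constant — late cycling needs a slowly emptying lung, early cycling a
fast one — each class receives a per-patient affinity from the probe
(down to ~0 when its window is unreachable), and the globally balanced
class pool is allocated to records accordingly. The class balance stays
exact by construction; what the affinity changes is *which* patient hosts
which breath, reproducing the clinically observed co-occurrence
(ineffective efforts and late cycling in obstructive patients, early
cycling in restrictive ones). Within a record, breath order favours
placing delay-sensitive breaths after short-inspiration breaths, records
hosting them draw the calmer half of the cardiac-amplitude range and the
slow end of the breathing-rate range, and obstructive archetypes are
sampled somewhat more often. Intended-versus-realised agreement is ~91 %
at the 600-breath scale; mismatches are relabeled truthfully from the
realised timing, never forced.

Noise is added after labeling: white noise low-pass filtered to 15 Hz
(5th-order Butterworth), scaled so the realised SNR equals a uniform draw
from 15–16 dB for pressure and 30–31 dB for flow. SNR is interpreted in
dB on total mean-square power (the unit is not printed with the ranges; a
linear power ratio of 15 would be implausibly clean against visibly noisy
clinical traces). The written volume channel is re-integrated from the
noisy flow, as a ventilator would display it; ground-truth labels and
events always come from the noiseless internal signals.

Output is delimited text per record plus a JSON sidecar (events,
per-breath intended class, realised label, delays, five markers,
induction settings, configuration) and a manifest with per-record seeds;
any record or the whole dataset regenerates byte-identically from the
manifest seed. Record failures are reported in the manifest, never
hidden.

## What the synthetic data does and does not show

The generator emulates PSV waveform morphology (rounded inspiratory flow
peaks, end-inspiratory pressure rise from muscle relaxation and falling
turbulent losses, exponential passive expiration, expiratory flow
limitation in obstructive archetypes, autoPEEP-delayed triggering) and
exact asynchrony timing. It does not emulate multi-compartment
heterogeneity, gas exchange, secretions, leaks, humidifiers, brand-
specific servo control loops, expiratory muscle activity, or behavioural
breath-to-breath variability beyond the sampled parameter ranges. Tests
passing on this data therefore validate detection logic against the
modeled mechanisms, not against the full variability of clinical
recordings.

## Numerical choices and scales

Tolerances: curve inversions to 1e-9 L; static equilibria to ~1e-12;
volume conservation per breath better than 1e-3 L; linear-limit
equivalence with closed-form RC/RLC solutions better than 1 %. Determinism
is bitwise for fixed seeds (all randomness flows from
`numpy.random.default_rng` seeds recorded in the manifests). Test-suite
problem sizes: property checks run on records of 2–20 breaths; the
dataset-level checks generate 12-breath two-archetype sets plus one
600-breath balanced set (about two minutes of compute at roughly 15–30×
real time on one core).
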