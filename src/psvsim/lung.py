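"""Nonlinear one-compartment lung-airway mechanics.

The patient is a lumped pneumatic network with three airway resistances in
series -- upper airway (Rohrer, flow-dependent), collapsible segment
(volume-dependent, responsible for expiratory flow limitation) and small
airways (alveolar-volume-dependent) -- feeding an alveolar compartment.
Three sigmoidal pressure-volume curves describe the storage elements: the
collapsible-segment compliance, the alveolar (lung tissue) compliance and
the chest wall.  A linear Kelvin body (``Cve``/``Rve``) in series with the
lung recoil adds tissue visco-elasticity.  All functions here are pure and
operate on scalars or numpy arrays; the dynamic assembly lives in
:mod:`psvsim.solver`.

Sign and volume conventions
---------------------------
Pressures are in cmH2O relative to atmosphere, volumes in L, flows in L/s
(positive into the patient).  The alveolar volume ``VA`` is an absolute gas
volume (its sigmoid spans 0..Al); the chest-wall volume ``Vcw`` spans
RV..RV+(TLC-RV)/0.99.  During simulation the lung gas volume ``Vc + VA``
and the chest-wall volume are identical by construction (the chest-wall
curve is evaluated at the summed gas volume), which mirrors the series
ordering of the Kelvin body and chest wall in the source network.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "LungParameters",
    "LungState",
    "CurveDomainError",
    "AirwayCollapseError",
    "upper_airway_resistance",
    "collapsible_resistance",
    "small_airway_resistance",
    "collapsible_volume",
    "chest_wall_volume",
    "alveolar_volume",
    "collapsible_pressure",
    "chest_wall_pressure",
    "alveolar_pressure",
    "invert_volume_curve",
    "static_equilibrium",
]


class CurveDomainError(ValueError):
    """A volume was requested at or outside a curve asymptote."""


class AirwayCollapseError(RuntimeError):
    """The collapsible-segment volume left its admissible range."""


@dataclass(frozen=True)
class LungParameters:
    """All constants of the patient-side network for one virtual patient.

    Units: resistive constants ``Au``/``Kc``/``As``/``Bs``/``Rve``/``Rd`` in
    cmH2O.s/L, ``Ku`` in cmH2O.s^2/L^2, volumes (``Vcmax``, ``Vstar``,
    ``RV``, ``TLC``, ``Al``) in L, ``Ac`` in 1/cmH2O, ``Bc``/``Acw``/
    ``Bcw``/``Dl`` in cmH2O, ``Bl`` in 1/cmH2O, ``Ks``/``Dc`` dimensionless,
    ``Cve`` in L/cmH2O.

    ``Rd`` is the very high initialisation resistance of the source network;
    the solver replaces it with an exact algebraic equilibrium solve, so it
    only matters for fidelity experiments.
    """

    Au: float
    Ku: float
    Kc: float
    Vcmax: float
    As: float
    Ks: float
    Bs: float
    Vstar: float
    RV: float
    TLC: float
    Ac: float
    Bc: float
    Dc: float
    Acw: float
    Bcw: float
    Al: float
    Bl: float
    Dl: float
    Cve: float
    Rve: float
    Rd: float = 1.0e7
    archetype: str = "healthy"

    def __post_init__(self) -> None:
        if not (self.TLC > self.RV > 0):
            raise ValueError("require TLC > RV > 0")
        if self.Vcmax <= 0:
            raise ValueError("Vcmax must be positive")
        for name in ("Al", "Bl", "Bcw", "Dc"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("Au", "Ku", "Kc", "As", "Bs", "Cve", "Rve", "Rd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.Vstar == self.RV:
            raise ValueError("Vstar must differ from RV (degenerate Rs curve)")
        # Rd must dominate any airway resistance at zero flow by >= 1e4.
        r0 = self.Au + self.Kc + self.As * math.exp(max(self.Ks, 0.0)) + self.Bs
        if self.Rd < 1.0e4 * max(r0, 1.0):
            raise ValueError("Rd must be >= 1e4 x the zero-flow airway resistance")

    def with_(self, **kwargs) -> "LungParameters":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass
class LungState:
    """Instantaneous state of the patient network.

    Volumes are the state variables of record (the conserved quantities of
    the capacitors); the pressures stored here are derived via the curve
    inversions and kept for inspection.
    """

    Vc: float
    VA: float
    Vve: float
    Vcw: float
    Pc: float
    Pt: float
    Pcw: float
    Pmus: float = 0.0
    Qcw: float = 0.0
    PipPEEP: float = 0.0


# ---------------------------------------------------------------------------
# resistances


def upper_airway_resistance(Au, Ku, flow):
    """Rohrer resistance of the upper airway: ``Au + Ku*|flow|``.

    Even in the flow sign; the turbulent term grows linearly with |flow|.
    """
    return Au + Ku * np.abs(flow)


def collapsible_resistance(Kc, Vcmax, Vc):
    """Collapsible-segment resistance ``Kc*(Vcmax/Vc)**2``.

    Strictly decreasing in ``Vc``; diverges as the segment empties, which
    is the mechanism behind expiratory flow limitation.

    Raises
    ------
    AirwayCollapseError
        If ``Vc <= 0`` (the solver's collapse guard must prevent this).
    """
    if np.any(np.asarray(Vc) <= 0):
        raise AirwayCollapseError("collapsible airway volume Vc <= 0")
    return Kc * (Vcmax / np.asarray(Vc, dtype=float)) ** 2


def small_airway_resistance(As, Ks, Bs, Vstar, RV, VA):
    """Small-airway resistance ``As*exp(Ks*(VA-RV)/(Vstar-RV)) + Bs``.

    With ``Ks < 0`` (the physiological choice made by the archetype tuner)
    the resistance falls as the lung inflates: elastic recoil tethers the
    small airways open at high volume.
    """
    if Vstar == RV:
        raise ValueError("Vstar must differ from RV")
    return As * np.exp(Ks * (np.asarray(VA, dtype=float) - RV) / (Vstar - RV)) + Bs


# ---------------------------------------------------------------------------
# pressure-volume curves (all strictly increasing in their pressure argument)


def collapsible_volume(Ac, Bc, Dc, Vcmax, Pc):
    """Collapsible-segment volume ``Vcmax / (1+exp(-Ac*(Pc-Bc)))**Dc``."""
    return Vcmax / (1.0 + np.exp(-Ac * (np.asarray(Pc, dtype=float) - Bc))) ** Dc


def chest_wall_volume(TLC, RV, Acw, Bcw, Pcw):
    """Chest-wall volume ``(TLC-RV)/(0.99+exp(-(Pcw-Acw)/Bcw)) + RV``.

    The 0.99 denominator constant is deliberate: the upper asymptote is
    ``RV + (TLC-RV)/0.99``, about 1 % above TLC.
    """
    return (TLC - RV) / (0.99 + np.exp(-(np.asarray(Pcw, dtype=float) - Acw) / Bcw)) + RV


def alveolar_volume(Al, Bl, Dl, Pt):
    """Alveolar volume ``Al / (1+exp(-Bl*(Pt-Dl)))`` (Venegas sigmoid)."""
    return Al / (1.0 + np.exp(-Bl * (np.asarray(Pt, dtype=float) - Dl)))


# ---------------------------------------------------------------------------
# closed-form (logit) inversions


def collapsible_pressure(Ac, Bc, Dc, Vcmax, Vc):
    """Pressure at which the collapsible curve stores ``Vc`` (0 < Vc < Vcmax)."""
    Vc = np.asarray(Vc, dtype=float)
    if np.any(Vc <= 0) or np.any(Vc >= Vcmax):
        raise CurveDomainError("Vc outside the open range (0, Vcmax)")
    return Bc - np.log((Vcmax / Vc) ** (1.0 / Dc) - 1.0) / Ac


def chest_wall_pressure(TLC, RV, Acw, Bcw, Vcw):
    """Pressure at which the chest-wall curve stores ``Vcw``."""
    Vcw = np.asarray(Vcw, dtype=float)
    hi = RV + (TLC - RV) / 0.99
    if np.any(Vcw <= RV) or np.any(Vcw >= hi):
        raise CurveDomainError("Vcw outside the open range (RV, RV+(TLC-RV)/0.99)")
    return Acw - Bcw * np.log((TLC - RV) / (Vcw - RV) - 0.99)


def alveolar_pressure(Al, Bl, Dl, VA):
    """Transmural pressure at which the alveolar curve stores ``VA``."""
    VA = np.asarray(VA, dtype=float)
    if np.any(VA <= 0) or np.any(VA >= Al):
        raise CurveDomainError("VA outside the open range (0, Al)")
    return Dl - np.log(Al / VA - 1.0) / Bl


_CURVES = {
    "collapsible": (
        lambda p, x: collapsible_volume(p.Ac, p.Bc, p.Dc, p.Vcmax, x),
        lambda p, v: collapsible_pressure(p.Ac, p.Bc, p.Dc, p.Vcmax, v),
    ),
    "chest_wall": (
        lambda p, x: chest_wall_volume(p.TLC, p.RV, p.Acw, p.Bcw, x),
        lambda p, v: chest_wall_pressure(p.TLC, p.RV, p.Acw, p.Bcw, v),
    ),
    "alveolar": (
        lambda p, x: alveolar_volume(p.Al, p.Bl, p.Dl, x),
        lambda p, v: alveolar_pressure(p.Al, p.Bl, p.Dl, v),
    ),
}


def invert_volume_curve(curve: str, params: LungParameters, volume: float) -> float:
    """Return the unique pressure p with curve(p) = ``volume``.

    ``curve`` is one of ``"collapsible"``, ``"chest_wall"``, ``"alveolar"``.
    The closed-form logit inversion is used (all three curves are logistic);
    the result is verified to |curve(p) - V| < 1e-9 L and refined by
    bracketed root-finding in the (rare) case the closed form is not tight
    enough in floating point.

    Raises
    ------
    CurveDomainError
        For volumes at or outside the asymptotes.
    """
    try:
        forward, inverse = _CURVES[curve]
    except KeyError:
        raise ValueError(f"unknown curve {curve!r}") from None
    p = float(inverse(params, volume))
    if abs(float(forward(params, p)) - volume) < 1e-9:
        return p
    # fall back on a bracketed solve around the closed-form estimate
    lo, hi = p - 1.0, p + 1.0
    while float(forward(params, lo)) > volume:
        lo -= 1.0
    while float(forward(params, hi)) < volume:
        hi += 1.0
    return float(brentq(lambda x: float(forward(params, x)) - volume, lo, hi, xtol=1e-12))


# ---------------------------------------------------------------------------
# static balance


def static_equilibrium(params: LungParameters, pressure: float = 0.0):
    """Zero-flow equilibrium of the patient network at an applied airway pressure.

    With no flow every airway node sits at the applied pressure, the Kelvin
    body is relaxed, and the pleural pressure satisfies

        Ppl = Pcw(V),  V = VA(P - Ppl) + Vc(P - Ppl),

    i.e. transmural and collapsible-segment pressures share the common value
    ``P - Ppl``.  Returns ``(Ppl, Vc, VA)``; the equilibrium lung volume
    (= FRC when P = 0 and the muscles are relaxed) is ``Vc + VA``.

    Raises
    ------
    ValueError
        If no equilibrium exists in the physiological volume range, naming
        the violated bound.
    """
    p = params

    def residual(ppl: float) -> float:
        trans = pressure - ppl
        v = float(collapsible_volume(p.Ac, p.Bc, p.Dc, p.Vcmax, trans)) + float(
            alveolar_volume(p.Al, p.Bl, p.Dl, trans)
        )
        if v <= p.RV * (1 + 1e-12):
            # below the chest-wall asymptote: recoil pressure -> -inf
            return -1.0e9
        hi = p.RV + (p.TLC - p.RV) / 0.99
        if v >= hi:
            return 1.0e9
        return float(chest_wall_pressure(p.TLC, p.RV, p.Acw, p.Bcw, v)) - ppl

    lo, hi = -80.0, 80.0
    if residual(lo) < 0:
        raise ValueError(
            "no static equilibrium: lung volume exceeds the chest-wall range "
            "even at extreme negative pleural pressure"
        )
    if residual(hi) > 0:
        raise ValueError(
            "no static equilibrium: lung volume below residual volume even at "
            "extreme positive pleural pressure"
        )
    ppl = float(brentq(residual, lo, hi, xtol=1e-12, rtol=8.9e-16))
    trans = pressure - ppl
    vc = float(collapsible_volume(p.Ac, p.Bc, p.Dc, p.Vcmax, trans))
    va = float(alveolar_volume(p.Al, p.Bl, p.Dl, trans))
    return ppl, vc, va
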