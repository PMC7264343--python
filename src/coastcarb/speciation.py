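"""Nonlinear speciation solver for the seawater CO2 system.

All solvers find the root of the total-alkalinity balance in pH on the
total scale with a safeguarded Newton iteration bracketed on
pH in [2, 12] (absolute tolerance 1e-8 pH).  Concentration units are
umol kg-1 for TA, DIC and the carbonate species and uatm for pCO2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from coastcarb.constants import (
    ConstantOptions,
    EquilibriumConstants,
    compute_constants,
)

__all__ = [
    "CarbonateState",
    "ConvergenceError",
    "solve_from_dic_ta",
    "solve_from_pco2_ta",
    "solve_from_ph_ta",
    "alkalinity_residual",
]

PH_LO, PH_HI = 2.0, 12.0
PH_TOL = 1e-8
MAX_ITER = 100


class ConvergenceError(RuntimeError):
    """The pH iteration failed to bracket or converge on a root."""


@dataclass(frozen=True)
class CarbonateState:
    """Fully speciated carbonate system of one surface water parcel.

    Attributes
    ----------
    T, S : float
        Temperature (degC) and practical salinity.
    TA, DIC : float
        Total alkalinity and dissolved inorganic carbon, umol kg-1.
    pH : float
        Total-scale pH.
    pCO2 : float
        Seawater CO2 partial pressure, uatm.
    CO2aq, HCO3, CO3 : float
        Carbonate species, umol kg-1.
    Omega_arag : float
        Aragonite saturation state, [Ca][CO3]/Ksp.
    revelle : float or None
        Revelle factor if attached by :func:`coastcarb.thermo.revelle_factor`.
    """

    T: float
    S: float
    TA: float
    DIC: float
    pH: float
    pCO2: float
    CO2aq: float
    HCO3: float
    CO3: float
    Omega_arag: float
    PO4: float = 0.0
    SiO4: float = 0.0
    revelle: float | None = None

    @property
    def dic_over_ta(self) -> float:
        return self.DIC / self.TA


def _nutrient_alkalinity(h: float, k: EquilibriumConstants, PO4: float, SiO4: float) -> float:
    """Phosphate + silicate alkalinity (mol kg-1) at [H+] ``h`` (total)."""
    if PO4 <= 0.0 and SiO4 <= 0.0:
        return 0.0
    alk = 0.0
    if PO4 > 0.0:
        denom = (
            h**3 + k.KP1 * h**2 + k.KP1 * k.KP2 * h + k.KP1 * k.KP2 * k.KP3
        )
        h3po4 = PO4 * h**3 / denom
        hpo4 = PO4 * k.KP1 * k.KP2 * h / denom
        po4 = PO4 * k.KP1 * k.KP2 * k.KP3 / denom
        alk += hpo4 + 2.0 * po4 - h3po4
    if SiO4 > 0.0:
        alk += SiO4 * k.KSi / (k.KSi + h)
    return alk


def alkalinity_residual(
    pH: float,
    DIC_mol: float,
    TA_mol: float,
    k: EquilibriumConstants,
    PO4_mol: float = 0.0,
    SiO4_mol: float = 0.0,
) -> float:
    """TA balance residual (mol kg-1): modelled alkalinity minus TA.

    Includes carbonate, borate, water, free-proton, bisulfate, fluoride
    and (when supplied) phosphate/silicate terms.
    """
    h = 10.0**-pH
    denom = h * h + k.K1 * h + k.K1 * k.K2
    hco3 = DIC_mol * k.K1 * h / denom
    co3 = DIC_mol * k.K1 * k.K2 / denom
    boh4 = k.BT * k.KB / (k.KB + h)
    oh = k.Kw / h
    h_free = h / k.free_to_total
    hso4 = k.ST * h_free / (k.KS + h_free)
    hf = k.FT * h_free / (k.KF + h_free)
    return (
        hco3
        + 2.0 * co3
        + boh4
        + oh
        + _nutrient_alkalinity(h, k, PO4_mol, SiO4_mol)
        - h_free
        - hso4
        - hf
        - TA_mol
    )


def _solve_ph(f, lo: float = PH_LO, hi: float = PH_HI) -> float:
    """Safeguarded Newton on a bracketed monotone-ish residual ``f(pH)``.

    The derivative is taken numerically; whenever the Newton step leaves
    the current bracket, it is replaced by bisection.  Deterministic.
    """
    flo, fhi = f(lo), f(hi)
    if flo == 0.0:
        return lo
    if fhi == 0.0:
        return hi
    if flo * fhi > 0.0:
        raise ConvergenceError(
            f"no alkalinity-balance root in pH [{lo}, {hi}] "
            f"(residuals {flo:.3e}, {fhi:.3e})"
        )
    x = 0.5 * (lo + hi)
    for _ in range(MAX_ITER):
        fx = f(x)
        if fx == 0.0:
            return x
        # maintain the bracket
        if fx * flo < 0.0:
            hi = x
        else:
            lo, flo = x, fx
        dh = 1e-4
        dfdx = (f(x + dh) - f(x - dh)) / (2.0 * dh)
        if dfdx != 0.0:
            x_new = x - fx / dfdx
        else:
            x_new = 0.5 * (lo + hi)
        if not (lo < x_new < hi):
            x_new = 0.5 * (lo + hi)
        if abs(x_new - x) < PH_TOL:
            return x_new
        x = x_new
    raise ConvergenceError(f"pH iteration did not converge within {MAX_ITER} steps")


def _speciate(pH: float, DIC_mol: float, k: EquilibriumConstants) -> tuple[float, float, float]:
    h = 10.0**-pH
    denom = h * h + k.K1 * h + k.K1 * k.K2
    co2 = DIC_mol * h * h / denom
    hco3 = DIC_mol * k.K1 * h / denom
    co3 = DIC_mol * k.K1 * k.K2 / denom
    return co2, hco3, co3


def _state(
    pH: float, DIC_mol: float, TA: float, k: EquilibriumConstants, PO4: float, SiO4: float
) -> CarbonateState:
    co2, hco3, co3 = _speciate(pH, DIC_mol, k)
    pco2 = co2 / (k.K0 * k.fCO2_factor) * 1e6
    omega = k.Ca * co3 / k.Ksp_arag
    return CarbonateState(
        T=k.T,
        S=k.S,
        TA=TA,
        DIC=DIC_mol * 1e6,
        pH=pH,
        pCO2=pco2,
        CO2aq=co2 * 1e6,
        HCO3=hco3 * 1e6,
        CO3=co3 * 1e6,
        Omega_arag=omega,
        PO4=PO4,
        SiO4=SiO4,
    )


def _check_nutrients(PO4: float, SiO4: float) -> None:
    if PO4 < 0.0 or SiO4 < 0.0:
        raise ValueError(f"negative nutrient concentration: PO4={PO4}, SiO4={SiO4}")


def solve_from_dic_ta(
    DIC: float,
    TA: float,
    T: float,
    S: float,
    PO4: float = 0.0,
    SiO4: float = 0.0,
    options: ConstantOptions | None = None,
) -> CarbonateState:
    """Speciate from the (DIC, TA) pair.  Inputs in umol kg-1, degC.

    Raises ``ValueError`` on non-positive DIC/TA, DIC/TA ratio outside
    (0.4, 1.3), or negative nutrients; ``ConvergenceError`` if no root
    exists in pH [2, 12].
    """
    if DIC <= 0.0 or TA <= 0.0:
        raise ValueError(f"DIC and TA must be positive (got DIC={DIC}, TA={TA})")
    if not (0.4 < DIC / TA < 1.3):
        raise ValueError(f"DIC/TA ratio {DIC / TA:.3f} outside supported range (0.4, 1.3)")
    _check_nutrients(PO4, SiO4)
    k = compute_constants(T, S, options)
    dic_mol, ta_mol = DIC * 1e-6, TA * 1e-6
    po4_mol, sio4_mol = PO4 * 1e-6, SiO4 * 1e-6
    pH = _solve_ph(lambda x: alkalinity_residual(x, dic_mol, ta_mol, k, po4_mol, sio4_mol))
    return _state(pH, dic_mol, TA, k, PO4, SiO4)


def solve_from_pco2_ta(
    pCO2: float,
    TA: float,
    T: float,
    S: float,
    PO4: float = 0.0,
    SiO4: float = 0.0,
    options: ConstantOptions | None = None,
) -> CarbonateState:
    """Speciate from the (pCO2, TA) pair; DIC is an output."""
    if pCO2 <= 0.0 or TA <= 0.0:
        raise ValueError(f"pCO2 and TA must be positive (got pCO2={pCO2}, TA={TA})")
    _check_nutrients(PO4, SiO4)
    k = compute_constants(T, S, options)
    ta_mol = TA * 1e-6
    po4_mol, sio4_mol = PO4 * 1e-6, SiO4 * 1e-6
    co2 = k.K0 * k.fCO2_factor * pCO2 * 1e-6  # Henry's law via fCO2

    def resid(pH: float) -> float:
        h = 10.0**-pH
        hco3 = k.K1 * co2 / h
        co3 = k.K1 * k.K2 * co2 / (h * h)
        boh4 = k.BT * k.KB / (k.KB + h)
        oh = k.Kw / h
        h_free = h / k.free_to_total
        hso4 = k.ST * h_free / (k.KS + h_free)
        hf = k.FT * h_free / (k.KF + h_free)
        return (
            hco3
            + 2.0 * co3
            + boh4
            + oh
            + _nutrient_alkalinity(h, k, po4_mol, sio4_mol)
            - h_free
            - hso4
            - hf
            - ta_mol
        )

    pH = _solve_ph(resid)
    h = 10.0**-pH
    dic_mol = co2 * (1.0 + k.K1 / h + k.K1 * k.K2 / (h * h))
    return _state(pH, dic_mol, TA, k, PO4, SiO4)


def solve_from_ph_ta(
    pH: float,
    TA: float,
    T: float,
    S: float,
    PO4: float = 0.0,
    SiO4: float = 0.0,
    options: ConstantOptions | None = None,
) -> CarbonateState:
    """Speciate from the (pH, TA) pair; DIC follows from the carbonate alkalinity."""
    if TA <= 0.0:
        raise ValueError(f"TA must be positive (got {TA})")
    if not (PH_LO <= pH <= PH_HI):
        raise ValueError(f"pH {pH} outside [{PH_LO}, {PH_HI}]")
    _check_nutrients(PO4, SiO4)
    k = compute_constants(T, S, options)
    ta_mol = TA * 1e-6
    po4_mol, sio4_mol = PO4 * 1e-6, SiO4 * 1e-6
    h = 10.0**-pH
    boh4 = k.BT * k.KB / (k.KB + h)
    oh = k.Kw / h
    h_free = h / k.free_to_total
    hso4 = k.ST * h_free / (k.KS + h_free)
    hf = k.FT * h_free / (k.KF + h_free)
    carb_alk = ta_mol - boh4 - oh + h_free + hso4 + hf - _nutrient_alkalinity(
        h, k, po4_mol, sio4_mol
    )
    # carb_alk = DIC * K1*(h + 2 K2)/(h^2 + K1 h + K1 K2)
    denom = h * h + k.K1 * h + k.K1 * k.K2
    dic_mol = carb_alk * denom / (k.K1 * (h + 2.0 * k.K2))
    if dic_mol <= 0.0:
        raise ConvergenceError(f"non-physical DIC for pH={pH}, TA={TA}")
    return _state(pH, dic_mol, TA, k, PO4, SiO4)
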