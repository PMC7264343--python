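"""Equilibrium constants of the seawater CO2 system.

All constants are returned on the **total proton scale** at surface
pressure (0 dbar).  The carbonic-acid constants are the Mehrbach
measurements as refitted by Dickson & Millero (1987); the remaining
formulations follow the conventional CO2SYS defaults:

=============  ==========================================
K0             Weiss (1974)
K1, K2         Mehrbach et al. (1973) refit by
               Dickson & Millero (1987), SWS -> total
KB             Dickson (1990b)
Kw             Millero (1995), SWS -> total
Ksp_arag       Mucci (1983)
KS (bisulfate) Dickson (1990a), free scale
KF             Dickson & Riley (1979), free scale
BT             Uppstrom (1974), proportional to S
               (Lee et al. 2010 available via options)
Ca             Riley & Tongudai (1967), proportional to S
KP1..KP3, KSi  Millero (1995), SWS -> total
=============  ==========================================

The borate and aragonite-solubility choices are configurable through
:class:`ConstantOptions` because the source analyses do not pin them
down; the defaults above are documented as the assumed set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = ["ConstantOptions", "EquilibriumConstants", "compute_constants", "fugacity_factor"]

T_MIN, T_MAX = -2.0, 40.0
S_MIN, S_MAX = 0.0, 42.0


@dataclass(frozen=True)
class ConstantOptions:
    """Swappable formulation choices for :func:`compute_constants`.

    Attributes
    ----------
    borate:
        Total-borate-from-salinity formulation, ``"uppstrom74"``
        (default) or ``"lee10"``.
    fugacity:
        If True (default), Henry's-law exchange between pCO2 and
        dissolved CO2 goes through the CO2 fugacity coefficient
        (Weiss 1974 virial expression), matching CO2SYS behaviour
        for a pCO2 input pair.
    """

    borate: str = "uppstrom74"
    fugacity: bool = True

    def __post_init__(self) -> None:
        if self.borate not in ("uppstrom74", "lee10"):
            raise ValueError(f"unknown borate formulation: {self.borate!r}")


DEFAULT_OPTIONS = ConstantOptions()


@dataclass(frozen=True)
class EquilibriumConstants:
    """Full thermodynamic constant set at one (T, S), total scale, 0 dbar.

    Units: K0 mol kg-1 atm-1; K1, K2, KB mol kg-1; Kw mol2 kg-2;
    Ksp_arag mol2 kg-2; BT, Ca, ST, FT mol kg-1.
    """

    T: float
    S: float
    K0: float
    K1: float
    K2: float
    KB: float
    Kw: float
    Ksp_arag: float
    BT: float
    Ca: float
    # acid-base medium species needed for the full alkalinity balance
    ST: float
    KS: float
    FT: float
    KF: float
    KP1: float
    KP2: float
    KP3: float
    KSi: float
    free_to_total: float
    fCO2_factor: float
    options: ConstantOptions = field(default=DEFAULT_OPTIONS, compare=False)

    @property
    def k1_over_k2(self) -> float:
        return self.K1 / self.K2


def fugacity_factor(T_c: float) -> float:
    """fCO2 / pCO2 at 1 atm total pressure (Weiss 1974 virial coefficients)."""
    T = T_c + 273.15
    b = -1636.75 + 12.0408 * T - 0.0327957 * T**2 + 3.16528e-5 * T**3
    delta = 57.7 - 0.118 * T
    # cm3 mol-1 coefficients, P = 1.01325 bar, R = 83.1451 cm3 bar K-1 mol-1
    return math.exp((b + 2.0 * delta) * 1.01325 / (83.1451 * T))


def compute_constants(
    T: float, S: float, options: ConstantOptions | None = None
) -> EquilibriumConstants:
    """Evaluate the constant set at temperature ``T`` (degC) and salinity ``S``.

    Raises
    ------
    ValueError
        If T is outside [-2, 40] degC or S outside (0, 42].
    """
    if options is None:
        options = DEFAULT_OPTIONS
    if not (T_MIN <= T <= T_MAX):
        raise ValueError(f"temperature {T} degC outside [{T_MIN}, {T_MAX}]")
    if not (S_MIN < S <= S_MAX):
        raise ValueError(f"salinity {S} outside ({S_MIN}, {S_MAX}]")

    TK = T + 273.15
    lnTK = math.log(TK)
    sqS = math.sqrt(S)

    # CO2 solubility, mol kg-1 atm-1 (Weiss 1974)
    K0 = math.exp(
        -60.2409
        + 93.4517 * (100.0 / TK)
        + 23.3585 * math.log(TK / 100.0)
        + S * (0.023517 - 0.023656 * (TK / 100.0) + 0.0047036 * (TK / 100.0) ** 2)
    )

    # conservative seawater totals, mol kg-1
    ST = 0.14 / 96.062 * S / 1.80655
    FT = 0.000067 / 18.998 * S / 1.80655
    Ca = 0.02128 / 40.087 * S / 1.80655
    if options.borate == "lee10":
        BT = 0.0004326 * S / 35.0
    else:
        BT = 0.0004157 * S / 35.0

    # bisulfate (Dickson 1990a, free scale) on the ionic-strength grid
    I = 19.924 * S / (1000.0 - 1.005 * S)
    KS = math.exp(
        -4276.1 / TK
        + 141.328
        - 23.093 * lnTK
        + (-13856.0 / TK + 324.57 - 47.986 * lnTK) * math.sqrt(I)
        + (35474.0 / TK - 771.54 + 114.723 * lnTK) * I
        - 2698.0 / TK * I**1.5
        + 1776.0 / TK * I**2
        + math.log(1.0 - 0.001005 * S)
    )
    # hydrogen fluoride (Dickson & Riley 1979, free scale)
    KF = math.exp(1590.2 / TK - 12.641 + 1.525 * math.sqrt(I) + math.log(1.0 - 0.001005 * S))

    free_to_total = 1.0 + ST / KS
    sws_to_total = free_to_total / (1.0 + ST / KS + FT / KF)

    # carbonic acid: Mehrbach refit by Dickson & Millero 1987 (SWS -> total)
    pK1 = 3670.7 / TK - 62.008 + 9.7944 * lnTK - 0.0118 * S + 0.000116 * S**2
    pK2 = 1394.7 / TK + 4.777 - 0.0184 * S + 0.000118 * S**2
    K1 = 10.0**-pK1 * sws_to_total
    K2 = 10.0**-pK2 * sws_to_total

    # boric acid (Dickson 1990b, already total scale)
    KB = math.exp(
        (-8966.90 - 2890.53 * sqS - 77.942 * S + 1.728 * S**1.5 - 0.0996 * S**2) / TK
        + 148.0248
        + 137.1942 * sqS
        + 1.62142 * S
        + (-24.4344 - 25.085 * sqS - 0.2474 * S) * lnTK
        + 0.053105 * sqS * TK
    )

    # water (Millero 1995, SWS -> total)
    Kw = (
        math.exp(
            148.9802
            - 13847.26 / TK
            - 23.6521 * lnTK
            + (-5.977 + 118.67 / TK + 1.0495 * lnTK) * sqS
            - 0.01615 * S
        )
        * sws_to_total
    )

    # aragonite solubility product (Mucci 1983)
    Ksp_arag = 10.0 ** (
        -171.945
        - 0.077993 * TK
        + 2903.293 / TK
        + 71.595 * math.log10(TK)
        + (-0.068393 + 0.0017276 * TK + 88.135 / TK) * sqS
        - 0.10018 * S
        + 0.0059415 * S**1.5
    )

    # phosphoric acid (Millero 1995 composite, SWS -> total)
    KP1 = (
        math.exp(
            -4576.752 / TK
            + 115.525
            - 18.453 * lnTK
            + (-106.736 / TK + 0.69171) * sqS
            + (-0.65643 / TK - 0.01844) * S
        )
        * sws_to_total
    )
    KP2 = (
        math.exp(
            -8814.715 / TK
            + 172.0883
            - 27.927 * lnTK
            + (-160.340 / TK + 1.3566) * sqS
            + (0.37335 / TK - 0.05778) * S
        )
        * sws_to_total
    )
    KP3 = (
        math.exp(
            -3070.75 / TK
            - 18.141
            + (17.27039 / TK + 2.81197) * sqS
            + (-44.99486 / TK - 0.09984) * S
        )
        * sws_to_total
    )
    # silicic acid (Millero 1995, SWS -> total); ionic-strength form
    KSi = (
        math.exp(
            -8904.2 / TK
            + 117.385
            - 19.334 * lnTK
            + (-458.79 / TK + 3.5913) * math.sqrt(I)
            + (188.74 / TK - 1.5998) * I
            + (-12.1652 / TK + 0.07871) * I**2
            + math.log(1.0 - 0.001005 * S)
        )
        * sws_to_total
    )

    return EquilibriumConstants(
        T=T,
        S=S,
        K0=K0,
        K1=K1,
        K2=K2,
        KB=KB,
        Kw=Kw,
        Ksp_arag=Ksp_arag,
        BT=BT,
        Ca=Ca,
        ST=ST,
        KS=KS,
        FT=FT,
        KF=KF,
        KP1=KP1,
        KP2=KP2,
        KP3=KP3,
        KSi=KSi,
        free_to_total=free_to_total,
        fCO2_factor=fugacity_factor(T) if options.fugacity else 1.0,
        options=options,
    )
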