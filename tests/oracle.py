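"""Independent reference implementation used only by the tests.

Evaluates the same published constant formulations as the package but
with separately written code, and solves the alkalinity balance with
scipy's brentq instead of the package's safeguarded Newton iteration.
Kept free of any imports from ``coastcarb``.
"""

import numpy as np
from scipy.optimize import brentq


def ref_constants(t_c, s):
    """Constant set (total scale, 0 dbar) as a plain dict, mol/kg units."""
    t = t_c + 273.15
    # Weiss 1974 solubility
    k0 = np.exp(
        9345.17 / t - 60.2409 + 23.3585 * np.log(t / 100.0)
        + s * (0.023517 - 0.00023656 * t + 0.0047036 * (t / 100.0) ** 2)
    )
    ist = 19.924 * s / (1000.0 - 1.005 * s)
    st = 0.02824 * s / 35.0
    ft = 7e-5 * s / 35.0
    # Dickson 1990a bisulfate (free scale)
    ks = np.exp(
        -4276.1 / t + 141.328 - 23.093 * np.log(t)
        + (-13856.0 / t + 324.57 - 47.986 * np.log(t)) * ist ** 0.5
        + (35474.0 / t - 771.54 + 114.723 * np.log(t)) * ist
        - 2698.0 / t * ist ** 1.5 + 1776.0 / t * ist ** 2
    ) * (1.0 - 0.001005 * s)
    # Dickson & Riley 1979 HF (free scale)
    kf = np.exp(1590.2 / t - 12.641 + 1.525 * ist ** 0.5) * (1.0 - 0.001005 * s)
    f2t = 1.0 + st / ks
    s2t = f2t / (1.0 + st / ks + ft / kf)
    # Mehrbach refit (Dickson & Millero 1987), SWS, converted to total
    k1 = 10.0 ** -(3670.7 / t - 62.008 + 9.7944 * np.log(t) - 0.0118 * s + 0.000116 * s * s)
    k2 = 10.0 ** -(1394.7 / t + 4.777 - 0.0184 * s + 0.000118 * s * s)
    k1, k2 = k1 * s2t, k2 * s2t
    # Dickson 1990b boric acid (total)
    kb = np.exp(
        (-8966.90 - 2890.53 * s ** 0.5 - 77.942 * s + 1.728 * s ** 1.5 - 0.0996 * s ** 2) / t
        + 148.0248 + 137.1942 * s ** 0.5 + 1.62142 * s
        - (24.4344 + 25.085 * s ** 0.5 + 0.2474 * s) * np.log(t)
        + 0.053105 * s ** 0.5 * t
    )
    # Millero 1995 water (SWS -> total)
    kw = np.exp(
        148.9802 - 13847.26 / t - 23.6521 * np.log(t)
        + (118.67 / t - 5.977 + 1.0495 * np.log(t)) * s ** 0.5 - 0.01615 * s
    ) * s2t
    # Mucci 1983 aragonite
    kspa = 10.0 ** (
        -171.945 - 0.077993 * t + 2903.293 / t + 71.595 * np.log10(t)
        + (-0.068393 + 0.0017276 * t + 88.135 / t) * s ** 0.5
        - 0.10018 * s + 0.0059415 * s ** 1.5
    )
    bt = 0.0004157 * s / 35.0
    ca = 0.010282 * s / 35.0
    return dict(k0=k0, k1=k1, k2=k2, kb=kb, kw=kw, kspa=kspa, bt=bt, ca=ca,
                st=st, ks=ks, ft=ft, kf=kf, f2t=f2t)


def fug(t_c):
    t = t_c + 273.15
    b = -1636.75 + 12.0408 * t - 0.0327957 * t * t + 3.16528e-5 * t ** 3
    return np.exp((b + 2.0 * (57.7 - 0.118 * t)) * 1.01325 / (83.1451 * t))


def _balance(ph, dic, ta, c):
    h = 10.0 ** -ph
    den = h * h + c["k1"] * h + c["k1"] * c["k2"]
    hfree = h / c["f2t"]
    return (
        dic * c["k1"] * (h + 2.0 * c["k2"]) / den
        + c["bt"] / (1.0 + h / c["kb"])
        + c["kw"] / h
        - hfree
        - c["st"] / (1.0 + c["ks"] / hfree)
        - c["ft"] / (1.0 + c["kf"] / hfree)
        - ta
    )


def ref_solve_dic_ta(dic_u, ta_u, t_c, s):
    """(pH, pCO2 uatm, omega) from DIC and TA in umol/kg via brentq."""
    c = ref_constants(t_c, s)
    dic, ta = dic_u * 1e-6, ta_u * 1e-6
    ph = brentq(_balance, 2.0, 12.0, args=(dic, ta, c), xtol=1e-12)
    h = 10.0 ** -ph
    den = h * h + c["k1"] * h + c["k1"] * c["k2"]
    co2 = dic * h * h / den
    co3 = dic * c["k1"] * c["k2"] / den
    pco2 = co2 / (c["k0"] * fug(t_c)) * 1e6
    return ph, pco2, c["ca"] * co3 / c["kspa"]


def ref_solve_pco2_ta(pco2_u, ta_u, t_c, s):
    """(pH, DIC umol/kg) from pCO2 and TA via brentq on the CO2-anchored balance."""
    c = ref_constants(t_c, s)
    co2 = c["k0"] * fug(t_c) * pco2_u * 1e-6
    ta = ta_u * 1e-6

    def g(ph):
        h = 10.0 ** -ph
        hfree = h / c["f2t"]
        return (
            co2 * c["k1"] / h * (1.0 + 2.0 * c["k2"] / h)
            + c["bt"] / (1.0 + h / c["kb"])
            + c["kw"] / h
            - hfree
            - c["st"] / (1.0 + c["ks"] / hfree)
            - c["ft"] / (1.0 + c["kf"] / hfree)
            - ta
        )

    ph = brentq(g, 2.0, 12.0, xtol=1e-12)
    h = 10.0 ** -ph
    dic = co2 * (1.0 + c["k1"] / h + c["k1"] * c["k2"] / (h * h))
    return ph, dic * 1e6


def ref_schmidt(t_c):
    """Direct polynomial arithmetic, no shared code."""
    return (
        2116.8
        - 136.25 * t_c
        + 4.7353 * t_c ** 2
        - 0.092307 * t_c ** 3
        + 0.0007555 * t_c ** 4
    )
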