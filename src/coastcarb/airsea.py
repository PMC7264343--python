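"""Air-sea CO2 exchange and atmospheric-equilibrium deviation analysis.

Gas-transfer velocity follows k = 0.251 W^2 (Sc/660)^-0.5 (cm h-1) with
the quartic CO2-in-seawater Schmidt-number polynomial (S = 35 fit,
valid -2..40 degC).  The flux law is

    F = 0.24 k K0 (pCO2_sea - pCO2_atm) * rho/1000   [mmol m-2 day-1]

positive from ocean to atmosphere; 0.24 converts cm h-1 to m day-1 and
rho/1000 converts the per-kilogram solubility to per-volume.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from coastcarb.constants import ConstantOptions, compute_constants
from coastcarb.speciation import CarbonateState, solve_from_dic_ta, solve_from_pco2_ta

__all__ = [
    "schmidt_number",
    "gas_transfer_velocity",
    "co2_flux",
    "equilibrium_state",
    "deviation_analysis",
    "RHO_SW",
]

log = logging.getLogger(__name__)

#: fixed surface seawater density for per-mass <-> per-volume conversion, kg m-3
RHO_SW = 1025.0

# Schmidt number for CO2 in seawater, quartic in T (S=35 fit)
_SC_COEF = (2116.8, -136.25, 4.7353, -0.092307, 0.0007555)


def schmidt_number(T: float, S: float = 35.0) -> float:
    """CO2-in-seawater Schmidt number at ``T`` degC.

    The polynomial is a salinity-35 fit; ``S`` is accepted for interface
    symmetry but does not enter the fit.
    """
    T = float(T)
    if not (-2.0 <= T <= 40.0):
        raise ValueError(f"temperature {T} degC outside Schmidt-number fit range [-2, 40]")
    a0, a1, a2, a3, a4 = _SC_COEF
    return a0 + a1 * T + a2 * T**2 + a3 * T**3 + a4 * T**4


def gas_transfer_velocity(W: float, Sc: float) -> float:
    """Piston velocity k = 0.251 W^2 (Sc/660)^-0.5, cm h-1."""
    if W < 0.0:
        raise ValueError(f"wind speed must be non-negative (got {W})")
    if Sc <= 0.0:
        raise ValueError(f"Schmidt number must be positive (got {Sc})")
    return 0.251 * W**2 * (Sc / 660.0) ** -0.5


def co2_flux(
    state: CarbonateState,
    pCO2_atm: float,
    W: float,
    options: ConstantOptions | None = None,
) -> float:
    """Air-sea CO2 flux, mmol m-2 day-1, positive ocean-to-atmosphere."""
    k = compute_constants(state.T, state.S, options)
    sc = schmidt_number(state.T, state.S)
    ktr = gas_transfer_velocity(W, sc)
    # K0 [mol kg-1 atm-1] * dpCO2 [uatm] = umol kg-1; * rho/1000 -> mmol m-3
    return 0.24 * ktr * k.K0 * (state.pCO2 - pCO2_atm) * RHO_SW / 1000.0


def equilibrium_state(
    TA: float,
    T: float,
    S: float,
    pCO2_atm: float,
    options: ConstantOptions | None = None,
) -> CarbonateState:
    """Carbonate state at full equilibrium with atmospheric pCO2.

    Yields the equilibrium DIC, Omega_arag, pH and pCO2 companion values
    for a sample of given TA, T, S.
    """
    return solve_from_pco2_ta(pCO2_atm, TA, T, S, options=options)


_DEV_PARAMS = ("dic", "omega_arag", "ph", "pco2")


def deviation_analysis(
    transect: pd.DataFrame,
    pCO2_atm: float,
    options: ConstantOptions | None = None,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Observed-minus-equilibrium deviations and their Pearson correlations.

    Parameters
    ----------
    transect:
        Bottle table with at least ``sst_c``, ``sss``, ``ta_umol_kg``,
        ``dic_umol_kg`` columns (the bottle-CSV schema).  Covariate
        columns (``do_percent``, ``no3_umol_kg``) are carried through.
    pCO2_atm:
        Atmospheric pCO2, uatm (scalar for the transect).

    Returns
    -------
    (table, correlations):
        ``table`` has one row per input sample with observed,
        equilibrium and deviation (obs - eq) columns for DIC,
        Omega_arag, pH and pCO2, plus ``dpco2_airsea`` = pCO2_obs -
        pCO2_atm.  ``correlations`` maps ``"ddic_vs_dpco2"`` etc. to
        Pearson r over pairwise-complete rows; NaN when fewer than
        3 valid rows.
    """
    rows = []
    n_skipped = 0
    for _, s in transect.iterrows():
        rec: dict[str, float] = {
            "sst_c": s["sst_c"],
            "sss": s["sss"],
            "ta_umol_kg": s["ta_umol_kg"],
        }
        for cov in ("do_percent", "no3_umol_kg", "lat_degn"):
            if cov in transect.columns:
                rec[cov] = s[cov]
        try:
            obs = solve_from_dic_ta(
                s["dic_umol_kg"], s["ta_umol_kg"], s["sst_c"], s["sss"], options=options
            )
            eq = equilibrium_state(
                s["ta_umol_kg"], s["sst_c"], s["sss"], pCO2_atm, options=options
            )
        except (ValueError, TypeError):
            n_skipped += 1
            for p in _DEV_PARAMS:
                rec[f"{p}_obs"] = np.nan
                rec[f"{p}_eq"] = np.nan
                rec[f"d{p}"] = np.nan
            rec["dpco2_airsea"] = np.nan
            rows.append(rec)
            continue
        obs_vals = {
            "dic": obs.DIC,
            "omega_arag": obs.Omega_arag,
            "ph": obs.pH,
            "pco2": obs.pCO2,
        }
        eq_vals = {
            "dic": eq.DIC,
            "omega_arag": eq.Omega_arag,
            "ph": eq.pH,
            "pco2": eq.pCO2,
        }
        for p in _DEV_PARAMS:
            rec[f"{p}_obs"] = obs_vals[p]
            rec[f"{p}_eq"] = eq_vals[p]
            rec[f"d{p}"] = obs_vals[p] - eq_vals[p]
        rec["dpco2_airsea"] = obs.pCO2 - pCO2_atm
        rows.append(rec)
    if n_skipped:
        log.warning("deviation_analysis: %d rows could not be speciated", n_skipped)
    table = pd.DataFrame(rows)

    # deviations smaller than the solver tolerance (1e-3 of a unit) carry
    # no signal: report the correlation as undefined rather than fitting noise
    correlations: dict[str, float] = {}
    for p in ("dic", "omega_arag", "ph"):
        pair = table[[f"d{p}", "dpco2_airsea"]].dropna()
        x, y = pair[f"d{p}"].to_numpy(), pair["dpco2_airsea"].to_numpy()
        if len(pair) < 3 or np.ptp(x) < 1e-3 or np.ptp(y) < 1e-3:
            correlations[f"d{p}_vs_dpco2"] = float("nan")
        else:
            correlations[f"d{p}_vs_dpco2"] = float(stats.pearsonr(x, y).statistic)
    return table, correlations
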