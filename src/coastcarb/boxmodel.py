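"""Daily mixed-layer box model of the surface-ocean carbonate system.

State is DIC (umol kg-1) in a single homogeneous box of fixed depth.
Each day, in order:

1. the carbonate system is solved with temperature, salinity, DIC and
   TA valid at t_n;
2. the DIC increments from air-sea exchange (from the pCO2 at t_n),
   biology and vertical mixing are applied to give DIC at t_n+1;
3. the system is re-solved with T, S and TA still at t_n but DIC at
   t_n+1, so that all carbon parameters of a step share one set of
   physical conditions;
4. T, S and TA(S) advance at the start of the next step.

TA is diagnosed from salinity alone and never responds to the carbon
fluxes.  A companion series DIC_eq (pCO2 relaxed to the atmosphere,
i.e. infinitely fast exchange) is evaluated every day.

The air-sea DIC increment is capped so a single 1-day step cannot
overshoot the equilibrium DIC; this keeps the explicit scheme stable
when the transfer velocity is scaled far beyond physical winds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from coastcarb.airsea import RHO_SW, gas_transfer_velocity, schmidt_number
from coastcarb.constants import ConstantOptions, compute_constants
from coastcarb.speciation import (
    CarbonateState,
    ConvergenceError,
    solve_from_dic_ta,
    solve_from_pco2_ta,
)

__all__ = [
    "ForcingSeries",
    "ModelParams",
    "Trajectory",
    "RelaxationError",
    "REGION_PRESETS",
    "ta_from_salinity",
    "chl_to_ncp",
    "step",
    "run",
    "efolding_experiment",
]

log = logging.getLogger(__name__)

MOLAR_MASS_C = 12.011  # g mol-1


class RelaxationError(RuntimeError):
    """A pulse-decay experiment did not relax within its horizon."""


#: Region presets: TA-S anchoring chosen so S=35 -> TA=2280 umol kg-1,
#: winds 7 m s-1 (summer) / 10.5 m s-1 (winter), and the NWA winter
#: vertical-mixing window of exactly 155 days (day-of-year >= 272 or
#: <= 61, i.e. late September through early March).
REGION_PRESETS: dict[str, dict] = {
    "nwa": {
        "ta_slope": 46.6,
        "ta_intercept": 649.0,
        "winter_mix_rate": 0.1,
        "winter_mix_doy": (272, 61),
        "sst_mean": 11.0,
        "sst_amp": 8.5,
        "sss_mean": 32.2,
        "sss_amp": 0.8,
        "bloom_day": 105,
    },
    "sab": {
        "ta_slope": 46.6,
        "ta_intercept": 649.0,
        "winter_mix_rate": 0.0,
        "winter_mix_doy": None,
        "sst_mean": 24.0,
        "sst_amp": 4.0,
        "sss_mean": 36.2,
        "sss_amp": 0.3,
        "bloom_day": 75,
    },
}


@dataclass(frozen=True)
class ModelParams:
    """Box-model configuration.

    ``mld_m`` converts the per-area flux law to a per-volume DIC
    tendency; it is **not** constrained by the source analyses (default
    20 m) and materially sets the relaxation timescale.
    """

    ta_slope: float = 46.6  # umol kg-1 per salinity unit
    ta_intercept: float = 649.0  # umol kg-1
    pco2_atm: float = 395.0  # uatm, seasonally invariant
    mld_m: float = 20.0
    c_to_chl: float = 60.0  # g C per g Chl
    spinup_days: int = 180
    winter_mix_rate: float = 0.1  # mmol m-3 day-1
    winter_mix_doy: tuple[int, int] | None = (272, 61)
    options: ConstantOptions | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.mld_m <= 0.0:
            raise ValueError(f"mixed-layer depth must be positive (got {self.mld_m})")
        if self.spinup_days < 0:
            raise ValueError(f"spinup_days must be >= 0 (got {self.spinup_days})")

    @classmethod
    def for_region(cls, region: str, **overrides) -> "ModelParams":
        preset = REGION_PRESETS[region]
        kw = {
            "ta_slope": preset["ta_slope"],
            "ta_intercept": preset["ta_intercept"],
            "winter_mix_rate": preset["winter_mix_rate"],
            "winter_mix_doy": preset["winter_mix_doy"],
        }
        kw.update(overrides)
        return cls(**kw)


@dataclass(frozen=True)
class ForcingSeries:
    """Daily model drivers (equal-length, gap-free arrays).

    ncp: net community production, mmol C m-3 day-1, DIC **sink**
    positive.  vmix: vertical DIC supply, mmol C m-3 day-1, source
    positive.
    """

    day: np.ndarray
    sst: np.ndarray
    sss: np.ndarray
    wind: np.ndarray
    ncp: np.ndarray
    vmix: np.ndarray

    def __post_init__(self) -> None:
        arrays = {
            "day": self.day, "sst": self.sst, "sss": self.sss,
            "wind": self.wind, "ncp": self.ncp, "vmix": self.vmix,
        }
        n = len(self.day)
        for name, a in arrays.items():
            a = np.asarray(a, dtype=float)
            object.__setattr__(self, name, a)
            if len(a) != n:
                raise ValueError(f"forcing series {name!r} length {len(a)} != {n}")
            if np.any(~np.isfinite(a)):
                raise ValueError(f"forcing series {name!r} contains gaps/non-finite values")
        if np.any(self.wind < 0.0):
            raise ValueError("wind speeds must be non-negative")

    def __len__(self) -> int:
        return len(self.day)

    def row(self, i: int) -> dict[str, float]:
        return {
            "sst": float(self.sst[i]),
            "sss": float(self.sss[i]),
            "wind": float(self.wind[i]),
            "ncp": float(self.ncp[i]),
            "vmix": float(self.vmix[i]),
        }


@dataclass(frozen=True)
class Trajectory:
    """Daily model output (post-spin-up) plus run configuration.

    ``data`` columns: day, sst_c, sss, ta, dic, ph_total, pco2_uatm,
    omega_arag, co3_umol_kg, dic_eq, flux_airsea, flux_bio, flux_mix
    (flux_* are the DIC increments applied during that day,
    umol kg-1 day-1, so dic[t+1] - dic[t] = sum of the three).
    """

    data: pd.DataFrame
    params: ModelParams


def ta_from_salinity(S: float, params: ModelParams) -> float:
    """Linear TA(S) = slope * S + intercept, umol kg-1."""
    if np.any(np.asarray(S) <= 0.0):
        raise ValueError(f"salinity must be positive (got {S})")
    return params.ta_slope * S + params.ta_intercept


def chl_to_ncp(chl: np.ndarray, c_to_chl: float = 60.0) -> np.ndarray:
    """Convert a daily chlorophyll series to a daily NCP series.

    Day-over-day differences between consecutive valid observations are
    averaged in 7-day blocks, scaled by the C:Chl ratio and the molar
    mass of carbon, and linearly interpolated back to daily resolution.

    Parameters
    ----------
    chl:
        Daily chlorophyll, mg Chl m-3; NaN marks missing days.
    c_to_chl:
        Carbon-to-chlorophyll mass ratio, g g-1.

    Returns
    -------
    ncp, mmol C m-3 day-1, positive = biological DIC drawdown.
    """
    chl = np.asarray(chl, dtype=float)
    if chl.ndim != 1:
        raise ValueError("chl must be a 1-D daily series")
    if np.nanmin(chl, initial=0.0) < 0.0:
        raise ValueError("chlorophyll must be non-negative")
    n = len(chl)
    # per-day Chl change wherever two consecutive days are both valid
    dchl = np.full(n, np.nan)
    valid = np.isfinite(chl)
    pair = valid[1:] & valid[:-1]
    dchl[1:][pair] = np.diff(chl)[pair]

    n_weeks = int(np.ceil(n / 7))
    centers = np.empty(n_weeks)
    means = np.empty(n_weeks)
    n_empty = 0
    for w in range(n_weeks):
        block = dchl[7 * w : 7 * (w + 1)]
        centers[w] = 7 * w + (len(block) - 1) / 2.0
        if np.all(~np.isfinite(block)):
            means[w] = 0.0
            n_empty += 1
        else:
            means[w] = np.nanmean(block)
    if n_empty:
        log.warning("chl_to_ncp: %d week(s) with no valid Chl pairs set to zero NCP", n_empty)
    daily = np.interp(np.arange(n), centers, means)
    return daily * c_to_chl / MOLAR_MASS_C


def _gas_increment(
    state: CarbonateState, wind: float, dic_eq: float, params: ModelParams
) -> float:
    """Air-sea DIC increment for one day, umol kg-1 (positive = uptake).

    d(DIC)/dt = -0.24 k K0 (pCO2_sea - pCO2_atm) / mld; the seawater
    density cancels between the per-area flux and the per-mass state.
    The step is capped at the distance to equilibrium DIC.
    """
    k = compute_constants(state.T, state.S, params.options)
    ktr = gas_transfer_velocity(wind, schmidt_number(state.T, state.S))
    ddic = -0.24 * ktr * k.K0 * (state.pCO2 - params.pco2_atm) / params.mld_m
    gap = dic_eq - state.DIC
    if abs(ddic) > abs(gap):
        ddic = gap
    return ddic


def step(
    state: CarbonateState,
    forcing_day: dict[str, float],
    params: ModelParams,
    dic_eq: float | None = None,
) -> tuple[CarbonateState, dict[str, float]]:
    """Advance one day; returns the t_n+1 state and the DIC increments.

    The returned state is solved with T, S and TA at t_n and DIC at
    t_n+1.  ``dic_eq`` (equilibrium DIC under the t_n conditions) may be
    passed in to avoid re-solving it.
    """
    if dic_eq is None:
        dic_eq = solve_from_pco2_ta(
            params.pco2_atm, state.TA, state.T, state.S, options=params.options
        ).DIC
    d_gas = _gas_increment(state, forcing_day["wind"], dic_eq, params)
    d_bio = -forcing_day["ncp"] * 1000.0 / RHO_SW  # mmol m-3 -> umol kg-1, sink
    d_mix = forcing_day["vmix"] * 1000.0 / RHO_SW
    dic_next = state.DIC + d_gas + d_bio + d_mix
    next_state = solve_from_dic_ta(dic_next, state.TA, state.T, state.S, options=params.options)
    return next_state, {"airsea": d_gas, "bio": d_bio, "mix": d_mix}


def run(forcing: ForcingSeries, params: ModelParams | None = None) -> Trajectory:
    """Run spin-up plus the full forcing window; spin-up is discarded.

    The model is initialized at the first spin-up day with TA from
    salinity and DIC at equilibrium with atmospheric pCO2.  Spin-up
    re-uses the forcing cyclically, aligned so its last day leads into
    forcing day 0.
    """
    if params is None:
        params = ModelParams()
    n = len(forcing)
    if n == 0:
        raise ValueError("empty forcing series")
    if params.spinup_days > 0 and n < 1:
        raise ValueError("forcing too short for spin-up")
    # cyclic index sequence: spin-up wraps the forcing so that the last
    # spin-up day is forcing day n-1, then the reported window 0..n-1
    spin_idx = [(i - params.spinup_days) % n for i in range(params.spinup_days)]
    sched = [(i, False) for i in spin_idx] + [(i, True) for i in range(n)]

    i0 = sched[0][0]
    ta0 = ta_from_salinity(float(forcing.sss[i0]), params)
    state = solve_from_pco2_ta(
        params.pco2_atm, ta0, float(forcing.sst[i0]), float(forcing.sss[i0]),
        options=params.options,
    )
    dic = state.DIC

    records: list[dict[str, float]] = []
    for day_no, (i, report) in enumerate(sched):
        sst, sss = float(forcing.sst[i]), float(forcing.sss[i])
        ta = ta_from_salinity(sss, params)
        try:
            state = solve_from_dic_ta(dic, ta, sst, sss, options=params.options)
            dic_eq = solve_from_pco2_ta(
                params.pco2_atm, ta, sst, sss, options=params.options
            ).DIC
            _, incr = step(state, forcing.row(i), params, dic_eq=dic_eq)
        except ConvergenceError as exc:
            raise ConvergenceError(f"box model failed on day {day_no}: {exc}") from exc
        if report:
            records.append(
                {
                    "day": float(forcing.day[i]),
                    "sst_c": sst,
                    "sss": sss,
                    "ta": ta,
                    "dic": dic,
                    "ph_total": state.pH,
                    "pco2_uatm": state.pCO2,
                    "omega_arag": state.Omega_arag,
                    "co3_umol_kg": state.CO3,
                    "dic_eq": dic_eq,
                    "flux_airsea": incr["airsea"],
                    "flux_bio": incr["bio"],
                    "flux_mix": incr["mix"],
                }
            )
        dic = dic + incr["airsea"] + incr["bio"] + incr["mix"]
    return Trajectory(data=pd.DataFrame(records), params=params)


def efolding_experiment(
    params: ModelParams,
    dic_pulse: float,
    wind: float,
    T: float = 18.0,
    S: float = 35.0,
    horizon_days: int = 600,
    return_series: bool = False,
):
    """e-folding time (days) of an excess-pCO2 pulse relaxed by gas exchange.

    A steady box (pCO2 = atmosphere, no biology or mixing) receives a
    one-day DIC addition of ``dic_pulse`` umol kg-1; everything else is
    held constant.  Returns the (linearly interpolated) time at which
    the excess pCO2 first falls below 1/e of its initial value; with
    ``return_series=True``, returns ``(tau, excess_array)`` where the
    array holds the daily excess pCO2 from day 0 up to the crossing.

    Raises
    ------
    RelaxationError
        If the excess has not decayed to 1/e within ``horizon_days``
        (e.g. wind -> 0, the closed-system limit).
    """
    if dic_pulse <= 0.0:
        raise ValueError(f"dic_pulse must be positive (got {dic_pulse})")
    ta = ta_from_salinity(S, params)
    base = solve_from_pco2_ta(params.pco2_atm, ta, T, S, options=params.options)
    dic_eq = base.DIC
    dic = dic_eq + dic_pulse
    quiet = {"wind": wind, "ncp": 0.0, "vmix": 0.0}

    state = solve_from_dic_ta(dic, ta, T, S, options=params.options)
    excess0 = state.pCO2 - params.pco2_atm
    if excess0 <= 0.0:
        raise ValueError("DIC pulse produced no positive pCO2 excess")
    target = excess0 / np.e
    series = [excess0]
    prev_excess, prev_t = excess0, 0.0
    for t in range(1, horizon_days + 1):
        state, _ = step(state, quiet, params, dic_eq=dic_eq)
        excess = state.pCO2 - params.pco2_atm
        series.append(excess)
        if excess <= target:
            # linear interpolation between (t-1, prev) and (t, excess)
            frac = (prev_excess - target) / (prev_excess - excess)
            tau = prev_t + frac
            return (tau, np.asarray(series)) if return_series else tau
        if excess >= prev_excess and wind > 0.0:
            raise RelaxationError(f"excess pCO2 not decaying (day {t})")
        prev_excess, prev_t = excess, float(t)
    raise RelaxationError(
        f"excess pCO2 did not reach 1/e of its initial value within {horizon_days} days"
    )
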