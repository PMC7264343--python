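"""Open- vs closed-system temperature framework, critical pH, Revelle factor.

The two limiting thermal regimes of surface seawater:

* *closed system* — no gas exchange, DIC and TA held fixed while the
  thermodynamic constants shift with temperature;
* *open system* — complete equilibration, pCO2 pinned at the atmosphere
  while DIC adjusts.

``gas_exchange_term`` decomposes the open curve into the closed
(internal-equilibrium) part and the gas-exchange part relative to a
reference temperature:  term(T) = open(T) - closed(T) + open(T_ref).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from coastcarb.constants import ConstantOptions, compute_constants
from coastcarb.speciation import CarbonateState, solve_from_dic_ta, solve_from_pco2_ta
from coastcarb.speciation import ConvergenceError

__all__ = [
    "TemperatureCurve",
    "SPECIES",
    "closed_system_curve",
    "open_system_curve",
    "gas_exchange_term",
    "normalize_to_temperature",
    "critical_ph",
    "revelle_factor",
    "DEFAULT_T_GRID",
]

#: species tracked along every temperature curve
SPECIES = ("CO2aq", "pCO2", "H", "pH", "CO3", "Omega_arag", "DIC", "K0", "K1_over_K2")

DEFAULT_T_GRID = np.arange(0.0, 30.0 + 0.25, 0.5)


@dataclass(frozen=True)
class TemperatureCurve:
    """Per-species values along a strictly increasing temperature grid."""

    temperatures: np.ndarray
    values: dict[str, np.ndarray]
    regime: str

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, dtype=float)
        if t.ndim != 1 or t.size < 1:
            raise ValueError("temperature grid must be a 1-D array")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("temperature grid must be strictly increasing")
        for name in SPECIES:
            if name not in self.values:
                raise ValueError(f"curve missing species {name!r}")
            if len(self.values[name]) != t.size:
                raise ValueError(f"species {name!r} length mismatch with grid")

    def __getitem__(self, species: str) -> np.ndarray:
        return self.values[species]

    def at(self, T: float) -> dict[str, float]:
        """Species values at grid point ``T`` (exact match required)."""
        idx = np.flatnonzero(np.isclose(self.temperatures, T))
        if idx.size == 0:
            raise KeyError(f"temperature {T} not on the curve grid")
        i = int(idx[0])
        return {name: float(self.values[name][i]) for name in SPECIES}


def _row(state: CarbonateState, options: ConstantOptions | None) -> dict[str, float]:
    k = compute_constants(state.T, state.S, options)
    return {
        "CO2aq": state.CO2aq,
        "pCO2": state.pCO2,
        "H": 10.0**-state.pH * 1e9,  # nmol kg-1
        "pH": state.pH,
        "CO3": state.CO3,
        "Omega_arag": state.Omega_arag,
        "DIC": state.DIC,
        "K0": k.K0,
        "K1_over_K2": k.k1_over_k2,
    }


def _curve(rows: list[dict[str, float]], grid: np.ndarray, regime: str) -> TemperatureCurve:
    return TemperatureCurve(
        temperatures=np.asarray(grid, dtype=float),
        values={name: np.array([r[name] for r in rows]) for name in SPECIES},
        regime=regime,
    )


def closed_system_curve(
    ref: CarbonateState,
    T_grid=DEFAULT_T_GRID,
    options: ConstantOptions | None = None,
) -> TemperatureCurve:
    """Re-solve (DIC_ref, TA_ref) at every grid temperature (no gas exchange)."""
    rows = []
    for T in np.asarray(T_grid, dtype=float):
        try:
            st = solve_from_dic_ta(ref.DIC, ref.TA, float(T), ref.S, options=options)
        except ConvergenceError as exc:
            raise ConvergenceError(f"closed-system solve failed at T={T} degC: {exc}") from exc
        rows.append(_row(st, options))
    return _curve(rows, T_grid, "closed")


def open_system_curve(
    TA: float,
    S: float,
    pCO2_atm: float,
    T_grid=DEFAULT_T_GRID,
    options: ConstantOptions | None = None,
) -> TemperatureCurve:
    """Solve (pCO2_atm, TA) at every grid temperature (full equilibration)."""
    if TA <= 0.0 or pCO2_atm <= 0.0:
        raise ValueError("TA and pCO2_atm must be positive")
    rows = []
    for T in np.asarray(T_grid, dtype=float):
        try:
            st = solve_from_pco2_ta(pCO2_atm, TA, float(T), S, options=options)
        except ConvergenceError as exc:
            raise ConvergenceError(f"open-system solve failed at T={T} degC: {exc}") from exc
        rows.append(_row(st, options))
    return _curve(rows, T_grid, "open")


def gas_exchange_term(
    open_curve: TemperatureCurve,
    closed_curve: TemperatureCurve,
    ref_T: float,
) -> TemperatureCurve:
    """Per-species decomposition term(T) = open(T) - closed(T) + open(ref_T)."""
    if open_curve.temperatures.shape != closed_curve.temperatures.shape or not np.allclose(
        open_curve.temperatures, closed_curve.temperatures
    ):
        raise ValueError("open and closed curves are on different temperature grids")
    ref = open_curve.at(ref_T)
    values = {
        name: open_curve[name] - closed_curve[name] + ref[name] for name in SPECIES
    }
    return TemperatureCurve(
        temperatures=open_curve.temperatures.copy(), values=values, regime="gas_exchange"
    )


def normalize_to_temperature(
    state: CarbonateState,
    T_target: float,
    options: ConstantOptions | None = None,
) -> CarbonateState:
    """Closed-system normalization: re-solve (DIC, TA) at ``T_target``.

    DIC and TA are unchanged (no gas exchange); pH, pCO2, Omega shift
    with the constants.  The conventional use is T_target = 25 degC.
    """
    return solve_from_dic_ta(
        state.DIC, state.TA, T_target, state.S, PO4=state.PO4, SiO4=state.SiO4, options=options
    )


def critical_ph(T: float, S: float = 35.0, options: ConstantOptions | None = None) -> float:
    """pH at which [CO2aq] = [CO3--]: -0.5 log10(K1 K2), total scale.

    This is the acid-base state of maximal pH sensitivity to CO2
    addition (DIC/TA near 1).  Values assume S = 35 unless given.
    """
    k = compute_constants(T, S, options)
    return -0.5 * np.log10(k.K1 * k.K2)


def revelle_factor(
    state: CarbonateState,
    delta_dic: float = 1.0,
    options: ConstantOptions | None = None,
) -> float:
    """Revelle factor (dpCO2/pCO2)/(dDIC/DIC) at fixed T, S, TA.

    Estimated by a symmetric finite difference of +-``delta_dic``
    umol kg-1 around the solved state.
    """
    if not (0.0 < delta_dic <= 2.0):
        raise ValueError(f"delta_dic {delta_dic} outside (0, 2] umol kg-1")
    hi = solve_from_dic_ta(
        state.DIC + delta_dic, state.TA, state.T, state.S,
        PO4=state.PO4, SiO4=state.SiO4, options=options,
    )
    lo = solve_from_dic_ta(
        state.DIC - delta_dic, state.TA, state.T, state.S,
        PO4=state.PO4, SiO4=state.SiO4, options=options,
    )
    dpco2 = hi.pCO2 - lo.pCO2
    ddic = hi.DIC - lo.DIC
    return (dpco2 / state.pCO2) / (ddic / state.DIC)
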