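"""Synthetic cruise transects and seasonal forcing.

The generators emulate the *statistical structure* of coastal margin
surveys — meridional SST/SSS/TA gradients with labelled upwelling,
river-plume and bloom anomalies — and idealized seasonal forcing for a
cold northern (NWA) and a warm southern (SAB) mixed-layer box.  All
gradient amplitudes are emulation choices, configurable through the
keyword arguments; none are observational values.

Every generator is a pure function of its configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from coastcarb.airsea import equilibrium_state
from coastcarb.boxmodel import REGION_PRESETS, ForcingSeries, chl_to_ncp

__all__ = ["make_transect", "make_forcing", "TransectConfig"]

MARGINS = ("atlantic_gom", "ccs")
MODES = ("equilibrium", "perturbed")
LABELS = ("background", "upwelling", "river_plume", "bloom")


@dataclass(frozen=True)
class TransectConfig:
    """Gradient/noise amplitudes for :func:`make_transect` (emulation choices)."""

    ta_slope: float = 46.6
    ta_intercept: float = 649.0
    sigma_ta: float = 2.0  # umol kg-1 measurement noise
    sigma_dic: float = 2.0
    pco2_atm: float = 395.0
    # labelled process anomalies (perturbed mode)
    upwelling_dic: float = 60.0
    upwelling_sst: float = -3.0
    upwelling_no3: float = 12.0
    upwelling_do: float = -15.0
    bloom_dic: float = -30.0
    bloom_do: float = 15.0
    plume_sss: float = -3.0
    plume_dic: float = -25.0
    plume_do: float = 10.0


_MARGIN_GEOMETRY = {
    # lat range, SST south->north, SSS south->north, cruise tag, lon anchor
    "atlantic_gom": dict(
        lat=(25.0, 44.0), sst=(30.0, 5.0), sss=(36.5, 31.0),
        cruise="SYN-ATL", lon0=-80.0, lon_per_lat=0.55, date="2015-07-15",
        p_label={"upwelling": 0.05, "river_plume": 0.10, "bloom": 0.10},
    ),
    "ccs": dict(
        lat=(32.0, 48.0), sst=(16.0, 11.0), sss=(33.6, 32.4),
        cruise="SYN-CCS", lon0=-118.0, lon_per_lat=-0.45, date="2016-06-01",
        p_label={"upwelling": 0.25, "river_plume": 0.05, "bloom": 0.12},
    ),
}


def make_transect(
    margin: str,
    n: int,
    mode: str = "equilibrium",
    seed: int = 0,
    config: TransectConfig | None = None,
) -> pd.DataFrame:
    """Generate a cruise-like bottle table (the bottle-CSV schema).

    ``equilibrium`` mode sets DIC exactly to the equilibrium value for
    each sample's (TA, SST, SSS) at the configured atmospheric pCO2, so
    downstream deviations vanish by construction (DIC measurement noise
    is therefore *not* applied in this mode).  ``perturbed`` mode
    injects labelled upwelling / river-plume / bloom anomalies and
    Gaussian measurement noise.
    """
    if margin not in MARGINS:
        raise ValueError(f"unknown margin {margin!r}; expected one of {MARGINS}")
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    if n < 3:
        raise ValueError(f"need at least 3 samples (got {n})")
    cfg = config or TransectConfig()
    geo = _MARGIN_GEOMETRY[margin]
    rng = np.random.default_rng(seed)

    lat = np.linspace(geo["lat"][0], geo["lat"][1], n) + rng.normal(0.0, 0.05, n)
    frac = (lat - geo["lat"][0]) / (geo["lat"][1] - geo["lat"][0])
    sst = geo["sst"][0] + (geo["sst"][1] - geo["sst"][0]) * frac + rng.normal(0.0, 0.3, n)
    sss = geo["sss"][0] + (geo["sss"][1] - geo["sss"][0]) * frac + rng.normal(0.0, 0.1, n)
    lon = geo["lon0"] + geo["lon_per_lat"] * (lat - geo["lat"][0])

    do_pct = np.full(n, 100.0) + rng.normal(0.0, 2.0, n)
    no3 = np.clip(rng.normal(2.0, 0.8, n), 0.0, None)
    po4 = np.clip(rng.normal(0.3, 0.1, n), 0.0, None)
    sio4 = np.clip(rng.normal(3.0, 1.0, n), 0.0, None)

    labels = np.array(["background"] * n, dtype=object)
    dic_anom = np.zeros(n)
    if mode == "perturbed":
        p = geo["p_label"]
        u = rng.uniform(size=n)
        up = u < p["upwelling"]
        plume = (~up) & (u < p["upwelling"] + p["river_plume"])
        bloom = (~up) & (~plume) & (u < p["upwelling"] + p["river_plume"] + p["bloom"])
        labels[up], labels[plume], labels[bloom] = "upwelling", "river_plume", "bloom"
        sst[up] += cfg.upwelling_sst
        no3[up] += cfg.upwelling_no3
        do_pct[up] += cfg.upwelling_do
        dic_anom[up] += cfg.upwelling_dic
        sss[plume] += cfg.plume_sss
        do_pct[plume] += cfg.plume_do
        dic_anom[plume] += cfg.plume_dic
        do_pct[bloom] += cfg.bloom_do
        dic_anom[bloom] += cfg.bloom_dic

    ta = cfg.ta_slope * sss + cfg.ta_intercept + rng.normal(0.0, cfg.sigma_ta, n)
    dic = np.empty(n)
    for i in range(n):
        dic[i] = equilibrium_state(ta[i], sst[i], sss[i], cfg.pco2_atm).DIC
    if mode == "perturbed":
        dic += dic_anom + rng.normal(0.0, cfg.sigma_dic, n)

    return pd.DataFrame(
        {
            "cruise": geo["cruise"],
            "station": np.arange(1, n + 1),
            "date_iso": geo["date"],
            "lat_degn": lat,
            "lon_dege": lon,
            "sst_c": sst,
            "sss": sss,
            "ta_umol_kg": ta,
            "dic_umol_kg": dic,
            "do_percent": do_pct,
            "no3_umol_kg": no3,
            "po4_umol_kg": po4,
            "sio4_umol_kg": sio4,
            "label": labels,
        }
    )


def _doy(i: int) -> int:
    return i % 365 + 1


def make_forcing(
    region: str,
    year_days: int = 365,
    seed: int = 0,
    noise_sst: float = 0.0,
    noise_sss: float = 0.0,
    chl_background: float = 0.5,
    chl_bloom_amp: float = 0.6,
    chl_bloom_sigma: float = 18.0,
    c_to_chl: float = 60.0,
) -> tuple[ForcingSeries, pd.DataFrame]:
    """Idealized daily forcing plus the chlorophyll series it derives from.

    SST follows a sinusoid (minimum in mid-February), SSS peaks in
    winter with a summer minimum, winds sit at 7 m s-1 in summer and
    10.5 m s-1 in winter with 15-day linear ramps, chlorophyll carries
    a Gaussian spring bloom, and the NWA preset adds 0.1 mmol m-3 day-1
    of DIC on exactly the 155-day late-September-to-early-March window.
    Optional Gaussian noise on SST/SSS is seeded and reproducible.
    """
    if region not in REGION_PRESETS:
        raise ValueError(f"unknown region {region!r}; expected one of {tuple(REGION_PRESETS)}")
    if year_days < 365:
        raise ValueError(f"year_days must cover at least one year (got {year_days})")
    preset = REGION_PRESETS[region]
    rng = np.random.default_rng(seed)
    day = np.arange(year_days)
    doy = np.array([_doy(i) for i in day])

    phase = 2.0 * np.pi * (doy - 45) / 365.0
    sst = preset["sst_mean"] - preset["sst_amp"] * np.cos(phase)
    sss = preset["sss_mean"] + preset["sss_amp"] * np.cos(phase)
    if noise_sst > 0.0:
        sst = sst + rng.normal(0.0, noise_sst, year_days)
    if noise_sss > 0.0:
        sss = sss + rng.normal(0.0, noise_sss, year_days)

    wind = _seasonal_wind(doy)

    chl = chl_background + chl_bloom_amp * np.exp(
        -0.5 * ((doy - preset["bloom_day"]) / chl_bloom_sigma) ** 2
    )
    ncp = chl_to_ncp(chl, c_to_chl=c_to_chl)

    vmix = np.zeros(year_days)
    if preset["winter_mix_doy"] is not None and preset["winter_mix_rate"] > 0.0:
        lo, hi = preset["winter_mix_doy"]
        vmix[(doy >= lo) | (doy <= hi)] = preset["winter_mix_rate"]

    forcing = ForcingSeries(day=day.astype(float), sst=sst, sss=sss, wind=wind, ncp=ncp, vmix=vmix)
    chl_table = pd.DataFrame({"day": day, "chl_mg_m3": chl})
    return forcing, chl_table


def _seasonal_wind(doy: np.ndarray) -> np.ndarray:
    """7 m s-1 summer / 10.5 m s-1 winter with 15-day linear ramps.

    Winter spans day-of-year >= 274 or < 91; ramps run over the 15 days
    following each transition (doy 91..105 down, 274..288 up).
    """
    w = np.where((doy >= 274) | (doy < 91), 10.5, 7.0).astype(float)
    down = (doy >= 91) & (doy < 91 + 15)
    w[down] = 10.5 + (7.0 - 10.5) * (doy[down] - 91 + 1) / 15.0
    up = (doy >= 274) & (doy < 274 + 15)
    w[up] = 7.0 + (10.5 - 7.0) * (doy[up] - 274 + 1) / 15.0
    return w
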