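import numpy as np
import pytest
from scipy import stats

from coastcarb import (
    chl_to_ncp,
    efolding_experiment,
    run,
    solve_from_dic_ta,
    solve_from_pco2_ta,
    step,
    ta_from_salinity,
)
from coastcarb.boxmodel import (
    ForcingSeries,
    ModelParams,
    RelaxationError,
)

PARAMS = ModelParams()


class TestTAFromSalinity:
    def test_default_anchor(self):
        assert ta_from_salinity(35.0, PARAMS) == pytest.approx(2280.0, abs=1e-9)

    def test_strictly_increasing(self):
        sals = np.arange(20.0, 38.0, 0.5)
        tas = [ta_from_salinity(s, PARAMS) for s in sals]
        assert np.all(np.diff(tas) > 0.0)

    def test_region_presets_share_anchor(self):
        for region in ("nwa", "sab"):
            p = ModelParams.for_region(region)
            assert ta_from_salinity(35.0, p) == pytest.approx(2280.0)

    def test_guard(self):
        with pytest.raises(ValueError):
            ta_from_salinity(-1.0, PARAMS)


class TestChlToNCP:
    def test_constant_chl_zero_ncp(self):
        assert np.allclose(chl_to_ncp(np.full(70, 0.8)), 0.0)

    def test_steady_bloom_unit_conversion(self):
        # Chl rising 0.1 mg m-3 day-1 -> NCP = 0.1 * 60 / 12.011
        chl = 0.1 * np.arange(35, dtype=float)
        ncp = chl_to_ncp(chl, c_to_chl=60.0)
        assert ncp[10] == pytest.approx(0.1 * 60.0 / 12.011, rel=1e-9)
        assert ncp[10] == pytest.approx(0.5, rel=5e-3)

    def test_all_gap_weeks_zero_with_warning(self, caplog):
        chl = np.full(21, np.nan)
        chl[:7] = 1.0
        with caplog.at_level("WARNING"):
            ncp = chl_to_ncp(chl)
        assert np.allclose(ncp[14:], 0.0)
        assert any("no valid Chl pairs" in r.message for r in caplog.records)

    def test_negative_chl_rejected(self):
        with pytest.raises(ValueError):
            chl_to_ncp(np.array([0.5, -0.1, 0.5]))


class TestStep:
    def _steady(self):
        return solve_from_pco2_ta(395.0, 2280.0, 18.0, 35.0)

    def test_quiescent_day_is_steady(self):
        st = self._steady()
        nxt, incr = step(st, {"wind": 7.0, "ncp": 0.0, "vmix": 0.0}, PARAMS)
        assert incr["airsea"] == pytest.approx(0.0, abs=1e-9)
        assert nxt.DIC == pytest.approx(st.DIC, abs=1e-6)

    def test_zero_wind_no_gas_exchange(self):
        st = solve_from_dic_ta(2100.0, 2280.0, 18.0, 35.0)  # supersaturated
        _, incr = step(st, {"wind": 0.0, "ncp": 0.0, "vmix": 0.0}, PARAMS)
        assert incr["airsea"] == 0.0

    def test_supersaturated_outgasses(self):
        st = solve_from_dic_ta(2100.0, 2280.0, 18.0, 35.0)
        nxt, incr = step(st, {"wind": 7.0, "ncp": 0.0, "vmix": 0.0}, PARAMS)
        assert incr["airsea"] < 0.0
        assert nxt.DIC < st.DIC

    def test_bio_and_mixing_signs(self):
        st = self._steady()
        _, incr = step(st, {"wind": 0.0, "ncp": 0.2, "vmix": 0.1}, PARAMS)
        assert incr["bio"] < 0.0  # NCP is a DIC sink
        assert incr["mix"] > 0.0
        # mmol m-3 -> umol kg-1 via the fixed density
        assert incr["mix"] == pytest.approx(0.1 * 1000.0 / 1025.0)


class TestRun:
    def test_budget_closure_exact(self, nwa_trajectory):
        d = nwa_trajectory.data
        lhs = np.diff(d["dic"].to_numpy())
        rhs = (d["flux_airsea"] + d["flux_bio"] + d["flux_mix"]).to_numpy()[:-1]
        assert np.max(np.abs(lhs - rhs)) < 1e-10

    def test_ta_tracks_salinity_only(self, nwa_trajectory):
        d = nwa_trajectory.data
        p = nwa_trajectory.params
        expected = p.ta_slope * d["sss"] + p.ta_intercept
        assert np.array_equal(d["ta"].to_numpy(), expected.to_numpy())

    def test_spinup_discarded(self, nwa_forcing, nwa_trajectory):
        forcing, _ = nwa_forcing
        assert len(nwa_trajectory.data) == len(forcing)

    def test_winter_dic_max_omega_min(self, nwa_trajectory):
        d = nwa_trajectory.data
        doy = d["day"].to_numpy() % 365 + 1
        cold_window = (doy >= 335) | (doy <= 90)
        lagged_cold = (doy >= 335) | (doy <= 135)  # + the 1-2 month exchange lag
        assert cold_window[int(d["dic"].idxmax())]
        assert lagged_cold[int(d["omega_arag"].idxmin())]
        # winter-vs-summer contrast
        summer = (doy >= 182) & (doy <= 273)
        assert d.loc[cold_window, "dic"].mean() > d.loc[summer, "dic"].mean()

    def test_spring_to_summer_pco2_up_ph_down(self, nwa_trajectory):
        d = nwa_trajectory.data.set_index(nwa_trajectory.data["day"] % 365 + 1)
        spring = d.loc[92:120]
        summer = d.loc[182:212]
        assert summer["pco2_uatm"].mean() > spring["pco2_uatm"].mean()
        assert summer["ph_total"].mean() < spring["ph_total"].mean()

    def test_dic_lags_equilibrium_by_one_to_two_months(self, nwa_trajectory):
        d = nwa_trajectory.data
        x = d["dic"].to_numpy() - d["dic"].mean()
        y = d["dic_eq"].to_numpy() - d["dic_eq"].mean()
        lags = np.arange(0, 120)
        cc = [np.corrcoef(x[l:], y[: len(y) - l])[0, 1] for l in lags]
        peak = int(lags[int(np.argmax(cc))])
        assert 30 <= peak <= 60

    def test_instantaneous_limit_converges_to_dic_eq(self, nwa_forcing):
        forcing, _ = nwa_forcing
        fast = ForcingSeries(
            day=forcing.day, sst=forcing.sst, sss=forcing.sss,
            wind=forcing.wind * 100.0, ncp=forcing.ncp, vmix=forcing.vmix,
        )
        d = run(fast, ModelParams.for_region("nwa")).data
        assert np.abs(d["dic"] - d["dic_eq"]).max() < 2.0

    def test_sab_contrast(self, nwa_trajectory, sab_trajectory):
        dn, ds = nwa_trajectory.data, sab_trajectory.data
        assert np.all(
            (ds["dic"] / ds["ta"]).to_numpy() < (dn["dic"] / dn["ta"]).to_numpy()
        )
        assert np.all(ds["omega_arag"].to_numpy() > dn["omega_arag"].to_numpy())

    def test_empty_forcing_rejected(self):
        with pytest.raises(ValueError):
            run(
                ForcingSeries(
                    day=np.array([]), sst=np.array([]), sss=np.array([]),
                    wind=np.array([]), ncp=np.array([]), vmix=np.array([]),
                )
            )


class TestForcingValidation:
    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            ForcingSeries(
                day=np.arange(3.0), sst=np.zeros(3), sss=np.full(3, 33.0),
                wind=np.zeros(2), ncp=np.zeros(3), vmix=np.zeros(3),
            )

    def test_gap_rejected(self):
        with pytest.raises(ValueError, match="gaps"):
            ForcingSeries(
                day=np.arange(3.0), sst=np.array([5.0, np.nan, 5.0]), sss=np.full(3, 33.0),
                wind=np.zeros(3), ncp=np.zeros(3), vmix=np.zeros(3),
            )

    def test_negative_wind_rejected(self):
        with pytest.raises(ValueError, match="wind"):
            ForcingSeries(
                day=np.arange(3.0), sst=np.full(3, 5.0), sss=np.full(3, 33.0),
                wind=np.array([1.0, -1.0, 1.0]), ncp=np.zeros(3), vmix=np.zeros(3),
            )


class TestEfolding:
    def test_tau_decreases_with_wind(self):
        taus = [efolding_experiment(PARAMS, 20.0, w) for w in (5.0, 7.0, 10.0, 14.0)]
        assert np.all(np.diff(taus) < 0.0)

    def test_closed_system_limit(self):
        with pytest.raises(RelaxationError):
            efolding_experiment(PARAMS, 20.0, 0.0, horizon_days=200)

    def test_small_pulse_single_exponential(self):
        tau, series = efolding_experiment(PARAMS, 5.0, 7.0, return_series=True)
        t = np.arange(len(series))
        fit = stats.linregress(t, np.log(series))
        assert fit.rvalue**2 > 0.99
        assert -1.0 / fit.slope == pytest.approx(tau, rel=0.1)

    def test_mld_doubling_doubles_tau(self):
        t20 = efolding_experiment(ModelParams(mld_m=20.0), 10.0, 7.0)
        t40 = efolding_experiment(ModelParams(mld_m=40.0), 10.0, 7.0)
        assert t40 / t20 == pytest.approx(2.0, rel=0.15)

    def test_guard(self):
        with pytest.raises(ValueError):
            efolding_experiment(PARAMS, -5.0, 7.0)
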