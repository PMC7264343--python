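# coastcarb

Surface-ocean carbonate chemistry along ocean margins: a seawater
CO₂-system speciation solver (total pH scale), the open- vs
closed-system temperature framework, Revelle-factor buffer analysis,
atmospheric-equilibrium predictions with observation deviations, and a
daily mixed-layer box model with air–sea gas exchange, biological
production and vertical mixing — plus synthetic cruise/forcing
generators so the full pipeline runs with no external data.

## Library quick start

```python
import coastcarb as cc

# speciate from the (pCO2, TA) pair — the open-system reference parcel
st = cc.solve_from_pco2_ta(pCO2=395, TA=2280, T=18, S=35)
st.DIC          # 2038.6 umol/kg
st.Omega_arag   # aragonite saturation state

cc.critical_ph(3.0)          # pH where [CO2aq]=[CO3--]: 7.705 at 3 degC
cc.revelle_factor(st)        # buffer factor by central finite difference

# open/closed temperature curves and the gas-exchange decomposition
open_c  = cc.open_system_curve(2280, 35, 395)
closed_c = cc.closed_system_curve(st)
term = cc.gas_exchange_term(open_c, closed_c, ref_T=18.0)

# mixed-layer box model, cold northern preset
forcing, chl = cc.make_forcing("nwa", year_days=365, seed=1)
traj = cc.run(forcing, cc.ModelParams.for_region("nwa"))
traj.data[["day", "dic", "dic_eq", "pco2_uatm", "omega_arag"]]
```

### Conventions and defaults

* Units: µmol kg⁻¹ (TA, DIC, ions), µatm (pCO₂), total-scale pH,
  surface pressure only.
* Carbonic-acid constants: Mehrbach refit (Dickson & Millero 1987);
  borate, boric-acid, water, aragonite-solubility and calcium
  formulations follow the conventional CO2SYS defaults (see
  `coastcarb.constants`; borate and the fugacity handling are
  swappable via `ConstantOptions`).
* Henry's law is applied through the CO₂ fugacity coefficient by
  default (`ConstantOptions(fugacity=False)` disables it).
* The critical-pH values quoted above assume S = 35.
* Box model: explicit daily steps; TA diagnosed from salinity only;
  atmospheric pCO₂ 395 µatm, seasonally invariant; mixed-layer depth
  `mld_m` defaults to 20 m — it is an assumption, not an observed
  value, and it directly sets the air–sea relaxation timescale.
* Gas-transfer velocity k = 0.251 W² (Sc/660)^−0.5 (cm h⁻¹); flux
  0.24·k·K₀·ΔpCO₂ with a fixed 1025 kg m⁻³ density for per-mass ↔
  per-volume conversion.

## Command line

```bash
coastcarb solve --dic 2038.6 --ta 2280 --temp 18 --sal 35
coastcarb tempcurves --out curves.csv
coastcarb synth --seed 1 --margin ccs --mode perturbed --n 100 --transect-out bottles.csv
coastcarb equil bottles.csv --atm-pco2 395 --out deviations.csv
coastcarb boxmodel --region nwa --days 365 --seed 1 --out trajectory.csv
```

`synth` output follows the bottle-CSV schema (`cruise, station,
date_iso, lat_degn, lon_dege, sst_c, sss, ta_umol_kg, dic_umol_kg,
do_percent, no3_umol_kg, po4_umol_kg, sio4_umol_kg, label`); `equil`
reads the same schema.  Numeric CSV output is fixed to 6 significant
digits, so re-runs with the same seed are byte-identical.

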