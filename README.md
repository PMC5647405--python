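# trophicast

Temperature-forced food-web simulation and forecasting for shelf-sea
ecosystems. `trophicast` balances a steady-state mass-balance food web,
perturbs it through time with foraging-arena consumption dynamics, modulates
each group's consumption by a species-specific thermal niche, fits
vulnerability and primary-production parameters to observed time series by
AIC-ranked stepwise search, quantifies parameter uncertainty with Monte Carlo
envelopes, and projects the fitted system under combined fishing and climate
(RCP-style warming) scenarios.

## The scientific problem

Fisheries management targets (e.g. fishing at F_MSY) are usually derived from
single-stock models that ignore both trophic interactions and ocean warming.
This package implements the multispecies alternative: a mass-balanced food
web whose dynamics respond to temperature through per-species thermal
tolerance envelopes, so that the biomass and catch consequences of a harvest
policy can be evaluated *jointly* with a warming trajectory. The core
questions it answers are: how well can vulnerability (top-down vs bottom-up
control) and primary-production anomalies be recovered from noisy survey
series, how wide are the resulting uncertainty envelopes, and in which
direction do biomass and catch move under combined fishing/warming futures?

## Model summary

- **Mass balance** (`trophicast.foodweb`): for each group,
  `B·PB·EE = Σ_j Q_ij + Y_i`; exactly one of {B, EE} may be unknown per
  group. Unbalanced solutions (EE outside [0, 1]) are flagged, not rejected.
- **Consumption** (`trophicast.dynamics`): foraging-arena functional
  response per predator–prey link,
  `Q = env·a·v·B·P·T_i·T_j·M / (v + v·T_i·M + a·M·P·T_j/D)`,
  integrated with fixed-step RK4 (monthly by default, numba-compiled).
  Search rates are calibrated so the baseline reproduces the balanced
  consumption exactly; producers follow a calibrated logistic, detritus is a
  passive pool.
- **Thermal niches** (`trophicast.thermal`): two-sided Gaussian response,
  equal to 1 exactly at the optimum; niches are built from tolerance
  envelopes (t_min, p10, p90, t_max) and can be aggregated across species
  with weighted geometric means.
- **Fitting** (`trophicast.fitting`): log-scale sum of squares, AIC/AICc,
  Akaike weights; stepwise search over the number of fitted vulnerabilities
  and primary-production spline anomaly points with warm-started restarts.
- **Uncertainty & validation** (`trophicast.uncertainty`): pedigree-driven
  Monte Carlo re-balancing with rejection of infeasible draws; percentile
  envelopes; chronological fit/holdout splits (A/B/C = last 7/5/3 years) and
  RMSD skill tables.
- **Scenarios** (`trophicast.scenarios`): deep-water temperature from SST,
  mirrored AMO projection, RCP anomaly builders with seeded interannual
  variability, fishing step/ramp policies, cumulative-change summaries, and a
  shipped F_status-quo/F_MSY reference table.
- **Synthetic data** (`trophicast.synthetic`): seeded generators for
  balanced webs (3/6/12 groups), temperature series, thermal niches, planted
  vulnerability/anomaly truths, and lognormal observation noise — used by the
  test suite and the `synth` CLI command.

## Worked example (CLI)

Generate a synthetic study, balance it, fit it, and project a scenario. All
output below is real.

```text
$ trophicast synth --out model --seed 7
synthetic model written to model

$ trophicast balance model --out run
model balanced

$ trophicast fit model --out run --seed 7
best configuration: fishing + 1 Vs + 3 PP_anomaly (AIC -1068.93)
```

`run/fit_report.csv` ranks every configuration (the synthetic truth plants
one strong top-down link and a 3-point production anomaly, and the search
recovers exactly that structure as the Akaike-best model):

```text
                         name  parameters        ss  ss_reduction_pct          aic  akaike_weight
fishing + 1 Vs + 3 PP_anomaly           4  2.236198         96.525867 -1068.934737   1.000000e+00
       fishing + 3 PP_anomaly           3  7.929833         87.680298  -777.256440   4.601110e-64
               fishing + 1 Vs           1 58.066475          9.788563  -319.354545  1.701098e-163
                      fishing           0 62.438364          2.996444  -304.513334  1.018595e-166
                     baseline           0 64.367088          0.000000  -297.455303  2.987924e-168
```

The fitted vulnerability is well above the neutral value 2 (the planted truth
is strongly top-down): `run/fit_best.yaml` contains
`vulnerabilities: {predator: 30.63}`.

```text
$ trophicast mc model --fit-params run/fit_best.yaml --trials 50 --seed 7 --out run
accepted 50/50 trials

$ trophicast validate model --fit-params run/fit_best.yaml --scheme A --out run
holdout pooled RMSD: 1.3332

$ cat > scenario.yaml <<EOF
name: msy
f:
  predator: 0.05
start_year: 2014
end_year: 2050
EOF

$ trophicast project model --scenario scenario.yaml --fit-params run/fit_best.yaml --out run
scenario msy: cumulative biomass change 1%, catch change -13%
```

(A negative catch "decrease" means catch increases: fishing the predator at
the lower rate lets its biomass, and therefore the sustainable yield, rise.)
`trophicast report run` collates fit, RMSD, and cumulative-change tables.

## Worked example (Python API)

```pycon
>>> from trophicast.thermal import build_niche
>>> niche = build_niche(t_min=5.0, p10=10.8, p90=16.8, t_max=22.0)
>>> niche.t_opt, niche.sigma_lower, niche.sigma_upper
(13.8, 4.4, 4.1)
>>> niche.response(13.8)
1.0
>>> round(niche.response(10.5), 4)
0.7548
```

## Reproduction

The acceptance target is the defining identity of the thermal niche — the
response at the optimum temperature:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
# {"t1": {"value": 1.0, "n": 1}}
```

The value is exactly 1.0 for any seed; the comparison is exact equality.
`tests/test_acceptance.py` holds one test per acceptance criterion
(equilibrium preservation, the consumption-rate oracle, the thermal
calibration oracle, planted-truth recovery over 20 seeds, Monte Carlo
envelope behaviour, validation splits, scenario direction properties, and
the printed-number targets). See `docs/methods.md` for model details,
parameter defaults, and design decisions.
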