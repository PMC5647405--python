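# Methods

This note documents the model equations, parameter conventions, numerical
choices, and deliberate design decisions implemented in `trophicast`.

## 1. Mass balance (`trophicast.foodweb`)

For every group *i* the steady-state production budget is

```
B_i · PB_i · EE_i = Σ_j Q_ij + Y_i
```

with `B` biomass (t·km⁻²), `PB` production/biomass (yr⁻¹), `EE` ecotrophic
efficiency, `Q_ij = B_j · QB_j · DC_ij` the consumption of *i* by predator
*j*, and `Y_i` the fishery catch (t·km⁻²·yr⁻¹). Exactly one of {B, EE} may be
unknown per group; unknown biomasses are solved by linear elimination in
trophic order (circular dependencies among unknowns are detected and
reported). After solving, EE is always recomputed from the master equation.
A solution with any EE outside [0, 1] is returned with `balanced=False` and a
per-group diagnosis rather than raised — unbalanced inputs are a modelling
state, not a programming error. Producers use `QB = 0`; detritus receives
unassimilated consumption (default assimilation 0.8) plus non-predation
deaths and loses mass through a calibrated export term. Multi-stanza pairs
are linked by a first-order maturation flow `k · B_juvenile`.

## 2. Foraging-arena dynamics (`trophicast.dynamics`)

Per-link consumption:

```
Q_ij = env · a_ij · v_ij · B_i · P_j · T_i · T_j · M_ij
       ─────────────────────────────────────────────────
       v_ij + v_ij · T_i · M_ij + a_ij · M_ij · P_j · T_j / D_j
```

where `B_i` prey biomass, `P_j` predator *pool* biomass (the predator's own
biomass by default; a `literal_prey_pool` switch uses the prey-side pool
instead), `T` thermal responses, `M` mediation (1), `D_j` handling time, and
`env` an external forcing multiplier (e.g. the primary-production anomaly on
producer links). The numerator is *not* divided by `D`; this is the algebra
that reproduces the hand-checkable values 0.8, 8/9, and 1.0 (see the
acceptance tests).

**Vulnerability convention.** With `D = ∞` and all responses at 1 the
equation degenerates to `Q = a·B·P/2` — `v` cancels and cannot be fitted.
The package therefore defaults to a finite handling time `D = 1 yr` and a
*multiplier* vulnerability scaling: a user-facing `v ∈ (1, ∞)` (2 = mixed
control, large = top-down) is converted to a flow rate
`v_rate = v · Q⁰/B⁰_prey` before entering the equation. A `"rate"` mode
passes raw values for hand calculations. Search rates are calibrated per
link in closed form, `a = 2·v_rate·Q⁰ / (pool⁰·(v_rate·B⁰ − Q⁰/D))`, so the
balanced consumption is reproduced exactly at baseline; an infeasible link
(denominator ≤ 0) raises an error naming the link and the minimum feasible v.

Producers follow a logistic `dB/dt = r·B·(1 − B/K) − predation − catch` with
`K = 10·B⁰` and `r = PB/(1 − 1/10)` so the baseline is an exact equilibrium.
Detritus is a passive pool with a calibrated export closure.

Integration is fixed-step classical RK4, 12 steps per year by default
(`SimOptions.steps_per_year`), compiled with numba. Reported outputs are
annual mean biomass and accumulated catch. `run(..., start_biomass=...)`
restarts from an arbitrary state; splicing a hindcast into a projection is
bit-exact when forcings agree (verified in the tests).

## 3. Thermal niches (`trophicast.thermal`)

Two-sided Gaussian response:

```
T(t) = exp(−(t − t_opt)² / (2·σ²)),   σ = σ_lower if t < t_opt else σ_upper
```

so `T(t_opt) = 1` exactly. `build_niche(t_min, p10, p90, t_max)` sets
`t_opt = (p10 + p90)/2` and `σ = (edge distance)/2` on each side with a
0.5 °C floor. Niches aggregate across species by biomass-weighted geometric
means of the (positively shifted) envelope parameters; juvenile stanzas get a
+1 °C optimum offset. A plankton fallback uses the mean of the local
temperature series with σ = 10 °C (effectively eurythermal).

## 4. Fitting (`trophicast.fitting`)

Objective: `SS = Σ w·(ln obs − ln pred)²` over all observed biomass/catch
series. `AIC = n·ln(SS/n) + 2k`; AICc adds the small-sample correction;
Akaike weights are normalised relative likelihoods. Free parameters:
per-predator vulnerabilities (fitted as `v = 1 + exp(θ)` so v > 1 always)
and a primary-production anomaly spline (PCHIP in log space, `k` = number of
knots). `k_params = n_vulnerabilities + n_spline_points`.

`stepwise_fit` evaluates a nested ladder (baseline → fishing → fishing +
anomaly → fishing + Vs + anomaly). Vulnerable predators are chosen by a
*conditioned greedy*: a preliminary anomaly-only fit absorbs the
production signal, then predators are ranked by their marginal SS reduction
conditional on that anomaly, and each richer configuration is warm-started
from the previous optimum (Nelder–Mead with restarts). With the default test
configuration (`max_v=1, spline_counts=(0,3), n_restarts=2, fatol=1e-7`),
the planted truth is recovered in 20/20 synthetic seeds (v > 2 classification
and anomaly correlation ≈ 1.0).

## 5. Uncertainty and validation (`trophicast.uncertainty`)

Monte Carlo: per-group pedigree CVs (0–0.8) drive uniform ±CV draws of B,
PB, QB and EE; each draw is re-balanced and rejected if infeasible
(EE ∉ [0, 1] or negative solved biomass). PB draws are capped at CV 0.1 by
default (production ratios are usually the best-known inputs, and wide PB
perturbation destabilises the producer closure). If more than
`max_draw_factor` (50) draws per accepted trial are needed the run aborts
with a RuntimeError rather than silently returning a biased envelope.
Envelopes are 5/50/95 percentiles of annual biomass and catch across
accepted trials. With CV = 0 every draw equals the baseline and the envelope
collapses exactly.

Validation: chronological splits A/B/C hold out the last 7/5/3 years
(requiring a span of ≥ 29 years; explicit holdout year lists are also
accepted). RMSD is computed on the natural scale per series, with a pooled
row equal to the root of the mean of all pooled squared deviations.

## 6. Scenarios (`trophicast.scenarios`)

- `dit_from_sst`: deep-water temperature as SST − 0.61 °C (or a
  multiplicative factor).
- `mirror_amo`: reflects a smoothed AMO series about a pivot year (2012) and
  wraps at the 62-year recurrence, so projected minima repeat with ~62-year
  spacing.
- `build_future_temperature`: last historical temperature + RCP anomaly
  (anchored at 0 in the first projection year) + seeded interannual
  variability (scaled by the window-smoothed rolling SD of detrended
  historical residuals) + optional AMO deviation. The composition is exactly
  additive.
- `rcp_anomaly`: end-of-century warming totals 1.0/1.8/2.2/3.7 °C for labels
  2.6/4.5/6.5/8.5, linear or convex shape.
- `project`: runs a scenario with step-change fishing mortalities or a
  geometric ramp (`f_ramp_per_year`), splicing from a hindcast end state.
- `cumulative_change(initial, final)` returns the rounded percent decrease
  (15.8 → 13.5 gives 15; 3.04 → 2.42 gives 20); negative values mean an
  increase.
- A reference table of status-quo vs MSY fishing mortalities for 11 shelf
  species ships with the package (`load_fmsy_table`).

## 7. Synthetic generator (`trophicast.synthetic`)

Seeded presets for 3-, 6-, and 12-group balanced webs; a 29-year (1985–2013)
temperature series (trend + oscillation + noise in a 7–12 °C shelf band);
niches with boreal/eurythermal contrast; a planted truth (one strong
top-down link, v = 50; a 3-knot production anomaly; a 1.5× fishing ramp);
and multiplicative lognormal observation noise with unit mean. The generator
exists to exercise the estimation machinery — it is not a calibrated model of
any real system, and its parameters are fixed independently of the tests that
consume it.

## 8. Numerical and design decisions

- RK4 at 12 steps/yr; halving the step changes annual means by < 1e-3
  (the annual-mean quadrature is the dominant O(dt²) term).
- All randomness flows from explicit integer seeds < 2³¹ through
  `numpy.random.default_rng`; identical seeds give byte-identical CLI output.
- Errors in user-supplied files raise `InputError` naming the file (and line
  where applicable); the CLI exits 2 for user errors and 1 for internal ones,
  and writes a `manifest_<command>.json` (command, version, seed, config
  hash, outputs) per command so runs are auditable.
- Known limitations: no spatial structure; mediation is fixed at 1; the
  producer carrying-capacity multiplier (10×) is a closure assumption;
  pedigree draws are uniform, not triangular/beta; fitting assumes lognormal
  observation error with known relative weights.
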