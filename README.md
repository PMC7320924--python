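# stagemap

Small-area disease mapping of **early- and late-stage cancer incidence**,
for cancer epidemiologists and registry analysts who want to monitor
inequalities in early detection.

Evaluating early detection through the *proportion* of cases diagnosed
late is treacherous: rising early-stage incidence (better awareness, or
overdiagnosis) lowers the late-stage proportion without any change in
late-stage risk, and deprivation comparisons on proportions can look
dramatic when the real difference lies in early-stage incidence.
`stagemap` instead maps *stage-specific incidences* at small-area
resolution and keeps the proportion-based analysis alongside, so the
contrast between the two readings is explicit.

## What it computes

For case data (area, sex, 5-year age band 30–34…90+, year, stage
I / II / III–IV) and stratified person-years:

* **Direct age standardisation** of yearly stage-specific rates
  (European Standard Population 2013 weights, user-overridable).
* **Indirectly standardised incidence ratios** per small area:
  SIR_i = O_i / E_i with expected counts from the sex–age rates of a
  comparison population (whole region, or one urban subarea).
* **Besag–York–Mollié smoothing** by MCMC:
  O_i ~ Poisson(E_i θ_i), log θ_i = α + u_i + v_i, u ~ ICAR(τ_u)
  (sum-to-zero), v_i ~ N(0, τ_v⁻¹), Gamma priors on the precisions —
  yielding smoothed SIRs θ̂_i, credible intervals, the posterior
  probability PP_i = Pr(θ_i > 1 | data), the structured variance share,
  and DIC. A zero-inflated Poisson variant supports model choice.
* **Signal classification** of PP into five map colours
  (red > 0.90 ≥ light red > 0.80 ≥ yellow > 0.20 ≥ light green > 0.10 ≥
  green) and cross-stage concordance summaries.
* **Deprivation regressions**: weighted ecological regression of
  ln θ̂_i on income-quintile (inverse-variance weights, with optional
  posterior-propagated intervals), and case-level logistic regression of
  late-stage odds on age, sex and quintile.
* **Kulldorff spatial scan** (purely spatial Poisson likelihood-ratio
  scan with Monte Carlo inference) as a sensitivity cross-check of the
  PP signals.
* A **synthetic-data module** that generates lattice geographies,
  populations and stage-specific cases with exactly the generative
  structure the smoother assumes, so the whole pipeline is testable
  without registry access.

The scientific conventions, sampler details, validation scenarios and
known limitations are documented in [docs/methods.md](docs/methods.md).

## Worked example

```python
import numpy as np
import stagemap as sm

# Published stage-count table: late-stage proportions by deprivation
counts = sm.load_cmm_stage_counts("region_quintile")
print(sm.stage_proportions_from_counts(counts, "II-IV")[
    ["I", "II", "III-IV", "total", "prop_late"]].round(2))
```

```
          I   II  III-IV  total  prop_late
level
Q1      973  418     110   1501       0.35
Q2     1362  490     139   1991       0.32
Q3     1457  469     159   2085       0.30
Q4     1574  447     140   2161       0.27
Q5     1936  449     179   2564       0.24
```

The late-stage proportion falls from 0.35 in the poorest fifth of areas
to 0.24 in the wealthiest — at face value a strong deprivation gradient
in late diagnosis. The incidence-based pipeline shows what actually
drives such gradients:

```python
geo = sm.generate_geography(10, 10, income_spatial_trend=1.0, seed=1)
pop = sm.generate_population(geo, mean_area_pop=1600, n_years=9, seed=2)
params = sm.RiskModelParams(
    quintile_log_effects={"I": np.array([0, .1, .1, .17, .3]),   # early stage
                          "II": np.zeros(5), "III-IV": np.zeros(5)},
    seed=3)
cases = sm.simulate_cases(pop, geo, params)
print(f"{len(cases)} simulated cases over {geo.n_areas} areas")

O = sm.observed_counts(cases, "I", geo.area_ids)
E = sm.expected_counts(cases, pop, geo.area_ids, "I", areas=geo.area_ids)
sir = sm.compute_sir(O, E, stage="I")
fit = sm.BYMSmoother(n_iter=6000, burn_in=3000, thin=3, n_chains=2,
                     random_state=4).fit(sir[["O", "E"]], geo)
print(f"smoothed SIR range: {fit.theta_.min():.2f}-{fit.theta_.max():.2f}, "
      f"structured variance fraction: {fit.variance_fraction_:.2f}")

signals = sm.classify_signals(fit.pp_)
print(signals["class"].value_counts().to_dict())

reg = sm.ecological_regression(fit.theta_, fit.var_log_sir_,
                               geo.areas["quintile"])
print(reg.summary_table().round(2))
```

```
454 simulated cases over 100 areas
smoothed SIR range: 0.50-2.11, structured variance fraction: 0.98
{'strong_lowered': 37, 'neutral': 31, 'strong_elevated': 13,
 'moderate_elevated': 10, 'moderate_lowered': 9}
          estimate  ci_low  ci_high
quintile
Q1            1.00    1.00     1.00
Q2            0.99    0.77     1.28
Q3            1.02    0.79     1.31
Q4            1.19    0.93     1.53
Q5            1.23    0.95     1.60
```

Here the simulation planted the deprivation gradient in *stage I*
(early) incidence only: wealthier areas have up to exp(0.3) ≈ 1.35-fold
higher early-stage incidence and identical late-stage incidence. The
ecological regression on smoothed stage-I SIRs recovers that rising
trend (1.00 → 1.23 across quintiles); a proportion-based analysis of the
same data would have flagged the *poorest* areas as having the worst
late-stage burden. The signal map classifies 13 areas as strong
elevated-incidence signals (PP > 0.90) and 37 as strong lowered signals.

## Command line

Each pipeline stage is a subcommand (`stagemap simulate | standardise |
smooth | classify | ecoreg | caseor | scan`), and `stagemap run --config
cfg.yaml` executes the whole pipeline — ingest/simulate, standardise,
smooth per stage, classify, concordance, regressions, scan — writing
CSV/GeoJSON artifacts plus a JSON run manifest. All randomness is
controlled by a single seed; reruns are byte-identical.

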