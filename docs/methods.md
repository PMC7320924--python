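# Methods

`stagemap` implements "cancer stage mapping": monitoring inequalities in
early cancer detection through small-area, stage-specific *incidences*
rather than through the proportion of cases diagnosed late. The package
covers the whole workflow — synthetic registry-like data, direct and
indirect age standardisation, Bayesian spatial smoothing, signal
classification, deprivation regressions, and a spatial-scan sensitivity
check — so every stage is testable without access to confidential
registry data.

## Why incidence, not case proportions

The conventional measure, the proportion of cases with a late-stage
tumour, conflates the numerator of interest (late-stage incidence) with
early-stage incidence in its denominator. A population whose early-stage
incidence rises (e.g. through higher awareness or overdiagnosis) shows a
falling late-stage *proportion* with no change in late-stage *risk*; in
deprivation comparisons the same artefact makes deprived areas look
dramatically worse on proportions even when their late-stage incidence
is ordinary. The package keeps the case-level logistic analysis
(`LateStageLogistic`) precisely so this caveat can be demonstrated next
to the incidence-based maps.

## Data model

Cases carry (area, sex, 5-year age band 30–34 … 90+, diagnosis year,
stage I / II / III–IV). Melanoma staging follows the clinical rule:
nodal or distant spread → III–IV; Breslow thickness ≤ 1.0 mm, or
1.1–2.0 mm without ulceration → I; 1.1–2.0 mm with ulceration, or
> 2.0 mm → II. Localised records without a positive thickness are
unstageable and are excluded with a tally by the readers.

Populations are person-years per (area, sex, age band, year). Geography
is a set of small areas (emulating units of ~600–2,600 residents) with
an adjacency graph, centroids, and median household income; deprivation
is quintiles of *areas* by income (Q1 poorest), computed separately per
analysis scope (whole region, or one urban subarea), with ties broken by
area id and group boundaries at ranks ⌈k·n/5⌉.

## Standardisation

* Direct (time trends): rate = 10⁵ · Σ_a w_a r_a / Σ_a w_a per year and
  stage, with age-specific rates r_a pooled over sex (a by-sex option
  exists). Default weights are the 2013 European Standard Population
  restricted to the thirteen adult bands (7000 ×4, 6500, 6000, 5500,
  5000, 4000, 2500, 1500, 800, 200), renormalised; any non-negative
  weight vector can be supplied.
* Indirect (mapping): reference rates per (sex, age band) come from the
  comparison population pooled over the study years — the whole region
  for regional maps, the urban subarea for local maps. E_i sums each
  area's person-years against those rates; SIR_i = O_i / E_i. Internal
  comparison therefore calibrates exactly: Σ E_i = Σ O_i. Areas with
  E = 0 and O = 0 carry an undefined SIR and are dropped from smoothing
  input with a warning; E = 0 with O > 0 is a data error.

## BYM smoothing

For one stage, O_i ~ Poisson(E_i·θ_i), log θ_i = α + u_i + v_i, with u
an intrinsic CAR (ICAR) field on the adjacency graph (precision τ_u) and
v i.i.d. Gaussian noise (precision τ_v). Priors: α ~ N(0, 100²)
(effectively flat); τ_u, τ_v ~ Gamma(0.5, 0.0005) — a concrete rendering
of "minimally informative" precision priors, configurable via
`PriorSpec`; the test-suite's robustness harness shows the smoothed SIRs
move by < 5% under Gamma(1, 0.01) or Gamma(0.1, 0.001) on a fixture with
E = 20 per area.

Sampling is Metropolis-within-Gibbs: conjugate Gamma updates for the
precisions (the ICAR quadratic form has rank n − 1 on a connected
graph); adaptive random-walk Metropolis for α and, vectorised over graph
colour classes (v over all sites at once), for the fields, targeting
~35% single-site acceptance with Robbins–Monro adaptation frozen after
burn-in. The ICAR level is fixed by recentring u to mean zero after
every sweep and transferring the mean into α, which leaves the
likelihood untouched. Defaults: 4 chains × 20,000 iterations, 10,000
burn-in, thinning 5; a split-chain convergence statistic above 1.1
triggers a warning. Areas without neighbours have u pinned at 0 (with a
warning) or raise, per `island_policy`; graphs that are disconnected
beyond such islands are rejected because the ICAR level is not
identified across components.

Summaries: θ̂_i is the posterior mean by default (median available);
PP_i = Pr(θ_i > 1 | data) is the fraction of retained draws above 1;
95% credible intervals are percentile-based; `variance_fraction` is the
posterior mean of var(u)/(var(u)+var(v)) with empirical variances across
areas within each draw (the "structured share"); DIC = D̄ + pD with
pD = D̄ − D(θ̄) evaluated at the posterior-mean θ (and posterior-mean
mixing weight for the zero-inflated model).

The zero-inflated alternative replaces the likelihood by
π·δ₀ + (1−π)·Poisson(E_i θ_i) with one global π ~ Beta(1, 1), sampled by
data augmentation of structural-zero indicators. With no zeros in the
data the posterior of π collapses towards 0 and the fit reduces to the
plain model.

### Correctness anchor

On toy graphs the same hierarchy is integrated numerically
(`stagemap.validation.bym_reference_posterior`): a wide quadrature grid
over (log τ_u, log τ_v), and at each node Laplace + multivariate-t
importance sampling of the log-concave conditional over (α, sum-to-zero
coordinates of u, v). Grid and sampler share no code; on a 4-area path
with O = (12, 6, 11, 9), E = 10 the MCMC posterior means agree with the
reference within 2% relative (measured ~0.3%).

## Signals

PP is banded into five classes: > 0.90 red (strong elevated);
0.90 ≥ PP > 0.80 light red (moderate elevated); 0.80 ≥ PP > 0.20 yellow;
0.20 ≥ PP > 0.10 light green; ≤ 0.10 green — boundaries belong to the
lower class. The upper cut-offs follow published simulation work on
exceedance-probability signalling; the lower ones mirror them (no
two-sided optimality study exists). Cross-stage concordance counts, for
the areas signalling in stage A (PP beyond the moderate cut-off, a
configurable choice), the share whose stage-B smoothed SIR lies on the
same side of 1.

## Deprivation regressions

* Ecological: weighted least squares of ln θ̂_i on quintile indicators
  (Q1 reference), weights = inverse posterior variances of ln θ_i.
  exp(β) are ratios between average-level incidences with Wald 95% CIs.
  These Wald intervals treat θ̂_i as fixed data; because the smoothed
  SIRs carry correlated posterior uncertainty the Wald widths understate
  the real uncertainty of the contrast. `propagate_draws` therefore
  refits the WLS on each retained posterior draw of log θ and combines
  results by Rubin's rules (within + between variance, t quantiles) —
  the interval we recommend, and the one whose frequentist calibration
  the acceptance suite measures.
* Case-level: logistic regression (statsmodels GLM-Binomial, i.e. IRLS)
  of late-stage odds on age band, sex and quintile; reference levels age
  30–34, female, Q5. Two late definitions (II–IV, III–IV). Suspected
  quasi-complete separation (enormous standard errors) raises with
  advice rather than returning garbage.

Where a stage shows no elevated/lowered signals the ecological output
still reports estimates, alongside a flag saying whether any signals
exist, rather than suppressing rows.

## Spatial scan

The classical purely spatial Poisson scan: circular windows grown over
centroid-distance-ordered neighbours up to half the total expected count
(configurable), conditional Poisson LLR, Monte Carlo p-value
(1 + #{null max-LLR ≥ observed}) / (n_sim + 1) under multinomial
redistribution of the total count. Secondary clusters are greedily
non-overlapping; their p-values are conservative (compared against the
null maximum). `compare_signal_sets` reports the Jaccard overlap of the
top cluster with the red + light-red signal set.

## Synthetic data: what it emulates, and what it does not

The generator mirrors the smoothing model: stratum counts are Poisson
with intensity person_years · baseline(sex, age, stage) ·
exp(α + quintile effect + u_i + v_i), the ICAR field drawn exactly (eigen
decomposition of the Laplacian restricted to its row space). Defaults
encode the study conditions: lattice geographies of ~2,000 areas with
rook adjacency; area-year totals inside 600–2,600 (mean 1,600); 9 years;
a fixed adult age pyramid with an even sex split; stage baselines 20 / 5
/ 2 per 100,000 person-years with log-linear age slopes (steeper for
later stages, so the late-stage share rises with age); log-normal
incomes (median 220, σ = 0.2) with an optional west–east log-income
gradient and an optional autocorrelated "patchiness" component.

Not emulated: true administrative boundaries, migration, registry
linkage artefacts, tumour biology, spatio-temporal trends, or
stage-misclassification. Passing tests therefore demonstrate the
*machinery* (standardisation identities, sampler correctness, estimator
calibration under the stated generative model), not the epidemiology of
any real region.

`simulate_cases(balance_fields_on=...)` recentres the nuisance fields
within label groups (e.g. deprivation quintiles). Effect-recovery
experiments use it so that the nominal quintile effects are exactly the
area-level estimand; without balancing, each replicate's realised
contrast includes a random field imbalance that no area-level method can
separate from deprivation — the package's own diagnostics show intervals
covering the realised contrast well before covering the nominal one.

## Validation scenarios (problem sizes used)

Chosen so the full suite runs comfortably on one CPU:

* Sampler vs numerical reference: 4 areas, E = 10 (2% tolerance).
* Effect recovery: 20 replicates of a 20×10 lattice, income gradient
  2.0, τ_u = 20, τ_v = 400, E ≈ 10/area, quintile log-effects
  (0, .1, .1, .17, .3); mean recovered ratios within 20% relative and
  propagated-interval coverage ≥ 80%.
* Signal calibration: 10×10 lattice, E = 20; null red fraction < 10%
  across 20 replicates; a planted RR = 2 block reaches PP > 0.80 in
  ≥ 50% of its areas.
* Model choice: 10×10 lattice, E = 2 (no zero inflation); Poisson DIC ≤
  zero-inflated DIC in ≥ 80% of 10 replicates.
* Scan: planted RR = 3 disc on a 10×10 lattice with E = 5; p ≤ 0.01 and
  ≥ 70% overlap; 20 null replicates with p > 0.05 in ≥ 18.

## Numerical conventions and degenerate inputs

Quintile ties break by ascending area id. Empty strata contribute rate 0
to direct standardisation with a logged warning; cases in an empty
stratum are an error. SIRs with E = O = 0 are missing, excluded from
smoothing with a warning. All-zero count vectors fit with a warning
(prior-dominated posterior). Posterior probabilities outside [0, 1],
non-monotone cut-offs, fewer than 19 scan simulations, fewer than 100
retained draws for PP, and scan windows above half the expected total
are rejected. Identical seeds give identical retained draws, byte-
identical pipeline CSVs, and identical scan results.

## Known limitations

* Single global α per stage; no covariates inside the BYM model, no
  spatio-temporal smoothing.
* Shrinkage attenuates area-level contrasts at small E; the ecological
  regression inherits this (visible as recovered Q5 ratios slightly
  below truth in the validation scenario). Plain Wald intervals on the
  ecological regression are anti-conservative; use the posterior-
  propagated intervals.
* The scan's Monte Carlo p-values for secondary clusters are
  conservative by construction.
* DIC discrimination between Poisson and zero-inflated likelihoods is
  weak on datasets where both fit (margins of order 1); the reported
  preference percentage is genuinely stochastic across seeds.
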