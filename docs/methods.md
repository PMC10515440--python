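# Methods

## Risk model

Population average risk treats an individual's tolerance (the dose at which
an adverse effect appears) and exposure as independent lognormals. On the
log10 dose scale both are normal — tolerance N(μ_tox, σ_tox), exposure
N(μ_exp, σ_exp) — and the probability that a random individual's exposure
exceeds their tolerance is

    R = Φ((μ_exp − μ_tox) / √(σ_exp² + σ_tox²)).

All locations and spreads live on the log10 scale; "lognormal with
parameters (μ, u)" is implemented as normal(μ, u) on log10(dose), because
mitigation and the regulatory action manipulate μ_exp by log10 amounts.
A proportionate cut of *k*% in mean exposure shifts μ_exp by
log10(1 − k/100); *k* = 100 is treated as a special case with risk exactly
0, since the shift is −∞. Exposure locations are derived from (ED50,
population median risk) rather than taken from a printed median exposure,
which is treated as a rounded display of the same quantity.

Uncertainty is supported on the two location parameters only, as
independent normals. Uncertainty on the spreads σ_tox, σ_exp is explicitly
not implemented (a toxicity test does not narrow inter-individual
variability); requesting it raises `NotImplementedError`. Because risk is a
probit of μ_exp − μ_tox, normal location uncertainty folds into the same
closed form — uncertainty variances add to variability variances inside the
probit — and every percentile or expectation used anywhere in the package
reduces to one dimension in that location difference.

## Uncertainty, tests, and conjugate updating

Uncertainty magnitudes are quoted in orders of magnitude (OM): the central
99.975% range of the distribution measured in factors of 10. That range
spans 7.325 standard deviations of a normal, so OM / 7.325 gives the log10
sd. Conversions are kept at full precision everywhere (7/7.325 = 0.9556…,
4/7.325 = 0.5461…, 2/7.325 = 0.2730…); two-decimal displays such as 0.96 or
0.55 are rounding, not inputs.

A test is specified by the posterior width it *achieves*, not by a fixed
observation noise: the noise sd is back-derived per prior by inverting the
conjugate update, σ_S = (u′⁻² − u₀⁻²)^(−1/2). Under this reading the
preposterior distribution of the posterior mean is N(prior center,
√(u₀² − u′²)) — information moves the mean exactly as much as it shrinks
the spread (law of total variance) — and the preposterior decision
probabilities take closed forms that match the reported per-test values; a
fixed-σ_S reading does not. A test nominally wider than the prior raises
`InfeasibleTestError` rather than clamping; an exactly-as-wide test is
legal and worthless.

## Costs and timing

Years are integers 1..y_TH with discount factor (1+r)^−(y−1). Health costs
at the unmitigated risk accrue from year 1. Controls, and the health
savings they buy, begin in year

    t_test + t_DM + t_imp + impl_year_offset,

with `impl_year_offset = 1` by default: implementation completes during
year t_test + t_DM + t_imp, and the first *controlled* year is the next
one. This start-year convention is the one the packaged illustrative
scenarios are calibrated under; the alternative reading (offset 0, the
implementation year itself already controlled) is exposed as a
configuration switch because benefit-risk dollar values are sensitive to it
(roughly 10–25% on EVDSI-type metrics in scenario 1). t_DM defaults to 0;
the preset tests fold evaluation time into their durations.

The control-cost curve ramps exponentially from the fixed overhead ACC_F at
k = 0 to ACC_max at k = 100:

    ACC_k = ACC_F + (ACC_max − ACC_F) · (10^(ηk/100) − 1) / (10^η − 1).

The exponent applies to the *fraction* k/100, the only reading under which
the curve spans [ACC_F, ACC_max]. η = 0 is accepted and evaluates the
linear limit of the ramp, which the steepness sensitivity sweep exercises;
η = 0 yields the highest control cost at interior k, consistent with the
curve family being ordered in η. Population is constant over the horizon,
and implementation time is independent of the mitigation level.

## Decision rules

The target-risk decision maker (TRDM) compares the lower/upper percentiles
(defaults 5th/95th, with the percentile z kept at full precision rather
than 1.645) of the risk uncertainty distribution against the target risk
level; between them it is undecided, and when it regulates it applies a
fixed 90% exposure cut. Control costs never enter its valuation, which is
pure expected total health cost. After a test in the mixed-uncertainty
scenario, the percentile band combines residual exposure uncertainty with
the reduced toxicity uncertainty as independent normals.

The benefit-risk decision maker (BRDM) minimises expected total social cost
over an integer percent grid 0..100 (matching the integer optima the
analysis reports; finer grids are configurable). Ties resolve toward the
smaller mitigation level — least intervention — a convention that the
analysis itself never exercises but that makes the argmin well defined.

## Numerical evaluation

Expectations over one normal variable with a continuous integrand (the
BRDM's grid minimum is continuous and piecewise smooth in the conditional
mean) use Gauss–Hermite quadrature, 64 nodes by default. TRDM expectations
contain a jump at the regulate threshold, where fixed-node quadrature
converges slowly; they are instead computed exactly as bivariate-normal
probabilities, E[Φ((m+α)/s)·1{m>τ}] being a Φ₂ evaluation. A seeded
Monte-Carlo twin of every preposterior integral (default 10⁵ draws) is kept
as a verification path and exercised in the test suite (agreement within
3 standard errors); quadrature mode is the default and seed-free, so
reports are bitwise reproducible.

BRDM preposterior decision probabilities need the measure of the region
where the optimal mitigation is positive; the optimal-policy switch points
are located by a 257-point quantile scan plus bisection, and exact normal
masses are summed between them.

Delayed-perfect-information values (behind the CoD_PI / CoD_PPI report
fields) are evaluated at the longest test duration in the configuration —
the natural bound when comparing the slowest actual strategy against
perfection — and at 0 when no tests are configured.

## Scenario presets

The six presets (`fatal-s1` … `acute-s3`) encode the two illustrative
applications: 350M people, 20-year horizon, 5% discount rate, 2-year
implementation, ACC_max $2.2B/yr with η = 2, ED50 = 50 mg/kg-bw/day,
σ_tox = 0.697, σ_exp = 0.5, Test A (4 OM, 1 y, $0.005M) and Test B (2 OM,
5 y, $5M). The fatal outcome uses V = $8.8M, B_y = 1/80, TRL = 10⁻⁷,
median lifetime risk 10⁻⁸; the acute outcome V = $50, B_y = 365,
TRL = 10⁻⁵, median daily risk 10⁻⁶. Scenarios place prior uncertainty of
7 OM (s1) or 5 OM (s2) on μ_tox, and s3 splits 7 OM of combined
uncertainty into 5 OM on μ_tox plus √24 OM on μ_exp (widths add in
quadrature). Acute and fatal share one code path and differ only in
(V, B_y, TRL, median risk).

These scenarios are deliberately stylised: a single chemical, a single
endpoint, independent parameters, constant population, known control costs,
and lognormal shapes throughout. Passing tests therefore demonstrate the
machinery — closed forms, conjugate preposterior analysis, discounted
optimisation — under those assumptions, not the behaviour of real testing
programmes, where correlated priors, non-lognormal dose response,
portfolio effects across chemicals, and uncertain control costs all matter.

## Known limitations

* Deep-tail quantities (regulate probabilities of order 0.1% and the
  health-cost values they dominate) are sensitive to whether OM conversions
  are rounded before use; with full-precision conversions some small
  reported per-test health-cost values in the narrower-prior scenarios
  differ from two-decimal-rounded evaluations by tens of percent, while all
  headline quantities agree to better than 1%.
* No non-conjugate updating, no uncertainty on spreads or control costs,
  no subgroup structure, no multi-endpoint or multi-chemical aggregation.
* ROI is undefined (NaN, with a warning) for zero-cost tests; ENBS is still
  reported.
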