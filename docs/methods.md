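# Methods

## The model

The thermal summation law states that an insect reared at constant
temperature T completes development after time D once it has accumulated a
fixed thermal budget of k = D(T − t0) degree-days above its lower
developmental threshold t0. Classical practice estimates a single (k, t0)
pair per species — by OLS of the development rate 1/D on T (the linear
degree-day model), or by the Ikemoto–Takai linearization DT = t0·D + k
fitted with reduced major axis (RMA) regression — and treats k as a
constant. Real rearing datasets, however, mix subgroups (large vs small
individuals, regular results vs outliers) and show substantial individual
variation in k.

`thermomix` models the thermal budget as a random variable K distributed
as a finite mixture of Weibull distributions with component-specific
thresholds. Conditional on component l (weight w_l) and on the rearing
temperature T, the development time D has density

    f(d | T, l) = f_W(d·(T − t0_l); κ_l, λ_l) · (T − t0_l),

where f_W is the Weibull density with shape κ_l and scale λ_l and the
(T − t0_l) factor is the Jacobian of the change of variables k ↦ d.
Temperature is treated as a fixed covariate: under the assumed
independence of the temperature design from the component structure, T
carries no information about the K-parameters, so conditioning on it loses
nothing while keeping the likelihood simple. Individuals that died before
the landmark stage never enter the data; no censoring model is applied.

Two kinds of interval follow from a fitted mixture and must not be
confused:

* **Interval estimate for realizations of K** — the central equal-tailed
  quantile range [Q((1−γ)/2), Q((1+γ)/2)] of the mixture (or of one
  component). It brackets the stated fraction γ of actual cases and does
  not shrink as n grows. This is the quantity of forensic interest: age
  intervals for casework derive from it.
* **Confidence interval for E[K]** — obtained by a parametric bootstrap
  (refit on datasets simulated from the point fit, percentile interval of
  the replicate mixture means Σ w_l λ_l Γ(1+1/κ_l)). It shrinks as
  1/√n and measures estimator precision only.

The ±1.96·SE interval often attached to Ikemoto–Takai estimates is of the
second kind pressed into service as the first; its empirical coverage of
individual cases is therefore far below nominal and degrades further with
sample size. The evaluation module measures exactly this.

## Fitting

The mixture is fitted by EM:

* **E-step** — responsibilities r_il ∝ w_l f(d_i | T_i, l), computed in
  log space with log-sum-exp normalization; rows sum to one to machine
  precision.
* **M-step** — weights are the mean responsibilities (sum to one by
  construction). Each component maximizes its weighted log-likelihood by
  profiling the threshold: for fixed t0 the weighted Weibull MLE reduces
  to a one-dimensional score equation in κ, solved by bracketed root
  finding on κ ∈ [0.5, 200] (powers taken in log space so large shapes
  stay finite), with λ in closed form; a bounded scalar search then
  maximizes over t0. If the inner optimizer's result scores below the
  previous iterate's parameters under the current responsibilities, the
  previous parameters are kept — making every iteration a guaranteed
  generalized-EM ascent step, which the tests assert to 1e−9.
* **Initialization** — a provisional t0 from the degree-day fit (clamped
  into bounds) converts records to provisional k values; quantile slices
  of k define L groups whose method-of-moments Weibull parameters seed the
  components. Restarts beyond the first jitter the provisional t0
  uniformly within ±2 °C and perturb the slice boundaries, all driven by
  the single configured seed.
* **Safeguards** — t0 is constrained to [min(T) − 30 °C, min(T) − 0.5 °C]
  (the model needs T > t0 strictly; fitted thresholds for both studied
  species sit 3–5 °C below the coldest viable rearing temperature, so the
  0.5 °C margin is inactive at the optimum). A restart aborts if any
  component weight falls below 1/n. Densities are floored at 1e−300 in
  log space.

Defaults: 2 components (the finding for both studied species; BIC
selection over L with p = 4L − 1 free parameters is available), 10
restarts, absolute log-likelihood tolerance 1e−8, 500 iterations max.
Components are reported sorted by expected K ascending, which gives
stable labels.

## Interval computation

Component-scope k-intervals use the closed-form Weibull quantile
λ(−ln(1−p))^(1/κ). Combined-scope intervals invert the mixture CDF by
bracketed bisection on [0, 10·λ_max] (the CDF is strictly monotone, so the
bracket is guaranteed; tolerance 1e−9). Equal-tailed central quantiles are
used rather than highest-density regions: the published interval
endpoints for both species are reproduced exactly by the 2.5%/97.5%
mixture quantiles, confirming the choice.

Age intervals at temperature T: for a single component, divide its
k-quantiles by (T − t0_l). For the combined scope the components carry
*different* thresholds, so the development-time mixture CDF
F_D(d | T) = Σ w_l F_W(d(T − t0_l)) is inverted directly by bisection
(tolerance 1e−6 days); dividing combined k-quantiles by any single
(T − t0) is not equivalent and is not done. Reference tables in the field
often print a single t0 next to a combined-population interval; since no
single threshold describes a combined interval here, the interval table
carries per-component thresholds in an annotation column instead.

## Labeling rules

With two fitted components, records are hard-assigned by maximum
responsibility and two rule families run in order:

1. if the weight ratio max(w)/min(w) ≥ 3 and neither body length
   (two-sided Mann–Whitney U; exact null for combined n ≤ 20, tie-corrected
   normal approximation otherwise) nor sex ratio (2×2 chi-squared, no
   continuity correction) differs at α = 0.05, the dominant component is
   the *regular* population and the minor one collects *outliers*;
2. otherwise, if the length difference is significant, the component with
   the smaller mean length is the *small-insect* population;
3. otherwise both components stay *unlabeled*.

The dominance ratio 3.0 quantifies "substantially larger": the two studied
species have weight ratios ≈ 6.7 (fires) and ≈ 1.44 (does not). Records
missing length are dropped pairwise from the U-test; weight (mg) is never
used for labeling since only lengths are published per component. The
"w/o outliers" analysis keeps the mixture fitted on all records and uses
the regular component's own quantiles, evaluated on regular-assigned
records only — excluding outliers from fitting as well would change the
component parameters, which the published intervals show was not done.

## Synthetic data

The generator draws, per individual: a component from the mixture weights;
a temperature uniformly from the rearing design (real per-temperature
cohort sizes are unpublished); K ~ Weibull(κ_l, λ_l); D = K/(T − t0_l);
body length ~ Normal(mean_l, 0.8 mm) truncated at zero; sex ~
Bernoulli(0.5). Two presets carry the published fitted parameters,
component mean lengths and rearing designs of the studied species
(Creophilus maxillosus: weights 0.87/0.13, seven viable temperatures
15–30 °C; Necrodes littoralis: weights 0.41/0.59, ten temperatures
14–30 °C). The length SD and sex ratio are not published; 0.8 mm and 0.5
are package defaults chosen so the labeling rules are exercised
realistically (the length SD makes the published 0.8 mm mean-length gap
of N. littoralis strongly significant at n ≈ 10³, and any gap of that
order detectable, without making components trivially separable).

What the generator does not emulate: mortality and censoring, unequal
per-temperature cohort sizes, any correlation between size and K within a
component, or measurement error in temperature. Passing tests therefore
demonstrate correctness of the estimation machinery under the model's own
assumptions, not robustness to real-data features outside them.

## Numerical and testing choices

* Simulation sizes in the test suite mirror the study scale where it
  matters (n = 2000 for parameter recovery, matching the larger dataset's
  order of magnitude; 10,000 fresh records for coverage checks) and are
  scaled down for repeated-fit properties (BIC selection checks at
  n = 500, bootstrap CIs at n ≤ 1000 with ≤ 40 replicates, EM-ascent
  checks on 100 instances of n = 60).
* Parameter recovery at n = 2000 is demanding for the N. littoralis-style
  preset because its components overlap heavily (mean K 381 vs 409
  degree-days, SDs ≈ 33): the weight estimate has sampling SD ≈ 0.03, so
  a ±0.05 recovery band holds for most but not all seeds (8/10 in a
  survey). The fitted solution is the true ML optimum in the failing
  seeds as well — EM started from the generator truth converges to the
  same, higher-likelihood, point.
* The SE-based baseline interval is expected to under-cover even on
  homogeneous single-population data (coverage ≈ 0.07 at n = 2000, since
  its width shrinks as 1/√n while the population spread does not); the
  divergence between the methods is therefore not a mixture artifact but
  a category difference between confidence intervals and interval
  estimates.
* RMA standard errors use the large-sample approximations
  se_b = |b|√((1−r²)/n), se_a = √(s_y²(1−r²)/n + x̄²·se_b²); OLS fitting
  and SEs are available behind a flag. The Ikemoto–Takai fit runs on all
  individual records by default (per-temperature median aggregation is
  provided for comparison with common published practice but is not the
  default). No Kelvin conversion anywhere; DT uses °C as the
  linearization is written.
* Degenerate inputs: datasets need ≥ 2 distinct temperatures for any fit,
  ≥ 3 records and positive variance for RMA, n ≥ 10·L for EM. A zero SE
  yields a degenerate (point) interval rather than an error.

## Known limitations

Component count selection beyond BIC (e.g. bootstrap LRT) is out of
scope, as are alternative component families (gamma, lognormal),
covariate-dependent weights, censoring for individuals that died, and
propagation through fluctuating temperature profiles. The original
Ikemoto–Takai data-point exclusion protocol is deliberately not
implemented; comparisons use the full-data fit.
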