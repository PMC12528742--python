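# thermomix

Interval estimation of insect thermal summation parameters from rearing
data, for forensic entomology and thermal ecology.

Estimating a postmortem interval from insect evidence rests on the law of
total effective temperature: an insect reared at constant temperature *T*
completes development after time *D* once it has accumulated a fixed
thermal budget *k* = *D*(*T* − *t*₀) degree-days above its lower
developmental threshold *t*₀. Classical estimators (the linear degree-day
model; the Ikemoto–Takai linearization *DT* = *t*₀·*D* + *k* with reduced
major axis regression) return a single (*k*, *t*₀) point per species,
hiding the substantial variation between individuals and the latent
subgroups (large vs small insects, regular results vs outliers) present
in real rearing datasets.

`thermomix` instead treats the thermal budget as a random variable *K*
distributed as a **finite mixture of Weibull distributions** with
component-specific thresholds:

> conditional on component *l* (weight *w_l*) and temperature *T*, the
> development time has density
> *f*(*d* | *T*, *l*) = *f*_W(*d*(*T* − *t*₀⁽ˡ⁾); *κ_l*, *λ_l*) · (*T* − *t*₀⁽ˡ⁾),

fitted by an EM algorithm in which the threshold is a distribution
parameter (profiled out in the M-step). From the fitted mixture the
package produces:

- **interval estimates** of *k* capturing a chosen fraction of actual
  cases (central mixture quantiles — these do not shrink with *n*);
- **confidence intervals** for E[*K*] (parametric bootstrap — these do);
- **age intervals** — development time at a given temperature — for
  casework;
- **biological labels** for the detected component populations
  (regular/outlier by weight dominance plus Mann–Whitney and chi-squared
  screens; large/small insects by significant length differences);
- **empirical coverage** comparisons against the widespread
  Ikemoto–Takai ±1.96·SE approximation, whose coverage of individual
  cases collapses because it brackets the estimator, not the realizations.

A synthetic-data module generates rearing datasets with the assumed
structure, including presets carrying the published fitted parameters and
rearing designs of two carrion beetles, *Creophilus maxillosus* and
*Necrodes littoralis*.

## Worked example

```python
import thermomix as tm

# the published two-component fit for N. littoralis
model = tm.preset_model("necrodes_littoralis")

ki = tm.k_interval(model, level=0.95, scope="combined")
print(f"95% of thermal budgets fall in [{ki.lower:.1f}, {ki.upper:.1f}] ADD")
# 95% of thermal budgets fall in [314.8, 461.2] ADD

lo, hi = tm.age_interval(model, temp=18.0, level=0.95)
print(f"at 18 °C, development takes {lo:.1f}-{hi:.1f} days for 95% of cases")
# at 18 °C, development takes 38.0-59.2 days for 95% of cases

# full pipeline on simulated data: sample, fit by EM, label, evaluate
data = tm.sample_dataset(tm.species_preset("necrodes_littoralis", n=2000, seed=1))
fit = tm.em_fit(data, tm.FitConfig(n_components=2, seed=1))
for c in fit.components:
    print(f"w={c.weight:.2f} shape={c.shape:.1f} scale={c.scale:.1f} t0={c.t0:.2f}")
# w=0.43 shape=14.4 scale=398.2 t0=9.48
# w=0.57 shape=14.2 scale=424.2 t0=10.22

cov = tm.coverage_probability(data, fit, level=0.95)
print(f"empirical coverage of the 95% age intervals: {cov.overall:.3f}")
# empirical coverage of the 95% age intervals: 0.951
```

The interval `[314.8, 461.2]` brackets 95% of individual thermal budgets
(rounded, `[315, 461]` accumulated degree-days); the EM fit recovers the
generating weights, Weibull shapes/scales and thresholds from 2000
simulated individuals; and the resulting 95% age intervals empirically
cover ≈95% of cases — while the ±1.96·SE interval of the Ikemoto–Takai
baseline covers far fewer (run `examples/compare_methods.py` to see the
gap).

Short narrative scripts in `examples/` cover each capability:
simulating data, fitting and model selection, interval tables, component
labeling and the head-to-head coverage comparison. A thin CLI wraps the
same functions (`thermomix simulate|fit|intervals|age|label|evaluate|baseline-it`).

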