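"""Head-to-head empirical coverage: mixture intervals vs the SE approximation.

Fits both the Weibull mixture and the Ikemoto-Takai RMA baseline on the
same simulated two-component dataset and measures the fraction of
individuals whose development time falls inside each method's 95% age
interval.
"""

import thermomix as tm

data = tm.sample_dataset(tm.species_preset("necrodes_littoralis", n=2000, seed=3))
comparison = tm.compare_methods(data, tm.FitConfig(n_components=2, n_restarts=3, seed=3))
print(comparison.table.round(3).to_string(index=False))
print(
    "\nThe mixture interval targets 95% of actual cases and its empirical\n"
    "coverage sits near 0.95. The +-1.96*SE interval around the Ikemoto-Takai\n"
    "point estimate brackets the *estimator* of k - its width shrinks with\n"
    "sample size - so its coverage of individual cases collapses. That gap is\n"
    "the reason interval estimates, not SE-based confidence intervals, should\n"
    "back insect-age statements in casework."
)
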