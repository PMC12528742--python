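"""Interval estimation from a fitted Weibull mixture.

Two distinct kinds of interval are produced, and keeping them apart is the
point of the method:

* an *interval estimate* for realizations of the thermal budget K — the
  central [(1-level)/2, (1+level)/2] quantile range of the mixture (or of a
  single component), which brackets the stated fraction of actual cases
  and does not shrink with sample size;
* a *confidence interval* for the estimator of E[K] — obtained here by a
  parametric bootstrap, which does shrink as 1/sqrt(n).

Age (development-time) intervals at a given temperature follow from the
k-intervals through k = D(T - t0). For a single component this is a plain
division by (T - t0); for the combined mixture the components carry
different thresholds, so the development-time mixture CDF
F_D(d | T) = sum_l w_l F_W(d (T - t0_l)) is inverted numerically instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .data_model import Dataset
from .weibull_mix import FitConfig, MixtureModel, em_fit, weibull_quantile

logger = logging.getLogger(__name__)

COMBINED = "combined"


@dataclass(frozen=True)
class ThermalInterval:
    """A (lower, upper) range of k in accumulated degree-days.

    ``scope`` identifies what the interval describes: the full mixture
    ("combined"), a single component ("component:<index>") or the
    Ikemoto–Takai SE approximation ("ikemoto_takai").
    """

    lower: float
    upper: float
    level: float
    scope: str = COMBINED

    def __post_init__(self) -> None:
        if not (0 <= self.lower <= self.upper):
            raise ValueError(f"need 0 <= lower <= upper, got [{self.lower}, {self.upper}]")
        if not (0 < self.level < 1):
            raise ValueError(f"level must be in (0, 1), got {self.level}")

    @property
    def width(self) -> float:
        return self.upper - self.lower

    def contains(self, x) -> np.ndarray | bool:
        x = np.asarray(x)
        out = (x >= self.lower) & (x <= self.upper)
        return bool(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class IntervalTable:
    """Rows of (level, scope, lower, upper, t0) across levels and scopes."""

    frame: pd.DataFrame

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def _parse_scope(scope: str | int, model: MixtureModel) -> int | None:
    """None for combined, else a validated component index."""
    if scope == COMBINED:
        return None
    if isinstance(scope, str) and scope.startswith("component:"):
        scope = int(scope.split(":", 1)[1])
    if not isinstance(scope, (int, np.integer)):
        raise ValueError(f"invalid scope {scope!r}")
    if not (0 <= scope < model.n_components):
        raise ValueError(
            f"component index {scope} out of range for {model.n_components}-component model"
        )
    return int(scope)


def mixture_cdf_k(model: MixtureModel, x) -> np.ndarray | float:
    """Mixture CDF of K: F(x) = sum_l w_l F_W(x; shape_l, scale_l)."""
    x = np.asarray(x, dtype=float)
    out = sum(
        c.weight * stats.weibull_min.cdf(x, c.shape, scale=c.scale)
        for c in model.components
    )
    return float(out) if out.ndim == 0 else out


def mixture_quantile_k(model: MixtureModel, p: float) -> float:
    """Invert the mixture CDF of K by bisection (monotone, bracketed)."""
    if not (0 <= p < 1):
        raise ValueError("p must lie in [0, 1)")
    if p == 0:
        return 0.0
    hi = 10.0 * max(c.scale for c in model.components)
    while mixture_cdf_k(model, hi) < p:  # heavy tails (shape < 1) need a wider bracket
        hi *= 4.0
    return float(
        optimize.brentq(lambda x: mixture_cdf_k(model, x) - p, 0.0, hi, xtol=1e-9, rtol=1e-12)
    )


def k_interval(model: MixtureModel, level: float = 0.95, scope: str | int = COMBINED) -> ThermalInterval:
    """Central interval capturing ``level`` of the realizations of K.

    Endpoints are the (1-level)/2 and (1+level)/2 quantiles of the chosen
    component's Weibull distribution, or of the full mixture CDF inverted
    numerically. Full precision; round only for presentation.
    """
    if not (0 < level < 1):
        raise ValueError(f"level must be in (0, 1), got {level}")
    p_lo, p_hi = (1 - level) / 2, (1 + level) / 2
    j = _parse_scope(scope, model)
    if j is None:
        lo = mixture_quantile_k(model, p_lo)
        hi = mixture_quantile_k(model, p_hi)
        name = COMBINED
    else:
        c = model.components[j]
        lo = weibull_quantile(p_lo, c.shape, c.scale)
        hi = weibull_quantile(p_hi, c.shape, c.scale)
        name = f"component:{j}"
    return ThermalInterval(lower=lo, upper=hi, level=level, scope=name)


def dev_time_cdf(model: MixtureModel, d, temp: float) -> np.ndarray | float:
    """CDF of development time D at temperature ``temp`` under the mixture.

    F_D(d | T) = sum_l w_l F_W(d (T - t0_l); shape_l, scale_l); each
    component contributes through its own threshold.
    """
    d = np.asarray(d, dtype=float)
    out = 0.0
    for c in model.components:
        dt = temp - c.t0
        if dt <= 0:
            raise ValueError(
                f"temperature {temp}°C is at or below component threshold t0={c.t0}°C"
            )
        out = out + c.weight * stats.weibull_min.cdf(d * dt, c.shape, scale=c.scale)
    return float(out) if out.ndim == 0 else out


def age_interval(
    model: MixtureModel, temp: float, level: float = 0.95, scope: str | int = COMBINED
) -> tuple[float, float]:
    """Development-time (age) interval in days at a rearing temperature.

    Component scope divides that component's k-quantiles by (T - t0_l);
    combined scope inverts the development-time mixture CDF by bisection
    (the components' thresholds differ, so dividing combined k-quantiles
    by a single T - t0 would be wrong).
    """
    if not (0 < level < 1):
        raise ValueError(f"level must be in (0, 1), got {level}")
    j = _parse_scope(scope, model)
    if j is not None:
        c = model.components[j]
        dt = temp - c.t0
        if dt <= 0:
            raise ValueError(
                f"temperature {temp}°C is at or below component threshold t0={c.t0}°C"
            )
        ki = k_interval(model, level, scope=j)
        return ki.lower / dt, ki.upper / dt
    if temp <= model.max_t0():
        raise ValueError(
            f"temperature {temp}°C is at or below the maximum threshold {model.max_t0()}°C"
        )
    p_lo, p_hi = (1 - level) / 2, (1 + level) / 2
    dt_min = min(temp - c.t0 for c in model.components)
    d_hi = 10.0 * max(c.scale for c in model.components) / dt_min
    while dev_time_cdf(model, d_hi, temp) < p_hi:
        d_hi *= 4.0

    def q(p: float) -> float:
        return float(
            optimize.brentq(lambda d: dev_time_cdf(model, d, temp) - p, 0.0, d_hi, xtol=1e-6)
        )

    return q(p_lo), q(p_hi)


def interval_table(model: MixtureModel, levels) -> IntervalTable:
    """One row per (level x scope) for the combined mixture and each component.

    Component rows carry that component's t0; combined rows annotate the
    full list of component thresholds (they genuinely differ, so no single
    t0 describes the combined scope).
    """
    levels = list(levels)
    if not levels:
        raise ValueError("levels must be nonempty")
    rows = []
    all_t0 = ";".join(f"{c.t0:g}" for c in model.components)
    for level in levels:
        ki = k_interval(model, level, COMBINED)
        rows.append(
            {"level": level, "scope": COMBINED, "lower": ki.lower, "upper": ki.upper,
             "t0": np.nan, "t0_annotation": all_t0}
        )
        for j, c in enumerate(model.components):
            ki = k_interval(model, level, j)
            rows.append(
                {"level": level, "scope": f"component:{j}", "lower": ki.lower,
                 "upper": ki.upper, "t0": c.t0, "t0_annotation": f"{c.t0:g}"}
            )
    return IntervalTable(pd.DataFrame(rows))


def mean_k_ci(
    data: Dataset,
    config: FitConfig = FitConfig(),
    level: float = 0.95,
    n_boot: int = 1000,
    seed: int = 0,
) -> ThermalInterval:
    """Parametric-bootstrap confidence interval for the mixture mean E[K].

    Refits the mixture on ``n_boot`` datasets simulated from the point fit
    (same n and empirical temperature design), takes the mixture mean
    sum_l w_l lambda_l Gamma(1 + 1/kappa_l) of each replicate, and returns
    the percentile interval. Unlike the interval estimate for realizations
    of K, this interval shrinks as 1/sqrt(n).
    """
    from .synthetic import sample_from_model

    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    fit = em_fit(data, config)
    temps = data.temp
    rng = np.random.default_rng(seed)
    # fewer restarts per replicate: the truth-adjacent init is reliable here
    boot_cfg = replace(config, n_restarts=max(2, config.n_restarts // 3))
    means = []
    n_fail = 0
    for _ in range(n_boot):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        sim = sample_from_model(fit, temps, seed=rep_seed)
        try:
            rep = em_fit(sim, replace(boot_cfg, seed=rep_seed))
        except Exception as exc:  # noqa: BLE001 — replicate failures are counted
            n_fail += 1
            logger.debug("bootstrap replicate failed: %s", exc)
            continue
        means.append(rep.mean_k())
    if n_fail > 0.2 * n_boot:
        raise RuntimeError(
            f"parametric bootstrap unstable: {n_fail}/{n_boot} replicate fits failed"
        )
    lo, hi = np.percentile(means, [100 * (1 - level) / 2, 100 * (1 + level) / 2])
    return ThermalInterval(lower=float(lo), upper=float(hi), level=level, scope=COMBINED)
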