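"""The thermal summation law and the two classical baseline estimators.

The law of total effective temperature states that an insect completes
development once it has accumulated a fixed thermal budget

    k = D (T - t0)          [degree-days]

where D is the development time, T the rearing temperature and t0 the
lower developmental threshold. Two classical ways of estimating (k, t0)
from rearing data are implemented:

* the linear degree-day model of Campbell and colleagues — ordinary least
  squares of the development rate 1/D on T;
* the Ikemoto–Takai linearization D·T = t0·D + k, fitted by reduced major
  axis (RMA) regression, the pairing its authors proposed.

A commonly used (but not recommended) interval approximation for the
Ikemoto–Takai thermal constant, point estimate ± z standard errors, is
provided by :func:`it_k_interval`; the package's mixture-based intervals
(:mod:`thermomix.intervals`) are the alternative it is compared against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data_model import Dataset


class EstimationError(RuntimeError):
    """A fit could not produce a meaningful estimate."""


@dataclass(frozen=True)
class DegreeDayFit:
    """Result of the linear degree-day (Campbell) fit."""

    k_hat: float  # thermal constant, degree-days
    t0_hat: float  # lower developmental threshold, °C
    r_squared: float

    def __post_init__(self) -> None:
        if not self.k_hat > 0:
            raise ValueError(f"k_hat must be positive, got {self.k_hat}")


@dataclass(frozen=True)
class ITFit:
    """Result of the Ikemoto–Takai RMA fit of DT on D.

    The RMA slope estimates t0 and the intercept estimates k. Standard
    errors are the large-sample RMA approximations
    se_slope = |b|·sqrt((1-r²)/n) and
    se_intercept = sqrt(s_y²(1-r²)/n + x̄²·se_slope²).
    """

    t0_hat: float
    k_hat: float
    se_t0: float
    se_k: float
    r: float
    n_points: int

    def __post_init__(self) -> None:
        if self.n_points < 3:
            raise ValueError("ITFit requires at least 3 points")
        if self.se_t0 < 0 or self.se_k < 0:
            raise ValueError("standard errors must be nonnegative")
        if not self.k_hat > 0:
            raise ValueError(f"k_hat must be positive, got {self.k_hat}")


def effective_k(dev_time: float, temp: float, t0: float) -> float:
    """Accumulated degree-days k = D(T - t0) for one individual.

    Raises
    ------
    ValueError
        If ``temp <= t0`` — no development occurs at or below the
        threshold, so the record cannot have completed development there.
    """
    dev_time = np.asarray(dev_time, dtype=float)
    temp = np.asarray(temp, dtype=float)
    if np.any(temp <= t0):
        raise ValueError(
            f"temperature {temp} is below developmental threshold t0={t0}"
        )
    out = dev_time * (temp - t0)
    return float(out) if out.ndim == 0 else out


def degree_day_fit(data: Dataset) -> DegreeDayFit:
    """Fit the linear degree-day model by OLS of 1/D on T.

    With slope s and intercept a of the regression 1/D = s·T + a, the
    thermal constant is k = 1/s and the threshold t0 = -a/s.
    """
    data.require_temperature_spread(2)
    D = data.dev_time
    T = data.temp
    if np.any(D <= 0):
        raise ValueError("all development times must be positive")
    if np.ptp(T) == 0:
        raise EstimationError("singular design: all temperatures equal")
    res = stats.linregress(T, 1.0 / D)
    if res.slope <= 0:
        raise EstimationError(
            "no positive thermal constant: fitted development-rate slope is not positive"
        )
    return DegreeDayFit(
        k_hat=1.0 / res.slope,
        t0_hat=-res.intercept / res.slope,
        r_squared=float(res.rvalue**2),
    )


def ikemoto_takai_fit(data: Dataset, method: str = "rma") -> ITFit:
    """Fit the Ikemoto–Takai linearization DT = t0·D + k.

    Applied to all individual records — no aggregation to per-temperature
    medians. ``method="rma"`` (default) uses reduced major axis regression
    (slope = sign(r)·s_y/s_x); ``method="ols"`` uses ordinary least
    squares with its textbook standard errors.

    .. note::
        The original protocol's iterative exclusion of points outside the
        linear temperature range is deliberately not implemented.
    """
    D = data.dev_time
    n = len(D)
    if n < 3:
        raise EstimationError("Ikemoto–Takai fit requires at least 3 records")
    x = D
    y = D * data.temp
    sx = float(np.std(x, ddof=1))
    sy = float(np.std(y, ddof=1))
    if sx == 0:
        raise EstimationError("zero variance in development time")
    if sy == 0:
        raise EstimationError("zero variance in D*T")
    r = float(np.corrcoef(x, y)[0, 1])

    if method == "rma":
        b = float(np.sign(r) if r != 0 else 1.0) * sy / sx
        se_b = abs(b) * np.sqrt(max(0.0, 1.0 - r**2) / n)
    elif method == "ols":
        b = r * sy / sx
        # OLS slope SE with n-2 dof
        se_b = sy / sx * np.sqrt(max(0.0, 1.0 - r**2) / (n - 2))
    else:
        raise ValueError(f"unknown method {method!r}; use 'rma' or 'ols'")
    xbar = float(np.mean(x))
    a = float(np.mean(y)) - b * xbar
    se_a = float(np.sqrt(sy**2 * max(0.0, 1.0 - r**2) / n + xbar**2 * se_b**2))
    return ITFit(t0_hat=float(b), k_hat=float(a), se_t0=float(se_b), se_k=se_a, r=r, n_points=n)


def aggregate_by_temperature_median(data: Dataset) -> Dataset:
    """Reduce each temperature's cohort to its median development time.

    Reproduces the common published practice of fitting thermal models on
    one point per rearing temperature; the package's default is to use
    every individual record instead.
    """
    from .data_model import DevelopmentRecord

    df = data.to_frame()
    med = df.groupby("temp_C")["dev_time_days"].median()
    records = [DevelopmentRecord(float(d), float(t)) for t, d in med.items()]
    return Dataset(records, species_label=data.species_label)


def it_k_interval(fit: ITFit, z: float = 1.96):
    """Normal-approximation interval for k: [k̂ − z·SE, k̂ + z·SE].

    This reproduces the widespread ad-hoc practice of reporting the point
    estimate plus/minus 1.96 standard errors. The nominal level is
    recorded as 2Φ(z) − 1; the empirical coverage of realized k values is
    generally far below it because the SE measures estimator precision,
    not population spread.
    """
    from .intervals import ThermalInterval

    if z <= 0:
        raise ValueError(f"z must be positive, got {z}")
    level = float(2 * stats.norm.cdf(z) - 1)
    return ThermalInterval(
        lower=fit.k_hat - z * fit.se_k,
        upper=fit.k_hat + z * fit.se_k,
        level=level,
        scope="ikemoto_takai",
    )
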