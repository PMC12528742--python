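"""Finite Weibull mixture over the thermal constant, fitted by EM.

The model: each individual belongs to a latent component population l
(weight w_l). Within component l the thermal budget K = D(T - t0_l) is
Weibull-distributed with shape kappa_l and scale lambda_l, and the lower
developmental threshold t0_l is itself a distribution parameter estimated
alongside the Weibull parameters. Rearing temperature T is treated as a
fixed covariate; conditional on T and component l, the development time D
has density

    f(d | T, l) = f_W(d (T - t0_l); kappa_l, lambda_l) * (T - t0_l)

where the (T - t0_l) factor is the Jacobian of the change of variables
k -> d. The E-step computes component responsibilities from these
Jacobian-corrected densities in log space; the M-step maximizes each
component's weighted log-likelihood by profiling: for a fixed t0 the
weighted Weibull MLE has a one-dimensional score equation in the shape
(solved by bracketed root finding) and a closed-form scale, leaving a
bounded one-dimensional search over t0.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, special, stats
from scipy.special import logsumexp

from .data_model import Dataset

logger = logging.getLogger(__name__)

SHAPE_MIN, SHAPE_MAX = 0.5, 200.0


def _weibull_logpdf(k: np.ndarray, shape: float, scale: float) -> np.ndarray:
    """log f_W(k; shape, scale) for positive k, vectorized without the
    scipy frozen-distribution overhead (this sits in the EM inner loop)."""
    z = k / scale
    return math.log(shape / scale) + (shape - 1.0) * np.log(z) - z**shape


class FitError(RuntimeError):
    """The EM fit failed (all restarts degenerate or invalid)."""


@dataclass(frozen=True)
class WeibullComponent:
    """One mixture component: weight, Weibull shape/scale over k, and its
    developmental threshold t0 (°C)."""

    weight: float
    shape: float
    scale: float
    t0: float

    def __post_init__(self) -> None:
        if not (0 < self.weight <= 1):
            raise ValueError(f"weight must be in (0, 1], got {self.weight}")
        if not (SHAPE_MIN <= self.shape <= SHAPE_MAX):
            raise ValueError(
                f"shape must lie in [{SHAPE_MIN}, {SHAPE_MAX}], got {self.shape}"
            )
        if not self.scale > 0:
            raise ValueError(f"scale must be positive, got {self.scale}")

    @property
    def mean_k(self) -> float:
        """E[K] = scale * Gamma(1 + 1/shape), in degree-days."""
        return self.scale * float(special.gamma(1 + 1 / self.shape))

    @property
    def sd_k(self) -> float:
        g1 = special.gamma(1 + 1 / self.shape)
        g2 = special.gamma(1 + 2 / self.shape)
        return self.scale * float(np.sqrt(g2 - g1**2))


@dataclass
class MixtureModel:
    """An ordered list of components plus fit metadata.

    Components are kept sorted by expected thermal budget E[K] ascending,
    which gives stable labels across EM restarts.
    """

    components: list[WeibullComponent]
    loglik: float = float("nan")
    n_obs: int = 0
    n_iter: int = 0
    converged: bool = False
    seed: int = 0

    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def weights(self) -> np.ndarray:
        return np.array([c.weight for c in self.components])

    def validate(self) -> None:
        if not self.components:
            raise ValueError("model must have at least one component")
        total = float(self.weights.sum())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"component weights must sum to 1, got {total}")
        means = [c.mean_k for c in self.components]
        if any(means[i] > means[i + 1] for i in range(len(means) - 1)):
            raise ValueError("components must be sorted by expected K ascending")

    def sorted_by_mean_k(self) -> "MixtureModel":
        comps = sorted(self.components, key=lambda c: c.mean_k)
        return replace(self, components=comps)

    def mean_k(self) -> float:
        """Mixture mean of K: sum_l w_l * lambda_l * Gamma(1 + 1/kappa_l)."""
        return float(sum(c.weight * c.mean_k for c in self.components))

    def max_t0(self) -> float:
        return max(c.t0 for c in self.components)


@dataclass(frozen=True)
class FitConfig:
    """EM configuration.

    tol is the absolute log-likelihood change declaring convergence;
    t0_margin keeps every threshold at least that many °C below the
    coldest rearing temperature, so T > t0 holds strictly for all data.
    """

    n_components: int = 2
    n_restarts: int = 10
    tol: float = 1e-8
    max_iter: int = 500
    t0_margin: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if self.tol <= 0 or self.t0_margin <= 0:
            raise ValueError("tol and t0_margin must be positive")


def weibull_quantile(p, shape: float, scale: float):
    """Closed-form Weibull quantile scale * (-ln(1-p))**(1/shape).

    Defined for p in [0, 1); strictly increasing in p.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p >= 1)):
        raise ValueError("p must lie in [0, 1)")
    out = scale * (-np.log1p(-p)) ** (1.0 / shape)
    return float(out) if out.ndim == 0 else out


def _log_density_matrix(data: Dataset, model: MixtureModel) -> np.ndarray:
    """n_obs x n_components matrix of log[f_W(D(T-t0_l)) * (T-t0_l)].

    The Jacobian term log(T - t0_l) is mandatory: the Weibull density lives
    on the k scale while the data live on the D scale.
    """
    D = data.dev_time
    T = data.temp
    logf = np.empty((len(D), model.n_components))
    for j, c in enumerate(model.components):
        dt = T - c.t0
        if np.any(dt <= 0):
            bad = int(np.argmax(dt <= 0))
            raise ValueError(
                f"record {bad} (temp={T[bad]}°C) is at or below component "
                f"{j} threshold t0={c.t0}°C"
            )
        k = D * dt
        logf[:, j] = _weibull_logpdf(k, c.shape, c.scale) + np.log(dt)
    return logf


def mixture_loglik(data: Dataset, model: MixtureModel) -> float:
    """Observed-data log-likelihood sum_i log sum_l w_l f(D_i | T_i, l)."""
    logf = _log_density_matrix(data, model)
    logw = np.log(model.weights)
    return float(logsumexp(logf + logw, axis=1).sum())


def e_step(data: Dataset, model: MixtureModel) -> np.ndarray:
    """Posterior component responsibilities, one row per record.

    Computed in log space; every row sums to one to machine precision.
    """
    logf = _log_density_matrix(data, model)
    logpost = logf + np.log(model.weights)
    logpost -= logsumexp(logpost, axis=1, keepdims=True)
    return np.exp(logpost)


# ---------------------------------------------------------------------------
# M-step: weighted Weibull MLE with a profiled threshold
# ---------------------------------------------------------------------------

def _weighted_weibull_mle(k: np.ndarray, r: np.ndarray) -> tuple[float, float]:
    """Weighted Weibull MLE (shape, scale) for positive data k with weights r.

    Solves the profile score equation in the shape,
        1/kappa = sum(r k^kappa ln k)/sum(r k^kappa) - sum(r ln k)/sum(r),
    by bracketed root finding on [SHAPE_MIN, SHAPE_MAX]; the scale then has
    the closed form (sum(r k^kappa)/sum(r))**(1/kappa). Powers are taken in
    log space to stay finite at large shapes.
    """
    logk = np.log(k)
    rsum = r.sum()
    wmean_logk = float(np.dot(r, logk) / rsum)

    def score(kappa: float) -> float:
        # log-space weighted mean of k^kappa and of k^kappa * ln k
        a = kappa * logk + np.log(r + 1e-300)
        amax = a.max()
        ek = np.exp(a - amax)
        s1 = ek.sum()
        s2 = float(np.dot(ek, logk))
        return 1.0 / kappa - (s2 / s1 - wmean_logk)

    lo, hi = SHAPE_MIN, SHAPE_MAX
    flo, fhi = score(lo), score(hi)
    if flo <= 0:  # extremely dispersed data: boundary solution
        kappa = lo
    elif fhi >= 0:  # nearly degenerate data: boundary solution
        kappa = hi
    else:
        kappa = float(optimize.brentq(score, lo, hi, xtol=1e-10))
    a = kappa * logk + np.log(r + 1e-300)
    amax = a.max()
    log_mean_kpow = amax + math.log(np.exp(a - amax).sum() / rsum)
    scale = math.exp(log_mean_kpow / kappa)
    return kappa, scale


def _component_objective(
    t0: float, D: np.ndarray, T: np.ndarray, r: np.ndarray
) -> tuple[float, float, float]:
    """Profile objective over t0: returns (objective, shape, scale)."""
    dt = T - t0
    k = D * dt
    kappa, lam = _weighted_weibull_mle(k, r)
    obj = float(np.dot(r, _weibull_logpdf(k, kappa, lam) + np.log(dt)))
    return obj, kappa, lam


def m_step_component(
    data: Dataset,
    responsibilities: np.ndarray,
    t0_bounds: tuple[float, float],
) -> WeibullComponent:
    """Maximize one component's weighted log-likelihood over (shape, scale, t0).

    The threshold is profiled out by bounded scalar maximization; for each
    candidate t0 the inner weighted Weibull MLE is exact. The returned
    component's weight is a placeholder (1.0) — the caller sets mixture
    weights from the mean responsibilities.
    """
    r = np.asarray(responsibilities, dtype=float)
    if r.sum() <= 0:
        raise ValueError("responsibilities must have positive total mass")
    D, T = data.dev_time, data.temp
    lo, hi = t0_bounds
    if hi >= T.min():
        raise ValueError(
            f"t0 upper bound {hi} must stay below the minimum temperature {T.min()}"
        )

    res = optimize.minimize_scalar(
        lambda t0: -_component_objective(t0, D, T, r)[0],
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-5},
    )
    t0 = float(res.x)
    # bounded Brent can sit at the edge when the profile is monotone
    for edge in (lo, hi):
        if _component_objective(edge, D, T, r)[0] > -res.fun:
            t0 = edge
            logger.warning("t0 profile is monotone; returning boundary value %.3f", edge)
    obj, kappa, lam = _component_objective(t0, D, T, r)
    if kappa in (SHAPE_MIN, SHAPE_MAX):
        logger.warning("shape estimate hit bound %.1f", kappa)
    return WeibullComponent(weight=1.0, shape=kappa, scale=lam, t0=t0)


# ---------------------------------------------------------------------------
# EM driver
# ---------------------------------------------------------------------------

def _moment_init(k: np.ndarray) -> tuple[float, float]:
    """Method-of-moments Weibull init from a sample of k values.

    Uses the standard coefficient-of-variation power-law approximation for
    the shape, clipped to the legal range.
    """
    m, s = float(np.mean(k)), float(np.std(k))
    if s <= 0:
        return 50.0, m
    kappa = float(np.clip((s / m) ** -1.086, SHAPE_MIN, SHAPE_MAX))
    lam = m / float(special.gamma(1 + 1 / kappa))
    return kappa, lam


def _initial_model(
    data: Dataset, L: int, t0_bounds: tuple[float, float], rng: np.random.Generator,
    jitter: bool,
) -> MixtureModel:
    """Data-driven initialization.

    A provisional threshold from the degree-day fit (clamped to bounds)
    converts each record to a provisional k; quantile slices of k define L
    groups whose method-of-moments Weibull parameters seed the components.
    Restarts after the first jitter the provisional t0 within ±2 °C and
    perturb the slice assignment.
    """
    from .thermal_laws import EstimationError, degree_day_fit

    lo, hi = t0_bounds
    try:
        t0_prov = degree_day_fit(data).t0_hat
    except (EstimationError, ValueError):
        t0_prov = lo + 0.75 * (hi - lo)
    t0_prov = float(np.clip(t0_prov, lo, hi))
    if jitter:
        t0_prov = float(np.clip(t0_prov + rng.uniform(-2.0, 2.0), lo, hi))

    k = data.dev_time * (data.temp - t0_prov)
    order = np.argsort(k)
    if jitter:
        # perturb group boundaries by swapping a random 20% of adjacent ranks
        n_swap = max(1, len(k) // 5)
        idx = rng.integers(0, len(k) - 1, size=n_swap)
        order[idx], order[idx + 1] = order[idx + 1].copy(), order[idx].copy()
    groups = np.array_split(order, L)
    comps = []
    for g in groups:
        kappa, lam = _moment_init(k[g])
        comps.append(
            WeibullComponent(weight=len(g) / len(k), shape=kappa, scale=lam, t0=t0_prov)
        )
    w = np.array([c.weight for c in comps])
    w /= w.sum()
    comps = [replace(c, weight=float(wi)) for c, wi in zip(comps, w)]
    return MixtureModel(components=comps)


def _em_single(
    data: Dataset, L: int, config: FitConfig, t0_bounds: tuple[float, float],
    init: MixtureModel,
) -> tuple[MixtureModel, list[float]]:
    """One EM run from a given initialization; returns model and loglik trace."""
    n = len(data)
    model = init
    trace: list[float] = []
    ll_prev = -np.inf
    for it in range(1, config.max_iter + 1):
        resp = e_step(data, model)
        weights = resp.mean(axis=0)
        if np.any(weights < 1.0 / n):
            raise FitError(
                f"degenerate component (weight {weights.min():.2e} < 1/n); "
                "consider fewer components"
            )
        comps = []
        D, T = data.dev_time, data.temp
        for j in range(L):
            c = m_step_component(data, resp[:, j], t0_bounds)
            # guaranteed ascent: never replace the previous parameters with
            # a numerically inferior inner-optimizer result
            old = model.components[j]
            r_j = resp[:, j]
            new_obj = float(np.dot(r_j, _weibull_logpdf(D * (T - c.t0), c.shape, c.scale)
                                   + np.log(T - c.t0)))
            old_obj = float(np.dot(r_j, _weibull_logpdf(D * (T - old.t0), old.shape, old.scale)
                                   + np.log(T - old.t0)))
            if old_obj > new_obj:
                c = old
            comps.append(replace(c, weight=float(weights[j])))
        model = MixtureModel(components=comps)
        ll = mixture_loglik(data, model)
        trace.append(ll)
        if ll < ll_prev - 1e-9:
            logger.warning("log-likelihood decreased by %.3e at iteration %d", ll_prev - ll, it)
        if abs(ll - ll_prev) < config.tol:
            return (
                replace(model, loglik=ll, n_obs=n, n_iter=it, converged=True),
                trace,
            )
        ll_prev = ll
    return replace(model, loglik=ll_prev, n_obs=n, n_iter=config.max_iter, converged=False), trace


def em_fit(data: Dataset, config: FitConfig = FitConfig()) -> MixtureModel:
    """Fit an L-component Weibull mixture by EM with multiple restarts.

    Returns the restart with the highest converged log-likelihood, its
    components sorted by expected K ascending. Raises :class:`FitError`
    if every restart collapses a component.
    """
    L = config.n_components
    n = len(data)
    if n < 10 * L:
        raise ValueError(f"need at least {10 * L} observations for {L} components, got {n}")
    data.require_temperature_spread(2)
    tmin = float(data.temp.min())
    t0_bounds = (tmin - 30.0, tmin - config.t0_margin)

    rng = np.random.default_rng(config.seed)
    best: MixtureModel | None = None
    failures: list[str] = []
    for restart in range(config.n_restarts):
        init = _initial_model(data, L, t0_bounds, rng, jitter=restart > 0)
        try:
            model, trace = _em_single(data, L, config, t0_bounds, init)
        except (FitError, ValueError) as exc:
            failures.append(str(exc))
            continue
        logger.debug("restart %d: loglik trace %s", restart, trace[-3:])
        if best is None or model.loglik > best.loglik:
            best = model
    if best is None:
        raise FitError(
            "all restarts degenerate — " + (failures[0] if failures else "no detail")
        )
    best = replace(best, seed=config.seed).sorted_by_mean_k()
    best.validate()
    return best


def select_n_components(
    data: Dataset, config: FitConfig = FitConfig(), max_components: int = 3
) -> MixtureModel:
    """Choose the component count by BIC.

    BIC = -2 loglik + p ln(n) with p = 4L - 1 free parameters
    (L weights minus one constraint, plus shape/scale/t0 per component);
    ties break toward the smaller model.
    """
    if max_components < 1:
        raise ValueError("max_components must be >= 1")
    best: MixtureModel | None = None
    best_bic = np.inf
    for L in range(1, max_components + 1):
        try:
            model = em_fit(data, replace(config, n_components=L))
        except (FitError, ValueError) as exc:
            logger.warning("L=%d failed: %s", L, exc)
            continue
        p = 4 * L - 1
        bic = -2 * model.loglik + p * math.log(model.n_obs)
        logger.debug("L=%d BIC=%.2f", L, bic)
        if bic < best_bic - 1e-12:
            best, best_bic = model, bic
    if best is None:
        raise FitError("no component count could be fitted")
    return best
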