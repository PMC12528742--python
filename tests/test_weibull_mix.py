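import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from thermomix import (
    Dataset,
    DevelopmentRecord,
    FitConfig,
    MixtureModel,
    WeibullComponent,
    e_step,
    em_fit,
    m_step_component,
    mixture_loglik,
    select_n_components,
    weibull_quantile,
)
from thermomix.synthetic import sample_dataset
from thermomix.weibull_mix import FitError, _em_single, _initial_model

from conftest import single_component_design


class TestWeibullQuantile:
    def test_support_lower_bound(self):
        assert weibull_quantile(0.0, 14.0, 400.0) == 0.0

    def test_quantile_at_one_minus_exp_minus_one_is_scale(self):
        p = 1 - math.exp(-1)
        for shape in (0.7, 1.0, 5.0, 14.0):
            assert weibull_quantile(p, shape, 442.74) == pytest.approx(442.74, rel=1e-12)

    def test_published_lower_endpoint_of_regular_component(self):
        # 2.5% quantile of the dominant C. maxillosus component
        assert round(weibull_quantile(0.025, 14.03, 442.74)) == 341

    def test_matches_scipy_ppf(self):
        ps = np.linspace(0.01, 0.99, 17)
        mine = weibull_quantile(ps, 6.72, 556.66)
        ref = stats.weibull_min.ppf(ps, 6.72, scale=556.66)
        np.testing.assert_allclose(mine, ref, rtol=1e-12)

    @pytest.mark.parametrize("shape", [0.7, 1.0, 5.0, 14.0])
    @pytest.mark.parametrize("frac", [0.5, 1.0, 1.5])
    def test_cdf_round_trip(self, shape, frac):
        lam = 400.0
        x = frac * lam
        p = stats.weibull_min.cdf(x, shape, scale=lam)
        if p < 1.0:
            assert weibull_quantile(p, shape, lam) == pytest.approx(x, rel=1e-9)
        else:
            # deep upper tail (CDF rounds to 1.0 in double precision): the
            # same identity holds in survival space, Q = lam*(-ln sf)^(1/shape)
            sf = stats.weibull_min.sf(x, shape, scale=lam)
            assert lam * (-np.log(sf)) ** (1.0 / shape) == pytest.approx(x, rel=1e-9)

    @given(
        p1=st.floats(0.001, 0.998),
        p2=st.floats(0.001, 0.998),
        shape=st.floats(0.5, 50.0),
    )
    @settings(max_examples=50, derandomize=True)
    def test_strictly_increasing_in_p(self, p1, p2, shape):
        if p1 == p2:
            return
        lo, hi = sorted((p1, p2))
        assert weibull_quantile(lo, shape, 300.0) < weibull_quantile(hi, shape, 300.0)

    def test_domain_error_outside_unit_interval(self):
        with pytest.raises(ValueError):
            weibull_quantile(1.0, 14.0, 400.0)
        with pytest.raises(ValueError):
            weibull_quantile(-0.1, 14.0, 400.0)


def _one_record_model(t0=10.0, lam=50.0, temp=20.0):
    """Single exponential-tail component (shape 1) with k = lam exactly."""
    d = lam / (temp - t0)
    data = Dataset([DevelopmentRecord(d, temp)])
    model = MixtureModel([WeibullComponent(1.0, 1.0, lam, t0)])
    return data, model, temp - t0


class TestMixtureLoglik:
    def test_closed_form_single_record_shape_one(self):
        # k = lam, shape 1: density (1/lam) e^{-1}, plus the Jacobian (T - t0)
        data, model, jac = _one_record_model()
        expected = math.log((1.0 / 50.0) * math.exp(-1.0) * jac)
        assert mixture_loglik(data, model) == pytest.approx(expected, rel=1e-12)

    def test_jacobian_term_present(self):
        # same k-value at two thresholds: loglik must differ by log ratio of (T-t0)
        lam, temp = 50.0, 20.0
        lls = []
        for t0 in (10.0, 15.0):
            d = lam / (temp - t0)
            data = Dataset([DevelopmentRecord(d, temp)])
            model = MixtureModel([WeibullComponent(1.0, 1.0, lam, t0)])
            lls.append(mixture_loglik(data, model))
        assert lls[1] - lls[0] == pytest.approx(math.log(5.0 / 10.0), rel=1e-12)

    def test_duplicating_records_doubles_loglik(self, necrodes_model, single_component_data):
        ds = single_component_data
        doubled = Dataset(list(ds.records) * 2)
        assert mixture_loglik(doubled, necrodes_model) == pytest.approx(
            2 * mixture_loglik(ds, necrodes_model), rel=1e-12
        )

    def test_permutation_invariant(self, necrodes_model, single_component_data):
        rng = np.random.default_rng(0)
        perm = list(rng.permutation(len(single_component_data)))
        shuffled = Dataset([single_component_data.records[i] for i in perm])
        assert mixture_loglik(shuffled, necrodes_model) == pytest.approx(
            mixture_loglik(single_component_data, necrodes_model), rel=1e-12
        )

    def test_record_below_threshold_identified(self, necrodes_model):
        ds = Dataset([DevelopmentRecord(30.0, 20.0), DevelopmentRecord(30.0, 10.0)])
        with pytest.raises(ValueError, match="record 1"):
            mixture_loglik(ds, necrodes_model)


class TestEStep:
    def test_single_component_all_ones(self, single_component_data):
        model = MixtureModel([WeibullComponent(1.0, 14.0, 400.0, 10.0)])
        resp = e_step(single_component_data, model)
        np.testing.assert_array_equal(resp, 1.0)

    def test_identical_components_return_weights(self, single_component_data):
        c = WeibullComponent(0.3, 14.0, 400.0, 10.0)
        model = MixtureModel([c, replace(c, weight=0.7)])
        resp = e_step(single_component_data, model)
        np.testing.assert_allclose(resp[:, 0], 0.3, rtol=1e-12)
        np.testing.assert_allclose(resp[:, 1], 0.7, rtol=1e-12)

    def test_rows_sum_to_one(self, necrodes_model):
        ds = sample_dataset(
            __import__("thermomix").species_preset("necrodes_littoralis", n=500, seed=3)
        )
        resp = e_step(ds, necrodes_model)
        np.testing.assert_allclose(resp.sum(axis=1), 1.0, atol=1e-12)

    def test_matches_bayes_rule_oracle(self, necrodes_model):
        # brute-force densities via scipy on a 2-record instance
        ds = Dataset([DevelopmentRecord(25.0, 26.0), DevelopmentRecord(20.0, 30.0)])
        resp = e_step(ds, necrodes_model)
        for i, rec in enumerate(ds):
            num = []
            for c in necrodes_model.components:
                dt = rec.temp - c.t0
                k = rec.dev_time * dt
                num.append(c.weight * stats.weibull_min.pdf(k, c.shape, scale=c.scale) * dt)
            expected = np.array(num) / sum(num)
            np.testing.assert_allclose(resp[i], expected, atol=1e-10)


class TestMStep:
    def test_recovers_single_component_parameters(self):
        ds = sample_dataset(single_component_design(n=1000, seed=4))
        comp = m_step_component(ds, np.ones(len(ds)), (15.0 - 30.0, 15.0 - 0.5))
        assert comp.shape == pytest.approx(14.0, rel=0.15)
        assert comp.scale == pytest.approx(400.0, rel=0.03)
        assert abs(comp.t0 - 10.0) <= 0.5

    def test_objective_at_estimate_beats_truth(self):
        ds = sample_dataset(single_component_design(n=1000, seed=4))
        D, T = ds.dev_time, ds.temp

        def obj(shape, scale, t0):
            k = D * (T - t0)
            return float(
                np.sum(stats.weibull_min.logpdf(k, shape, scale=scale) + np.log(T - t0))
            )

        comp = m_step_component(ds, np.ones(len(ds)), (-15.0, 14.5))
        assert obj(comp.shape, comp.scale, comp.t0) >= obj(14.0, 400.0, 10.0) - 1e-6

    def test_beats_dense_grid_search_on_five_points(self):
        # independent brute-force oracle over (shape, scale, t0)
        ds = Dataset(
            [
                DevelopmentRecord(28.0, 25.0),
                DevelopmentRecord(30.5, 25.0),
                DevelopmentRecord(41.0, 20.0),
                DevelopmentRecord(44.0, 20.0),
                DevelopmentRecord(80.0, 15.0),
            ]
        )
        r = np.array([1.0, 1.0, 1.0, 0.8, 0.6])
        D, T = ds.dev_time, ds.temp

        def obj(shape, scale, t0):
            k = D * (T - t0)
            return float(
                np.dot(r, stats.weibull_min.logpdf(k, shape, scale=scale) + np.log(T - t0))
            )

        bounds = (15.0 - 30.0, 15.0 - 0.5)
        comp = m_step_component(ds, r, bounds)
        fitted = obj(comp.shape, comp.scale, comp.t0)
        best_grid = -np.inf
        for t0 in np.linspace(bounds[0], bounds[1], 30):
            for shape in np.geomspace(0.6, 60.0, 40):
                for scale in np.geomspace(100.0, 1500.0, 40):
                    best_grid = max(best_grid, obj(shape, scale, t0))
        assert fitted >= best_grid - 1e-6

    def test_zero_mass_responsibilities_rejected(self, single_component_data):
        with pytest.raises(ValueError):
            m_step_component(single_component_data, np.zeros(1000), (-15.0, 14.5))


class TestEmFit:
    def test_recovers_two_component_generator(self):
        from thermomix import species_preset

        ds = sample_dataset(species_preset("necrodes_littoralis", n=2000, seed=1))
        model = em_fit(ds, FitConfig(n_components=2, n_restarts=4, seed=1))
        truth = [(0.41, 14.57, 394.44, 9.52), (0.59, 13.67, 423.95, 10.21)]
        for c, (w, shape, scale, t0) in zip(model.components, truth):
            assert abs(c.weight - w) <= 0.05
            assert c.shape == pytest.approx(shape, rel=0.20)
            assert c.scale == pytest.approx(scale, rel=0.03)
            assert abs(c.t0 - t0) <= 0.7

    def test_one_component_fit_equals_direct_mle(self, single_component_data):
        ds = single_component_data
        model = em_fit(ds, FitConfig(n_components=1, n_restarts=2, seed=0))
        tmin = float(ds.temp.min())
        direct = m_step_component(ds, np.ones(len(ds)), (tmin - 30.0, tmin - 0.5))
        assert model.components[0].shape == pytest.approx(direct.shape, abs=1e-5)
        assert model.components[0].scale == pytest.approx(direct.scale, rel=1e-6)
        assert model.components[0].t0 == pytest.approx(direct.t0, abs=1e-3)

    def test_loglik_trace_non_decreasing(self, single_component_data):
        ds = single_component_data
        tmin = float(ds.temp.min())
        bounds = (tmin - 30.0, tmin - 0.5)
        cfg = FitConfig(n_components=2, seed=0, tol=1e-8, max_iter=60)
        rng = np.random.default_rng(0)
        init = _initial_model(ds, 2, bounds, rng, jitter=False)
        _, trace = _em_single(ds, 2, cfg, bounds, init)
        diffs = np.diff(trace)
        assert np.all(diffs >= -1e-9)

    def test_two_component_loglik_dominates_one_component(self, single_component_data):
        m1 = em_fit(single_component_data, FitConfig(n_components=1, n_restarts=2, seed=0))
        m2 = em_fit(single_component_data, FitConfig(n_components=2, n_restarts=3, seed=0))
        assert m2.loglik >= m1.loglik - 1e-6  # nesting

    def test_record_order_equivariance(self):
        from thermomix import species_preset

        ds = sample_dataset(species_preset("necrodes_littoralis", n=400, seed=9))
        rng = np.random.default_rng(1)
        shuffled = Dataset([ds.records[i] for i in rng.permutation(len(ds))])
        cfg = FitConfig(n_components=2, n_restarts=2, seed=5)
        m_a = em_fit(ds, cfg)
        m_b = em_fit(shuffled, cfg)
        for a, b in zip(m_a.components, m_b.components):
            assert a.scale == pytest.approx(b.scale, rel=1e-3)
            assert a.weight == pytest.approx(b.weight, abs=1e-3)

    def test_too_few_observations_rejected(self):
        ds = Dataset([DevelopmentRecord(10.0 + i, 20.0 + (i % 2)) for i in range(12)])
        with pytest.raises(ValueError, match="observations"):
            em_fit(ds, FitConfig(n_components=2))

    def test_components_sorted_by_mean_k(self, necrodes_model):
        means = [c.mean_k for c in necrodes_model.components]
        assert means == sorted(means)


class TestSelectNComponents:
    def test_bic_formula(self):
        # hand formula on a fixed triple: BIC = -2 ll + (4L-1) ln n
        ll, L, n = -5000.0, 2, 954
        assert -2 * ll + (4 * L - 1) * math.log(n) == pytest.approx(
            10000 + 7 * math.log(954)
        )

    def test_prefers_one_component_on_homogeneous_data(self):
        n_correct = 0
        for seed in range(3):
            ds = sample_dataset(single_component_design(n=500, seed=100 + seed))
            model = select_n_components(
                ds, FitConfig(n_restarts=2, seed=seed), max_components=2
            )
            n_correct += model.n_components == 1
        assert n_correct >= 2
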