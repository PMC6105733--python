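"""Scalar-noise likelihood, posteriors, estimator maps, response densities."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from intervalbayes import PriorSpec
from intervalbayes import observers as ob
from intervalbayes.validation import mc_posterior_mean

from conftest import make_params


class TestScalarLikelihood:
    def test_peak_value_at_mean(self, prior):
        w, ts = 0.1, 800.0
        assert ob.scalar_likelihood(ts, ts, w) == pytest.approx(
            1.0 / (math.sqrt(2 * math.pi) * w * ts)
        )

    def test_matches_closed_form_gaussian(self):
        # independent evaluation of the closed form at (t_m=700, t_s=800, w=0.1)
        t_m, t_s, w = 700.0, 800.0, 0.1
        sd = w * t_s
        expected = math.exp(-0.5 * ((t_m - t_s) / sd) ** 2) / (
            math.sqrt(2 * math.pi) * sd
        )
        assert ob.scalar_likelihood(t_m, t_s, w) == pytest.approx(expected, rel=1e-12)

    def test_normalizes_over_tm(self):
        total, _ = quad(lambda tm: ob.scalar_likelihood(tm, 800.0, 0.15), -2000, 6000)
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_skewed_in_ts_at_fixed_tm(self):
        # as a function of t_s the density is not symmetric around t_m
        tm, w = 800.0, 0.2
        below = ob.scalar_likelihood(tm, tm - 100.0, w)
        above = ob.scalar_likelihood(tm, tm + 100.0, w)
        assert not np.isclose(below, above, rtol=1e-3)

    @pytest.mark.parametrize("bad", [{"t_s": -800.0}, {"t_s": 0.0}, {"w": 0.0}, {"w": -0.1}])
    def test_domain_errors(self, bad):
        kw = {"t_m": 700.0, "t_s": 800.0, "w": 0.1, **bad}
        with pytest.raises(ValueError):
            ob.scalar_likelihood(kw["t_m"], kw["t_s"], kw["w"])


class TestPosteriors:
    def test_normalization_and_support(self, prior):
        grid = np.linspace(500, 1100, 1201)
        post = ob.posterior_1meas(grid, 750.0, 0.15, prior)
        assert np.trapezoid(post, grid) == pytest.approx(1.0, abs=1e-6)
        assert np.all(post >= 0)
        assert np.all(post[(grid < prior.t_min) | (grid > prior.t_max)] == 0)

    def test_grid_must_cover_prior(self, prior):
        with pytest.raises(ValueError, match="cover"):
            ob.posterior_1meas(np.linspace(650, 1100, 100), 750.0, 0.1, prior)

    def test_uninformative_likelihood_limit(self, prior):
        # as w -> inf the exponential flattens but the scalar-noise
        # prefactor 1/(w t_s) survives: the limit posterior is
        # proportional to 1/t_s on the support, not flat
        grid = np.linspace(prior.t_min, prior.t_max, 801)
        post = ob.posterior_1meas(grid, 800.0, 1e4, prior)
        limit = (1.0 / grid) / math.log(prior.t_max / prior.t_min)
        np.testing.assert_allclose(post, limit, rtol=1e-4)

    def test_rejection_sampling_oracle(self, prior, rng):
        # ABC rejection: accept t_s draws whose noisy measurement lands near t_m1
        t_m1, w = 750.0, 0.15
        ts = rng.uniform(prior.t_min, prior.t_max, 4_000_000)
        tm = rng.normal(ts, w * ts)
        kept = ts[np.abs(tm - t_m1) < 2.0]
        assert kept.size > 5_000
        grid = np.linspace(prior.t_min, prior.t_max, 401)
        post = ob.posterior_1meas(grid, t_m1, w, prior)
        quad_mean = np.trapezoid(grid * post, grid)
        se = kept.std(ddof=1) / math.sqrt(kept.size)
        assert quad_mean == pytest.approx(kept.mean(), abs=3 * se + 1.0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        t_m1=st.floats(550, 1050),
        t_m2=st.floats(550, 1050),
        w=st.floats(0.03, 0.4),
    )
    def test_recursive_equals_batch(self, t_m1, t_m2, w):
        prior_local = PriorSpec()
        grid = np.linspace(prior_local.t_min, prior_local.t_max, 401)
        batch = ob.posterior_2meas_batch(grid, t_m1, t_m2, w, prior_local)
        rec = ob.posterior_2meas_recursive(grid, t_m1, t_m2, w, prior_local)
        assert np.max(np.abs(batch - rec)) < 1e-9

    def test_two_measurements_sharpen(self, prior):
        grid = np.linspace(prior.t_min, prior.t_max, 801)
        one = ob.posterior_1meas(grid, 800.0, 0.15, prior)
        two = ob.posterior_2meas_batch(grid, 800.0, 800.0, 0.15, prior)

        def sd(post):
            m = np.trapezoid(grid * post, grid)
            return math.sqrt(np.trapezoid((grid - m) ** 2 * post, grid))

        assert sd(two) < sd(one)


class TestBlsMaps:
    def test_bls1_monotone_bounded_regressive(self, prior):
        # strictly increasing on a 1 ms grid over the physically relevant
        # range; far below the prior the 1/t_s likelihood prefactor
        # dominates and the map turns over (near t_m ~ 320 ms for w=0.1)
        args = np.arange(400.0, 2500.0, 1.0)
        est = ob.bls1_map(args, 0.1, prior)
        assert np.all(np.diff(est) > 0)
        assert np.all((est > prior.t_min) & (est < prior.t_max))
        # regression toward the prior mean
        assert ob.bls1_map(650.0, 0.1, prior) > 650.0
        assert ob.bls1_map(950.0, 0.1, prior) < 950.0

    def test_bls1_noiseless_and_uninformative_limits(self, prior):
        for t in (650.0, 800.0, 950.0):
            assert ob.bls1_map(t, 1e-4, prior) == pytest.approx(t, abs=0.01)
        # w -> inf: likelihood tends to 1/(w t_s), so the estimate tends
        # to width / log(t_max/t_min), slightly below the prior mean
        limit = prior.width / math.log(prior.t_max / prior.t_min)
        for t in (300.0, 800.0, 1500.0):
            assert ob.bls1_map(t, 1e3, prior) == pytest.approx(limit, abs=0.5)

    def test_bls1_monte_carlo_oracle(self, prior, rng):
        est = ob.bls1_map(700.0, 0.1, prior)
        mc, se = mc_posterior_mean(700.0, 0.1, prior, n_draws=1_000_000, rng=rng)
        assert est == pytest.approx(mc, abs=3 * se)

    def test_bls2_symmetric(self, prior, rng):
        a = rng.uniform(500, 1100, 50)
        b = rng.uniform(500, 1100, 50)
        np.testing.assert_allclose(
            ob.bls2_map(a, b, 0.1, prior), ob.bls2_map(b, a, 0.1, prior), rtol=1e-12
        )

    def test_bls2_noiseless_limit(self, prior):
        for t in (650.0, 800.0, 950.0):
            assert ob.bls2_map(t, t, 1e-4, prior) == pytest.approx(t, abs=0.01)

    def test_bls2_independent_quadrature_and_mc_oracles(self, prior, rng):
        t1, t2, w = 650.0, 950.0, 0.12
        est = ob.bls2_map(t1, t2, w, prior)

        def integrand(ts, moment):
            return (
                ts**moment
                * ob.scalar_likelihood(t1, ts, w)
                * ob.scalar_likelihood(t2, ts, w)
            )

        num, _ = quad(integrand, prior.t_min, prior.t_max, args=(1,), limit=200)
        den, _ = quad(integrand, prior.t_min, prior.t_max, args=(0,), limit=200)
        assert est == pytest.approx(num / den, rel=1e-7)
        mc, se = mc_posterior_mean(t1, w, prior, t_m2=t2, n_draws=1_000_000, rng=rng)
        assert est == pytest.approx(mc, abs=3 * se)

    def test_blsmem_reduces_to_bls2(self, prior):
        a, b = np.meshgrid(np.linspace(600, 1000, 9), np.linspace(600, 1000, 9))
        np.testing.assert_allclose(
            ob.blsmem_map(a, b, 0.1, 0.1, prior),
            ob.bls2_map(a, b, 0.1, prior),
            atol=1e-9,
        )

    def test_blsmem_infinite_memory_noise_ignores_first_value(self, prior):
        # as w_mem -> inf the first likelihood tends to 1/(w_mem t_s):
        # the estimate becomes independent of t_m1 but keeps a 1/t_s
        # tilt, E[t_s * (1/t_s) lambda] / E[(1/t_s) lambda]
        num, _ = quad(lambda ts: ob.scalar_likelihood(850.0, ts, 0.1),
                      prior.t_min, prior.t_max)
        den, _ = quad(lambda ts: ob.scalar_likelihood(850.0, ts, 0.1) / ts,
                      prior.t_min, prior.t_max)
        limit = num / den
        for t1 in (600.0, 800.0, 1000.0):
            assert ob.blsmem_map(t1, 850.0, 1e4, 0.1, prior) == pytest.approx(
                limit, abs=0.05
            )

    def test_blsmem_quadrature_oracle(self, prior):
        t1, t2, w_mem, w = 600.0, 1000.0, 0.2, 0.1
        est = ob.blsmem_map(t1, t2, w_mem, w, prior)

        def integrand(ts, moment):
            return (
                ts**moment
                * ob.scalar_likelihood(t1, ts, w_mem)
                * ob.scalar_likelihood(t2, ts, w)
            )

        num, _ = quad(integrand, prior.t_min, prior.t_max, args=(1,), limit=200)
        den, _ = quad(integrand, prior.t_min, prior.t_max, args=(0,), limit=200)
        assert est == pytest.approx(num / den, rel=1e-7)

    def test_blsmem_weighs_second_measurement_more(self, prior):
        # with noisier memory of the first measurement, moving t_m2 moves
        # the estimate more than moving t_m1 by the same amount
        d_first = ob.blsmem_map(900.0, 800.0, 0.2, 0.1, prior) - ob.blsmem_map(
            800.0, 800.0, 0.2, 0.1, prior
        )
        d_second = ob.blsmem_map(800.0, 900.0, 0.2, 0.1, prior) - ob.blsmem_map(
            800.0, 800.0, 0.2, 0.1, prior
        )
        assert d_second > d_first > 0


class TestSequentialEstimators:
    def test_first_ekf_update_is_bls1(self, prior):
        state = ob.EstimatorState.initial(prior)
        for t_m in (620.0, 800.0, 990.0):
            new = ob.ekf_update(state, t_m, 0.1, prior)
            assert new.last_gain == 1.0
            assert new.w == pytest.approx(0.1)
            assert new.t_e == pytest.approx(ob.bls1_map(t_m, 0.1, prior), abs=1e-12)

    def test_second_gain_is_half(self, prior):
        state = ob.EstimatorState.initial(prior)
        state = ob.ekf_update(state, 700.0, 0.1, prior)
        state = ob.ekf_update(state, 900.0, 0.1, prior)
        assert state.last_gain == pytest.approx(0.5)
        assert state.w == pytest.approx(0.1 / math.sqrt(2))

    def test_estimate_weber_fraction_strictly_decreases(self, prior):
        state = ob.EstimatorState.initial(prior)
        ws = []
        for t_m in (700.0, 900.0, 800.0, 750.0):
            state = ob.ekf_update(state, t_m, 0.1, prior)
            ws.append(state.w)
        assert all(b < a for a, b in zip(ws, ws[1:]))

    def test_two_updates_match_hand_trace(self, prior):
        # step-by-step trace written out with direct bls1_map calls
        w, t_m1, t_m2 = 0.1, 700.0, 900.0
        te1 = ob.bls1_map(t_m1, w, prior)
        x2 = t_m2 - te1
        te2 = te1 + 0.5 * (ob.bls1_map(x2 + prior.mean, w, prior) - prior.mean)
        assert ob.ekf_estimate([t_m1, t_m2], w, prior) == pytest.approx(te2, abs=1e-12)

    def test_ekf_order_dependence(self, prior):
        fwd = ob.ekf_estimate([650.0, 950.0], 0.1, prior)
        bwd = ob.ekf_estimate([950.0, 650.0], 0.1, prior)
        assert abs(fwd - bwd) > 0.5
        lo = prior.t_min - 0.25 * prior.width
        hi = prior.t_max + 0.25 * prior.width
        assert lo < fwd < hi and lo < bwd < hi

    def test_ekf_bounded_for_symmetric_input(self, prior):
        est = ob.ekf_estimate([800.0, 800.0], 0.1, prior)
        assert prior.t_min < est < prior.t_max

    def test_empty_measurements_rejected(self, prior):
        with pytest.raises(ValueError):
            ob.ekf_estimate([], 0.1, prior)
        with pytest.raises(ValueError):
            ob.lne_estimate([], 0.1, prior)

    def test_lne_running_mean_and_gains(self, prior):
        state = ob.EstimatorState.initial(prior)
        state = ob.lne_update(state, 700.0)
        assert state.last_gain == 1.0
        assert state.running_mean == 700.0
        state = ob.lne_update(state, 900.0)
        assert state.last_gain == 0.5
        assert state.running_mean == pytest.approx(0.5 * (700.0 + 900.0))

    def test_lne_is_bls1_of_the_mean_and_symmetric(self, prior):
        a, b, w = 650.0, 950.0, 0.1
        est = ob.lne_estimate([a, b], w, prior)
        assert est == pytest.approx(ob.bls1_map(0.5 * (a + b), w, prior), abs=1e-12)
        assert est == pytest.approx(ob.lne_estimate([b, a], w, prior), abs=1e-12)

    def test_one_measurement_all_models_coincide(self, prior):
        for t_m in (640.0, 820.0, 970.0):
            ref = ob.bls1_map(t_m, 0.1, prior)
            assert ob.ekf_estimate([t_m], 0.1, prior) == pytest.approx(ref, abs=1e-9)
            assert ob.lne_estimate([t_m], 0.1, prior) == pytest.approx(ref, abs=1e-9)


class TestResponseDensities:
    def test_production_peak_location_and_value(self):
        te, w_p, b = 800.0, 0.1, 25.0
        grid = np.linspace(0, 2000, 8001)
        dens = ob.production_density(grid, te, w_p, b)
        assert grid[np.argmax(dens)] == pytest.approx(te + b, abs=0.5)
        assert ob.production_density(te, te, w_p, 0.0) == pytest.approx(
            1.0 / (math.sqrt(2 * math.pi) * w_p * te)
        )

    def test_production_normalizes(self):
        total, _ = quad(lambda tp: ob.production_density(tp, 800.0, 0.12, 30.0), -2000, 5000)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_mixture_degenerate_cases(self):
        grid = np.linspace(0, 2000, 501)
        p0 = make_params(gamma=0.0)
        np.testing.assert_allclose(
            ob.response_mixture_density(grid, 800.0, p0),
            ob.production_density(grid, 800.0, p0.w_p, p0.b),
        )
        p1 = make_params(gamma=1.0)
        np.testing.assert_allclose(
            ob.response_mixture_density(grid, 800.0, p1), 1.0 / 2000.0
        )
        assert ob.response_mixture_density(2500.0, 800.0, p1) == 0.0

    def test_mixture_tail_is_lapse_floor(self):
        p = make_params(gamma=0.05)
        assert ob.response_mixture_density(1999.0, 700.0, p) == pytest.approx(
            0.05 / 2000.0, rel=1e-6
        )

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        tp=st.floats(0, 2000),
        te=st.floats(600, 1000),
        gamma=st.floats(0.001, 0.3),
    )
    def test_mixture_floor_property(self, tp, te, gamma):
        p = make_params(gamma=gamma)
        assert ob.response_mixture_density(tp, te, p) >= gamma / 2000.0 * (1 - 1e-12)


class TestBls1Table:
    def test_matches_direct_evaluation(self, prior, rng):
        table = ob.Bls1Table(0.1, prior, lo=0.0, hi=2000.0)
        probes = rng.uniform(0.0, 2000.0, 200)
        np.testing.assert_allclose(
            table(probes), ob.bls1_map(probes, 0.1, prior), atol=5e-4
        )

    def test_monotone_and_range_checked(self, prior):
        table = ob.Bls1Table(0.1, prior, lo=100.0, hi=1500.0)
        assert np.all(np.diff(table(np.linspace(400, 1500, 500))) > 0)
        with pytest.raises(ValueError, match="range"):
            table(1501.0)

    def test_csv_export_round_trips(self, prior, tmp_path):
        table = ob.Bls1Table(0.1, prior, lo=600.0, hi=1000.0, step=10.0)
        path = tmp_path / "table.csv"
        table.to_csv(path)
        loaded = np.loadtxt(path, delimiter=",", skiprows=1)
        np.testing.assert_allclose(loaded[:, 0], table.args)
        np.testing.assert_allclose(loaded[:, 1], table.values)
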