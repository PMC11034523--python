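"""Survival-model fitting: round trips, recovery from noise, comparison."""

import math

import numpy as np
import pytest

from twopac.core import TwoPhaseParams, survival_fraction
from twopac.fitting import (
    GompertzParams,
    SurvivalCurve,
    WeibullParams,
    compare_models,
    fit_gompertz,
    fit_smurf_line,
    fit_two_phase,
    fit_weibull,
    gompertz_survival,
    r_squared,
    weibull_survival,
)
from twopac.simulate import empirical_survival, simulate_cohort


def curve_from(fn, horizon=2000, floor=1e-3) -> SurvivalCurve:
    """Daily-sampled survival curve until the fraction falls below `floor`."""
    t = np.arange(0.0, float(horizon))
    S = fn(t)
    keep = S >= floor
    return SurvivalCurve(times=t[keep], alive_fraction=S[keep])


class TestRSquared:
    def test_perfect_prediction(self):
        obs = np.array([1.0, 0.7, 0.3, 0.1])
        assert r_squared(obs, obs) == 1.0

    def test_mean_prediction_scores_zero(self):
        obs = np.array([1.0, 0.8, 0.5, 0.2])
        assert r_squared(obs, np.full(4, obs.mean())) == pytest.approx(0.0, abs=1e-12)

    def test_hand_arithmetic(self):
        obs = [1.0, 0.8, 0.5, 0.2]
        pred = [0.9, 0.8, 0.6, 0.1]
        assert r_squared(obs, pred) == pytest.approx(1 - 0.03 / 0.3675, abs=1e-12)
        assert r_squared(obs, pred) == pytest.approx(0.9184, abs=5e-5)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            r_squared([0.5, 0.5], [0.4, 0.6])


class TestSmurfLine:
    def test_exact_two_point_line(self):
        import pandas as pd

        counts = pd.DataFrame(
            {"time": [10.0, 20.0], "n_smurf": [10, 20], "n_nonsmurf": [90, 80]}
        )
        line = fit_smurf_line(counts)
        assert line.a == pytest.approx(0.01, abs=1e-12)
        assert line.b == pytest.approx(0.0, abs=1e-12)

    def test_single_time_point_rejected(self):
        import pandas as pd

        counts = pd.DataFrame({"time": [10.0], "n_smurf": [5], "n_nonsmurf": [95]})
        with pytest.raises(ValueError):
            fit_smurf_line(counts)

    def test_saturated_points_excluded(self):
        import pandas as pd

        counts = pd.DataFrame(
            {
                "time": [10.0, 20.0, 200.0],
                "n_smurf": [10, 20, 7],
                "n_nonsmurf": [90, 80, 0],
            }
        )
        line = fit_smurf_line(counts)
        assert line.a == pytest.approx(0.01, abs=1e-12)

    def test_recovers_generating_line_from_cohort(self):
        params = TwoPhaseParams.from_line(0.0041, -0.012, k=0.3)
        rec = simulate_cohort(params, 50_000, seed=2)
        from twopac.simulate import smurf_assay

        counts = smurf_assay(rec, np.arange(0.0, 90.0))
        line = fit_smurf_line(counts)
        assert line.a == pytest.approx(0.0041, rel=0.05)
        assert line.t0 == pytest.approx(params.t0, abs=1.0)


class TestTwoPhaseFit:
    def test_noise_free_self_fit_reproduces_curve(self, default_params):
        curve = curve_from(lambda t: survival_fraction(t, default_params))
        res = fit_two_phase(curve)
        assert res.sse <= 1e-10
        assert res.r2 >= 1.0 - 1e-8
        # the death-slope product and the onset age are the identified
        # quantities on a curve that ends before Smurf saturation
        assert res.params["a"] * res.params["k"] == pytest.approx(
            default_params.a * default_params.k, rel=1e-4
        )
        assert res.params["t0"] == pytest.approx(default_params.t0, abs=1e-3)

    def test_fixed_k_recovers_all_parameters(self, default_params):
        curve = curve_from(lambda t: survival_fraction(t, default_params))
        res = fit_two_phase(curve, k_mode="fixed", k_value=default_params.k)
        assert res.params["a"] == pytest.approx(default_params.a, rel=1e-4)
        assert res.params["t0"] == pytest.approx(default_params.t0, abs=1e-3)
        assert res.r2 >= 1.0 - 1e-8

    def test_free_fit_identifiable_when_tail_is_observed(self):
        """With the exponential tail in view, all three parameters return."""
        rng = np.random.default_rng(99)
        for _ in range(10):
            a = 10.0 ** rng.uniform(-2, math.log10(0.05))
            k = a * rng.uniform(2.0, 8.0)  # saturation survival above the floor
            t0 = rng.uniform(2.0, 20.0)
            gen = TwoPhaseParams(a=a, t0=t0, k=k)
            curve = curve_from(lambda t: survival_fraction(t, gen))
            res = fit_two_phase(curve)
            assert res.params["a"] == pytest.approx(a, rel=5e-4)
            assert res.params["k"] == pytest.approx(k, rel=5e-4)
            assert res.params["t0"] == pytest.approx(t0, rel=5e-4)

    def test_underdetermined_curve_rejected(self):
        curve = SurvivalCurve(np.array([0.0, 10.0, 20.0]), np.array([1.0, 0.6, 0.2]))
        with pytest.raises(ValueError):
            fit_two_phase(curve)

    def test_curve_not_reaching_half_rejected(self):
        curve = SurvivalCurve(np.arange(5.0), np.array([1.0, 0.9, 0.85, 0.8, 0.75]))
        with pytest.raises(ValueError):
            fit_two_phase(curve)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_recovers_slope_from_noisy_cohort(self, default_params, seed):
        """Sampling noise at n = 10,000 leaves the slope within 5%."""
        rec = simulate_cohort(default_params, 10_000, seed=seed)
        grid = np.arange(0.0, rec.death_time.max() + 1.0)
        curve = empirical_survival(rec, grid)
        res = fit_two_phase(curve, k_mode="fixed", k_value=default_params.k)
        assert res.params["a"] == pytest.approx(default_params.a, rel=0.05)


class TestGompertzFit:
    def test_round_trip_of_published_values(self):
        gen = GompertzParams(a0=0.0061, g=0.1029)
        curve = curve_from(lambda t: gompertz_survival(t, gen))
        res = fit_gompertz(curve)
        assert res.params["a0"] == pytest.approx(0.0061, rel=5e-4)
        assert res.params["g"] == pytest.approx(0.1029, rel=5e-4)
        assert res.r2 >= 1.0 - 1e-10

    def test_constant_hazard_limit_drives_g_small(self):
        curve = curve_from(lambda t: np.exp(-0.05 * np.asarray(t)))
        res = fit_gompertz(curve)
        assert res.converged
        assert res.params["g"] < 1e-2
        assert res.params["a0"] == pytest.approx(0.05, rel=0.05)


class TestWeibullFit:
    def test_round_trip_of_published_values(self):
        gen = WeibullParams(scale_a=0.000327, shape_k=2.729554)
        curve = curve_from(lambda t: weibull_survival(t, gen))
        res = fit_weibull(curve)
        assert res.params["scale_a"] == pytest.approx(0.000327, rel=5e-4)
        assert res.params["shape_k"] == pytest.approx(2.729554, rel=5e-4)
        assert res.r2 >= 1.0 - 1e-10

    def test_exponential_special_case(self):
        gen = WeibullParams(scale_a=0.03, shape_k=1.0)
        curve = curve_from(lambda t: weibull_survival(t, gen))
        res = fit_weibull(curve)
        assert res.params["shape_k"] == pytest.approx(1.0, abs=1e-3)

    def test_shape_agrees_with_likelihood_oracle(self):
        """Curve-based least squares vs maximum likelihood on raw deaths.

        The oracle fits the same family by a different route (individual
        death times, likelihood maximisation via lifelines); the two shape
        estimates must agree to a few percent at large n.
        """
        from lifelines import WeibullFitter
        from scipy import stats

        shape, lam = 2.7, 35.0
        deaths = stats.weibull_min(c=shape, scale=lam).rvs(
            50_000, random_state=np.random.default_rng(21)
        )
        wf = WeibullFitter().fit(deaths)
        import pandas as pd

        rec = pd.DataFrame({"death_time": deaths})
        grid = np.arange(0.0, deaths.max() + 1.0)
        curve = empirical_survival(rec, grid)
        keep = curve.alive_fraction >= 1e-3
        curve = SurvivalCurve(curve.times[keep], curve.alive_fraction[keep])
        ours = fit_weibull(curve)
        assert ours.params["shape_k"] == pytest.approx(wf.rho_, rel=0.05)


class TestRoundTripIdentifiability:
    """Noise-free curves generated by each family return their parameters."""

    def test_gompertz_family(self):
        rng = np.random.default_rng(31)
        for _ in range(50):
            a0 = 10.0 ** rng.uniform(-4, -2)
            g = 10.0 ** rng.uniform(math.log10(0.03), math.log10(0.3))
            gen = GompertzParams(a0=a0, g=g)
            res = fit_gompertz(curve_from(lambda t: gompertz_survival(t, gen)))
            assert res.params["a0"] == pytest.approx(a0, rel=5e-4)
            assert res.params["g"] == pytest.approx(g, rel=5e-4)

    def test_weibull_family(self):
        rng = np.random.default_rng(32)
        for _ in range(50):
            shape = rng.uniform(1.0, 4.0)
            t_med = rng.uniform(20.0, 60.0)
            scale = math.log(2.0) / t_med**shape
            gen = WeibullParams(scale_a=scale, shape_k=shape)
            res = fit_weibull(curve_from(lambda t: weibull_survival(t, gen)))
            assert res.params["scale_a"] == pytest.approx(scale, rel=5e-4)
            assert res.params["shape_k"] == pytest.approx(shape, rel=5e-4)

    def test_two_phase_family_with_known_smurf_mortality(self):
        rng = np.random.default_rng(33)
        for _ in range(50):
            a = 10.0 ** rng.uniform(-3, math.log10(0.02))
            t0 = rng.uniform(2.0, 30.0)
            k = 10.0 ** rng.uniform(-1, 0)
            gen = TwoPhaseParams(a=a, t0=t0, k=k)
            res = fit_two_phase(
                curve_from(lambda t: survival_fraction(t, gen)),
                k_mode="fixed",
                k_value=k,
            )
            assert res.params["a"] == pytest.approx(a, rel=5e-4)
            assert res.params["t0"] == pytest.approx(t0, rel=5e-4)


class TestUnitInvariance:
    def test_rescaling_time_rescales_parameters_only(self):
        """Refitting in hours changes parameters by dimensional factors."""
        gen = GompertzParams(a0=0.0061, g=0.1029)
        days = curve_from(lambda t: gompertz_survival(t, gen))
        hours = SurvivalCurve(days.times * 24.0, days.alive_fraction)
        rd = fit_gompertz(days)
        rh = fit_gompertz(hours)
        assert rh.params["a0"] == pytest.approx(rd.params["a0"] / 24.0, rel=1e-5)
        assert rh.params["g"] == pytest.approx(rd.params["g"] / 24.0, rel=1e-5)
        assert abs(rd.r2 - rh.r2) < 1e-8

        wgen = WeibullParams(scale_a=0.000327, shape_k=2.729554)
        wdays = curve_from(lambda t: weibull_survival(t, wgen))
        whours = SurvivalCurve(wdays.times * 24.0, wdays.alive_fraction)
        wd = fit_weibull(wdays)
        wh = fit_weibull(whours)
        assert wh.params["shape_k"] == pytest.approx(wd.params["shape_k"], rel=1e-5)
        assert wh.params["scale_a"] == pytest.approx(
            wd.params["scale_a"] / 24.0 ** wd.params["shape_k"], rel=1e-4
        )
        assert abs(wd.r2 - wh.r2) < 1e-8


class TestCompareModels:
    def test_two_phase_wins_on_its_own_data(self, default_params):
        curve = curve_from(lambda t: survival_fraction(t, default_params))
        ranked = compare_models(curve)
        assert ranked[0].model_name == "2pac"
        assert ranked[0].r2 >= 1.0 - 1e-8

    def test_gompertz_wins_on_its_own_data(self):
        gen = GompertzParams(a0=0.0061, g=0.1029)
        curve = curve_from(lambda t: gompertz_survival(t, gen))
        ranked = compare_models(curve)
        assert ranked[0].model_name == "gompertz"

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_all_models_fit_simulated_cohorts_well(self, default_params, seed):
        """All three families reach r2 > 0.99 on two-phase cohorts."""
        rec = simulate_cohort(default_params, 10_000, seed=seed)
        grid = np.arange(0.0, rec.death_time.max() + 1.0)
        curve = empirical_survival(rec, grid)
        ranked = compare_models(curve)
        for res in ranked:
            assert res.r2 > 0.99

    def test_failures_do_not_abort_comparison(self):
        # a curve ending above 0.5 is unfittable for every family
        curve = SurvivalCurve(np.arange(6.0), np.linspace(1.0, 0.8, 6))
        ranked = compare_models(curve)
        assert len(ranked) == 3
        assert all(not r.converged for r in ranked)
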