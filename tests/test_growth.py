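"""Growth-curve fitting: closed-form properties, oracles, selection."""

import numpy as np
import pytest

from cladodem import growth
from cladodem.growth import (
    CladodeTrajectory,
    GrowthParams,
    bootstrap_params,
    exponential_phase_duration,
    fit_parametric,
    fit_spline,
    gompertz_value,
    logistic_value,
    per_plant_params,
    select_best,
)


def make_traj(t, y, gender="male"):
    return CladodeTrajectory("p1", gender, "c1", np.asarray(t), np.asarray(y))


GRID13 = np.linspace(0.0, 120.0, 13)


class TestModelFunctions:
    def test_gompertz_asymptote(self):
        assert gompertz_value(1e9, 2.0, 10.0, 0.05) == pytest.approx(2.0)

    def test_gompertz_inflection_value_is_A_over_e(self):
        # the inner double exponential equals 1 exactly at t = lam + A/(mu*e)
        A, lam, mu = 2.0, 10.0, 0.05
        t_inf = lam + A / (mu * np.e)
        assert gompertz_value(t_inf, A, lam, mu) == pytest.approx(A / np.e)

    def test_logistic_midpoint_value_is_half_A(self):
        # inner exponent 0 at t = lam + A/(2*mu)
        A, lam, mu = 3.0, 12.0, 0.1
        t_mid = lam + A / (2.0 * mu)
        assert logistic_value(t_mid, A, lam, mu) == pytest.approx(A / 2.0)


class TestParametricFit:
    def test_noiseless_13_point_recovery(self):
        y = gompertz_value(GRID13, 2.0, 10.0, 0.05)
        fit = fit_parametric(make_traj(GRID13, y), "gompertz")
        assert fit.converged and fit.rss <= 1e-10
        assert fit.A == pytest.approx(2.0, abs=1e-6)
        assert fit.lam == pytest.approx(10.0, abs=1e-6)
        assert fit.mu == pytest.approx(0.05, abs=1e-6)

    def test_noisy_fit_beats_dense_grid_search_oracle(self):
        rng = np.random.default_rng(11)
        t = np.linspace(0, 63, 10)
        y = gompertz_value(t, 2.9, 15.0, 0.107) + rng.normal(0, 0.02, t.size)
        fit = fit_parametric(make_traj(t, y), "gompertz")
        # brute-force RSS oracle over a dense parameter box
        As = np.linspace(2.5, 3.3, 40)
        lams = np.linspace(10, 20, 40)
        mus = np.linspace(0.07, 0.15, 40)
        best = np.inf
        for A in As:
            pred = gompertz_value(t[None, None, :], A, lams[:, None, None],
                                  mus[None, :, None])
            rss = ((pred - y) ** 2).sum(axis=-1)
            best = min(best, float(rss.min()))
        assert fit.rss <= best + 1e-6

    def test_day_shift_moves_only_lambda(self):
        rng = np.random.default_rng(5)
        t = np.linspace(0, 63, 10)
        y = gompertz_value(t, 2.9, 15.0, 0.107) + rng.normal(0, 0.01, t.size)
        f0 = fit_parametric(make_traj(t, y), "gompertz")
        f1 = fit_parametric(make_traj(t + 50.0, y), "gompertz")
        assert f1.lam - f0.lam == pytest.approx(50.0, abs=1e-4)
        assert f1.A == pytest.approx(f0.A, abs=1e-6)
        assert f1.mu == pytest.approx(f0.mu, abs=1e-6)

    @pytest.mark.parametrize("truth", ["gompertz", "logistic"])
    def test_aic_identifies_generating_model(self, truth):
        rng = np.random.default_rng(3)
        t = np.linspace(0, 63, 10)
        fun = gompertz_value if truth == "gompertz" else logistic_value
        wins = 0
        n = 40
        for _ in range(n):
            y = fun(t, 2.9, 15.0, 0.107) + rng.normal(0, 0.02, t.size)
            traj = make_traj(t, y)
            fits = {m: fit_parametric(traj, m) for m in ("gompertz", "logistic")}
            if fits[truth].aic < fits[
                "logistic" if truth == "gompertz" else "gompertz"
            ].aic:
                wins += 1
        assert wins >= 0.9 * n

    def test_unknown_model_rejected(self):
        y = gompertz_value(GRID13, 2.0, 10.0, 0.05)
        with pytest.raises(ValueError):
            fit_parametric(make_traj(GRID13, y), "richards")


class TestSpline:
    def test_noiseless_gompertz_within_five_percent(self):
        # a grid reaching deep into the plateau, so the window maximum
        # approximates the asymptote
        y = gompertz_value(GRID13, 2.0, 10.0, 0.05)
        fit = fit_spline(make_traj(GRID13, y))
        assert fit.A == pytest.approx(2.0, rel=0.05)
        assert fit.lam == pytest.approx(10.0, rel=0.05, abs=0.5)
        assert fit.mu == pytest.approx(0.05, rel=0.05)

    def test_constant_trajectory_is_degenerate(self):
        fit = fit_spline(make_traj(np.arange(6.0), np.full(6, 1.3)))
        assert fit.degenerate and fit.mu == 0.0

    def test_linear_trajectory_lambda_is_the_t_intercept(self):
        t = np.arange(8.0)
        y = 0.4 * t - 1.2  # crosses zero at t = 3
        fit = fit_spline(make_traj(t, y))
        assert fit.lam == pytest.approx(3.0, abs=1e-6)
        assert fit.mu == pytest.approx(0.4, abs=1e-6)

    def test_too_few_points_is_a_precondition_error(self):
        with pytest.raises(ValueError):
            make_traj([0, 1, 2, 3], [0, 1, 2, 3])


class TestBootstrapAndSelection:
    def test_bootstrap_reproducible_under_seed(self):
        rng = np.random.default_rng(2)
        t = np.linspace(0, 63, 10)
        y = gompertz_value(t, 2.9, 15.0, 0.107) + rng.normal(0, 0.02, t.size)
        traj = make_traj(t, y)
        b1 = bootstrap_params(traj, "gompertz", n_boot=50, seed=9)
        b2 = bootstrap_params(traj, "gompertz", n_boot=50, seed=9)
        assert b1 == b2

    def test_noiseless_bootstrap_interval_collapses(self):
        y = gompertz_value(GRID13, 2.0, 10.0, 0.05)
        boot = bootstrap_params(make_traj(GRID13, y), "gompertz", n_boot=40, seed=1)
        for lo, hi in boot["ci90"].values():
            assert hi - lo < 1e-6

    def test_noiseless_data_selects_parametric(self):
        y = gompertz_value(GRID13, 2.0, 10.0, 0.05)
        best = select_best(make_traj(GRID13, y), n_boot=40, seed=0)
        assert best.model == "gompertz"

    def test_spline_returned_when_parametric_fails(self, monkeypatch):
        y = gompertz_value(GRID13, 2.0, 10.0, 0.05)
        traj = make_traj(GRID13, y)
        monkeypatch.setattr(
            growth, "fit_parametric",
            lambda *a, **k: GrowthParams(model="gompertz", converged=False),
        )
        best = select_best(traj, n_boot=10, seed=0)
        assert best.model == "spline"


class TestDerivedQuantities:
    def test_exponential_phase_arithmetic(self):
        assert exponential_phase_duration((2.0, 0.0, 0.1)) == pytest.approx(20.0)

    def test_doubling_mu_halves_duration(self):
        d1 = exponential_phase_duration((2.0, 5.0, 0.05))
        d2 = exponential_phase_duration((2.0, 5.0, 0.10))
        assert d1 == pytest.approx(2 * d2)

    def test_nonpositive_mu_rejected(self):
        with pytest.raises(ValueError):
            exponential_phase_duration((2.0, 5.0, 0.0))

    def test_per_plant_means_and_weights(self):
        import pandas as pd

        fits = pd.DataFrame(
            {
                "plant_id": ["p1", "p1", "p2"],
                "gender": ["male", "male", "female"],
                "cladode_id": ["c1", "c2", "c1"],
                "A": [1.0, 3.0, 5.0],
                "lam": [10.0, 14.0, 9.0],
                "mu": [0.1, 0.3, 0.2],
            }
        )
        pp = per_plant_params(fits).set_index("plant_id")
        assert pp.loc["p1", "A"] == pytest.approx(2.0)
        assert pp.loc["p1", "n_cladodes"] == 2
        assert pp.loc["p2", "A"] == pytest.approx(5.0)
        assert pp.loc["p2", "n_cladodes"] == 1

    def test_fit_table_invariant_to_row_order(self, small_bundle):
        from cladodem.growth import fit_growth_table

        df = small_bundle.growth
        f1, _ = fit_growth_table(df, n_boot=0, seed=0, selection="aic")
        shuffled = df.sample(frac=1.0, random_state=0)
        f2, _ = fit_growth_table(shuffled, n_boot=0, seed=0, selection="aic")
        merged = f1.merge(f2, on=["plant_id", "cladode_id"], suffixes=("_a", "_b"))
        assert np.allclose(merged.A_a, merged.A_b)
        assert np.allclose(merged.mu_a, merged.mu_b)
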