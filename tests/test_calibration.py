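"""Calibration layouts, objective and (small-scale) fitting."""

import numpy as np
import pytest

from phenoflex import (CalibrationProblem, CultivarRequirements, Observation,
                       OptimizerBudget, TruthSpec, build_parameter_vector,
                       calibrate, decode_vector, default_bounds,
                       generate_bloom_observations, objective_rmse,
                       observations_for_calibration)
from phenoflex.calibration import (CONSTANTS, build_layout, _stacks,
                                   bounds_for_layout)


def make_problem(seasons, scheme="baseline", cultivars=("a", "b", "c"),
                 n_obs=4, **kwargs):
    years = sorted(seasons)[:n_obs]
    obs = tuple(Observation(cultivar=c, season=y, observed_doy=80.0 + 2 * i,
                            series=seasons[y])
                for i, c in enumerate(cultivars) for y in years)
    return CalibrationProblem(scheme=scheme, observations=obs, **kwargs)


class TestBoundsAndLayout:
    def test_default_bounds_table(self):
        b = default_bounds()
        assert b["yc"] == (5.0, 80.0)
        assert b["zc"] == (100.0, 700.0)
        assert b["s1"] == (0.1, 1.2)
        assert b["theta_c"] == (286.0, 287.0)
        assert b["tau"] == (16.0, 48.0)
        assert b["pie_c"] == (24.0, 50.0)
        assert b["Tf"] == (2.0, 10.0)
        assert b["slope"] == (1.2, 5.0)
        assert b["Tb"] == (0.0, 10.0)
        assert b["Tu"] == (15.0, 30.0)

    def test_fixed_constants(self):
        assert CONSTANTS == {"theta_star": 279.0, "Tc": 36.0}

    @pytest.mark.parametrize("scheme,k,expected", [
        ("baseline", 6, 18),       # 3 per cultivar
        ("baseline", 3, 9),
        ("cultivar_fit", 1, 10),   # all free parameters of one cultivar
        ("cultivar_fit", 3, 30),
        ("combined_fit", 3, 16),   # 3K + 7 shared
        ("combined_fit", 1, 10),
    ])
    def test_vector_lengths(self, seasons_5yr, scheme, k, expected):
        cultivars = tuple(f"cv{i}" for i in range(k))
        problem = make_problem(seasons_5yr, scheme, cultivars)
        layout, x0 = build_parameter_vector(problem)
        assert layout.size == expected
        assert x0.size == expected
        lo, hi = np.array(bounds_for_layout(problem, layout)).T
        assert np.all(x0 >= lo) and np.all(x0 <= hi)

    def test_combined_fit_across_species_rejected(self, seasons_5yr):
        problem = make_problem(
            seasons_5yr, "combined_fit", ("a", "b"),
            species_map={"a": "almond", "b": "cherry"})
        with pytest.raises(ValueError, match="per species"):
            build_parameter_vector(problem)

    def test_encode_decode_round_trip(self, seasons_5yr):
        for scheme in ("baseline", "cultivar_fit", "combined_fit"):
            problem = make_problem(seasons_5yr, scheme)
            layout, x0 = build_parameter_vector(problem)
            named = layout.decode_named(x0)
            np.testing.assert_array_equal(layout.encode(named), x0)


class TestObjective:
    def test_zero_on_self_consistent_observations(self, seasons_5yr):
        """Noise-free observations generated by the model itself give an
        objective at the truth vector within the sub-day convention."""
        truth = TruthSpec(obs_noise_sd=0.0)
        phen = generate_bloom_observations(seasons_5yr, truth, seed=0)
        obs = observations_for_calibration(phen, seasons_5yr)
        problem = CalibrationProblem(scheme="combined_fit",
                                     observations=tuple(obs))
        layout = build_layout(problem)
        values = {f"shared:{k}": v for k, v in [
            ("theta_c", truth.shared_chill.theta_c),
            ("tau", truth.shared_chill.tau),
            ("pie_c", truth.shared_chill.pie_c),
            ("Tf", truth.Tf), ("slope", truth.slope),
            ("Tb", truth.heat.Tb), ("Tu", truth.heat.Tu)]}
        for c, r in truth.cultivars.items():
            values |= {f"{c}:yc": r.yc, f"{c}:zc": r.zc, f"{c}:s1": r.s1}
        f = objective_rmse(layout.encode(values), problem, layout)
        # continuous predictions vs integer days: residuals within half a day
        assert f <= 0.5

    def test_matches_hand_recomputed_rmse(self, seasons_5yr, default_chill,
                                          default_heat):
        from phenoflex import simulate_season
        from phenoflex._kernels import bloom_time_continuous
        from phenoflex.constants import KELVIN_OFFSET

        problem = make_problem(seasons_5yr, "baseline", ("only",), n_obs=4)
        layout, _ = build_parameter_vector(problem)
        vec = layout.encode({"only:yc": 30.0, "only:zc": 250.0,
                             "only:s1": 0.5})
        f = objective_rmse(vec, problem, layout)
        req = CultivarRequirements(yc=30.0, zc=250.0, s1=0.5)
        sq = []
        for o in problem.observations:
            c, h = default_chill, default_heat
            # calibration quantizes hourly temperatures to 0.01 degC
            temps = np.rint(o.series.temps_c / 0.01) * 0.01
            hours, _ = bloom_time_continuous(
                temps, c.E0, c.E1, c.A0, c.A1,
                c.Tf + KELVIN_OFFSET, c.slope, h.Tb, h.Tu, h.Tc,
                req.yc, req.zc, req.s1)
            assert hours >= 0
            pred = o.series.start_doy + hours / 24.0
            sq.append((pred - (o.observed_doy + 0.5)) ** 2)
        assert f == pytest.approx(float(np.sqrt(np.mean(sq))), abs=1e-9)

    def test_infeasible_vector_returns_finite_penalty(self, seasons_5yr):
        problem = make_problem(seasons_5yr, "combined_fit")
        layout, x0 = build_parameter_vector(problem)
        bad = x0.copy()
        bad[layout.index("shared:tau")] = -5.0  # invalid intermediate params
        f = objective_rmse(bad, problem, layout)
        assert np.isfinite(f) and f >= 1e5

    def test_no_bloom_penalty_dominates(self, seasons_5yr):
        problem = make_problem(seasons_5yr, "baseline", ("only",), n_obs=2)
        layout, _ = build_parameter_vector(problem)
        blooms = layout.encode({"only:yc": 30.0, "only:zc": 200.0,
                                "only:s1": 0.5})
        never = layout.encode({"only:yc": 80.0, "only:zc": 700.0,
                               "only:s1": 1.2})
        f_bloom = objective_rmse(blooms, problem, layout)
        f_never = objective_rmse(never, problem, layout)
        assert f_never > f_bloom
        assert f_never > 30.0


class TestCalibrate:
    def test_degenerate_bounds_return_that_point(self, seasons_5yr):
        problem = make_problem(seasons_5yr, "baseline", ("only",), n_obs=3)
        point = {"yc": (30.0, 30.0), "zc": (250.0, 250.0), "s1": (0.5, 0.5)}
        bounds = default_bounds() | point
        problem = CalibrationProblem(scheme="baseline",
                                     observations=problem.observations,
                                     bounds=bounds, seed=1)
        fit = calibrate(problem)
        assert fit.params["only"].req.yc == 30.0
        layout = build_layout(problem)
        expected = objective_rmse(fit.vector, problem, layout)
        assert fit.objective == pytest.approx(expected)

    def test_noise_free_baseline_recovery(self, seasons_5yr):
        """The baseline scheme refits requirement parameters of synthetic
        noise-free observations to within a day at a modest budget."""
        truth = TruthSpec(obs_noise_sd=0.0)
        phen = generate_bloom_observations(seasons_5yr, truth, seed=0)
        # regenerate observations using the default submodels as the truth
        from phenoflex.params import ModelParams

        problem0 = CalibrationProblem(
            scheme="baseline",
            observations=tuple(observations_for_calibration(phen, seasons_5yr)))
        default_models = {
            c: ModelParams(chill=problem0.default_chill,
                           heat=problem0.default_heat,
                           req=CultivarRequirements(yc=30.0 + 5 * i,
                                                    zc=200.0 + 40 * i,
                                                    s1=0.5))
            for i, c in enumerate(("early", "late"))}
        from phenoflex import simulate_model

        obs = []
        for c, m in default_models.items():
            for year, s in seasons_5yr.items():
                p = simulate_model(s, m)
                if p.bloomed:
                    obs.append(Observation(cultivar=c, season=year,
                                           observed_doy=float(p.bloom_doy),
                                           series=s))
        problem = CalibrationProblem(
            scheme="baseline", observations=tuple(obs), seed=7,
            budget=OptimizerBudget(popsize=10, maxiter=60))
        fit = calibrate(problem)
        assert fit.objective <= 1.0

    def test_same_seed_reproducible(self, seasons_5yr):
        problem = make_problem(
            seasons_5yr, "baseline", ("only",), n_obs=3, seed=5,
            budget=OptimizerBudget(popsize=5, maxiter=10, polish_maxfev=200))
        a = calibrate(problem)
        b = calibrate(problem)
        np.testing.assert_array_equal(a.vector, b.vector)
        assert a.objective == b.objective

    def test_scheme_nesting_on_shared_truth(self, seasons_5yr):
        """Richer parameterizations fit calibration data at least as well:
        cultivar-fit <= combined-fit <= baseline (+ optimizer-noise
        tolerance), on data generated from one shared submodel."""
        truth = TruthSpec(obs_noise_sd=1.0)
        phen = generate_bloom_observations(seasons_5yr, truth, seed=21)
        obs = tuple(observations_for_calibration(phen, seasons_5yr))
        budgets = {
            # per-cultivar searches are low-dimensional; the joint
            # combined-fit search gets its full rescue pipeline
            "baseline": OptimizerBudget(popsize=8, maxiter=60,
                                        polish_maxfev=600),
            "cultivar_fit": OptimizerBudget(popsize=10, maxiter=120,
                                            polish_maxfev=1500),
            "combined_fit": OptimizerBudget(popsize=10, maxiter=120,
                                            polish_maxfev=1500,
                                            scan_keep=4, zoom_maxiter=60),
        }
        objectives = {}
        for scheme, budget in budgets.items():
            problem = CalibrationProblem(scheme=scheme, observations=obs,
                                         seed=13, budget=budget)
            objectives[scheme] = calibrate(problem).objective
        tol = 0.5  # optimizer noise at fixed seed
        assert objectives["cultivar_fit"] <= objectives["combined_fit"] + tol
        assert objectives["combined_fit"] <= objectives["baseline"] + tol

    def test_local_only_budget_requires_x0(self, seasons_5yr):
        problem = make_problem(
            seasons_5yr, "baseline", ("only",), n_obs=3,
            budget=OptimizerBudget(global_stage=False))
        with pytest.raises(ValueError):
            calibrate(problem)
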