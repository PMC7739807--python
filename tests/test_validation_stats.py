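"""Correlations, OLS fits, the model grid, and LOSO-CV aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from runload.errors import (
    CollinearityError,
    DataError,
    DegenerateSplitError,
    UndefinedCorrelationError,
)
from runload.load_metrics import SessionSummary
from runload.validation_stats import (
    CVResult,
    fit_linear,
    loso_cv,
    model_grid,
    pearson_r2,
    relative_error,
    two_step_mean,
)


def make_session(runner, session, load, duration=40.0, distance=7000.0,
                 speed=3.0, n_steps=7000):
    return SessionSummary(
        runner_id=runner,
        session_id=session,
        duration_min=duration,
        distance_m=distance,
        avg_speed_mps=speed,
        n_steps=n_steps,
        cumulative_load_g=load,
        mean_acc_v_g=load / n_steps,
        sd_acc_v_g=0.5,
    )


def random_sessions(rng, n_runners=4, max_sessions=5):
    sessions = []
    for r in range(n_runners):
        for s in range(int(rng.integers(1, max_sessions + 1))):
            duration = float(rng.uniform(20, 120))
            speed = float(rng.uniform(2, 4.5))
            n_steps = int(duration * (150 + 10 * speed))
            load = float(n_steps * rng.uniform(4, 8))
            sessions.append(
                make_session(
                    f"R{r}", f"R{r}-S{s}", load, duration,
                    speed * duration * 60, speed, n_steps,
                )
            )
    return sessions


class TestPearsonR2:
    def test_exact_linear_relation(self):
        x = np.arange(10.0)
        assert pearson_r2(x, 2 * x + 1) == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_vectors(self):
        x = np.array([1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        assert pearson_r2(x, y) == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson_r2(np.ones(5), np.arange(5.0))

    def test_equals_simple_ols_r_squared(self, rng):
        x = rng.uniform(0, 10, 200)
        y = 1.5 * x + rng.normal(0, 2, 200)
        fit = fit_linear(x[:, None], y)
        assert pearson_r2(x, y) == pytest.approx(fit.r_squared, rel=1e-9)


class TestFitLinear:
    def test_two_point_interpolation(self):
        fit = fit_linear(np.array([[0.0], [1.0]]), np.array([3.0, 5.0]))
        assert fit.coefficients == pytest.approx([3.0, 2.0])
        assert fit.r_squared == pytest.approx(1.0)

    def test_pure_noise_finds_nothing(self):
        rng = np.random.default_rng(2024)
        X = rng.standard_normal((10_000, 3))
        y = rng.standard_normal(10_000)
        fit = fit_linear(X, y)
        assert fit.r_squared < 0.01
        assert np.all(np.abs(fit.coefficients[1:]) < 3 * fit.stderrs[1:])

    def test_recovers_generating_coefficients(self):
        # per-step features drawn at realistic magnitudes, response built
        # from known coefficients of the acceleration-to-force model
        rng = np.random.default_rng(7)
        n = 4000
        acc_v = rng.normal(2.9, 0.33, n)
        acc_ml = np.abs(rng.normal(0.47, 0.25, n))
        acc_ap = np.abs(rng.normal(0.75, 0.18, n))
        speed = rng.choice([2.22, 3.33, 4.44], n)
        truth = np.array([0.46, 0.62, 0.81, 0.46, 0.01])
        X = np.column_stack([acc_v, acc_ml, acc_ap, speed])
        y = truth[0] + X @ truth[1:] + rng.normal(0, 0.15, n)
        fit = fit_linear(X, y, ("acc_v", "acc_ml", "acc_ap", "speed"))
        for est, se, true in zip(fit.coefficients, fit.stderrs, truth):
            assert abs(est - true) < 2 * se

    def test_collinearity_names_offenders(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(50)
        X = np.column_stack([x, 2 * x, rng.standard_normal(50)])
        with pytest.raises(CollinearityError) as exc:
            fit_linear(X, rng.standard_normal(50), ("a", "a_doubled", "b"))
        assert "a_doubled" in exc.value.columns

    def test_residual_orthogonality(self, rng):
        X = rng.uniform(0, 5, (300, 3))
        y = 1.0 + X @ np.array([0.5, -1.0, 2.0]) + rng.normal(0, 1, 300)
        fit = fit_linear(X, y)
        resid = y - fit.predict(X)
        scale = len(y) * np.abs(X).max()
        for j in range(3):
            assert abs(float(resid @ X[:, j])) / scale < 1e-8


class TestModelGrid:
    def test_exact_steps_response(self):
        rng = np.random.default_rng(1)
        sessions = random_sessions(rng, n_runners=6)
        sessions = [
            make_session(s.runner_id, s.session_id, float(s.n_steps),
                         s.duration_min, s.distance_m, s.avg_speed_mps, s.n_steps)
            for s in sessions
        ]
        grid = model_grid(sessions).set_index("predictors")
        assert grid.loc["n_steps", "r_squared"] == pytest.approx(1.0, abs=1e-9)

    def test_sorted_ascending_and_nested_monotone(self, cohort_seed1):
        _, _, summaries = cohort_seed1
        grid = model_grid(summaries)
        r2 = grid["r_squared"].to_numpy()
        assert np.all(np.diff(r2) >= -1e-12)
        by_subset = {row["predictors"]: row["r_squared"]
                     for row in grid.to_dict("records")}
        nested = [
            ("distance_km", "distance_km+avg_speed_mps"),
            ("duration_min", "duration_min+distance_km"),
            ("n_steps", "avg_speed_mps+n_steps"),
            ("distance_km+n_steps", "duration_min+distance_km+n_steps"),
            ("duration_min+distance_km+n_steps",
             "duration_min+distance_km+avg_speed_mps+n_steps"),
        ]
        for smaller, larger in nested:
            assert by_subset[larger] >= by_subset[smaller] - 1e-12

    def test_empty_subset_rejected(self, cohort_seed1):
        _, _, summaries = cohort_seed1
        with pytest.raises(DataError):
            model_grid(summaries, ((),))


def brute_force_loso(sessions, predictors):
    """Independent LOSO oracle: per-fold normal-equation refit via lstsq."""
    import pandas as pd

    frame = pd.DataFrame(
        [
            {
                "runner_id": s.runner_id,
                "duration_min": s.duration_min,
                "distance_km": s.distance_m / 1000.0,
                "avg_speed_mps": s.avg_speed_mps,
                "n_steps": s.n_steps,
                "load": s.cumulative_load_g,
            }
            for s in sessions
        ]
    )
    runners = list(dict.fromkeys(frame["runner_id"]))
    per_runner = {}
    for runner in runners:
        train = frame[frame["runner_id"] != runner]
        test = frame[frame["runner_id"] == runner]
        A = np.column_stack(
            [np.ones(len(train))] + [train[p].to_numpy() for p in predictors]
        )
        beta, *_ = np.linalg.lstsq(A, train["load"].to_numpy(), rcond=None)
        At = np.column_stack(
            [np.ones(len(test))] + [test[p].to_numpy() for p in predictors]
        )
        per_runner[runner] = float(np.mean(np.abs(test["load"].to_numpy() - At @ beta)))
    global_mae = float(np.mean(list(per_runner.values())))
    mean_load = float(
        np.mean(
            [
                frame.loc[frame["runner_id"] == r, "load"].mean()
                for r in runners
            ]
        )
    )
    return per_runner, global_mae, mean_load, 100.0 * global_mae / mean_load


class TestLosoCV:
    def test_identical_linear_data_zero_error(self):
        sessions = []
        for r, runner in enumerate(["A", "B"]):
            for s in range(3):
                n_steps = 5000 + 1000 * s + 100 * r
                load = 2.0 * n_steps + 10.0  # same exact law for everyone
                sessions.append(
                    make_session(runner, f"{runner}-S{s}", load, n_steps=n_steps)
                )
        cv = loso_cv(sessions, ("n_steps",))
        assert cv.global_mae_g == pytest.approx(0.0, abs=1e-6)
        assert cv.relative_error_pct == pytest.approx(0.0, abs=1e-8)

    def test_two_step_aggregation_defining_case(self):
        errors = {"A": np.array([1.0, 3.0]), "B": np.array([5.0])}
        per_runner = {r: float(np.mean(e)) for r, e in errors.items()}
        assert per_runner == {"A": 2.0, "B": 5.0}
        assert float(np.mean(list(per_runner.values()))) == 3.5
        pooled = float(np.mean(np.concatenate(list(errors.values()))))
        assert pooled == 3.0
        assert two_step_mean(errors) == 3.5

    def test_two_step_equals_pooled_when_balanced(self, rng):
        balanced = {f"R{i}": rng.uniform(0, 10, 4) for i in range(5)}
        pooled = float(np.mean(np.concatenate(list(balanced.values()))))
        assert two_step_mean(balanced) == pytest.approx(pooled, rel=1e-12)

    def test_single_runner_rejected(self):
        sessions = [make_session("A", f"S{i}", 1000.0 * (i + 1)) for i in range(3)]
        with pytest.raises(DegenerateSplitError):
            loso_cv(sessions)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        sessions = random_sessions(rng, n_runners=int(rng.integers(3, 6)))
        predictors = ("duration_min", "distance_km", "avg_speed_mps", "n_steps")
        cv = loso_cv(sessions, predictors)
        per_runner, global_mae, mean_load, rel = brute_force_loso(sessions, predictors)
        for runner, mae in per_runner.items():
            assert cv.per_runner_mae[runner] == pytest.approx(mae, rel=1e-8, abs=1e-8)
        assert cv.global_mae_g == pytest.approx(global_mae, rel=1e-8, abs=1e-8)
        assert cv.aggregated_mean_load_g == pytest.approx(mean_load, rel=1e-8)
        assert cv.relative_error_pct == pytest.approx(rel, rel=1e-8, abs=1e-8)

    def test_invariants_on_result(self, cohort_seed1):
        _, _, summaries = cohort_seed1
        cv = loso_cv(summaries)
        assert cv.global_mae_g == pytest.approx(
            float(np.mean(list(cv.per_runner_mae.values()))), rel=1e-12
        )
        assert cv.relative_error_pct == pytest.approx(
            100 * cv.global_mae_g / cv.aggregated_mean_load_g, rel=1e-12
        )


class TestRelativeError:
    def test_quarter(self):
        assert relative_error(50.0, 200.0) == 25.0

    def test_full_precision_then_rounding(self):
        value = relative_error(10_908.0, 35_271.0)
        assert value == pytest.approx(30.926, abs=0.001)
        assert round(value) == 31

    def test_equal_inputs_are_hundred_percent(self):
        assert relative_error(123.4, 123.4) == 100.0

    def test_zero_load_rejected(self):
        with pytest.raises(DataError):
            relative_error(10.0, 0.0)
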