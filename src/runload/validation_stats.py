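"""The statistical layer: correlations, OLS fits, the spatiotemporal model
grid, and leave-one-subject-out cross-validation (LOSO-CV).

LOSO-CV answers the practically relevant question: how well would a
regression on spatiotemporal parameters predict the cumulative load of a
runner the model has never seen? Errors are aggregated in two steps —
first the mean absolute error within each runner, then the unweighted mean
across runners — so runners who logged many sessions are not overweighted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from runload.errors import (
    CollinearityError,
    DataError,
    DegenerateSplitError,
    UndefinedCorrelationError,
)
from runload.load_metrics import SessionSummary, sessions_frame

#: Spatiotemporal predictors available to the session-load models.
#: Distance is expressed in km and duration in minutes in all model tables.
SPATIOTEMPORAL_PREDICTORS = ("duration_min", "distance_km", "avg_speed_mps", "n_steps")

#: The default model grid: all non-empty predictor subsets actually tabled
#: in the cohort analysis (singletons, selected pairs, and the nested
#: steps-augmented models up to the full four-predictor model).
DEFAULT_GRID: tuple[tuple[str, ...], ...] = (
    ("avg_speed_mps",),
    ("distance_km",),
    ("distance_km", "avg_speed_mps"),
    ("duration_min",),
    ("duration_min", "distance_km"),
    ("duration_min", "avg_speed_mps"),
    ("n_steps",),
    ("avg_speed_mps", "n_steps"),
    ("distance_km", "n_steps"),
    ("duration_min", "distance_km", "n_steps"),
    ("duration_min", "distance_km", "avg_speed_mps", "n_steps"),
)


@dataclass(frozen=True)
class LinearModelFit:
    """An ordinary-least-squares fit with intercept."""

    predictor_names: tuple[str, ...]
    coefficients: np.ndarray  # intercept first, then one per predictor
    stderrs: np.ndarray
    r_squared: float
    n_obs: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return self.coefficients[0] + X @ self.coefficients[1:]


@dataclass(frozen=True)
class CVResult:
    """Leave-one-subject-out errors under two-step aggregation."""

    predictor_names: tuple[str, ...]
    per_runner_mae: dict[str, float]
    global_mae_g: float
    aggregated_mean_load_g: float
    relative_error_pct: float


def pearson_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson product-moment correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise DataError("pearson_r2 expects equal-length 1-D arrays, length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero-variance input")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def fit_linear(
    X: np.ndarray | pd.DataFrame,
    y: np.ndarray,
    predictor_names: tuple[str, ...] | None = None,
) -> LinearModelFit:
    """OLS with intercept; raises :class:`CollinearityError` naming the
    redundant columns when the design matrix is rank deficient."""
    if isinstance(X, pd.DataFrame):
        if predictor_names is None:
            predictor_names = tuple(X.columns)
        X = X.to_numpy(dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.ndim != 2:
        raise DataError("X must be 2-D")
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if predictor_names is None:
        predictor_names = tuple(f"x{i}" for i in range(p))
    if y.shape != (n,):
        raise DataError(f"y has shape {y.shape}, expected ({n},)")
    if n < p + 1:
        raise DataError(f"need at least p + 1 = {p + 1} observations, got {n}")
    design = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(design)
    if rank < p + 1:
        offenders = _dependent_columns(design, predictor_names)
        raise CollinearityError(
            f"design matrix rank {rank} < {p + 1}; dependent columns: {offenders}",
            columns=offenders,
        )
    res = sm.OLS(y, design).fit()
    return LinearModelFit(
        predictor_names=tuple(predictor_names),
        coefficients=np.asarray(res.params, dtype=float),
        stderrs=np.asarray(res.bse, dtype=float),
        r_squared=float(res.rsquared),
        n_obs=n,
    )


def _dependent_columns(design: np.ndarray, names: tuple[str, ...]) -> tuple[str, ...]:
    # A column is flagged when adding it does not increase the rank of the
    # columns before it (intercept included).
    offenders = []
    rank = np.linalg.matrix_rank(design[:, :1])
    for j in range(1, design.shape[1]):
        new_rank = np.linalg.matrix_rank(design[:, : j + 1])
        if new_rank == rank:
            offenders.append(names[j - 1])
        rank = new_rank
    return tuple(offenders)


def _grid_frame(sessions: list[SessionSummary]) -> pd.DataFrame:
    frame = sessions_frame(sessions)
    frame["distance_km"] = frame["distance_m"] / 1000.0
    return frame


def model_grid(
    sessions: list[SessionSummary],
    subsets: tuple[tuple[str, ...], ...] = DEFAULT_GRID,
) -> pd.DataFrame:
    """One OLS fit of cumulative load per predictor subset.

    Returns a table with one row per subset (columns: ``predictors``,
    ``r_squared``, ``n_obs``) sorted by R² ascending, the layout the
    cohort analysis tables use.
    """
    frame = _grid_frame(sessions)
    rows = []
    for subset in subsets:
        if not subset:
            raise DataError("empty predictor subset")
        unknown = set(subset) - set(SPATIOTEMPORAL_PREDICTORS)
        if unknown:
            raise DataError(f"unknown predictors {sorted(unknown)}")
        fit = fit_linear(
            frame[list(subset)], frame["cumulative_load_g"].to_numpy(), tuple(subset)
        )
        rows.append(
            {
                "predictors": "+".join(subset),
                "r_squared": fit.r_squared,
                "n_obs": fit.n_obs,
            }
        )
    out = pd.DataFrame(rows).sort_values("r_squared", kind="stable")
    return out.reset_index(drop=True)


def two_step_mean(values_by_runner: dict[str, np.ndarray]) -> float:
    """Mean within each runner first, then unweighted mean across runners."""
    per_runner = [float(np.mean(v)) for v in values_by_runner.values()]
    return float(np.mean(per_runner))


def loso_cv(
    sessions: list[SessionSummary],
    predictors: tuple[str, ...] = SPATIOTEMPORAL_PREDICTORS,
) -> CVResult:
    """Leave-one-subject-out CV of the session-load regression.

    For each runner, an OLS model is fitted on every other runner's
    sessions (unweighted) and predicts the held-out runner's session
    loads. Absolute errors are aggregated two-step; the mean true load in
    the relative-error denominator is aggregated by the same two-step
    procedure.
    """
    frame = _grid_frame(sessions)
    runners = frame["runner_id"].unique()
    if len(runners) < 2:
        raise DegenerateSplitError("LOSO-CV needs at least 2 runners")
    y = frame["cumulative_load_g"].to_numpy()
    X = frame[list(predictors)].to_numpy(dtype=float)
    abs_errors: dict[str, np.ndarray] = {}
    for runner in runners:
        held = (frame["runner_id"] == runner).to_numpy()
        fit = fit_linear(X[~held], y[~held], tuple(predictors))
        pred = fit.predict(X[held])
        abs_errors[str(runner)] = np.abs(y[held] - pred)
    per_runner = {r: float(np.mean(e)) for r, e in abs_errors.items()}
    global_mae = float(np.mean(list(per_runner.values())))
    loads_by_runner = {
        str(r): frame.loc[frame["runner_id"] == r, "cumulative_load_g"].to_numpy()
        for r in runners
    }
    mean_load = two_step_mean(loads_by_runner)
    return CVResult(
        predictor_names=tuple(predictors),
        per_runner_mae=per_runner,
        global_mae_g=global_mae,
        aggregated_mean_load_g=mean_load,
        relative_error_pct=relative_error(global_mae, mean_load),
    )


def relative_error(global_mae: float, aggregated_mean_load: float) -> float:
    """Relative prediction error, percent: 100 * MAE / mean load.

    Returned at full precision; round to the nearest percent for display.
    """
    if global_mae < 0 or aggregated_mean_load <= 0:
        raise DataError("MAE must be >= 0 and mean load > 0")
    return 100.0 * global_mae / aggregated_mean_load
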