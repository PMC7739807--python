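"""Session- and runner-level load statistics.

The central statistic is the cumulative load of a training session: the
sum over all steps of the per-step peak vertical acceleration, in g. A
session therefore accumulates load through both how often the runner's
foot strikes the ground (volume) and how hard each strike is (magnitude).
Runner-level pooling averages session statistics unweighted, so long
sessions do not dominate a runner's profile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from runload.errors import DataError, EmptySessionError, GroupingError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SessionRecord:
    """One training session: per-step ACC_v peaks plus GPS-style metadata."""

    runner_id: str
    session_id: str
    acc_v_peaks: np.ndarray
    duration_min: float
    distance_m: float
    avg_speed_mps: float

    def __post_init__(self) -> None:
        peaks = np.asarray(self.acc_v_peaks, dtype=float)
        if peaks.ndim != 1 or peaks.size == 0:
            raise EmptySessionError(
                f"session {self.session_id}: empty or non-vector step stream"
            )
        if min(self.duration_min, self.distance_m, self.avg_speed_mps) <= 0:
            raise DataError(f"session {self.session_id}: non-positive metadata")
        object.__setattr__(self, "acc_v_peaks", peaks)

    @property
    def n_steps(self) -> int:
        return int(self.acc_v_peaks.size)


@dataclass(frozen=True)
class SessionSummary:
    """Session-level load statistics plus the spatiotemporal fields."""

    runner_id: str
    session_id: str
    duration_min: float
    distance_m: float
    avg_speed_mps: float
    n_steps: int
    cumulative_load_g: float
    mean_acc_v_g: float
    sd_acc_v_g: float


@dataclass(frozen=True)
class RunnerPool:
    """Unweighted runner-level aggregates over that runner's sessions."""

    runner_id: str
    n_sessions: int
    pooled_cumulative_load_g: float
    pooled_mean_acc_v_g: float
    pooled_sd_acc_v_g: float


def cumulative_load(peaks: np.ndarray) -> float:
    """Cumulative load of a session: the sum of all per-step ACC_v peaks (g)."""
    peaks = np.asarray(peaks, dtype=float)
    if peaks.size == 0:
        raise EmptySessionError("cumulative load of an empty session is undefined")
    if np.any(peaks <= 0):
        raise DataError("per-step peaks must be positive")
    return float(np.sum(peaks))


def session_summary(rec: SessionRecord) -> SessionSummary:
    """Cumulative load plus mean and SD (n-1 denominator) of the step peaks."""
    if rec.n_steps < 2:
        raise DataError(
            f"session {rec.session_id}: SD undefined with {rec.n_steps} step(s)"
        )
    return SessionSummary(
        runner_id=rec.runner_id,
        session_id=rec.session_id,
        duration_min=rec.duration_min,
        distance_m=rec.distance_m,
        avg_speed_mps=rec.avg_speed_mps,
        n_steps=rec.n_steps,
        cumulative_load_g=cumulative_load(rec.acc_v_peaks),
        mean_acc_v_g=float(np.mean(rec.acc_v_peaks)),
        sd_acc_v_g=float(np.std(rec.acc_v_peaks, ddof=1)),
    )


def pool_runner(
    sessions: list[SessionSummary], min_sessions: int = 3
) -> RunnerPool | None:
    """Runner-level pooling: unweighted means of per-session statistics.

    The pooled SD is the mean of the per-session SDs (a within-session
    variability summary), not a variance-weighted combination; see
    :func:`conventional_pooled_sd` for the latter. Runners with fewer than
    ``min_sessions`` sessions return ``None`` (excluded).
    """
    if not sessions:
        raise EmptySessionError("no sessions to pool")
    ids = {s.runner_id for s in sessions}
    if len(ids) != 1:
        raise GroupingError(f"sessions belong to multiple runners: {sorted(ids)}")
    if len(sessions) < min_sessions:
        return None
    return RunnerPool(
        runner_id=sessions[0].runner_id,
        n_sessions=len(sessions),
        pooled_cumulative_load_g=float(np.mean([s.cumulative_load_g for s in sessions])),
        pooled_mean_acc_v_g=float(np.mean([s.mean_acc_v_g for s in sessions])),
        pooled_sd_acc_v_g=float(np.mean([s.sd_acc_v_g for s in sessions])),
    )


def conventional_pooled_sd(sessions: list[SessionSummary]) -> float:
    """Variance-weighted pooled SD across sessions (the textbook meaning).

    sqrt( sum_i (n_i - 1) s_i^2 / sum_i (n_i - 1) ). Provided for contrast
    with the mean-of-SDs pooling used by :func:`pool_runner`.
    """
    if not sessions:
        raise EmptySessionError("no sessions to pool")
    dof = np.array([s.n_steps - 1 for s in sessions], dtype=float)
    var = np.array([s.sd_acc_v_g**2 for s in sessions])
    return float(np.sqrt(np.sum(dof * var) / np.sum(dof)))


def pool_cohort(
    summaries: list[SessionSummary], min_sessions: int = 3
) -> tuple[list[RunnerPool], list[str]]:
    """Pool every runner in a cohort; returns (pools, excluded_runner_ids)."""
    by_runner: dict[str, list[SessionSummary]] = {}
    for s in summaries:
        by_runner.setdefault(s.runner_id, []).append(s)
    pools, excluded = [], []
    for runner_id in sorted(by_runner):
        pool = pool_runner(by_runner[runner_id], min_sessions=min_sessions)
        if pool is None:
            excluded.append(runner_id)
        else:
            pools.append(pool)
    if excluded:
        logger.info(
            "pool_cohort: %d runners excluded with fewer than %d sessions",
            len(excluded),
            min_sessions,
        )
    return pools, excluded


def sessions_frame(summaries: list[SessionSummary]) -> pd.DataFrame:
    """Session table in the canonical column order."""
    cols = [
        "runner_id",
        "session_id",
        "duration_min",
        "distance_m",
        "avg_speed_mps",
        "n_steps",
        "cumulative_load_g",
        "mean_acc_v_g",
        "sd_acc_v_g",
    ]
    return pd.DataFrame(
        [{c: getattr(s, c) for c in cols} for s in summaries], columns=cols
    )


def summaries_from_csv(path) -> list[SessionSummary]:
    """Read a canonical session table (see :func:`sessions_frame`) back in."""
    frame = pd.read_csv(path)
    required = {
        "runner_id",
        "session_id",
        "duration_min",
        "distance_m",
        "avg_speed_mps",
        "n_steps",
        "cumulative_load_g",
        "mean_acc_v_g",
        "sd_acc_v_g",
    }
    missing = required - set(frame.columns)
    if missing:
        raise DataError(f"session table missing columns: {sorted(missing)}")
    return [
        SessionSummary(
            runner_id=str(row.runner_id),
            session_id=str(row.session_id),
            duration_min=float(row.duration_min),
            distance_m=float(row.distance_m),
            avg_speed_mps=float(row.avg_speed_mps),
            n_steps=int(row.n_steps),
            cumulative_load_g=float(row.cumulative_load_g),
            mean_acc_v_g=float(row.mean_acc_v_g),
            sd_acc_v_g=float(row.sd_acc_v_g),
        )
        for row in frame.itertuples()
    ]


def cohort_descriptives(summaries: list[SessionSummary]) -> pd.DataFrame:
    """Median and (min-max) range of the seven session-level descriptives."""
    if not summaries:
        raise EmptySessionError("no sessions")
    frame = sessions_frame(summaries)
    quantities = {
        "duration_min": frame["duration_min"],
        "distance_km": frame["distance_m"] / 1000.0,
        "avg_speed_mps": frame["avg_speed_mps"],
        "n_steps": frame["n_steps"],
        "cumulative_load_g": frame["cumulative_load_g"],
        "mean_acc_v_g": frame["mean_acc_v_g"],
        "sd_acc_v_g": frame["sd_acc_v_g"],
    }
    rows = [
        {
            "quantity": name,
            "median": float(series.median()),
            "min": float(series.min()),
            "max": float(series.max()),
        }
        for name, series in quantities.items()
    ]
    return pd.DataFrame(rows).set_index("quantity")
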