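"""End-to-end workflows: indoor validation and outdoor cohort analysis.

The indoor workflow mirrors the lab protocol: filter the force plate at
45 Hz, segment stances at the 50 N threshold, reconstruct marker
acceleration (20 Hz filters), align the IMU clock by cross-correlation,
extract per-step features, and fit the acceleration-to-force regression.

The outdoor workflow mirrors field monitoring: summarize sessions
(cumulative load, mean/SD of the vertical peaks), pool runners, fit the
spatiotemporal model grid, and run leave-one-subject-out CV.

Every report embeds the fully resolved configuration and seed, so a report
can be reproduced from its own provenance block.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from runload.errors import DataError
from runload.gait_events import (
    StanceInterval,
    StepDetectionConfig,
    detect_contacts_grf,
    detect_steps_acc,
    match_steps,
)
from runload.load_metrics import (
    SessionRecord,
    cohort_descriptives,
    pool_cohort,
    session_summary,
    sessions_frame,
)
from runload.preprocess import (
    FilterSpec,
    SampledTrace,
    lowpass,
    map_interval_between_rates,
    marker_acceleration,
    xcorr_lag,
)
from runload.step_features import (
    StepFeatures,
    features_frame,
    normalize_bw,
    peak_accelerations,
    vgrf_peak,
)
from runload.synthetic import (
    CohortParams,
    TreadmillParams,
    gen_outdoor_cohort,
    gen_treadmill_trial,
)
from runload.validation_stats import (
    DEFAULT_GRID,
    SPATIOTEMPORAL_PREDICTORS,
    fit_linear,
    loso_cv,
    model_grid,
    pearson_r2,
)

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable pipeline constants, with lab-protocol defaults."""

    force_filter: FilterSpec = field(
        default_factory=lambda: FilterSpec(order=3, cutoff_hz=45.0)
    )
    kinematics_filter: FilterSpec = field(
        default_factory=lambda: FilterSpec(order=3, cutoff_hz=20.0)
    )
    detection: StepDetectionConfig = field(default_factory=StepDetectionConfig)
    vgrf_window: tuple[float, float] = (0.4, 0.6)
    min_sessions: int = 3
    max_lag_s: float = 0.2
    max_match_offset_s: float = 0.1
    max_unmatched_fraction: float = 0.2
    signed_vertical: bool = True
    remove_gravity_offset: bool = False

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs: dict[str, Any] = {}
        if "force_filter" in raw:
            kwargs["force_filter"] = FilterSpec(**raw["force_filter"])
        if "kinematics_filter" in raw:
            kwargs["kinematics_filter"] = FilterSpec(**raw["kinematics_filter"])
        if "detection" in raw:
            kwargs["detection"] = StepDetectionConfig(**raw["detection"])
        for key in (
            "vgrf_window",
            "min_sessions",
            "max_lag_s",
            "max_match_offset_s",
            "max_unmatched_fraction",
            "signed_vertical",
            "remove_gravity_offset",
        ):
            if key in raw:
                value = raw[key]
                kwargs[key] = tuple(value) if key == "vgrf_window" else value
        return cls(**kwargs)


class AlignmentError(DataError):
    """Too many steps could not be matched across modalities."""


def process_indoor_trial(
    force: SampledTrace,
    imu: SampledTrace,
    marker: SampledTrace,
    speed_mps: float,
    body_mass_kg: float,
    subject_id: str = "S1",
    config: PipelineConfig | None = None,
) -> tuple[list[StepFeatures], dict[str, Any]]:
    """Run the full indoor extraction on one paired trial.

    Returns the per-step features (one per GRF stance that maps cleanly to
    the IMU timebase) and a diagnostics dict with the recovered lag and
    the step-count bookkeeping of both detectors.
    """
    cfg = config or PipelineConfig()
    force_f = lowpass(force, cfg.force_filter)
    stances = detect_contacts_grf(force_f, cfg.detection)
    force_bw = normalize_bw(force_f, body_mass_kg)

    marker_acc = marker_acceleration(marker.channel(0), cfg.kinematics_filter)
    imu_v = imu.channel(0)
    max_lag = int(round(cfg.max_lag_s * imu.rate))
    lag = xcorr_lag(imu_v, marker_acc, max_lag=max_lag)

    features: list[StepFeatures] = []
    imu_stances: list[StanceInterval] = []
    for idx, stance in enumerate(stances):
        mapped = map_interval_between_rates(stance, force.rate, imu.rate)
        start = mapped.start + lag
        end = mapped.end + lag
        if start < 0 or end > imu.n_samples:
            continue  # stance fell off the lag-shifted IMU record
        imu_stance = StanceInterval(start, end, imu.rate)
        imu_stances.append(imu_stance)
        acc_v, acc_ap, acc_ml = peak_accelerations(
            imu,
            imu_stance,
            signed_vertical=cfg.signed_vertical,
            remove_gravity_offset=cfg.remove_gravity_offset,
        )
        features.append(
            StepFeatures(
                subject_id=subject_id,
                step_index=idx,
                speed_mps=speed_mps,
                stance_s=stance.duration_s,
                vgrf_peak_bw=vgrf_peak(force_bw, stance, cfg.vgrf_window),
                acc_v_g=acc_v,
                acc_ap_g=acc_ap,
                acc_ml_g=acc_ml,
            )
        )

    acc_steps = detect_steps_acc(imu_v, cfg.detection)
    pairs, unmatched_ref, unmatched_cand = match_steps(
        imu_stances, acc_steps, cfg.max_match_offset_s
    )
    n_ref = len(imu_stances)
    if n_ref and len(unmatched_ref) / n_ref > cfg.max_unmatched_fraction:
        raise AlignmentError(
            f"{len(unmatched_ref)}/{n_ref} GRF steps unmatched by the "
            "accelerometer detector; check alignment"
        )
    diagnostics = {
        "lag_samples": lag,
        "n_grf_steps": len(stances),
        "n_imu_steps": len(acc_steps),
        "n_matched": len(pairs),
        "n_unmatched_grf": len(unmatched_ref),
        "n_unmatched_imu": len(unmatched_cand),
    }
    logger.info("indoor trial at %.2f m/s: %s", speed_mps, diagnostics)
    return features, diagnostics


def run_indoor_validation(
    seed: int = 1,
    speeds: tuple[float, ...] = (2.22, 3.33, 4.44),
    n_steps_per_speed: int = 100,
    config: PipelineConfig | None = None,
    treadmill_kwargs: dict[str, Any] | None = None,
) -> dict[str, Any]:
    """Simulate and analyse the indoor validation protocol end to end.

    One paired trial is generated per speed; the report carries per-speed
    mean +/- SD of the four per-step magnitudes, the squared correlations
    of each acceleration axis with the vGRF peak, and the four-predictor
    regression of vGRF peak on ACC_v, ACC_ml, ACC_ap and speed.
    """
    cfg = config or PipelineConfig()
    treadmill_kwargs = dict(treadmill_kwargs or {})
    all_features: list[StepFeatures] = []
    per_speed: dict[str, Any] = {}
    rng = np.random.default_rng(seed)
    for speed in speeds:
        params = TreadmillParams(
            speed_mps=speed,
            n_steps=n_steps_per_speed,
            seed=int(rng.integers(0, 2**31 - 1)),
            **treadmill_kwargs,
        )
        force, imu, marker, _ = gen_treadmill_trial(params)
        feats, diag = process_indoor_trial(
            force, imu, marker, speed, params.body_mass_kg, config=cfg
        )
        all_features.extend(feats)
        frame = features_frame(feats)
        per_speed[f"{speed:.2f}"] = {
            "n_steps": len(feats),
            "diagnostics": diag,
            "means": {
                c: float(frame[c].mean())
                for c in ("vgrf_peak_bw", "acc_v_g", "acc_ap_g", "acc_ml_g")
            },
            "sds": {
                c: float(frame[c].std(ddof=1))
                for c in ("vgrf_peak_bw", "acc_v_g", "acc_ap_g", "acc_ml_g")
            },
        }

    frame = features_frame(all_features)
    vgrf = frame["vgrf_peak_bw"].to_numpy()
    r2 = {
        axis: pearson_r2(frame[col].to_numpy(), vgrf)
        for axis, col in (
            ("acc_v", "acc_v_g"),
            ("acc_ap", "acc_ap_g"),
            ("acc_ml", "acc_ml_g"),
        )
    }
    # speed is constant (collinear with the intercept) in single-speed runs
    if len(set(speeds)) > 1:
        cols, names = ["acc_v_g", "acc_ml_g", "acc_ap_g", "speed_mps"], (
            "acc_v",
            "acc_ml",
            "acc_ap",
            "speed",
        )
    else:
        cols, names = ["acc_v_g", "acc_ml_g", "acc_ap_g"], ("acc_v", "acc_ml", "acc_ap")
    fit = fit_linear(frame[cols], vgrf, names)
    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "workflow": "indoor_validation",
        "seed": seed,
        "config": cfg.to_dict(),
        "n_steps_total": len(all_features),
        "per_speed": per_speed,
        "r_squared": r2,
        "regression": {
            "predictors": list(fit.predictor_names),
            "intercept": float(fit.coefficients[0]),
            "coefficients": {
                name: float(c)
                for name, c in zip(fit.predictor_names, fit.coefficients[1:])
            },
            "r_squared": fit.r_squared,
            "n_obs": fit.n_obs,
        },
    }
    return report


def run_outdoor_analysis(
    records: list[SessionRecord] | None = None,
    seed: int = 1,
    config: PipelineConfig | None = None,
    cohort_kwargs: dict[str, Any] | None = None,
    run_loso: bool = True,
) -> dict[str, Any]:
    """Cohort analysis: descriptives, pooling, model grid, LOSO-CV.

    When ``records`` is None a synthetic cohort is generated with the
    given seed. The LOSO block reports the full four-predictor model and
    the reduced model without step count (duration + distance + speed).
    """
    cfg = config or PipelineConfig()
    if records is None:
        records, _ = gen_outdoor_cohort(
            CohortParams(seed=seed, **(cohort_kwargs or {}))
        )
    summaries = [session_summary(r) for r in records]
    n_runners = len({s.runner_id for s in summaries})
    descriptives = cohort_descriptives(summaries)
    pools, excluded = pool_cohort(summaries, min_sessions=cfg.min_sessions)
    grid = model_grid(summaries, DEFAULT_GRID)

    report: dict[str, Any] = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "workflow": "outdoor_analysis",
        "seed": seed,
        "config": cfg.to_dict(),
        "n_runners": n_runners,
        "n_sessions": len(summaries),
        "n_runners_pooled": len(pools),
        "n_runners_excluded": len(excluded),
        "descriptives": {
            q: {k: float(v) for k, v in row.items()}
            for q, row in descriptives.to_dict("index").items()
        },
        "pooled": {
            "median_pooled_cumulative_load_g": float(
                np.median([p.pooled_cumulative_load_g for p in pools])
            )
            if pools
            else None,
            "median_pooled_mean_acc_v_g": float(
                np.median([p.pooled_mean_acc_v_g for p in pools])
            )
            if pools
            else None,
            "median_pooled_sd_acc_v_g": float(
                np.median([p.pooled_sd_acc_v_g for p in pools])
            )
            if pools
            else None,
        },
        "model_grid": grid.to_dict("records"),
    }
    if run_loso:
        if n_runners < 2:
            raise DataError("LOSO-CV needs at least 2 runners; pass run_loso=False")
        loso_blocks = {}
        for label, predictors in (
            ("full", SPATIOTEMPORAL_PREDICTORS),
            ("no_steps", ("duration_min", "distance_km", "avg_speed_mps")),
        ):
            cv = loso_cv(summaries, predictors)
            loso_blocks[label] = {
                "predictors": list(cv.predictor_names),
                "global_mae_g": cv.global_mae_g,
                "aggregated_mean_load_g": cv.aggregated_mean_load_g,
                "relative_error_pct": cv.relative_error_pct,
                "relative_error_rounded_pct": int(round(cv.relative_error_pct)),
            }
        report["loso_cv"] = loso_blocks
    return report


def write_report(report: dict[str, Any], path: str | Path) -> None:
    """Write a report as stable, human-diffable JSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_session_table(records: list[SessionRecord], path: str | Path) -> None:
    """Write session summaries as the canonical CSV table."""
    frame = sessions_frame([session_summary(r) for r in records])
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False)
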