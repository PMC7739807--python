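"""Synthetic running data with exact ground truth.

Two generators emulate the two study settings:

* :func:`gen_treadmill_trial` — a paired force-plate (1000 Hz) + trunk-IMU
  (200 Hz) + optical-marker (200 Hz) treadmill trial. Each step is a
  half-sine vGRF stance with an optional early impact transient; the
  vertical IMU channel shapes an acceleration burst whose per-step peak is
  an affine map of the step's true vGRF peak plus Gaussian noise, so the
  population r² between the two peak series is a direct generator
  parameter. A constant known lag is inserted between the IMU and the
  force/marker timebases.

* :func:`gen_outdoor_cohort` — a cohort of runners with persistent,
  runner-specific loading styles (log-normal mean vertical peak
  acceleration, a small fraction of "heavy" styles above 10 g), realistic
  session durations and speeds, and exact session bookkeeping
  (distance = speed * duration, steps = cadence * duration).

All ground truth is returned alongside the signals, which makes end-to-end
identity tests of the extraction pipeline possible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from runload.errors import DataError
from runload.gait_events import StanceInterval
from runload.load_metrics import SessionRecord
from runload.preprocess import GRAVITY_MS2, SampledTrace

# Per-speed magnitude calibration: mean and SD of the per-step peaks at the
# three treadmill protocol speeds (BW for force, g for acceleration).
SPEED_GRID = np.array([2.22, 3.33, 4.44])
VGRF_MEAN_BW = np.array([2.44, 2.71, 2.85])
VGRF_SD_BW = np.array([0.21, 0.28, 0.31])
ACC_AP_MEAN_G = np.array([0.59, 0.78, 0.89])
ACC_AP_SD_G = np.array([0.14, 0.16, 0.19])
ACC_ML_MEAN_G = np.array([0.33, 0.50, 0.58])
ACC_ML_SD_G = np.array([0.17, 0.26, 0.29])


@dataclass(frozen=True)
class TreadmillParams:
    """Parameters of one constant-speed treadmill trial."""

    speed_mps: float = 3.33
    n_steps: int = 100
    cadence_spm: float = 170.0
    stance_s: float = 0.25
    body_mass_kg: float = 70.0
    force_rate_hz: float = 1000.0
    imu_rate_hz: float = 200.0
    #: affine acceleration-force link, g = intercept + slope * BW
    acc_slope_g_per_bw: float = 0.794
    acc_intercept_g: float = 0.800
    #: population r² of the per-step ACC_v / vGRF-peak relation across the
    #: three-speed protocol; sets the mapping noise in closed form unless
    #: acc_noise_sd_g is given explicitly.
    target_r2: float = 0.797
    acc_noise_sd_g: float | None = None
    #: white sensor noise added to the IMU trace samples
    imu_white_noise_g: float = 0.01
    #: early impact transient: extra amplitude (BW), onset as stance
    #: fraction, exponential decay time constant (s); amplitude 0 disables
    transient_amp_bw: float = 0.5
    transient_frac: float = 0.15
    transient_tau_s: float = 0.010
    #: constant delay of the IMU clock behind the force/marker clock,
    #: in IMU samples
    imu_lag_samples: int = 11
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_steps < 1:
            raise DataError("n_steps must be >= 1")
        if not (140 <= self.cadence_spm <= 220):
            raise DataError("cadence outside plausible running range [140, 220]")
        if self.stance_s <= 0 or self.body_mass_kg <= 0:
            raise DataError("stance duration and body mass must be positive")
        if not (0 < self.target_r2 < 1):
            raise DataError("target_r2 must lie in (0, 1)")

    def noise_sd(self) -> float:
        """Mapping-noise SD implied by the target population r².

        With acc = a + b*vgrf + e, r² = b² Var(vgrf) / (b² Var(vgrf) + Var(e)),
        so sd(e) = b * sd(vgrf) * sqrt((1 - r²) / r²). Var(vgrf) is the
        pooled (equal-weight mixture) variance over the protocol speeds.
        """
        if self.acc_noise_sd_g is not None:
            return self.acc_noise_sd_g
        var_mix = float(np.mean(VGRF_SD_BW**2) + np.var(VGRF_MEAN_BW))
        return (
            self.acc_slope_g_per_bw
            * np.sqrt(var_mix)
            * np.sqrt((1.0 - self.target_r2) / self.target_r2)
        )


@dataclass(frozen=True)
class TreadmillTruth:
    """Exact per-step ground truth of one generated trial (force timebase)."""

    stances: list[StanceInterval]
    vgrf_peaks_bw: np.ndarray
    acc_v_peaks_g: np.ndarray
    acc_ap_peaks_g: np.ndarray
    acc_ml_peaks_g: np.ndarray
    speed_mps: float
    imu_lag_samples: int


def _peaked_envelope(n: int) -> np.ndarray:
    """Half-sine envelope over n samples whose maximum is exactly 1.0."""
    env = np.sin(np.pi * np.arange(n) / (n - 1))
    return env / env.max()


def _interp_speed(speed: float, table: np.ndarray) -> float:
    return float(np.interp(speed, SPEED_GRID, table))


def gen_treadmill_trial(
    p: TreadmillParams,
) -> tuple[SampledTrace, SampledTrace, SampledTrace, TreadmillTruth]:
    """Generate one treadmill trial: (force N, imu 3-axis g, marker m, truth)."""
    rng = np.random.default_rng(p.seed)
    period_s = 60.0 / p.cadence_spm
    if p.stance_s >= period_s:
        raise DataError("stance duration must be shorter than the step period")
    pad_s = 1.0
    total_s = 2 * pad_s + p.n_steps * period_s
    nf = int(round(total_s * p.force_rate_hz))
    ni = int(round(total_s * p.imu_rate_hz))

    # per-step true peak magnitudes
    mean_bw = _interp_speed(p.speed_mps, VGRF_MEAN_BW)
    sd_bw = _interp_speed(p.speed_mps, VGRF_SD_BW)
    vgrf_bw = rng.normal(mean_bw, sd_bw, p.n_steps)
    while np.any(vgrf_bw <= 0.5):  # keep stances well above the 50 N threshold
        bad = vgrf_bw <= 0.5
        vgrf_bw[bad] = rng.normal(mean_bw, sd_bw, bad.sum())
    acc_v = (
        p.acc_intercept_g
        + p.acc_slope_g_per_bw * vgrf_bw
        + rng.normal(0.0, p.noise_sd(), p.n_steps)
    )
    acc_ap = np.abs(
        rng.normal(
            _interp_speed(p.speed_mps, ACC_AP_MEAN_G),
            _interp_speed(p.speed_mps, ACC_AP_SD_G),
            p.n_steps,
        )
    )
    ml_mag = np.abs(
        rng.normal(
            _interp_speed(p.speed_mps, ACC_ML_MEAN_G),
            _interp_speed(p.speed_mps, ACC_ML_SD_G),
            p.n_steps,
        )
    )
    ml_sign = np.where(np.arange(p.n_steps) % 2 == 0, 1.0, -1.0)  # alternate feet

    # --- force trace (1000 Hz), half-sine stances + optional transient ---
    force = np.zeros(nf)
    n_st = int(round(p.stance_s * p.force_rate_hz))
    if n_st % 2 == 0:
        n_st += 1
    env_f = _peaked_envelope(n_st)
    stances: list[StanceInterval] = []
    mass_g = p.body_mass_kg * GRAVITY_MS2
    for i in range(p.n_steps):
        s = int(round((pad_s + i * period_s) * p.force_rate_hz))
        stance_wave = vgrf_bw[i] * mass_g * env_f
        if p.transient_amp_bw > 0:
            k0 = int(round(p.transient_frac * n_st))
            k = np.arange(n_st) - k0
            pulse = np.where(
                k >= 0, np.exp(-k / (p.transient_tau_s * p.force_rate_hz)), 0.0
            )
            stance_wave = stance_wave + p.transient_amp_bw * mass_g * pulse
        force[s : s + n_st] += stance_wave
        stances.append(StanceInterval(s, s + n_st, p.force_rate_hz))

    # --- IMU trace (200 Hz): burst per step, delayed by the inserted lag ---
    n_bi = int(round(p.stance_s * p.imu_rate_hz))
    if n_bi % 2 == 0:
        n_bi += 1
    env_i = _peaked_envelope(n_bi)
    imu = np.zeros((ni, 3))
    imu[:, 0] = 1.0  # at rest the vertical channel reads +1 g
    marker = np.zeros(ni)
    sigma_m = 0.060  # marker-bump width, s
    t_imu = np.arange(ni) / p.imu_rate_hz
    for i in range(p.n_steps):
        mid_s = pad_s + i * period_s + p.stance_s / 2.0
        c = int(round(mid_s * p.imu_rate_hz))
        lo = c - n_bi // 2
        imu[lo : lo + n_bi, 0] += (acc_v[i] - 1.0) * env_i
        imu[lo : lo + n_bi, 1] += acc_ap[i] * env_i
        imu[lo : lo + n_bi, 2] += ml_sign[i] * ml_mag[i] * env_i
        # downward displacement bump whose 2nd derivative peaks at the
        # burst apex with amplitude tied to this step's acceleration
        amp_m = (acc_v[i] - 1.0) * GRAVITY_MS2 * sigma_m**2
        marker -= amp_m * np.exp(-((t_imu - mid_s) ** 2) / (2 * sigma_m**2))
    if p.imu_white_noise_g > 0:
        imu += rng.normal(0.0, p.imu_white_noise_g, imu.shape)
    if p.imu_lag_samples != 0:
        lag = p.imu_lag_samples
        if lag > 0:
            rest = np.tile(imu[:1], (lag, 1))
            imu = np.vstack([rest, imu[:-lag]])
        else:
            rest = np.tile(imu[-1:], (-lag, 1))
            imu = np.vstack([imu[-lag:], rest])
    marker += 1.0  # sensor sits about 1 m above the ground

    force_trace = SampledTrace(force, p.force_rate_hz, "N")
    imu_trace = SampledTrace(imu, p.imu_rate_hz, "g")
    marker_trace = SampledTrace(marker, p.imu_rate_hz, "m")
    truth = TreadmillTruth(
        stances=stances,
        vgrf_peaks_bw=vgrf_bw,
        acc_v_peaks_g=acc_v,
        acc_ap_peaks_g=acc_ap,
        acc_ml_peaks_g=ml_mag,
        speed_mps=p.speed_mps,
        imu_lag_samples=p.imu_lag_samples,
    )
    return force_trace, imu_trace, marker_trace, truth


# ---------------------------------------------------------------------------
# Outdoor cohort
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortParams:
    """Parameters of the synthetic outdoor cohort.

    Defaults target a ~500-session cohort of 96 recreational runners:
    log-normal runner loading styles with median per-step peak ~5.5 g, a
    small designated fraction of heavy styles above 10 g, log-normal
    session durations (median 42 min) and roughly normal speeds around
    3 m/s, and cadence linear in speed with a persistent runner offset.
    """

    n_runners: int = 96
    #: sessions per runner: with prob short_session_prob a count in {1, 2},
    #: otherwise 3 + Poisson(poisson_extra_sessions)
    short_session_prob: float = 0.40
    poisson_extra_sessions: float = 5.0
    #: runner loading style: log-normal mean per-step ACC_v peak (g)
    runner_mean_log_mu: float = float(np.log(5.54))
    runner_mean_log_sigma: float = 0.25
    #: fraction of runners with heavy styles (mean peak above 10 g)
    heavy_style_fraction: float = 3 / 96
    heavy_style_range_g: tuple[float, float] = (10.05, 10.6)
    #: per-session multiplicative jitter on the runner mean (log-SD)
    session_mean_log_jitter: float = 0.05
    #: within-session per-step SD: log-normal, median ~0.9 g
    within_sd_log_mu: float = float(np.log(0.9))
    within_sd_log_sigma: float = 0.35
    #: session speed (m/s): normal, clipped to the plausible range
    speed_mean_mps: float = 3.0
    speed_sd_mps: float = 0.45
    speed_range_mps: tuple[float, float] = (2.0, 4.65)
    #: session duration (min): log-normal median 42, clipped
    duration_log_mu: float = float(np.log(42.0))
    duration_log_sigma: float = 0.50
    duration_range_min: tuple[float, float] = (14.0, 228.0)
    #: cadence (steps/min) = intercept + slope * speed + runner offset + jitter
    cadence_intercept_spm: float = 150.0
    cadence_slope_spm_per_mps: float = 10.0
    cadence_runner_sd_spm: float = 15.0
    cadence_session_sd_spm: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_runners < 1:
            raise DataError("n_runners must be >= 1")
        if not (0.0 <= self.heavy_style_fraction <= 0.1):
            raise DataError("heavy_style_fraction must lie in [0, 0.1]")
        if min(self.runner_mean_log_sigma, self.within_sd_log_sigma) <= 0:
            raise DataError("scale parameters must be positive")


@dataclass(frozen=True)
class CohortTruth:
    """Ground truth of a generated cohort, keyed by runner id."""

    runner_mean_g: dict[str, float]
    runner_cadence_offset_spm: dict[str, float]
    heavy_runners: tuple[str, ...]


def gen_outdoor_cohort(p: CohortParams) -> tuple[list[SessionRecord], CohortTruth]:
    """Generate the outdoor cohort: (session records, ground truth)."""
    rng = np.random.default_rng(p.seed)
    n_heavy = int(round(p.heavy_style_fraction * p.n_runners))
    heavy_idx = set(rng.choice(p.n_runners, size=n_heavy, replace=False).tolist())

    records: list[SessionRecord] = []
    runner_mean: dict[str, float] = {}
    runner_cad: dict[str, float] = {}
    heavy_ids: list[str] = []
    for r in range(p.n_runners):
        runner_id = f"R{r + 1:03d}"
        if r in heavy_idx:
            mean_g = rng.uniform(*p.heavy_style_range_g)
            heavy_ids.append(runner_id)
        else:
            mean_g = float(
                np.exp(rng.normal(p.runner_mean_log_mu, p.runner_mean_log_sigma))
            )
            while mean_g > 10.0:  # keep heavy styles the designated fraction
                mean_g = float(
                    np.exp(rng.normal(p.runner_mean_log_mu, p.runner_mean_log_sigma))
                )
        cad_off = rng.normal(0.0, p.cadence_runner_sd_spm)
        runner_mean[runner_id] = mean_g
        runner_cad[runner_id] = cad_off
        if rng.random() < p.short_session_prob:
            n_sessions = int(rng.integers(1, 3))
        else:
            n_sessions = 3 + int(rng.poisson(p.poisson_extra_sessions))
        for s in range(n_sessions):
            speed = float(
                np.clip(
                    rng.normal(p.speed_mean_mps, p.speed_sd_mps), *p.speed_range_mps
                )
            )
            duration = float(
                np.clip(
                    np.exp(rng.normal(p.duration_log_mu, p.duration_log_sigma)),
                    *p.duration_range_min,
                )
            )
            cadence = float(
                np.clip(
                    p.cadence_intercept_spm
                    + p.cadence_slope_spm_per_mps * speed
                    + cad_off
                    + rng.normal(0.0, p.cadence_session_sd_spm),
                    140.0,
                    220.0,
                )
            )
            n_steps = int(round(cadence * duration))
            distance = speed * duration * 60.0
            sess_mean = mean_g * float(
                np.exp(rng.normal(0.0, p.session_mean_log_jitter))
            )
            sd = float(np.exp(rng.normal(p.within_sd_log_mu, p.within_sd_log_sigma)))
            peaks = rng.normal(sess_mean, sd, n_steps)
            while np.any(peaks <= 0):  # truncate the step-peak distribution at 0
                bad = peaks <= 0
                peaks[bad] = rng.normal(sess_mean, sd, int(bad.sum()))
            records.append(
                SessionRecord(
                    runner_id=runner_id,
                    session_id=f"{runner_id}-S{s + 1:03d}",
                    acc_v_peaks=peaks,
                    duration_min=duration,
                    distance_m=distance,
                    avg_speed_mps=speed,
                )
            )
    truth = CohortTruth(
        runner_mean_g=runner_mean,
        runner_cadence_offset_spm=runner_cad,
        heavy_runners=tuple(heavy_ids),
    )
    return records, truth
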