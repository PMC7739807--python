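"""Per-step magnitudes: active vGRF peak and tri-axial trunk-acceleration peaks.

The active vGRF peak is read in the 40-60% stance window, which excludes
the early impact transient and captures the mid-stance force maximum.
Acceleration peaks are taken over the whole stance: the vertical channel
as the signed maximum (its impact peaks are large and positive), the
anteroposterior and mediolateral channels as the maximum absolute value
(they are small and their sign depends on footedness and lean).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from runload.errors import DataError, TooShortError, UnitError
from runload.gait_events import StanceInterval
from runload.preprocess import GRAVITY_MS2, SampledTrace


@dataclass(frozen=True)
class StepFeatures:
    """The per-step quantities the regression layer consumes."""

    subject_id: str
    step_index: int
    speed_mps: float
    stance_s: float
    vgrf_peak_bw: float
    acc_v_g: float
    acc_ap_g: float
    acc_ml_g: float


def features_frame(steps: list[StepFeatures]) -> pd.DataFrame:
    """Per-step feature table in the canonical column order."""
    cols = [
        "subject_id",
        "step_index",
        "speed_mps",
        "stance_s",
        "vgrf_peak_bw",
        "acc_v_g",
        "acc_ap_g",
        "acc_ml_g",
    ]
    return pd.DataFrame([{c: getattr(s, c) for c in cols} for s in steps], columns=cols)


def normalize_bw(force: SampledTrace, body_mass_kg: float) -> SampledTrace:
    """Normalize a force trace to body-weight multiples (BW)."""
    if force.units != "N":
        raise UnitError(f"expected N, got {force.units!r}")
    if not body_mass_kg > 0:
        raise DataError(f"body mass must be positive, got {body_mass_kg}")
    return replace(
        force, values=force.values / (body_mass_kg * GRAVITY_MS2), units="BW"
    )


def vgrf_peak(
    force_bw: SampledTrace,
    stance: StanceInterval,
    window: tuple[float, float] = (0.4, 0.6),
) -> float:
    """Maximum vGRF inside a fractional stance window (default 40-60%).

    Window endpoints round outward (floor on the lower, ceil on the upper,
    both inclusive) so the window is never empty even for short stances.
    """
    if force_bw.n_channels != 1:
        raise DataError("vgrf_peak expects a single-channel trace")
    lo_f, hi_f = window
    if not (0.0 <= lo_f < hi_f <= 1.0):
        raise DataError(f"bad window {window}")
    if stance.end > force_bw.n_samples:
        raise DataError("stance extends beyond trace")
    n = stance.n_samples
    if n < 5:
        raise TooShortError(f"stance of {n} samples too short for a windowed peak")
    lo = stance.start + int(np.floor(lo_f * n))
    hi = stance.start + int(np.ceil(hi_f * n))
    segment = force_bw.values[lo : hi + 1, 0]
    return float(np.max(segment))


def peak_accelerations(
    acc3: SampledTrace,
    stance: StanceInterval,
    signed_vertical: bool = True,
    remove_gravity_offset: bool = False,
) -> tuple[float, float, float]:
    """Peak trunk accelerations (g) over a stance: (vertical, ap, ml).

    Vertical uses the signed maximum by default, ap/ml the maximum absolute
    value; ``signed_vertical=False`` switches the vertical channel to the
    absolute rule as well. Accelerations are used as the sensor measures
    them, gravity included; ``remove_gravity_offset`` subtracts 1 g from
    the vertical channel first.
    """
    if acc3.units != "g":
        raise UnitError(f"expected g, got {acc3.units!r}")
    if acc3.n_channels != 3:
        raise DataError("peak_accelerations expects a tri-axial trace")
    start, end = stance.start, min(stance.end, acc3.n_samples)
    if end <= start:
        raise TooShortError("stance empty after mapping to the IMU timebase")
    seg = acc3.values[start:end]
    v = seg[:, 0] - (1.0 if remove_gravity_offset else 0.0)
    acc_v = float(np.max(v) if signed_vertical else np.max(np.abs(v)))
    acc_ap = float(np.max(np.abs(seg[:, 1])))
    acc_ml = float(np.max(np.abs(seg[:, 2])))
    return acc_v, acc_ap, acc_ml
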