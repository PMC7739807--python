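"""Signal conditioning for force-plate and trunk-IMU running records.

Filtering, numerical differentiation, marker-based acceleration
reconstruction, cross-correlation alignment of the IMU against the
optical/force timebase, and index plumbing between sampling rates
(force plates run at 1000 Hz, the trunk IMU at 200 Hz).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd
from scipy import signal

from runload.errors import (
    DataError,
    InvalidFilterError,
    TooShortError,
    UndefinedCorrelationError,
)

if TYPE_CHECKING:  # pragma: no cover
    from runload.gait_events import StanceInterval

#: Standard gravity used for N <-> BW and m/s^2 <-> g conversions.
GRAVITY_MS2 = 9.81

_VALID_UNITS = {"N", "g", "m", "m/s", "m/s^2", "BW"}

#: How physical units advance under time differentiation.
_UNIT_DERIVATIVE = {"m": "m/s", "m/s": "m/s^2"}


@dataclass(frozen=True)
class SampledTrace:
    """A uniformly sampled scalar or tri-axial signal.

    ``values`` has shape ``(n,)`` or ``(n, 1)`` for single-channel signals
    (force, marker displacement) and ``(n, 3)`` for tri-axial acceleration
    ordered vertical / anteroposterior / mediolateral.
    """

    values: np.ndarray
    rate: float
    units: str
    t0: float = 0.0

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim == 1:
            values = values[:, None]
        if values.ndim != 2 or values.shape[1] not in (1, 3):
            raise DataError(
                f"trace must have 1 or 3 channels, got shape {values.shape}"
            )
        if values.shape[0] < 2:
            raise TooShortError("trace needs at least 2 samples")
        if not np.all(np.isfinite(values)):
            raise DataError("trace contains non-finite samples")
        if not self.rate > 0:
            raise DataError(f"sampling rate must be positive, got {self.rate}")
        if self.units not in _VALID_UNITS:
            raise DataError(f"unknown units {self.units!r}; expected {_VALID_UNITS}")
        object.__setattr__(self, "values", values)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.rate

    def channel(self, index: int) -> "SampledTrace":
        """Extract a single channel as a new trace."""
        return replace(self, values=self.values[:, index])


@dataclass(frozen=True)
class FilterSpec:
    """A low-pass Butterworth filter specification.

    ``zero_phase`` selects forward-backward (filtfilt) application, which
    cancels group delay so peak timing is preserved; its magnitude response
    is the square of the one-pass response (gain 1/2 at the cutoff for any
    Butterworth order).
    """

    order: int = 3
    cutoff_hz: float = 45.0
    kind: str = "lowpass"
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if self.order < 1:
            raise InvalidFilterError(f"filter order must be >= 1, got {self.order}")
        if not self.cutoff_hz > 0:
            raise InvalidFilterError(f"cutoff must be positive, got {self.cutoff_hz}")
        if self.kind != "lowpass":
            raise InvalidFilterError(f"only low-pass filters supported, got {self.kind!r}")

    def min_samples(self) -> int:
        """Shortest trace the filter accepts.

        The odd-reflection pad used by forward-backward filtering spans
        ``3 * (order + 1)`` samples; traces shorter than three such spans
        are rejected rather than padded into meaninglessness.
        """
        return 9 * (self.order + 1)


def lowpass(trace: SampledTrace, spec: FilterSpec) -> SampledTrace:
    """Low-pass Butterworth filter, applied independently per channel.

    Raises :class:`InvalidFilterError` if the cutoff reaches the Nyquist
    frequency and :class:`TooShortError` when the trace cannot absorb the
    filter warm-up (see :meth:`FilterSpec.min_samples`).
    """
    nyquist = trace.rate / 2.0
    if spec.cutoff_hz >= nyquist:
        raise InvalidFilterError(
            f"cutoff {spec.cutoff_hz} Hz >= Nyquist {nyquist} Hz at rate {trace.rate} Hz"
        )
    if trace.n_samples < spec.min_samples():
        raise TooShortError(
            f"trace of {trace.n_samples} samples shorter than filter warm-up "
            f"({spec.min_samples()} samples)"
        )
    b, a = signal.butter(spec.order, spec.cutoff_hz, btype="low", fs=trace.rate)
    if spec.zero_phase:
        filtered = signal.filtfilt(b, a, trace.values, axis=0, padtype="odd")
    else:
        filtered = signal.lfilter(b, a, trace.values, axis=0)
    return replace(trace, values=filtered)


def filter_gain(spec: FilterSpec, freq_hz: float, rate: float) -> float:
    """Steady-state amplitude gain of the filter at one frequency.

    Direct evaluation of the digital Butterworth frequency response;
    squared when the spec is zero-phase (forward-backward application).
    """
    b, a = signal.butter(spec.order, spec.cutoff_hz, btype="low", fs=rate)
    _, h = signal.freqz(b, a, worN=[freq_hz], fs=rate)
    gain = float(np.abs(h[0]))
    return gain**2 if spec.zero_phase else gain


def differentiate(trace: SampledTrace) -> SampledTrace:
    """Time derivative: central differences inside, one-sided at the ends.

    Second-order accurate and delay-free, so differentiated signals stay
    aligned with their source. Units advance (m -> m/s -> m/s^2).
    """
    if trace.n_channels != 1:
        raise DataError("differentiate expects a single-channel trace")
    if trace.n_samples < 3:
        raise TooShortError("need at least 3 samples to differentiate")
    deriv = np.gradient(trace.values[:, 0], 1.0 / trace.rate, edge_order=2)
    units = _UNIT_DERIVATIVE.get(trace.units)
    if units is None:
        raise DataError(f"cannot advance units {trace.units!r} under differentiation")
    return SampledTrace(deriv, trace.rate, units, trace.t0)


def marker_acceleration(
    displacement: SampledTrace, spec20: FilterSpec | None = None
) -> SampledTrace:
    """Vertical acceleration reconstructed from marker displacement.

    Pipeline: low-pass the displacement, differentiate to velocity,
    low-pass again, differentiate to acceleration (both filters default to
    third-order 20 Hz, the conventional kinematics cutoff). Output in m/s^2.
    """
    if displacement.units != "m":
        raise DataError(f"marker displacement must be in m, got {displacement.units!r}")
    if spec20 is None:
        spec20 = FilterSpec(order=3, cutoff_hz=20.0)
    velocity = differentiate(lowpass(displacement, spec20))
    return differentiate(lowpass(velocity, spec20))


def ms2_to_g(trace: SampledTrace) -> SampledTrace:
    """Convert an acceleration trace from m/s^2 to g (standard gravity 9.81)."""
    if trace.units != "m/s^2":
        raise DataError(f"expected m/s^2, got {trace.units!r}")
    return SampledTrace(trace.values / GRAVITY_MS2, trace.rate, "g", trace.t0)


def xcorr_lag(a: SampledTrace, b: SampledTrace, max_lag: int) -> int:
    """Integer lag maximising the normalized cross-correlation of a against b.

    A positive lag means ``a`` lags (is delayed relative to) ``b``:
    ``a[n] ~ b[n - lag]``. Both signals are mean-removed per overlap and the
    correlation normalized, so the result is invariant to affine rescaling
    of either signal. Ties are broken toward the smallest ``|lag|``, then
    negative before positive, so the output is deterministic.
    """
    if a.rate != b.rate:
        raise DataError(f"rates differ: {a.rate} vs {b.rate}")
    if a.n_channels != 1 or b.n_channels != 1:
        raise DataError("xcorr_lag expects single-channel traces")
    xa = a.values[:, 0]
    xb = b.values[:, 0]
    if np.ptp(xa) == 0 or np.ptp(xb) == 0:
        raise UndefinedCorrelationError("zero-variance input, correlation undefined")
    max_lag = int(max_lag)
    if max_lag < 0 or max_lag >= min(len(xa), len(xb)) - 1:
        raise DataError(f"max_lag {max_lag} leaves no overlap")

    # |lag| ascending, negative preferred on ties; strict > keeps the first.
    lags = sorted(range(-max_lag, max_lag + 1), key=lambda l: (abs(l), l))
    best_lag = 0
    best_corr = -np.inf
    for lag in lags:
        if lag >= 0:
            seg_a = xa[lag:]
            seg_b = xb[: len(xb) - lag] if lag else xb
        else:
            seg_a = xa[: len(xa) + lag]
            seg_b = xb[-lag:]
        n = min(len(seg_a), len(seg_b))
        if n < 2:
            continue
        seg_a = seg_a[:n] - seg_a[:n].mean()
        seg_b = seg_b[:n] - seg_b[:n].mean()
        denom = np.linalg.norm(seg_a) * np.linalg.norm(seg_b)
        if denom == 0:
            continue
        corr = float(seg_a @ seg_b) / denom
        if corr > best_corr + 1e-12:
            best_corr = corr
            best_lag = lag
    return best_lag


def map_interval_between_rates(
    interval: "StanceInterval", rate_from: float, rate_to: float
) -> "StanceInterval":
    """Re-index a stance interval onto another sampling rate.

    Start rounds down and end rounds up, so a non-empty interval never maps
    to an empty one and the time span never shrinks by more than one sample
    period of the coarser rate.
    """
    from runload.gait_events import StanceInterval

    if rate_from <= 0 or rate_to <= 0:
        raise DataError("rates must be positive")
    ratio = rate_to / rate_from
    start = int(np.floor(interval.start * ratio))
    end = int(np.ceil(interval.end * ratio))
    if end <= start:
        end = start + 1
    return StanceInterval(start=start, end=end, rate=rate_to)


# ---------------------------------------------------------------------------
# Trace I/O: delimited text with a two-line header carrying rate and units.
# ---------------------------------------------------------------------------

_CHANNEL_COLUMNS = {1: ["value"], 3: ["v", "ap", "ml"]}


def write_trace(trace: SampledTrace, path: str | Path) -> None:
    """Write a trace as CSV: metadata comment line, then ``t,<channels>``."""
    path = Path(path)
    cols = _CHANNEL_COLUMNS[trace.n_channels]
    frame = pd.DataFrame(trace.values, columns=cols)
    frame.insert(0, "t", trace.times)
    with open(path, "w") as fh:
        fh.write(f"# rate_hz={trace.rate!r} units={trace.units} t0={trace.t0!r}\n")
        frame.to_csv(fh, index=False, float_format="%.10g")


def read_trace(path: str | Path) -> SampledTrace:
    """Read a trace written by :func:`write_trace`.

    Validates that the time column is uniformly sampled at the declared
    rate to within 1 ppm.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise DataError(f"{path}: missing metadata header line")
        meta = dict(
            item.split("=", 1) for item in header.lstrip("#").split() if "=" in item
        )
        try:
            rate = float(meta["rate_hz"])
            units = meta["units"]
            t0 = float(meta.get("t0", 0.0))
        except (KeyError, ValueError) as exc:
            raise DataError(f"{path}: bad metadata header: {header!r}") from exc
        frame = pd.read_csv(fh)
    if "t" not in frame.columns:
        raise DataError(f"{path}: no time column 't'")
    t = frame["t"].to_numpy()
    dt = np.diff(t)
    if len(dt) and np.max(np.abs(dt * rate - 1.0)) > 1e-6:
        raise DataError(f"{path}: time column not uniform at {rate} Hz within 1 ppm")
    values = frame.drop(columns="t").to_numpy()
    return SampledTrace(values, rate, units, t0)
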