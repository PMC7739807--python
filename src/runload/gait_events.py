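"""Segment running signals into foot contacts and match steps across modalities.

Two detectors are provided: the reference detector thresholds the
force-plate vGRF at 50 N (a foot is on the ground while the plate reads
more than 50 N), and the field detector finds impact peaks in the vertical
trunk-acceleration channel alone, which is all a wearable records outdoors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sp_signal

from runload.errors import DataError, UnitError
from runload.preprocess import FilterSpec, SampledTrace, lowpass

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StanceInterval:
    """One foot contact as a half-open sample-index interval ``[start, end)``."""

    start: int
    end: int
    rate: float

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise DataError(f"bad interval [{self.start}, {self.end})")
        if self.rate <= 0:
            raise DataError("interval rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.end - self.start

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate

    @property
    def mid_time_s(self) -> float:
        return (self.start + self.end) / 2.0 / self.rate


@dataclass(frozen=True)
class StepDetectionConfig:
    """Parameters of both step detectors.

    ``grf_threshold_n`` is the contact threshold on the force plate.
    The remaining fields govern the accelerometer-only detector and the
    stance-duration gate: running stances last roughly 0.1-0.35 s, so the
    [0.08, 0.6] s gate rejects treadmill-start artifacts and walking
    while keeping every plausible running contact. ``refractory_s`` caps
    cadence at 240 steps/min; ``stance_window_s`` is the fixed window the
    accelerometer detector places around each impact peak.
    """

    grf_threshold_n: float = 50.0
    min_stance_s: float = 0.08
    max_stance_s: float = 0.6
    refractory_s: float = 0.25
    acc_peak_min_g: float = 1.4
    stance_window_s: float = 0.30
    acc_lowpass_hz: float = 10.0

    def __post_init__(self) -> None:
        if min(
            self.grf_threshold_n,
            self.min_stance_s,
            self.max_stance_s,
            self.refractory_s,
            self.acc_peak_min_g,
            self.stance_window_s,
            self.acc_lowpass_hz,
        ) <= 0:
            raise DataError("all detection parameters must be positive")
        if self.min_stance_s >= self.max_stance_s:
            raise DataError("min_stance_s must be < max_stance_s")
        if self.refractory_s < self.min_stance_s:
            raise DataError("refractory_s must be >= min_stance_s")


def detect_contacts_grf(
    force: SampledTrace, cfg: StepDetectionConfig | None = None
) -> list[StanceInterval]:
    """Foot contacts from vGRF: maximal runs of samples above the threshold.

    Runs whose duration falls outside the stance gate are discarded (and
    logged), as are contacts truncated by the recording boundary, whose
    peaks would be biased low.
    """
    cfg = cfg or StepDetectionConfig()
    if force.units != "N":
        raise UnitError(f"GRF detector expects force in N, got {force.units!r}")
    if force.n_channels != 1:
        raise DataError("GRF detector expects a single-channel trace")
    above = force.values[:, 0] > cfg.grf_threshold_n
    edges = np.flatnonzero(np.diff(above.astype(np.int8)))
    starts = edges[~above[edges]] + 1
    ends = edges[above[edges]] + 1
    if above[0]:
        starts = np.concatenate(([0], starts))
    if above[-1]:
        ends = np.concatenate((ends, [force.n_samples]))

    intervals: list[StanceInterval] = []
    n_rejected = 0
    n_truncated = 0
    for s, e in zip(starts, ends):
        if s == 0 or e == force.n_samples:
            n_truncated += 1
            continue
        duration = (e - s) / force.rate
        if not (cfg.min_stance_s <= duration <= cfg.max_stance_s):
            n_rejected += 1
            continue
        intervals.append(StanceInterval(int(s), int(e), force.rate))
    if n_rejected or n_truncated:
        logger.info(
            "detect_contacts_grf: kept %d contacts, rejected %d by duration gate, "
            "dropped %d truncated by recording boundary",
            len(intervals),
            n_rejected,
            n_truncated,
        )
    return intervals


def detect_steps_acc(
    acc_v: SampledTrace, cfg: StepDetectionConfig | None = None
) -> list[StanceInterval]:
    """Steps from the vertical trunk-acceleration channel alone.

    Impact peaks are local maxima of the low-pass-filtered vertical channel
    exceeding ``acc_peak_min_g``, separated by at least the refractory
    period. Each peak is emitted as a fixed stance window centered on it;
    windows clipped by the recording boundary are dropped.
    """
    cfg = cfg or StepDetectionConfig()
    if acc_v.units != "g":
        raise UnitError(f"accelerometer detector expects g, got {acc_v.units!r}")
    if acc_v.n_channels != 1:
        raise DataError("pass the vertical channel only")
    spec = FilterSpec(order=3, cutoff_hz=cfg.acc_lowpass_hz)
    smooth = lowpass(acc_v, spec).values[:, 0]
    distance = max(1, int(round(cfg.refractory_s * acc_v.rate)))
    peaks, _ = sp_signal.find_peaks(smooth, height=cfg.acc_peak_min_g, distance=distance)
    half = int(round(cfg.stance_window_s * acc_v.rate / 2.0))
    intervals = []
    for p in peaks:
        start, end = int(p) - half, int(p) + half
        if start < 0 or end > acc_v.n_samples:
            continue
        intervals.append(StanceInterval(start, max(end, start + 1), acc_v.rate))
    return intervals


def match_steps(
    ref: list[StanceInterval],
    cand: list[StanceInterval],
    max_offset_s: float = 0.1,
) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """Greedy one-to-one matching of steps by nearest mid-stance time.

    Both lists must already live on lag-corrected timebases. Candidate
    pairs are taken closest-first, each step used at most once, and pairs
    further apart than ``max_offset_s`` are never formed. Returns
    ``(pairs, unmatched_ref_indices, unmatched_cand_indices)`` with pairs
    sorted by reference index.
    """
    mids_r = np.array([iv.mid_time_s for iv in ref])
    mids_c = np.array([iv.mid_time_s for iv in cand])
    candidates = []
    for i, tr in enumerate(mids_r):
        close = np.flatnonzero(np.abs(mids_c - tr) <= max_offset_s)
        for j in close:
            candidates.append((abs(mids_c[j] - tr), i, int(j)))
    candidates.sort()
    used_r: set[int] = set()
    used_c: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for _, i, j in candidates:
        if i in used_r or j in used_c:
            continue
        used_r.add(i)
        used_c.add(j)
        pairs.append((i, j))
    pairs.sort()
    unmatched_ref = [i for i in range(len(ref)) if i not in used_r]
    unmatched_cand = [j for j in range(len(cand)) if j not in used_c]
    return pairs, unmatched_ref, unmatched_cand
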