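"""Artifact masking and speed-based behavioral segmentation.

EEG epochs analyzed downstream are the "Still" portions of the recording:
segments where the animal's smoothed center-of-mass speed stays at or below
1 cm/s (anything faster for >= 1 s is "Moving"), minus amplitude artifacts
(|signal| > 0.6 mV for longer than 1 s, padded by 1.5 s on both sides).
Still includes quiet wakefulness and sleep; no sleep scoring is attempted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import intervals as iv

__all__ = [
    "EpochMask",
    "BehavioralSegments",
    "StillEpochs",
    "detect_artifacts",
    "smooth_tracking",
    "classify_behavior",
    "extract_still_epochs",
]

ARTIFACT_THRESHOLD_MV = 0.6
ARTIFACT_MIN_DURATION_S = 1.0
ARTIFACT_PADDING_S = 1.5
SMOOTHING_WINDOW_S = 0.166
SPEED_THRESHOLD_CM_S = 1.0
MOVING_MIN_DURATION_S = 1.0


@dataclass(frozen=True)
class EpochMask:
    """Labelled list of half-open [start, end) intervals in seconds."""

    intervals: list
    label: str
    extent: tuple

    def __post_init__(self) -> None:
        merged = iv.clip(self.intervals, self.extent)
        object.__setattr__(self, "intervals", merged)

    @property
    def total_seconds(self) -> float:
        return iv.total_length(self.intervals)


@dataclass(frozen=True)
class BehavioralSegments:
    """Still/Moving partition of the recording extent."""

    still: list
    moving: list
    extent: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "still", iv.clip(self.still, self.extent))
        object.__setattr__(self, "moving", iv.clip(self.moving, self.extent))
        if iv.intersect(self.still, self.moving):
            raise ValueError("still and moving intervals overlap")
        covered = iv.total_length(self.still) + iv.total_length(self.moving)
        span = self.extent[1] - self.extent[0]
        if abs(covered - span) > 1e-6 * max(span, 1.0):
            raise ValueError("still + moving do not partition the recording")


@dataclass(frozen=True)
class StillEpochs:
    """Signal epochs surviving behavior and artifact exclusion."""

    epochs: list = field(default_factory=list)
    intervals: list = field(default_factory=list)
    total_seconds: float = 0.0
    diagnostic: str | None = None

    def __bool__(self) -> bool:
        return bool(self.epochs)


def detect_artifacts(
    signal,
    fs: float,
    threshold: float = ARTIFACT_THRESHOLD_MV,
    min_duration: float = ARTIFACT_MIN_DURATION_S,
    padding: float = ARTIFACT_PADDING_S,
) -> EpochMask:
    """Mask amplitude artifacts: |signal| above ``threshold`` (mV, two-sided)
    for longer than ``min_duration`` s, padded by ``padding`` s per side.
    Overlapping padded intervals are merged; the mask is clipped to the
    recording extent.
    """
    signal = np.asarray(signal, dtype=float)
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if not np.all(np.isfinite(signal)):
        bad = int(np.argmax(~np.isfinite(signal)))
        raise ValueError(f"non-finite sample at index {bad}")
    duration = signal.size / fs
    above = np.abs(signal) > threshold
    raw = []
    for i0, i1 in _runs(above):
        if (i1 - i0) / fs > min_duration:
            raw.append((i0 / fs - padding, i1 / fs + padding))
    return EpochMask(intervals=raw, label="artifact", extent=(0.0, duration))


def smooth_tracking(trajectory: pd.DataFrame, window: float = SMOOTHING_WINDOW_S) -> pd.DataFrame:
    """Gaussian-smooth the x/y columns of a uniformly sampled trajectory.

    The kernel has total support ``window`` seconds and sd = support / 6
    (truncated, renormalized to unit mass); output length equals input
    length (edge replication padding).  Windows shorter than two samples
    pass the trajectory through with a warning.
    """
    t = trajectory["time_s"].to_numpy(dtype=float)
    dt = _uniform_dt(t)
    n = int(round(window / dt))
    if n < 2:
        warnings.warn(
            f"smoothing window {window} s spans fewer than 2 samples at "
            f"dt={dt:.4f} s; returning trajectory unchanged",
            stacklevel=2,
        )
        return trajectory.copy()
    half = n // 2
    taps = np.arange(-half, half + 1) * dt
    kernel = np.exp(-(taps**2) / (2.0 * (window / 6.0) ** 2))
    kernel /= kernel.sum()
    out = trajectory.copy()
    for col in ("x_cm", "y_cm"):
        x = trajectory[col].to_numpy(dtype=float)
        padded = np.concatenate([np.full(half, x[0]), x, np.full(half, x[-1])])
        out[col] = np.convolve(padded, kernel, mode="valid")
    return out


def classify_behavior(
    trajectory: pd.DataFrame,
    speed_threshold: float = SPEED_THRESHOLD_CM_S,
    min_duration: float = MOVING_MIN_DURATION_S,
    smooth_window: float | None = SMOOTHING_WINDOW_S,
) -> BehavioralSegments:
    """Partition the recording into Moving / Still by center-of-mass speed.

    Speed is computed from central differences of the (smoothed) positions;
    maximal runs with speed > ``speed_threshold`` lasting at least
    ``min_duration`` s are Moving, the complement is Still.
    """
    t = trajectory["time_s"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("trajectory timestamps must be strictly increasing")
    dt = _uniform_dt(t)
    if smooth_window is not None:
        trajectory = smooth_tracking(trajectory, smooth_window)
    x = trajectory["x_cm"].to_numpy(dtype=float)
    y = trajectory["y_cm"].to_numpy(dtype=float)
    speed = np.hypot(np.gradient(x, t), np.gradient(y, t))
    extent = (float(t[0]), float(t[-1]) + dt)
    moving = []
    for i0, i1 in _runs(speed > speed_threshold):
        start, end = t[i0], (t[i1 - 1] + dt if i1 == t.size else t[i1])
        if end - start >= min_duration:
            moving.append((start, end))
    moving = iv.merge(moving)
    still = iv.complement(moving, extent)
    return BehavioralSegments(still=still, moving=moving, extent=extent)


def extract_still_epochs(
    signal,
    fs: float,
    segments: BehavioralSegments,
    artifacts: EpochMask,
    min_epoch: float,
) -> StillEpochs:
    """Signal restricted to still-minus-artifact intervals.

    Remnants shorter than ``min_epoch`` s (which must cover at least one
    spectral analysis window) are dropped.  An empty result carries a
    diagnostic message instead of silently yielding zero-length spectra.
    """
    signal = np.asarray(signal, dtype=float)
    usable = iv.subtract(segments.still, artifacts.intervals)
    kept, epochs = [], []
    for s, e in usable:
        if e - s >= min_epoch:
            i0, i1 = int(round(s * fs)), int(round(e * fs))
            if i1 > i0:
                kept.append((s, e))
                epochs.append(signal[i0:i1])
    if not epochs:
        still_s = iv.total_length(segments.still)
        return StillEpochs(
            diagnostic=(
                f"no still epoch of >= {min_epoch} s survives artifact "
                f"exclusion (still: {still_s:.1f} s, artifact mask: "
                f"{artifacts.total_seconds:.1f} s)"
            )
        )
    return StillEpochs(
        epochs=epochs, intervals=kept, total_seconds=iv.total_length(kept)
    )


def _runs(mask: np.ndarray):
    """Index pairs (i0, i1) of maximal True runs, half-open."""
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


def _uniform_dt(t: np.ndarray, jitter_tol: float = 0.1) -> float:
    dts = np.diff(t)
    if dts.size == 0:
        raise ValueError("trajectory needs at least two samples")
    dt = float(np.median(dts))
    if np.any(np.abs(dts - dt) > jitter_tol * dt):
        raise ValueError("trajectory sampling is not uniform (jitter > 10%)")
    return dt
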