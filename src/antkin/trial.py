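"""Marker trajectories and the signal-conditioning steps applied before IK.

A :class:`MarkerTrial` holds time-indexed 3D positions of tracked landmarks
(millimetres, uniform sampling).  Conditioning mirrors standard gait-analysis
practice: zero-phase fourth-order Butterworth low-pass at 5 Hz, downsampling
from the 300 Hz acquisition rate to 100 Hz, and cropping to a single manually
identified gait cycle (lift-off to lift-off of the left middle leg).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

from .errors import InvalidInputError, InvalidParameterError

__all__ = ["MarkerTrial", "GaitCycle", "lowpass_filter", "resample", "crop_cycle"]


@dataclass
class MarkerTrial:
    """Uniformly sampled marker trajectories.

    ``data`` has shape (n_frames, n_markers, 3) in mm; samples flagged in
    ``missing`` (n_frames, n_markers) are invalid and their coordinates are
    NaN.  ``time`` starts at ``t0`` and advances by 1/rate.
    """

    marker_names: list
    data: np.ndarray
    rate: float
    missing: np.ndarray = None
    t0: float = 0.0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[1] != len(self.marker_names) \
                or self.data.shape[2] != 3:
            raise InvalidInputError(
                f"data must be (frames, {len(self.marker_names)}, 3), got {self.data.shape}")
        if self.rate <= 0:
            raise InvalidParameterError("sampling rate must be positive")
        if self.missing is None:
            self.missing = ~np.all(np.isfinite(self.data), axis=2)
        else:
            self.missing = np.asarray(self.missing, dtype=bool)
            if self.missing.shape != self.data.shape[:2]:
                raise InvalidInputError("missing flags must be (frames, markers)")
        self.data = self.data.copy()
        self.data[self.missing] = np.nan
        if not np.all(np.isfinite(self.data[~self.missing])):
            raise InvalidInputError("non-finite coordinates in samples not flagged missing")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_markers(self) -> int:
        return self.data.shape[1]

    @property
    def time(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_frames) / self.rate

    @property
    def duration(self) -> float:
        return (self.n_frames - 1) / self.rate

    def marker(self, name: str) -> np.ndarray:
        return self.data[:, self.marker_names.index(name), :]

    def frame_dict(self, i: int, include_missing: bool = False) -> dict:
        """Marker name -> (3,) position at frame ``i`` (missing skipped by default)."""
        out = {}
        for m, name in enumerate(self.marker_names):
            if self.missing[i, m] and not include_missing:
                continue
            out[name] = self.data[i, m]
        return out

    def to_dataframe(self) -> pd.DataFrame:
        """Wide table: time plus <marker>_X/_Y/_Z columns (mm)."""
        cols = {"time": self.time}
        for m, name in enumerate(self.marker_names):
            for k, ax in enumerate("XYZ"):
                cols[f"{name}_{ax}"] = self.data[:, m, k]
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def copy(self) -> "MarkerTrial":
        return replace(self, data=self.data.copy(), missing=self.missing.copy(),
                       marker_names=list(self.marker_names))


@dataclass(frozen=True)
class GaitCycle:
    """Half-open frame range [start, end) of one gait cycle."""

    start_index: int
    end_index: int
    note: str = ""

    def __post_init__(self):
        if not 0 <= self.start_index < self.end_index:
            raise InvalidInputError("need 0 <= start < end")


def _interpolate_short_gaps(x: np.ndarray, missing: np.ndarray, max_gap: int):
    """Linearly fill missing runs of length <= max_gap; return still-bad mask."""
    x = x.copy()
    bad = missing.copy()
    n = len(x)
    idx = np.arange(n)
    for m in range(x.shape[1]):
        col_bad = bad[:, m]
        if not col_bad.any():
            continue
        if col_bad.all():
            continue  # caller decides what to do with fully missing channels
        runs = []
        start = None
        for i in range(n):
            if col_bad[i] and start is None:
                start = i
            elif not col_bad[i] and start is not None:
                runs.append((start, i))
                start = None
        if start is not None:
            runs.append((start, n))
        good = ~col_bad
        for a, b in runs:
            if b - a <= max_gap and a > 0 and b < n:
                for k in range(3):
                    x[a:b, m, k] = np.interp(idx[a:b], idx[good], x[good, m, k])
                bad[a:b, m] = False
    return x, bad


def lowpass_filter(trial: MarkerTrial, cutoff_hz: float = 5.0, order: int = 4,
                   max_gap: int = 10) -> MarkerTrial:
    """Zero-phase Butterworth low-pass of every coordinate channel.

    A forward-backward pass of an ``order``-th Butterworth filter (effective
    attenuation is the squared magnitude response) with reflective padding of
    ``3 * order`` samples.  Gaps of at most ``max_gap`` frames are linearly
    interpolated first; channels with longer gaps keep their missing flags
    (their valid leading/trailing spans are left unfiltered rather than
    filtered across a hole).
    """
    nyq = trial.rate / 2.0
    if not 0 < cutoff_hz < nyq:
        raise InvalidParameterError(f"cutoff must lie in (0, {nyq}) Hz, got {cutoff_hz}")
    if np.all(trial.missing):
        raise InvalidInputError("all samples missing; nothing to filter")
    b, a = butter(order, cutoff_hz / nyq)
    data, still_bad = _interpolate_short_gaps(trial.data, trial.missing, max_gap)
    out = data.copy()
    padlen = min(3 * order, trial.n_frames - 1)
    for m in range(trial.n_markers):
        if still_bad[:, m].any():
            continue
        out[:, m, :] = filtfilt(b, a, data[:, m, :], axis=0, padtype="even", padlen=padlen)
    return replace(trial, data=out, missing=still_bad, marker_names=list(trial.marker_names))


def resample(trial: MarkerTrial, target_rate_hz: float) -> MarkerTrial:
    """Downsample to ``target_rate_hz``.

    Integer rate ratios use exact index decimation (300 -> 100 Hz keeps every
    third sample); non-integer ratios interpolate linearly on a uniform grid
    spanning the same interval.  Upsampling is not provided.
    """
    if target_rate_hz <= 0:
        raise InvalidParameterError("target rate must be positive")
    if target_rate_hz > trial.rate * (1 + 1e-9):
        raise InvalidParameterError("upsampling is not supported")
    ratio = trial.rate / target_rate_hz
    if abs(ratio - round(ratio)) < 1e-9:
        step = int(round(ratio))
        data = trial.data[::step]
        missing = trial.missing[::step]
    else:
        t_new = trial.t0 + np.arange(int(np.floor(trial.duration * target_rate_hz)) + 1) \
            / target_rate_hz
        t_old = trial.time
        data = np.empty((len(t_new), trial.n_markers, 3))
        for m in range(trial.n_markers):
            for k in range(3):
                data[:, m, k] = np.interp(t_new, t_old, trial.data[:, m, k])
        missing = np.zeros(data.shape[:2], dtype=bool)
        # a resampled sample is missing if any contributing original sample was
        bad_t = trial.missing
        for m in range(trial.n_markers):
            if bad_t[:, m].any():
                missing[:, m] = np.interp(t_new, t_old, bad_t[:, m].astype(float)) > 0
    return replace(trial, data=np.ascontiguousarray(data), missing=np.ascontiguousarray(missing),
                   rate=float(target_rate_hz), marker_names=list(trial.marker_names))


def crop_cycle(trial: MarkerTrial, cycle: GaitCycle) -> MarkerTrial:
    """Keep frames [start, end) of one gait cycle; time restarts at zero."""
    if cycle.end_index > trial.n_frames:
        raise InvalidInputError(
            f"cycle [{cycle.start_index}, {cycle.end_index}) exceeds {trial.n_frames} frames")
    sl = slice(cycle.start_index, cycle.end_index)
    return replace(trial, data=trial.data[sl].copy(), missing=trial.missing[sl].copy(),
                   t0=0.0, marker_names=list(trial.marker_names))
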