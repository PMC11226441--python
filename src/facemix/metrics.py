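"""Motion-diversity index and objective control-error metrics.

The diversity index asks how often the *kind* of movement a person makes
changes over a trial.  Each motion channel (overall, head, periocular,
perioral) is smoothed and z-normalised, prominent peaks are detected per
channel, all peaks are merged into one time-ordered sequence, and the index
counts switches of the peak-bearing channel per minute.  An actor who blinks,
then nods, then talks switches often; an actor who only nods does not.

The control error quantifies the objective discrepancy between an actor's own
motion and the motion of the face displayed back to them, after compensating
the constant display latency.  Under full control with zero noise it is
exactly zero; mixing in a second actor at weight ``1 - w`` raises it by
``(1 - w)`` times the RMS displacement difference between the two actors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks
from scipy.ndimage import uniform_filter1d

from .kinematics import MotionChannelSet
from .trajectory import LandmarkTrajectory

__all__ = [
    "PeakEvent",
    "DiversityResult",
    "ControlErrorResult",
    "DiversityParams",
    "smooth_and_zscore",
    "detect_peaks",
    "diversity_index",
    "estimate_latency",
    "motion_error",
]

#: Channel merge order; ties in peak time are broken by this order.
DIVERSITY_CHANNELS = ("overall", "head", "periocular", "perioral")


@dataclass(frozen=True)
class PeakEvent:
    time_s: float
    channel: str
    prominence: float


@dataclass
class DiversityResult:
    peaks: list[PeakEvent]
    switch_count: int
    index: float  # switches per minute


@dataclass
class ControlErrorResult:
    latency_est_frames: int
    mean_error: float


@dataclass
class DiversityParams:
    """Peak-detection settings for the diversity index.

    Defaults target sub-second facial actions with one dominant action at a
    time: 0.5 s smoothing, 1 z-unit prominence, 0.3 s minimum separation.
    ``include_overall`` keeps the overall-motion channel in the switching set;
    dropping it removes a channel that is correlated with all others.
    """

    smooth_window_s: float = 0.5
    min_prominence: float = 1.0
    min_separation_s: float = 0.3
    include_overall: bool = True


def smooth_and_zscore(series: np.ndarray, window_s: float, fps: float) -> np.ndarray:
    """Centred moving-average smoothing followed by per-trial z-normalisation.

    A constant input maps to all zeros (zero-variance guard); ``window_s = 0``
    skips smoothing and only z-scores.
    """
    series = np.asarray(series, dtype=float)
    if window_s < 0:
        raise ValueError("window_s must be >= 0")
    w = int(round(window_s * fps))
    if w > 1:
        if w >= len(series):
            raise ValueError("smoothing window must be shorter than the series")
        series = uniform_filter1d(series, size=w, mode="nearest")
    sd = series.std()
    # relative guard: constant inputs can pick up ulp-level wobble in smoothing
    if sd <= 1e-12 * (1.0 + abs(series.mean())):
        return np.zeros_like(series)
    return (series - series.mean()) / sd


def detect_peaks(
    normalized_series: np.ndarray,
    fps: float,
    min_prominence: float = 1.0,
    min_separation_s: float = 0.3,
    channel: str = "",
) -> list[PeakEvent]:
    """Prominent local maxima, at least ``min_separation_s`` apart.

    When two candidates fall within the separation window the higher one is
    kept (tie: the earlier).  Returns an empty list for flat series.
    """
    if min_prominence <= 0:
        raise ValueError("min_prominence must be > 0")
    series = np.asarray(normalized_series, dtype=float)
    distance = max(1, int(round(min_separation_s * fps)))
    locs, props = find_peaks(series, prominence=min_prominence, distance=distance)
    return [
        PeakEvent(time_s=loc / fps, channel=channel, prominence=float(p))
        for loc, p in zip(locs, props["prominences"])
    ]


def _pooled_channels(channel_set: MotionChannelSet, include_overall: bool) -> dict[str, np.ndarray]:
    """Pool left+right periocular into one channel; keep the canonical order."""
    pooled = {
        "overall": np.asarray(channel_set["overall"]),
        "head": np.asarray(channel_set["head"]),
        "periocular": 0.5
        * (np.asarray(channel_set["left_periocular"]) + np.asarray(channel_set["right_periocular"])),
        "perioral": np.asarray(channel_set["perioral"]),
    }
    if not include_overall:
        pooled.pop("overall")
    return pooled


def diversity_index(channel_set: MotionChannelSet, params: DiversityParams | None = None) -> DiversityResult:
    """Peak-switching motion-diversity index of one trial.

    Peaks are detected per channel on the smoothed, z-scored series, merged
    in time (ties broken by the fixed channel order
    overall < head < periocular < perioral), and the index is the number of
    adjacent peak pairs with different channel labels, per minute of trial.
    Zero or one total peaks give an index of 0.
    """
    params = params or DiversityParams()
    pooled = _pooled_channels(channel_set, params.include_overall)
    order = {name: i for i, name in enumerate(DIVERSITY_CHANNELS)}
    events: list[PeakEvent] = []
    for name, series in pooled.items():
        z = smooth_and_zscore(series, params.smooth_window_s, channel_set.fps)
        events.extend(
            detect_peaks(z, channel_set.fps, params.min_prominence, params.min_separation_s, channel=name)
        )
    events.sort(key=lambda e: (e.time_s, order[e.channel]))
    switches = sum(1 for a, b in zip(events, events[1:]) if a.channel != b.channel)
    minutes = channel_set.duration_s / 60.0
    return DiversityResult(peaks=events, switch_count=switches, index=switches / minutes)


def estimate_latency(
    driving_overall: np.ndarray, displayed_overall: np.ndarray, max_lag_s: float, fps: float
) -> int:
    """Best non-negative lag (frames) aligning displayed onto driving motion.

    Scans lags ``0..max_lag`` and returns the argmax of the cross-correlation
    of the mean-centred series; ties resolve to the smallest lag.  Zero-variance
    input returns 0 with a warning.
    """
    if max_lag_s < 0:
        raise ValueError("max_lag_s must be >= 0")
    x = np.asarray(driving_overall, dtype=float)
    y = np.asarray(displayed_overall, dtype=float)
    if x.shape != y.shape:
        raise ValueError("series must have equal length")
    if x.std() == 0 or y.std() == 0:
        warnings.warn("zero-variance motion series: latency estimate defaults to 0")
        return 0
    x = x - x.mean()
    y = y - y.mean()
    max_lag = min(int(round(max_lag_s * fps)), len(x) - 1)
    corrs = np.array([np.dot(x[: len(x) - lag], y[lag:]) for lag in range(max_lag + 1)])
    return int(np.argmax(corrs))  # argmax returns the first (smallest) maximiser


def motion_error(
    driving_traj: LandmarkTrajectory,
    displayed_traj: LandmarkTrajectory,
    max_lag_s: float = 0.5,
    latency_frames: int | None = None,
) -> ControlErrorResult:
    """Objective control error between an actor's motion and the display.

    Both trajectories are converted to displacement-from-neutral fields, the
    display latency is estimated from the overall-motion series (or supplied),
    the displayed field is shifted back by that lag, and the error is the mean
    over the overlapping frames of the RMS landmark-displacement difference.
    The two trajectories may belong to different identities as long as the
    landmark topology matches.
    """
    if driving_traj.n_frames != displayed_traj.n_frames:
        raise ValueError("driving and displayed trajectories must share the frame count")
    if driving_traj.n_landmarks != displayed_traj.n_landmarks:
        raise ValueError("driving and displayed trajectories must share the landmark topology")
    d_drv = driving_traj.displacements()
    d_dsp = displayed_traj.displacements()
    if latency_frames is None:
        drv_mag = np.concatenate([[0.0], np.linalg.norm(np.diff(d_drv, axis=0), axis=-1).mean(-1)])
        dsp_mag = np.concatenate([[0.0], np.linalg.norm(np.diff(d_dsp, axis=0), axis=-1).mean(-1)])
        latency_frames = estimate_latency(drv_mag, dsp_mag, max_lag_s, driving_traj.fps)
    lag = int(latency_frames)
    a = d_drv[: d_drv.shape[0] - lag] if lag else d_drv
    b = d_dsp[lag:] if lag else d_dsp
    per_frame_rms = np.sqrt(np.mean(np.sum((a - b) ** 2, axis=-1), axis=-1))
    return ControlErrorResult(latency_est_frames=lag, mean_error=float(per_frame_rms.mean()))
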