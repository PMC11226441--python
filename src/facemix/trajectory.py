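"""Landmark-trajectory container shared by every analysis stage.

A trajectory is a ``(T, K, 3)`` array of dimensionless landmark coordinates
sampled at a fixed frame rate.  Coordinates carry no metric unit: the paradigm
this package emulates measures motion relative to the video frame, so all
downstream magnitudes are dimensionless as well.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

__all__ = ["LandmarkTrajectory"]


@dataclass
class LandmarkTrajectory:
    """Per-frame 3D coordinates of K facial landmarks.

    Parameters
    ----------
    coords:
        Array of shape ``(T, K, 3)``; ``T >= 2`` frames, finite values.
    fps:
        Sampling rate in frames per second, ``> 0``.
    topology_id:
        Label of the landmark topology (e.g. ``"toy"``, ``"facemesh468"``).
        Trajectories can only be mixed/compared when topologies agree.
    meta:
        Free-form trial identifiers.  The key ``"neutral"`` may hold the
        ``(K, 3)`` neutral (rest) pose used to form displacement fields;
        when absent, frame 0 is treated as the rest pose.
    """

    coords: np.ndarray
    fps: float
    topology_id: str = "unknown"
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords)
        if not np.issubdtype(self.coords.dtype, np.floating):
            self.coords = self.coords.astype(float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError(f"coords must have shape (T, K, 3), got {self.coords.shape}")
        if self.coords.shape[0] < 2:
            raise ValueError("a trajectory needs at least 2 frames")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords contain non-finite values")
        if not self.fps > 0:
            raise ValueError(f"fps must be positive, got {self.fps}")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_landmarks(self) -> int:
        return self.coords.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps

    @property
    def neutral(self) -> np.ndarray:
        """Rest pose used as the displacement origin (meta override or frame 0)."""
        ref = self.meta.get("neutral")
        if ref is None:
            return self.coords[0]
        return np.asarray(ref, dtype=self.coords.dtype)

    def displacements(self) -> np.ndarray:
        """``(T, K, 3)`` displacement-from-neutral field."""
        return self.coords - self.neutral[None]

    # ------------------------------------------------------------------ I/O

    def to_long_frame(self, trial_id: str = "trial") -> pd.DataFrame:
        """Long CSV layout: one row per (frame, landmark), 0-based frame index."""
        T, K, _ = self.coords.shape
        frames = np.repeat(np.arange(T), K)
        lms = np.tile(np.arange(K), T)
        flat = self.coords.reshape(T * K, 3)
        return pd.DataFrame(
            {
                "trial_id": trial_id,
                "frame": frames,
                "landmark_id": lms,
                "x": flat[:, 0],
                "y": flat[:, 1],
                "z": flat[:, 2],
            }
        )

    @classmethod
    def from_long_frame(
        cls, df: pd.DataFrame, fps: float, topology_id: str = "unknown"
    ) -> "LandmarkTrajectory":
        required = {"frame", "landmark_id", "x", "y", "z"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"long trajectory table missing columns: {sorted(missing)}")
        df = df.sort_values(["frame", "landmark_id"])
        T = df["frame"].nunique()
        K = df["landmark_id"].nunique()
        if len(df) != T * K:
            raise ValueError("long trajectory table is not a complete frame x landmark grid")
        coords = df[["x", "y", "z"]].to_numpy(dtype=float).reshape(T, K, 3)
        meta: dict[str, Any] = {}
        if "trial_id" in df.columns:
            meta["trial_id"] = str(df["trial_id"].iloc[0])
        return cls(coords=coords, fps=fps, topology_id=topology_id, meta=meta)
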