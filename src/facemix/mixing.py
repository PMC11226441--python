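"""Convex mixing of two actors' motion and the display latency.

The paradigm drives a displayed face by a weighted average of two actors'
motion representations: with participant weight ``w = 1`` the participant has
full control, with ``w = 0.5`` the two actors' movement vectors are averaged
(partial control).  Mixing acts on displacement-from-neutral fields, the
mesh-level analogue of a generative animator's latent motion vectors: face
identity is carried entirely by the target neutral mesh, motion by the
displacement field.  The display chain adds a constant feedback latency
(default 9 frames, i.e. about 300 ms at 30 fps).

A sole mover under ``w = 0.5`` keeps full *directional* control while the
amplitude halves; an optional renormalisation flag restores unit gain for
users who prefer amplitude-preserving mixing (off by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh import NeutralMesh
from .trajectory import LandmarkTrajectory

__all__ = ["MixingConfig", "mix_displacements", "apply_latency", "render_displayed"]


@dataclass
class MixingConfig:
    """Participant weight and display latency of the control manipulation."""

    w: float = 0.5  # participant weight: 1 = full control, 0.5 = partial
    latency_frames: int = 9  # ~300 ms at 30 fps
    renormalize: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.w <= 1.0:
            raise ValueError(f"mixing weight must lie in [0, 1], got {self.w}")
        if self.latency_frames < 0 or int(self.latency_frames) != self.latency_frames:
            raise ValueError("latency_frames must be a non-negative integer")
        self.latency_frames = int(self.latency_frames)


def mix_displacements(
    disp_a: np.ndarray, disp_b: np.ndarray, w: float, renormalize: bool = False
) -> np.ndarray:
    """Framewise convex combination ``w * disp_a + (1 - w) * disp_b``.

    Both inputs are ``(T, K, 3)`` displacement-from-neutral fields on the same
    topology.  With ``renormalize`` the result is scaled by
    ``1 / sqrt(w**2 + (1-w)**2)`` so that mixing two independent
    equal-variance motions preserves expected amplitude.
    """
    disp_a = np.asarray(disp_a)
    disp_b = np.asarray(disp_b)
    if disp_a.shape != disp_b.shape:
        raise ValueError(f"displacement shapes differ: {disp_a.shape} vs {disp_b.shape}")
    if not 0.0 <= w <= 1.0:
        raise ValueError(f"mixing weight must lie in [0, 1], got {w}")
    mixed = w * disp_a + (1.0 - w) * disp_b
    if renormalize:
        mixed = mixed / np.sqrt(w**2 + (1.0 - w) ** 2)
    return mixed


def apply_latency(traj: np.ndarray, latency_frames: int) -> np.ndarray:
    """Delay a ``(T, ...)`` framewise array by ``latency_frames``.

    Frame ``t`` of the output equals frame ``max(0, t - latency_frames)`` of
    the input (the display shows its first frame until real input arrives).
    """
    traj = np.asarray(traj)
    T = traj.shape[0]
    if latency_frames < 0:
        raise ValueError("latency_frames must be >= 0")
    if latency_frames >= T:
        raise ValueError(f"latency_frames={latency_frames} must be below the frame count {T}")
    if latency_frames == 0:
        return traj.copy()
    idx = np.maximum(0, np.arange(T) - latency_frames)
    return traj[idx]


def render_displayed(
    target_mesh: NeutralMesh,
    mixed_displacements: np.ndarray,
    config: MixingConfig,
    fps: float = 30.0,
) -> LandmarkTrajectory:
    """Animate a target identity with a (possibly foreign) motion field.

    The displayed trajectory is the target neutral mesh plus the
    latency-shifted displacement field.  The target mesh may belong to a
    different identity than the motion source: this is exactly the paradigm's
    separation of facial appearance (static photo) from motion.
    """
    mixed_displacements = np.asarray(mixed_displacements)
    if mixed_displacements.ndim != 3 or mixed_displacements.shape[1:] != (target_mesh.n_landmarks, 3):
        raise ValueError(
            f"displacement field {mixed_displacements.shape} does not match target mesh "
            f"with {target_mesh.n_landmarks} landmarks"
        )
    delayed = apply_latency(mixed_displacements, config.latency_frames)
    coords = target_mesh.coords.astype(delayed.dtype, copy=False)[None] + delayed
    return LandmarkTrajectory(
        coords=coords,
        fps=fps,
        topology_id=target_mesh.topology_id,
        meta={"neutral": target_mesh.coords.copy(), "latency_frames": config.latency_frames},
    )
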