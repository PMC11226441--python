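"""Rigid/non-rigid decomposition of landmark motion and moving distances.

Facial motion mixes two components: rigid head motion (rotation plus
translation of the whole head) and non-rigid facial-muscle motion (eyes,
lips).  To report them separately we fit, per frame, the least-squares rigid
transform of the neutral pose onto the frame over the ``head_rigid`` landmark
set (Kabsch/Procrustes without scaling), then

* the *head* channel is the per-frame mean landmark displacement of the
  rigidly reconstructed head region (translation contributes its vector norm,
  rotation its mean chord length),
* region channels (*periocular*, *perioral*) are measured after re-expressing
  every frame in the head-stabilised coordinate frame, and
* the *overall* channel is the raw mean per-landmark displacement.

"Moving distance" is the path length of such a channel over a trial: the sum
of per-frame magnitudes, not the net start-to-end displacement.
"""

from __future__ import annotations

import numpy as np

from .mesh import NeutralMesh
from .trajectory import LandmarkTrajectory

__all__ = [
    "rigid_align",
    "rigid_align_series",
    "head_motion_series",
    "region_motion_series",
    "overall_motion_series",
    "moving_distance",
    "compute_channels",
    "MotionChannelSet",
]

#: Channel names in canonical order (also the tie-break order for peak merging).
CHANNEL_ORDER = ("overall", "head", "left_periocular", "right_periocular", "perioral")


class MotionChannelSet(dict):
    """Named per-frame magnitude series plus the sampling rate.

    Behaves as a ``dict`` channel-name -> 1-D array; all series share one
    length and all magnitudes are non-negative.
    """

    def __init__(self, channels: dict[str, np.ndarray], fps: float):
        lengths = {len(v) for v in channels.values()}
        if len(lengths) != 1:
            raise ValueError("all channels must have equal length")
        for name, v in channels.items():
            if np.any(np.asarray(v) < 0):
                raise ValueError(f"channel {name!r} has negative magnitudes")
        super().__init__(channels)
        self.fps = float(fps)

    @property
    def duration_s(self) -> float:
        return len(next(iter(self.values()))) / self.fps


def _kabsch(A: np.ndarray, B: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Batched proper rigid fit of reference points A (n,3) onto frames B (...,n,3).

    Returns rotations (...,3,3), translations (...,3) and RMS residuals (...).
    """
    a0 = A.mean(axis=0)
    Ac = A - a0
    b0 = B.mean(axis=-2)
    Bc = B - b0[..., None, :]
    H = np.swapaxes(Bc, -1, -2) @ Ac  # cross-covariance (frame x ref)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.zeros(U.shape[:-2] + (3, 3))
    D[..., 0, 0] = 1.0
    D[..., 1, 1] = 1.0
    D[..., 2, 2] = d
    R = U @ D @ Vt
    t = b0 - (R @ a0)
    fit = A @ np.swapaxes(R, -1, -2) + t[..., None, :]
    residual = np.sqrt(np.mean(np.sum((fit - B) ** 2, axis=-1), axis=-1))
    return R, t, residual


def rigid_align(
    frame_coords: np.ndarray, reference_coords: np.ndarray, index_set: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid transform (no scaling) of the reference onto one frame.

    Solves ``argmin_{R,t} sum_i ||R a_i + t - b_i||^2`` with ``det(R) = +1``
    over the landmarks in ``index_set`` (all landmarks when omitted).

    Returns ``(rotation, translation, residual)`` where residual is the RMS
    misfit after alignment.  Raises on degenerate (collinear) point sets.
    """
    frame_coords = np.asarray(frame_coords, dtype=float)
    reference_coords = np.asarray(reference_coords, dtype=float)
    if index_set is not None:
        frame_coords = frame_coords[index_set]
        reference_coords = reference_coords[index_set]
    if frame_coords.shape[0] < 3:
        raise ValueError("rigid alignment needs at least 3 points")
    # collinearity check: rank of the centred reference must be >= 2
    centred = reference_coords - reference_coords.mean(axis=0)
    if np.linalg.matrix_rank(centred, tol=1e-10) < 2:
        raise ValueError("degenerate (collinear) point set: rigid rotation not identifiable")
    R, t, res = _kabsch(reference_coords, frame_coords)
    return R, t, float(res)


def rigid_align_series(traj: LandmarkTrajectory, mesh_or_ref) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-frame rigid head pose of a whole trajectory (batched Kabsch).

    ``mesh_or_ref`` is a :class:`NeutralMesh` (the ``head_rigid`` region is
    used) or an explicit index set together with the trajectory's own neutral.
    Returns ``(R, t, residual)`` with shapes ``(T,3,3)``, ``(T,3)``, ``(T,)``.
    """
    if isinstance(mesh_or_ref, NeutralMesh):
        idx = mesh_or_ref.region("head_rigid")
        ref = mesh_or_ref.coords
    else:
        idx = np.asarray(mesh_or_ref, dtype=int)
        ref = traj.neutral
    A = ref[idx].astype(traj.coords.dtype, copy=False)
    centred = A - A.mean(axis=0)
    if np.linalg.matrix_rank(centred, tol=1e-10) < 2:
        raise ValueError("degenerate (collinear) head_rigid point set")
    B = traj.coords[:, idx, :]
    return _kabsch(A, B)


def _frame_step_magnitude(points: np.ndarray) -> np.ndarray:
    """Mean per-landmark frame-to-frame displacement; first frame set to 0."""
    d = np.diff(points, axis=0)
    steps = np.sqrt((d * d).sum(axis=-1)).mean(axis=-1)
    return np.concatenate([[0.0], steps])


def head_motion_series(traj: LandmarkTrajectory, mesh: NeutralMesh) -> np.ndarray:
    """Per-frame rigid head-motion magnitude.

    The rigid transform fitted on the ``head_rigid`` landmarks is applied to
    the neutral head region, and the magnitude is the mean frame-to-frame
    landmark displacement of that rigid reconstruction: a pure translation by
    ``v`` per frame gives ``||v||``; a pure rotation gives the mean chord
    length of the region points under the incremental rotation.
    """
    R, t, _ = rigid_align_series(traj, mesh)
    head = mesh.coords[mesh.region("head_rigid")].astype(R.dtype, copy=False)
    rigid_pts = head @ R.transpose(0, 2, 1) + t[:, None, :]
    return _frame_step_magnitude(rigid_pts)


def _stabilised_coords(traj: LandmarkTrajectory, mesh: NeutralMesh) -> np.ndarray:
    """Re-express every frame in the head-fixed frame (undo the rigid pose)."""
    R, t, _ = rigid_align_series(traj, mesh)
    return (traj.coords - t[:, None, :]) @ R  # R^T (p - t), batched


def region_motion_series(
    traj: LandmarkTrajectory, mesh: NeutralMesh, region: str, remove_rigid: bool = True
) -> np.ndarray:
    """Per-frame mean landmark displacement within one named region.

    With ``remove_rigid`` (default) the trajectory is first head-stabilised, so
    purely rigid motion yields a numerically zero series and the result
    reflects facial-muscle motion only.
    """
    idx = mesh.region(region)  # raises KeyError on unknown region
    coords = _stabilised_coords(traj, mesh) if remove_rigid else traj.coords
    return _frame_step_magnitude(coords[:, idx, :])


def overall_motion_series(traj: LandmarkTrajectory) -> np.ndarray:
    """Per-frame mean displacement over all landmarks, rigid motion included."""
    return _frame_step_magnitude(traj.coords)


def moving_distance(series: np.ndarray, per_second: bool = False, fps: float | None = None) -> float:
    """Path length of a magnitude series: the sum of per-frame magnitudes.

    ``per_second`` divides by the trial duration (needs ``fps``); the study's
    trials share one duration, so the default reports the raw path length.
    """
    series = np.asarray(series, dtype=float)
    if not np.all(np.isfinite(series)):
        raise ValueError("motion series contains non-finite values")
    total = float(series.sum())
    if per_second:
        if fps is None:
            raise ValueError("per-second normalisation needs fps")
        total /= len(series) / fps
    return total


def compute_channels(traj: LandmarkTrajectory, mesh: NeutralMesh,
                     remove_rigid: bool = True) -> MotionChannelSet:
    """All named motion channels of one trial.

    ``overall`` keeps rigid motion in; ``head`` is the rigid component; the
    periocular and perioral channels are head-stabilised by default.
    """
    R, t, _ = rigid_align_series(traj, mesh)
    head = mesh.coords[mesh.region("head_rigid")].astype(R.dtype, copy=False)
    rigid_pts = head @ R.transpose(0, 2, 1) + t[:, None, :]
    stab = (traj.coords - t[:, None, :]) @ R if remove_rigid else traj.coords
    channels = {
        "overall": _frame_step_magnitude(traj.coords),
        "head": _frame_step_magnitude(rigid_pts),
        "left_periocular": _frame_step_magnitude(stab[:, mesh.region("left_periocular"), :]),
        "right_periocular": _frame_step_magnitude(stab[:, mesh.region("right_periocular"), :]),
        "perioral": _frame_step_magnitude(stab[:, mesh.region("perioral"), :]),
    }
    return MotionChannelSet(channels, fps=traj.fps)
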