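"""Seeded generator of naturalistic single-actor facial motion.

The generator emulates a person freely moving their head and face in front of
a webcam for one trial.  Motion has two layers:

* a continuous rigid head wander -- low-frequency sinusoids plus a smooth
  first-order autoregressive walk in rotation and translation; and
* a stream of discrete facial *actions* at Poisson times: short eye
  (blink/squeeze) or mouth (open-close) gestures.  The channel of consecutive
  actions switches with a probability set by ``switch_rate``, the expected
  number of cross-channel switches per minute.

``switch_rate`` is the generative knob behind the motion-diversity index (an
explorative actor changes the kind of movement more often), while
``exploration_multiplier`` scales every amplitude and drives moving distance.
Both are raised together for exploration-mode motion.

All deformations are linear in their amplitude parameters and are applied in
the neutral (head-local) frame before the rigid head transform, so head
stabilisation recovers them exactly, and random-stream consumption does not
depend on any amplitude (scaling an amplitude rescales the identical
realisation).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .mesh import NeutralMesh
from .trajectory import LandmarkTrajectory

__all__ = ["ActorMotionParams", "generate_actor_motion", "explore_variant"]

_AR_COEF = 0.99  # smoothness of the autoregressive head-pose walk


@dataclass
class ActorMotionParams:
    """Amplitudes, frequencies and rates of one actor's spontaneous motion.

    Units: rotation amplitudes in radians, translations in mesh units
    (dimensionless), frequencies in Hz, ``action_rate`` in facial actions per
    second, ``switch_rate`` in expected action-channel switches per minute.
    ``exploration_multiplier`` scales every amplitude; it is the single knob
    separating exploitative (precise, small) from explorative (large)
    movement, while ``switch_rate`` separates repetitive from diverse
    action sequences.
    """

    head_rot_amp: tuple[float, float, float] = (0.06, 0.08, 0.04)
    head_rot_freq: tuple[float, float, float] = (0.09, 0.055, 0.07)
    head_trans_amp: tuple[float, float, float] = (0.020, 0.015, 0.010)
    head_trans_freq: tuple[float, float, float] = (0.065, 0.08, 0.045)
    walk_sd: float = 0.5  # smooth-walk scale, relative to each amplitude
    head_gesture_rate: float = 0.1  # discrete head repositionings per second
    head_gesture_amp: float = 0.12
    head_gesture_duration_s: float = 0.8
    action_rate: float = 0.5
    switch_rate: float = 3.0
    blink_amp: float = 0.5  # eyelid-closure fraction per eye action
    blink_duration_s: float = 0.40
    mouth_amp: float = 0.30  # radial opening fraction per mouth action
    mouth_freq: float = 1.2  # one open-close cycle per action at this frequency
    exploration_multiplier: float = 1.0
    noise_sd: float = 0.001

    def validate(self, fps: float) -> None:
        amps = (*self.head_rot_amp, *self.head_trans_amp, self.blink_amp, self.mouth_amp,
                self.action_rate, self.switch_rate, self.noise_sd,
                self.exploration_multiplier, self.walk_sd, self.blink_duration_s,
                self.head_gesture_rate, self.head_gesture_amp, self.head_gesture_duration_s)
        if any(a < 0 for a in amps):
            raise ValueError("all amplitudes and rates must be >= 0")
        nyquist = fps / 2.0
        freqs = (*self.head_rot_freq, *self.head_trans_freq, self.mouth_freq)
        if any(f >= nyquist for f in freqs):
            raise ValueError(f"all frequencies must be below the Nyquist rate {nyquist} Hz")


def explore_variant(
    params: ActorMotionParams,
    amplitude_gain: float = 1.6,
    switch_rate: float = 18.0,
) -> ActorMotionParams:
    """Exploration-mode version of ``params``: larger, more diverse motion."""
    return replace(
        params,
        exploration_multiplier=params.exploration_multiplier * amplitude_gain,
        switch_rate=switch_rate,
    )


def _euler_rotmats(angles: np.ndarray) -> np.ndarray:
    """Batched intrinsic x-y-z rotation matrices for (T, 3) Euler angles."""
    ax, ay, az = angles[:, 0], angles[:, 1], angles[:, 2]
    cx, sx, cy, sy, cz, sz = np.cos(ax), np.sin(ax), np.cos(ay), np.sin(ay), np.cos(az), np.sin(az)
    R = np.empty((angles.shape[0], 3, 3))
    R[:, 0, 0] = cy * cz
    R[:, 0, 1] = -cy * sz
    R[:, 0, 2] = sy
    R[:, 1, 0] = cx * sz + sx * sy * cz
    R[:, 1, 1] = cx * cz - sx * sy * sz
    R[:, 1, 2] = -sx * cy
    R[:, 2, 0] = sx * sz - cx * sy * cz
    R[:, 2, 1] = sx * cz + cx * sy * sz
    R[:, 2, 2] = cx * cy
    return R


def _ar1_walk(rng: np.random.Generator, T: int, n: int) -> np.ndarray:
    """Smooth stationary random walks with unit marginal variance, (T, n).

    Two cascaded AR(1) filters give a twice-smoothed walk whose velocity is
    itself smooth, emulating slow postural drift rather than jitter.
    """
    from scipy.signal import lfilter

    w = rng.standard_normal((T, n))
    c = np.sqrt(1.0 - _AR_COEF**2)
    for _ in range(2):
        w = lfilter([c], [1.0, -_AR_COEF], w, axis=0)
    sd = w.std(axis=0)
    sd[sd == 0] = 1.0
    return w / sd


def _action_stream(
    rng: np.random.Generator, duration_s: float, action_rate: float, switch_rate: float
) -> tuple[np.ndarray, np.ndarray]:
    """Facial-action times (s) and channels (0 = eyes, 1 = mouth).

    Consecutive actions change channel with probability
    ``switch_rate / (60 * action_rate)`` (capped at 1), so the expected number
    of cross-channel switches per minute equals ``switch_rate``.  Each channel
    is guaranteed at least one action so no analysis channel is left with a
    pure-noise series.
    """
    if action_rate <= 0:
        return np.empty(0), np.empty(0, dtype=int)
    n = max(2, int(rng.poisson(action_rate * duration_s)))
    times = np.sort(rng.uniform(0.0, duration_s, size=n))
    p_switch = min(1.0, switch_rate / (60.0 * action_rate)) if switch_rate > 0 else 0.0
    channels = np.empty(n, dtype=int)
    channels[0] = int(rng.integers(2))
    flips = rng.random(n - 1) < p_switch
    for i in range(1, n):
        channels[i] = 1 - channels[i - 1] if flips[i - 1] else channels[i - 1]
    if len(np.unique(channels)) == 1:  # guarantee both channels appear
        channels[int(rng.integers(n))] = 1 - channels[0]
    return times, channels


def _pulse_envelope(T: int, fps: float, times: np.ndarray, duration_s: float) -> np.ndarray:
    """Sum of raised-cosine pulses of the given duration at the given times."""
    env = np.zeros(T)
    half = max(1, int(round(duration_s * fps / 2)))
    pulse = 0.5 * (1 - np.cos(np.linspace(0, 2 * np.pi, 2 * half + 1)))
    for t0 in times:
        i = int(round(t0 * fps))
        a, b = max(0, i - half), min(T, i + half + 1)
        if a < b:
            env[a:b] = np.maximum(env[a:b], pulse[a - (i - half): b - (i - half)])
    return env


def generate_actor_motion(
    mesh: NeutralMesh,
    params: ActorMotionParams,
    duration_s: float,
    fps: float,
    seed: int | np.random.Generator,
) -> LandmarkTrajectory:
    """Simulate one actor's landmark trajectory for a single trial.

    The head moves as a rigid body (rotation about the head centroid plus
    translation); eye actions deform only the periocular regions and mouth
    actions only the perioral region, both applied in the neutral frame before
    the rigid transform.  Identical ``(mesh, params, duration, fps, seed)``
    yield bitwise-identical output.
    """
    params.validate(fps)
    T = int(round(duration_s * fps))
    if T < 2:
        raise ValueError("trial too short: needs at least 2 frames")
    rng = np.random.default_rng(seed)
    m = params.exploration_multiplier
    tgrid = np.arange(T) / fps

    # --- rigid head pose: sinusoid + smooth AR(1) walk, both scaled by amplitude
    phases = rng.uniform(0, 2 * np.pi, size=6)
    walks = _ar1_walk(rng, T, 6)
    rot_amp = m * np.asarray(params.head_rot_amp)
    trans_amp = m * np.asarray(params.head_trans_amp)
    angles = rot_amp * (
        np.sin(2 * np.pi * np.asarray(params.head_rot_freq) * tgrid[:, None] + phases[:3])
        + params.walk_sd * walks[:, :3]
    )
    trans = trans_amp * (
        np.sin(2 * np.pi * np.asarray(params.head_trans_freq) * tgrid[:, None] + phases[3:])
        + params.walk_sd * walks[:, 3:]
    )

    # --- discrete head repositionings: sparse translation pulses whose velocity
    #     dominates the head (and overall) motion channels
    if params.head_gesture_rate > 0:
        n_gest = max(1, int(rng.poisson(params.head_gesture_rate * duration_s)))
        gest_times = np.sort(rng.uniform(0.0, duration_s, size=n_gest))
        dirs = rng.standard_normal((n_gest, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        half = max(1, int(round(params.head_gesture_duration_s * fps / 2)))
        pulse = 0.5 * (1 - np.cos(np.linspace(0, 2 * np.pi, 2 * half + 1)))
        for t0, d in zip(gest_times, dirs):
            i = int(round(t0 * fps))
            a, b = max(0, i - half), min(T, i + half + 1)
            if a < b:
                trans[a:b] += (m * params.head_gesture_amp) * pulse[a - (i - half): b - (i - half), None] * d

    # --- facial action stream: eye and mouth gesture pulses, channel-switching
    times, channels = _action_stream(rng, duration_s, params.action_rate, params.switch_rate)
    blink_env = _pulse_envelope(T, fps, times[channels == 0], params.blink_duration_s)
    mouth_env = _pulse_envelope(T, fps, times[channels == 1], 1.0 / params.mouth_freq)

    # single precision throughout the heavy tensor work: trajectories are
    # synthetic webcam-scale data, far above float32 resolution
    deform = np.zeros((T, mesh.n_landmarks, 3), dtype=np.float32)
    blink32 = blink_env.astype(np.float32)
    mouth32 = mouth_env.astype(np.float32)
    for region in ("left_periocular", "right_periocular"):
        idx = mesh.region(region)
        center = mesh.coords[idx].mean(axis=0)
        closure = (center - mesh.coords[idx]).astype(np.float32)  # lids collapse toward the eye centre
        deform[:, idx, :] += np.float32(m * params.blink_amp) * blink32[:, None, None] * closure[None]
    mouth_idx = mesh.region("perioral")
    mouth_center = mesh.coords[mouth_idx].mean(axis=0)
    radial = (mesh.coords[mouth_idx] - mouth_center).astype(np.float32)  # lips open radially
    deform[:, mouth_idx, :] += np.float32(m * params.mouth_amp) * mouth32[:, None, None] * radial[None]

    # --- compose: rigid transform of (neutral + deformation) about head centroid
    head_centroid = mesh.coords[mesh.region("head_rigid")].mean(axis=0).astype(np.float32)
    R = _euler_rotmats(angles).astype(np.float32)
    local = mesh.coords.astype(np.float32)[None] + deform - head_centroid
    coords = local @ R.transpose(0, 2, 1) + head_centroid + trans[:, None, :].astype(np.float32)

    if params.noise_sd > 0:
        coords = coords + np.float32(params.noise_sd) * rng.standard_normal(
            coords.shape, dtype=np.float32
        )

    return LandmarkTrajectory(
        coords=coords,
        fps=fps,
        topology_id=mesh.topology_id,
        meta={"neutral": mesh.coords.copy()},
    )
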