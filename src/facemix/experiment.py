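"""Full synthetic two-actor experiments in the study's 2x2 within design.

One experiment emulates 20 participants x {self, other} face x {full,
partial} control x 5 repetitions of 20-s trials at 30 fps.  Each trial:

1. the participant's spontaneous motion is simulated (exploitation-mode
   parameters for the self-face, exploration-mode parameters -- larger
   amplitudes, more frequent dominant-channel switches -- for the other-face);
2. in partial-control trials an independent experimenter motion is simulated
   and the two displacement fields are mixed 50/50; the displayed face is the
   target identity's neutral mesh animated by the (latency-delayed, slightly
   noisy) mixed field;
3. motion channels, moving distances and the diversity index are computed
   from the participant's own motion; the objective control error between the
   participant's motion and the display is computed and mapped to the
   sensorimotor consistency ``c = clip(1 - error / error_scale, 0, 1)``;
4. agency ratings come from the two-mode agency curves at ``c`` and
   self-identification ratings from the additive appearance+control model,
   both with participant-level random intercepts and trial noise.

Identical (design, params, seed) reproduce the trial table bitwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import agency
from .agency import AgencyCurveParams, IdentificationCoeffs, RatingNoise, mode_for_face, soa_curve
from .kinematics import compute_channels, moving_distance
from .mesh import NeutralMesh, make_neutral_mesh
from .metrics import DiversityParams, diversity_index, motion_error
from .mixing import MixingConfig, mix_displacements, render_displayed
from .motion import ActorMotionParams, explore_variant, generate_actor_motion
from .trajectory import LandmarkTrajectory

__all__ = ["ExperimentDesign", "ExperimentParams", "generate_experiment", "TRIAL_COLUMNS"]

TRIAL_COLUMNS = [
    "participant", "face", "control", "repetition",
    "agency_rating", "identification_rating",
    "consistency", "motion_error", "latency_est",
    "dist_overall", "dist_head", "dist_eye_l", "dist_eye_r", "dist_lip",
    "diversity",
]


@dataclass
class ExperimentDesign:
    """Factorial layout of one experiment (defaults = the study's design)."""

    n_participants: int = 20
    faces: tuple[str, str] = ("self", "other")
    controls: tuple[str, str] = ("full", "partial")
    reps: int = 5
    trial_duration_s: float = 20.0
    fps: float = 30.0

    def __post_init__(self) -> None:
        if self.n_participants < 1 or self.reps < 1:
            raise ValueError("n_participants and reps must be >= 1")
        if self.trial_duration_s <= 0 or self.fps <= 0:
            raise ValueError("trial_duration_s and fps must be > 0")
        n_frames = self.trial_duration_s * self.fps
        if abs(n_frames - round(n_frames)) > 1e-9:
            raise ValueError("trial_duration_s x fps must give an integer frame count")

    @property
    def n_trials(self) -> int:
        return self.n_participants * len(self.faces) * len(self.controls) * self.reps


@dataclass
class ExperimentParams:
    """Everything that shapes a synthetic experiment besides the layout.

    ``error_scale`` converts the dimensionless control error into the
    consistency axis of the agency curves; ``display_noise_sd`` emulates the
    small reconstruction jitter of the video-generation chain that keeps even
    full-control trials short of perfect consistency.  Between-participant
    variability enters as lognormal amplitude / switch-rate multipliers and a
    shared Gaussian rating intercept.
    """

    topology_id: str = "toy"
    n_landmarks: int = 64
    self_motion: ActorMotionParams = field(default_factory=ActorMotionParams)
    explore_amplitude_gain: float = 1.6
    explore_switch_rate: float = 18.0
    experimenter_motion: ActorMotionParams | None = None
    mixing: MixingConfig = field(default_factory=lambda: MixingConfig(w=0.5, latency_frames=9))
    display_noise_sd: float = 0.003
    error_scale: float = 0.12
    curves: dict[str, AgencyCurveParams] = field(default_factory=lambda: dict(agency.DEFAULT_CURVES))
    agency_noise: RatingNoise = field(default_factory=lambda: RatingNoise(sd=8.0))
    identification: IdentificationCoeffs = field(default_factory=IdentificationCoeffs)
    identification_noise: RatingNoise = field(default_factory=lambda: RatingNoise(sd=10.0))
    participant_intercept_sd: float = 5.0
    participant_amplitude_sd: float = 0.12  # lognormal sigma on amplitudes
    participant_switch_sd: float = 0.20  # lognormal sigma on switch rate
    diversity: DiversityParams = field(default_factory=DiversityParams)

    def motion_for(self, face: str) -> ActorMotionParams:
        """Participant motion parameters under a face condition."""
        if mode_for_face(face) == "exploit":
            return self.self_motion
        return explore_variant(self.self_motion, self.explore_amplitude_gain, self.explore_switch_rate)


def _participant_mesh(base: NeutralMesh, rng: np.random.Generator) -> NeutralMesh:
    """Identity variation: a small smooth deterministic shape offset."""
    offset = rng.normal(0.0, 0.02, size=base.coords.shape)
    return NeutralMesh(coords=base.coords + offset,
                       region_map={k: v.copy() for k, v in base.region_map.items()},
                       topology_id=base.topology_id)


def generate_experiment(
    design: ExperimentDesign | None = None,
    params: ExperimentParams | None = None,
    seed: int | np.random.SeedSequence = 0,
    store_trajectories: bool = False,
) -> tuple[pd.DataFrame, dict[str, dict[str, LandmarkTrajectory]]]:
    """Simulate a complete experiment; returns (trial table, trajectory store).

    The store maps trial ids to the participant's driving trajectory and the
    displayed trajectory; it is only populated when ``store_trajectories`` is
    set (full stores are large).
    """
    design = design or ExperimentDesign()
    params = params or ExperimentParams()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(int(seed))
    ss_participants, ss_trials, ss_ratings = ss.spawn(3)
    part_rng = np.random.default_rng(ss_participants)
    rating_rng = np.random.default_rng(ss_ratings)
    trial_seeds = ss_trials.spawn(design.n_trials * 2)  # participant + experimenter streams

    base_mesh = make_neutral_mesh(params.topology_id, params.n_landmarks)
    exp_mesh = _participant_mesh(base_mesh, part_rng)  # the experimenter's identity
    experimenter_motion = params.experimenter_motion or replace(
        params.self_motion, exploration_multiplier=1.2, switch_rate=8.0
    )

    rows: list[dict] = []
    store: dict[str, dict[str, LandmarkTrajectory]] = {}
    trial_i = 0
    for p in range(design.n_participants):
        p_mesh = _participant_mesh(base_mesh, part_rng)
        amp_mult = float(np.exp(part_rng.normal(0.0, params.participant_amplitude_sd)))
        switch_mult = float(np.exp(part_rng.normal(0.0, params.participant_switch_sd)))
        intercept = float(part_rng.normal(0.0, params.participant_intercept_sd))
        for face in design.faces:
            motion = params.motion_for(face)
            motion = replace(
                motion,
                exploration_multiplier=motion.exploration_multiplier * amp_mult,
                switch_rate=motion.switch_rate * switch_mult,
            )
            for control in design.controls:
                w = 1.0 if control == "full" else params.mixing.w
                for rep in range(1, design.reps + 1):
                    seed_p, seed_e = trial_seeds[2 * trial_i], trial_seeds[2 * trial_i + 1]
                    trial_i += 1
                    traj_p = generate_actor_motion(
                        p_mesh, motion, design.trial_duration_s, design.fps,
                        np.random.default_rng(seed_p),
                    )
                    disp_p = traj_p.displacements()
                    if control == "partial":
                        traj_e = generate_actor_motion(
                            exp_mesh, experimenter_motion, design.trial_duration_s, design.fps,
                            np.random.default_rng(seed_e),
                        )
                        mixed = mix_displacements(disp_p, traj_e.displacements(), w,
                                                  params.mixing.renormalize)
                    else:
                        mixed = disp_p
                    target = p_mesh if face == "self" else exp_mesh
                    displayed = render_displayed(target, mixed, params.mixing, fps=design.fps)
                    if params.display_noise_sd > 0:
                        # reconstruction jitter of the display chain, modelled as
                        # per-frame global registration offsets
                        noise_rng = np.random.default_rng(seed_p.spawn(1)[0])
                        jitter = np.float32(params.display_noise_sd) * noise_rng.standard_normal(
                            (displayed.n_frames, 1, 3), dtype=np.float32
                        )
                        displayed.coords = displayed.coords + jitter

                    channels = compute_channels(traj_p, p_mesh)
                    div = diversity_index(channels, params.diversity)
                    err = motion_error(traj_p, displayed)
                    c = float(np.clip(1.0 - err.mean_error / params.error_scale, 0.0, 1.0))

                    agency_rating = float(np.clip(
                        soa_curve(c, params.curves[mode_for_face(face)])
                        + intercept
                        + rating_rng.normal(0.0, params.agency_noise.sd),
                        0.0, 100.0,
                    ))
                    ident_rating = float(np.clip(
                        params.identification.intercept
                        + params.identification.beta_self * (face == "self")
                        + params.identification.beta_control * (control == "full")
                        + intercept
                        + rating_rng.normal(0.0, params.identification_noise.sd),
                        0.0, 100.0,
                    ))

                    trial_id = f"p{p:02d}_{face}_{control}_r{rep}"
                    rows.append({
                        "participant": f"p{p:02d}",
                        "face": face,
                        "control": control,
                        "repetition": rep,
                        "agency_rating": agency_rating,
                        "identification_rating": ident_rating,
                        "consistency": c,
                        "motion_error": err.mean_error,
                        "latency_est": err.latency_est_frames,
                        "dist_overall": moving_distance(channels["overall"]),
                        "dist_head": moving_distance(channels["head"]),
                        "dist_eye_l": moving_distance(channels["left_periocular"]),
                        "dist_eye_r": moving_distance(channels["right_periocular"]),
                        "dist_lip": moving_distance(channels["perioral"]),
                        "diversity": div.index,
                    })
                    if store_trajectories:
                        store[trial_id] = {"driving": traj_p, "displayed": displayed}
    table = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    return table, store
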