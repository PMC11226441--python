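"""Neutral face meshes and named landmark regions.

Motion analysis needs a rest pose plus a partition of the landmarks into the
regions whose movement is quantified separately: the rigid head, the two
periocular (eye) regions, the perioral (lip) region, and everything else.
Two topologies ship with the package:

``"toy"``
    A procedural face-shaped mesh of any size ``K >= 12`` (default 64).
    Fast, deterministic, and used throughout the synthetic experiments.
``"facemesh468"``
    The 468-landmark layout produced by common face-tracking pipelines.
    The eye/lip region index sets are read from a packaged JSON map that
    follows the MediaPipe FaceMesh contour convention; coordinates are
    still procedural (the package ships no canonical face scan).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

__all__ = ["NeutralMesh", "REGION_NAMES", "make_neutral_mesh"]

#: Canonical region order used everywhere downstream.
REGION_NAMES = ("head_rigid", "left_periocular", "right_periocular", "perioral", "other")


@dataclass
class NeutralMesh:
    """Rest-pose landmark coordinates plus the named region partition.

    Invariants: regions are disjoint, each is non-empty, together they cover
    a subset of ``range(K)``, and ``K >= 12``.
    """

    coords: np.ndarray  # (K, 3), dimensionless
    region_map: dict[str, np.ndarray] = field(default_factory=dict)
    topology_id: str = "toy"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError(f"coords must be (K, 3), got {self.coords.shape}")
        if self.coords.shape[0] < 12:
            raise ValueError("a mesh needs at least 12 landmarks")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("mesh coordinates must be finite")
        self.region_map = {k: np.asarray(v, dtype=int) for k, v in self.region_map.items()}
        seen: set[int] = set()
        K = self.coords.shape[0]
        for name in REGION_NAMES:
            idx = self.region_map.get(name)
            if idx is None or len(idx) == 0:
                raise ValueError(f"region {name!r} is missing or empty")
            if idx.min() < 0 or idx.max() >= K:
                raise ValueError(f"region {name!r} has out-of-range landmark indices")
            s = set(int(i) for i in idx)
            if seen & s:
                raise ValueError(f"region {name!r} overlaps another region")
            seen |= s

    @property
    def n_landmarks(self) -> int:
        return self.coords.shape[0]

    def region(self, name: str) -> np.ndarray:
        if name not in self.region_map:
            raise KeyError(f"unknown region {name!r}; known: {sorted(self.region_map)}")
        return self.region_map[name]


def _ring(center: np.ndarray, rx: float, ry: float, n: int, z: float) -> np.ndarray:
    """n points on an axis-aligned ellipse around ``center`` at depth offset z."""
    th = 2.0 * np.pi * np.arange(n) / n
    pts = np.stack(
        [center[0] + rx * np.cos(th), center[1] + ry * np.sin(th), np.full(n, center[2] + z)],
        axis=1,
    )
    return pts


def _toy_mesh(K: int) -> NeutralMesh:
    """Deterministic face-shaped layout for any K >= 12.

    Region sizes scale with K but every named region keeps >= 2 points.
    """
    n_head = max(4, round(0.30 * K))
    n_eye = max(2, round(0.12 * K))
    n_mouth = max(2, round(0.18 * K))
    n_other = K - n_head - 2 * n_eye - n_mouth
    if n_other < 1:  # shrink the head allocation for very small K
        n_head += n_other - 1
        n_other = 1
    if n_head < 4:
        raise ValueError(f"K={K} too small to allocate all regions")

    parts: list[np.ndarray] = []
    # Rigid head: face oval plus a nose-bridge line (non-collinear by construction).
    n_oval = max(3, n_head - 3)
    n_nose = n_head - n_oval
    parts.append(_ring(np.array([0.0, 0.0, 0.05]), 0.85, 1.05, n_oval, 0.0))
    nose_y = np.linspace(0.45, -0.15, max(n_nose, 1))
    parts.append(np.stack([np.zeros_like(nose_y), nose_y, np.full_like(nose_y, 0.38)], axis=1)[:n_nose])
    # Periocular rings (subject's left = +x).
    parts.append(_ring(np.array([0.35, 0.35, 0.25]), 0.13, 0.08, n_eye, 0.0))
    parts.append(_ring(np.array([-0.35, 0.35, 0.25]), 0.13, 0.08, n_eye, 0.0))
    # Perioral ring.
    parts.append(_ring(np.array([0.0, -0.45, 0.25]), 0.26, 0.12, n_mouth, 0.0))
    # Remaining landmarks: cheeks/forehead lattice.
    t = np.arange(n_other)
    gx = 0.6 * np.cos(2.4 * t + 0.7)
    gy = 0.75 * np.sin(1.7 * t + 0.2)
    parts.append(np.stack([gx, gy, np.full(n_other, 0.18)], axis=1))

    coords = np.concatenate(parts, axis=0)
    assert coords.shape[0] == K
    ofs = np.cumsum([0, n_oval, n_nose, n_eye, n_eye, n_mouth])
    region_map = {
        "head_rigid": np.arange(0, ofs[2]),
        "left_periocular": np.arange(ofs[2], ofs[3]),
        "right_periocular": np.arange(ofs[3], ofs[4]),
        "perioral": np.arange(ofs[4], ofs[5]),
        "other": np.arange(ofs[5], K),
    }
    return NeutralMesh(coords=coords, region_map=region_map, topology_id="toy")


def _facemesh468() -> NeutralMesh:
    with resources.files("facemix.data").joinpath("facemesh468_regions.json").open() as fh:
        spec = json.load(fh)
    K = int(spec["n_landmarks"])
    named = {name: np.asarray(idx, dtype=int) for name, idx in spec["regions"].items()}
    used = np.concatenate(list(named.values()))
    named["other"] = np.setdiff1d(np.arange(K), used)
    # Procedural coordinates: reuse the toy layout positions but scatter the
    # named indices onto it so region geometry stays face-like.
    base = _toy_mesh(64)
    coords = np.zeros((K, 3))
    centers = {
        "head_rigid": np.array([0.0, 0.1, 0.2]),
        "left_periocular": np.array([0.35, 0.35, 0.25]),
        "right_periocular": np.array([-0.35, 0.35, 0.25]),
        "perioral": np.array([0.0, -0.45, 0.25]),
        "other": np.array([0.0, 0.0, 0.1]),
    }
    radii = {"head_rigid": (0.85, 1.05), "left_periocular": (0.13, 0.08),
             "right_periocular": (0.13, 0.08), "perioral": (0.26, 0.12), "other": (0.7, 0.85)}
    for name, idx in named.items():
        rx, ry = radii[name]
        ring = _ring(centers[name], rx, ry, len(idx), 0.0)
        coords[idx] = ring
    del base
    return NeutralMesh(coords=coords, region_map=named, topology_id="facemesh468")


def make_neutral_mesh(topology_id: str = "toy", K: int | None = None) -> NeutralMesh:
    """Build a deterministic neutral mesh for a named topology.

    Parameters
    ----------
    topology_id:
        ``"toy"`` (procedural, any ``K >= 12``) or ``"facemesh468"``
        (packaged region map, ``K`` fixed at 468).
    K:
        Landmark count for the toy topology (default 64).

    Calling twice with the same arguments returns identical coordinate arrays.
    """
    if topology_id == "toy":
        return _toy_mesh(64 if K is None else int(K))
    if topology_id == "facemesh468":
        if K not in (None, 468):
            raise ValueError("facemesh468 topology has exactly 468 landmarks")
        return _facemesh468()
    raise ValueError(f"unknown topology_id {topology_id!r}")
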