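"""Two-mode exploration-exploitation model of the sense of agency.

The model formalises the idea that a prior belief of control changes how
sensorimotor evidence is turned into an agency judgment.  Watching one's own
face induces a belief of control and the *exploitation* mode: high
sensitivity to prediction errors, so agency collapses steeply as soon as
control is imperfect.  Watching another person's face gives no such prior and
engages the *exploration* mode: judgments lean on action-feedback
regularities and degrade gently.

Each mode maps sensorimotor consistency ``c`` (0 = no control, 1 = perfect
control; operationalised as one minus the normalised motion error) to a 0-100
agency rating through a four-parameter logistic

    rating(c) = b + A / (1 + exp(-k * (c - c0)))

with slope ``k``, midpoint ``c0``, asymptote ``A`` and baseline ``b``.  The
exploitation curve is steeper (larger ``k``, midpoint close to 1); at the
defaults the two curves cross exactly once inside (0, 1), so the
self-face/exploitation mode yields *lower* agency whenever control is
imperfect but higher agency under perfect control.

Self-identification is modelled separately as an additive two-factor rating:
a large appearance term (self vs. other face) plus a smaller motion-control
term, reflecting that facial appearance dominates narrow self-identification
while control still contributes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "AgencyCurveParams",
    "RatingNoise",
    "CurveFit",
    "DEFAULT_CURVES",
    "soa_curve",
    "mode_for_face",
    "simulate_ratings",
    "fit_curves",
    "identification_model",
    "IdentificationCoeffs",
]

MODES = ("exploit", "explore")


@dataclass
class AgencyCurveParams:
    """One mode's agency curve: rating = b + A / (1 + exp(-k (c - c0)))."""

    mode: str
    k: float  # slope, > 0
    c0: float  # midpoint on the consistency axis, in (0, 1)
    A: float  # asymptote, rating units
    b: float  # baseline, rating units

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.k <= 0:
            raise ValueError("slope k must be > 0")
        if not 0.0 < self.c0 < 1.0:
            raise ValueError("midpoint c0 must lie in (0, 1)")
        if self.A < 0 or self.b < 0 or self.A + self.b > 100:
            raise ValueError("need A >= 0, b >= 0 and A + b <= 100 (ratings live on 0-100)")


#: Default curve family: steep exploitation, gentle exploration, one crossing
#: inside (0, 1) with exploit > explore only near perfect control.
DEFAULT_CURVES: dict[str, AgencyCurveParams] = {
    "exploit": AgencyCurveParams(mode="exploit", k=20.0, c0=0.88, A=85.0, b=5.0),
    "explore": AgencyCurveParams(mode="explore", k=6.0, c0=0.60, A=70.0, b=15.0),
}


@dataclass
class RatingNoise:
    """Gaussian trial noise on ratings, truncated to the 0-100 scale."""

    sd: float = 8.0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("noise sd must be >= 0")


def soa_curve(c, params: AgencyCurveParams):
    """Predicted agency rating at sensorimotor consistency ``c`` in [0, 1].

    Monotonically non-decreasing in ``c`` for every valid parameter set.
    Accepts scalars or arrays; values outside [0, 1] raise.
    """
    c_arr = np.asarray(c, dtype=float)
    if np.any((c_arr < 0) | (c_arr > 1)):
        raise ValueError("sensorimotor consistency c must lie in [0, 1]")
    out = params.b + params.A / (1.0 + np.exp(-params.k * (c_arr - params.c0)))
    return float(out) if np.isscalar(c) or c_arr.ndim == 0 else out


def mode_for_face(face: str) -> str:
    """Map the face factor to the agency mode: self -> exploit, other -> explore."""
    norm = str(face).strip().lower()
    if norm == "self":
        return "exploit"
    if norm == "other":
        return "explore"
    raise ValueError(f"unknown face label {face!r}; expected 'self' or 'other'")


def simulate_ratings(
    consistency: np.ndarray,
    face_labels,
    params_by_mode: dict[str, AgencyCurveParams] | None = None,
    noise: RatingNoise | None = None,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Generate per-trial agency ratings from the two-mode curve family.

    ``rating = clip(curve(c, mode(face)) + N(0, sd), 0, 100)``, seeded.
    """
    params_by_mode = params_by_mode or DEFAULT_CURVES
    noise = noise or RatingNoise()
    rng = np.random.default_rng(seed)
    consistency = np.asarray(consistency, dtype=float)
    modes = np.array([mode_for_face(f) for f in face_labels])
    if modes.shape[0] != consistency.shape[0]:
        raise ValueError("consistency and face_labels must have equal length")
    ratings = np.empty_like(consistency)
    for mode in MODES:
        sel = modes == mode
        if sel.any():
            ratings[sel] = soa_curve(consistency[sel], params_by_mode[mode])
    if noise.sd > 0:
        ratings = ratings + rng.normal(0.0, noise.sd, size=ratings.shape)
    return np.clip(ratings, 0.0, 100.0)


@dataclass
class CurveFit:
    """Result of fitting one mode's curve: parameters, residual, convergence."""

    params: AgencyCurveParams
    rms_residual: float
    converged: bool
    n_trials: int
    message: str = ""


def _fit_one_mode(c: np.ndarray, y: np.ndarray, mode: str, n_starts: int,
                  rng: np.random.Generator) -> CurveFit:
    if np.unique(np.round(c, 12)).size < 8:
        raise ValueError(f"mode {mode!r}: need >= 8 distinct consistency values to fit 4 parameters")

    def resid(theta):
        k, c0, A, b = theta
        return b + A / (1.0 + np.exp(-k * (c - c0))) - y

    lo = [1e-2, 1e-3, 0.0, 0.0]
    hi = [500.0, 1.0 - 1e-3, 100.0, 100.0]
    base_starts = [
        (3.0, 0.5, y.max() - y.min() + 1.0, max(y.min(), 0.0)),
        (10.0, 0.7, 70.0, 10.0),
        (30.0, 0.9, 80.0, 5.0),
        (60.0, 0.85, 85.0, 5.0),
        (6.0, 0.3, 60.0, 20.0),
    ]
    starts = list(base_starts)
    for _ in range(max(0, n_starts - len(base_starts))):
        starts.append((10 ** rng.uniform(0, 2), rng.uniform(0.1, 0.95),
                       rng.uniform(30, 95), rng.uniform(0, 30)))
    best = None
    ok = False
    for x0 in starts[:max(n_starts, len(base_starts))]:
        x0 = np.clip(x0, lo, hi)
        try:
            sol = least_squares(resid, x0, bounds=(lo, hi), method="trf")
        except Exception:
            continue
        ok = ok or sol.success
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        return CurveFit(
            params=AgencyCurveParams(mode, 1.0, 0.5, 50.0, 25.0),
            rms_residual=float("inf"), converged=False, n_trials=len(c),
            message="all optimiser starts failed",
        )
    k, c0, A, b = best.x
    A = min(A, 100.0 - min(b, 100.0))  # keep the 0-100 invariant after clipping
    params = AgencyCurveParams(mode=mode, k=float(k), c0=float(c0), A=float(A), b=float(b))
    rms = float(np.sqrt(np.mean(resid(best.x) ** 2)))
    return CurveFit(params=params, rms_residual=rms, converged=ok, n_trials=len(c),
                    message="" if ok else "optimiser did not report convergence")


def fit_curves(
    ratings: np.ndarray,
    consistency: np.ndarray,
    face_labels,
    n_starts: int = 5,
    seed: int | np.random.Generator = 0,
) -> dict[str, CurveFit]:
    """Per-mode nonlinear least-squares fit of the four-parameter curve.

    Trials are split by face label into the two modes and each mode is fitted
    with multi-start trust-region least squares (``n_starts`` seeded starts,
    bounded parameters).  Non-convergence is flagged on the result, never
    raised.
    """
    ratings = np.asarray(ratings, dtype=float)
    consistency = np.asarray(consistency, dtype=float)
    modes = np.array([mode_for_face(f) for f in face_labels])
    rng = np.random.default_rng(seed)
    out: dict[str, CurveFit] = {}
    for mode in MODES:
        sel = modes == mode
        fit = _fit_one_mode(consistency[sel], ratings[sel], mode, n_starts, rng)
        if not fit.converged:
            warnings.warn(f"curve fit for mode {mode!r} did not converge: {fit.message}")
        out[mode] = fit
    return out


@dataclass
class IdentificationCoeffs:
    """Additive self-identification model: appearance dominates control."""

    intercept: float = 20.0
    beta_self: float = 45.0
    beta_control: float = 12.0

    def __post_init__(self) -> None:
        if self.beta_self < 0 or self.beta_control < 0:
            raise ValueError("beta_self and beta_control must be >= 0")


def identification_model(
    face_labels,
    control_labels,
    coeffs: IdentificationCoeffs | None = None,
    noise: RatingNoise | None = None,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Simulate self-identification ratings.

    ``rating = clip(intercept + beta_self * [face=self] + beta_control *
    [control=full] + N(0, sd), 0, 100)``.  The default coefficients make the
    appearance term dominate the control term.
    """
    coeffs = coeffs or IdentificationCoeffs()
    noise = noise or RatingNoise(sd=10.0)
    rng = np.random.default_rng(seed)
    face = np.array([str(f).strip().lower() for f in face_labels])
    control = np.array([str(c).strip().lower() for c in control_labels])
    bad = set(face) - {"self", "other"}
    if bad:
        raise ValueError(f"unknown face labels: {sorted(bad)}")
    bad = set(control) - {"full", "partial"}
    if bad:
        raise ValueError(f"unknown control labels: {sorted(bad)}")
    ratings = (
        coeffs.intercept
        + coeffs.beta_self * (face == "self")
        + coeffs.beta_control * (control == "full")
    ).astype(float)
    if noise.sd > 0:
        ratings = ratings + rng.normal(0.0, noise.sd, size=ratings.shape)
    return np.clip(ratings, 0.0, 100.0)
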