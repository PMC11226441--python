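"""Statistical battery for 2x2 within-subject experiments.

Implements the study-style analysis chain: per-participant cell means, the
2x2 (face x control) repeated-measures ANOVA with partial eta squared,
Bonferroni-corrected paired follow-ups with Cohen's d_z, signal-detection
d-prime, and power / sample-size calculations based on the noncentral t
distribution.

The 2x2 within-subject ANOVA is computed in closed form from orthogonal
contrasts: each effect (face, control, interaction) has 1 numerator degree of
freedom and its F statistic equals the square of the paired t test on the
corresponding per-participant contrast scores.  This makes the implementation
exactly testable against a brute-force sums-of-squares decomposition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AnovaEffect",
    "PowerSpec",
    "aggregate_cell_means",
    "rm_anova_2x2",
    "partial_eta_sq",
    "paired_t",
    "bonferroni_threshold",
    "dprime",
    "power_t",
    "sample_size_t",
    "repetition_trend",
]

FACE_LEVELS = ("self", "other")
CONTROL_LEVELS = ("full", "partial")


@dataclass
class AnovaEffect:
    """One effect of the 2x2 within-subject ANOVA."""

    effect: str  # 'face' | 'control' | 'interaction'
    F: float
    df1: int
    df2: int
    p: float
    eta_p2: float


@dataclass
class PowerSpec:
    """Effect size and error rates for a t-test power analysis."""

    d: float
    alpha: float = 0.05
    power_target: float = 0.8
    tails: int = 1
    design: str = "paired"  # 'paired' | 'independent'

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0.0 < self.power_target < 1.0:
            raise ValueError("power_target must lie in (0, 1)")
        if self.tails not in (1, 2):
            raise ValueError("tails must be 1 or 2")
        if self.design not in ("paired", "independent"):
            raise ValueError("design must be 'paired' or 'independent'")


def aggregate_cell_means(trial_table: pd.DataFrame, value_column: str) -> pd.DataFrame:
    """Per-participant means over repetitions for each face x control cell.

    Returns a frame with one row per participant and columns
    ``self_full, self_partial, other_full, other_partial``.  A participant
    missing any cell raises with the participant and cell named.
    """
    required = {"participant", "face", "control", value_column}
    missing = required - set(trial_table.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    cells = (
        trial_table.groupby(["participant", "face", "control"], observed=True)[value_column]
        .mean()
        .unstack(["face", "control"])
    )
    out = pd.DataFrame(index=cells.index)
    for face in FACE_LEVELS:
        for control in CONTROL_LEVELS:
            if (face, control) not in cells.columns:
                raise ValueError(f"no trials at all for cell ({face}, {control})")
            col = cells[(face, control)]
            if col.isna().any():
                who = col.index[col.isna()][0]
                raise ValueError(f"participant {who!r} is missing cell ({face}, {control})")
            out[f"{face}_{control}"] = col
    return out


def _contrast_f(scores: np.ndarray) -> tuple[float, float]:
    """(F, p) of the 1-df within-subject effect carried by contrast scores."""
    n = len(scores)
    mean = scores.mean()
    var = scores.var(ddof=1)
    if var == 0:
        if mean == 0:
            return 0.0, 1.0
        warnings.warn("zero error variance: F reported as +inf")
        return float("inf"), 0.0
    F = n * mean**2 / var  # = t^2 of the one-sample t on the contrast
    p = float(sps.f.sf(F, 1, n - 1))
    return float(F), p


def rm_anova_2x2(cell_means: pd.DataFrame) -> list[AnovaEffect]:
    """2x2 (face x control) repeated-measures ANOVA from cell means.

    Each effect is the 1-df within-subject test on an orthogonal contrast of
    the four cells; ``F = t^2`` of the paired t on that contrast, with
    ``df = (1, n - 1)``.  Partial eta squared is ``F / (F + df2)``.
    """
    cols = ["self_full", "self_partial", "other_full", "other_partial"]
    missing = set(cols) - set(cell_means.columns)
    if missing:
        raise ValueError(f"cell-mean table missing columns: {sorted(missing)}")
    n = len(cell_means)
    if n < 3:
        raise ValueError("need at least 3 participants")
    y = cell_means[cols].to_numpy(dtype=float)  # (n, 4) in the fixed cell order
    contrasts = {
        "face": 0.5 * np.array([1, 1, -1, -1], dtype=float),  # self - other
        "control": 0.5 * np.array([1, -1, 1, -1], dtype=float),  # full - partial
        "interaction": 0.5 * np.array([1, -1, -1, 1], dtype=float),
    }
    effects = []
    for name, w in contrasts.items():
        F, p = _contrast_f(y @ w)
        effects.append(
            AnovaEffect(effect=name, F=F, df1=1, df2=n - 1, p=p, eta_p2=partial_eta_sq(F, 1, n - 1))
        )
    return effects


def partial_eta_sq(F: float, df1: int, df2: int) -> float:
    """Partial eta squared from an F statistic: F*df1 / (F*df1 + df2)."""
    if F < 0:
        raise ValueError("F must be >= 0")
    if np.isinf(F):
        return 1.0
    return F * df1 / (F * df1 + df2)


def paired_t(x: np.ndarray, y: np.ndarray, tails: int = 2) -> tuple[float, int, float, float]:
    """Paired t test with Cohen's d_z.

    Returns ``(t, df, p, d_z)`` where ``d_z = mean(diff) / sd(diff)``.
    ``tails=1`` tests the directional hypothesis mean(x - y) > 0.
    Nonzero constant differences raise (the statistic is undefined); exactly
    identical samples return ``t = 0, p = 1``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    diff = x - y
    sd = diff.std(ddof=1)
    if sd == 0:
        if np.all(diff == 0):
            return 0.0, n - 1, 1.0 if tails == 2 else 0.5, 0.0
        raise ValueError("zero-variance differences: paired t undefined")
    d_z = diff.mean() / sd
    t = d_z * np.sqrt(n)
    df = n - 1
    p = float(sps.t.sf(t, df)) if tails == 1 else float(2 * sps.t.sf(abs(t), df))
    return float(t), df, p, float(d_z)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Bonferroni-corrected significance level alpha / m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    return alpha / m


def dprime(hit_rate: float, fa_rate: float, n_trials: int | None = None) -> float:
    """Signal-detection sensitivity d' = z(hit) - z(false alarm).

    Extreme rates of exactly 0 or 1 are undefined under the normal quantile;
    when ``n_trials`` is given they are replaced by ``1/(2N)`` and
    ``1 - 1/(2N)`` (the standard log-linear-free correction), otherwise they
    raise.
    """
    rates = []
    for r in (hit_rate, fa_rate):
        if not 0.0 <= r <= 1.0:
            raise ValueError("rates must lie in [0, 1]")
        if r in (0.0, 1.0):
            if n_trials is None:
                raise ValueError("rate of 0 or 1 needs n_trials for the 1/(2N) correction")
            r = 1.0 / (2 * n_trials) if r == 0.0 else 1.0 - 1.0 / (2 * n_trials)
        rates.append(r)
    return float(sps.norm.ppf(rates[0]) - sps.norm.ppf(rates[1]))


def power_t(n: int, spec: PowerSpec) -> float:
    """Achieved power of a t test at sample size ``n`` via the noncentral t.

    Paired design: ``df = n - 1``, noncentrality ``d * sqrt(n)``.  Independent
    design: ``n`` per group, ``df = 2n - 2``, noncentrality ``d * sqrt(n/2)``.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if spec.design == "paired":
        df = n - 1
        nc = spec.d * np.sqrt(n)
    else:
        df = 2 * n - 2
        nc = spec.d * np.sqrt(n / 2.0)
    crit = sps.t.ppf(1.0 - spec.alpha / spec.tails, df)
    power = float(sps.nct.sf(crit, df, nc))
    if spec.tails == 2:
        power += float(sps.nct.cdf(-crit, df, nc))
    return power


def sample_size_t(spec: PowerSpec, n_max: int = 100_000) -> int:
    """Smallest n with power >= the target, scanning upward from n = 2."""
    if spec.d == 0:
        raise ValueError("power target unreachable at d = 0")
    for n in range(2, n_max + 1):
        if power_t(n, spec) >= spec.power_target:
            return n
    raise ValueError(f"no n <= {n_max} reaches power {spec.power_target}")


def repetition_trend(trial_table: pd.DataFrame, value_column: str) -> pd.DataFrame:
    """Test for a linear repetition (practice/habituation) trend per condition.

    Within each participant x condition cell, the least-squares slope of the
    value against the repetition index is computed; per condition, the slopes
    are tested against zero with a one-sample t.  Returns one row per
    condition with ``mean_slope, t, df, p``.
    """
    required = {"participant", "face", "control", "repetition", value_column}
    missing = required - set(trial_table.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    rows = []
    for (face, control), cond in trial_table.groupby(["face", "control"], observed=True):
        slopes = []
        for _, sub in cond.groupby("participant", observed=True):
            if sub["repetition"].nunique() < 2:
                raise ValueError("repetition trend needs >= 2 repetitions per cell")
            slope = np.polyfit(sub["repetition"].to_numpy(dtype=float),
                               sub[value_column].to_numpy(dtype=float), 1)[0]
            slopes.append(slope)
        slopes = np.asarray(slopes)
        n = len(slopes)
        sd = slopes.std(ddof=1)
        if sd == 0:
            t, p = (0.0, 1.0) if np.allclose(slopes.mean(), 0) else (float("inf"), 0.0)
        else:
            t = slopes.mean() / (sd / np.sqrt(n))
            p = float(2 * sps.t.sf(abs(t), n - 1))
        rows.append({"face": face, "control": control, "mean_slope": slopes.mean(),
                     "t": float(t), "df": n - 1, "p": p})
    return pd.DataFrame(rows)
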