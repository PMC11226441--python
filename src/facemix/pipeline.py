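"""End-to-end orchestration: simulate -> analyse -> fit -> report.

The pipeline turns a single config (YAML or JSON) plus a master seed into a
trial table CSV, ANOVA effect sets for every dependent variable, and fitted
agency-curve parameters.  Identical config + seed reproduce every output
byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import stats
from .agency import fit_curves
from .experiment import TRIAL_COLUMNS, ExperimentDesign, ExperimentParams, generate_experiment
from .stats import aggregate_cell_means, repetition_trend, rm_anova_2x2

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "read_trial_table",
    "write_trial_table",
    "anova_battery",
]

log = logging.getLogger("facemix")

#: Dependent variables analysed by the study-style ANOVA battery.
DEPENDENT_VARIABLES = [
    "agency_rating", "identification_rating",
    "dist_overall", "dist_head", "dist_eye_l", "dist_eye_r", "dist_lip",
    "diversity",
]

_RATING_COLUMNS = ("agency_rating", "identification_rating")
_LABELS = {"face": {"self", "other"}, "control": {"full", "partial"}}


@dataclass
class PipelineConfig:
    """Master configuration: design + generator parameters + seed + output dir.

    Round-trips losslessly through YAML/JSON; the master seed deterministically
    derives every stage seed.
    """

    design: ExperimentDesign = field(default_factory=ExperimentDesign)
    params: ExperimentParams = field(default_factory=ExperimentParams)
    seed: int = 0
    output_dir: str | None = None

    def to_dict(self) -> dict[str, Any]:
        return _dataclass_to_dict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        return _dataclass_from_dict(cls, d)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict(), sort_keys=False)
        )
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        raw = path.read_text()
        data = json.loads(raw) if path.suffix == ".json" else yaml.safe_load(raw)
        return cls.from_dict(data)


def _dataclass_to_dict(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _dataclass_to_dict(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {k: _dataclass_to_dict(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_dataclass_to_dict(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def _dataclass_from_dict(cls: type, d: Any) -> Any:
    from .agency import AgencyCurveParams, IdentificationCoeffs, RatingNoise
    from .metrics import DiversityParams
    from .mixing import MixingConfig
    from .motion import ActorMotionParams

    if d is None:
        return None
    nested = {
        "design": ExperimentDesign, "params": ExperimentParams,
        "self_motion": ActorMotionParams, "experimenter_motion": ActorMotionParams,
        "mixing": MixingConfig, "agency_noise": RatingNoise,
        "identification_noise": RatingNoise, "identification": IdentificationCoeffs,
        "diversity": DiversityParams,
    }
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in d:
            continue
        v = d[f.name]
        if f.name == "curves" and isinstance(v, dict):
            v = {m: AgencyCurveParams(**p) if isinstance(p, dict) else p for m, p in v.items()}
        elif f.name in nested and isinstance(v, dict):
            v = _dataclass_from_dict(nested[f.name], v)
        elif isinstance(v, list):
            v = tuple(v)
        kwargs[f.name] = v
    return cls(**kwargs)


# ---------------------------------------------------------------- trial I/O

def write_trial_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a trial table CSV with the documented header."""
    _validate_trial_table(table)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)


def read_trial_table(path: str | Path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read and validate a trial table CSV.

    ``column_map`` renames externally supplied columns onto the package schema
    (``{"their_name": "our_name"}``), for datasets exported by other tools.
    """
    table = pd.read_csv(path)
    if column_map:
        table = table.rename(columns=column_map)
    _validate_trial_table(table)
    return table


def _validate_trial_table(table: pd.DataFrame) -> None:
    required = {"participant", "face", "control", "repetition"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"trial table missing required columns: {sorted(missing)}")
    for col, allowed in _LABELS.items():
        bad = ~table[col].astype(str).str.lower().isin(allowed)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"row {row}: invalid {col} label {table[col].iloc[row]!r} (allowed: {sorted(allowed)})"
            )
    for col in _RATING_COLUMNS:
        if col not in table.columns:
            continue
        vals = table[col].to_numpy(dtype=float)
        bad = (vals < 0) | (vals > 100) | ~np.isfinite(vals)
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(f"row {row}: {col}={vals[row]} outside the 0-100 rating scale")


# ------------------------------------------------------------------ battery

def anova_battery(table: pd.DataFrame, variables: list[str] | None = None) -> dict[str, list[stats.AnovaEffect]]:
    """2x2 repeated-measures ANOVA for every dependent variable present."""
    variables = variables or [v for v in DEPENDENT_VARIABLES if v in table.columns]
    out = {}
    for var in variables:
        cells = aggregate_cell_means(table, var)
        out[var] = rm_anova_2x2(cells)
    return out


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute simulate -> kinematics/metrics -> rating models -> stats -> fit.

    Returns a bundle with the trial table, ANOVA effects per dependent
    variable, the fitted agency curves and the repetition-trend check; when
    ``config.output_dir`` is set, writes ``trials.csv``, ``effects.json``,
    ``fitted_curves.json`` and ``pipeline.log`` there.
    """
    stage_times: dict[str, float] = {}
    t0 = time.perf_counter()
    log.info("simulate: %d participants x %d reps", config.design.n_participants, config.design.reps)
    try:
        table, _ = generate_experiment(config.design, config.params, seed=config.seed)
    except Exception as exc:  # pragma: no cover - defensive
        raise RuntimeError(f"stage 'simulate' failed: {exc}") from exc
    stage_times["simulate"] = time.perf_counter() - t0

    t1 = time.perf_counter()
    try:
        effects = anova_battery(table)
        trend = repetition_trend(table, "agency_rating") if config.design.reps >= 2 else None
    except Exception as exc:
        raise RuntimeError(f"stage 'stats' failed: {exc}") from exc
    stage_times["stats"] = time.perf_counter() - t1

    t2 = time.perf_counter()
    try:
        fits = fit_curves(
            table["agency_rating"].to_numpy(),
            table["consistency"].to_numpy(),
            table["face"],
            seed=np.random.SeedSequence(config.seed).spawn(1)[0].generate_state(1)[0] % (2**31),
        )
    except Exception as exc:
        raise RuntimeError(f"stage 'fit' failed: {exc}") from exc
    stage_times["fit"] = time.perf_counter() - t2

    bundle = {
        "trial_table": table,
        "effects": effects,
        "fitted_curves": fits,
        "repetition_trend": trend,
        "stage_times_s": stage_times,
    }
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_trial_table(table, out / "trials.csv")
        effects_json = {
            var: [dataclasses.asdict(e) for e in effs] for var, effs in effects.items()
        }
        (out / "effects.json").write_text(json.dumps(effects_json, indent=2))
        curves_json = {
            mode: {
                "params": dataclasses.asdict(fit.params),
                "rms_residual": fit.rms_residual,
                "converged": fit.converged,
                "n_trials": fit.n_trials,
            }
            for mode, fit in fits.items()
        }
        (out / "fitted_curves.json").write_text(json.dumps(curves_json, indent=2))
        with open(out / "pipeline.log", "w") as fh:
            for stage, dt in stage_times.items():
                fh.write(f"{stage}: {dt:.2f} s\n")
    for stage, dt in stage_times.items():
        log.info("stage %s finished in %.2f s", stage, dt)
    return bundle
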