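"""Columnar text I/O for records, cohorts and configuration.

All CSV files use scientific notation with 12 significant digits, so a
write-then-read round trip is lossless at that precision.  Configuration
files are flat YAML key-value mappings whose keys mirror the dataclass
field names of :class:`RadarConfig`, :class:`VitalProfile` and
:class:`NoiseSpec` (the field names are disjoint across the three types).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from .demod import PhaseRecord
from .evaluation import Subject, TrialResult, results_frame
from .rates import RateSeries
from .signal_model import NoiseSpec, QuadratureRecord, RadarConfig, VitalProfile

FLOAT_FORMAT = "%.12g"

PathLike = Union[str, Path]


def write_quadrature_csv(record: QuadratureRecord, path: PathLike) -> None:
    df = pd.DataFrame(
        {"t_s": record.times, "i_v": record.i_samples, "q_v": record.q_samples}
    )
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_quadrature_csv(path: PathLike) -> QuadratureRecord:
    df = pd.read_csv(path)
    _require_columns(df, ("t_s", "i_v", "q_v"), path)
    return QuadratureRecord(
        sample_rate=_infer_sample_rate(df["t_s"].to_numpy()),
        i_samples=df["i_v"].to_numpy(),
        q_samples=df["q_v"].to_numpy(),
    )


def write_phase_csv(phase: PhaseRecord, path: PathLike) -> None:
    df = pd.DataFrame({"t_s": phase.times, "phase_rad": phase.phase_samples})
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_phase_csv(path: PathLike) -> PhaseRecord:
    df = pd.read_csv(path)
    _require_columns(df, ("t_s", "phase_rad"), path)
    return PhaseRecord(
        sample_rate=_infer_sample_rate(df["t_s"].to_numpy()),
        phase_samples=df["phase_rad"].to_numpy(),
    )


def write_rates_csv(series: RateSeries, path: PathLike) -> None:
    """No-rate / warm-up ticks are written as empty fields."""
    df = pd.DataFrame(
        {"t_s": series.tick_times, "rr_bpm": series.rr_bpm, "hr_bpm": series.hr_bpm}
    )
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_rates_csv(path: PathLike, window_length: float = 0.0) -> RateSeries:
    df = pd.read_csv(path)
    _require_columns(df, ("t_s", "rr_bpm", "hr_bpm"), path)
    return RateSeries(
        tick_times=df["t_s"].to_numpy(),
        rr_bpm=df["rr_bpm"].to_numpy(),
        hr_bpm=df["hr_bpm"].to_numpy(),
        window_length=window_length,
    )


def write_subjects_csv(subjects: Sequence[Subject], path: PathLike) -> None:
    rows = []
    for s in subjects:
        rows.append(
            {
                "id": s.id,
                "weight_lb": s.weight_lb,
                "height_in": s.height_in,
                "age_yr": s.age_yr,
                "gender": s.gender,
                "posture": s.posture,
                "rr_bpm": s.profile.rr_bpm,
                "hr_bpm": s.profile.hr_bpm,
                "resp_amplitude": s.profile.resp_amplitude,
                "heart_amplitude": s.profile.heart_amplitude,
                "thermal_std": s.noise.thermal_std,
                "phase_walk_std": s.noise.phase_walk_std,
                "seed": s.noise.seed,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False, float_format=FLOAT_FORMAT)


def write_results_csv(results: Sequence[TrialResult], path: PathLike) -> None:
    results_frame(results).to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_results_csv(path: PathLike) -> list[TrialResult]:
    df = pd.read_csv(path)
    _require_columns(
        df,
        ("subject_id", "measured_rr", "measured_hr", "reference_rr", "reference_hr"),
        path,
    )
    return [
        TrialResult(
            subject_id=str(row.subject_id),
            measured_rr=float(row.measured_rr),
            measured_hr=float(row.measured_hr),
            reference_rr=float(row.reference_rr),
            reference_hr=float(row.reference_hr),
        )
        for row in df.itertuples()
    ]


def load_config(path: PathLike) -> Tuple[RadarConfig, VitalProfile, NoiseSpec]:
    """Read a flat key-value config file; unknown keys are an error."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must be a key-value mapping")
    parts = []
    known: set = set()
    for cls in (RadarConfig, VitalProfile, NoiseSpec):
        names = {f.name for f in dataclasses.fields(cls)}
        known |= names
        kwargs = {k: v for k, v in data.items() if k in names}
        if cls is VitalProfile and "resp_harmonic_weights" in kwargs:
            kwargs["resp_harmonic_weights"] = tuple(kwargs["resp_harmonic_weights"])
        parts.append(cls(**kwargs))
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return tuple(parts)  # type: ignore[return-value]


def dump_config(
    config: RadarConfig, profile: VitalProfile, noise: NoiseSpec
) -> dict:
    """Flatten the three configuration dataclasses into one mapping."""
    out: dict = {}
    for obj in (config, profile, noise):
        d = dataclasses.asdict(obj)
        d = {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}
        out.update(d)
    return out


def _infer_sample_rate(times: np.ndarray) -> float:
    if len(times) < 2:
        raise ValueError("need at least two rows to infer the sample rate")
    dt = np.diff(times)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
        raise ValueError("time column is not uniformly spaced")
    return 1.0 / float(dt[0])


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path: PathLike) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
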