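"""Synthetic digital-phenotyping cohorts with plantable relapse signatures.

No patient data ship with this package, so every stage is exercised on
generated cohorts that reproduce the statistical structure the pipeline
assumes:

* **Surveys** — per day, section and question, a latent Gaussian is drawn
  around the section's baseline mean. Questions within a section share a
  daily factor (correlation ``within_section_corr``), which is what makes
  chained-equation imputation informative and gives MCA a dominant
  component. Inside a pre-relapse window the latent SD is multiplied by
  ``relapse_sd_inflation`` and the mean shifted by ``relapse_mean_shift`` —
  the "erratic responding" signature. Values are snapped to the nearest
  legal ordinal level and deleted MCAR with probability ``missing_rate``.
* **GPS** — ``pings_per_day`` evenly spread timestamps per day; each ping is
  at the home coordinate with probability q (q' inside pre-relapse windows,
  q' > q models withdrawal/elevated home time), otherwise at one of a few
  "other" locations, with ~30 m Gaussian coordinate jitter.

Everything is deterministic given (seed, patient_index): survey, GPS and
relapse draws each use an independent derived seed stream.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    GpsTable,
    RelapseAnnotation,
    SurveySchema,
    SurveyTable,
    ValidationError,
    default_schema,
    make_gps_table,
    make_survey_table,
    write_gps,
    write_relapse,
    write_schema,
    write_survey,
)

logger = logging.getLogger(__name__)

DEFAULT_BASELINE_MEANS = {
    "mood": 1.5,
    "sleep": 1.2,
    "social": 1.8,
    "anxiety": 1.4,
    "psychosis": 1.0,
}


@dataclass(frozen=True)
class GpsConfig:
    """home is (lat, lon) in degrees; other locations are scattered 0.5-3 km
    away. q / q_prerelapse are the per-ping home probabilities outside and
    inside pre-relapse windows."""

    home: tuple[float, float] = (12.9716, 77.5946)
    n_other_locations: int = 3
    home_ping_prob_control: float = 0.6
    home_ping_prob_prerelapse: float = 0.85
    pings_per_day: int = 48
    jitter_m: float = 30.0

    def __post_init__(self) -> None:
        for p in (self.home_ping_prob_control, self.home_ping_prob_prerelapse):
            if not 0.0 <= p <= 1.0:
                raise ValidationError("home ping probabilities must be in [0, 1]")


@dataclass(frozen=True)
class SynthConfig:
    """Cohort-level generator settings; defaults are the study conditions
    the pipeline is validated under (a 24-patient, ~6-month cohort with a
    threefold response-SD inflation and elevated home time in the 30 days
    before each relapse, ~20% MCAR survey missingness)."""

    n_patients: int = 24
    span_days: int = 180
    start_date: str = "2021-06-01"
    schema: SurveySchema = field(default_factory=default_schema)
    relapse_spec: Mapping[int, Sequence[int]] | None = None  # patient -> day offsets
    baseline_response_mean: Mapping[str, float] | float = field(
        default_factory=lambda: dict(DEFAULT_BASELINE_MEANS)
    )
    baseline_response_sd: float = 0.5
    within_section_corr: float = 0.6
    relapse_sd_inflation: float = 3.0
    relapse_mean_shift: float = 0.5
    relapse_window_days: int = 30
    missing_rate: float = 0.2
    gps: GpsConfig = field(default_factory=GpsConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValidationError("missing_rate must be in [0, 1)")
        if self.relapse_sd_inflation < 1.0:
            raise ValidationError("relapse_sd_inflation must be >= 1")
        if not 0.0 <= self.within_section_corr <= 1.0:
            raise ValidationError("within_section_corr must be in [0, 1]")

    def section_mean(self, section: str) -> float:
        if isinstance(self.baseline_response_mean, Mapping):
            return float(self.baseline_response_mean.get(section, 1.5))
        return float(self.baseline_response_mean)


def _rng(config: SynthConfig, patient_index: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(patient_index, stream))
    )


def _relapse_days(config: SynthConfig, patient_index: int) -> list[int]:
    """Relapse day offsets for one patient: explicit from relapse_spec, else
    drawn (none / one / two relapses with probability 1/4, 1/2, 1/4)."""
    if config.relapse_spec is not None:
        days = sorted(int(d) for d in config.relapse_spec.get(patient_index, []))
    else:
        rng = _rng(config, patient_index, 2)
        n = int(rng.choice([0, 1, 2], p=[0.25, 0.5, 0.25]))
        days = []
        if n >= 1:
            lo = min(60, config.span_days - 2)
            days.append(int(rng.integers(lo, max(lo + 1, config.span_days - 40))))
        if n >= 2:
            lo2 = days[0] + 40
            if lo2 < config.span_days - 5:
                days.append(int(rng.integers(lo2, config.span_days - 5)))
        days = sorted(days)
    for d in days:
        if not 0 <= d < config.span_days:
            raise ValidationError(
                f"relapse day offset {d} outside span of {config.span_days} days"
            )
    return days


def _prerelapse_mask(config: SynthConfig, relapse_days: list[int]) -> np.ndarray:
    days = np.arange(config.span_days)
    mask = np.zeros(config.span_days, dtype=bool)
    for r in relapse_days:
        mask |= (days >= r - config.relapse_window_days) & (days < r)
    return mask


def _snap_to_levels(values: np.ndarray, levels: Sequence[int]) -> np.ndarray:
    lv = np.asarray(levels, dtype=float)
    idx = np.abs(values[..., None] - lv).argmin(axis=-1)
    return lv[idx]


def _generate_survey(
    config: SynthConfig, patient_index: int, patient_id: str, relapse_days: list[int]
) -> SurveyTable:
    rng = _rng(config, patient_index, 0)
    schema = config.schema
    start = pd.Timestamp(config.start_date)
    dates = start + pd.to_timedelta(np.arange(config.span_days), unit="D")
    in_window = _prerelapse_mask(config, relapse_days)
    sd_scale = np.where(in_window, config.relapse_sd_inflation, 1.0)
    mean_shift = np.where(in_window, config.relapse_mean_shift, 0.0)
    rho = config.within_section_corr

    frames = []
    for section in schema.sections:
        qids = schema.questions[section]
        nq = len(qids)
        day_factor = rng.standard_normal(config.span_days)
        noise = rng.standard_normal((config.span_days, nq))
        latent = (
            config.section_mean(section)
            + mean_shift[:, None]
            + config.baseline_response_sd
            * sd_scale[:, None]
            * (np.sqrt(rho) * day_factor[:, None] + np.sqrt(1.0 - rho) * noise)
        )
        for j, q in enumerate(qids):
            responses = _snap_to_levels(latent[:, j], schema.levels[(section, q)])
            frames.append(
                pd.DataFrame(
                    {
                        "patient_id": patient_id,
                        "date": dates,
                        "section": section,
                        "question_id": q,
                        "response": responses,
                    }
                )
            )
    df = pd.concat(frames, ignore_index=True)
    if config.missing_rate > 0:
        drop = rng.random(len(df)) < config.missing_rate
        df.loc[drop, "response"] = np.nan
    return make_survey_table(df, schema)


def _generate_gps(
    config: SynthConfig, patient_index: int, patient_id: str, relapse_days: list[int]
) -> GpsTable:
    rng = _rng(config, patient_index, 1)
    g = config.gps
    start = pd.Timestamp(config.start_date)
    in_window = _prerelapse_mask(config, relapse_days)

    # fixed "other" location layout per patient, 0.5-3 km from home
    angles = rng.uniform(0, 2 * np.pi, g.n_other_locations)
    dists = rng.uniform(500, 3000, g.n_other_locations)
    deg_per_m_lat = 1.0 / 111_320.0
    deg_per_m_lon = deg_per_m_lat / np.cos(np.deg2rad(g.home[0]))
    others = np.column_stack(
        [
            g.home[0] + dists * np.sin(angles) * deg_per_m_lat,
            g.home[1] + dists * np.cos(angles) * deg_per_m_lon,
        ]
    )

    n_days, ppd = config.span_days, g.pings_per_day
    total = n_days * ppd
    day_idx = np.repeat(np.arange(n_days), ppd)
    minute_step = 24 * 60 / ppd
    minutes = (
        np.tile(np.arange(ppd), n_days) * minute_step
        + rng.uniform(0, minute_step * 0.5, total)
    )
    timestamps = start + pd.to_timedelta(day_idx * 24 * 60 + minutes, unit="m")

    p_home = np.where(in_window[day_idx], g.home_ping_prob_prerelapse,
                      g.home_ping_prob_control)
    at_home = rng.random(total) < p_home
    which_other = (
        rng.integers(0, g.n_other_locations, total)
        if g.n_other_locations > 0
        else np.zeros(total, dtype=int)
    )
    base = np.where(
        at_home[:, None],
        np.asarray(g.home)[None, :],
        others[which_other] if g.n_other_locations > 0 else np.asarray(g.home)[None, :],
    )
    jitter = rng.standard_normal((total, 2)) * g.jitter_m
    lat = base[:, 0] + jitter[:, 0] * deg_per_m_lat
    lon = base[:, 1] + jitter[:, 1] * deg_per_m_lon
    df = pd.DataFrame(
        {
            "patient_id": patient_id,
            "timestamp": timestamps,
            "latitude": lat,
            "longitude": lon,
        }
    )
    return make_gps_table(df)


def generate_patient(
    config: SynthConfig, patient_index: int
) -> tuple[SurveyTable, GpsTable, RelapseAnnotation]:
    """One patient's (survey, GPS, relapse annotation) triple, fully
    deterministic given (config.seed, patient_index)."""
    patient_id = f"P{patient_index:03d}"
    relapse_days = _relapse_days(config, patient_index)
    start = pd.Timestamp(config.start_date)
    annotation = RelapseAnnotation(
        patient_id, tuple(start + pd.Timedelta(days=d) for d in relapse_days)
    )
    survey = _generate_survey(config, patient_index, patient_id, relapse_days)
    gps = _generate_gps(config, patient_index, patient_id, relapse_days)
    return survey, gps, annotation


def generate_cohort(config: SynthConfig, out_dir: str | Path) -> Path:
    """Write a full cohort to *out_dir*: per-patient survey/GPS/annotation
    files, the survey schema, and a manifest. Byte-identical for a given
    seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_schema(config.schema, out / "schema.yaml")
    patients = []
    if config.n_patients == 0:
        logger.warning("n_patients=0: writing manifest only")
    for i in range(config.n_patients):
        survey, gps, annotation = generate_patient(config, i)
        pid = annotation.patient_id
        write_survey(survey, out / f"{pid}_survey.csv")
        write_gps(gps, out / f"{pid}_gps.csv")
        write_relapse([annotation], out / f"{pid}_relapse.json")
        patients.append(
            {
                "patient_id": pid,
                "survey": f"{pid}_survey.csv",
                "gps": f"{pid}_gps.csv",
                "relapse": f"{pid}_relapse.json",
                "n_relapses": len(annotation.relapse_dates),
            }
        )
    manifest = {
        "seed": config.seed,
        "n_patients": config.n_patients,
        "span_days": config.span_days,
        "start_date": config.start_date,
        "missing_rate": config.missing_rate,
        "relapse_sd_inflation": config.relapse_sd_inflation,
        "relapse_mean_shift": config.relapse_mean_shift,
        "schema": "schema.yaml",
        "patients": patients,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def null_config(config: SynthConfig | None = None) -> SynthConfig:
    """The matched no-signal variant: relapse windows exist but carry no
    effect (inflation 1, shift 0, q' = q). Used for false-positive checks."""
    base = config or SynthConfig()
    return replace(
        base,
        relapse_sd_inflation=1.0,
        relapse_mean_shift=0.0,
        gps=replace(
            base.gps, home_ping_prob_prerelapse=base.gps.home_ping_prob_control
        ),
    )
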