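"""Tabular input/output and validated domain containers.

The pipeline consumes three kinds of exported tables, all plain CSV:

* long-format ordinal survey responses (``patient_id,date,section,question_id,response``),
* GPS pings (``patient_id,timestamp,latitude,longitude``),
* relapse annotations (CSV with ``patient_id,relapse_date`` rows, or JSON
  ``{"patient_id": ..., "relapse_dates": [...]}``).

A :class:`SurveySchema` (YAML or JSON) declares the survey sections, their
questions, and the legal ordinal levels per question; validation against it
happens at read time so downstream stages can assume clean data.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

SURVEY_COLUMNS = ["patient_id", "date", "section", "question_id", "response"]
GPS_COLUMNS = ["patient_id", "timestamp", "latitude", "longitude"]


class ValidationError(ValueError):
    """Raised when an input table violates a declared invariant."""


class ParseError(ValueError):
    """Raised when a file cannot be parsed at all (bad CSV, bad timestamp...)."""


# ---------------------------------------------------------------------------
# Schema
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SurveySchema:
    """Ordered sections -> ordered questions -> ordered ordinal levels.

    ``questions`` maps section name to an ordered list of question ids;
    ``levels`` maps (section, question_id) to the sorted list of legal
    integer levels for that question.
    """

    sections: tuple[str, ...]
    questions: Mapping[str, tuple[str, ...]]
    levels: Mapping[tuple[str, str], tuple[int, ...]]

    def __post_init__(self) -> None:
        if not self.sections:
            raise ValidationError("schema must declare at least one section")
        for s in self.sections:
            qs = self.questions.get(s, ())
            if not qs:
                raise ValidationError(f"section {s!r} has no questions")
            if len(set(qs)) != len(qs):
                raise ValidationError(f"duplicate question ids in section {s!r}")
            for q in qs:
                lv = self.levels.get((s, q), ())
                if len(lv) < 2:
                    raise ValidationError(
                        f"question {q!r} in section {s!r} needs >=2 ordinal levels"
                    )

    @property
    def total_questions(self) -> int:
        return sum(len(self.questions[s]) for s in self.sections)

    def question_count(self, section: str) -> int:
        return len(self.questions[section])

    def to_dict(self) -> dict:
        return {
            "sections": [
                {
                    "name": s,
                    "questions": [
                        {"id": q, "levels": list(self.levels[(s, q)])}
                        for q in self.questions[s]
                    ],
                }
                for s in self.sections
            ]
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SurveySchema":
        sections: list[str] = []
        questions: dict[str, tuple[str, ...]] = {}
        levels: dict[tuple[str, str], tuple[int, ...]] = {}
        for sec in d["sections"]:
            name = sec["name"]
            sections.append(name)
            qids = []
            for q in sec["questions"]:
                qids.append(q["id"])
                levels[(name, q["id"])] = tuple(sorted(int(v) for v in q["levels"]))
            questions[name] = tuple(qids)
        return cls(tuple(sections), questions, levels)


DEFAULT_SECTIONS = ("mood", "sleep", "social", "anxiety", "psychosis")


def default_schema(
    questions_per_section: Sequence[int] = (5, 4, 3, 5, 4),
    n_levels: int = 4,
) -> SurveySchema:
    """The standard five-section survey layout (mood, sleep, social, anxiety,
    psychosis) with ordinal levels ``0..n_levels-1`` per question."""
    questions = {}
    levels = {}
    for s, nq in zip(DEFAULT_SECTIONS, questions_per_section):
        qids = tuple(f"{s}_q{i + 1}" for i in range(nq))
        questions[s] = qids
        for q in qids:
            levels[(s, q)] = tuple(range(n_levels))
    return SurveySchema(DEFAULT_SECTIONS, questions, levels)


def read_schema(path: str | Path) -> SurveySchema:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return SurveySchema.from_dict(json.loads(text))
    return SurveySchema.from_dict(yaml.safe_load(text))


def write_schema(schema: SurveySchema, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(schema.to_dict(), indent=2))
    else:
        path.write_text(yaml.safe_dump(schema.to_dict(), sort_keys=False))


# ---------------------------------------------------------------------------
# Survey table
# ---------------------------------------------------------------------------


@dataclass
class SurveyTable:
    """Long-format ordinal survey responses.

    ``df`` has columns patient_id (str), date (datetime64, midnight-normalized),
    section (str), question_id (str), response (float; NaN marks missing).
    Rows are unique on (patient_id, date, section, question_id) and sorted.
    """

    df: pd.DataFrame
    schema: SurveySchema

    def __post_init__(self) -> None:
        self.df = self.df.reset_index(drop=True)

    @property
    def is_complete(self) -> bool:
        return not self.df["response"].isna().any()

    def for_section(self, section: str) -> "SurveyTable":
        return SurveyTable(self.df[self.df["section"] == section].copy(), self.schema)

    def for_patient(self, patient_id: str) -> "SurveyTable":
        return SurveyTable(
            self.df[self.df["patient_id"] == patient_id].copy(), self.schema
        )

    def patients(self) -> list[str]:
        return sorted(self.df["patient_id"].unique())


def _validate_survey_frame(df: pd.DataFrame, schema: SurveySchema) -> pd.DataFrame:
    bad_sections = set(df["section"].unique()) - set(schema.sections)
    if bad_sections:
        raise ValidationError(f"sections not in schema: {sorted(bad_sections)}")

    known = set(schema.levels)
    pairs = set(zip(df["section"], df["question_id"]))
    bad_q = pairs - known
    if bad_q:
        raise ValidationError(f"questions not in schema: {sorted(bad_q)}")

    observed = df[df["response"].notna()]
    bad_rows = []
    for (s, q), sub in observed.groupby(["section", "question_id"], sort=False):
        legal = set(schema.levels[(s, q)])
        mask = ~sub["response"].isin(legal)
        if mask.any():
            bad_rows.extend(sub.index[mask].tolist())
    if bad_rows:
        sample = df.loc[bad_rows[:5], SURVEY_COLUMNS]
        raise ValidationError(
            f"{len(bad_rows)} responses outside declared levels; first offenders:\n"
            f"{sample.to_string(index=False)}"
        )

    n_before = len(df)
    df = df.drop_duplicates(
        subset=["patient_id", "date", "section", "question_id"], keep="last"
    )
    n_dup = n_before - len(df)
    if n_dup:
        logger.warning("collapsed %d duplicate survey rows (kept last occurrence)", n_dup)
    return df.sort_values(["patient_id", "date", "section", "question_id"]).reset_index(
        drop=True
    )


def make_survey_table(df: pd.DataFrame, schema: SurveySchema) -> SurveyTable:
    """Validate an in-memory long-format frame into a :class:`SurveyTable`."""
    df = df.copy()
    df["patient_id"] = df["patient_id"].astype(str)
    df["date"] = pd.to_datetime(df["date"]).dt.normalize()
    df["response"] = pd.to_numeric(df["response"], errors="coerce")
    return SurveyTable(_validate_survey_frame(df, schema), schema)


def read_survey(path: str | Path, schema: SurveySchema) -> SurveyTable:
    """Read a long-format survey CSV and validate it against *schema*.

    Duplicate (patient, date, section, question) rows collapse keeping the
    last occurrence; any response outside its question's declared levels is a
    :class:`ValidationError` listing the offending rows.
    """
    try:
        df = pd.read_csv(path, dtype={"patient_id": str, "question_id": str})
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"cannot parse survey CSV {path}: {exc}") from exc
    missing_cols = set(SURVEY_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ParseError(f"survey CSV {path} missing columns {sorted(missing_cols)}")
    try:
        df["date"] = pd.to_datetime(df["date"], format="ISO8601").dt.normalize()
    except Exception as exc:
        raise ParseError(f"unparseable date in {path}: {exc}") from exc
    df["response"] = pd.to_numeric(df["response"], errors="coerce")
    return SurveyTable(_validate_survey_frame(df, schema), schema)


def write_survey(table: SurveyTable, path: str | Path) -> None:
    out = table.df.copy()
    out["date"] = out["date"].dt.strftime("%Y-%m-%d")
    out["response"] = out["response"].map(
        lambda v: "" if pd.isna(v) else str(int(v))
    )
    out[SURVEY_COLUMNS].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# GPS table
# ---------------------------------------------------------------------------


@dataclass
class GpsTable:
    """GPS pings sorted by (patient_id, timestamp); coordinates in degrees."""

    df: pd.DataFrame

    def for_patient(self, patient_id: str) -> "GpsTable":
        return GpsTable(
            self.df[self.df["patient_id"] == patient_id].reset_index(drop=True)
        )

    def patients(self) -> list[str]:
        return sorted(self.df["patient_id"].unique())


def make_gps_table(df: pd.DataFrame) -> GpsTable:
    df = df.copy()
    df["patient_id"] = df["patient_id"].astype(str)
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    lat, lon = df["latitude"].astype(float), df["longitude"].astype(float)
    bad = (lat.abs() > 90) | (lon.abs() > 180) | lat.isna() | lon.isna()
    if bad.any():
        raise ValidationError(
            f"{int(bad.sum())} GPS rows with out-of-range coordinates "
            f"(|lat|<=90, |lon|<=180 required)"
        )
    df["latitude"], df["longitude"] = lat, lon
    df = df.sort_values(["patient_id", "timestamp"], kind="stable").reset_index(drop=True)
    return GpsTable(df)


def read_gps(path: str | Path) -> GpsTable:
    """Read a GPS ping CSV, validating coordinates and sorting by time."""
    try:
        df = pd.read_csv(path, dtype={"patient_id": str})
    except Exception as exc:  # pragma: no cover
        raise ParseError(f"cannot parse GPS CSV {path}: {exc}") from exc
    missing_cols = set(GPS_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ParseError(f"GPS CSV {path} missing columns {sorted(missing_cols)}")
    if df.empty:
        df = df.assign(timestamp=pd.to_datetime(df["timestamp"]))
        return GpsTable(df.reset_index(drop=True))
    try:
        df["timestamp"] = pd.to_datetime(df["timestamp"], format="ISO8601")
    except Exception as exc:
        raise ParseError(f"unparseable timestamp in {path}: {exc}") from exc
    return make_gps_table(df)


def write_gps(table: GpsTable, path: str | Path) -> None:
    out = table.df.copy()
    out["timestamp"] = out["timestamp"].map(lambda t: t.isoformat())
    out[GPS_COLUMNS].to_csv(path, index=False, float_format="%.8f")


# ---------------------------------------------------------------------------
# Relapse annotations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RelapseAnnotation:
    """Clinically logged relapse dates for one patient, sorted ascending."""

    patient_id: str
    relapse_dates: tuple[pd.Timestamp, ...]

    def __post_init__(self) -> None:
        dates = tuple(pd.Timestamp(d).normalize() for d in self.relapse_dates)
        if len(set(dates)) != len(dates):
            raise ValidationError(
                f"duplicate relapse dates for patient {self.patient_id}"
            )
        object.__setattr__(self, "relapse_dates", tuple(sorted(dates)))


def read_relapse(path: str | Path) -> list[RelapseAnnotation]:
    """Read relapse annotations from CSV (patient_id,relapse_date rows) or
    JSON (an object or list of ``{"patient_id", "relapse_dates"}``)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        records = payload if isinstance(payload, list) else [payload]
        return [
            RelapseAnnotation(
                str(r["patient_id"]),
                tuple(pd.Timestamp(d) for d in r.get("relapse_dates", [])),
            )
            for r in records
        ]
    df = pd.read_csv(path, dtype={"patient_id": str})
    if not {"patient_id", "relapse_date"} <= set(df.columns):
        raise ParseError(f"relapse CSV {path} needs patient_id,relapse_date columns")
    out = []
    for pid, sub in df.groupby("patient_id", sort=True):
        out.append(
            RelapseAnnotation(pid, tuple(pd.to_datetime(sub["relapse_date"])))
        )
    return out


def write_relapse(annotations: Sequence[RelapseAnnotation], path: str | Path) -> None:
    path = Path(path)
    payload = [
        {
            "patient_id": a.patient_id,
            "relapse_dates": [d.strftime("%Y-%m-%d") for d in a.relapse_dates],
        }
        for a in annotations
    ]
    path.write_text(json.dumps(payload, indent=2))


# ---------------------------------------------------------------------------
# Labeled matrices (coassociation, MCA scores)
# ---------------------------------------------------------------------------


def write_matrix(
    matrix: pd.DataFrame, path: str | Path, allow_missing: bool = False
) -> None:
    """Write a labeled matrix (coassociation, MCA scores...) as CSV.

    Row labels go in the first column, column labels in the header; values are
    formatted to 12 significant digits so a read-back round-trips within 1e-9
    relative error. NaN entries are an error unless *allow_missing* is set.
    """
    values = matrix.to_numpy(dtype=float)
    if np.isnan(values).any() and not allow_missing:
        raise ValidationError(
            "matrix contains NaN entries; pass allow_missing=True to write anyway"
        )
    if not np.isfinite(values[~np.isnan(values)]).all():
        raise ValidationError("matrix contains non-finite entries")
    out = matrix.copy()
    if isinstance(out.index, pd.DatetimeIndex):
        out.index = out.index.strftime("%Y-%m-%d")
    if isinstance(out.columns, pd.DatetimeIndex):
        out.columns = out.columns.strftime("%Y-%m-%d")
    out.to_csv(path, float_format="%.12g", index_label="label")


def read_matrix(path: str | Path, parse_dates: bool = False) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    df.index.name = None
    if parse_dates:
        df.index = pd.to_datetime(df.index)
        try:
            df.columns = pd.to_datetime(df.columns)
        except (ValueError, TypeError):
            pass
    return df
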