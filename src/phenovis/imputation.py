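"""Missing-response imputation: LOCF and chained equations (MICE).

Survey adherence is never perfect, so the per-date analyses downstream (MCA
trends, date vectors) need complete tables. Two fill strategies are offered:

* **LOCF** (last observation carried forward): each missing cell takes the
  most recent earlier observation of the same question. Cheap, assumes
  behavioral persistence day-to-day.
* **MICE** (multiple imputation by chained equations): per patient and
  section, the dates x questions matrix is completed by iteratively
  regressing each question on the others, exploiting the correlation between
  questions answered on the same day. Imputed values are rounded to the
  nearest legal ordinal level.

Both operate on the full calendar-day grid from a patient's first to last
observed survey date, so sparse reporting still yields a daily trend.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.impute import IterativeImputer

from .io import SurveySchema, SurveyTable, ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ImputationConfig:
    """Settings for the fill step.

    mice_iterations is the number of chained-equation sweeps over the
    variables; mice_chains > 1 averages several posterior-sampling chains
    and re-rounds (the pipeline consumes a single completed table).
    leading_missing_policy controls cells before the first observation of a
    question: "backfill_first" copies the first observed value backwards,
    "drop_date" leaves those dates out of that question's series.
    """

    method: Literal["locf", "mice"] = "locf"
    mice_iterations: int = 10
    mice_chains: int = 1
    seed: int = 0
    leading_missing_policy: Literal["backfill_first", "drop_date"] = "backfill_first"

    def __post_init__(self) -> None:
        if self.method not in ("locf", "mice"):
            raise ValidationError(f"unknown imputation method {self.method!r}")
        if self.mice_iterations < 1 or self.mice_chains < 1:
            raise ValidationError("mice_iterations and mice_chains must be >= 1")


def _patient_grid(df: pd.DataFrame) -> pd.DatetimeIndex:
    """All calendar days from first to last observed survey date."""
    return pd.date_range(df["date"].min(), df["date"].max(), freq="D")


def _pivot_section(
    df: pd.DataFrame, schema: SurveySchema, section: str, grid: pd.DatetimeIndex
) -> pd.DataFrame:
    """dates x questions matrix for one patient-section, NaN where missing."""
    qids = list(schema.questions[section])
    sub = df[df["section"] == section]
    wide = sub.pivot_table(
        index="date", columns="question_id", values="response", aggfunc="last"
    )
    return wide.reindex(index=grid, columns=qids)


def _melt_section(
    wide: pd.DataFrame, patient_id: str, section: str
) -> pd.DataFrame:
    long = wide.rename_axis(index="date", columns="question_id").stack().rename(
        "response"
    ).reset_index()
    long["patient_id"] = patient_id
    long["section"] = section
    return long[["patient_id", "date", "section", "question_id", "response"]]


def _round_to_levels(values: np.ndarray, levels: tuple[int, ...]) -> np.ndarray:
    """Snap each value to the nearest legal ordinal level."""
    lv = np.asarray(levels, dtype=float)
    idx = np.abs(values[:, None] - lv[None, :]).argmin(axis=1)
    return lv[idx]


def impute_locf(table: SurveyTable, config: ImputationConfig | None = None) -> SurveyTable:
    """Carry each question's last observed value forward over the daily grid.

    Raises :class:`ValidationError` for a (patient, question) with zero
    observations — there is nothing to carry.
    """
    config = config or ImputationConfig(method="locf")
    pieces = []
    for pid, pdf in table.df.groupby("patient_id", sort=True):
        grid = _patient_grid(pdf)
        for section in table.schema.sections:
            wide = _pivot_section(pdf, table.schema, section, grid)
            empty = [q for q in wide.columns if wide[q].notna().sum() == 0]
            if empty:
                raise ValidationError(
                    f"patient {pid}: no observations to carry forward for "
                    f"question(s) {empty} in section {section!r}"
                )
            filled = wide.ffill()
            if config.leading_missing_policy == "backfill_first":
                filled = filled.bfill()
            else:  # drop_date: leading-missing cells stay absent from output
                pass
            pieces.append(_melt_section(filled, pid, section))
    out = pd.concat(pieces, ignore_index=True)
    out = out.dropna(subset=["response"]).sort_values(
        ["patient_id", "date", "section", "question_id"]
    )
    return SurveyTable(out.reset_index(drop=True), table.schema)


def _mice_complete_matrix(
    wide: pd.DataFrame,
    schema: SurveySchema,
    section: str,
    config: ImputationConfig,
    rng_seed: int,
) -> pd.DataFrame:
    """Complete one dates x questions matrix by chained equations."""
    values = wide.to_numpy(dtype=float)
    observed_mask = ~np.isnan(values)
    qids = list(wide.columns)

    # Columns too sparse for a conditional model get a mode fill up front.
    for j, q in enumerate(qids):
        n_obs = int(observed_mask[:, j].sum())
        if n_obs >= 2:
            continue
        legal = schema.levels[(section, q)]
        if n_obs == 1:
            fill = values[observed_mask[:, j], j][0]
        else:
            fill = float(legal[len(legal) // 2])
        logger.warning(
            "section %s question %s has %d observed values; mode-filling with %s",
            section, q, n_obs, fill,
        )
        values[~observed_mask[:, j], j] = fill
        observed_mask[:, j] = True

    if not (~observed_mask).any():
        return pd.DataFrame(values, index=wide.index, columns=qids)

    seeds = np.random.SeedSequence(rng_seed).generate_state(config.mice_chains)
    chains = []
    for c in range(config.mice_chains):
        imputer = IterativeImputer(
            max_iter=config.mice_iterations,
            initial_strategy="most_frequent",
            sample_posterior=config.mice_chains > 1,
            random_state=int(seeds[c] % (2**31)),
            tol=1e-4,
        )
        chains.append(imputer.fit_transform(values))
    completed = np.mean(chains, axis=0)
    if config.mice_chains > 1:
        logger.info("averaged %d MICE chains before rounding", config.mice_chains)

    for j, q in enumerate(qids):
        legal = schema.levels[(section, q)]
        col = completed[:, j]
        col[~observed_mask[:, j]] = _round_to_levels(
            col[~observed_mask[:, j]], legal
        )
        completed[:, j] = col
    completed[observed_mask] = values[observed_mask]  # never touch observed cells
    return pd.DataFrame(completed, index=wide.index, columns=qids)


def impute_mice(table: SurveyTable, config: ImputationConfig | None = None) -> SurveyTable:
    """Fill missing responses by chained-equations regression, per patient
    and per section (the questions of a section are the variable set).

    Missing cells start at the column mode; each sweep regresses one question
    on the others and replaces its missing entries with model predictions
    (posterior draws when averaging several chains). Final fills are rounded
    to the nearest legal level. Deterministic given ``config.seed``.
    """
    config = config or ImputationConfig(method="mice")
    pieces = []
    master = np.random.SeedSequence(config.seed)
    for pid, pdf in table.df.groupby("patient_id", sort=True):
        grid = _patient_grid(pdf)
        for si, section in enumerate(table.schema.sections):
            wide = _pivot_section(pdf, table.schema, section, grid)
            sub_seed = int(
                np.random.SeedSequence(
                    entropy=master.entropy,
                    spawn_key=(zlib.crc32(pid.encode()) % (2**31), si),
                ).generate_state(1)[0]
                % (2**31)
            )
            completed = _mice_complete_matrix(
                wide, table.schema, section, config, sub_seed
            )
            pieces.append(_melt_section(completed, pid, section))
    out = pd.concat(pieces, ignore_index=True).sort_values(
        ["patient_id", "date", "section", "question_id"]
    )
    return SurveyTable(out.reset_index(drop=True), table.schema)


def impute(table: SurveyTable, config: ImputationConfig) -> SurveyTable:
    """Dispatch on ``config.method``."""
    if config.method == "locf":
        return impute_locf(table, config)
    return impute_mice(table, config)
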