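"""Per-section multiple correspondence analysis (MCA) of survey responses.

Each survey section is analyzed separately: every study date becomes a row of
an indicator (one-hot) matrix with one column per (question, ordinal level)
pair. Correspondence analysis of that matrix yields

* principal inertias (eigenvalues) describing how much response variation
  each component carries,
* date scores on the first component — the daily "trend" of the section, and
* eigengaps on the inertia proportions: a large first eigengap means one
  dominant, internally consistent response dimension; a flat spectrum means
  erratic answering.

The implementation is the standard indicator-matrix CA: correspondence
matrix ``P = Z / N``, standardized residuals
``S = Dr^{-1/2} (P - r c^T) Dc^{-1/2}``, thin SVD of ``S``; eigenvalues are
squared singular values and row principal coordinates are
``Dr^{-1/2} U Sigma``. Subtracting the rank-one margin product removes the
trivial constant dimension before the SVD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import SurveySchema, SurveyTable, ValidationError

_ZERO_INERTIA_TOL = 1e-12


@dataclass
class IndicatorMatrix:
    """One-hot coding of a section's complete responses.

    Rows are dates; columns are (question_id, level) pairs in schema order.
    Every row sums to Q, the number of questions in the section.
    """

    section: str
    dates: pd.DatetimeIndex
    columns: list[tuple[str, int]]
    values: np.ndarray  # (n_dates, n_columns) of 0/1
    n_questions: int

    def mean_responses(self) -> np.ndarray:
        """Per-date mean raw ordinal response, recovered from the coding."""
        levels = np.array([lv for _, lv in self.columns], dtype=float)
        return (self.values * levels).sum(axis=1) / self.n_questions


def build_indicator(
    section_table: SurveyTable, schema: SurveySchema, section: str | None = None
) -> IndicatorMatrix:
    """Build the dates x (question, level) indicator matrix for one section.

    The table must be complete (post-imputation) for that section: a missing
    (date, question) cell raises :class:`ValidationError`.
    """
    df = section_table.df
    if section is None:
        present = df["section"].unique()
        if len(present) != 1:
            raise ValidationError(
                f"expected a single-section table, found sections {sorted(present)}"
            )
        section = str(present[0])
    else:
        df = df[df["section"] == section]
    if df["response"].isna().any():
        raise ValidationError("indicator matrix needs complete responses; impute first")

    qids = list(schema.questions[section])
    wide = df.pivot_table(
        index="date", columns="question_id", values="response", aggfunc="last"
    ).reindex(columns=qids)
    if wide.isna().any().any():
        missing = int(wide.isna().sum().sum())
        raise ValidationError(
            f"{missing} missing (date, question) cells in section {section!r}; "
            "impute first"
        )

    columns: list[tuple[str, int]] = []
    blocks = []
    for q in qids:
        levels = schema.levels[(section, q)]
        col = wide[q].to_numpy()
        block = (col[:, None] == np.asarray(levels)[None, :]).astype(float)
        if not np.all(block.sum(axis=1) == 1):
            bad = np.where(block.sum(axis=1) != 1)[0]
            raise ValidationError(
                f"responses outside declared levels for question {q!r} "
                f"at rows {bad[:5].tolist()}"
            )
        blocks.append(block)
        columns.extend((q, int(lv)) for lv in levels)
    values = np.hstack(blocks)
    return IndicatorMatrix(
        section=section,
        dates=pd.DatetimeIndex(wide.index),
        columns=columns,
        values=values,
        n_questions=len(qids),
    )


@dataclass
class McaResult:
    """Eigenstructure and date scores of one section's MCA."""

    section: str
    dates: pd.DatetimeIndex
    eigenvalues: np.ndarray  # principal inertias, non-increasing
    inertia_proportions: np.ndarray
    row_scores: pd.DataFrame  # dates x components, principal coordinates
    first_eigengap: float
    second_eigengap: float
    total_inertia: float
    degenerate: bool = False
    column_loadings: np.ndarray = field(default=None, repr=False)  # type: ignore


def _component_signs(
    scores: np.ndarray, loadings: np.ndarray, mean_resp: np.ndarray
) -> np.ndarray:
    """Resolve SVD sign indeterminacy: each component correlates >= 0 with
    the dates' mean raw response; exact ties make the leading loading
    positive."""
    centered = mean_resp - mean_resp.mean()
    signs = np.ones(scores.shape[1])
    for k in range(scores.shape[1]):
        cov = float(scores[:, k] @ centered)
        if abs(cov) > 1e-12:
            signs[k] = np.sign(cov)
        else:
            nz = np.nonzero(np.abs(loadings[:, k]) > 1e-12)[0]
            if nz.size:
                signs[k] = np.sign(loadings[nz[0], k])
    return signs


def fit_mca(indicator: IndicatorMatrix) -> McaResult:
    """Correspondence analysis of the indicator matrix.

    Returns eigenvalues sorted non-increasing, inertia proportions, and row
    principal coordinates with a deterministic sign convention. When all
    dates answered identically there is zero inertia: the result carries
    all-zero eigenvalues and scores and ``degenerate=True``.
    """
    Z = np.asarray(indicator.values, dtype=float)
    n, J = Z.shape
    if n < 2:
        raise ValidationError("MCA needs at least 2 dates")
    Q = indicator.n_questions
    row_sums = Z.sum(axis=1)
    if not np.allclose(row_sums, Q):
        raise ValidationError("indicator rows must each sum to the question count")

    N = Z.sum()
    P = Z / N
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    keep = c > 0  # unused levels carry no mass and no inertia
    S = (P[:, keep] - np.outer(r, c[keep])) / np.sqrt(
        np.outer(r, c[keep])
    )

    n_comp = max(min(n, int(keep.sum())) - 1, 1)
    total_inertia = float((S * S).sum())
    comp_names = [f"component_{k + 1}" for k in range(n_comp)]
    if total_inertia < _ZERO_INERTIA_TOL:
        zeros = np.zeros(n_comp)
        return McaResult(
            section=indicator.section,
            dates=indicator.dates,
            eigenvalues=zeros,
            inertia_proportions=zeros.copy(),
            row_scores=pd.DataFrame(
                np.zeros((n, n_comp)), index=indicator.dates, columns=comp_names
            ),
            first_eigengap=0.0,
            second_eigengap=0.0,
            total_inertia=0.0,
            degenerate=True,
            column_loadings=np.zeros((int(keep.sum()), n_comp)),
        )

    U, sigma, Vt = np.linalg.svd(S, full_matrices=False)
    U, sigma, Vt = U[:, :n_comp], sigma[:n_comp], Vt[:n_comp]
    eigenvalues = sigma**2
    scores = U * sigma[None, :] / np.sqrt(r)[:, None]
    loadings = Vt.T

    signs = _component_signs(scores, loadings, indicator.mean_responses())
    scores = scores * signs[None, :]
    loadings = loadings * signs[None, :]

    proportions = eigenvalues / eigenvalues.sum()
    padded = np.concatenate([proportions, np.zeros(max(0, 3 - proportions.size))])
    return McaResult(
        section=indicator.section,
        dates=indicator.dates,
        eigenvalues=eigenvalues,
        inertia_proportions=proportions,
        row_scores=pd.DataFrame(scores, index=indicator.dates, columns=comp_names),
        first_eigengap=float(padded[0] - padded[1]),
        second_eigengap=float(padded[1] - padded[2]),
        total_inertia=total_inertia,
        degenerate=False,
        column_loadings=loadings,
    )


def eigengaps(result: McaResult) -> tuple[float, float]:
    """(p1 - p2, p2 - p3) on inertia proportions, zero-padded below 3
    components; (0, 0) for a degenerate (zero-inertia) fit."""
    if result.degenerate:
        return 0.0, 0.0
    p = np.concatenate(
        [result.inertia_proportions, np.zeros(max(0, 3 - result.inertia_proportions.size))]
    )
    return float(p[0] - p[1]), float(p[1] - p[2])


def mca_trend(result: McaResult) -> pd.Series:
    """First-component date scores — the section's daily trend series."""
    return result.row_scores.iloc[:, 0].rename(result.section)


def fit_section(
    table: SurveyTable, schema: SurveySchema, section: str
) -> McaResult:
    """Convenience: indicator + fit for one section of a complete table."""
    return fit_mca(build_indicator(table.for_section(section), schema, section))
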