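"""Control vs pre-relapse window statistics on the MCA trends.

A relapse window is the 30 days leading up to a clinically logged relapse
date; the control window is the earliest clean 30-day stretch of the study
containing no relapse window. Summarizing the per-section MCA trend inside
each window (n, mean, sample SD) quantifies what the trend charts show
visually: response behavior becomes erratic — SD inflates — in the month
before relapse. A section is flagged anomalous for a relapse window when its
trend SD there exceeds the control SD by a configurable ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .io import RelapseAnnotation, ValidationError

logger = logging.getLogger(__name__)

SD_FLOOR = 1e-6


@dataclass(frozen=True)
class WindowPolicy:
    """window_days fixes the "month" to 30 days for determinism; the control
    window is the earliest window_days-long stretch free of any relapse
    window (override control_start to pin it elsewhere)."""

    window_days: int = 30
    control_start: pd.Timestamp | None = None


@dataclass(frozen=True)
class AnalysisWindow:
    label: str
    start: pd.Timestamp  # inclusive
    end: pd.Timestamp  # exclusive

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(f"empty window {self.label}: {self.start}..{self.end}")

    def contains(self, dates: pd.DatetimeIndex) -> np.ndarray:
        return (dates >= self.start) & (dates < self.end)

    @property
    def n_days(self) -> int:
        return int((self.end - self.start).days)


def define_windows(
    annotation: RelapseAnnotation,
    span: tuple[pd.Timestamp, pd.Timestamp],
    policy: WindowPolicy | None = None,
) -> list[AnalysisWindow]:
    """Build [r - window_days, r) relapse windows plus one control window.

    Windows are clipped to the study span and to each other (a second
    relapse within window_days of the first starts its window at the first
    relapse date), so windows never overlap. Truncation is logged; n in the
    downstream summary reflects it.
    """
    policy = policy or WindowPolicy()
    span_start = pd.Timestamp(span[0]).normalize()
    span_end = pd.Timestamp(span[1]).normalize() + pd.Timedelta(days=1)
    wdays = pd.Timedelta(days=policy.window_days)

    relapse_windows: list[AnalysisWindow] = []
    prev_end = span_start
    for i, r in enumerate(annotation.relapse_dates, start=1):
        r = pd.Timestamp(r).normalize()
        if not (span_start <= r < span_end):
            raise ValidationError(
                f"relapse date {r.date()} outside study span for "
                f"patient {annotation.patient_id}"
            )
        start = max(r - wdays, span_start, prev_end)
        if start >= r:
            logger.warning(
                "relapse %d of patient %s leaves no pre-relapse days; skipped",
                i, annotation.patient_id,
            )
            continue
        if start > r - wdays:
            logger.warning(
                "relapse window %d of patient %s truncated to %d days",
                i, annotation.patient_id, (r - start).days,
            )
        relapse_windows.append(AnalysisWindow(f"relapse-{i}", start, r))
        prev_end = r

    if policy.control_start is not None:
        cstart = pd.Timestamp(policy.control_start).normalize()
        cend = min(cstart + wdays, span_end)
        control = AnalysisWindow("control", cstart, cend)
    else:
        control = _earliest_clean_window(span_start, span_end, relapse_windows, wdays)
    return [control] + relapse_windows


def _earliest_clean_window(
    span_start: pd.Timestamp,
    span_end: pd.Timestamp,
    relapse_windows: list[AnalysisWindow],
    wdays: pd.Timedelta,
) -> AnalysisWindow:
    day = pd.Timedelta(days=1)
    start = span_start
    while start + wdays <= span_end:
        end = start + wdays
        clash = [w for w in relapse_windows if (start < w.end) and (w.start < end)]
        if not clash:
            return AnalysisWindow("control", start, end)
        start = max(w.end for w in clash)  # jump past the conflict
    # no clean full-length stretch: fall back to the longest clean prefix
    logger.warning("no clean %s-day control stretch; truncating", wdays.days)
    first_block = min(
        (w.start for w in relapse_windows), default=span_end
    )
    end = min(span_start + wdays, first_block, span_end)
    return AnalysisWindow("control", span_start, end)


def summarize_windows(
    trends: Mapping[str, pd.Series], windows: list[AnalysisWindow]
) -> pd.DataFrame:
    """Per (section, window) n / mean / sample-SD of the MCA trend values.

    Sample SD uses ddof=1 and is reported as 0 for single-value windows;
    empty windows get n=0 with missing mean/SD.
    """
    rows = []
    for section, series in trends.items():
        dates = pd.DatetimeIndex(series.index)
        for w in windows:
            vals = series.to_numpy()[w.contains(dates)]
            n = len(vals)
            if n == 0:
                mean, sd = np.nan, np.nan
            elif n == 1:
                mean, sd = float(vals[0]), 0.0
            else:
                mean, sd = float(np.mean(vals)), float(np.std(vals, ddof=1))
            rows.append(
                {"section": section, "window": w.label, "n": n, "mean": mean, "sd": sd}
            )
    return pd.DataFrame(rows)


def flag_anomalous_windows(
    summary: pd.DataFrame, ratio_threshold: float = 2.0, eps: float = SD_FLOOR
) -> pd.DataFrame:
    """Flag (section, relapse-window) pairs whose trend SD is at least
    ``ratio_threshold`` times the control SD (floored at *eps* so a
    perfectly flat control still allows flagging).

    Returns the summary with ``sd_ratio``, ``flagged`` and ``flag_reason``
    columns; control rows and rows with missing statistics are never flagged
    and carry the reason.
    """
    out = summary.copy()
    out["sd_ratio"] = np.nan
    out["flagged"] = False
    out["flag_reason"] = ""
    control = (
        out[out["window"] == "control"].set_index("section")["sd"].to_dict()
    )
    for idx, row in out.iterrows():
        if row["window"] == "control":
            out.at[idx, "flag_reason"] = "control window"
            continue
        c_sd = control.get(row["section"])
        if c_sd is None or np.isnan(c_sd):
            out.at[idx, "flag_reason"] = "no control SD available"
            continue
        if row["n"] == 0 or np.isnan(row["sd"]):
            out.at[idx, "flag_reason"] = "empty window"
            continue
        ratio = row["sd"] / max(c_sd, eps)
        out.at[idx, "sd_ratio"] = ratio
        if ratio >= ratio_threshold:
            out.at[idx, "flagged"] = True
        else:
            out.at[idx, "flag_reason"] = "below threshold"
    return out
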