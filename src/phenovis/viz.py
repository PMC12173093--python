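"""Static charts and the two-panel comparative HTML report.

Five chart types cover the analytics outputs:

* ``mca_trend`` — per-section daily first-component trend lines with relapse
  dates marked,
* ``eigengap`` — per-section bars of first/second eigengaps (response
  consistency diagnostic),
* ``coassociation`` — date x date consensus heatmap with a dashed marker one
  month before each relapse,
* ``home_time`` — month calendar grid, cells shaded by home-time percentage,
* ``location_pies`` — month calendar of pie glyphs of daily dwell fractions.

This module is pure presentation: it draws precomputed results and embeds
the exact numbers it was given (as a JSON block) plus full parameter
provenance in every fragment, so any report can be audited and regenerated.
"""

from __future__ import annotations

import base64
import html
import io as _io
import json
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")  # report rendering is always headless

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib import colormaps

FEATURES = ("mca_trend", "eigengap", "coassociation", "home_time", "location_pies")


@dataclass
class PanelSpec:
    """What one report panel shows and with which parameters."""

    patient_id: str
    feature: str
    parameters: dict = field(default_factory=dict)
    relapse_dates: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.feature not in FEATURES:
            raise ValueError(f"unknown feature {self.feature!r}; expected {FEATURES}")

    def caption(self) -> str:
        params = ", ".join(f"{k}={v}" for k, v in sorted(self.parameters.items()))
        return f"patient {self.patient_id} — {self.feature}" + (
            f" ({params})" if params else ""
        )


def _fig_to_img(fig) -> str:
    buf = _io.BytesIO()
    fig.savefig(buf, format="png", dpi=110, bbox_inches="tight")
    plt.close(fig)
    data = base64.b64encode(buf.getvalue()).decode("ascii")
    return f'<img alt="chart" src="data:image/png;base64,{data}"/>'


def _data_block(payload) -> str:
    return (
        '<script type="application/json" class="panel-data">'
        + json.dumps(payload, default=str)
        + "</script>"
    )


def _placeholder(spec: PanelSpec, reason: str) -> str:
    return (
        '<div class="panel placeholder">'
        f"<h3>{html.escape(spec.caption())}</h3>"
        f"<p>No data to display: {html.escape(reason)}</p></div>"
    )


# ---------------------------------------------------------------------------
# individual chart renderers
# ---------------------------------------------------------------------------


def _render_mca_trend(spec: PanelSpec, trends: dict) -> tuple[str, dict]:
    sections = list(trends)
    fig, axes = plt.subplots(
        len(sections), 1, figsize=(8, 1.8 * len(sections)), sharex=True, squeeze=False
    )
    for ax, section in zip(axes.ravel(), sections):
        series = trends[section]
        ax.plot(pd.DatetimeIndex(series.index), series.to_numpy(), lw=0.8)
        for r in spec.relapse_dates:
            ax.axvline(pd.Timestamp(r), color="crimson", ls="--", lw=1)
        ax.set_ylabel(section, fontsize=8)
    axes.ravel()[-1].set_xlabel("date")
    fig.suptitle(f"MCA first-component trend — patient {spec.patient_id}", fontsize=10)
    payload = {
        s: {str(d.date()): float(v) for d, v in trends[s].items()} for s in sections
    }
    return _fig_to_img(fig), payload


def _render_eigengap(spec: PanelSpec, gaps: dict) -> tuple[str, dict]:
    sections = list(gaps)
    first = [gaps[s][0] for s in sections]
    second = [gaps[s][1] for s in sections]
    x = np.arange(len(sections))
    fig, ax = plt.subplots(figsize=(7, 3.2))
    ax.bar(x - 0.2, first, width=0.4, label="first eigengap")
    ax.bar(x + 0.2, second, width=0.4, label="second eigengap")
    ax.set_xticks(x, sections)
    ax.set_ylabel("inertia-proportion gap")
    ax.legend(fontsize=8)
    ax.set_title(f"Response consistency — patient {spec.patient_id}", fontsize=10)
    payload = {s: [float(gaps[s][0]), float(gaps[s][1])] for s in sections}
    return _fig_to_img(fig), payload


def _render_coassociation(spec: PanelSpec, matrix: pd.DataFrame) -> tuple[str, dict]:
    dates = pd.DatetimeIndex(matrix.index)
    fig, ax = plt.subplots(figsize=(5.5, 5))
    im = ax.imshow(matrix.to_numpy(), vmin=0, vmax=1, cmap="viridis", origin="lower")
    for r in spec.relapse_dates:
        marker = pd.Timestamp(r) - pd.Timedelta(days=30)
        if dates.min() <= marker <= dates.max():
            pos = int(np.searchsorted(dates, marker))
            ax.axvline(pos, color="black", ls=":", lw=1.2)
            ax.axhline(pos, color="black", ls=":", lw=1.2)
    fig.colorbar(im, ax=ax, label="coassociation")
    ax.set_title(f"Date-clustering consensus — patient {spec.patient_id}", fontsize=10)
    step = max(1, len(dates) // 8)
    ticks = np.arange(0, len(dates), step)
    ax.set_xticks(ticks, [str(dates[t].date()) for t in ticks], rotation=90, fontsize=6)
    ax.set_yticks(ticks, [str(dates[t].date()) for t in ticks], fontsize=6)
    payload = {
        "dates": [str(d.date()) for d in dates],
        "values": matrix.to_numpy().round(12).tolist(),
    }
    return _fig_to_img(fig), payload


def _month_grid(month: pd.Period, week_start_monday: bool = True):
    """Yield (date, week_row, weekday_col) for every day of the month."""
    first = month.to_timestamp()
    ndays = month.days_in_month
    offset = first.dayofweek if week_start_monday else (first.dayofweek + 1) % 7
    for d in range(ndays):
        date = first + pd.Timedelta(days=d)
        slot = offset + d
        yield date, slot // 7, slot % 7


def _select_month(spec: PanelSpec, index: pd.DatetimeIndex) -> pd.Period:
    if "month" in spec.parameters:
        return pd.Period(spec.parameters["month"], freq="M")
    return pd.Period(index.min(), freq="M")


def _render_home_time(spec: PanelSpec, summary: pd.DataFrame) -> tuple[str, dict]:
    month = _select_month(spec, pd.DatetimeIndex(summary.index))
    cmap = colormaps["YlOrRd"]
    fig, ax = plt.subplots(figsize=(7, 5))
    ax.set_xlim(0, 7)
    ax.set_ylim(6, 0)
    ax.axis("off")
    payload = {}
    for date, row, col in _month_grid(month):
        val = (
            summary.at[date, "home_time_pct"] if date in summary.index else np.nan
        )
        has_pings = (
            date in summary.index and int(summary.at[date, "ping_count"]) > 0
        )
        if has_pings and not pd.isna(val):
            color = cmap(val / 100.0)
            payload[str(date.date())] = float(val)
        else:
            color = "white"  # blank cell: no data that day
            payload[str(date.date())] = None
        ax.add_patch(
            plt.Rectangle((col, row), 1, 1, facecolor=color, edgecolor="0.7")
        )
        ax.text(col + 0.05, row + 0.25, str(date.day), fontsize=7, color="0.3")
    ax.set_title(
        f"Home time {month} — patient {spec.patient_id} (white = no data; "
        "0% pale to 100% dark)",
        fontsize=9,
    )
    return _fig_to_img(fig), payload


def _render_location_pies(spec: PanelSpec, summary: pd.DataFrame) -> tuple[str, dict]:
    month = _select_month(spec, pd.DatetimeIndex(summary.index))
    frac_cols = [c for c in summary.columns if c.startswith("frac_")]
    cmap = colormaps["tab10"]
    fig, ax = plt.subplots(figsize=(7, 5))
    ax.set_xlim(0, 7)
    ax.set_ylim(6, 0)
    ax.axis("off")
    payload = {}
    for date, row, col in _month_grid(month):
        cx, cy = col + 0.5, row + 0.5
        ax.add_patch(
            plt.Rectangle((col, row), 1, 1, facecolor="white", edgecolor="0.7")
        )
        ax.text(col + 0.05, row + 0.2, str(date.day), fontsize=6, color="0.3")
        if date not in summary.index or int(summary.at[date, "ping_count"]) == 0:
            payload[str(date.date())] = None
            continue
        fracs = summary.loc[date, frac_cols].to_numpy(dtype=float)
        payload[str(date.date())] = {
            c.removeprefix("frac_"): float(v) for c, v in zip(frac_cols, fracs)
        }
        theta = 90.0
        for i, frac in enumerate(fracs):
            if frac <= 0:
                continue
            sweep = 360.0 * frac
            ax.add_patch(
                matplotlib.patches.Wedge(
                    (cx, cy), 0.38, theta - sweep, theta, facecolor=cmap(i % 10),
                    edgecolor="0.4", lw=0.3,
                )
            )
            theta -= sweep
    handles = [
        matplotlib.patches.Patch(
            facecolor=cmap(i % 10), label=c.removeprefix("frac_")
        )
        for i, c in enumerate(frac_cols)
    ]
    ax.legend(handles=handles, loc="lower right", fontsize=6)
    ax.set_title(
        f"Daily dwell by location {month} — patient {spec.patient_id}", fontsize=9
    )
    return _fig_to_img(fig), payload


_RENDERERS = {
    "mca_trend": _render_mca_trend,
    "eigengap": _render_eigengap,
    "coassociation": _render_coassociation,
    "home_time": _render_home_time,
    "location_pies": _render_location_pies,
}


def render_chart(spec: PanelSpec, results) -> str:
    """Render one panel to a self-contained HTML fragment.

    *results* is the precomputed analysis object for ``spec.feature``
    (trend dict, eigengap dict, coassociation frame, or daily-summary
    frame). Empty results yield a placeholder panel with an explanation.
    The fragment embeds the rendered chart, the input numbers as a JSON
    ``panel-data`` block, and a provenance line with all parameters.
    """
    empty = (
        results is None
        or (hasattr(results, "__len__") and len(results) == 0)
    )
    if empty:
        return _placeholder(spec, "empty results")
    img, payload = _RENDERERS[spec.feature](spec, results)
    provenance = {
        "patient_id": spec.patient_id,
        "feature": spec.feature,
        "parameters": spec.parameters,
        "relapse_dates": [str(pd.Timestamp(r).date()) for r in spec.relapse_dates],
    }
    return (
        '<div class="panel">'
        f"<h3>{html.escape(spec.caption())}</h3>"
        + img
        + _data_block(payload)
        + '<p class="provenance">'
        + html.escape(json.dumps(provenance, default=str))
        + "</p></div>"
    )


def render_report(
    left: PanelSpec,
    right: PanelSpec,
    out_path: str | Path,
    left_results=None,
    right_results=None,
    title: str = "Comparative report",
) -> Path:
    """Write a self-contained two-panel HTML report.

    The two panels share one layout so any pair of (patient, feature,
    parameter) combinations can be compared side by side — the same
    patient under two imputation methods, two patients on one feature, etc.
    A failed/empty side degrades to a placeholder panel.
    """
    fragments = []
    for spec, results in ((left, left_results), (right, right_results)):
        try:
            fragments.append(render_chart(spec, results))
        except Exception as exc:  # degrade, never lose the other panel
            fragments.append(_placeholder(spec, f"rendering failed: {exc}"))
    doc = f"""<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>{html.escape(title)}</title>
<style>
body {{ font-family: sans-serif; margin: 1em; }}
.row {{ display: flex; gap: 1em; }}
.panel {{ flex: 1; border: 1px solid #ccc; padding: 0.5em; }}
.panel img {{ max-width: 100%; }}
.placeholder {{ background: #fafafa; color: #888; }}
.provenance {{ font-size: 0.7em; color: #666; word-break: break-all; }}
</style></head>
<body><h2>{html.escape(title)}</h2>
<div class="row">{fragments[0]}{fragments[1]}</div>
</body></html>
"""
    out = Path(out_path)
    out.parent.mkdir(parents=True, exist_ok=True)
    out.write_text(doc)
    return out
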