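"""End-to-end orchestration: cohort in, per-patient analytics + reports out.

``run_pipeline`` walks a cohort directory (as written by
:func:`phenovis.synth.generate_cohort`, or any directory with the same
manifest layout), and for each patient runs imputation, per-section MCA,
AV/CV clustering ensembles with coassociation matrices, passive GPS
summaries, and control/pre-relapse window statistics, then renders a
two-panel comparative report page. All numeric intermediates are written as
CSV; a run manifest records versions, seeds and parameters so any output is
traceable and the whole run is reproducible bit-for-bit.

A patient whose data breaks one stage is logged and skipped — sparse
real-world recording must not kill a cohort run; the run fails only if
every patient fails.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clustering import EnsembleConfig, build_ensemble, coassociation, date_vectors
from .imputation import ImputationConfig, impute
from .io import (
    RelapseAnnotation,
    read_gps,
    read_relapse,
    read_schema,
    read_survey,
    write_matrix,
)
from .mca import build_indicator, eigengaps, fit_mca, mca_trend
from .passive import PassiveConfig, daily_summaries, find_significant_locations
from .viz import PanelSpec, render_report
from .windows import WindowPolicy, define_windows, flag_anomalous_windows, summarize_windows

logger = logging.getLogger(__name__)

# stage ids for seed fan-out; one stream per (stage, patient)
_STAGE_IMPUTE, _STAGE_CLUSTER, _STAGE_PASSIVE = 0, 1, 2


@dataclass
class PipelineConfig:
    data_dir: str | Path = "data"
    output_dir: str | Path = "output"
    imputation: ImputationConfig = field(default_factory=ImputationConfig)
    ensemble: EnsembleConfig = field(default_factory=EnsembleConfig)
    passive: PassiveConfig = field(default_factory=PassiveConfig)
    window_policy: WindowPolicy = field(default_factory=WindowPolicy)
    ratio_threshold: float = 2.0
    seed: int = 0
    render_reports: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs: dict = {}
        for key in ("data_dir", "output_dir", "ratio_threshold", "seed",
                    "render_reports"):
            if key in raw:
                kwargs[key] = raw[key]
        if "imputation" in raw:
            kwargs["imputation"] = ImputationConfig(**raw["imputation"])
        if "ensemble" in raw:
            ens = {
                k: tuple(v) if isinstance(v, list) else v
                for k, v in raw["ensemble"].items()
            }
            kwargs["ensemble"] = EnsembleConfig(**ens)
        if "passive" in raw:
            kwargs["passive"] = PassiveConfig(**raw["passive"])
        if "window_policy" in raw:
            kwargs["window_policy"] = WindowPolicy(**raw["window_policy"])
        return cls(**kwargs)


def _stage_seed(master: int, stage: int, patient_index: int) -> int:
    return int(
        np.random.SeedSequence(master, spawn_key=(stage, patient_index))
        .generate_state(1)[0]
        % (2**31)
    )


def _write_csv(df: pd.DataFrame, path: Path, **kwargs) -> None:
    df.to_csv(path, float_format="%.12g", **kwargs)


def process_patient(
    config: PipelineConfig,
    patient_index: int,
    survey,
    gps,
    annotation: RelapseAnnotation,
    out_dir: Path,
) -> dict:
    """Run every analysis stage for one patient; returns a result record."""
    pid = annotation.patient_id
    out_dir.mkdir(parents=True, exist_ok=True)
    schema = survey.schema

    imp_cfg = ImputationConfig(
        method=config.imputation.method,
        mice_iterations=config.imputation.mice_iterations,
        mice_chains=config.imputation.mice_chains,
        seed=_stage_seed(config.seed, _STAGE_IMPUTE, patient_index),
        leading_missing_policy=config.imputation.leading_missing_policy,
    )
    complete = impute(survey, imp_cfg)

    trends: dict[str, pd.Series] = {}
    gaps: dict[str, tuple[float, float]] = {}
    score_frames = []
    for section in schema.sections:
        result = fit_mca(build_indicator(complete.for_section(section), schema, section))
        trends[section] = mca_trend(result)
        gaps[section] = eigengaps(result)
        scores = result.row_scores.copy()
        scores.columns = [f"{section}.{c}" for c in scores.columns]
        score_frames.append(scores.iloc[:, :2])
    trend_frame = pd.DataFrame(trends)
    write_matrix(trend_frame, out_dir / "mca_trends.csv")
    gap_frame = pd.DataFrame(gaps, index=["first_eigengap", "second_eigengap"]).T
    _write_csv(gap_frame, out_dir / "eigengaps.csv", index_label="section")

    cluster_seed = _stage_seed(config.seed, _STAGE_CLUSTER, patient_index)
    coassoc = {}
    kind_seeds = {}
    for kind in ("AV", "CV"):
        vectors = date_vectors(complete, kind)
        ens_cfg = EnsembleConfig(
            strategies=config.ensemble.strategies,
            methods=config.ensemble.methods,
            k_list=config.ensemble.k_list,
            k_max_natural=config.ensemble.k_max_natural,
            restarts=config.ensemble.restarts,
            seed=cluster_seed + (0 if kind == "AV" else 1),
        )
        matrix = coassociation(build_ensemble(vectors, ens_cfg))
        coassoc[kind] = matrix
        kind_seeds[kind] = ens_cfg.seed
        write_matrix(matrix, out_dir / f"coassociation_{kind.lower()}.csv")

    passive_cfg = PassiveConfig(
        max_locations=config.passive.max_locations,
        radius_m=config.passive.radius_m,
        max_gap_minutes=config.passive.max_gap_minutes,
        min_dwell_fraction=config.passive.min_dwell_fraction,
        seed=_stage_seed(config.seed, _STAGE_PASSIVE, patient_index),
    )
    locations = find_significant_locations(gps, passive_cfg)
    daily = daily_summaries(gps, locations, passive_cfg)
    _write_csv(daily, out_dir / "daily_locations.csv", index_label="date")
    _write_csv(
        locations.locations.drop(columns=["first_visit"]),
        out_dir / "significant_locations.csv",
        index=False,
    )

    span = (complete.df["date"].min(), complete.df["date"].max())
    wins = define_windows(annotation, span, config.window_policy)
    summary = flag_anomalous_windows(
        summarize_windows(trends, wins), config.ratio_threshold
    )
    _write_csv(summary, out_dir / "window_summary.csv", index=False)

    report_path = None
    if config.render_reports:
        relapses = list(annotation.relapse_dates)
        left = PanelSpec(
            pid, "mca_trend",
            {"imputation": imp_cfg.method, "seed": imp_cfg.seed},
            relapses,
        )
        right = PanelSpec(
            pid, "coassociation",
            {"kind": "AV", "seed": kind_seeds["AV"]}, relapses,
        )
        report_path = out_dir / "report.html"
        render_report(
            left, right, report_path,
            left_results=trends, right_results=coassoc["AV"],
            title=f"Patient {pid}",
        )

    n_flagged = int(summary["flagged"].sum())
    return {
        "patient_id": pid,
        "output_dir": str(out_dir),
        "report": str(report_path) if report_path else None,
        "n_relapses": len(annotation.relapse_dates),
        "n_flagged_section_windows": n_flagged,
        "seeds": {
            "imputation": imp_cfg.seed,
            "clustering": cluster_seed,
            "passive": passive_cfg.seed,
        },
    }


def load_cohort(data_dir: str | Path):
    """Read a cohort directory's manifest and yield per-patient inputs."""
    data_dir = Path(data_dir)
    manifest = json.loads((data_dir / "manifest.json").read_text())
    schema = read_schema(data_dir / manifest["schema"])
    for entry in manifest["patients"]:
        survey = read_survey(data_dir / entry["survey"], schema)
        gps = read_gps(data_dir / entry["gps"])
        annotations = read_relapse(data_dir / entry["relapse"])
        yield survey, gps, annotations[0]


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the full pipeline over a cohort directory; returns the output
    directory containing per-patient results, an index page and the run
    manifest."""
    out_root = Path(config.output_dir)
    out_root.mkdir(parents=True, exist_ok=True)
    records, failures = [], []
    for i, (survey, gps, annotation) in enumerate(load_cohort(config.data_dir)):
        pid = annotation.patient_id
        try:
            rec = process_patient(
                config, i, survey, gps, annotation, out_root / pid
            )
            records.append(rec)
        except Exception as exc:
            logger.exception("patient %s failed; skipping", pid)
            failures.append({"patient_id": pid, "error": str(exc)})
    if not records:
        raise RuntimeError(
            f"all {len(failures)} patients failed; first error: "
            f"{failures[0]['error'] if failures else 'empty cohort'}"
        )

    manifest = {
        "phenovis_version": __version__,
        "python_version": platform.python_version(),
        "seed": config.seed,
        "parameters": {
            "imputation": vars(config.imputation) | {},
            "ensemble": {
                "strategies": list(config.ensemble.strategies),
                "methods": list(config.ensemble.methods),
                "k_list": list(config.ensemble.k_list),
                "k_max_natural": config.ensemble.k_max_natural,
                "restarts": config.ensemble.restarts,
                "seed": config.ensemble.seed,
            },
            "passive": vars(config.passive) | {},
            "window_days": config.window_policy.window_days,
            "ratio_threshold": config.ratio_threshold,
        },
        "patients": records,
        "failures": failures,
    }
    (out_root / "run_manifest.json").write_text(
        json.dumps(manifest, indent=2, default=str)
    )

    if config.render_reports:
        items = "\n".join(
            f'<li><a href="{r["patient_id"]}/report.html">{r["patient_id"]}</a> — '
            f'{r["n_relapses"]} relapse(s), '
            f'{r["n_flagged_section_windows"]} flagged section-window(s)</li>'
            for r in records
        )
        (out_root / "index.html").write_text(
            "<!DOCTYPE html><html><head><meta charset='utf-8'>"
            "<title>Cohort index</title></head><body>"
            f"<h2>Cohort index ({len(records)} patients)</h2><ul>{items}</ul>"
            "</body></html>"
        )
    return out_root
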