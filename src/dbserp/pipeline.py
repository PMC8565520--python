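"""End-to-end orchestration: simulate/load -> clean -> ERP -> features -> models."""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as dio
from .classify import full_pipeline_classification
from .core import PipelineConfig, Recording, ValidationError
from .erp import ERP, average_epochs, extract_epochs, zscore_erp
from .features import build_feature_table, feature_key
from .montage import make_montage, occipital_channel
from .preprocess import clean
from .simulate import SimulationConfig, simulate_cohort
from .stats_single import cv_single_feature, biomarker_cv_report, ttest_independent


class StageError(RuntimeError):
    """Raised when a pipeline stage fails, naming the stage and session."""

    def __init__(self, stage: str, session_id: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed for session {session_id!r}: {cause}")
        self.stage = stage
        self.session_id = session_id
        self.__cause__ = cause


def session_to_erp(
    recording: Recording, config: PipelineConfig, preprocess: bool = True
) -> ERP:
    """Clean (optionally), epoch and average one session."""
    sid = recording.meta.session_id
    try:
        rec = clean(recording, config)[0] if preprocess else recording
    except Exception as exc:  # noqa: BLE001
        raise StageError("preprocess", sid, exc) from exc
    try:
        epochs = extract_epochs(rec, config.epoch_window_ms)
        erp = average_epochs(epochs)
    except Exception as exc:  # noqa: BLE001
        raise StageError("erp", sid, exc) from exc
    if config.features_on_zscored:
        erp = zscore_erp(erp)
    return erp


def cohort_feature_table(
    sim_config: SimulationConfig,
    config: PipelineConfig | None = None,
    preprocess: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Simulate the cohort, run it through the pipeline, return the feature
    table plus per-session ground truth (sessions are processed one at a time
    to bound memory)."""
    config = config or PipelineConfig()
    montage = make_montage(sim_config.n_channels)
    erps, truths = [], {}
    for sess in simulate_cohort(sim_config, montage):
        erps.append(session_to_erp(sess.recording, config, preprocess))
        truths[sess.session_id] = sess.ground_truth
    table = build_feature_table(
        erps, montage, config.windows_ms, config.energy_mode
    )
    return table, truths


#: The three standard pairwise biomarker analyses: (positive, negative, location)
SINGLE_FEATURE_ANALYSES = (
    ("ZI", "VMR", "medial_fronto_central"),
    ("ZI", "DLR", "right_fronto_central"),
    ("DLR", "VMR", "__occipital__"),  # resolved to the montage's Oz analogue
)


def single_feature_report(
    table: pd.DataFrame, config: PipelineConfig, montage=None
) -> dict:
    """Latency-biomarker report for the three standard pairwise comparisons."""
    montage = montage or make_montage(64)
    oz = occipital_channel(montage)
    out = {}
    for pos, neg, location in SINGLE_FEATURE_ANALYSES:
        loc = oz if location == "__occipital__" else location
        key = feature_key(loc, "middle", "max_latency")
        sub = table[table["region"].isin([pos, neg])]
        values = sub[key].to_numpy()
        labels = sub["region"].to_numpy()
        tt = ttest_independent(values[labels == pos], values[labels == neg],
                               welch=config.welch_ttest)
        rep = cv_single_feature(
            values, labels, positive_class=pos, k=config.cv_folds, seed=config.rng_seed
        )
        out[f"{pos}_vs_{neg}"] = {
            "feature": key,
            "t": tt.t,
            "p": tt.p,
            "df": tt.df,
            "cv": biomarker_cv_report(rep),
        }
    return out


def run_pipeline(
    config: PipelineConfig | None = None,
    sim_config: SimulationConfig | None = None,
    session_paths: list[tuple[str, str]] | None = None,
    out_dir=None,
    analyses: tuple[str, ...] = ("single_feature", "classify"),
) -> dict:
    """Execute the full analysis and return (and optionally write) a report.

    Inputs are either a simulation spec (``sim_config``) or a list of
    (edf_path, events_path) pairs.  Outputs, when ``out_dir`` is given:
    ``features.csv`` and ``report.json``.  Deterministic given the configs.
    """
    config = config or PipelineConfig()
    if (sim_config is None) == (session_paths is None):
        raise ValidationError("provide exactly one of sim_config or session_paths")
    if sim_config is not None:
        montage = make_montage(sim_config.n_channels)
        table, _truth = cohort_feature_table(sim_config, config)
    else:
        montage = make_montage(64)
        erps = []
        for edf_path, events_path in session_paths:
            rec = dio.read_recording(edf_path, events_path)
            rec.validate_for_pipeline()
            erps.append(session_to_erp(rec, config))
        table = build_feature_table(erps, montage, config.windows_ms, config.energy_mode)

    report: dict = {
        "n_sessions": int(len(table)),
        "regions": table["region"].value_counts().to_dict(),
        "config": config.to_dict(),
    }
    if "single_feature" in analyses and table["region"].nunique() >= 2:
        report["single_feature"] = single_feature_report(table, config, montage)
    if "classify" in analyses and table["region"].nunique() >= 2:
        loc = full_pipeline_classification(table, config)
        report["classification"] = {
            name: {
                "chosen_c": rep.chosen_c,
                "n_features": len(rep.selected_features[0]),
                "metrics_mean": rep.mean().to_dict(),
                "metrics_sd": rep.sd().to_dict(),
                **(
                    {"confusion": rep.confusion, "classes": rep.classes}
                    if rep.confusion is not None
                    else {}
                ),
            }
            for name, rep in loc.runs.items()
        }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        dio.write_feature_table(table, out_dir / "features.csv")
        dio.save_report(report, out_dir / "report.json")
    report["feature_table"] = table
    return report
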