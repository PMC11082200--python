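"""End-to-end orchestration: simulate -> extract -> select -> indices -> model.

The pipeline is a sequence of pure stages over in-memory objects; every
stage can persist its output as CSV so partial runs can be resumed. A
machine-readable report tracks counts through every filter (trials
generated, motion-excluded, ROIs retained, undefined-correlation drops,
converged models) so that record losses are always attributable to a named
rule.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import mixed_models, roi_selection, similarity_indices, synthetic_data, trial_glm
from .synthetic_data import SynthConfig, SynthStudy

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ResultsBundle", "run_all", "extract_study_patterns", "compute_study_indices"]


@dataclass
class RunConfig:
    """Analysis parameters plus the synthetic-study block.

    Defaults equal the emulated design's constants: 4-s windows, 3 windows
    per 12-s epoch, >= 100-voxel and >= 25%-overlap ROI retention, the
    3-of-6 motion-outlier trial exclusion, and FDR at Q = 0.05.
    """

    synth: SynthConfig = field(default_factory=SynthConfig)
    window_seconds: float = 4.0
    windows_per_epoch: int = 3
    min_voxels: int = 100
    min_overlap: float = 0.25
    motion_threshold: int = 3
    highpass_seconds: float = 100.0
    fdr_q: float = 0.05
    df_method: str = "satterthwaite"
    include_nuisance_in_lmem: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.seed is not None:
            self.synth = dataclasses.replace(self.synth, seed=self.seed)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        synth_kwargs = raw.pop("synth", {})
        if "jitter_choices" in synth_kwargs:
            synth_kwargs["jitter_choices"] = tuple(synth_kwargs["jitter_choices"])
        if synth_kwargs.get("affected_rois") is not None:
            synth_kwargs["affected_rois"] = tuple(synth_kwargs["affected_rois"])
        return cls(synth=SynthConfig(**synth_kwargs), **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["synth"]["jitter_choices"] = list(self.synth.jitter_choices)
        if d["synth"]["affected_rois"] is not None:
            d["synth"]["affected_rois"] = list(d["synth"]["affected_rois"])
        return d

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class ResultsBundle:
    config: RunConfig
    roi_table: pd.DataFrame
    index_table: pd.DataFrame
    lmem_terms: pd.DataFrame
    simple_slopes: pd.DataFrame
    report: dict


def extract_study_patterns(study: SynthStudy, cfg: RunConfig, rois) -> tuple[list, dict]:
    """LSS pattern extraction over every run, with exclusion accounting."""
    patterns = []
    totals = {"n_ecft_trials": 0, "n_motion_excluded": 0,
              "n_rank_deficient": 0, "n_analyzed": 0}
    for run in study.runs:
        pats, rep = trial_glm.estimate_trial_patterns(
            run,
            study.events,
            study.atlas_flat,
            rois,
            filler_events=study.fillers.get((run.subject_id, run.run_id), ()),
            window_s=cfg.window_seconds,
            n_windows=cfg.windows_per_epoch,
            epoch_s=study.config.epoch_seconds,
            highpass_s=cfg.highpass_seconds,
            motion_threshold=cfg.motion_threshold,
        )
        patterns.extend(pats)
        for key in totals:
            totals[key] += rep[key]
    return patterns, totals


def compute_study_indices(study: SynthStudy, patterns) -> tuple[pd.DataFrame, dict]:
    cov = similarity_indices.attach_trial_metadata(study.covariates, study.events)
    records, rep = similarity_indices.compute_index_records(patterns, cov)
    if not records.empty:
        records = similarity_indices.residualize_shift(records)
    return records, rep


def run_all(config: RunConfig, out_dir=None) -> ResultsBundle:
    """Execute the whole pipeline on a synthetic study."""
    stage = "simulate"
    try:
        study = synthetic_data.generate_study(config.synth)

        stage = "select_rois"
        rois = roi_selection.select_rois(
            study.atlas, study.mask,
            min_voxels=config.min_voxels, min_overlap=config.min_overlap,
        )
        roi_df = roi_selection.roi_table(rois)
        retained = [r.label for r in rois if r.retained]

        stage = "extract_patterns"
        if retained:
            patterns, glm_report = extract_study_patterns(study, config, retained)
        else:
            patterns, glm_report = [], {"n_ecft_trials": 0, "n_motion_excluded": 0,
                                        "n_rank_deficient": 0, "n_analyzed": 0}

        stage = "indices"
        if patterns:
            index_table, idx_report = compute_study_indices(study, patterns)
        else:
            index_table = pd.DataFrame()
            idx_report = {"n_trial_roi_candidates": 0, "n_motion_excluded": 0,
                          "n_zero_variance_dropped": 0, "n_cftcft_unavailable": 0}

        stage = "model"
        if not index_table.empty:
            terms, slopes, failures = mixed_models.run_roi_sweep(
                index_table, retained, q=config.fdr_q,
                include_nuisance=config.include_nuisance_in_lmem,
                df_method=config.df_method,
            )
        else:
            terms, slopes, failures = pd.DataFrame(), pd.DataFrame(), []
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc

    n_trials = glm_report["n_ecft_trials"]
    report = {
        "config_hash": config.content_hash(),
        "n_subjects": study.config.n_subjects,
        "n_runs_total": len(study.runs),
        "n_rois": len(rois),
        "n_rois_retained": len(retained),
        "trials": {
            "generated_ecft": n_trials,
            "motion_excluded": glm_report["n_motion_excluded"],
            "rank_deficient": glm_report["n_rank_deficient"],
            "analyzed": glm_report["n_analyzed"],
            "accounting_ok": n_trials
            == glm_report["n_motion_excluded"]
            + glm_report["n_rank_deficient"]
            + glm_report["n_analyzed"],
        },
        "records": idx_report,
        "models": {
            "fitted": int(len(terms.groupby(["roi_label", "index_kind"]))) if not terms.empty else 0,
            "converged": int(
                terms.groupby(["roi_label", "index_kind"])["converged"].first().sum()
            ) if not terms.empty else 0,
            "failures": failures,
        },
    }

    bundle = ResultsBundle(
        config=config, roi_table=roi_df, index_table=index_table,
        lmem_terms=terms, simple_slopes=slopes, report=report,
    )
    if out_dir is not None:
        persist_bundle(bundle, out_dir)
    return bundle


def persist_bundle(bundle: ResultsBundle, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.roi_table.to_csv(out / "roi_table.csv", index=False)
    bundle.index_table.to_csv(out / "index_records.csv", index=False)
    bundle.lmem_terms.to_csv(out / "lmem_terms.csv", index=False)
    bundle.simple_slopes.to_csv(out / "simple_slopes.csv", index=False)
    (out / "report.json").write_text(json.dumps(_jsonable(bundle.report), indent=2))
    (out / "config.yaml").write_text(yaml.safe_dump(bundle.config.to_dict()))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.bool_):
        return bool(obj)
    return obj
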