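"""Single-trial FIR/LSS pattern estimation.

Each eCFT trial of interest is fitted with its own GLM (Least Squares
Separate): the focal recall and counterfactual-simulation epochs are
modelled with a finite impulse response basis of three 4-s windows (two TRs
each at TR = 2 s), while every other event in the run enters through five
pooled nuisance regressors (other recalls, other upward simulations, other
downward simulations, the odd/even filler task, and button presses)
convolved with a double-gamma response plus temporal derivatives. Per-TR
confound time series, motion-outlier indicator columns, discrete-cosine
drift terms (100-s high-pass) and an intercept complete the design.

Patterns are the per-window maps of t-statistics of the focal FIR
parameters, restricted to atlas ROIs. Trials whose focal epoch contains
three or more (out of six) motion-outlier TRs are excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.linalg

from .hrf import convolve_events

logger = logging.getLogger(__name__)

__all__ = [
    "BoldRun",
    "TrialEvent",
    "WindowPattern",
    "TrialGlmFit",
    "RankDeficientDesignError",
    "EventOutOfRunError",
    "WINDOWS",
    "EPOCHS",
    "BUTTON_PRESS_DURATION_S",
    "fir_columns",
    "build_lss_design",
    "fit_trial_glm",
    "apply_motion_exclusion",
    "extract_roi_patterns",
    "estimate_trial_patterns",
]

WINDOWS = ("w0_4", "w4_8", "w8_12")
EPOCHS = ("recall", "cft")
ECFT_CONDITIONS = ("upward", "downward")
BUTTON_PRESS_DURATION_S = 0.1
DEFAULT_EPOCH_S = 12.0


class RankDeficientDesignError(ValueError):
    """Raised when the GLM design matrix is rank deficient."""

    def __init__(self, offending: Sequence[str]):
        self.offending = list(offending)
        super().__init__(f"rank-deficient design; offending columns: {self.offending}")


class EventOutOfRunError(ValueError):
    """Raised when an event (or its FIR windows) extends past the run."""


@dataclass
class BoldRun:
    """One functional run: voxel x TR signal plus per-TR confounds."""

    subject_id: str
    run_id: int
    signal: np.ndarray  # (n_voxels, n_trs)
    tr_seconds: float
    confounds: pd.DataFrame  # one row per TR
    outlier_flags: np.ndarray  # bool, (n_trs,)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.outlier_flags = np.asarray(self.outlier_flags, dtype=bool)
        if self.signal.ndim != 2:
            raise ValueError("signal must be 2-D (voxels x TRs)")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if len(self.confounds) != self.n_trs:
            raise ValueError("confound rows must match TR count")
        if self.outlier_flags.shape != (self.n_trs,):
            raise ValueError("outlier_flags length must match TR count")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal contains non-finite values (missing TRs?)")

    @property
    def n_voxels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_trs(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_trs * self.tr_seconds


@dataclass(frozen=True)
class TrialEvent:
    """One recall trial, optionally followed by a counterfactual epoch."""

    subject_id: str
    run_id: int
    memory_id: str
    condition: str  # upward | downward | none
    recall_onset: float
    cft_onset: float | None = None
    jitter_s: int | None = None
    prev_condition: str = "no_previous"
    button_press_times: tuple = ()

    def __post_init__(self) -> None:
        if self.condition not in ("upward", "downward", "none"):
            raise ValueError(f"unknown condition {self.condition!r}")
        is_ecft = self.condition in ECFT_CONDITIONS
        if is_ecft != (self.cft_onset is not None):
            raise ValueError("cft_onset must be present iff condition is upward/downward")
        if is_ecft:
            if self.jitter_s not in (1, 2, 3):
                raise ValueError("jitter_s must be 1, 2 or 3 on eCFT trials")
            gap = self.cft_onset - (self.recall_onset + DEFAULT_EPOCH_S)
            if abs(gap - self.jitter_s) > 1e-6:
                raise ValueError("cft_onset - (recall_onset + 12 s) must equal jitter_s")
        if self.prev_condition not in ("upward", "downward", "none", "no_previous"):
            raise ValueError(f"unknown prev_condition {self.prev_condition!r}")

    @property
    def is_ecft(self) -> bool:
        return self.condition in ECFT_CONDITIONS


@dataclass
class WindowPattern:
    """Per trial x epoch x window, the t-statistic vector within one ROI."""

    subject_id: str
    run_id: int
    memory_id: str
    condition: str
    epoch: str  # recall | cft
    window: str  # w0_4 | w4_8 | w8_12
    roi_label: int
    values: np.ndarray | None
    excluded: bool = False
    exclude_reason: str = ""

    def __post_init__(self) -> None:
        if self.epoch not in EPOCHS:
            raise ValueError(f"unknown epoch {self.epoch!r}")
        if self.window not in WINDOWS:
            raise ValueError(f"unknown window {self.window!r}")
        if not self.excluded:
            if self.values is None or not np.all(np.isfinite(self.values)):
                raise ValueError("non-excluded pattern must carry finite values")


@dataclass
class TrialGlmFit:
    """Focal-column estimates from one LSS model."""

    betas: dict  # (epoch, window) -> (n_voxels,) array
    tstats: dict  # (epoch, window) -> (n_voxels,) array
    residual_df: int
    column_names: list = field(default_factory=list)


def patterns_to_frame(patterns: Sequence[WindowPattern]) -> pd.DataFrame:
    """Tabular (parquet-friendly) view of window patterns, one row each."""
    return pd.DataFrame(
        {
            "subject_id": [p.subject_id for p in patterns],
            "run_id": [p.run_id for p in patterns],
            "memory_id": [p.memory_id for p in patterns],
            "condition": [p.condition for p in patterns],
            "epoch": [p.epoch for p in patterns],
            "window": [p.window for p in patterns],
            "roi_label": [p.roi_label for p in patterns],
            "excluded": [p.excluded for p in patterns],
            "exclude_reason": [p.exclude_reason for p in patterns],
            "values": [None if p.values is None else list(p.values)
                       for p in patterns],
        }
    )


def frame_to_patterns(frame: pd.DataFrame) -> list[WindowPattern]:
    """Inverse of :func:`patterns_to_frame`."""
    patterns = []
    for rec in frame.to_dict("records"):
        values = rec["values"]
        patterns.append(
            WindowPattern(
                subject_id=rec["subject_id"], run_id=int(rec["run_id"]),
                memory_id=rec["memory_id"], condition=rec["condition"],
                epoch=rec["epoch"], window=rec["window"],
                roi_label=int(rec["roi_label"]),
                values=None if values is None else np.asarray(values, float),
                excluded=bool(rec["excluded"]),
                exclude_reason=rec["exclude_reason"] or "",
            )
        )
    return patterns


def onset_to_tr_index(onset: float, tr: float) -> int:
    """First TR whose acquisition starts at or after ``onset`` (grid snap)."""
    return int(np.ceil(onset / tr - 1e-9))


def fir_columns(
    onset: float,
    tr: float,
    n_trs: int,
    window_s: float = 4.0,
    n_windows: int = 3,
) -> np.ndarray:
    """Indicator FIR columns: one per consecutive ``window_s`` window.

    Windows start at the nearest TR boundary at or after ``onset`` and span
    ``window_s / tr`` TRs each (two TRs for the default 4-s windows at
    TR = 2 s).
    """
    tpw = int(round(window_s / tr))
    if tpw < 1:
        raise ValueError("window shorter than one TR")
    start = onset_to_tr_index(onset, tr)
    if start < 0:
        raise EventOutOfRunError(f"onset {onset} before run start")
    cols = np.zeros((n_trs, n_windows))
    for w in range(n_windows):
        lo = start + w * tpw
        hi = lo + tpw
        if hi > n_trs:
            raise EventOutOfRunError(
                f"FIR window {w} of event at {onset} s extends past run end"
            )
        cols[lo:hi, w] = 1.0
    return cols


def _dct_drift_basis(n_trs: int, tr: float, cutoff_s: float) -> np.ndarray:
    """Discrete-cosine drift columns implementing a ``cutoff_s`` high-pass."""
    order = int(np.floor(2.0 * n_trs * tr / cutoff_s))
    t = np.arange(n_trs)
    cols = [np.cos(np.pi * k * (t + 0.5) / n_trs) for k in range(1, order + 1)]
    if not cols:
        return np.empty((n_trs, 0))
    return np.column_stack(cols)


def _epoch_windows_ok(onset: float, run: BoldRun, epoch_s: float) -> None:
    end_idx = onset_to_tr_index(onset, run.tr_seconds) + int(
        round(epoch_s / run.tr_seconds)
    )
    if end_idx > run.n_trs:
        raise EventOutOfRunError(f"epoch at {onset} s extends past run end")


def build_lss_design(
    focal: TrialEvent,
    all_events: Sequence[TrialEvent],
    run: BoldRun,
    filler_events: Sequence[tuple] = (),
    window_s: float = 4.0,
    n_windows: int = 3,
    epoch_s: float = DEFAULT_EPOCH_S,
    highpass_s: float = 100.0,
) -> tuple[np.ndarray, list, dict]:
    """Assemble the Least-Squares-Separate design for one focal trial.

    Returns ``(X, names, meta)`` where ``meta['focal_cols']`` maps
    ``(epoch, window)`` to the design column index.
    """
    if focal.run_id != run.run_id or focal.subject_id != run.subject_id:
        raise ValueError("focal event does not belong to this run")
    if focal.recall_onset + epoch_s > run.duration_s:
        raise EventOutOfRunError("focal recall epoch outside run")
    tr, n_trs = run.tr_seconds, run.n_trs

    cols: list[np.ndarray] = []
    names: list[str] = []
    focal_cols: dict = {}

    # Focal FIR columns: recall epoch, then the CFT epoch on eCFT trials.
    fir = fir_columns(focal.recall_onset, tr, n_trs, window_s, n_windows)
    for w, wname in enumerate(WINDOWS[:n_windows]):
        focal_cols[("recall", wname)] = len(cols)
        cols.append(fir[:, w])
        names.append(f"focal_recall_{wname}")
    if focal.is_ecft:
        fir = fir_columns(focal.cft_onset, tr, n_trs, window_s, n_windows)
        for w, wname in enumerate(WINDOWS[:n_windows]):
            focal_cols[("cft", wname)] = len(cols)
            cols.append(fir[:, w])
            names.append(f"focal_cft_{wname}")

    # Five categories of pooled nuisance events, double-gamma convolved,
    # each with its temporal derivative.
    run_events = [
        e for e in all_events if e.run_id == run.run_id and e.subject_id == run.subject_id
    ]
    categories: dict[str, tuple[list, list]] = {
        "other_recall": ([], []),
        "other_upward_cft": ([], []),
        "other_downward_cft": ([], []),
        "oddeven_task": ([], []),
        "button_press": ([], []),
    }
    for ev in run_events:
        same = ev.memory_id == focal.memory_id
        if not same:
            categories["other_recall"][0].append(ev.recall_onset)
            categories["other_recall"][1].append(epoch_s)
            if ev.is_ecft:
                key = f"other_{ev.condition}_cft"
                categories[key][0].append(ev.cft_onset)
                categories[key][1].append(epoch_s)
        # button presses on all tasks, including the focal trial's own
        for t in ev.button_press_times:
            categories["button_press"][0].append(t)
            categories["button_press"][1].append(BUTTON_PRESS_DURATION_S)
    for onset, dur in filler_events:
        categories["oddeven_task"][0].append(onset)
        categories["oddeven_task"][1].append(dur)

    for cat, (onsets, durations) in categories.items():
        if not onsets:
            continue
        reg, dreg = convolve_events(onsets, durations, n_trs, tr)
        cols.append(reg)
        names.append(cat)
        cols.append(dreg)
        names.append(f"{cat}_derivative")

    # Confound columns (demeaned so the intercept keeps its meaning).
    for col in run.confounds.columns:
        v = np.asarray(run.confounds[col], dtype=float)
        cols.append(v - v.mean())
        names.append(f"confound_{col}")

    # One indicator column per flagged TR (censoring).
    for idx in np.flatnonzero(run.outlier_flags):
        ind = np.zeros(n_trs)
        ind[idx] = 1.0
        cols.append(ind)
        names.append(f"outlier_tr{idx}")

    drift = _dct_drift_basis(n_trs, tr, highpass_s)
    for k in range(drift.shape[1]):
        cols.append(drift[:, k])
        names.append(f"drift_dct{k + 1}")

    cols.append(np.ones(n_trs))
    names.append("intercept")

    X = np.column_stack(cols)
    meta = {"focal_cols": focal_cols, "n_trs": n_trs}
    return X, names, meta


def fit_trial_glm(
    run: BoldRun,
    design: np.ndarray,
    names: Sequence[str],
    focal_cols: Mapping,
) -> TrialGlmFit:
    """Voxelwise OLS for one LSS design; returns focal betas and t-maps.

    t = beta / SE(beta) with residual df = n_TRs - n_columns. Degenerate
    standard errors (numerically exact fits) are floored at a tiny scale so
    that t-maps remain proportional to beta maps instead of blowing up.
    """
    X = np.asarray(design, dtype=float)
    n, k = X.shape
    if n != run.n_trs:
        raise ValueError("design rows must match TR count")
    if n - k <= 0:
        raise ValueError(f"non-positive residual df ({n} TRs, {k} columns)")

    Q, R, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    rdiag = np.abs(np.diag(R))
    tol = rdiag.max() * max(n, k) * np.finfo(float).eps
    rank = int(np.sum(rdiag > tol))
    if rank < k:
        offending = [names[i] for i in piv[rank:]]
        raise RankDeficientDesignError(offending)

    Y = run.signal.T  # (n_trs, n_voxels)
    coef_piv = scipy.linalg.solve_triangular(R, Q.T @ Y)
    beta = np.empty_like(coef_piv)
    beta[piv] = coef_piv

    resid = Y - X @ beta
    df = n - k
    sigma2 = np.einsum("ij,ij->j", resid, resid) / df

    Rinv = scipy.linalg.solve_triangular(R, np.eye(k))
    diag_piv = np.einsum("ij,ij->i", Rinv, Rinv)  # diag((X'X)^-1) in pivoted order
    diag = np.empty(k)
    diag[piv] = diag_piv

    se_floor = 1e-10 * max(1.0, float(np.sqrt(np.mean(Y**2))))
    betas, tstats = {}, {}
    for key, j in focal_cols.items():
        se = np.sqrt(sigma2 * diag[j])
        tstats[key] = beta[j] / np.maximum(se, se_floor)
        betas[key] = beta[j]
    return TrialGlmFit(betas=betas, tstats=tstats, residual_df=df, column_names=list(names))


def apply_motion_exclusion(
    focal: TrialEvent,
    run: BoldRun,
    epoch: str = "any",
    threshold: int = 3,
    epoch_s: float = DEFAULT_EPOCH_S,
) -> bool:
    """True iff >= ``threshold`` of the TRs covering a focal 12-s epoch are flagged.

    ``epoch`` selects 'recall', 'cft', or 'any' (either epoch trips the rule;
    the LSS model of a trial covers both of its epochs).
    """
    onsets = []
    if epoch in ("recall", "any"):
        onsets.append(focal.recall_onset)
    if epoch in ("cft", "any"):
        if focal.is_ecft:
            onsets.append(focal.cft_onset)
        elif epoch == "cft":
            raise ValueError("trial has no CFT epoch")
    if epoch not in ("recall", "cft", "any"):
        raise ValueError(f"unknown epoch {epoch!r}")

    tpe = int(round(epoch_s / run.tr_seconds))
    for onset in onsets:
        start = onset_to_tr_index(onset, run.tr_seconds)
        if start + tpe > run.n_trs:
            raise EventOutOfRunError(f"epoch at {onset} s extends past run end")
        if int(run.outlier_flags[start : start + tpe].sum()) >= threshold:
            return True
    return False


def extract_roi_patterns(
    tmaps: Mapping,
    atlas_flat: np.ndarray,
    rois: Iterable[int],
    trial: TrialEvent,
    excluded: bool = False,
    exclude_reason: str = "",
) -> list[WindowPattern]:
    """Slice per-window t-maps into per-ROI pattern vectors."""
    atlas_flat = np.asarray(atlas_flat)
    patterns = []
    for roi in rois:
        vox = np.flatnonzero(atlas_flat == roi)
        if vox.size == 0:
            raise ValueError(f"ROI label {roi} absent from atlas")
        for (epoch, window), tmap in tmaps.items():
            values = None if tmap is None else np.asarray(tmap)[vox].copy()
            patterns.append(
                WindowPattern(
                    subject_id=trial.subject_id,
                    run_id=trial.run_id,
                    memory_id=trial.memory_id,
                    condition=trial.condition,
                    epoch=epoch,
                    window=window,
                    roi_label=int(roi),
                    values=values,
                    excluded=excluded,
                    exclude_reason=exclude_reason,
                )
            )
    return patterns


def estimate_trial_patterns(
    run: BoldRun,
    events: Sequence[TrialEvent],
    atlas_flat: np.ndarray,
    rois: Sequence[int],
    filler_events: Sequence[tuple] = (),
    window_s: float = 4.0,
    n_windows: int = 3,
    epoch_s: float = DEFAULT_EPOCH_S,
    highpass_s: float = 100.0,
    motion_threshold: int = 3,
) -> tuple[list[WindowPattern], dict]:
    """Run the full LSS sweep over one run's eCFT trials.

    Returns all window patterns (6 per ROI per retained trial) plus an
    accounting dict of trial counts and motion exclusions.
    """
    run_events = [
        e for e in events if e.run_id == run.run_id and e.subject_id == run.subject_id
    ]
    focal_trials = [e for e in run_events if e.is_ecft]
    patterns: list[WindowPattern] = []
    empty = {(e, w): None for e in EPOCHS for w in WINDOWS[:n_windows]}
    n_excluded = 0
    n_rank_deficient = 0
    for focal in focal_trials:
        if apply_motion_exclusion(
            focal, run, epoch="any", threshold=motion_threshold, epoch_s=epoch_s
        ):
            n_excluded += 1
            patterns.extend(
                extract_roi_patterns(
                    empty, atlas_flat, rois, focal,
                    excluded=True, exclude_reason="motion_outliers",
                )
            )
            continue
        X, names, meta = build_lss_design(
            focal, run_events, run, filler_events,
            window_s=window_s, n_windows=n_windows,
            epoch_s=epoch_s, highpass_s=highpass_s,
        )
        try:
            fit = fit_trial_glm(run, X, names, meta["focal_cols"])
        except RankDeficientDesignError as exc:
            # e.g. every TR of a focal FIR window censored by outlier
            # indicators -> that window's column is an exact sum of
            # indicator columns and the trial pattern is unidentifiable
            logger.warning(
                "trial %s/%s: %s; trial excluded", focal.subject_id,
                focal.memory_id, exc,
            )
            n_rank_deficient += 1
            patterns.extend(
                extract_roi_patterns(
                    empty, atlas_flat, rois, focal,
                    excluded=True, exclude_reason="rank_deficient_design",
                )
            )
            continue
        patterns.extend(extract_roi_patterns(fit.tstats, atlas_flat, rois, focal))
    report = {
        "n_ecft_trials": len(focal_trials),
        "n_motion_excluded": n_excluded,
        "n_rank_deficient": n_rank_deficient,
        "n_analyzed": len(focal_trials) - n_excluded - n_rank_deficient,
    }
    return patterns, report
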