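"""Trial-level neural pattern similarity (NPS) indices.

Two per-trial summaries of multivoxel pattern similarity, both on the
Fisher-z scale:

* Recall-CFT similarity shift: z(r(Recall[4-8 s], CFT[4-8 s])) minus
  z(r(Recall[4-8 s], CFT[0-4 s])) for the same trial and ROI. Negative
  values mean the simulation's pattern diverges from the memory's pattern
  as the counterfactual is elaborated. Only the middle recall window is
  used: similarity involving the late recall window or the late CFT window
  is confounded by BOLD temporal autocorrelation across the short jittered
  gap and is deliberately never computed.
* CFT-CFT similarity: the mean Fisher-z correlation between one trial's
  CFT[4-8 s] pattern and every other same-condition CFT[4-8 s] pattern
  from *different* runs (same-run pairs are excluded to avoid
  autocorrelation-inflated similarity). High values indicate a generalized
  representation shared across simulations of that kind.

The raw shift index is additionally residualized on the recall-to-CFT
interval (1/2/3 s) and the previous trial's condition, with the grand
intercept added back so that downstream intercept tests keep estimating
the mean shift.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import patsy

from .trial_glm import WindowPattern

logger = logging.getLogger(__name__)

__all__ = [
    "ZeroVariancePatternError",
    "fisher_z",
    "nps_correlation",
    "recall_cft_shift_raw",
    "cft_cft_similarity",
    "residualize_shift",
    "compute_index_records",
    "R_CLIP",
]

R_CLIP = 1.0 - 1e-7

SHIFT_RAW = "recall_cft_shift_raw"
SHIFT_ADJ = "recall_cft_shift_adjusted"
CFT_SIM = "cft_cft_similarity"


class ZeroVariancePatternError(ValueError):
    """Correlation undefined: a pattern vector has zero variance."""


def fisher_z(r) -> np.ndarray | float:
    """Fisher transform arctanh(r), clipping |r| at 1 - 1e-7.

    Odd and strictly increasing on [-1, 1]; raises for |r| > 1.
    """
    arr = np.asarray(r, dtype=float)
    if np.any(np.abs(arr) > 1.0 + 1e-12):
        raise ValueError("correlation outside [-1, 1]")
    out = np.arctanh(np.clip(arr, -R_CLIP, R_CLIP))
    return float(out) if np.isscalar(r) or arr.ndim == 0 else out


def nps_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Fisher-z of the Pearson correlation between two voxel patterns."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("patterns must be 1-D and equal length")
    if a.size < 2:
        raise ValueError("patterns must have length >= 2")
    ac = a - a.mean()
    bc = b - b.mean()
    na = np.linalg.norm(ac)
    nb = np.linalg.norm(bc)
    if na == 0.0 or nb == 0.0:
        raise ZeroVariancePatternError("zero-variance pattern; correlation undefined")
    r = float(np.dot(ac, bc) / (na * nb))
    return fisher_z(np.clip(r, -1.0, 1.0))


def recall_cft_shift_raw(
    recall_w4_8: np.ndarray,
    cft_w0_4: np.ndarray,
    cft_w4_8: np.ndarray,
) -> float:
    """Raw Recall-CFT similarity shift for one trial and ROI."""
    late = nps_correlation(recall_w4_8, cft_w4_8)
    early = nps_correlation(recall_w4_8, cft_w0_4)
    return late - early


def cft_cft_similarity(
    focal: np.ndarray,
    others: Sequence[tuple],
    focal_run: int,
    focal_condition: str,
) -> tuple[float | None, int]:
    """Mean cross-run same-condition NPS for one trial's CFT[4-8 s] pattern.

    ``others`` is a sequence of ``(pattern, run_id, condition)`` covering the
    candidate eCFT instances. Returns ``(value, m)``; value is None when no
    same-condition different-run partner exists (m = 0).
    """
    zs = []
    for pattern, run_id, condition in others:
        if condition != focal_condition or run_id == focal_run:
            continue
        zs.append(nps_correlation(focal, pattern))
    if not zs:
        return None, 0
    return float(np.mean(zs)), len(zs)


def _pattern_key(p: WindowPattern) -> tuple:
    return (p.subject_id, p.run_id, p.memory_id, p.epoch, p.window, p.roi_label)


def compute_index_records(
    patterns: Sequence[WindowPattern],
    covariates: pd.DataFrame,
) -> tuple[pd.DataFrame, dict]:
    """Build the per-trial x ROI index table from window patterns.

    ``covariates`` needs columns subject_id, memory_id, stai_y2, arousal.
    Trial metadata (condition, jitter, previous condition) must be attached
    to the patterns upstream via ``attach_trial_metadata`` or supplied in
    ``covariates`` as extra columns jitter_s / prev_condition.

    Returns the long IndexRecord table (one row per trial x ROI x index
    kind) and an accounting dict (motion-excluded, zero-variance and
    no-partner drops).
    """
    cov = covariates.set_index(["subject_id", "memory_id"])
    by_key = {_pattern_key(p): p for p in patterns}

    # enumerate analyzable trials per ROI
    trials: dict[tuple, WindowPattern] = {}
    n_excluded = 0
    for p in patterns:
        if p.epoch == "cft" and p.window == "w4_8":
            tkey = (p.subject_id, p.memory_id, p.roi_label)
            if p.excluded:
                n_excluded += 1
                continue
            trials[tkey] = p

    rows = []
    n_zero_variance = 0
    n_no_partner = 0
    # group focal CFT patterns per (subject, roi, condition) for the
    # cross-run similarity pool
    pool: dict[tuple, list] = {}
    for (subj, mem, roi), p in trials.items():
        pool.setdefault((subj, roi, p.condition), []).append(p)

    for (subj, mem, roi), cft_late in sorted(trials.items()):
        meta = cov.loc[(subj, mem)]
        if isinstance(meta, pd.DataFrame):
            meta = meta.iloc[0]
        base = {
            "subject_id": subj,
            "memory_id": mem,
            "run_id": cft_late.run_id,
            "roi_label": roi,
            "condition": cft_late.condition,
            "jitter_s": meta.get("jitter_s", np.nan),
            "prev_condition": meta.get("prev_condition", "no_previous"),
            "anxiety": float(meta["stai_y2"]),
            "arousal": float(meta["arousal"]),
        }

        recall = by_key.get((subj, cft_late.run_id, mem, "recall", "w4_8", roi))
        cft_early = by_key.get((subj, cft_late.run_id, mem, "cft", "w0_4", roi))
        if recall is not None and cft_early is not None and not recall.excluded:
            try:
                value = recall_cft_shift_raw(
                    recall.values, cft_early.values, cft_late.values
                )
                rows.append({**base, "index_kind": SHIFT_RAW, "value": value, "m": np.nan})
            except ZeroVariancePatternError:
                n_zero_variance += 1
                logger.warning(
                    "zero-variance pattern; dropping shift record %s/%s roi %s",
                    subj, mem, roi,
                )

        others = [
            (q.values, q.run_id, q.condition)
            for q in pool[(subj, roi, cft_late.condition)]
            if q.memory_id != mem
        ]
        try:
            value, m = cft_cft_similarity(
                cft_late.values, others, cft_late.run_id, cft_late.condition
            )
        except ZeroVariancePatternError:
            n_zero_variance += 1
            value, m = None, 0
        if value is None:
            n_no_partner += 1
        else:
            rows.append({**base, "index_kind": CFT_SIM, "value": value, "m": m})

    records = pd.DataFrame(rows)
    report = {
        "n_trial_roi_candidates": len(trials) + n_excluded,
        "n_motion_excluded": n_excluded,
        "n_zero_variance_dropped": n_zero_variance,
        "n_cftcft_unavailable": n_no_partner,
    }
    return records, report


def residualize_shift(records: pd.DataFrame) -> pd.DataFrame:
    """Two-step nuisance removal for the raw shift index.

    Per ROI (pooling subjects and trials), the raw index is regressed on
    categorical recall-to-CFT interval and categorical previous-trial
    condition by OLS; the adjusted index is the residual plus the grand
    intercept, so the mean is preserved. Nuisance levels absent from the
    data are dropped from the design (patsy builds levels from the data).

    Returns a copy of ``records`` with adjusted rows appended
    (index_kind = 'recall_cft_shift_adjusted').
    """
    raw = records[records["index_kind"] == SHIFT_RAW]
    if raw.empty:
        return records.copy()
    adjusted_frames = []
    for roi, grp in raw.groupby("roi_label"):
        grp = grp.copy()
        n_jitter = grp["jitter_s"].nunique()
        n_prev = grp["prev_condition"].nunique()
        if n_jitter < 3 or n_prev < 4:
            logger.info(
                "ROI %s: nuisance levels present jitter=%d prev=%d; absent levels dropped",
                roi, n_jitter, n_prev,
            )
        terms = []
        if n_jitter > 1:
            terms.append("C(jitter_s)")
        if n_prev > 1:
            terms.append("C(prev_condition)")
        if terms:
            X = patsy.dmatrix(" + ".join(terms), grp, return_type="dataframe")
            y = grp["value"].to_numpy()
            beta, *_ = np.linalg.lstsq(X.to_numpy(), y, rcond=None)
            resid = y - X.to_numpy() @ beta
            grp["value"] = resid + y.mean()
        grp["index_kind"] = SHIFT_ADJ
        adjusted_frames.append(grp)
    out = pd.concat([records] + adjusted_frames, ignore_index=True)
    return out


def attach_trial_metadata(covariates: pd.DataFrame, events) -> pd.DataFrame:
    """Merge per-trial jitter and previous-condition info into covariates."""
    rows = [
        {
            "subject_id": e.subject_id,
            "memory_id": e.memory_id,
            "jitter_s": e.jitter_s,
            "prev_condition": e.prev_condition,
        }
        for e in events
        if e.is_ecft
    ]
    meta = pd.DataFrame(rows)
    return covariates.merge(meta, on=["subject_id", "memory_id"], how="left")
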