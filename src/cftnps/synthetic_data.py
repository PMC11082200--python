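"""Synthetic eCFT fMRI studies with known ground-truth pattern dynamics.

The generator emulates the structure of the scanning session: each subject
contributes ``n_runs`` functional runs whose trials interleave 12-s
autobiographical-recall epochs, a jittered 1-3 s gap and a 12-s
counterfactual-simulation (CFT) epoch on eCFT trials, 1.5-s fixations and
odd/even filler blocks with button presses throughout. Memories are split
evenly across upward eCFT, downward eCFT and No-eCFT conditions.

Voxel signals place epoch-specific latent patterns into an FIR-consistent
boxcar time course (one pattern per 4-s window) plus AR(1) noise. Latent
patterns are fixed mixtures of per-ROI orthonormalized Gaussian factors
(run-level retrieval-network and simulation-state components, subject-level
condition templates, per-memory content, per-trial residuals), so the
injected correlations hold *exactly in the sample*, per ROI:

* z(corr(recall[4-8], cft[4-8])) - z(corr(recall[4-8], cft[0-4])) equals
  ``drift_intercept + anxiety_by_condition_slope * anxiety_z * sign(cond)``
  (+ a subject-level random intercept), and
* the correlation between same-condition CFT patterns from *different runs*
  equals ``tanh(base_z + anxiety_by_condition_slope * anxiety_z *
  sign(cond))`` via the condition template loading; same-run pairs are
  additionally inflated by the shared run state, the artifact the same-run
  exclusion rule exists for,

where sign(upward) = +1 and sign(downward) = -1 and anxiety is the
cohort-standardized trait score. Filler-task and button-press activity use
one double-gamma-convolved pattern each per subject, and motion outliers
are flagged at a configurable rate.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .hrf import convolve_events
from .trial_glm import BoldRun, TrialEvent, WINDOWS

logger = logging.getLogger(__name__)

__all__ = ["SynthConfig", "GroundTruth", "SynthStudy", "generate_study", "write_study", "read_study"]

CONDITION_SIGN = {"upward": 1.0, "downward": -1.0}
MOTION_COLS = ("trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z")
CONFOUND_COLS = ("csf", "wm", "framewise_displacement", "dvars") + MOTION_COLS


@dataclass
class SynthConfig:
    """Study-generation parameters.

    Defaults follow the emulated design: 3 runs, 15 memories per condition
    (45 total), TR = 2 s, 12-s epochs, jitter drawn from {1, 2, 3} s, and a
    cohort of 39 subjects whose trait-anxiety scores span the recruited
    spectrum (uniform on [20, 70]). ``drift_intercept`` and
    ``anxiety_by_condition_slope`` are Fisher-z effect sizes (the latter
    per SD of anxiety).
    """

    n_subjects: int = 39
    n_runs: int = 3
    trials_per_condition: int = 15
    tr_seconds: float = 2.0
    epoch_seconds: float = 12.0
    jitter_choices: tuple = (1, 2, 3)
    n_rois: int = 8
    voxels_per_roi: int = 250
    drift_intercept: float = -0.05
    anxiety_by_condition_slope: float = 0.02
    noise_sd: float = 0.1
    ar1_coef: float = 0.3
    outlier_rate: float = 0.02
    seed: int = 0
    # latent-model knobs
    base_recall_cft_r: float = 0.25
    base_within_condition_r: float = 0.2
    subject_shift_sd: float = 0.09
    subject_similarity_sd: float = 0.03
    within_epoch_r: float = 0.7
    run_shared_recall_var: float = 0.5
    run_shared_cft_var: float = 0.5
    jitter_effect: float = 0.0
    prev_condition_effect: float = 0.0
    affected_rois: tuple | None = None  # None = every ROI carries the effects
    mask_coverage: float = 1.0
    hrf_convolve_epochs: bool = False
    keep_latent_patterns: bool = False
    max_run_seconds: float = 1800.0

    def __post_init__(self) -> None:
        for name in ("n_subjects", "n_runs", "trials_per_condition", "n_rois"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive count")
        if self.voxels_per_roi < 2:
            raise ValueError("voxels_per_roi < 2: pattern correlation undefined")
        if not (0.0 <= self.ar1_coef < 1.0):
            raise ValueError("ar1_coef must lie in [0, 1)")
        if not set(self.jitter_choices) <= {1, 2, 3}:
            raise ValueError("jitter_choices must be a subset of {1, 2, 3}")
        if self.tr_seconds <= 0 or self.epoch_seconds <= 0:
            raise ValueError("durations must be positive")
        if self.noise_sd < 0 or self.outlier_rate < 0 or self.outlier_rate > 1:
            raise ValueError("noise_sd >= 0 and outlier_rate in [0, 1] required")
        if not (0.0 <= self.mask_coverage <= 1.0):
            raise ValueError("mask_coverage must lie in [0, 1]")
        for name in ("run_shared_recall_var", "run_shared_cft_var"):
            if not (0.0 <= getattr(self, name) < 1.0):
                raise ValueError(f"{name} must lie in [0, 1)")
        if self.within_epoch_r < self.run_shared_recall_var:
            raise ValueError(
                "within_epoch_r must be >= run_shared_recall_var (the shared "
                "run component bounds within-epoch pattern stability from below)"
            )
        est = self._estimated_run_seconds()
        if est > self.max_run_seconds:
            raise ValueError(
                f"requested epochs overflow run length ({est:.0f} s > "
                f"{self.max_run_seconds:.0f} s); reduce trials or epochs"
            )

    def _estimated_run_seconds(self) -> float:
        per_run = -(-self.trials_per_condition * 3 // self.n_runs)
        worst_trial = 2 * self.epoch_seconds + 3 + 1.5 + 6.0 + 2 * self.tr_seconds
        return 8.0 + per_run * worst_trial + 16.0

    @property
    def window_seconds(self) -> float:
        return self.epoch_seconds / 3.0


@dataclass
class GroundTruth:
    """Injected latent targets: one row per eCFT trial, plus subject table."""

    trials: pd.DataFrame  # subject_id, memory_id, condition, z_early, z_late, ...
    subjects: pd.DataFrame  # subject_id, stai_y2, anxiety_z, u_shift, v_similarity

    def validate(self) -> None:
        r = np.tanh(self.trials[["z_early", "z_late", "z_similarity"]].to_numpy())
        if not np.all((r > -1.0) & (r < 1.0)):
            raise ValueError("true correlations must lie in (-1, 1)")


@dataclass
class SynthStudy:
    """Everything a downstream analysis needs, in memory."""

    config: SynthConfig
    runs: list  # list[BoldRun]
    events: list  # list[TrialEvent]
    fillers: dict  # (subject_id, run_id) -> list[(onset, duration)]
    covariates: pd.DataFrame  # subject_id, memory_id, stai_y2, arousal
    atlas: np.ndarray  # 3-D integer labels
    mask: np.ndarray  # 3-D binary
    affine: np.ndarray
    roi_labels: list
    truth: GroundTruth
    latent_patterns: dict = field(default_factory=dict)

    @property
    def atlas_flat(self) -> np.ndarray:
        return self.atlas.reshape(-1)


def _build_atlas(cfg: SynthConfig) -> tuple[np.ndarray, np.ndarray]:
    """Pack each ROI into a 5x5xNz block separated by background slices."""
    side = 5
    per_slice = side * side
    nz = -(-cfg.voxels_per_roi // per_slice)
    shape = (side, side, cfg.n_rois * (nz + 1) + 1)
    atlas = np.zeros(shape, dtype=np.int32)
    mask = np.zeros(shape, dtype=np.uint8)
    for r in range(cfg.n_rois):
        z0 = r * (nz + 1)
        block = np.zeros(per_slice * nz, dtype=np.int32)
        block[: cfg.voxels_per_roi] = r + 1
        atlas[:, :, z0 : z0 + nz] = block.reshape(side, side, nz)
        m = np.zeros(per_slice * nz, dtype=np.uint8)
        m[: int(round(cfg.mask_coverage * cfg.voxels_per_roi))] = 1
        mask[:, :, z0 : z0 + nz] = m.reshape(side, side, nz)
    return atlas, mask


def _orthonormal_factors(raw: np.ndarray, roi_vox: dict) -> np.ndarray:
    """Orthonormalize factor columns within each ROI (after centering).

    Columns are rescaled to unit sample variance within the ROI, so any
    fixed linear mixture of factors realises its population correlation
    structure *exactly* in the sample. ROIs with fewer voxels than factors
    cannot support an orthonormal set; there the centered raw draws are
    kept (correlations then hold only in expectation, logged once).
    """
    out = raw.copy()
    n_fac = raw.shape[1]
    warned = False
    for vox in roi_vox.values():
        block = raw[vox, :]
        block = block - block.mean(axis=0, keepdims=True)
        if len(vox) > n_fac + 1:
            q, _ = np.linalg.qr(block)
            # fix QR sign convention for determinism across BLAS builds
            signs = np.sign(np.einsum("ij,ij->j", q, block))
            signs[signs == 0] = 1.0
            out[vox, :] = q * signs * np.sqrt(len(vox))
        else:
            if not warned:
                logger.warning(
                    "ROI of %d voxels cannot hold %d orthonormal factors; "
                    "injected correlations are exact only in expectation",
                    len(vox), n_fac,
                )
                warned = True
            sd = block.std(axis=0, ddof=0)
            sd[sd == 0] = 1.0
            out[vox, :] = block / sd
    return out


def _ar1_noise(rng, shape: tuple, sd: float, phi: float) -> np.ndarray:
    if sd == 0.0:
        return np.zeros(shape)
    v, t = shape
    out = np.empty(shape)
    out[:, 0] = sd * rng.standard_normal(v)
    innov_sd = sd * np.sqrt(1.0 - phi**2)
    for i in range(1, t):
        out[:, i] = phi * out[:, i - 1] + innov_sd * rng.standard_normal(v)
    return out


def _confounds(rng, n_trs: int, cfg: SynthConfig) -> tuple[pd.DataFrame, np.ndarray]:
    flags = rng.random(n_trs) < cfg.outlier_rate
    data = {}
    data["csf"] = _ar1_noise(rng, (1, n_trs), 1.0, 0.5)[0]
    data["wm"] = _ar1_noise(rng, (1, n_trs), 1.0, 0.5)[0]
    fd = np.abs(rng.normal(0.1, 0.05, n_trs))
    fd[flags] = 0.55 + np.abs(rng.normal(0.0, 0.3, int(flags.sum())))
    data["framewise_displacement"] = fd
    dvars = np.abs(rng.normal(1.0, 0.2, n_trs))
    dvars[flags] += 1.0
    data["dvars"] = dvars
    for col in MOTION_COLS:
        data[col] = np.cumsum(rng.normal(0.0, 0.02, n_trs))
    return pd.DataFrame(data), flags


def _snap(t: float, tr: float) -> float:
    return float(np.ceil(t / tr - 1e-9) * tr)


def generate_study(config: SynthConfig) -> SynthStudy:
    """Generate a complete synthetic study (seeded, deterministic)."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    atlas, mask = _build_atlas(cfg)
    roi_labels = list(range(1, cfg.n_rois + 1))
    affected = set(roi_labels if cfg.affected_rois is None else cfg.affected_rois)
    atlas_flat = atlas.reshape(-1)
    roi_vox = {r: np.flatnonzero(atlas_flat == r) for r in roi_labels}
    v_total = atlas_flat.size

    # subject-level draws
    subject_ids = [f"sub{i + 1:02d}" for i in range(cfg.n_subjects)]
    anxiety = rng.uniform(20.0, 70.0, cfg.n_subjects)
    anx_sd = anxiety.std(ddof=0)
    anxiety_z = (anxiety - anxiety.mean()) / (anx_sd if anx_sd > 0 else 1.0)
    u_shift = rng.normal(0.0, cfg.subject_shift_sd, cfg.n_subjects)
    v_sim = rng.normal(0.0, cfg.subject_similarity_sd, cfg.n_subjects)

    z_e_base = np.arctanh(cfg.base_recall_cft_r)
    z_sim_base = np.arctanh(cfg.base_within_condition_r)
    prev_sign = {"upward": 1.0, "downward": -1.0, "none": 0.0, "no_previous": 0.0}

    runs: list[BoldRun] = []
    events: list[TrialEvent] = []
    fillers: dict = {}
    cov_rows = []
    truth_rows = []
    latent: dict = {}

    tr = cfg.tr_seconds
    n_windows = 3
    window_s = cfg.epoch_seconds / n_windows
    tpw = int(round(window_s / tr))

    a_sh = np.sqrt(cfg.run_shared_recall_var)
    b_sh = np.sqrt(1.0 - cfg.run_shared_recall_var)

    for s_idx, subj in enumerate(subject_ids):
        z_a = anxiety_z[s_idx]
        filler_pattern = rng.standard_normal(v_total)
        button_pattern = rng.standard_normal(v_total)

        # memory bookkeeping
        memories = []
        for c_idx, cond in enumerate(("upward", "downward", "none")):
            for j in range(cfg.trials_per_condition):
                memories.append((f"m{c_idx * cfg.trials_per_condition + j + 1:02d}", cond))
        arousal = rng.integers(1, 8, size=len(memories))
        for (mem, cond), ar in zip(memories, arousal):
            cov_rows.append(
                {"subject_id": subj, "memory_id": mem, "condition": cond,
                 "stai_y2": anxiety[s_idx], "arousal": int(ar)}
            )

        # distribute memories across runs, per condition, then shuffle per run
        run_trials: list[list] = [[] for _ in range(cfg.n_runs)]
        for cond in ("upward", "downward", "none"):
            mems = [m for m, c in memories if c == cond]
            perm = rng.permutation(len(mems))
            for i, p in enumerate(perm):
                run_trials[i % cfg.n_runs].append((mems[p], cond))
        for lst in run_trials:
            order = rng.permutation(len(lst))
            lst[:] = [lst[i] for i in order]

        # Latent factor bank, orthonormalized within each ROI. Factors:
        # run-level task-network states (a retrieval network shared by every
        # recall epoch of a run, a simulation state shared by every CFT
        # epoch of a run -- these emulate common task activation and the
        # same-run similarity inflation the exclusion rule guards against),
        # subject-level condition templates (carrying within-condition
        # similarity across runs), per-memory content and per-trial CFT
        # residuals. Per-ROI orthonormalization makes every injected sample
        # correlation exact, so the only stochasticity the downstream mixed
        # model faces is genuine measurement noise -- a latent-level cluster
        # randomness (one random template realization per subject and
        # condition) would act as a subject-by-condition random effect the
        # random-intercept model does not represent, and would break its
        # calibration.
        ecft_mems = [m for m, c in memories if c != "none"]
        factor_names = (
            [f"recall_net_{r}" for r in range(1, cfg.n_runs + 1)]
            + [f"cft_state_{r}" for r in range(1, cfg.n_runs + 1)]
            + ["tmpl_upward", "tmpl_downward"]
            + [f"mem_{m}" for m, _ in memories]
            + [f"res_{m}" for m in ecft_mems]
        )
        raw = rng.standard_normal((v_total, len(factor_names)))
        factors = _orthonormal_factors(raw, roi_vox)
        fname_idx = {name: i for i, name in enumerate(factor_names)}

        def fac(name: str) -> np.ndarray:
            return factors[:, fname_idx[name]]

        for run_id in range(1, cfg.n_runs + 1):
            t_cursor = 8.0
            placements = []  # (flat pattern, start_tr_index) or hrf events
            hrf_placements = []  # (pattern, onset, duration)
            run_events = []
            run_fillers = []
            prev_cond = "no_previous"
            for mem, cond in run_trials[run_id - 1]:
                recall_onset = _snap(t_cursor, tr)
                presses = [recall_onset + rng.uniform(1.0, 5.0)]
                jitter = None
                cft_onset = None
                if cond in CONDITION_SIGN:
                    jitter = int(rng.choice(np.asarray(cfg.jitter_choices)))
                    cft_onset = recall_onset + cfg.epoch_seconds + jitter
                    presses.append(cft_onset + rng.uniform(1.0, 5.0))
                    trial_end = _snap(cft_onset, tr) + cfg.epoch_seconds
                else:
                    trial_end = recall_onset + cfg.epoch_seconds
                n_numbers = int(rng.integers(2, 5))
                filler_onset = trial_end + 1.5
                filler_dur = 1.5 * n_numbers
                run_fillers.append((filler_onset, filler_dur))
                presses.extend(
                    filler_onset + 1.5 * i + rng.uniform(0.3, 1.2)
                    for i in range(n_numbers)
                )
                t_cursor = filler_onset + filler_dur + 0.5

                event = TrialEvent(
                    subject_id=subj, run_id=run_id, memory_id=mem, condition=cond,
                    recall_onset=recall_onset, cft_onset=cft_onset, jitter_s=jitter,
                    prev_condition=prev_cond, button_press_times=tuple(presses),
                )
                run_events.append(event)
                prev_cond = cond

                # --- latent patterns for this trial ---
                # memory pattern M = run retrieval network + memory content
                recall_net = fac(f"recall_net_{run_id}")
                mem_content = fac(f"mem_{mem}")
                mem_pattern = a_sh * recall_net + b_sh * mem_content
                # flanking recall windows: corr(R_w, M) = within_epoch_r
                rho = cfg.within_epoch_r
                c_mix = (rho - cfg.run_shared_recall_var) / b_sh
                d_mix = np.sqrt(max(1.0 - cfg.run_shared_recall_var - c_mix**2, 0.0))
                r0 = (a_sh * recall_net + c_mix * mem_content
                      + d_mix * rng.standard_normal(v_total))
                r2 = (a_sh * recall_net + c_mix * mem_content
                      + d_mix * rng.standard_normal(v_total))
                win_patterns = {("recall", "w0_4"): r0,
                                ("recall", "w4_8"): mem_pattern,
                                ("recall", "w8_12"): r2}
                if cond in CONDITION_SIGN:
                    sign = CONDITION_SIGN[cond]
                    nuis = (cfg.jitter_effect * (jitter - 2)
                            + cfg.prev_condition_effect * prev_sign[event.prev_condition])
                    early = np.empty(v_total)
                    late = np.empty(v_total)
                    z_late_eff = None
                    z_sim_eff = None
                    for roi in roi_labels:
                        eff = 1.0 if roi in affected else 0.0
                        z_l = (z_e_base
                               + eff * (cfg.drift_intercept
                                        + cfg.anxiety_by_condition_slope * z_a * sign)
                               + u_shift[s_idx] + nuis)
                        z_s = (z_sim_base
                               + eff * cfg.anxiety_by_condition_slope * z_a * sign
                               + v_sim[s_idx])
                        if eff:
                            z_late_eff, z_sim_eff = z_l, z_s
                        a_e = np.tanh(z_e_base)
                        a_l = np.tanh(z_l)
                        w2 = float(np.clip(np.tanh(z_s), 1e-4, 0.8))
                        # keep the mixture a valid correlation structure
                        q2 = min(cfg.run_shared_cft_var,
                                 0.9 - w2 - max(a_e**2, a_l**2))
                        q2 = max(q2, 0.0)
                        w2 = min(w2, 0.98 - q2 - max(a_e**2, a_l**2))
                        w = np.sqrt(w2)
                        vox = roi_vox[roi]
                        u_e = np.sqrt(1.0 - a_e**2 - q2 - w2)
                        u_l = np.sqrt(1.0 - a_l**2 - q2 - w2)
                        tmpl = fac(f"tmpl_{cond}")[vox]
                        resid = fac(f"res_{mem}")[vox]
                        state = np.sqrt(q2) * fac(f"cft_state_{run_id}")[vox]
                        early[vox] = (a_e * mem_pattern[vox] + state
                                      + w * tmpl + u_e * resid)
                        late[vox] = (a_l * mem_pattern[vox] + state
                                     + w * tmpl + u_l * resid)
                    bg = atlas_flat == 0
                    bg_draw = rng.standard_normal(int(bg.sum()))
                    early[bg] = bg_draw
                    late[bg] = bg_draw
                    u3 = 0.8 * late + 0.6 * rng.standard_normal(v_total)
                    win_patterns[("cft", "w0_4")] = early
                    win_patterns[("cft", "w4_8")] = late
                    win_patterns[("cft", "w8_12")] = u3
                    truth_rows.append(
                        {"subject_id": subj, "run_id": run_id, "memory_id": mem,
                         "condition": cond, "jitter_s": jitter,
                         "prev_condition": event.prev_condition,
                         "z_early": z_e_base,
                         "z_late": z_late_eff if z_late_eff is not None else z_e_base,
                         "shift_target": (z_late_eff - z_e_base) if z_late_eff is not None else 0.0,
                         "z_similarity": z_sim_eff if z_sim_eff is not None else z_sim_base,
                         "stai_y2": anxiety[s_idx], "anxiety_z": z_a}
                    )
                    if cfg.keep_latent_patterns:
                        latent[(subj, run_id, mem)] = {
                            "recall_w4_8": mem_pattern.copy(),
                            "cft_w0_4": early.copy(),
                            "cft_w4_8": late.copy(),
                        }

                # --- place epoch signals on the TR grid ---
                for (epoch, wname), pattern in win_patterns.items():
                    onset = recall_onset if epoch == "recall" else cft_onset
                    start = int(np.ceil(_snap(onset, tr) / tr - 1e-9))
                    widx = WINDOWS.index(wname)
                    if cfg.hrf_convolve_epochs:
                        hrf_placements.append(
                            (pattern, _snap(onset, tr) + widx * window_s, window_s)
                        )
                    else:
                        placements.append((pattern, start + widx * tpw))

            total_s = t_cursor + 16.0
            n_trs = int(np.ceil(total_s / tr))
            signal = np.zeros((v_total, n_trs))
            for pattern, start in placements:
                signal[:, start : start + tpw] += pattern[:, None]
            for pattern, onset, dur in hrf_placements:
                reg, _ = convolve_events([onset], [dur], n_trs, tr)
                signal += pattern[:, None] * reg[None, :]
            # filler and button activity, double-gamma shaped
            if run_fillers:
                reg, _ = convolve_events(
                    [f[0] for f in run_fillers], [f[1] for f in run_fillers], n_trs, tr
                )
                signal += filler_pattern[:, None] * reg[None, :]
            press_times = [t for e in run_events for t in e.button_press_times]
            if press_times:
                reg, _ = convolve_events(press_times, [0.1] * len(press_times), n_trs, tr)
                signal += button_pattern[:, None] * reg[None, :]
            signal += _ar1_noise(rng, (v_total, n_trs), cfg.noise_sd, cfg.ar1_coef)

            confounds, flags = _confounds(rng, n_trs, cfg)
            runs.append(
                BoldRun(subject_id=subj, run_id=run_id, signal=signal,
                        tr_seconds=tr, confounds=confounds, outlier_flags=flags)
            )
            events.extend(run_events)
            fillers[(subj, run_id)] = run_fillers

    covariates = pd.DataFrame(cov_rows)
    truth = GroundTruth(
        trials=pd.DataFrame(truth_rows),
        subjects=pd.DataFrame(
            {"subject_id": subject_ids, "stai_y2": anxiety, "anxiety_z": anxiety_z,
             "u_shift": u_shift, "v_similarity": v_sim}
        ),
    )
    truth.validate()
    affine = np.diag([3.0, 3.0, 3.0, 1.0])
    return SynthStudy(
        config=cfg, runs=runs, events=events, fillers=fillers,
        covariates=covariates, atlas=atlas, mask=mask, affine=affine,
        roi_labels=roi_labels, truth=truth, latent_patterns=latent,
    )


# --------------------------------------------------------------------------
# on-disk round trip


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_study(study: SynthStudy, out_dir) -> dict:
    """Write NIfTI volumes, TSV events/confounds, CSV covariates, JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = study.config
    shape = study.atlas.shape
    files: list[str] = []

    nib.Nifti1Image(study.atlas.astype(np.int32), study.affine).to_filename(
        out / "atlas.nii.gz"
    )
    nib.Nifti1Image(study.mask.astype(np.uint8), study.affine).to_filename(
        out / "omnibus_mask.nii.gz"
    )
    files += ["atlas.nii.gz", "omnibus_mask.nii.gz"]

    bold_files = []
    for run in study.runs:
        stem = f"{run.subject_id}_run-{run.run_id}"
        vol = run.signal.reshape(*shape, run.n_trs)
        img = nib.Nifti1Image(vol, study.affine)
        img.header.set_zooms((*np.diag(study.affine)[:3], cfg.tr_seconds))
        img.to_filename(out / f"{stem}_bold.nii.gz")
        bold_files.append(f"{stem}_bold.nii.gz")

        conf = run.confounds.copy()
        conf["motion_outlier"] = run.outlier_flags.astype(int)
        conf.to_csv(out / f"{stem}_confounds.tsv", sep="\t", index=False)
        files.append(f"{stem}_confounds.tsv")

        rows = []
        for e in study.events:
            if (e.subject_id, e.run_id) != (run.subject_id, run.run_id):
                continue
            rows.append({"onset": e.recall_onset, "duration": cfg.epoch_seconds,
                         "trial_type": "recall", "memory_id": e.memory_id,
                         "condition": e.condition, "jitter_s": e.jitter_s,
                         "prev_condition": e.prev_condition})
            if e.is_ecft:
                rows.append({"onset": e.cft_onset, "duration": cfg.epoch_seconds,
                             "trial_type": f"cft_{e.condition}", "memory_id": e.memory_id,
                             "condition": e.condition, "jitter_s": e.jitter_s,
                             "prev_condition": e.prev_condition})
            for t in e.button_press_times:
                rows.append({"onset": t, "duration": 0.1, "trial_type": "button_press",
                             "memory_id": e.memory_id, "condition": e.condition,
                             "jitter_s": None, "prev_condition": None})
        for onset, dur in study.fillers[(run.subject_id, run.run_id)]:
            rows.append({"onset": onset, "duration": dur, "trial_type": "oddeven",
                         "memory_id": None, "condition": None,
                         "jitter_s": None, "prev_condition": None})
        ev = pd.DataFrame(rows).sort_values("onset")
        ev.to_csv(out / f"{stem}_events.tsv", sep="\t", index=False)
        files.append(f"{stem}_events.tsv")

    study.covariates.to_csv(out / "covariates.csv", index=False)
    study.truth.trials.to_csv(out / "truth_trials.csv", index=False)
    study.truth.subjects.to_csv(out / "truth_subjects.csv", index=False)
    files += ["covariates.csv", "truth_trials.csv", "truth_subjects.csv"]

    cfg_dict = asdict(cfg)
    cfg_dict["jitter_choices"] = list(cfg.jitter_choices)
    if cfg_dict["affected_rois"] is not None:
        cfg_dict["affected_rois"] = list(cfg_dict["affected_rois"])
    manifest = {
        "config": cfg_dict,
        "grid_shape": list(shape),
        "bold_files": bold_files,
        "files": sorted(files + bold_files),
    }
    manifest["sha256"] = {
        f: _sha256(out / f) for f in manifest["files"]
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def read_study(in_dir) -> SynthStudy:
    """Reconstruct a study from :func:`write_study` output (exact round trip)."""
    src = Path(in_dir)
    manifest = json.loads((src / "manifest.json").read_text())
    cfg_dict = dict(manifest["config"])
    cfg_dict["jitter_choices"] = tuple(cfg_dict["jitter_choices"])
    if cfg_dict["affected_rois"] is not None:
        cfg_dict["affected_rois"] = tuple(cfg_dict["affected_rois"])
    cfg = SynthConfig(**cfg_dict)

    atlas = np.asarray(nib.load(src / "atlas.nii.gz").dataobj).astype(np.int32)
    mask = np.asarray(nib.load(src / "omnibus_mask.nii.gz").dataobj).astype(np.uint8)
    affine = nib.load(src / "atlas.nii.gz").affine

    runs, events, fillers = [], [], {}
    for bold_file in manifest["bold_files"]:
        stem = bold_file.replace("_bold.nii.gz", "")
        subj, run_part = stem.split("_run-")
        run_id = int(run_part)
        vol = np.asarray(nib.load(src / bold_file).dataobj, dtype=float)
        signal = vol.reshape(-1, vol.shape[-1])
        conf = pd.read_csv(src / f"{stem}_confounds.tsv", sep="\t")
        flags = conf.pop("motion_outlier").to_numpy().astype(bool)
        runs.append(BoldRun(subject_id=subj, run_id=run_id, signal=signal,
                            tr_seconds=cfg.tr_seconds, confounds=conf,
                            outlier_flags=flags))
        ev = pd.read_csv(src / f"{stem}_events.tsv", sep="\t")
        fillers[(subj, run_id)] = [
            (row.onset, row.duration)
            for row in ev[ev.trial_type == "oddeven"].itertuples()
        ]
        presses = ev[ev.trial_type == "button_press"]
        for row in ev[ev.trial_type == "recall"].itertuples():
            mem = row.memory_id
            cft = ev[(ev.memory_id == mem) & ev.trial_type.str.startswith("cft_")]
            cft_onset = float(cft.onset.iloc[0]) if len(cft) else None
            jitter = int(row.jitter_s) if np.isfinite(row.jitter_s) else None
            events.append(TrialEvent(
                subject_id=subj, run_id=run_id, memory_id=mem,
                condition=row.condition, recall_onset=float(row.onset),
                cft_onset=cft_onset, jitter_s=jitter,
                prev_condition=row.prev_condition,
                button_press_times=tuple(presses[presses.memory_id == mem].onset),
            ))

    covariates = pd.read_csv(src / "covariates.csv")
    truth = GroundTruth(
        trials=pd.read_csv(src / "truth_trials.csv"),
        subjects=pd.read_csv(src / "truth_subjects.csv"),
    )
    return SynthStudy(config=cfg, runs=runs, events=events, fillers=fillers,
                      covariates=covariates, atlas=atlas, mask=mask,
                      affine=affine, roi_labels=list(range(1, cfg.n_rois + 1)),
                      truth=truth)
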