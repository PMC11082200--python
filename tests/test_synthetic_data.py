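import dataclasses
import json

import numpy as np
import pandas as pd
import pytest

from cftnps.similarity_indices import recall_cft_shift_raw
from cftnps.synthetic_data import (
    SynthConfig,
    generate_study,
    read_study,
    write_study,
)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_subjects": 0},
            {"n_runs": 0},
            {"voxels_per_roi": 1},
            {"ar1_coef": 1.0},
            {"ar1_coef": -0.1},
            {"jitter_choices": (1, 4)},
            {"outlier_rate": 1.5},
            {"mask_coverage": 2.0},
            {"tr_seconds": 0.0},
            {"run_shared_cft_var": 1.0},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SynthConfig(**kwargs)

    def test_epoch_overflow_rejected(self):
        with pytest.raises(ValueError, match="overflow"):
            SynthConfig(trials_per_condition=100, n_runs=1, max_run_seconds=600)


class TestStructure:
    def test_counts_and_condition_balance(self, tiny_study):
        cfg = tiny_study.config
        assert len(tiny_study.runs) == cfg.n_subjects * cfg.n_runs
        ev = pd.DataFrame(
            [{"subject": e.subject_id, "condition": e.condition}
             for e in tiny_study.events]
        )
        per = ev.groupby(["subject", "condition"]).size()
        assert (per == cfg.trials_per_condition).all()

    def test_event_invariants(self, tiny_study):
        for e in tiny_study.events:
            if e.is_ecft:
                assert e.jitter_s in (1, 2, 3)
                assert e.cft_onset - (e.recall_onset + 12.0) == pytest.approx(
                    e.jitter_s
                )
            else:
                assert e.cft_onset is None and e.jitter_s is None

    def test_prev_condition_chains_within_run(self, tiny_study):
        for (subj, run_id) in {(e.subject_id, e.run_id) for e in tiny_study.events}:
            seq = sorted(
                (e for e in tiny_study.events
                 if e.subject_id == subj and e.run_id == run_id),
                key=lambda e: e.recall_onset,
            )
            assert seq[0].prev_condition == "no_previous"
            for prev, cur in zip(seq, seq[1:]):
                assert cur.prev_condition == prev.condition

    def test_ground_truth_one_row_per_ecft_trial(self, tiny_study):
        n_ecft = sum(e.is_ecft for e in tiny_study.events)
        truth = tiny_study.truth.trials
        assert len(truth) == n_ecft
        assert not truth.duplicated(["subject_id", "memory_id"]).any()
        r = np.tanh(truth[["z_early", "z_late", "z_similarity"]].to_numpy())
        assert ((r > -1) & (r < 1)).all()

    def test_anxiety_spans_recruited_spectrum(self, tiny_study):
        anx = tiny_study.truth.subjects.stai_y2
        assert anx.between(20, 70).all()

    def test_atlas_and_mask_geometry(self, tiny_study):
        cfg = tiny_study.config
        flat = tiny_study.atlas_flat
        for label in range(1, cfg.n_rois + 1):
            assert (flat == label).sum() == cfg.voxels_per_roi
        assert (flat == 0).sum() > 0  # background present
        assert set(np.unique(tiny_study.mask)) <= {0, 1}


class TestDeterminism:
    def test_same_seed_bitwise_identical(self):
        cfg = SynthConfig(n_subjects=2, n_rois=2, voxels_per_roi=40, seed=5)
        a = generate_study(cfg)
        b = generate_study(cfg)
        for ra, rb in zip(a.runs, b.runs):
            np.testing.assert_array_equal(ra.signal, rb.signal)
            np.testing.assert_array_equal(ra.outlier_flags, rb.outlier_flags)
            pd.testing.assert_frame_equal(ra.confounds, rb.confounds)
        assert a.events == b.events
        pd.testing.assert_frame_equal(a.truth.trials, b.truth.trials)

    def test_different_seed_differs(self):
        cfg = SynthConfig(n_subjects=1, n_rois=2, voxels_per_roi=40, seed=5)
        other = dataclasses.replace(cfg, seed=6)
        assert not np.array_equal(
            generate_study(cfg).runs[0].signal,
            generate_study(other).runs[0].signal,
        )


class TestNullConfiguration:
    def test_latent_cft_windows_identical_without_drift(self):
        cfg = SynthConfig(
            n_subjects=2, n_rois=2, voxels_per_roi=50, seed=21,
            noise_sd=0.0, drift_intercept=0.0, anxiety_by_condition_slope=0.0,
            subject_shift_sd=0.0, keep_latent_patterns=True,
        )
        study = generate_study(cfg)
        assert study.latent_patterns
        for lat in study.latent_patterns.values():
            np.testing.assert_array_equal(lat["cft_w0_4"], lat["cft_w4_8"])
            shift = recall_cft_shift_raw(
                lat["recall_w4_8"], lat["cft_w0_4"], lat["cft_w4_8"]
            )
            assert shift == 0.0

    def test_latent_shift_equals_injected_target(self):
        cfg = SynthConfig(
            n_subjects=3, n_rois=2, voxels_per_roi=4000, seed=22,
            drift_intercept=-0.05, anxiety_by_condition_slope=0.02,
            subject_shift_sd=0.05, keep_latent_patterns=True,
            trials_per_condition=3,
        )
        study = generate_study(cfg)
        truth = study.truth.trials.set_index(["subject_id", "run_id", "memory_id"])
        got, want = [], []
        for key, lat in study.latent_patterns.items():
            got.append(recall_cft_shift_raw(
                lat["recall_w4_8"], lat["cft_w0_4"], lat["cft_w4_8"]
            ))
            want.append(truth.loc[key, "shift_target"])
        # at 4000 voxels the sample correlations concentrate on their targets
        np.testing.assert_allclose(got, want, atol=0.06)
        assert abs(np.mean(np.subtract(got, want))) < 0.01


class TestPipelineNull:
    def test_pipeline_shift_near_zero_without_injected_effects(self):
        # with identical latent CFT windows the only nonzero shift comes
        # from LSS cross-talk between the two windows' estimates (~1e-2
        # per trial); the study mean must sit well below the default
        # effect size
        cfg = SynthConfig(
            n_subjects=3, n_rois=1, voxels_per_roi=100, seed=24,
            noise_sd=0.0, drift_intercept=0.0, anxiety_by_condition_slope=0.0,
            subject_shift_sd=0.0, outlier_rate=0.0,
        )
        from cftnps.pipeline import (
            RunConfig,
            compute_study_indices,
            extract_study_patterns,
        )
        study = generate_study(cfg)
        patterns, _ = extract_study_patterns(study, RunConfig(synth=cfg, min_voxels=50), [1])
        records, _ = compute_study_indices(study, patterns)
        raw = records[records.index_kind == "recall_cft_shift_raw"]
        # no systematic drift; per-trial values carry only cross-talk
        # noise, whose scale is ~ a few / sqrt(n_voxels) per correlation
        assert abs(raw.value.mean()) < 0.01
        assert raw.value.std() < 0.1


class TestEffectMonotonicity:
    def test_recovered_mean_shift_increases_with_drift(self):
        means = []
        for drift in (-0.08, 0.0, 0.08):
            cfg = SynthConfig(
                n_subjects=2, n_rois=1, voxels_per_roi=150, seed=33,
                drift_intercept=drift, anxiety_by_condition_slope=0.0,
                subject_shift_sd=0.0, noise_sd=0.02, outlier_rate=0.0,
            )
            from cftnps.pipeline import (
                RunConfig,
                compute_study_indices,
                extract_study_patterns,
            )
            study = generate_study(cfg)
            run_cfg = RunConfig(synth=cfg, min_voxels=50)
            patterns, _ = extract_study_patterns(study, run_cfg, [1])
            records, _ = compute_study_indices(study, patterns)
            raw = records[records.index_kind == "recall_cft_shift_raw"]
            means.append(raw.value.mean())
        assert means[0] < means[1] < means[2]


class TestRoundTrip:
    def test_write_then_read_is_exact(self, tmp_path):
        cfg = SynthConfig(n_subjects=2, n_rois=2, voxels_per_roi=40, seed=8)
        study = generate_study(cfg)
        manifest = write_study(study, tmp_path)
        back = read_study(tmp_path)
        assert back.config == cfg
        for ra, rb in zip(study.runs, back.runs):
            np.testing.assert_array_equal(ra.signal, rb.signal)
            np.testing.assert_array_equal(ra.outlier_flags, rb.outlier_flags)
        np.testing.assert_array_equal(study.atlas, back.atlas)
        np.testing.assert_array_equal(study.mask, back.mask)
        assert sorted(e.memory_id for e in back.events) == sorted(
            e.memory_id for e in study.events
        )

    def test_manifest_lists_every_bold_file(self, tmp_path):
        cfg = SynthConfig(n_subjects=2, n_rois=1, voxels_per_roi=30, seed=9)
        manifest = write_study(generate_study(cfg), tmp_path)
        assert len(manifest["bold_files"]) == cfg.n_subjects * cfg.n_runs
        for f in manifest["files"]:
            assert (tmp_path / f).exists()
        assert set(manifest["sha256"]) == set(manifest["files"])

    def test_single_run_events_tsv_has_15_rows_per_condition(self, tmp_path):
        cfg = SynthConfig(n_subjects=1, n_runs=1, trials_per_condition=15,
                          n_rois=1, voxels_per_roi=30, seed=10)
        study = generate_study(cfg)
        write_study(study, tmp_path)
        ev = pd.read_csv(tmp_path / "sub01_run-1_events.tsv", sep="\t")
        recalls = ev[ev.trial_type == "recall"]
        assert recalls.condition.value_counts().to_dict() == {
            "upward": 15, "downward": 15, "none": 15,
        }

    def test_rewriting_same_study_gives_identical_hashes(self, tmp_path):
        cfg = SynthConfig(n_subjects=1, n_rois=1, voxels_per_roi=30, seed=12)
        m1 = write_study(generate_study(cfg), tmp_path / "a")
        m2 = write_study(generate_study(cfg), tmp_path / "b")
        assert m1["sha256"] == m2["sha256"]
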