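import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cftnps.similarity_indices import (
    R_CLIP,
    ZeroVariancePatternError,
    cft_cft_similarity,
    fisher_z,
    nps_correlation,
    recall_cft_shift_raw,
    residualize_shift,
)


def _pearson_reference(a, b):
    """Independent Pearson-r via explicit sums (oracle for nps_correlation)."""
    n = len(a)
    ma = math.fsum(a) / n
    mb = math.fsum(b) / n
    num = math.fsum((x - ma) * (y - mb) for x, y in zip(a, b))
    da = math.sqrt(math.fsum((x - ma) ** 2 for x in a))
    db = math.sqrt(math.fsum((y - mb) ** 2 for y in b))
    return num / (da * db)


class TestFisherZ:
    def test_zero_maps_to_zero(self):
        assert fisher_z(0.0) == 0.0

    def test_closed_form_value(self):
        assert fisher_z(0.5) == pytest.approx(0.5493061443340549, abs=1e-12)

    @given(st.floats(-1.0, 1.0))
    @settings(max_examples=50, deadline=None)
    def test_odd_function(self, r):
        assert fisher_z(-r) == pytest.approx(-fisher_z(r), abs=1e-12)

    @given(st.floats(-0.999, 0.998), st.floats(1e-4, 1e-3))
    @settings(max_examples=50, deadline=None)
    def test_strictly_increasing(self, r, dr):
        assert fisher_z(r + dr) > fisher_z(r)

    def test_unit_correlation_clipped_finite(self):
        assert fisher_z(1.0) == pytest.approx(np.arctanh(R_CLIP))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fisher_z(1.5)


class TestNpsCorrelation:
    def test_identity_pattern_hits_clip(self):
        a = np.array([1.0, 2.0, 5.0, -1.0])
        assert nps_correlation(a, a) == pytest.approx(np.arctanh(R_CLIP))

    def test_orthogonal_centered_patterns_give_zero(self):
        a = np.array([1.0, -1.0, 1.0, -1.0])
        b = np.array([1.0, 1.0, -1.0, -1.0])
        assert nps_correlation(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_five_voxel_hand_computation_oracle(self):
        a = [0.2, -1.4, 3.1, 0.8, -0.5]
        b = [1.0, 0.3, 2.2, -0.7, 0.1]
        expected = math.atanh(_pearson_reference(a, b))
        assert nps_correlation(np.array(a), np.array(b)) == pytest.approx(
            expected, abs=1e-12
        )

    def test_zero_variance_flagged(self):
        with pytest.raises(ZeroVariancePatternError):
            nps_correlation(np.ones(5), np.arange(5.0))


class TestRecallCftShift:
    def test_identical_cft_windows_give_zero(self):
        rng = np.random.default_rng(0)
        r, c = rng.standard_normal(20), rng.standard_normal(20)
        assert recall_cft_shift_raw(r, c, c) == 0.0

    def test_swapping_cft_windows_flips_sign(self):
        rng = np.random.default_rng(1)
        r, c1, c2 = (rng.standard_normal(20) for _ in range(3))
        assert recall_cft_shift_raw(r, c1, c2) == pytest.approx(
            -recall_cft_shift_raw(r, c2, c1), abs=1e-12
        )

    def test_toy_vectors_match_hand_computation(self):
        recall = [1.0, 2.0, 3.0, 4.0]
        early = [1.0, 3.0, 2.0, 4.0]
        late = [2.0, 1.0, 4.0, 3.0]
        expected = math.atanh(_pearson_reference(recall, late)) - math.atanh(
            _pearson_reference(recall, early)
        )
        got = recall_cft_shift_raw(np.array(recall), np.array(early), np.array(late))
        assert got == pytest.approx(expected, abs=1e-12)

    @given(st.floats(0.1, 50.0), st.floats(-5.0, 5.0))
    @settings(max_examples=50, deadline=None)
    def test_scale_and_offset_invariance(self, c, k):
        rng = np.random.default_rng(7)
        r, c1, c2 = (rng.standard_normal(15) for _ in range(3))
        base = recall_cft_shift_raw(r, c1, c2)
        moved = recall_cft_shift_raw(r * c + k, c1, c2 * c + k)
        assert moved == pytest.approx(base, abs=1e-9)


class TestCftCftSimilarity:
    def test_orthogonal_others_average_to_zero(self):
        focal = np.array([1.0, -1.0, 1.0, -1.0])
        other = np.array([1.0, 1.0, -1.0, -1.0])
        value, m = cft_cft_similarity(focal, [(other, 2, "upward")], 1, "upward")
        assert m == 1 and value == pytest.approx(0.0, abs=1e-12)

    def test_all_candidates_in_focal_run_unavailable(self):
        rng = np.random.default_rng(3)
        focal = rng.standard_normal(10)
        others = [(rng.standard_normal(10), 1, "upward") for _ in range(4)]
        value, m = cft_cft_similarity(focal, others, 1, "upward")
        assert value is None and m == 0

    def test_other_condition_never_pooled(self):
        rng = np.random.default_rng(4)
        focal = rng.standard_normal(10)
        others = [(rng.standard_normal(10), 2, "downward")]
        value, m = cft_cft_similarity(focal, others, 1, "upward")
        assert value is None and m == 0

    def test_three_cross_run_partners_match_hand_computation(self):
        rng = np.random.default_rng(5)
        focal = rng.standard_normal(8)
        partners = [rng.standard_normal(8) for _ in range(3)]
        expected = np.mean(
            [math.atanh(_pearson_reference(focal, p)) for p in partners]
        )
        value, m = cft_cft_similarity(
            focal,
            [(p, run, "upward") for p, run in zip(partners, (2, 2, 3))],
            focal_run=1,
            focal_condition="upward",
        )
        assert m == 3 and value == pytest.approx(expected, abs=1e-12)

    def test_same_run_high_correlation_partner_never_changes_index(self):
        rng = np.random.default_rng(6)
        focal = rng.standard_normal(12)
        cross_run = [(rng.standard_normal(12), 2, "upward") for _ in range(3)]
        adversarial = (2.0 * focal + 1.0, 1, "upward")  # near-perfect correlate
        clean, m0 = cft_cft_similarity(focal, cross_run, 1, "upward")
        poisoned, m1 = cft_cft_similarity(focal, cross_run + [adversarial], 1, "upward")
        assert m0 == m1 == 3
        assert poisoned == clean  # exact, not approximate


def _records(values, jitters, prevs, conditions=None):
    n = len(values)
    return pd.DataFrame(
        {
            "subject_id": [f"s{i % 4}" for i in range(n)],
            "memory_id": [f"m{i}" for i in range(n)],
            "run_id": 1,
            "roi_label": 1,
            "index_kind": "recall_cft_shift_raw",
            "value": values,
            "condition": conditions or ["upward", "downward"] * (n // 2),
            "jitter_s": jitters,
            "prev_condition": prevs,
            "anxiety": 40.0,
            "arousal": 4.0,
        }
    )


class TestResidualization:
    def _full_grid(self, rng, effect_jitter=0.0, effect_prev=0.0):
        jitters, prevs, values = [], [], []
        prev_levels = ["upward", "downward", "none", "no_previous"]
        for rep in range(6):
            for j in (1, 2, 3):
                for p in prev_levels:
                    jitters.append(j)
                    prevs.append(p)
                    values.append(
                        rng.normal()
                        + effect_jitter * j
                        + effect_prev * prev_levels.index(p)
                    )
        return _records(values, jitters, prevs)

    def test_adjusted_orthogonal_to_nuisance_dummies(self):
        rng = np.random.default_rng(8)
        records = self._full_grid(rng, effect_jitter=0.3, effect_prev=0.2)
        out = residualize_shift(records)
        adj = out[out.index_kind == "recall_cft_shift_adjusted"]
        for level in (1, 2, 3):
            dummy = (adj.jitter_s == level).astype(float)
            assert abs(np.corrcoef(adj.value, dummy)[0, 1]) < 1e-10
        for level in ("upward", "downward", "none", "no_previous"):
            dummy = (adj.prev_condition == level).astype(float)
            assert abs(np.corrcoef(adj.value, dummy)[0, 1]) < 1e-10

    def test_mean_preserved(self):
        rng = np.random.default_rng(9)
        records = self._full_grid(rng, effect_jitter=0.5)
        out = residualize_shift(records)
        adj = out[out.index_kind == "recall_cft_shift_adjusted"]
        assert adj.value.mean() == pytest.approx(records.value.mean(), abs=1e-12)

    def test_raw_already_orthogonal_passes_through(self):
        rng = np.random.default_rng(10)
        records = self._full_grid(rng)
        # orthogonalize values against the nuisance dummies by balancing:
        # subtract each cell's mean, keep the grand mean
        grand = records.value.mean()
        records["value"] = (
            records.value
            - records.groupby(["jitter_s", "prev_condition"])["value"].transform("mean")
            + grand
        )
        out = residualize_shift(records)
        adj = out[out.index_kind == "recall_cft_shift_adjusted"]
        np.testing.assert_allclose(
            adj.value.to_numpy(), records.value.to_numpy(), atol=1e-10
        )

    def test_constant_raw_index_stays_constant(self):
        records = _records([0.7] * 12, [1, 2, 3] * 4,
                           ["upward", "downward", "none", "no_previous"] * 3)
        out = residualize_shift(records)
        adj = out[out.index_kind == "recall_cft_shift_adjusted"]
        np.testing.assert_allclose(adj.value, 0.7, atol=1e-12)

    def test_missing_nuisance_level_dropped_not_fatal(self):
        records = _records([0.1, 0.4, -0.2, 0.3] * 3, [2] * 12,
                           ["none"] * 12)  # single level each
        out = residualize_shift(records)
        adj = out[out.index_kind == "recall_cft_shift_adjusted"]
        assert len(adj) == 12 and np.isfinite(adj.value).all()
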