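import numpy as np
import pandas as pd
import pytest

from cftnps.pipeline import RunConfig, compute_study_indices, extract_study_patterns
from cftnps.synthetic_data import SynthConfig, generate_study


@pytest.fixture(scope="session")
def tiny_config():
    return SynthConfig(
        n_subjects=3, n_rois=2, voxels_per_roi=60, seed=11,
        trials_per_condition=15, n_runs=3,
    )


@pytest.fixture(scope="session")
def tiny_study(tiny_config):
    return generate_study(tiny_config)


@pytest.fixture(scope="session")
def tiny_analysis(tiny_study):
    """Patterns and index records for the tiny study (shared, read-only)."""
    cfg = RunConfig(synth=tiny_study.config, min_voxels=50)
    patterns, glm_report = extract_study_patterns(tiny_study, cfg, [1, 2])
    records, idx_report = compute_study_indices(tiny_study, patterns)
    return {
        "patterns": patterns,
        "glm_report": glm_report,
        "records": records,
        "idx_report": idx_report,
    }


def make_lmem_fixture() -> pd.DataFrame:
    """Deterministic balanced trial table for mixed-model tests.

    Anxiety and arousal are written pre-standardized (population sd) so the
    in-model z-scoring is an identity and external fits see identical
    predictors.
    """
    rng = np.random.default_rng(42)
    n_sub = 12
    anx = rng.uniform(20, 70, n_sub)
    anx_z = (anx - anx.mean()) / anx.std(ddof=0)
    u = rng.normal(0, 0.05, n_sub)
    rows = []
    for i in range(n_sub):
        for cond in ("downward", "upward"):
            s = 1.0 if cond == "upward" else -1.0
            for jit in (1, 2, 3):
                for prev in ("upward", "downward", "none", "no_previous"):
                    arousal = float(rng.integers(1, 8))
                    eps = rng.normal(0, 0.05)
                    value = -0.05 + 0.03 * anx_z[i] * s + u[i] + eps
                    rows.append(
                        {"subject_id": f"s{i:02d}", "condition": cond,
                         "jitter_s": jit, "prev_condition": prev,
                         "anxiety": anx_z[i], "arousal": arousal,
                         "value": value}
                    )
    df = pd.DataFrame(rows)
    df["arousal"] = (df["arousal"] - df["arousal"].mean()) / df["arousal"].std(ddof=0)
    return df


@pytest.fixture()
def lmem_fixture():
    return make_lmem_fixture()
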