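import numpy as np
import pandas as pd
import pytest

from motorgrade.cohort import CohortSpec, generate_cohort
from motorgrade.network import ModelConfig
from motorgrade.preprocess import SegmentSet, preprocess_cohort


@pytest.fixture(scope="session")
def tiny_model_config():
    """Smallest config that still exercises branching + residuals."""
    return ModelConfig(filters=2, n_modules=2, base_kernel=9, head_pool=8, seed=0)


@pytest.fixture(scope="session")
def small_cohort():
    spec = CohortSpec(
        n_pd=8,
        n_hoa=3,
        tasks=("HM",),
        duration=10.0,
        severity_distribution=(0.3, 0.2, 0.0, 0.2, 0.3),
        seed=7,
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def small_segments(small_cohort):
    recordings, _ = small_cohort
    return preprocess_cohort(recordings)


def synthetic_segment_set(
    n_groups: int,
    segments_per_group: int = 3,
    p_high: float = 0.4,
    n_hoa_groups: int = 0,
    seed: int = 0,
    window_len: int = 8,
) -> SegmentSet:
    """A structurally valid SegmentSet without any signal simulation."""
    rng = np.random.default_rng(seed)
    rows, windows = [], []
    sid = 0
    for g in range(n_groups + n_hoa_groups):
        is_hoa = g >= n_groups
        label = "low" if is_hoa else ("high" if rng.random() < p_high else "low")
        for _ in range(segments_per_group):
            rows.append(
                {
                    "segment_id": f"seg{sid:05d}",
                    "group_id": f"{'hoa' if is_hoa else 'rec'}{g:04d}",
                    "cohort": "HOA" if is_hoa else "PD",
                    "task": "HM",
                    "label": label,
                }
            )
            windows.append(rng.normal(size=(window_len, 2)))
            sid += 1
    return SegmentSet(np.stack(windows), pd.DataFrame(rows))
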