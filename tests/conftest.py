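"""Shared fixtures: small synthetic cohorts and preprocessing configs."""

import numpy as np
import pandas as pd
import pytest

from serodisc import (CohortConfig, PreprocessConfig, SpectralDataset,
                      make_axis, simulate_cohort)


@pytest.fixture(scope="session")
def full_axis():
    return make_axis(4000.0, 450.0, 2.0)


@pytest.fixture(scope="session")
def small_cohort(full_axis):
    """10 vs 10 patients, strong effect, full axis."""
    cfg = CohortConfig(n_cases=10, n_controls=10, effect_size=3.0, seed=101)
    return simulate_cohort(cfg, full_axis)


@pytest.fixture(scope="session")
def null_cohort(full_axis):
    """Exchangeable classes (no planted effect)."""
    cfg = CohortConfig(n_cases=10, n_controls=10, effect_size=0.0, seed=202)
    return simulate_cohort(cfg, full_axis)


@pytest.fixture
def prep_cfg():
    return PreprocessConfig()


@pytest.fixture
def tiny_dataset():
    """2 patients x 9 replicates on a 6-point axis, hand-built."""
    axis = np.array([1800.0, 1600.0, 1400.0, 1200.0, 1100.0, 1000.0])
    rows, recs = [], []
    rng = np.random.default_rng(7)
    for pid, cls in (("p1", "cancer"), ("p2", "control")):
        for b in (1, 2, 3):
            for t in (1, 2, 3):
                rows.append(rng.uniform(0.1, 1.0, size=axis.size))
                recs.append((pid, cls, b, t))
    meta = pd.DataFrame(recs, columns=["patient_id", "class", "bio_rep", "tech_rep"])
    return SpectralDataset(np.vstack(rows), axis, meta)


def make_patient_dataset(n_cases, n_controls, n_points=12, reps=9, seed=0):
    """Random (non-spectral) dataset with the replicate structure, for
    split/consensus machinery tests."""
    rng = np.random.default_rng(seed)
    axis = np.linspace(2000.0, 1000.0, n_points)
    rows, recs = [], []
    for i in range(n_cases + n_controls):
        cls = "cancer" if i < n_cases else "control"
        pid = f"pt{i:03d}"
        for r in range(reps):
            rows.append(rng.normal(size=n_points))
            recs.append((pid, cls, r // 3 + 1, r % 3 + 1))
    meta = pd.DataFrame(recs, columns=["patient_id", "class", "bio_rep", "tech_rep"])
    return SpectralDataset(np.vstack(rows), axis, meta)
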