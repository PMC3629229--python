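import numpy as np
import pytest

from stochconn import (
    CohortDataset,
    CohortSpec,
    GroupSpec,
    MultichannelRecording,
    SubjectData,
    disc_layout,
    random_stable_connectivity,
    synthesize_cohort,
)
from stochconn.core import ConnectivityMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_layout():
    return disc_layout(12, radius=0.10)


@pytest.fixture(scope="session")
def small_cohort(small_layout):
    """Tiny two-group synthetic cohort with one planted connection change
    and different noise correlation lengths (case: longer range)."""
    base = random_stable_connectivity(
        small_layout.n_sensors, -2.0, density=0.3, seed=7, rotation_scale=6.0
    ).W
    spec = CohortSpec(
        layout=small_layout,
        base_connectivity=base,
        groups=(
            GroupSpec("control", 5, [], noise_correlation_length=0.02),
            GroupSpec("case", 4, [(2, 5, 8.0)], noise_correlation_length=0.06),
        ),
        dt=1.0 / 625,
        duration=6.0,
        jitter_scale=0.3,
        seed=11,
    )
    return synthesize_cohort(spec)


def make_recording(data, dt=1.0):
    data = np.asarray(data, float)
    ids = [f"ch{i:03d}" for i in range(data.shape[0])]
    return MultichannelRecording(channel_ids=ids, data=data, dt=dt)


def cohort_from_matrices(W_ref, W_case, dt=1.0):
    """Build a fitted cohort directly from stacks of drift matrices
    (dummy recordings), for statistics tests that need no signals."""
    n = W_ref[0].shape[0]
    ids = [f"ch{i:03d}" for i in range(n)]
    dummy = np.zeros((n, 3))
    subjects = []
    for g, stack in (("control", W_ref), ("case", W_case)):
        for k, W in enumerate(stack):
            sub = SubjectData(
                subject_id=f"{g}_{k:02d}",
                group=g,
                recording=MultichannelRecording(ids, dummy, dt),
                connectivity=ConnectivityMatrix(W=W, channel_ids=ids, lag_used=dt),
            )
            subjects.append(sub)
    return CohortDataset(
        subjects=subjects, layout=None, dt=dt, groups=("control", "case")
    )
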