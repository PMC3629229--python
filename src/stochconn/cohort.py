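"""Cohort container shared by the simulator, statistics, classification and
pipeline modules: a list of subjects with group labels, their recordings
and (after fitting) their connectivity and noise models."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    ConnectivityMatrix,
    MultichannelRecording,
    NoiseModel,
    fit_moup,
)
from .spatial import SensorLayout

__all__ = ["SubjectData", "CohortDataset", "fit_cohort"]


@dataclass
class SubjectData:
    subject_id: str
    group: str
    recording: MultichannelRecording
    connectivity: ConnectivityMatrix | None = None
    noise: NoiseModel | None = None
    C0: np.ndarray | None = None
    max_real_eigenvalue: float | None = None
    n_artifact_components: int = 0


@dataclass
class CohortDataset:
    """Two-group collection of subjects on a shared channel set.

    `groups` orders the labels as (reference, case); group differences are
    reported as case minus reference.
    """

    subjects: list[SubjectData]
    layout: SensorLayout | None
    dt: float
    groups: tuple[str, str]
    ground_truth: dict | None = None

    def __post_init__(self) -> None:
        labels = {s.group for s in self.subjects}
        if not labels.issubset(set(self.groups)):
            raise ValueError(f"subject groups {labels} not in declared {self.groups}")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def channel_ids(self) -> list[str]:
        return list(self.subjects[0].recording.channel_ids)

    def group_subjects(self, label: str) -> list[SubjectData]:
        return [s for s in self.subjects if s.group == label]

    def group_sizes(self) -> tuple[int, int]:
        return (
            len(self.group_subjects(self.groups[0])),
            len(self.group_subjects(self.groups[1])),
        )

    def connectivity_stack(self, label: str) -> np.ndarray:
        """(n_subjects_in_group, N, N) stack of fitted drift matrices."""
        subs = self.group_subjects(label)
        if any(s.connectivity is None for s in subs):
            raise ValueError(f"group '{label}' has unfitted subjects")
        return np.stack([s.connectivity.W for s in subs])


def fit_cohort(cohort: CohortDataset, lag_steps: int = 1) -> CohortDataset:
    """Fit every subject in place (drift, residuals, both Q estimates,
    stability) and return the cohort."""
    for sub in cohort.subjects:
        res = fit_moup(sub.recording, lag_steps=lag_steps)
        sub.connectivity = res.connectivity
        sub.noise = res.noise
        sub.C0 = res.C0
        sub.max_real_eigenvalue = res.stability.max_real_part
    return cohort
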