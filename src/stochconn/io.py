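"""Readers/writers for the canonical text formats, cohort manifests and the
end-to-end pipeline driver.

Canonical dialects (all UTF-8, tab-separated):

* recording: header row of channel ids; row k+1 holds the samples of
  channel k
* matrix: header row of channel ids; then one row per channel
* layout: columns ``id  x  y  z`` (meters; z optional -> 2-D only)
* manifest: JSON with ``dt``, ``groups`` [reference, case], ``layout``
  path, ``retained_channels`` and per-subject entries
  ``{id, path, group, artifact_components}``
"""

from __future__ import annotations

import json
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import classify as _classify
from . import spatial as _spatial
from . import stats as _stats
from .cohort import CohortDataset, SubjectData, fit_cohort
from .core import MultichannelRecording, center_signals, residual_diagnostics
from .simulate import remove_artifact_components
from .spatial import SensorLayout

__all__ = [
    "AnalysisConfig",
    "write_recording",
    "read_recording",
    "write_matrix",
    "read_matrix",
    "write_layout",
    "read_layout",
    "write_manifest",
    "load_cohort",
    "run_full_comparison",
]


@dataclass
class AnalysisConfig:
    """Reproducibility-relevant knobs of the full pipeline."""

    lag_steps: int = 1
    n_perm_connections: int = 10_000
    n_perm_labels: int = 10_000
    seed: int = 0
    svm_cost: float = _classify.DEFAULT_SVM_COST
    diagnostics_max_lag: int = 20
    crosstalk_max_distance: float = 0.10
    top_k_changes: int = 10

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


# ---------------------------------------------------------------- writers

def write_recording(path: str | Path, rec: MultichannelRecording) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(rec.channel_ids) + "\n")
        for row in rec.data:
            fh.write("\t".join(f"{v:.17e}" for v in row) + "\n")


def read_recording(path: str | Path, dt: float) -> MultichannelRecording:
    with open(path) as fh:
        ids = fh.readline().rstrip("\n").split("\t")
        data = np.loadtxt(fh, delimiter="\t", ndmin=2)
    if data.shape[0] != len(ids):
        raise ValueError(f"{path}: expected {len(ids)} channel rows, got {data.shape[0]}")
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{path}: recording contains non-finite values")
    return MultichannelRecording(channel_ids=ids, data=data, dt=dt)


def write_matrix(path: str | Path, M: np.ndarray, channel_ids: list[str]) -> None:
    M = np.asarray(M, float)
    with open(path, "w") as fh:
        fh.write("\t".join(channel_ids) + "\n")
        for row in M:
            fh.write("\t".join(f"{v:.17e}" for v in row) + "\n")


def read_matrix(path: str | Path) -> tuple[np.ndarray, list[str]]:
    with open(path) as fh:
        ids = fh.readline().rstrip("\n").split("\t")
        M = np.loadtxt(fh, delimiter="\t", ndmin=2)
    return M, ids


def write_layout(path: str | Path, layout: SensorLayout) -> None:
    with open(path, "w") as fh:
        if layout.pos3d is not None:
            fh.write("id\tx\ty\tz\n")
            for i, sid in enumerate(layout.ids):
                x, y, z = layout.pos3d[i]
                fh.write(f"{sid}\t{x:.17e}\t{y:.17e}\t{z:.17e}\n")
        else:
            fh.write("id\tx\ty\n")
            for i, sid in enumerate(layout.ids):
                x, y = layout.pos2d[i]
                fh.write(f"{sid}\t{x:.17e}\t{y:.17e}\n")


def read_layout(path: str | Path, project: bool = True) -> SensorLayout:
    """Read a layout file.  3-D layouts are stereographically projected to
    obtain the planar coordinates; 2-D files are used as-is."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        ids, rows = [], []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            ids.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
    coords = np.asarray(rows, float)
    if len(header) >= 4 and coords.shape[1] >= 3:
        pos3d = coords[:, :3]
        pos2d = _spatial.stereographic_projection(pos3d) if project else pos3d[:, :2]
        return SensorLayout(ids=ids, pos2d=pos2d, pos3d=pos3d)
    return SensorLayout(ids=ids, pos2d=coords[:, :2], pos3d=None)


def write_manifest(
    path: str | Path,
    cohort: CohortDataset,
    recording_paths: dict[str, str],
    layout_path: str | None = None,
) -> None:
    doc = {
        "dt": cohort.dt,
        "groups": list(cohort.groups),
        "layout": layout_path,
        "retained_channels": cohort.channel_ids,
        "subjects": [
            {
                "id": s.subject_id,
                "path": recording_paths[s.subject_id],
                "group": s.group,
                "artifact_components": s.n_artifact_components,
            }
            for s in cohort.subjects
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def load_cohort(manifest_path: str | Path) -> CohortDataset:
    """Load a cohort: read every recording, restrict to the retained
    channels (manifest order), center, and remove the recorded number of
    artifact components per subject."""
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        doc = json.load(fh)
    groups = tuple(doc["groups"])
    if len(groups) != 2:
        raise ValueError("manifest must declare exactly two group labels")
    dt = float(doc["dt"])
    base = manifest_path.parent
    layout = None
    if doc.get("layout"):
        layout = read_layout(base / doc["layout"])
    retained = doc.get("retained_channels")
    subjects = []
    for entry in doc["subjects"]:
        rec_path = base / entry["path"]
        if not rec_path.exists():
            raise FileNotFoundError(f"subject {entry['id']}: missing file {rec_path}")
        rec = read_recording(rec_path, dt)
        if retained:
            index = {cid: k for k, cid in enumerate(rec.channel_ids)}
            missing = [c for c in retained if c not in index]
            if missing:
                raise ValueError(
                    f"subject {entry['id']}: channel(s) {missing} absent from recording"
                )
            rows = [index[c] for c in retained]
            rec = MultichannelRecording(list(retained), rec.data[rows], dt)
        rec = center_signals(rec)
        k = int(entry.get("artifact_components", 0))
        if k:
            rec = remove_artifact_components(rec, k)
        subjects.append(
            SubjectData(
                subject_id=entry["id"],
                group=entry["group"],
                recording=rec,
                n_artifact_components=k,
            )
        )
    if retained and layout is not None:
        keep = [k for k, sid in enumerate(layout.ids) if sid in set(retained)]
        if len(keep) == len(retained):
            order = {sid: k for k, sid in enumerate(layout.ids)}
            rows = [order[c] for c in retained]
            layout = SensorLayout(
                ids=list(retained),
                pos2d=layout.pos2d[rows],
                pos3d=None if layout.pos3d is None else layout.pos3d[rows],
            )
    return CohortDataset(subjects=subjects, layout=layout, dt=dt, groups=groups)


# ------------------------------------------------------------- pipeline

def _seed_for(base_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the config seed."""
    tag = zlib.crc32(stage.encode())
    child = np.random.SeedSequence(base_seed, spawn_key=(tag,))
    return int(child.generate_state(1)[0])


def run_full_comparison(
    cohort: CohortDataset, config: AnalysisConfig | None = None
) -> dict:
    """Full downstream battery on a loaded cohort; returns a
    JSON-serializable bundle.

    Stages: per-subject fits (W, Q_E, Q_T, stability, residual
    diagnostics), connection-wise change maps and ranked changes, balance
    correlations with rank-sum group comparisons, W- and Q-feature
    classifier reports, spatial-complexity comparison and (when 3-D
    positions exist) cross-talk profiles.  Identical cohort + config +
    seeds give an identical bundle.
    """
    config = config or AnalysisConfig()
    ref_label, case_label = cohort.groups
    if any(len(cohort.group_subjects(g)) == 0 for g in cohort.groups):
        raise ValueError("both groups must be nonempty")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        fit_cohort(cohort, lag_steps=config.lag_steps)

    bundle: dict = {
        "config": {
            "lag_steps": config.lag_steps,
            "n_perm_connections": config.n_perm_connections,
            "n_perm_labels": config.n_perm_labels,
            "seed": config.seed,
            "svm_cost": config.svm_cost,
        },
        "groups": {"reference": ref_label, "case": case_label},
        "n_channels": len(cohort.channel_ids),
        "subjects": {},
    }

    max_lag = min(config.diagnostics_max_lag,
                  cohort.subjects[0].recording.n_samples - 2)
    for sub in cohort.subjects:
        diag = residual_diagnostics(sub.noise, max_lag=max_lag)
        bundle["subjects"][sub.subject_id] = {
            "group": sub.group,
            "max_real_eigenvalue": sub.max_real_eigenvalue,
            "stable": bool(sub.max_real_eigenvalue < 0),
            "noise_agreement": sub.noise.agreement,
            "whiteness_score": diag.whiteness_score,
            "mean_abs_skewness": float(np.mean(np.abs(diag.skewness))),
        }

    # connection-wise permutation maps
    maps = _stats.connectionwise_changes(
        cohort,
        n_perm=config.n_perm_connections,
        seed=_seed_for(config.seed, "connections"),
    )
    top_abs = _stats.rank_changes(maps, config.top_k_changes, kind="weighted")
    top_rel = _stats.rank_changes(maps, config.top_k_changes, kind="relative")
    bundle["connection_changes"] = {
        "n_permutations": maps.n_permutations,
        "max_abs_z": float(np.max(np.abs(maps.zmap))),
        "top_weighted": top_abs.to_dict(orient="records"),
        "top_relative": top_rel.to_dict(orient="records"),
    }

    # stability + balance group comparisons
    stab_ref = [s.max_real_eigenvalue for s in cohort.group_subjects(ref_label)]
    stab_case = [s.max_real_eigenvalue for s in cohort.group_subjects(case_label)]
    rs = _stats.ranksum_compare(stab_ref, stab_case)
    bundle["stability_comparison"] = {
        "reference_median": float(np.median(stab_ref)),
        "case_median": float(np.median(stab_case)),
        "p_value": rs.p_value,
    }
    balance_p = {}
    per_group_corr: dict[str, dict[str, list[float]]] = {g: {} for g in cohort.groups}
    for g in cohort.groups:
        for sub in cohort.group_subjects(g):
            rep = _stats.balance_analysis(sub.connectivity.W)
            for name, val in rep.correlations.items():
                per_group_corr[g].setdefault(name, []).append(val)
    for name in per_group_corr[ref_label]:
        a = per_group_corr[ref_label][name]
        b = per_group_corr[case_label][name]
        if np.all(np.isfinite(a)) and np.all(np.isfinite(b)):
            balance_p[name] = _stats.ranksum_compare(a, b).p_value
        else:
            balance_p[name] = None
    bundle["balance_comparison"] = balance_p

    # classification on W and on Q features
    bundle["classification"] = {}
    for source in ("W", "Q"):
        fs = _classify.features_from_cohort(cohort, source=source)
        report = _classify.label_permutation_significance(
            fs,
            n_perm=config.n_perm_labels,
            seed=_seed_for(config.seed, f"labels_{source}"),
            cost=config.svm_cost,
        )
        bundle["classification"][source] = {
            "confusion": {
                "tp": report.confusion.tp,
                "fn": report.confusion.fn,
                "tn": report.confusion.tn,
                "fp": report.confusion.fp,
            },
            "metrics": report.metrics,
            "p_values": report.p_values,
            "n_permutations": report.n_permutations,
        }

    # noise spatial structure
    if cohort.layout is not None:
        complexities: dict[str, list[float]] = {g: [] for g in cohort.groups}
        for sub in cohort.subjects:
            pattern = _spatial.dominant_noise_pattern(sub.noise.Q_empirical)
            score = _spatial.spatial_complexity(pattern, cohort.layout)
            complexities[sub.group].append(score)
            bundle["subjects"][sub.subject_id]["spatial_complexity"] = score
        rs = _stats.ranksum_compare(
            complexities[ref_label], complexities[case_label]
        )
        bundle["complexity_comparison"] = {
            "reference_median": float(np.median(complexities[ref_label])),
            "case_median": float(np.median(complexities[case_label])),
            "p_value": rs.p_value,
        }
        if cohort.layout.pos3d is not None:
            r_values: dict[str, list[float]] = {g: [] for g in cohort.groups}
            for sub in cohort.subjects:
                prof = _spatial.crosstalk_profile(
                    sub.C0, cohort.layout, config.crosstalk_max_distance
                )
                r_values[sub.group].append(prof.r)
                bundle["subjects"][sub.subject_id]["crosstalk_r"] = prof.r
            rs = _stats.ranksum_compare(r_values[ref_label], r_values[case_label])
            bundle["crosstalk_comparison"] = {
                "reference_median": float(np.median(r_values[ref_label])),
                "case_median": float(np.median(r_values[case_label])),
                "p_value": rs.p_value,
            }
    return bundle
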