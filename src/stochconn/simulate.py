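"""Synthetic recordings and cohorts with the statistical structure the
linear stochastic model assumes: stable random drift matrices, spatially
correlated driving noise over a sensor layout, exact (or Euler-Maruyama)
sampling of the process, planted group differences, and PCA artifact
removal."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla

from .cohort import CohortDataset, SubjectData
from .core import ConnectivityMatrix, MultichannelRecording
from .spatial import SensorLayout

__all__ = [
    "SimulationSpec",
    "GroupSpec",
    "CohortSpec",
    "disc_layout",
    "random_stable_connectivity",
    "spatial_noise_covariance",
    "simulate_moup",
    "synthesize_cohort",
    "remove_artifact_components",
]


@dataclass
class SimulationSpec:
    """Parameters for one synthetic recording.

    scheme 'exact' draws from the stationary AR(1) reduction of the
    process (x_{t+1} = e^{W dt} x_t + eta); 'euler' uses Euler-Maruyama.
    """

    W_true: np.ndarray
    Q_true: np.ndarray
    dt: float = 1.0 / 625
    duration: float = 30.0
    scheme: str = "exact"
    seed: int | np.random.Generator | None = 0

    def __post_init__(self) -> None:
        self.W_true = np.asarray(self.W_true, float)
        self.Q_true = np.asarray(self.Q_true, float)
        if self.W_true.shape != self.Q_true.shape or self.W_true.ndim != 2:
            raise ValueError("W_true and Q_true must be square with equal shape")
        if np.max(np.abs(self.Q_true - self.Q_true.T)) > 1e-10 * max(
            np.max(np.abs(self.Q_true)), 1e-300
        ):
            raise ValueError("Q_true must be symmetric")
        if self.scheme not in ("exact", "euler"):
            raise ValueError("scheme must be 'exact' or 'euler'")
        if self.duration / self.dt < 10:
            raise ValueError("need at least 10 samples (duration/dt >= 10)")


@dataclass
class GroupSpec:
    """One cohort arm: subject count, planted connection changes and the
    spatial correlation length of its driving noise."""

    label: str
    n_subjects: int
    connection_deltas: list[tuple[int, int, float]] = field(default_factory=list)
    noise_correlation_length: float = 0.05  # meters


@dataclass
class CohortSpec:
    """Two-arm synthetic cohort sharing a layout and base dynamics.

    `groups[0]` is the reference (control-like) arm; `groups[1]` receives
    its own `connection_deltas` on top of the shared base drift matrix.
    """

    layout: SensorLayout
    base_connectivity: np.ndarray
    groups: tuple[GroupSpec, GroupSpec]
    dt: float = 1.0 / 625
    duration: float = 30.0
    noise_variance: float = 1.0
    jitter_scale: float = 0.05  # std of Gaussian jitter on nonzero W entries
    seed: int = 0


def disc_layout(n_sensors: int = 141, radius: float = 0.10) -> SensorLayout:
    """Sunflower-packed disc of sensors (projected grid), with matching 3-D
    positions on a spherical cap of the same radius."""
    if n_sensors < 4:
        raise ValueError("need at least 4 sensors")
    k = np.arange(n_sensors)
    r = radius * np.sqrt((k + 0.5) / n_sensors)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    theta = k * golden
    pos2d = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    # map the planar radius onto a polar angle over most of a hemisphere
    phi = (r / radius) * (0.45 * np.pi)
    pos3d = radius * np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )
    ids = [f"ch{i:03d}" for i in range(n_sensors)]
    return SensorLayout(ids=ids, pos2d=pos2d, pos3d=pos3d)


def random_stable_connectivity(
    n_channels: int,
    target_max_real_part: float = -2.0,
    density: float = 0.2,
    seed: int | np.random.Generator | None = 0,
    coupling_scale: float | None = None,
    rotation_scale: float = 0.0,
) -> ConnectivityMatrix:
    """Random mixed-sign drift matrix, spectrally shifted so its maximal
    eigenvalue real part equals `target_max_real_part` (1/s).

    The matrix is a sparse asymmetric coupling block (fraction `density`
    of off-diagonal entries, scale `coupling_scale`) plus an optional
    dense skew-symmetric part of scale `rotation_scale`.  Rotational
    coupling adds oscillatory modes without touching stability and makes
    the drift much better identifiable from short records.  With
    density = 0 and rotation_scale = 0 the result is target * I.
    """
    if n_channels < 2:
        raise ValueError("need at least 2 channels")
    if target_max_real_part >= 0:
        raise ValueError("target max real part must be negative")
    rng = np.random.default_rng(seed)
    if coupling_scale is None:
        coupling_scale = abs(target_max_real_part) / np.sqrt(
            max(n_channels * density, 1.0)
        )
    mask = rng.random((n_channels, n_channels)) < density
    np.fill_diagonal(mask, False)
    G = np.where(mask, rng.normal(0.0, coupling_scale, (n_channels, n_channels)), 0.0)
    if rotation_scale > 0:
        A = rng.normal(0.0, rotation_scale, (n_channels, n_channels))
        G = G + (A - A.T) / np.sqrt(2.0)
    shift = target_max_real_part - float(np.max(np.linalg.eigvals(G).real))
    W = G + shift * np.eye(n_channels)
    ids = [f"ch{i:03d}" for i in range(n_channels)]
    return ConnectivityMatrix(W=W, channel_ids=ids, lag_used=0.0)


def spatial_noise_covariance(
    layout: SensorLayout | np.ndarray,
    correlation_length: float,
    variance: float = 1.0,
    ridge: float | None = None,
) -> np.ndarray:
    """Squared-exponential noise covariance over the 2-D layout:
    ``Q_ij = variance * exp(-d_ij^2 / (2 l^2))`` plus a small diagonal
    ridge guaranteeing strict positive definiteness.

    Coincident sensors simply receive full covariance (kernel value
    `variance`); they are not an error here.
    """
    if correlation_length <= 0:
        raise ValueError("correlation_length must be positive")
    pts = layout.pos2d if isinstance(layout, SensorLayout) else np.asarray(layout, float)
    if ridge is None:
        ridge = 1e-6 * variance
    diff = pts[:, None, :] - pts[None, :, :]
    d2 = (diff**2).sum(axis=-1)
    Q = variance * np.exp(-d2 / (2.0 * correlation_length**2))
    return Q + ridge * np.eye(len(pts))


def _psd_sqrt(M: np.ndarray) -> np.ndarray:
    lam, vec = np.linalg.eigh(0.5 * (M + M.T))
    lam = np.clip(lam, 0.0, None)
    return vec @ np.diag(np.sqrt(lam)) @ vec.T


def stationary_covariance(W: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Solve the stationary Lyapunov equation W C + C W^T + Q = 0."""
    C = sla.solve_continuous_lyapunov(W, -np.asarray(Q, float))
    return 0.5 * (C + C.T)


def simulate_moup(spec: SimulationSpec) -> MultichannelRecording:
    """Sample one trajectory of the linear stochastic system.

    Exact scheme: ``x_{t+1} = A x_t + eta`` with ``A = expm(W dt)`` and
    ``Cov(eta) = C - A C A^T`` where C is the stationary covariance; the
    initial state is drawn from the stationary law, so there is no burn-in
    transient.  Euler scheme: ``x_{t+1} = x_t + dt W x_t + sqrt(dt) L z``
    with ``L L^T = Q``.
    """
    rng = (
        spec.seed
        if isinstance(spec.seed, np.random.Generator)
        else np.random.default_rng(spec.seed)
    )
    W, Q, dt = spec.W_true, spec.Q_true, spec.dt
    n = W.shape[0]
    n_steps = int(round(spec.duration / dt))
    max_re = float(np.max(np.linalg.eigvals(W).real))
    x = np.empty((n, n_steps))
    if spec.scheme == "exact":
        if max_re >= 0:
            raise ValueError("exact scheme requires a stable W (no stationary law)")
        C = stationary_covariance(W, Q)
        A = sla.expm(W * dt)
        Sigma = C - A @ C @ A.T
        L_eta = _psd_sqrt(Sigma)
        x[:, 0] = _psd_sqrt(C) @ rng.standard_normal(n)
        z = rng.standard_normal((n, n_steps - 1))
        eta = L_eta @ z
        for t in range(1, n_steps):
            x[:, t] = A @ x[:, t - 1] + eta[:, t - 1]
    else:
        L = _psd_sqrt(Q) * np.sqrt(dt)
        if max_re < 0:
            x[:, 0] = _psd_sqrt(stationary_covariance(W, Q)) @ rng.standard_normal(n)
        else:
            x[:, 0] = 0.0
        z = rng.standard_normal((n, n_steps - 1))
        noise = L @ z
        A = np.eye(n) + dt * W
        for t in range(1, n_steps):
            x[:, t] = A @ x[:, t - 1] + noise[:, t - 1]
    ids = [f"ch{i:03d}" for i in range(n)]
    return MultichannelRecording(channel_ids=ids, data=x, dt=dt)


def _jittered_stable(
    base: np.ndarray,
    jitter_scale: float,
    rng: np.random.Generator,
    max_attempts: int = 100,
) -> np.ndarray:
    """Add i.i.d. Gaussian jitter to the nonzero entries of `base`,
    resampling until the result is stable."""
    mask = base != 0
    for _ in range(max_attempts):
        W = base.copy()
        W[mask] += rng.normal(0.0, jitter_scale, int(mask.sum()))
        if np.max(np.linalg.eigvals(W).real) < 0:
            return W
    raise RuntimeError(
        f"could not draw a stable jittered drift matrix in {max_attempts} attempts"
    )


def synthesize_cohort(spec: CohortSpec) -> CohortDataset:
    """Generate a two-arm cohort of recordings with planted differences.

    Ground truth (per-subject drift, per-group noise covariance, planted
    deltas) is recorded on the returned dataset for test assertions.
    """
    rng = np.random.default_rng(spec.seed)
    layout = spec.layout
    n = layout.n_sensors
    base = np.asarray(spec.base_connectivity, float)
    if base.shape != (n, n):
        raise ValueError("base_connectivity must match the layout size")
    subjects: list[SubjectData] = []
    truth: dict = {
        "groups": {},
        "subject_W": {},
        "dt": spec.dt,
        "duration": spec.duration,
        "seed": spec.seed,
    }
    for g_idx, group in enumerate(spec.groups):
        group_base = base.copy()
        for i, j, delta in group.connection_deltas:
            group_base[i, j] += delta
        Q_group = spatial_noise_covariance(
            layout, group.noise_correlation_length, spec.noise_variance
        )
        truth["groups"][group.label] = {
            "connection_deltas": [list(d) for d in group.connection_deltas],
            "noise_correlation_length": group.noise_correlation_length,
            "Q": Q_group,
        }
        for s in range(group.n_subjects):
            W_s = _jittered_stable(group_base, spec.jitter_scale, rng)
            rec = simulate_moup(
                SimulationSpec(
                    W_true=W_s,
                    Q_true=Q_group,
                    dt=spec.dt,
                    duration=spec.duration,
                    scheme="exact",
                    seed=rng,
                )
            )
            rec = MultichannelRecording(list(layout.ids), rec.data, spec.dt)
            sid = f"{group.label}_{s:02d}"
            truth["subject_W"][sid] = W_s
            subjects.append(SubjectData(subject_id=sid, group=group.label, recording=rec))
    return CohortDataset(
        subjects=subjects,
        layout=layout,
        dt=spec.dt,
        groups=(spec.groups[0].label, spec.groups[1].label),
        ground_truth=truth,
    )


def remove_artifact_components(
    rec: MultichannelRecording, k: int
) -> MultichannelRecording:
    """Project out the k leading principal components of the channels x
    samples block (high-amplitude artifacts such as eye blinks dominate
    the first few components).  k = 0 is the identity."""
    n = rec.n_channels
    if k < 0 or k >= n:
        raise ValueError(f"k must satisfy 0 <= k < {n}")
    if k == 0:
        return MultichannelRecording(list(rec.channel_ids), rec.data.copy(), rec.dt)
    X = rec.data - rec.data.mean(axis=1, keepdims=True)
    U, _, _ = np.linalg.svd(X, full_matrices=False)
    V = U[:, :k]
    cleaned = X - V @ (V.T @ X)
    return MultichannelRecording(list(rec.channel_ids), cleaned, rec.dt)
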