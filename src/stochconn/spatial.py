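"""Spatial structure of the background noise: sensor layouts, stereographic
projection, dominant noise patterns, leave-one-out interpolation complexity
and the covariance-vs-distance cross-talk profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SensorLayout",
    "SpatialPattern",
    "CrosstalkProfile",
    "fit_sphere",
    "stereographic_projection",
    "inverse_stereographic",
    "dominant_noise_pattern",
    "spatial_complexity",
    "crosstalk_profile",
]

# relative tolerance for detecting degenerate (repeated) eigenvalues
EIGEN_DEGENERACY_RTOL = 1e-8


@dataclass
class SensorLayout:
    """Sensor ids with projected 2-D coordinates and optional 3-D positions
    (meters)."""

    ids: list[str]
    pos2d: np.ndarray  # (M, 2)
    pos3d: np.ndarray | None = None  # (M, 3)

    def __post_init__(self) -> None:
        self.pos2d = np.asarray(self.pos2d, dtype=float)
        if self.pos2d.shape != (len(self.ids), 2):
            raise ValueError("pos2d must be (n_sensors, 2)")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("sensor ids must be unique")
        if self.pos3d is not None:
            self.pos3d = np.asarray(self.pos3d, dtype=float)
            if self.pos3d.shape != (len(self.ids), 3):
                raise ValueError("pos3d must be (n_sensors, 3)")
        # duplicate planar coordinates break the interpolation system
        d = _pairwise_distances(self.pos2d)
        np.fill_diagonal(d, np.inf)
        if np.min(d) == 0:
            raise ValueError("2-D sensor coordinates must be distinct")

    @property
    def n_sensors(self) -> int:
        return len(self.ids)


@dataclass
class SpatialPattern:
    """One scalar per sensor, with the eigen-weights that generated it."""

    values: np.ndarray
    weights: np.ndarray | None = None
    informative: bool = True


@dataclass
class CrosstalkProfile:
    """Covariance vs inter-sensor distance over close pairs."""

    table: pd.DataFrame  # columns: sensor_a, sensor_b, distance, covariance
    slope: float
    intercept: float
    r: float
    max_distance: float


def _pairwise_distances(points: np.ndarray) -> np.ndarray:
    diff = points[:, None, :] - points[None, :, :]
    return np.sqrt((diff**2).sum(axis=-1))


def fit_sphere(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares sphere fit: returns (center, radius).

    Linearizes |p|^2 = 2 c.p + (R^2 - |c|^2).
    """
    p = np.asarray(points, float)
    A = np.hstack([2 * p, np.ones((len(p), 1))])
    b = (p**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    center = sol[:3]
    radius = float(np.sqrt(sol[3] + center @ center))
    return center, radius


def _rotation_to_z(up: np.ndarray) -> np.ndarray:
    """Rotation matrix taking the unit vector `up` to +z."""
    u = np.asarray(up, float)
    u = u / np.linalg.norm(u)
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(u, z)
    c = float(u @ z)
    s = np.linalg.norm(v)
    if s < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)


def stereographic_projection(
    positions: np.ndarray,
    up: tuple[float, float, float] = (0.0, 0.0, 1.0),
    scale: float = 1.0,
) -> np.ndarray:
    """Project sensor positions from a fitted sphere onto a plane.

    The sphere is fitted to the point cloud; each point is radially snapped
    onto it.  The projection point is the inferior pole (opposite to `up`)
    and the image plane is tangent at the superior pole, so the superior
    pole maps to the origin and the equator to a circle of radius equal to
    the sphere diameter (times `scale`).
    """
    p = np.asarray(positions, float)
    center, radius = fit_sphere(p)
    R = _rotation_to_z(np.asarray(up, float))
    q = (p - center) @ R.T
    norms = np.linalg.norm(q, axis=1)
    if np.any(norms < 1e-12 * radius):
        raise ValueError("a sensor coincides with the sphere center")
    q = q * (radius / norms)[:, None]
    denom = radius + q[:, 2]
    if np.any(denom < 1e-9 * radius):
        raise ValueError("a sensor lies at the projection pole")
    xy = 2 * radius * q[:, :2] / denom[:, None]
    return scale * xy


def inverse_stereographic(
    xy: np.ndarray, radius: float, scale: float = 1.0
) -> np.ndarray:
    """Inverse of :func:`stereographic_projection` on the canonical
    (centered, up = +z) sphere."""
    xy = np.asarray(xy, float) / scale
    rho2 = (xy**2).sum(axis=1)
    z = radius * (4 * radius**2 - rho2) / (4 * radius**2 + rho2)
    xyz = np.empty((len(xy), 3))
    xyz[:, :2] = xy * ((radius + z) / (2 * radius))[:, None]
    xyz[:, 2] = z
    return xyz


def dominant_noise_pattern(Q: np.ndarray, sym_rtol: float = 1e-8) -> SpatialPattern:
    """Eigenvalue-weighted average of the eigenvectors of Q.

    Each unit eigenvector is oriented so that its largest-magnitude
    component is positive; weights are the raw eigenvalues normalized to
    sum 1.  A spectrum with (near-)repeated nonzero eigenvalues makes the
    eigenbasis arbitrary, so the pattern is flagged non-informative.
    """
    Q = np.asarray(Q, float)
    if Q.ndim != 2 or Q.shape[0] != Q.shape[1]:
        raise ValueError("Q must be square")
    scale = np.max(np.abs(Q)) or 1.0
    if np.max(np.abs(Q - Q.T)) > sym_rtol * scale:
        raise ValueError("Q is not symmetric within tolerance")
    lam, vec = np.linalg.eigh(0.5 * (Q + Q.T))
    total = lam.sum()
    if total <= 0:
        return SpatialPattern(
            values=np.zeros(Q.shape[0]), weights=np.zeros_like(lam), informative=False
        )
    # fix each eigenvector's sign by its largest-magnitude component
    for k in range(vec.shape[1]):
        j = int(np.argmax(np.abs(vec[:, k])))
        if vec[j, k] < 0:
            vec[:, k] = -vec[:, k]
    weights = lam / total
    values = vec @ weights
    lam_max = float(lam[-1])
    nonzero = lam[lam > 1e-12 * lam_max]
    informative = True
    if len(nonzero) > 1:
        gaps = np.diff(np.sort(nonzero))
        if np.any(gaps < EIGEN_DEGENERACY_RTOL * lam_max):
            informative = False
    return SpatialPattern(values=values, weights=weights, informative=informative)


def _biharmonic_kernel(r: np.ndarray) -> np.ndarray:
    """Green's function of the 2-D biharmonic operator, phi(r) = r^2 (ln r - 1)."""
    out = np.zeros_like(r)
    mask = r > 0
    rm = r[mask]
    out[mask] = rm**2 * (np.log(rm) - 1.0)
    return out


def _interpolate_loo(
    values: np.ndarray, points: np.ndarray, s: int, support: np.ndarray
) -> float:
    """Predict values[s] from the sensors in `support` with a biharmonic
    spline plus affine term (exact on constants and planes)."""
    pts = points[support]
    y = values[support]
    m = len(support)
    D = _pairwise_distances(pts)
    P = np.column_stack([np.ones(m), pts])  # 1, x, y
    A = np.zeros((m + 3, m + 3))
    A[:m, :m] = _biharmonic_kernel(D)
    A[:m, m:] = P
    A[m:, :m] = P.T
    rhs = np.concatenate([y, np.zeros(3)])
    try:
        sol = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular interpolation system (coincident or collinear sensors?)"
        ) from exc
    w, poly = sol[:m], sol[m:]
    d = np.linalg.norm(pts - points[s], axis=1)
    return float(
        _biharmonic_kernel(d) @ w + poly[0] + poly[1:] @ points[s]
    )


def spatial_complexity(
    pattern: SpatialPattern | np.ndarray,
    layout: SensorLayout | np.ndarray,
    n_neighbors: int | None = None,
) -> float:
    """Root-mean-square leave-one-out interpolation error of a sensor
    pattern on its 2-D layout.

    For each sensor, a smooth scattered-data interpolant (biharmonic
    spline) is fitted on all remaining sensors (or the `n_neighbors`
    nearest ones) and evaluated at the held-out position; the returned
    score is the RMS of the prediction errors.  Smooth, spatially extended
    patterns score low; patchy ones score high.
    """
    values = pattern.values if isinstance(pattern, SpatialPattern) else np.asarray(
        pattern, float
    )
    points = layout.pos2d if isinstance(layout, SensorLayout) else np.asarray(
        layout, float
    )
    m = len(values)
    if points.shape != (m, 2):
        raise ValueError("layout must provide one 2-D coordinate per value")
    if m < 4:
        raise ValueError("need at least 4 sensors")
    errors = np.empty(m)
    all_idx = np.arange(m)
    for s in range(m):
        support = all_idx[all_idx != s]
        if n_neighbors is not None:
            d = np.linalg.norm(points[support] - points[s], axis=1)
            support = support[np.argsort(d)[:n_neighbors]]
        pred = _interpolate_loo(values, points, s, support)
        errors[s] = values[s] - pred
    return float(np.sqrt(np.mean(errors**2)))


def crosstalk_profile(
    C0: np.ndarray,
    layout: SensorLayout,
    max_distance: float = 0.10,
) -> CrosstalkProfile:
    """Covariance between sensor pairs vs their 3-D distance, restricted to
    pairs closer than `max_distance` (meters), with a least-squares line
    and Pearson r."""
    C0 = np.asarray(C0, float)
    if layout.pos3d is None:
        raise ValueError("layout has no 3-D positions")
    m = layout.n_sensors
    if C0.shape != (m, m):
        raise ValueError("C0 must match the layout")
    D = _pairwise_distances(layout.pos3d)
    rows = []
    for i in range(m):
        for j in range(i + 1, m):
            if D[i, j] <= max_distance:
                rows.append((layout.ids[i], layout.ids[j], D[i, j], C0[i, j]))
    if not rows:
        raise ValueError(f"no sensor pairs within {max_distance} m")
    table = pd.DataFrame(rows, columns=["sensor_a", "sensor_b", "distance", "covariance"])
    d = table["distance"].to_numpy()
    c = table["covariance"].to_numpy()
    if len(rows) >= 2 and np.std(d) > 0:
        slope, intercept = np.polyfit(d, c, 1)
        r = float(np.corrcoef(d, c)[0, 1]) if np.std(c) > 0 else 0.0
    else:
        slope, intercept, r = 0.0, float(np.mean(c)), 0.0
    return CrosstalkProfile(
        table=table,
        slope=float(slope),
        intercept=float(intercept),
        r=r,
        max_distance=max_distance,
    )
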