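"""Fitting a linear stochastic (multivariate Ornstein-Uhlenbeck) model to
multichannel recordings.

The model is ``dx/dt = W x + xi`` with drift matrix ``W`` (directed
functional connectivity, units 1/s) and Gaussian white noise ``xi`` with
spatial covariance ``Q`` (``<xi(t) xi(t')^T> = Q delta(t - t')``).

Estimation uses lagged covariances: with the orientation
``C(tau) = <x(t+tau) x(t)^T>`` one has ``C(tau) = expm(W tau) C(0)``, and
for small lags ``W ~= (C(tau) C(0)^+ - I) / tau``.  Residuals of the
implied one-step regression give the empirical noise covariance
``Q_E = tau * Cov(residuals)``; the stationary Lyapunov identity gives the
theoretical one ``Q_T = -(W C0 + C0 W^T)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "MultichannelRecording",
    "ConnectivityMatrix",
    "LaggedCovariance",
    "NoiseModel",
    "StabilityReport",
    "ResidualDiagnostics",
    "FitResult",
    "DegenerateInputError",
    "center_signals",
    "lagged_covariance",
    "estimate_connectivity",
    "select_lag",
    "extract_residuals",
    "empirical_noise_covariance",
    "theoretical_noise_covariance",
    "noise_agreement",
    "stability_spectrum",
    "residual_diagnostics",
    "fit_moup",
]

#: relative singular-value cutoff for the pseudo-inverse of C(0)
PINV_RCOND = 1e-10


class DegenerateInputError(ValueError):
    """Raised when the data carry no usable signal (e.g. C(0) = 0)."""


@dataclass
class MultichannelRecording:
    """A block of N simultaneously sampled channels.

    Attributes
    ----------
    channel_ids : list of str
        Channel labels, one per row of ``data``.
    data : ndarray, shape (N, T)
        Signal values, interpreted relative to baseline.
    dt : float
        Sampling interval in seconds.
    """

    channel_ids: list[str]
    data: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D (channels x samples) array")
        if len(self.channel_ids) != self.data.shape[0]:
            raise ValueError("channel_ids length must match number of rows")
        if self.data.shape[1] < 3:
            raise ValueError("need at least 3 samples per channel")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite values")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples * self.dt


@dataclass
class ConnectivityMatrix:
    """Estimated drift matrix.  ``W[i, j]`` is the coupling from channel j
    onto channel i, in 1/s."""

    W: np.ndarray
    channel_ids: list[str]
    lag_used: float  # seconds

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        n = len(self.channel_ids)
        if self.W.shape != (n, n):
            raise ValueError("W must be square and match channel_ids")
        if not np.all(np.isfinite(self.W)):
            raise ValueError("W contains non-finite entries")

    @property
    def n_channels(self) -> int:
        return self.W.shape[0]


@dataclass
class LaggedCovariance:
    """Lagged covariance ``C(tau) = <x(t+tau) x(t)^T>`` (future x past)."""

    C: np.ndarray
    lag: float  # seconds


@dataclass
class NoiseModel:
    """Residual traces and the two noise-covariance estimates."""

    residuals: np.ndarray  # (N, T - lag_steps)
    Q_empirical: np.ndarray | None = None
    Q_theoretical: np.ndarray | None = None
    agreement: float | None = None


@dataclass
class StabilityReport:
    eigenvalues: np.ndarray  # complex, length N
    max_real_part: float
    stable: bool


@dataclass
class ResidualDiagnostics:
    """Per-channel Gaussianity and whiteness summaries of the residuals."""

    skewness: np.ndarray
    excess_kurtosis: np.ndarray
    normality_pvalues: np.ndarray
    autocorrelation: np.ndarray  # (N, max_lag + 1), lag 0 first
    whiteness_score: float  # max |autocorr| over channels and nonzero lags


@dataclass
class FitResult:
    """Convenience bundle produced by :func:`fit_moup`."""

    connectivity: ConnectivityMatrix
    noise: NoiseModel
    C0: np.ndarray
    stability: StabilityReport
    lag_steps: int
    dt: float


def center_signals(rec: MultichannelRecording) -> MultichannelRecording:
    """Remove each channel's temporal mean."""
    data = rec.data - rec.data.mean(axis=1, keepdims=True)
    return MultichannelRecording(list(rec.channel_ids), data, rec.dt)


def lagged_covariance(rec: MultichannelRecording, lag_steps: int) -> LaggedCovariance:
    """Sample lagged covariance over the ``T - lag_steps`` overlapping pairs.

    Signals are assumed centered; no per-window re-centering is applied.
    Divisor is ``n - 1`` with ``n`` the number of overlapping samples.
    """
    if lag_steps < 0:
        raise ValueError("lag_steps must be >= 0")
    T = rec.n_samples
    if lag_steps > T - 2:
        raise ValueError(f"lag_steps={lag_steps} too large for T={T} samples")
    x = rec.data
    future = x[:, lag_steps:]
    past = x[:, : T - lag_steps]
    n = T - lag_steps
    C = future @ past.T / (n - 1)
    if lag_steps == 0:
        C = 0.5 * (C + C.T)
    return LaggedCovariance(C=C, lag=lag_steps * rec.dt)


def estimate_connectivity(
    rec: MultichannelRecording, lag_steps: int = 1
) -> ConnectivityMatrix:
    """Estimate the drift matrix as ``W = (C(tau) C(0)^+ - I) / tau``.

    Uses the pseudo-inverse of the zero-lag covariance so that
    rank-deficient data (e.g. after artifact-component removal) are
    handled without failure.
    """
    if lag_steps < 1:
        raise ValueError("lag_steps must be >= 1")
    C0 = lagged_covariance(rec, 0).C
    if not np.any(C0):
        raise DegenerateInputError("zero-lag covariance is identically zero")
    Ct = lagged_covariance(rec, lag_steps).C
    tau = lag_steps * rec.dt
    C0_inv = np.linalg.pinv(C0, rcond=PINV_RCOND)
    W = (Ct @ C0_inv - np.eye(rec.n_channels)) / tau
    return ConnectivityMatrix(W=W, channel_ids=list(rec.channel_ids), lag_used=tau)


def extract_residuals(
    rec: MultichannelRecording, conn: ConnectivityMatrix, lag_steps: int
) -> NoiseModel:
    """Residual traces ``r(t) = (x(t+tau) - x(t))/tau - W x(t)``."""
    if conn.n_channels != rec.n_channels:
        raise ValueError("connectivity dimensions do not match the recording")
    T = rec.n_samples
    if lag_steps < 1 or lag_steps > T - 1:
        raise ValueError("invalid lag_steps for residual extraction")
    tau = lag_steps * rec.dt
    x = rec.data
    deriv = (x[:, lag_steps:] - x[:, : T - lag_steps]) / tau
    resid = deriv - conn.W @ x[:, : T - lag_steps]
    return NoiseModel(residuals=resid)


def empirical_noise_covariance(
    noise: NoiseModel, lag_steps: int, dt: float
) -> np.ndarray:
    """``Q_E = tau * Cov(residuals)`` (continuous-time noise convention)."""
    resid = noise.residuals
    if resid.shape[1] < 2:
        raise ValueError("need at least 2 residual samples")
    tau = lag_steps * dt
    Q = tau * np.atleast_2d(np.cov(resid, ddof=1))
    return 0.5 * (Q + Q.T)


def theoretical_noise_covariance(
    conn: ConnectivityMatrix | np.ndarray, C0: LaggedCovariance | np.ndarray
) -> np.ndarray:
    """Stationary Lyapunov identity ``Q_T = -(W C0 + C0 W^T)``."""
    W = conn.W if isinstance(conn, ConnectivityMatrix) else np.asarray(conn, float)
    C = C0.C if isinstance(C0, LaggedCovariance) else np.asarray(C0, float)
    if W.shape != C.shape or W.shape[0] != W.shape[1]:
        raise ValueError("W and C0 must be square matrices of equal size")
    if np.max(np.linalg.eigvals(W).real) >= 0:
        warnings.warn(
            "drift matrix is not stable; theoretical Q assumes stationarity",
            RuntimeWarning,
            stacklevel=2,
        )
    Q = -(W @ C + C @ W.T)
    return 0.5 * (Q + Q.T)


def noise_agreement(Q_E: np.ndarray, Q_T: np.ndarray) -> float:
    """Pearson correlation between corresponding entries of the two Q
    estimates.  NaN if either matrix is entrywise constant."""
    a = np.asarray(Q_E, float).ravel()
    b = np.asarray(Q_T, float).ravel()
    if a.shape != b.shape:
        raise ValueError("Q matrices must have the same shape")
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def select_lag(
    rec: MultichannelRecording, candidate_lag_steps: list[int] | tuple[int, ...]
) -> int:
    """Pick the fitting lag minimizing the trace of the one-step
    prediction-residual covariance; ties go to the smallest lag.

    The objective is ``trace(Cov(x(t+tau) - (I + tau W) x(t)))``, i.e. the
    residual covariance at the sampled scale (equal to ``tau * trace(Q_E)``).
    This is the quantity whose minimum sits at the smallest available lag
    for data generated by the model itself, and it quantifies the mean
    quadratic prediction error of the fit.
    """
    if len(candidate_lag_steps) == 0:
        raise ValueError("candidate lag list is empty")
    best_lag = None
    best_trace = np.inf
    for lag in sorted(candidate_lag_steps):
        conn = estimate_connectivity(rec, lag)
        noise = extract_residuals(rec, conn, lag)
        tau = lag * rec.dt
        tr = tau * float(np.trace(empirical_noise_covariance(noise, lag, rec.dt)))
        if tr < best_trace:
            best_trace = tr
            best_lag = lag
    return best_lag


def stability_spectrum(conn: ConnectivityMatrix | np.ndarray) -> StabilityReport:
    """Full eigenvalue spectrum of W and the linear-stability verdict.

    ``stable`` is False when the maximal real part is >= 0 (the fitted
    linear system would not relax back to equilibrium).
    """
    W = conn.W if isinstance(conn, ConnectivityMatrix) else np.asarray(conn, float)
    ev = np.linalg.eigvals(W)
    max_real = float(np.max(ev.real))
    return StabilityReport(eigenvalues=ev, max_real_part=max_real, stable=max_real < 0)


def _autocorrelation(trace: np.ndarray, max_lag: int) -> np.ndarray:
    x = trace - trace.mean()
    denom = float(x @ x)
    if denom == 0:
        out = np.zeros(max_lag + 1)
        out[0] = 1.0
        return out
    out = np.empty(max_lag + 1)
    out[0] = 1.0
    for lag in range(1, max_lag + 1):
        out[lag] = float(x[lag:] @ x[:-lag]) / denom
    return out


def residual_diagnostics(noise: NoiseModel, max_lag: int = 20) -> ResidualDiagnostics:
    """Gaussianity (moment-based omnibus test) and whiteness of the
    residual traces."""
    resid = noise.residuals
    n_samples = resid.shape[1]
    if n_samples < 30:
        raise ValueError("need at least 30 residual samples for diagnostics")
    if max_lag < 1 or max_lag >= n_samples:
        raise ValueError("max_lag must be in [1, n_samples)")
    skew = sps.skew(resid, axis=1)
    kurt = sps.kurtosis(resid, axis=1)
    pvals = np.array([sps.normaltest(row).pvalue for row in resid])
    ac = np.vstack([_autocorrelation(row, max_lag) for row in resid])
    whiteness = float(np.max(np.abs(ac[:, 1:])))
    return ResidualDiagnostics(
        skewness=np.asarray(skew, float),
        excess_kurtosis=np.asarray(kurt, float),
        normality_pvalues=pvals,
        autocorrelation=ac,
        whiteness_score=whiteness,
    )


def fit_moup(
    rec: MultichannelRecording,
    lag_steps: int = 1,
    center: bool = True,
) -> FitResult:
    """End-to-end single-subject fit: center, estimate W, extract residuals,
    compute both noise covariances and the stability spectrum."""
    if center:
        rec = center_signals(rec)
    conn = estimate_connectivity(rec, lag_steps)
    noise = extract_residuals(rec, conn, lag_steps)
    C0 = lagged_covariance(rec, 0).C
    noise.Q_empirical = empirical_noise_covariance(noise, lag_steps, rec.dt)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        noise.Q_theoretical = theoretical_noise_covariance(conn, C0)
    noise.agreement = noise_agreement(noise.Q_empirical, noise.Q_theoretical)
    stab = stability_spectrum(conn)
    if not stab.stable:
        warnings.warn(
            "fitted drift matrix is not linearly stable "
            f"(max real part {stab.max_real_part:.3g}/s)",
            RuntimeWarning,
            stacklevel=2,
        )
    return FitResult(
        connectivity=conn,
        noise=noise,
        C0=C0,
        stability=stab,
        lag_steps=lag_steps,
        dt=rec.dt,
    )
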