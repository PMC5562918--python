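"""Reference filters: exact Kalman-Bucy, weighted bootstrap particle filter,
and the constant-gain feedback / ensemble Kalman-Bucy variant.

The EnKBF shares the weight-free update code path and the empirical gain
operator with the core filter; the only behavioral difference is the
innovation term, which averages the per-particle prediction with the
ensemble prediction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.linalg import solve_continuous_are

from .models import SimulationRecord, StateSpaceModel
from .npf import FilterResult, run_filter

__all__ = [
    "KalmanState",
    "kalman_bucy_step",
    "riccati_steady_state",
    "run_kalman",
    "WeightedEnsemble",
    "effective_sample_size",
    "systematic_resample",
    "bootstrap_pf_step",
    "run_bootstrap_pf",
    "enkbf_step",
    "run_enkbf",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Kalman-Bucy
# ---------------------------------------------------------------------------

@dataclass
class KalmanState:
    mean: np.ndarray  # (n,)
    cov: np.ndarray   # (n, n)

    def __post_init__(self) -> None:
        self.mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        self.cov = np.atleast_2d(np.asarray(self.cov, dtype=float))
        if not np.allclose(self.cov, self.cov.T, atol=1e-8):
            raise ValueError("covariance must be symmetric")
        if np.min(np.linalg.eigvalsh(self.cov)) < -1e-8:
            raise ValueError("covariance must be positive semi-definite")


def kalman_bucy_step(
    state: KalmanState,
    dy: np.ndarray,
    A: np.ndarray,
    C: np.ndarray,
    model: StateSpaceModel,
    dt: float,
) -> KalmanState:
    """One Euler step of the Kalman-Bucy filter for f(x)=Ax, g(x)=Cx.

    K = P C^T Sigma_y^{-1}
    mean <- mean + A mean dt + K (dy - C mean dt)
    P    <- P + (A P + P A^T + Sigma_x - K Sigma_y K^T) dt
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    C = np.atleast_2d(np.asarray(C, dtype=float))
    P = state.cov
    K = P @ C.T @ model.sigma_y_inv
    dy = np.atleast_1d(np.asarray(dy, dtype=float))
    mean = state.mean + A @ state.mean * dt + K @ (dy - C @ state.mean * dt)
    P = P + (A @ P + P @ A.T + model.sigma_x - K @ model.sigma_y @ K.T) * dt
    P = 0.5 * (P + P.T)  # re-symmetrize against drift
    return KalmanState(mean=mean, cov=P)


def riccati_steady_state(
    A: np.ndarray, C: np.ndarray, sigma_x: np.ndarray, sigma_y: np.ndarray
) -> np.ndarray:
    """Stationary solution P of A P + P A^T - P C^T Sigma_y^{-1} C P + Sigma_x = 0."""
    A = np.atleast_2d(np.asarray(A, dtype=float))
    C = np.atleast_2d(np.asarray(C, dtype=float))
    sigma_x = np.atleast_2d(np.asarray(sigma_x, dtype=float))
    sigma_y = np.atleast_2d(np.asarray(sigma_y, dtype=float))
    return solve_continuous_are(A.T, C.T, sigma_x, sigma_y)


def run_kalman(
    model: StateSpaceModel,
    record: SimulationRecord,
    x0: Optional[np.ndarray] = None,
    P0: Optional[np.ndarray] = None,
) -> FilterResult:
    """Kalman-Bucy filter over a record; requires a linear model (A, C set)."""
    if model.A is None or model.C is None:
        raise ValueError("Kalman-Bucy filter requires a linear model with A, C")
    state = KalmanState(
        mean=np.zeros(model.n) if x0 is None else x0,
        cov=np.eye(model.n) if P0 is None else P0,
    )
    steps = record.steps
    means = np.empty((steps, model.n))
    keep = model.n * model.m <= 256
    W_trace = np.empty((steps, model.n, model.m)) if keep else None
    W_sum = np.zeros((model.n, model.m))
    for i in range(steps):
        K = state.cov @ model.C.T @ model.sigma_y_inv
        state = kalman_bucy_step(state, record.dy[i], model.A, model.C,
                                 model, record.dt)
        means[i] = state.mean
        W_sum += K
        if keep:
            W_trace[i] = K
    from .npf import ParticleEnsemble

    return FilterResult(
        times=record.times, mean=means, W=W_trace, W_time_avg=W_sum / steps,
        ensemble=ParticleEnsemble(state.mean[None, :]),
        snapshots={"final_cov": state.cov},
    )


# ---------------------------------------------------------------------------
# Weighted bootstrap particle filter
# ---------------------------------------------------------------------------

@dataclass
class WeightedEnsemble:
    """N weighted particles; weights nonnegative and summing to one."""

    z: np.ndarray  # (N, n)
    w: np.ndarray  # (N,)

    def __post_init__(self) -> None:
        self.z = np.atleast_2d(np.asarray(self.z, dtype=float))
        self.w = np.asarray(self.w, dtype=float)
        if self.w.shape != (self.z.shape[0],):
            raise ValueError("weights must be one per particle")
        if np.any(self.w < 0):
            raise ValueError("weights must be nonnegative")
        s = self.w.sum()
        if not np.isclose(s, 1.0):
            raise ValueError("weights must sum to 1")

    @property
    def N(self) -> int:
        return self.z.shape[0]

    @property
    def ess(self) -> float:
        return effective_sample_size(self.w)

    def mean(self) -> np.ndarray:
        return self.w @ self.z


def effective_sample_size(w: np.ndarray) -> float:
    """ESS = 1 / sum(w^2) for normalized weights."""
    return float(1.0 / np.sum(np.square(w)))


def systematic_resample(
    w: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Systematic resampling: indices drawn with one uniform offset."""
    N = len(w)
    positions = (rng.uniform() + np.arange(N)) / N
    return np.searchsorted(np.cumsum(w), positions)


def bootstrap_pf_step(
    ens: WeightedEnsemble,
    dy: np.ndarray,
    model: StateSpaceModel,
    dt: float,
    rng: np.random.Generator,
    resample_threshold: float = 0.5,
) -> tuple[WeightedEnsemble, bool]:
    """One bootstrap step: prior propagation, likelihood reweighting,
    systematic resampling when ESS < threshold * N.

    The observation-increment likelihood is the Euler-consistent Gaussian
    N(dy; g(z) dt, Sigma_y dt). Returns (ensemble, degenerated) where
    ``degenerated`` flags a total weight underflow (weights were reset).
    """
    z = ens.z
    noise = model.scale_process_noise(rng.standard_normal(z.shape)) * np.sqrt(dt)
    z = z + np.asarray(model.f(z)) * dt + noise

    dy = np.atleast_1d(np.asarray(dy, dtype=float))
    resid = dy[None, :] - np.asarray(model.g(z)) * dt
    # log N(dy; g(z)dt, Sigma_y dt), constants dropped (they cancel on
    # normalization)
    quad = np.einsum("ki,ij,kj->k", resid, model.sigma_y_inv, resid) / dt
    logw = np.log(ens.w, where=ens.w > 0,
                  out=np.full_like(ens.w, -np.inf)) - 0.5 * quad
    logw -= np.max(logw)
    w = np.exp(logw)
    s = w.sum()
    degenerated = not np.isfinite(s) or s <= 0
    if degenerated:
        logger.warning("bootstrap PF weights underflowed; resetting to uniform")
        w = np.full(ens.N, 1.0 / ens.N)
    else:
        w = w / s

    if effective_sample_size(w) < resample_threshold * ens.N:
        idx = systematic_resample(w, rng)
        z = z[idx]
        w = np.full(ens.N, 1.0 / ens.N)
    return WeightedEnsemble(z=z, w=w), degenerated


@dataclass
class BootstrapResult:
    times: np.ndarray
    mean: np.ndarray
    ess: np.ndarray
    degeneracy_events: int
    ensemble: WeightedEnsemble


def run_bootstrap_pf(
    model: StateSpaceModel,
    record: SimulationRecord,
    N: int,
    seed: Optional[int] = None,
    resample_threshold: float = 0.5,
    init: Optional[np.ndarray] = None,
) -> BootstrapResult:
    """Weighted bootstrap particle filter over a record.

    ``resample_threshold=0`` disables resampling (used to expose raw weight
    decay).
    """
    rng = np.random.default_rng(seed)
    z0 = model.draw_initial(N, rng) if init is None else np.asarray(init, float)
    ens = WeightedEnsemble(z=z0, w=np.full(N, 1.0 / N))
    steps = record.steps
    means = np.empty((steps, model.n))
    ess = np.empty(steps)
    events = 0
    for i in range(steps):
        ens, degenerated = bootstrap_pf_step(
            ens, record.dy[i], model, record.dt, rng, resample_threshold
        )
        events += int(degenerated)
        means[i] = ens.mean()
        ess[i] = ens.ess
    return BootstrapResult(times=record.times, mean=means, ess=ess,
                           degeneracy_events=events, ensemble=ens)


# ---------------------------------------------------------------------------
# EnKBF / constant-gain feedback variant
# ---------------------------------------------------------------------------

def enkbf_step(ensemble, dy, model, W, dt, rng):
    """Weight-free update with the averaged-prediction innovation
    dn^(k) = dy - 0.5 (g(z^(k)) + <g>) dt. Identical to the core step when
    all particles coincide."""
    from .npf import ParticleEnsemble, novelty, npf_step

    dn = novelty(ensemble, dy, model, dt)
    gz = np.asarray(model.g(ensemble.z))
    dn = dn + 0.5 * (gz - gz.mean(axis=0)) * dt
    return npf_step(ensemble, dy, model, W, dt, rng, dn=dn)


def run_enkbf(model, record, N, seed=None, **kwargs) -> FilterResult:
    """EnKBF run sharing the core loop; only the innovation differs."""
    return run_filter(model, record, N, seed=seed, innovation="enkbf",
                      **kwargs)
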