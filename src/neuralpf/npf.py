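"""Weight-free particle filter core.

An ensemble of N equally weighted particles z^(k) is propagated by

    z <- z + f(z) dt + W (dy - g(z) dt) + Sigma_x^{1/2} dω,

where the gain W couples the per-particle innovation (the "novelty") to the
state update. The empirical gain is the ensemble cross-covariance between
the state and the predicted observation, right-multiplied by Sigma_y^{-1}:

    W = cov_N(z, g(z)^T) Sigma_y^{-1},

with the population (1/N) normalization. Posterior functionals are plain
unweighted averages over the ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .models import DivergenceError, SimulationRecord, StateSpaceModel

__all__ = [
    "ParticleEnsemble",
    "empirical_gain",
    "novelty",
    "npf_step",
    "posterior_expectation",
    "region_certainty",
    "run_filter",
    "FilterResult",
]


@dataclass
class ParticleEnsemble:
    """N unweighted particles in R^n; the filter's posterior representation."""

    z: np.ndarray  # (N, n)

    def __post_init__(self) -> None:
        self.z = np.atleast_2d(np.asarray(self.z, dtype=float))
        if self.z.ndim != 2:
            raise ValueError("particle array must be 2-D (N, n)")
        if not np.all(np.isfinite(self.z)):
            raise ValueError("particle states must be finite")

    @property
    def N(self) -> int:
        return self.z.shape[0]

    @property
    def n(self) -> int:
        return self.z.shape[1]

    @classmethod
    def from_prior(
        cls, model: StateSpaceModel, N: int, rng: np.random.Generator
    ) -> "ParticleEnsemble":
        return cls(model.draw_initial(N, rng))


def empirical_gain(
    ensemble: ParticleEnsemble, model: StateSpaceModel
) -> np.ndarray:
    """Ensemble cross-covariance gain W = cov_N(z, g(z)^T) Sigma_y^{-1}.

    Population (1/N) normalization; for N = 1 the covariance is identically
    zero and so is the gain.
    """
    z = ensemble.z
    gz = np.asarray(model.g(z))
    zc = z - z.mean(axis=0)
    gc = gz - gz.mean(axis=0)
    cross = (zc.T @ gc) / ensemble.N  # (n, m)
    return cross @ model.sigma_y_inv


def novelty(
    ensemble: ParticleEnsemble,
    dy: np.ndarray,
    model: StateSpaceModel,
    dt: float,
) -> np.ndarray:
    """Per-particle innovation increments dn^(k) = dy - g(z^(k)) dt."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    dy = np.atleast_1d(np.asarray(dy, dtype=float))
    return dy[None, :] - np.asarray(model.g(ensemble.z)) * dt


def npf_step(
    ensemble: ParticleEnsemble,
    dy: np.ndarray,
    model: StateSpaceModel,
    W: np.ndarray,
    dt: float,
    rng: np.random.Generator,
    dn: Optional[np.ndarray] = None,
) -> ParticleEnsemble:
    """Advance every particle one Euler step with independent fresh noise.

    ``dn`` overrides the innovation batch (used by the EnKBF variant, which
    replaces the per-particle prediction by an averaged one).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    W = np.atleast_2d(np.asarray(W, dtype=float))
    if not np.all(np.isfinite(W)):
        raise DivergenceError("gain matrix became non-finite")
    if dn is None:
        dn = novelty(ensemble, dy, model, dt)
    z = ensemble.z
    noise = model.scale_process_noise(rng.standard_normal(z.shape)) * np.sqrt(dt)
    z_new = z + np.asarray(model.f(z)) * dt + dn @ W.T + noise
    bad = ~np.all(np.isfinite(z_new), axis=1)
    if np.any(bad):
        raise DivergenceError(
            f"particle {int(np.argmax(bad))} diverged during npf_step"
        )
    return ParticleEnsemble(z_new)


def posterior_expectation(
    ensemble: ParticleEnsemble,
    phi: Optional[Callable[[np.ndarray], np.ndarray]] = None,
) -> np.ndarray:
    """Unweighted ensemble average of phi; phi=None gives the posterior mean."""
    vals = ensemble.z if phi is None else np.asarray(phi(ensemble.z))
    if not np.all(np.isfinite(vals)):
        raise ValueError("phi returned non-finite values on the ensemble")
    return vals.mean(axis=0)


def region_certainty(ensemble: ParticleEnsemble, lo, hi) -> float:
    """Fraction of particles inside the axis-aligned box [lo, hi]."""
    lo = np.broadcast_to(np.atleast_1d(np.asarray(lo, float)), (ensemble.n,))
    hi = np.broadcast_to(np.atleast_1d(np.asarray(hi, float)), (ensemble.n,))
    if np.any(lo > hi):
        raise ValueError("interval must satisfy lo <= hi in every dimension")
    inside = np.all((ensemble.z >= lo) & (ensemble.z <= hi), axis=1)
    return float(inside.mean())


@dataclass
class FilterResult:
    """Per-step outputs of a filtering run."""

    times: np.ndarray
    mean: np.ndarray                    # (steps, n) posterior means
    W: Optional[np.ndarray]             # (steps, n, m) gain trace, if kept
    W_time_avg: np.ndarray              # (n, m)
    ensemble: ParticleEnsemble          # final ensemble
    snapshots: dict = field(default_factory=dict)  # step -> particle array
    var: Optional[np.ndarray] = None    # (steps, n) per-dim ensemble variance
    certainty: Optional[np.ndarray] = None  # (steps, n_boxes) box occupancies


def run_filter(
    model: StateSpaceModel,
    record: SimulationRecord,
    N: int,
    gain_mode: str = "empirical",
    seed: Optional[int] = None,
    W_fixed: Optional[np.ndarray] = None,
    innovation: str = "npf",
    init: Optional[np.ndarray] = None,
    keep_gain_trace: Optional[bool] = None,
    snapshot_every: int = 0,
    track_variance: bool = False,
    certainty_boxes: Optional[list] = None,
) -> FilterResult:
    """Run the filter over a simulated observation stream.

    Per step, in order: gain from the *pre-update* ensemble, novelty,
    particle update. ``mean[i]`` is the posterior mean after assimilating
    ``record.dy[i]``.

    Parameters
    ----------
    gain_mode
        ``"empirical"`` recomputes the ensemble gain each step; ``"fixed"``
        uses ``W_fixed`` throughout.
    innovation
        ``"npf"`` uses the per-particle prediction g(z^(k)); ``"enkbf"``
        averages it with the ensemble prediction, 0.5 (g(z^(k)) + <g>).
    """
    if record.dy.shape[1] != model.m:
        raise ValueError("record observation dimension does not match model")
    if record.x.shape[1] != model.n:
        raise ValueError("record hidden dimension does not match model")
    if innovation not in ("npf", "enkbf"):
        raise ValueError(f"unknown innovation kind {innovation!r}")
    if gain_mode == "fixed":
        if W_fixed is None:
            raise ValueError("gain_mode='fixed' requires W_fixed")
        W_fixed = np.atleast_2d(np.asarray(W_fixed, dtype=float))
        if W_fixed.shape != (model.n, model.m):
            raise ValueError("W_fixed must be shaped (n, m)")
    elif gain_mode != "empirical":
        raise ValueError(f"unknown gain_mode {gain_mode!r}")

    rng = np.random.default_rng(seed)
    if init is not None:
        ens = ParticleEnsemble(init)
        if ens.N != N:
            raise ValueError("init ensemble size does not match N")
    else:
        ens = ParticleEnsemble.from_prior(model, N, rng)

    steps = record.steps
    dt = record.dt
    means = np.empty((steps, model.n))
    variances = np.empty((steps, model.n)) if track_variance else None
    keep = (model.n * model.m <= 256) if keep_gain_trace is None else keep_gain_trace
    W_trace = np.empty((steps, model.n, model.m)) if keep else None
    W_sum = np.zeros((model.n, model.m))
    snapshots: dict = {}
    cert = (
        np.empty((steps, len(certainty_boxes)))
        if certainty_boxes else None
    )

    for i in range(steps):
        W = empirical_gain(ens, model) if gain_mode == "empirical" else W_fixed
        dn = novelty(ens, record.dy[i], model, dt)
        if innovation == "enkbf":
            gz = np.asarray(model.g(ens.z))
            dn = dn + 0.5 * (gz - gz.mean(axis=0)) * dt
        ens = npf_step(ens, record.dy[i], model, W, dt, rng, dn=dn)
        means[i] = ens.z.mean(axis=0)
        if track_variance:
            variances[i] = ens.z.var(axis=0)
        W_sum += W
        if keep:
            W_trace[i] = W
        if snapshot_every and i % snapshot_every == 0:
            snapshots[i] = ens.z.copy()
        if cert is not None:
            for b, (lo, hi) in enumerate(certainty_boxes):
                cert[i, b] = region_certainty(ens, lo, hi)

    return FilterResult(
        times=record.times,
        mean=means,
        W=W_trace,
        W_time_avg=W_sum / steps,
        ensemble=ens,
        snapshots=snapshots,
        var=variances,
        certainty=cert,
    )
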