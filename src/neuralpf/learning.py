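"""Online maximum-likelihood learning of the generative weight J and the
gain W, with the Hebbian small-noise approximation.

Scope: linear observation models g(x) = J x (J is m x n) on top of an
arbitrary hidden drift. Both the generative weight J and the decoding gain
W are learned by stochastic gradient ascent on the observation
log-likelihood

    L_t = ∫ <g>^T Sigma_y^{-1} dy - 0.5 <g>^T Sigma_y^{-1} <g> dt,

whose gradient requires the derivative of the particle states with respect
to the parameters (the filter derivative). We track it by forward
sensitivity propagation: differentiating the particle update with the noise
path held fixed gives, per particle,

    S' = S + (df/dx) S dt + (dW/dθ) dn + W d(dn)/dθ,
    d(dn)/dθ = -[dg/dθ + (dg/dx) S] dt,

with S = dz/dθ initialized at zero. The scheme is validated against
common-random-number finite differences in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .models import SimulationRecord, StateSpaceModel
from .npf import ParticleEnsemble

__all__ = [
    "LearnerState",
    "LikelihoodAccumulator",
    "loglik_increment",
    "hebbian_update",
    "ml_param_update",
    "gain_update",
    "advance_sensitivities",
    "run_learning",
    "LearningResult",
]


@dataclass
class LearnerState:
    """Learnable parameters plus per-particle sensitivity states.

    ``S_J[k, p, a, b]`` is d z^(k)_p / d J_ab; ``S_W[k, p, i, j]`` is
    d z^(k)_p / d W_ij. Both start at zero.
    """

    J: np.ndarray           # (m, n)
    W: np.ndarray           # (n, m)
    eta_J: float = 0.0
    eta_W: float = 0.0
    S_J: Optional[np.ndarray] = None  # (N, n, m, n)
    S_W: Optional[np.ndarray] = None  # (N, n, n, m)

    def __post_init__(self) -> None:
        self.J = np.atleast_2d(np.asarray(self.J, dtype=float))
        self.W = np.atleast_2d(np.asarray(self.W, dtype=float))
        if self.eta_J < 0 or self.eta_W < 0:
            raise ValueError("learning rates must be nonnegative")

    def init_sensitivities(self, N: int) -> None:
        m, n = self.J.shape
        self.S_J = np.zeros((N, n, m, n))
        self.S_W = np.zeros((N, n, n, m))


@dataclass
class LikelihoodAccumulator:
    """Running log-likelihood; the sum of its per-step increments."""

    L: float = 0.0
    increments: list = field(default_factory=list)

    def add(self, inc: float) -> None:
        self.increments.append(inc)
        self.L += inc


def loglik_increment(
    g_hat: np.ndarray, dy: np.ndarray, model: StateSpaceModel, dt: float
) -> float:
    """<g>^T Sigma_y^{-1} dy - 0.5 <g>^T Sigma_y^{-1} <g> dt."""
    g_hat = np.atleast_1d(np.asarray(g_hat, dtype=float))
    dy = np.atleast_1d(np.asarray(dy, dtype=float))
    v = model.sigma_y_inv @ g_hat
    return float(v @ dy - 0.5 * (v @ g_hat) * dt)


def hebbian_update(
    J: np.ndarray, dy: np.ndarray, x_hat: np.ndarray, dt: float, eta: float
) -> np.ndarray:
    """Local rule J <- J + eta (dy - J x_hat dt) x_hat^T.

    Small-observation-noise approximation of the ML rule for g(x) = J x:
    pre/post-synaptic product of the posterior mean and the mean novelty.
    """
    J = np.atleast_2d(np.asarray(J, dtype=float))
    dy = np.atleast_1d(np.asarray(dy, dtype=float))
    x_hat = np.atleast_1d(np.asarray(x_hat, dtype=float))
    resid = dy - (J @ x_hat) * dt
    return J + eta * np.outer(resid, x_hat)


def _g_mean_and_grads(state: LearnerState, z: np.ndarray):
    """<g>, d<g>/dJ and d<g>/dW from the ensemble and its sensitivities.

    d<g>/dJ_ab has the explicit term delta_{ia} <z_b> plus the implicit
    term through the particles, J (1/N) sum_k S_J; d<g>/dW is purely
    implicit (W enters <g> only through the states).
    """
    J = state.J
    m, n = J.shape
    g_bar = J @ z.mean(axis=0)
    # implicit parts: (m, m, n) and (m, n, m)
    grad_J = np.einsum("iq,kqab->iab", J, state.S_J) / len(z)
    idx = np.arange(m)
    grad_J[idx, idx, :] += z.mean(axis=0)[None, :]
    grad_W = np.einsum("iq,kqab->iab", J, state.S_W) / len(z)
    return g_bar, grad_J, grad_W


def _residual(state: LearnerState, z, dy, model, dt):
    g_bar = state.J @ z.mean(axis=0)
    return model.sigma_y_inv @ (np.atleast_1d(dy) - g_bar * dt)


def compute_dJ_ml(
    state: LearnerState, ensemble: ParticleEnsemble, dy, model, dt
) -> np.ndarray:
    """ML increment for J: eta_J (d<g>/dJ)^T Sigma_y^{-1} (dy - <g> dt)."""
    _, grad_J, _ = _g_mean_and_grads(state, ensemble.z)
    r = _residual(state, ensemble.z, dy, model, dt)
    dJ = state.eta_J * np.einsum("iab,i->ab", grad_J, r)
    if not np.all(np.isfinite(dJ)):
        raise FloatingPointError("non-finite gradient in J update")
    return dJ


def compute_dW_ml(
    state: LearnerState, ensemble: ParticleEnsemble, dy, model, dt
) -> np.ndarray:
    """ML increment for W: eta_W (d<g>/dW_ij)^T Sigma_y^{-1} (dy - <g> dt)."""
    _, _, grad_W = _g_mean_and_grads(state, ensemble.z)
    r = _residual(state, ensemble.z, dy, model, dt)
    dW = state.eta_W * np.einsum("iab,i->ab", grad_W, r)
    if not np.all(np.isfinite(dW)):
        raise FloatingPointError("non-finite gradient in W update")
    return dW


def advance_sensitivities(
    state: LearnerState,
    ensemble: ParticleEnsemble,
    dy,
    model: StateSpaceModel,
    dt: float,
) -> None:
    """Tangent recursion for S_J and S_W, in place, using pre-update z, J, W.

    Must be called with the same pre-step ensemble that the filter step
    consumed (the recursion differentiates that step with the noise held
    fixed).
    """
    z = ensemble.z
    N, n = z.shape
    J, W = state.J, state.W
    m = J.shape[0]
    F = np.asarray(model.f_jacobian(z))            # (N, n, n)
    dn = np.atleast_1d(np.asarray(dy, float))[None, :] - (z @ J.T) * dt

    # S_J' = S_J + F S_J dt - W [dg/dJ + J S_J] dt
    JS = np.einsum("iq,kqab->kiab", J, state.S_J)  # (N, m, m, n)
    dgdJ = np.zeros((N, m, m, n))
    idx = np.arange(m)
    dgdJ[:, idx, idx, :] = z[:, None, :]
    state.S_J = (
        state.S_J
        + np.einsum("kpq,kqab->kpab", F, state.S_J) * dt
        - np.einsum("pi,kiab->kpab", W, dgdJ + JS) * dt
    )

    # S_W' = S_W + F S_W dt + E_ij dn - W J S_W dt
    JSW = np.einsum("iq,kqab->kiab", J, state.S_W)  # (N, m, n, m)
    E_dn = np.zeros((N, n, n, m))
    idxn = np.arange(n)
    E_dn[:, idxn, idxn, :] = dn[:, None, :]
    state.S_W = (
        state.S_W
        + np.einsum("kpq,kqab->kpab", F, state.S_W) * dt
        + E_dn
        - np.einsum("pi,kiab->kpab", W, JSW) * dt
    )
    if not (np.all(np.isfinite(state.S_J)) and np.all(np.isfinite(state.S_W))):
        raise FloatingPointError("sensitivity states diverged")


def ml_param_update(
    state: LearnerState, ensemble: ParticleEnsemble, dy, model, dt
) -> LearnerState:
    """One online ML step for J (gradient with current sensitivities, then
    sensitivity advance). ``eta_J = 0`` is an exact no-op on J."""
    dJ = compute_dJ_ml(state, ensemble, dy, model, dt)
    new = replace(state, S_J=state.S_J, S_W=state.S_W)
    advance_sensitivities(new, ensemble, dy, model, dt)
    new.J = state.J + dJ
    return new


def gain_update(
    state: LearnerState, ensemble: ParticleEnsemble, dy, model, dt
) -> LearnerState:
    """One online ML step for the gain W (Eq.-(12)-style)."""
    dW = compute_dW_ml(state, ensemble, dy, model, dt)
    new = replace(state, S_J=state.S_J, S_W=state.S_W)
    advance_sensitivities(new, ensemble, dy, model, dt)
    new.W = state.W + dW
    return new


@dataclass
class LearningResult:
    times: np.ndarray
    J: np.ndarray            # (steps, m, n) parameter trajectory
    W: np.ndarray            # (steps, n, m)
    loglik: np.ndarray       # (steps,) running log-likelihood
    mean: np.ndarray         # (steps, n) posterior mean trajectory
    state: LearnerState
    g_bar: Optional[np.ndarray] = None       # (steps, m)
    grad_J: Optional[np.ndarray] = None      # (steps, m, m, n)
    grad_W: Optional[np.ndarray] = None      # (steps, m, n, m)


def run_learning(
    model: StateSpaceModel,
    record: SimulationRecord,
    N: int,
    which: str = "both",
    rule: str = "ml",
    eta_J: float = 1e-3,
    eta_W: float = 1e-3,
    J0: Optional[np.ndarray] = None,
    W0: Optional[np.ndarray] = None,
    seed: Optional[int] = None,
    track_grads: bool = False,
) -> LearningResult:
    """Interleave filtering and online parameter updates, one per dt step.

    ``model`` supplies the (known) hidden drift and noise levels; the
    observation map used by the filter is g(x) = J_hat x with the *current*
    estimate J_hat. ``which`` selects what is learned ({"J", "W", "both"});
    frozen parameters keep their initial values exactly. ``rule`` applies
    to J ("ml" or "hebb"); W is always learned by ML when selected.

    Per step: log-likelihood increment and parameter gradients from the
    pre-update ensemble -> filter step with the current (J, W) -> sensitivity
    advance -> parameter increments applied.
    """
    if which not in ("J", "W", "both"):
        raise ValueError(f"unknown 'which' {which!r}")
    if rule not in ("ml", "hebb"):
        raise ValueError(f"unknown rule {rule!r}")
    m, n = model.m, model.n
    J = np.eye(m, n) if J0 is None else np.atleast_2d(np.asarray(J0, float)).copy()
    W = np.zeros((n, m)) if W0 is None else np.atleast_2d(np.asarray(W0, float)).copy()
    learn_J = which in ("J", "both")
    learn_W = which in ("W", "both")
    state = LearnerState(
        J=J, W=W,
        eta_J=eta_J if learn_J else 0.0,
        eta_W=eta_W if learn_W else 0.0,
    )
    state.init_sensitivities(N)

    rng = np.random.default_rng(seed)
    z = model.draw_initial(N, rng)
    steps = record.steps
    dt = record.dt
    sdt = np.sqrt(dt)

    J_traj = np.empty((steps, m, n))
    W_traj = np.empty((steps, n, m))
    L_traj = np.empty(steps)
    mean_traj = np.empty((steps, n))
    g_traj = np.empty((steps, m)) if track_grads else None
    gJ_traj = np.empty((steps, m, m, n)) if track_grads else None
    gW_traj = np.empty((steps, m, n, m)) if track_grads else None
    acc = LikelihoodAccumulator()

    for i in range(steps):
        dy = record.dy[i]
        ens = ParticleEnsemble(z)
        g_bar, grad_J, grad_W = _g_mean_and_grads(state, z)
        acc.add(loglik_increment(g_bar, dy, model, dt))
        r = model.sigma_y_inv @ (dy - g_bar * dt)

        dJ = np.zeros_like(state.J)
        if learn_J and state.eta_J > 0:
            if rule == "ml":
                dJ = state.eta_J * np.einsum("iab,i->ab", grad_J, r)
            else:  # hebb: local, no Sigma_y^{-1}, explicit term only
                x_hat = z.mean(axis=0)
                dJ = state.eta_J * np.outer(dy - state.J @ x_hat * dt, x_hat)
        dW = np.zeros_like(state.W)
        if learn_W and state.eta_W > 0:
            dW = state.eta_W * np.einsum("iab,i->ab", grad_W, r)
        if not (np.all(np.isfinite(dJ)) and np.all(np.isfinite(dW))):
            raise FloatingPointError(f"non-finite gradient at step {i}")

        # filter step with current parameters (same draw order as run_filter)
        dn = dy[None, :] - (z @ state.J.T) * dt
        noise = model.scale_process_noise(rng.standard_normal(z.shape)) * sdt
        z = z + np.asarray(model.f(z)) * dt + dn @ state.W.T + noise
        if not np.all(np.isfinite(z)):
            raise FloatingPointError(f"particle states diverged at step {i}")

        advance_sensitivities(state, ens, dy, model, dt)
        state.J = state.J + dJ
        state.W = state.W + dW

        J_traj[i] = state.J
        W_traj[i] = state.W
        L_traj[i] = acc.L
        mean_traj[i] = z.mean(axis=0)
        if track_grads:
            g_traj[i] = g_bar
            gJ_traj[i] = grad_J
            gW_traj[i] = grad_W

    return LearningResult(
        times=record.times, J=J_traj, W=W_traj, loglik=L_traj,
        mean=mean_traj, state=state, g_bar=g_traj, grad_J=gJ_traj,
        grad_W=gW_traj,
    )
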