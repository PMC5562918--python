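"""State-space SDE models, Euler-Maruyama simulation, and analytic helpers.

A model is the pair of Ito diffusions

    dx_t = f(x_t) dt + Sigma_x^{1/2} dw_t          (hidden, dimension n)
    dy_t = g(x_t) dt + Sigma_y^{1/2} du_t          (observed, dimension m)

Observations are stored as increments ``dy`` rather than the cumulative
process: every downstream consumer (filters, learners, likelihoods) only
ever needs the increment, and increments avoid catastrophic cancellation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid, trapezoid

__all__ = [
    "DivergenceError",
    "StateSpaceModel",
    "SimulationRecord",
    "GridDensity",
    "simulate",
    "stationary_density",
    "model_zoo",
    "write_record",
    "read_record",
]


class DivergenceError(RuntimeError):
    """Raised when a trajectory or filter state becomes non-finite."""


def _is_diagonal(mat: np.ndarray) -> bool:
    return np.count_nonzero(mat - np.diag(np.diagonal(mat))) == 0


def _psd_sqrt(mat: np.ndarray) -> np.ndarray:
    """Symmetric square root of a PSD matrix (tolerates singular matrices)."""
    if _is_diagonal(mat):
        diag = np.diagonal(mat)
        if np.min(diag) < 0:
            raise ValueError("matrix is not positive semi-definite")
        return np.diag(np.sqrt(diag))
    vals, vecs = np.linalg.eigh(mat)
    if np.min(vals) < -1e-10 * max(1.0, np.max(np.abs(vals))):
        raise ValueError("matrix is not positive semi-definite")
    vals = np.clip(vals, 0.0, None)
    return (vecs * np.sqrt(vals)) @ vecs.T


@dataclass
class StateSpaceModel:
    """Generative pair (f, Sigma_x, g, Sigma_y) with dimensions n and m.

    Parameters
    ----------
    n, m
        Hidden and observed dimensions.
    f, g
        Drift and observation maps, vectorized over leading axes:
        ``f`` maps arrays of shape ``(..., n)`` to ``(..., n)``; ``g`` maps
        ``(..., n)`` to ``(..., m)``.
    sigma_x, sigma_y
        Process and observation noise covariances. ``sigma_y`` must be
        strictly positive definite (its inverse enters the gain and the
        log-likelihood); ``sigma_x`` may be singular.
    f_jac, g_jac
        Optional analytic Jacobians, shaped ``(..., n, n)`` and
        ``(..., m, n)``. Required by the sensitivity-based learners; a
        finite-difference fallback is provided for user models.
    A, C
        For linear models only: matrices with ``f(x) = A x``, ``g(x) = C x``.
        Enable the exact Kalman-Bucy reference filter.
    stationary_sample
        Optional sampler ``(size, rng) -> (size, n)`` from the stationary
        prior; used to initialize simulations and particle ensembles.
    """

    n: int
    m: int
    f: Callable[[np.ndarray], np.ndarray]
    sigma_x: np.ndarray
    g: Callable[[np.ndarray], np.ndarray]
    sigma_y: np.ndarray
    f_jac: Optional[Callable[[np.ndarray], np.ndarray]] = None
    g_jac: Optional[Callable[[np.ndarray], np.ndarray]] = None
    A: Optional[np.ndarray] = None
    C: Optional[np.ndarray] = None
    stationary_sample: Optional[Callable[[int, np.random.Generator], np.ndarray]] = None
    name: str = ""

    # caches filled in __post_init__
    sigma_y_inv: np.ndarray = field(init=False, repr=False)
    sqrt_sigma_x: np.ndarray = field(init=False, repr=False)
    sqrt_sigma_y: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.n < 1 or self.m < 1:
            raise ValueError("dimensions n and m must be positive integers")
        self.sigma_x = np.atleast_2d(np.asarray(self.sigma_x, dtype=float))
        self.sigma_y = np.atleast_2d(np.asarray(self.sigma_y, dtype=float))
        if self.sigma_x.shape != (self.n, self.n):
            raise ValueError(f"sigma_x must be {self.n}x{self.n}")
        if self.sigma_y.shape != (self.m, self.m):
            raise ValueError(f"sigma_y must be {self.m}x{self.m}")
        for name, mat in (("sigma_x", self.sigma_x), ("sigma_y", self.sigma_y)):
            if not np.allclose(mat, mat.T):
                raise ValueError(f"{name} must be symmetric")
        self.sqrt_sigma_x = _psd_sqrt(self.sigma_x)
        try:
            chol = np.linalg.cholesky(self.sigma_y)
        except np.linalg.LinAlgError as exc:
            raise ValueError("sigma_y must be strictly positive definite") from exc
        self.sqrt_sigma_y = chol
        self.sigma_y_inv = np.linalg.inv(self.sigma_y)
        # diagonal fast paths: dense (n, n) matmuls per step are wasteful
        # (and prohibitive at large d) when the noise is axis-aligned
        self._sx_diag = (np.diagonal(self.sqrt_sigma_x).copy()
                         if _is_diagonal(self.sqrt_sigma_x) else None)
        self._sy_diag = (np.diagonal(self.sqrt_sigma_y).copy()
                         if _is_diagonal(self.sqrt_sigma_y) else None)

    def scale_process_noise(self, xi: np.ndarray) -> np.ndarray:
        """Sigma_x^{1/2} applied to rows of standard-normal draws."""
        if self._sx_diag is not None:
            return xi * self._sx_diag
        return xi @ self.sqrt_sigma_x.T

    def scale_obs_noise(self, zeta: np.ndarray) -> np.ndarray:
        """Sigma_y^{1/2} applied to rows of standard-normal draws."""
        if self._sy_diag is not None:
            return zeta * self._sy_diag
        return zeta @ self.sqrt_sigma_y.T

    def f_jacobian(self, x: np.ndarray) -> np.ndarray:
        """df/dx at ``x``; analytic if supplied, else central differences."""
        if self.f_jac is not None:
            return self.f_jac(x)
        return _numeric_jacobian(self.f, x, self.n)

    def g_jacobian(self, x: np.ndarray) -> np.ndarray:
        """dg/dx at ``x``; analytic if supplied, else central differences."""
        if self.g_jac is not None:
            return self.g_jac(x)
        return _numeric_jacobian(self.g, x, self.m)

    def draw_initial(self, size: int, rng: np.random.Generator) -> np.ndarray:
        """Initial states: stationary prior if known, otherwise N(0, I)."""
        if self.stationary_sample is not None:
            return np.asarray(self.stationary_sample(size, rng), dtype=float)
        return rng.standard_normal((size, self.n))


def _numeric_jacobian(func, x, out_dim, eps=1e-6):
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    jac = np.empty(x.shape[:-1] + (out_dim, n))
    for j in range(n):
        dx = np.zeros(n)
        dx[j] = eps
        jac[..., :, j] = (func(x + dx) - func(x - dx)) / (2 * eps)
    return jac


@dataclass
class SimulationRecord:
    """Time grid, hidden trajectory and observation increments.

    ``x[i]`` is the state at ``times[i]``; ``dy[i]`` is the observation
    increment accumulated over ``[times[i], times[i] + dt)`` and generated
    from ``x[i]``.
    """

    dt: float
    times: np.ndarray
    x: np.ndarray
    dy: np.ndarray
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not (len(self.times) == len(self.x) == len(self.dy)):
            raise ValueError("times, x and dy must have equal length")

    @property
    def steps(self) -> int:
        return len(self.times)


def simulate(
    model: StateSpaceModel,
    T: float,
    dt: float,
    x0: Optional[np.ndarray] = None,
    seed: Optional[int] = None,
) -> SimulationRecord:
    """Euler-Maruyama simulation of hidden state and observation increments.

    x_{t+dt} = x_t + f(x_t) dt + Sigma_x^{1/2} sqrt(dt) xi,
    dy_t     = g(x_t) dt + Sigma_y^{1/2} sqrt(dt) zeta,

    with xi, zeta i.i.d. standard normal. Bit-reproducible for a fixed seed.
    ``x0=None`` draws from the model's stationary prior (falling back to 0).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if T < dt:
        raise ValueError("T must be at least dt")
    steps = int(round(T / dt))
    rng = np.random.default_rng(seed)
    if x0 is None:
        if model.stationary_sample is not None:
            x0 = model.draw_initial(1, rng)[0]
        else:
            x0 = np.zeros(model.n)
    x0 = np.atleast_1d(np.asarray(x0, dtype=float))
    if x0.shape != (model.n,) or not np.all(np.isfinite(x0)):
        raise ValueError(f"x0 must be a finite vector of dimension {model.n}")

    xi = rng.standard_normal((steps, model.n))
    zeta = rng.standard_normal((steps, model.m))
    sdt = np.sqrt(dt)
    noise_x = model.scale_process_noise(xi) * sdt

    x = np.empty((steps, model.n))
    cur = x0
    for i in range(steps):
        x[i] = cur
        drift = model.f(cur)
        if not np.all(np.isfinite(drift)):
            raise DivergenceError(f"drift became non-finite at step {i}")
        cur = cur + drift * dt + noise_x[i]
        if not np.all(np.isfinite(cur)):
            raise DivergenceError(f"hidden state diverged at step {i}")

    gx = model.g(x)
    if not np.all(np.isfinite(gx)):
        bad = int(np.argwhere(~np.all(np.isfinite(gx), axis=-1))[0, 0])
        raise DivergenceError(f"observation map non-finite at step {bad}")
    dy = gx * dt + model.scale_obs_noise(zeta) * sdt

    times = np.arange(steps) * dt
    return SimulationRecord(dt=dt, times=times, x=x, dy=dy, seed=seed)


@dataclass
class GridDensity:
    """Normalized density tabulated on a 1-D grid, with sampling and CDF."""

    grid: np.ndarray
    pdf: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.pdf = np.asarray(self.pdf, dtype=float)
        cdf = cumulative_trapezoid(self.pdf, self.grid, initial=0.0)
        self._cdf = cdf / cdf[-1]

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return np.interp(x, self.grid, self.pdf, left=0.0, right=0.0)

    def cdf(self, x: np.ndarray) -> np.ndarray:
        return np.interp(x, self.grid, self._cdf, left=0.0, right=1.0)

    def sample(self, size: int, rng: np.random.Generator) -> np.ndarray:
        """Inverse-CDF sampling."""
        u = rng.uniform(size=size)
        return np.interp(u, self._cdf, self.grid)


def stationary_density(
    model: StateSpaceModel,
    grid: Optional[np.ndarray] = None,
) -> GridDensity:
    """Stationary density of a scalar diffusion: p(x) ∝ exp((2/Σx)∫f).

    Requires ``n == 1`` and scalar ``sigma_x > 0``. Raises if the density
    does not decay at the grid boundaries (non-integrable tails or a grid
    that is too narrow).
    """
    if model.n != 1:
        raise ValueError("stationary_density requires a scalar hidden state")
    s2 = float(model.sigma_x[0, 0])
    if s2 <= 0:
        raise ValueError("stationary_density requires sigma_x > 0")
    if grid is None:
        grid = np.linspace(-5.0, 5.0, 4001)
    grid = np.asarray(grid, dtype=float)
    fvals = np.asarray(model.f(grid[:, None]))[:, 0]
    log_p = (2.0 / s2) * cumulative_trapezoid(fvals, grid, initial=0.0)
    log_p -= np.max(log_p)
    p = np.exp(log_p)
    if p[0] > 1e-6 or p[-1] > 1e-6:
        raise ValueError(
            "stationary density does not vanish at the grid boundaries; "
            "non-integrable tails or grid too narrow"
        )
    z = trapezoid(p, grid)
    if not np.isfinite(z) or z <= 0:
        raise ValueError("stationary density is not normalizable")
    return GridDensity(grid=grid, pdf=p / z)


# ---------------------------------------------------------------------------
# Model zoo
# ---------------------------------------------------------------------------

def _double_well_f(x):
    return 3.0 * x * (1.0 - x**2)


def _double_well_fjac(x):
    x = np.asarray(x, dtype=float)
    d = 3.0 - 9.0 * x**2
    n = x.shape[-1]
    jac = np.zeros(x.shape[:-1] + (n, n))
    idx = np.arange(n)
    jac[..., idx, idx] = d
    return jac


def _diag_jac_from_elementwise(deriv):
    """Lift an elementwise derivative map to a diagonal Jacobian."""

    def jac(x):
        x = np.asarray(x, dtype=float)
        d = deriv(x)
        n = x.shape[-1]
        out = np.zeros(x.shape[:-1] + (n, n))
        idx = np.arange(n)
        out[..., idx, idx] = d
        return out

    return jac


def model_zoo(name: str, **params) -> StateSpaceModel:
    """Built-in models.

    ``frog``
        1-D double-well hidden dynamics dx = 3x(1-x^2)dt + dw with a linear
        visual channel dv = J x dt + sigma_v dbeta and a sigmoid auditory
        channel da = tanh(2x)dt + sigma_a dgamma.
        Params: ``sigma_v2`` (default 0.1), ``sigma_a2`` (0.1), ``J`` (1.0).
    ``frog_visual``
        Same hidden dynamics, visual channel only (m=1, g = J x).
        Params: ``sigma_v2`` (0.1), ``J`` (1.0).
    ``linear_d``
        d independent OU dimensions dx_i = a x_i dt + dw_i with identity
        observation and unit noises; a = -0.75 so the per-dimension optimal
        (Kalman) steady-state MSE is exactly 0.5.
        Params: ``d``, ``a`` (-0.75), ``sigma_x2`` (1.0), ``sigma_y2`` (1.0).
    ``bimodal_d``
        d independent double-well copies with identity observation.
        Params: ``d``, ``sigma_x2`` (1.0), ``sigma_y2`` (1.0).
    """
    if name == "frog" or name == "frog_visual":
        sigma_v2 = float(params.pop("sigma_v2", 0.1))
        J = float(params.pop("J", 1.0))
        visual_only = name == "frog_visual"
        sigma_a2 = None if visual_only else float(params.pop("sigma_a2", 0.1))
        _reject_unknown(params, name)
        if sigma_v2 <= 0 or (sigma_a2 is not None and sigma_a2 <= 0):
            raise ValueError("noise variances must be positive")

        if visual_only:
            m, sigma_y = 1, np.array([[sigma_v2]])

            def g(x, J=J):
                return J * np.asarray(x, dtype=float)

            def g_jac(x, J=J):
                x = np.asarray(x, dtype=float)
                return np.broadcast_to(
                    np.array([[J]]), x.shape[:-1] + (1, 1)
                ).copy()

        else:
            m, sigma_y = 2, np.diag([sigma_v2, sigma_a2])

            def g(x, J=J):
                x = np.asarray(x, dtype=float)
                return np.concatenate([J * x, np.tanh(2.0 * x)], axis=-1)

            def g_jac(x, J=J):
                x = np.asarray(x, dtype=float)
                out = np.empty(x.shape[:-1] + (2, 1))
                out[..., 0, 0] = J
                out[..., 1, 0] = 2.0 / np.cosh(2.0 * x[..., 0]) ** 2
                return out

        model = StateSpaceModel(
            n=1, m=m, f=_double_well_f, sigma_x=np.array([[1.0]]),
            g=g, sigma_y=sigma_y, f_jac=_double_well_fjac, g_jac=g_jac,
            name=name,
        )
        dens = stationary_density(model, np.linspace(-4.0, 4.0, 4001))
        model.stationary_sample = lambda size, rng: dens.sample(size, rng)[:, None]
        return model

    if name == "linear_d":
        d = int(params.pop("d"))
        a = float(params.pop("a", -0.75))
        sigma_x2 = float(params.pop("sigma_x2", 1.0))
        sigma_y2 = float(params.pop("sigma_y2", 1.0))
        _reject_unknown(params, name)
        if d < 1:
            raise ValueError("d must be positive")
        if sigma_x2 <= 0 or sigma_y2 <= 0:
            raise ValueError("noise variances must be positive")
        if a >= 0:
            raise ValueError("linear_d requires a stable drift (a < 0)")
        A = a * np.eye(d)
        C = np.eye(d)
        stat_sd = np.sqrt(sigma_x2 / (2.0 * abs(a)))  # OU stationary std
        model = StateSpaceModel(
            n=d, m=d,
            f=lambda x, a=a: a * np.asarray(x, dtype=float),
            sigma_x=sigma_x2 * np.eye(d),
            g=lambda x: np.asarray(x, dtype=float),
            sigma_y=sigma_y2 * np.eye(d),
            f_jac=_diag_jac_from_elementwise(
                lambda x, a=a: np.full_like(x, a)
            ),
            g_jac=_diag_jac_from_elementwise(lambda x: np.ones_like(x)),
            A=A, C=C,
            stationary_sample=lambda size, rng, d=d, s=stat_sd: (
                s * rng.standard_normal((size, d))
            ),
            name=name,
        )
        return model

    if name == "bimodal_d":
        d = int(params.pop("d"))
        sigma_x2 = float(params.pop("sigma_x2", 1.0))
        sigma_y2 = float(params.pop("sigma_y2", 1.0))
        _reject_unknown(params, name)
        if d < 1:
            raise ValueError("d must be positive")
        if sigma_x2 <= 0 or sigma_y2 <= 0:
            raise ValueError("noise variances must be positive")
        model = StateSpaceModel(
            n=d, m=d, f=_double_well_f, sigma_x=sigma_x2 * np.eye(d),
            g=lambda x: np.asarray(x, dtype=float),
            sigma_y=sigma_y2 * np.eye(d),
            f_jac=_double_well_fjac,
            g_jac=_diag_jac_from_elementwise(lambda x: np.ones_like(x)),
            name=name,
        )
        dens = stationary_density(
            StateSpaceModel(
                n=1, m=1, f=_double_well_f,
                sigma_x=np.array([[sigma_x2]]),
                g=lambda x: np.asarray(x, dtype=float),
                sigma_y=np.array([[1.0]]),
            ),
            np.linspace(-4.0, 4.0, 4001),
        )
        model.stationary_sample = lambda size, rng, d=d: np.column_stack(
            [dens.sample(size, rng) for _ in range(d)]
        )
        return model

    raise ValueError(f"unknown model name: {name!r}")


def _reject_unknown(params: dict, name: str) -> None:
    if params:
        raise ValueError(f"unknown parameters for {name!r}: {sorted(params)}")


# ---------------------------------------------------------------------------
# Serialization (CSV table + JSON metadata sidecar)
# ---------------------------------------------------------------------------

def write_record(record: SimulationRecord, csv_path, meta_path=None) -> None:
    n = record.x.shape[1]
    m = record.dy.shape[1]
    cols = {"t": record.times}
    for i in range(n):
        cols[f"x_{i + 1}"] = record.x[:, i]
    for j in range(m):
        cols[f"dy_{j + 1}"] = record.dy[:, j]
    pd.DataFrame(cols).to_csv(csv_path, index=False)
    if meta_path is not None:
        meta = {"dt": record.dt, "steps": record.steps, "n": n, "m": m,
                "seed": record.seed}
        with open(meta_path, "w") as fh:
            json.dump(meta, fh, indent=2)


def read_record(csv_path, seed: Optional[int] = None) -> SimulationRecord:
    df = pd.read_csv(csv_path)
    xcols = sorted([c for c in df.columns if c.startswith("x_")],
                   key=lambda c: int(c[2:]))
    ycols = sorted([c for c in df.columns if c.startswith("dy_")],
                   key=lambda c: int(c[3:]))
    times = df["t"].to_numpy()
    dt = float(times[1] - times[0]) if len(times) > 1 else float(times[0])
    return SimulationRecord(
        dt=dt, times=times, x=df[xcols].to_numpy(), dy=df[ycols].to_numpy(),
        seed=seed,
    )
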