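"""Gradient-ascent simulation on the emotional payoff surface.

The fitted response surface is reinterpreted as a payoff function of the
three predictors (theta change, gamma change, affective shift), which are
treated as strategic inputs adjusted iteratively:

    x_{t+1} = clip( x_t + eta * grad_payoff(x_t) )

in standardized coordinates, until the payoff change falls below a
tolerance.  The resulting fixed point is a *constrained* stationary point
("local equilibrium"): with the reference coefficients the quadratic terms
(gamma^2, shift^2) are positive, so the unconstrained ascent diverges and a
bounded box (default +/-3 standardized units per coordinate) with projection
is mandatory -- trajectories typically terminate on the box boundary.

Standardized coordinates (per-predictor center/scale, taken from a cohort or
a generative configuration) let a single learning-rate scale work even
though the raw predictor scales span 1e-12 to 1e1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
import pandas as pd

from .exceptions import ConfigError, InputError
from .synthetic import GenerativeConfig, default_generative_config

__all__ = [
    "PayoffModel",
    "AscentConfig",
    "Trajectory",
    "payoff",
    "payoff_gradient",
    "ascend",
    "payoff_surface",
    "reference_payoff_model",
    "plot_surface",
    "plot_trajectory",
]

_MODES = ("net", "positive", "negative_reduction")


@dataclass
class PayoffModel:
    """Payoff surface built from the two outcome coefficient vectors.

    ``centers``/``scales`` define the standardized simulation coordinate
    system (order: theta, gamma, shift); ``bounds`` is a (3, 2) box in
    standardized units.
    """

    coef_positive: np.ndarray
    coef_negative: np.ndarray
    centers: np.ndarray
    scales: np.ndarray
    payoff_mode: str = "net"
    bounds: np.ndarray = None

    def __post_init__(self):
        self.coef_positive = np.asarray(self.coef_positive, dtype=float)
        self.coef_negative = np.asarray(self.coef_negative, dtype=float)
        self.centers = np.asarray(self.centers, dtype=float)
        self.scales = np.asarray(self.scales, dtype=float)
        if self.bounds is None:
            self.bounds = np.array([[-3.0, 3.0]] * 3)
        self.bounds = np.asarray(self.bounds, dtype=float)
        if self.coef_positive.shape != (7,) or self.coef_negative.shape != (7,):
            raise ConfigError("coefficient vectors must have exactly 7 entries")
        if self.payoff_mode not in _MODES:
            raise ConfigError(f"payoff_mode must be one of {_MODES}")
        if self.bounds.shape != (3, 2) or np.any(self.bounds[:, 0] >= self.bounds[:, 1]):
            raise ConfigError("bounds must be a (3, 2) box with low < high")
        if np.any(self.scales <= 0):
            raise ConfigError("scales must be > 0")

    @classmethod
    def from_config(cls, config: GenerativeConfig,
                    payoff_mode: str = "net", bounds=None) -> "PayoffModel":
        return cls(coef_positive=config.coef_positive,
                   coef_negative=config.coef_negative,
                   centers=[config.theta_mean, config.gamma_mean, config.shift_mean],
                   scales=[config.theta_sd, config.gamma_sd, config.shift_sd],
                   payoff_mode=payoff_mode, bounds=bounds)

    @classmethod
    def from_cohort(cls, cohort_frame: pd.DataFrame, coef_positive, coef_negative,
                    payoff_mode: str = "net", bounds=None) -> "PayoffModel":
        cols = ["theta_change", "gamma_change", "affective_shift"]
        return cls(coef_positive=coef_positive, coef_negative=coef_negative,
                   centers=cohort_frame[cols].mean().to_numpy(),
                   scales=cohort_frame[cols].std(ddof=0).to_numpy(),
                   payoff_mode=payoff_mode, bounds=bounds)

    def to_original(self, point_std: np.ndarray) -> np.ndarray:
        return self.centers + self.scales * np.asarray(point_std, dtype=float)

    def _check_inside(self, point_std: np.ndarray) -> np.ndarray:
        z = np.asarray(point_std, dtype=float)
        if z.shape != (3,):
            raise InputError("point must have 3 coordinates (theta, gamma, shift)")
        if np.any(z < self.bounds[:, 0] - 1e-12) or np.any(z > self.bounds[:, 1] + 1e-12):
            raise InputError(f"point {z} outside bounds {self.bounds.tolist()}")
        return z


def reference_payoff_model(payoff_mode: str = "net") -> PayoffModel:
    """The payoff model built from the reference generative configuration."""
    return PayoffModel.from_config(default_generative_config(),
                                   payoff_mode=payoff_mode)


def _poly(coef: np.ndarray, v: np.ndarray) -> float:
    th, ga, sh = v
    return float(coef[0] + coef[1] * th + coef[2] * ga + coef[3] * sh
                 + coef[4] * th * sh + coef[5] * ga ** 2 + coef[6] * sh ** 2)


def _poly_grad(coef: np.ndarray, v: np.ndarray) -> np.ndarray:
    th, ga, sh = v
    return np.array([
        coef[1] + coef[4] * sh,
        coef[2] + 2.0 * coef[5] * ga,
        coef[3] + coef[4] * th + 2.0 * coef[6] * sh,
    ])


def payoff(point_std, model: PayoffModel) -> float:
    """Payoff at a standardized point.

    ``net`` is predicted Delta_Positive minus predicted Delta_Negative;
    ``positive`` is Delta_Positive alone; ``negative_reduction`` is
    -Delta_Negative.
    """
    z = model._check_inside(point_std)
    v = model.to_original(z)
    if model.payoff_mode == "positive":
        return _poly(model.coef_positive, v)
    if model.payoff_mode == "negative_reduction":
        return -_poly(model.coef_negative, v)
    return _poly(model.coef_positive, v) - _poly(model.coef_negative, v)


def payoff_gradient(point_std, model: PayoffModel) -> np.ndarray:
    """Closed-form payoff gradient in standardized coordinates.

    Original-scale partials (b1 + b4*AS, b2 + 2*b5*dGamma,
    b3 + b4*dTheta + 2*b6*AS) chained through the coordinate scales.
    """
    z = model._check_inside(point_std)
    v = model.to_original(z)
    if model.payoff_mode == "positive":
        g = _poly_grad(model.coef_positive, v)
    elif model.payoff_mode == "negative_reduction":
        g = -_poly_grad(model.coef_negative, v)
    else:
        g = _poly_grad(model.coef_positive, v) - _poly_grad(model.coef_negative, v)
    return g * model.scales


@dataclass
class AscentConfig:
    """Per-parameter learning rates, stop tolerance, iteration cap, start."""

    eta: Tuple[float, float, float] = (0.1, 0.1, 0.1)
    epsilon: float = 1e-6
    max_iter: int = 50
    start: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def validate(self, model: PayoffModel) -> None:
        if np.any(np.asarray(self.eta) <= 0):
            raise ConfigError("all learning rates eta must be > 0")
        if self.epsilon <= 0:
            raise ConfigError("epsilon must be > 0")
        if self.max_iter < 1:
            raise ConfigError("max_iter must be >= 1")
        model._check_inside(np.asarray(self.start, dtype=float))


@dataclass
class Trajectory:
    """Iterate-by-iterate ascent path with convergence bookkeeping."""

    states_std: np.ndarray      # (k+1) x 3
    states_orig: np.ndarray     # (k+1) x 3
    payoffs: np.ndarray         # (k+1)
    converged: bool
    stop_reason: str            # tolerance | max_iter | boundary_fixed

    @property
    def iterations(self) -> int:
        return len(self.payoffs) - 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "iteration": np.arange(len(self.payoffs)),
            "theta_std": self.states_std[:, 0],
            "gamma_std": self.states_std[:, 1],
            "shift_std": self.states_std[:, 2],
            "theta": self.states_orig[:, 0],
            "gamma": self.states_orig[:, 1],
            "shift": self.states_orig[:, 2],
            "payoff": self.payoffs,
        })


def ascend(model: PayoffModel, config: AscentConfig = None) -> Trajectory:
    """Projected gradient ascent to a constrained fixed point.

    Steps are clipped to the box; the run stops when |payoff change| falls
    below epsilon (``converged``) or at ``max_iter``.  A converged stop with
    active clipping at the last step is labeled ``boundary_fixed`` --
    the "equilibrium" is then a constrained, not interior, optimum.
    """
    config = config or AscentConfig()
    config.validate(model)
    eta = np.asarray(config.eta, dtype=float)
    x = np.asarray(config.start, dtype=float)
    p = payoff(x, model)
    states, payoffs = [x.copy()], [p]
    converged, reason = False, "max_iter"
    for _ in range(config.max_iter):
        raw = x + eta * payoff_gradient(x, model)
        x_new = np.clip(raw, model.bounds[:, 0], model.bounds[:, 1])
        clipped = bool(np.any(raw != x_new))
        p_new = payoff(x_new, model)
        states.append(x_new.copy())
        payoffs.append(p_new)
        if abs(p_new - p) < config.epsilon:
            converged = True
            reason = "boundary_fixed" if clipped else "tolerance"
            x, p = x_new, p_new
            break
        x, p = x_new, p_new
    states = np.asarray(states)
    return Trajectory(states_std=states,
                      states_orig=np.vstack([model.to_original(s) for s in states]),
                      payoffs=np.asarray(payoffs),
                      converged=converged, stop_reason=reason)


def payoff_surface(model: PayoffModel, fixed_shift: float,
                   theta_grid: Sequence[float],
                   gamma_grid: Sequence[float]) -> np.ndarray:
    """Payoff over a (theta x gamma) standardized grid at a pinned shift.

    ``fixed_shift`` is in original units (PANAS points); grids are in
    standardized units and must lie inside the box.  Returns an array of
    shape (len(theta_grid), len(gamma_grid)).
    """
    theta_grid = np.asarray(theta_grid, dtype=float)
    gamma_grid = np.asarray(gamma_grid, dtype=float)
    shift_std = (fixed_shift - model.centers[2]) / model.scales[2]
    out = np.empty((theta_grid.size, gamma_grid.size))
    for i, th in enumerate(theta_grid):
        for j, ga in enumerate(gamma_grid):
            out[i, j] = payoff(np.array([th, ga, shift_std]), model)
    return out


def plot_surface(model: PayoffModel, fixed_shift: float = 10.0, n: int = 50,
                 ax=None):
    """Thin matplotlib veneer: heatmap of the payoff surface."""
    import matplotlib.pyplot as plt

    lo, hi = model.bounds[:2, 0], model.bounds[:2, 1]
    tg = np.linspace(lo[0], hi[0], n)
    gg = np.linspace(lo[1], hi[1], n)
    grid = payoff_surface(model, fixed_shift, tg, gg)
    if ax is None:
        _, ax = plt.subplots()
    im = ax.pcolormesh(gg, tg, grid, shading="auto")
    ax.set_xlabel("gamma change (std units)")
    ax.set_ylabel("theta change (std units)")
    ax.set_title(f"Emotional payoff, shift = {fixed_shift} PANAS points")
    ax.figure.colorbar(im, ax=ax, label="payoff")
    return ax


def plot_trajectory(trajectory: Trajectory, ax=None):
    """Thin matplotlib veneer: payoff across iterations."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(np.arange(len(trajectory.payoffs)), trajectory.payoffs, marker="o")
    ax.set_xlabel("iteration")
    ax.set_ylabel("payoff")
    ax.set_title(f"Ascent ({trajectory.stop_reason}, "
                 f"{trajectory.iterations} iterations)")
    return ax
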