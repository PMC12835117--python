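"""Few-step variance-preserving diffusion machinery.

The forward process corrupts a clean image ``x0`` through a short Markov
chain ``x_t = sqrt(1 - beta_t) x_{t-1} + sqrt(beta_t) eps`` (T steps, here
T=4 by default).  Because the per-step kernel is Gaussian and linear, the
marginal at step ``t`` is available in closed form, as is the denoising
posterior ``q(x_{t-1} | x_t, x0)``.  Sampling runs the chain backwards with
a network that predicts ``x0`` directly (x0-parameterization): at each step
the predicted clean image is pushed through the exact posterior.

The printed variance-range convention (beta_min=0.1, beta_max=20) cannot be
a per-step variance of the discrete kernel, which requires beta_t < 1.  The
discrete schedule is therefore derived from the continuous
variance-preserving rate ``beta(s) = beta_min + s (beta_max - beta_min)``,
``s in (0, 1]``, via

    beta_t = 1 - exp(-integral of beta(s) over ((t-1)/T, t/T])

which keeps every beta_t inside (0, 1) for any positive rate range and
makes ``alpha_bar_T = exp(-(beta_min + beta_max)/2)`` exactly.

All stochastic operations take the noise draw (or a seeded Generator) as an
explicit argument, so callers — and tests — control every source of
randomness.  The coefficient arithmetic uses plain operators only, so
``posterior_sample`` stays differentiable when ``x0_hat`` is an autograd
tracer during training.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "NoiseSchedule",
    "DiffusionState",
    "build_schedule",
    "forward_step",
    "forward_marginal",
    "posterior_params",
    "posterior_sample",
    "reverse_sample",
]


@dataclass(frozen=True)
class NoiseSchedule:
    """Per-step variances and cumulative signal factors of a T-step chain.

    Attributes
    ----------
    T : int
        Number of diffusion steps.
    beta : ndarray, shape (T,)
        Per-step noise variances ``beta_1 .. beta_T``, each in (0, 1).
        ``beta[t-1]`` is the variance used at step ``t``.
    alpha_bar : ndarray, shape (T+1,)
        Cumulative signal factors ``alpha_bar_0 .. alpha_bar_T`` with
        ``alpha_bar_0 = 1`` and ``alpha_bar_t = prod_{i<=t}(1 - beta_i)``.
    beta_tilde : ndarray, shape (T,)
        Posterior variances; ``beta_tilde[t-1]`` is the variance of
        ``q(x_{t-1} | x_t, x0)``.  ``beta_tilde_1 = 0`` exactly.
    """

    T: int
    beta: np.ndarray
    alpha_bar: np.ndarray
    beta_tilde: np.ndarray
    beta_min: float = 0.1
    beta_max: float = 20.0

    def __post_init__(self) -> None:
        if self.T < 1:
            raise ValueError(f"T must be >= 1, got {self.T}")
        if self.beta.shape != (self.T,):
            raise ValueError("beta must have shape (T,)")
        if self.alpha_bar.shape != (self.T + 1,):
            raise ValueError("alpha_bar must have shape (T+1,)")
        if not np.all((self.beta > 0) & (self.beta < 1)):
            raise ValueError("all beta_t must lie strictly inside (0, 1)")
        if self.alpha_bar[0] != 1.0:
            raise ValueError("alpha_bar_0 must equal 1")
        if not np.all(np.diff(self.alpha_bar) < 0):
            raise ValueError("alpha_bar must be strictly decreasing")

    def to_dict(self) -> dict:
        return {
            "T": self.T,
            "beta_min": self.beta_min,
            "beta_max": self.beta_max,
        }


@dataclass
class DiffusionState:
    """A chain state: image array plus its timestep (0 = clean data)."""

    x: np.ndarray
    t: int

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.x)):
            raise ValueError("state contains non-finite values")
        if self.t < 0:
            raise ValueError("t must be >= 0")


def build_schedule(T: int = 4, beta_min: float = 0.1, beta_max: float = 20.0) -> NoiseSchedule:
    """Discretize the linear variance-preserving rate into T kernel variances.

    ``beta_t = 1 - exp(-beta_min/T - (beta_max - beta_min) (2t-1) / (2 T^2))``.
    """
    if T < 1:
        raise ValueError(f"T must be >= 1, got {T}")
    if beta_min <= 0:
        raise ValueError(f"beta_min must be positive, got {beta_min}")
    if beta_max < beta_min:
        raise ValueError("beta_max must be >= beta_min")
    t = np.arange(1, T + 1, dtype=np.float64)
    integral = beta_min / T + (beta_max - beta_min) * (2.0 * t - 1.0) / (2.0 * T**2)
    beta = 1.0 - np.exp(-integral)
    alpha_bar = np.concatenate([[1.0], np.cumprod(1.0 - beta)])
    # beta_tilde_t = (1 - alpha_bar_{t-1}) / (1 - alpha_bar_t) * beta_t; zero at t=1
    beta_tilde = (1.0 - alpha_bar[:-1]) / (1.0 - alpha_bar[1:]) * beta
    return NoiseSchedule(T=T, beta=beta, alpha_bar=alpha_bar, beta_tilde=beta_tilde,
                         beta_min=beta_min, beta_max=beta_max)


def _check_t(t: int, T: int) -> None:
    if not 1 <= t <= T:
        raise ValueError(f"t must be in [1, {T}], got {t}")


def _check_shape(a, b, name: str) -> None:
    if np.shape(a) != np.shape(b):
        raise ValueError(f"{name} shape {np.shape(b)} does not match {np.shape(a)}")


def forward_step(x_prev: np.ndarray, t: int, sched: NoiseSchedule, noise: np.ndarray) -> np.ndarray:
    """One forward corruption step: ``x_t = sqrt(1-beta_t) x_{t-1} + sqrt(beta_t) eps``."""
    _check_t(t, sched.T)
    _check_shape(x_prev, noise, "noise")
    b = float(sched.beta[t - 1])
    return math.sqrt(1.0 - b) * x_prev + math.sqrt(b) * noise


def forward_marginal(x0: np.ndarray, t: int, sched: NoiseSchedule, noise: np.ndarray) -> np.ndarray:
    """Exact marginal of the chain: ``x_t = sqrt(ab_t) x0 + sqrt(1-ab_t) eps``.

    ``t = 0`` is allowed and returns ``x0`` unchanged (alpha_bar_0 = 1).
    """
    if t == 0:
        return x0
    _check_t(t, sched.T)
    _check_shape(x0, noise, "noise")
    ab = float(sched.alpha_bar[t])
    return math.sqrt(ab) * x0 + math.sqrt(1.0 - ab) * noise


def posterior_params(x0, x_t, t: int, sched: NoiseSchedule):
    """Mean and variance of the denoising posterior ``q(x_{t-1} | x_t, x0)``.

    mean = sqrt(ab_{t-1}) beta_t / (1-ab_t) * x0
         + sqrt(1-beta_t) (1-ab_{t-1}) / (1-ab_t) * x_t
    var  = beta_tilde_t  (scalar; exactly 0 at t=1)
    """
    _check_t(t, sched.T)
    b = float(sched.beta[t - 1])
    ab_prev = float(sched.alpha_bar[t - 1])
    ab = float(sched.alpha_bar[t])
    coef_x0 = math.sqrt(ab_prev) * b / (1.0 - ab)
    coef_xt = math.sqrt(1.0 - b) * (1.0 - ab_prev) / (1.0 - ab)
    mean = coef_x0 * x0 + coef_xt * x_t
    return mean, float(sched.beta_tilde[t - 1])


def posterior_sample(x0_hat, x_t, t: int, sched: NoiseSchedule, noise) -> np.ndarray:
    """Draw ``x_{t-1}`` from the posterior with ``x0`` replaced by a prediction.

    At ``t = 1`` the posterior variance is zero, so the result is exactly
    ``x0_hat`` irrespective of the noise argument.
    """
    _check_shape(x_t, noise, "noise")
    mean, var = posterior_params(x0_hat, x_t, t, sched)
    if var == 0.0:
        return mean
    return mean + math.sqrt(var) * noise


def reverse_sample(predict_x0, y, sched: NoiseSchedule, rng: np.random.Generator,
                   *, shape=None, z_source=None, x_T: np.ndarray | None = None) -> np.ndarray:
    """Run the T-step reverse chain with an x0-predicting model.

    Parameters
    ----------
    predict_x0 : callable ``(x_t, y, z, t) -> x0_hat``
        The denoising model; called exactly T times.
    y : conditioning input forwarded verbatim to the predictor.
    sched : NoiseSchedule
    rng : seeded numpy Generator used for the initial state and every
        posterior draw.
    shape : shape of the chain state; defaults to ``np.shape(y)``.
    z_source : optional callable ``(t, rng) -> z`` providing the latent code
        per step; ``None`` passes ``z = None`` through.
    x_T : optional explicit initial state (overrides the rng draw).

    Returns
    -------
    The t=0 state.  Because the final posterior variance is zero, a
    predictor that returns the true ``x0`` reproduces it exactly.
    """
    if shape is None:
        shape = np.shape(y)
    x_t = rng.standard_normal(shape) if x_T is None else np.asarray(x_T)
    if np.shape(x_t) != tuple(shape):
        raise ValueError(f"x_T shape {np.shape(x_t)} does not match {tuple(shape)}")
    for t in range(sched.T, 0, -1):
        z = z_source(t, rng) if z_source is not None else None
        x0_hat = predict_x0(x_t, y, z, t)
        noise = rng.standard_normal(shape)
        x_t = posterior_sample(x0_hat, x_t, t, sched, noise)
    return x_t
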