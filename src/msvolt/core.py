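"""Core types and densities of the multivariate stochastic volatility (MSV) model.

The model for a J-channel series ``y`` observed at times t = 0..T-1 is

.. math::

    y_{j,t} = \\exp(x_{j,t}/2)\\,\\epsilon^y_{j,t}, \\qquad
    \\epsilon^y_t \\sim \\mathcal{N}(0, I_J)

with latent log-volatility following a VAR(1) with full persistence matrix

.. math::

    x_t - \\mu = \\beta (x_{t-1} - \\mu) + \\epsilon^x_t, \\qquad
    \\epsilon^x_t \\sim \\mathcal{N}(0, \\Sigma),\\ \\Sigma = \\mathrm{diag}(\\sigma^2)

``beta[j, k]`` is the lag-one effect of channel k on channel j's log-volatility;
off-diagonal entries encode directed cross-channel influence.  Channels are
conditionally independent given their log-volatility paths.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, stats

__all__ = [
    "MSVParams",
    "PriorConfig",
    "LatentPaths",
    "observation_loglik",
    "log_prior",
    "stationarity_check",
    "linearize_observations",
    "stationary_moments",
]


@dataclass
class MSVParams:
    """Parameters (μ, β, Σ) of the MSV model.

    Attributes
    ----------
    mu : (J,) ndarray
        Unconditional mean log-volatility per channel (log of volts² after
        detrending, i.e. log-variance units).
    beta : (J, J) ndarray
        VAR(1) persistence matrix, unitless.  Convention:
        ``beta[j, k]`` = effect of channel k at t−1 on channel j at t.
    sigma2 : (J,) ndarray
        Volatility-of-volatility variances (diagonal of Σ), strictly positive.
    """

    mu: np.ndarray
    beta: np.ndarray
    sigma2: np.ndarray

    def __post_init__(self) -> None:
        self.mu = np.atleast_1d(np.asarray(self.mu, dtype=float))
        self.beta = np.atleast_2d(np.asarray(self.beta, dtype=float))
        self.sigma2 = np.atleast_1d(np.asarray(self.sigma2, dtype=float))
        J = self.mu.shape[0]
        if self.beta.shape != (J, J):
            raise ValueError(f"beta must be ({J}, {J}), got {self.beta.shape}")
        if self.sigma2.shape != (J,):
            raise ValueError(f"sigma2 must be ({J},), got {self.sigma2.shape}")

    @property
    def n_channels(self) -> int:
        return self.mu.shape[0]

    def validate(self) -> None:
        """Raise ValueError if the parameters are outside the model's support."""
        if not np.all(np.isfinite(self.mu)):
            raise ValueError("mu must be finite")
        if np.any(self.sigma2 < 0):
            raise ValueError("sigma2 must be non-negative")
        if not stationarity_check(self.beta):
            raise ValueError("beta fails the stationarity check "
                             "(needs spectral radius < 1 and all |entries| < 1)")

    def to_json(self) -> str:
        return json.dumps({
            "mu": self.mu.tolist(),
            "beta": self.beta.tolist(),
            "sigma2": self.sigma2.tolist(),
            "convention": "beta[j][k] = effect of channel k at t-1 on channel j at t",
        })

    @classmethod
    def from_json(cls, s: str) -> "MSVParams":
        d = json.loads(s)
        return cls(mu=np.array(d["mu"]), beta=np.array(d["beta"]),
                   sigma2=np.array(d["sigma2"]))

    def copy(self) -> "MSVParams":
        return MSVParams(self.mu.copy(), self.beta.copy(), self.sigma2.copy())


@dataclass
class PriorConfig:
    """Hyperparameters of the (relatively flat) priors.

    μ ~ MVN(0, mu_prior_var·I); per entry (β_{jk}+1)/2 ~ Beta(beta_a, beta_b);
    σ_j² ~ Gamma(sigma_gamma_shape, rate=sigma_gamma_rate), which for the
    defaults (1/2, 1/20) is the same law as ±σ_j ~ N(0, 10).
    """

    mu_prior_var: float = 1000.0
    beta_a: float = 20.0
    beta_b: float = 1.5
    sigma_gamma_shape: float = 0.5
    sigma_gamma_rate: float = 1.0 / 20.0

    def __post_init__(self) -> None:
        for name in ("mu_prior_var", "beta_a", "beta_b",
                     "sigma_gamma_shape", "sigma_gamma_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class LatentPaths:
    """Log-volatility trajectories, shape (events, channels, samples)."""

    x: np.ndarray = field()

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        if self.x.ndim != 3:
            raise ValueError("latent paths must be (events, channels, samples)")
        if not np.all(np.isfinite(self.x)):
            raise ValueError("latent paths must be finite")

    @property
    def shape(self):
        return self.x.shape


def stationarity_check(beta: np.ndarray) -> bool:
    """True iff ``beta`` defines a stationary VAR(1) inside the prior support.

    Requires spectral radius strictly below 1 (the stationarity condition for
    the latent VAR) *and* every entry in (−1, 1) (the support of the
    transformed-Beta prior).  Entrywise bounds alone do not bound the spectral
    radius, so both are checked.
    """
    beta = np.asarray(beta, dtype=float)
    if beta.ndim != 2 or beta.shape[0] != beta.shape[1]:
        raise ValueError("beta must be a square matrix")
    if not np.all(np.abs(beta) < 1.0):
        return False
    return float(np.max(np.abs(np.linalg.eigvals(beta)))) < 1.0


def observation_loglik(y: np.ndarray, x: np.ndarray | LatentPaths) -> float:
    """Conditional log-likelihood Σ log N(y; 0, exp(x)) over all entries.

    ``y`` and ``x`` may be any matching-shape arrays (scalar, per-channel, or
    the full events × channels × samples tensors); channels are conditionally
    independent given x so the total is a plain sum.
    """
    if isinstance(x, LatentPaths):
        x = x.x
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.shape != x.shape:
        raise ValueError(f"shape mismatch: y {y.shape} vs x {x.shape}")
    ll = -0.5 * (np.log(2.0 * np.pi) + x + y * y * np.exp(-x))
    return float(np.sum(ll))


def log_prior(params: MSVParams, cfg: PriorConfig | None = None) -> float:
    """Log prior density of (μ, β, σ²), −inf outside the support.

    The β term includes the Jacobian of the affine map b ↦ (b+1)/2 applied
    entrywise before the Beta density.  The support is the stationary region
    intersected with the entrywise box (−1, 1); the truncated prior is used
    unnormalized (the truncation constant is common to all valid β and
    cancels in MCMC ratios).
    """
    cfg = cfg or PriorConfig()
    if np.any(np.abs(params.beta) >= 1.0) or not stationarity_check(params.beta):
        return -np.inf
    if np.any(params.sigma2 <= 0):
        return -np.inf
    lp = float(np.sum(stats.norm.logpdf(params.mu, 0.0, np.sqrt(cfg.mu_prior_var))))
    lp += float(np.sum(stats.beta.logpdf((params.beta + 1.0) / 2.0,
                                         cfg.beta_a, cfg.beta_b))) \
        + params.beta.size * np.log(0.5)
    lp += float(np.sum(stats.gamma.logpdf(params.sigma2, cfg.sigma_gamma_shape,
                                          scale=1.0 / cfg.sigma_gamma_rate)))
    return lp


def linearize_observations(y: np.ndarray, offset: float | np.ndarray | None = None
                           ) -> np.ndarray:
    """Map observations to the linear state space: z = log(y² + c).

    Squaring and logging Eq-style observations turns the multiplicative model
    into an additive one, z = x + log ε², at the price of a non-Gaussian error
    handled downstream by a Gaussian-mixture approximation.  The offset c > 0
    guards exact zeros; by default c = 1e−8 × per-channel sample variance
    (scale-aware, negligible bias), with an absolute floor for identically
    zero channels.
    """
    y = np.asarray(y, dtype=float)
    if offset is None:
        var = np.var(y, axis=-1, keepdims=True)
        offset = 1e-8 * np.maximum(var, 1e-30)
    else:
        offset = np.asarray(offset, dtype=float)
        if np.any(offset <= 0):
            raise ValueError("offset must be positive")
    return np.log(y * y + offset)


def stationary_moments(params: MSVParams) -> tuple[np.ndarray, np.ndarray]:
    """Stationary mean and covariance of the latent VAR(1).

    The mean is μ; the covariance V solves the discrete Lyapunov equation
    V = β V βᵀ + Σ.
    """
    if not stationarity_check(params.beta):
        raise ValueError("stationary moments undefined: beta is not stationary")
    V = linalg.solve_discrete_lyapunov(params.beta, np.diag(params.sigma2))
    V = (V + V.T) / 2.0  # symmetrize numerical residue
    return params.mu.copy(), V


def check_summary_stationarity(beta: np.ndarray) -> bool:
    """Re-check a posterior-mean β and warn if it falls outside stationarity."""
    ok = stationarity_check(beta)
    if not ok:
        warnings.warn("posterior-mean beta is not stationary; the mean of "
                      "stationary draws need not itself be stationary",
                      RuntimeWarning, stacklevel=2)
    return ok
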