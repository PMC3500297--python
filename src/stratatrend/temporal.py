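"""Stationary AR(1) structure for the temporal residual field.

Each stratum carries a latent series gamma_j = (gamma_j1, ..., gamma_jT)
of residuals about its modelled log counts, with

    gamma_jt = rho * gamma_j,t-1 + e_t,   e_t ~ Normal(0, 1/tau),

initialised at the stationary marginal Normal(0, 1/(tau*(1-rho^2))).
Because the residual lives on the log scale, this is latent Gompertz
growth: expected log abundance at time t depends linearly on log
abundance at t-1 through rho.

``tau`` is the *innovation* precision throughout the package; the
marginal precision is tau*(1-rho^2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["AR1Params", "ar1_precision", "ar1_logdet", "ar1_quadform",
           "simulate_ar1"]


@dataclass(frozen=True)
class AR1Params:
    """rho: autocorrelation in (-1, 1); tau: innovation precision > 0;
    T: number of occasions >= 1."""

    rho: float
    tau: float
    T: int

    def __post_init__(self):
        if not abs(self.rho) < 1:
            raise ValueError(f"|rho| must be < 1, got {self.rho}")
        if not self.tau > 0:
            raise ValueError(f"tau must be > 0, got {self.tau}")
        if int(self.T) < 1 or self.T != int(self.T):
            raise ValueError(f"T must be a positive integer, got {self.T}")


def ar1_precision(params: AR1Params) -> np.ndarray:
    """Tridiagonal precision of the stationary AR(1).

    diag = tau*(1, 1+rho^2, ..., 1+rho^2, 1); off-diag = -tau*rho.  Its
    inverse is the stationary covariance rho^|t-s| / (tau*(1-rho^2)).
    """
    rho, tau, T = params.rho, params.tau, int(params.T)
    if T == 1:
        # a single occasion carries only the stationary marginal
        return np.array([[tau * (1.0 - rho**2)]])
    diag = np.full(T, 1.0 + rho**2)
    diag[0] = diag[-1] = 1.0
    Q = np.diag(tau * diag)
    off = -tau * rho * np.ones(T - 1)
    Q += np.diag(off, 1) + np.diag(off, -1)
    return Q


def ar1_logdet(params: AR1Params) -> float:
    """Closed-form log-determinant T*log(tau) + log(1 - rho^2)."""
    return float(params.T * np.log(params.tau) + np.log1p(-params.rho**2))


def ar1_quadform(x: np.ndarray, rho: float) -> np.ndarray:
    """x' R x with R the unit-innovation AR(1) precision, along axis -1.

    For x of shape (..., T):  x_1^2 + x_T^2 + (1+rho^2) * sum_{1<t<T} x_t^2
    - 2*rho * sum_t x_t x_{t+1}.  Multiply by tau to get the full
    quadratic form; used in conjugate precision updates and rho moves.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[-1] == 1:
        return (1.0 - rho**2) * x[..., 0] ** 2
    sq = (x**2).sum(axis=-1)
    inner = (x[..., 1:-1] ** 2).sum(axis=-1)
    cross = (x[..., :-1] * x[..., 1:]).sum(axis=-1)
    return sq + rho**2 * inner - 2.0 * rho * cross


def simulate_ar1(params: AR1Params, n_series: int,
                 seed=None) -> np.ndarray:
    """Simulate stationary AR(1) series; returns shape (n_series, T).

    ``seed`` may be an int or a numpy Generator.  Identical seeds give
    bitwise-identical output.
    """
    if n_series < 1:
        raise ValueError("n_series must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    rho, tau, T = params.rho, params.tau, int(params.T)
    sd_innov = 1.0 / np.sqrt(tau)
    sd_marg = sd_innov / np.sqrt(1.0 - rho**2)
    out = np.empty((n_series, T))
    out[:, 0] = rng.standard_normal(n_series) * sd_marg
    for t in range(1, T):
        out[:, t] = rho * out[:, t - 1] + rng.standard_normal(n_series) * sd_innov
    return out
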