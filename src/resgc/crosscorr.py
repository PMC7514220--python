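"""Exact stationary cross-correlation of a VAR(1) via Yule-Walker.

The lag-0 covariance solves the discrete Lyapunov (Yule-Walker) equation
S = A S A' + Sigma; lagged covariances follow from C(tau) = A C(tau-1).
Sign convention (documented in every output header): positive lag means the
driver X1 leads the driven X2, i.e. rho(tau >= 0) = corr(X1_{t-tau}, X2_t);
negative lags give corr(X2_{t-|tau|}, X1_t).

The mu -> inf ladder entry is built from the limiting model (a -> 0,
c -> b = e^{-h}, residual covariance per the tight-coupling limit), never by
plugging in a large finite mu.  Its lag-0 value is (1 + eps)^{-1/2}
independent of h — synchronisation stays incomplete for eps > 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_discrete_lyapunov

from .gc_analytic import limit_covariance
from .var_map import VAR1Model

__all__ = [
    "CCF",
    "stationary_covariance",
    "ccf",
    "ccf_limit",
    "max_ccf",
    "limit_model",
]


@dataclass
class CCF:
    """Cross-correlation over integer lags for one coupling value."""

    lags: np.ndarray
    rho: np.ndarray
    mu: float  # math.inf marks the tight-coupling limit

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=int)
        self.rho = np.asarray(self.rho, dtype=float)
        if self.lags.shape != self.rho.shape:
            raise ValueError("lags and rho must have matching shapes")
        if np.any(np.abs(self.rho) > 1.0 + 1e-12):
            raise ValueError("|rho| exceeds 1")


def stationary_covariance(model: VAR1Model) -> np.ndarray:
    """Lag-0 stationary covariance: unique solution of S = A S A' + Sigma."""
    if not model.is_stable:
        raise ValueError(
            f"unstable model (spectral radius {model.spectral_radius:.6g})"
        )
    S = solve_discrete_lyapunov(model.transition, model.Sigma)
    return 0.5 * (S + S.T)


def ccf(model: VAR1Model, max_lag: int, mu: float | None = None) -> CCF:
    """Cross-correlation at lags -max_lag..max_lag from exact moments."""
    if max_lag < 0:
        raise ValueError("max_lag must be >= 0")
    S = stationary_covariance(model)
    norm = math.sqrt(S[0, 0] * S[1, 1])
    A = model.transition
    lags = np.arange(-max_lag, max_lag + 1)
    rho = np.empty(lags.shape)
    M = S.copy()  # M(tau) = A^tau S = Cov(X_t, X_{t-tau})
    rho[max_lag] = S[1, 0] / norm
    for tau in range(1, max_lag + 1):
        M = A @ M
        rho[max_lag + tau] = M[1, 0] / norm  # X1 leads X2 by tau
        rho[max_lag - tau] = M[0, 1] / norm  # X2 leads X1 by tau
    rho = np.clip(rho, -1.0, 1.0)
    return CCF(lags=lags, rho=rho, mu=model_mu(model) if mu is None else mu)


def model_mu(model: VAR1Model) -> float:
    """Coupling implied by the triangular parameterisation, for labelling:
    mu = -ln(a)/h - 1 when a > 0 and h is known, else nan."""
    if model.h and model.h > 0 and model.a > 0:
        return max(0.0, -math.log(model.a) / model.h - 1.0)
    return float("nan")


def limit_model(eps: float, h: float) -> VAR1Model:
    """The tight-coupling limiting VAR(1): a -> 0, c -> b = e^{-h}, residual
    covariance Sigma11 [[1, 1], [1, 1 + eps/(1-e^{-2h})]] (Sigma11 = 1; all
    correlations are scale-free)."""
    b = math.exp(-h)
    return VAR1Model(b=b, c=b, a=0.0, Sigma=limit_covariance(eps, h, 1.0), h=h)


def ccf_limit(eps: float, h: float, max_lag: int) -> CCF:
    """Cross-correlation of the mu -> inf limiting model.

    Peak at lag 0 (instantaneous response) with value (1+eps)^{-1/2};
    lag-1 value e^{-h} (1+eps)^{-1/2}.
    """
    out = ccf(limit_model(eps, h), max_lag, mu=math.inf)
    return out


def max_ccf(c: CCF) -> tuple[int, float]:
    """Argmax of rho over the provided lags, first index breaking ties."""
    if c.rho.size == 0:
        raise ValueError("empty CCF")
    i = int(np.argmax(c.rho))
    return int(c.lags[i]), float(c.rho[i])
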