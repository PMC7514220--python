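"""Exact discretisation of the linear diffusion to a VAR(1).

Sampling the Ornstein-Uhlenbeck dynamics x' = Gamma x + noise at interval
``delta_t`` yields the stroboscopic map

    X_t = A X_{t-1} + theta_t,      A = exp(Gamma delta_t),

with residual covariance

    Sigma = int_0^delta_t  exp(Gamma t) D exp(Gamma^T t) dt.

For the lower-triangular Gamma = p[[-1, 0], [mu, -(1+mu)]] the transition
entries are, with h = p*delta_t,

    b = e^{-h},  a = e^{-(1+mu)h},  c = b - a,

and the Sigma integral has a closed form implemented in
:func:`residual_covariance_closed` (quadrature oracle:
:func:`residual_covariance_quadrature`).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad_vec
from scipy.linalg import expm

from .model_core import (
    ModelParams,
    State,
    _require_finite_mu,
    diffusion,
    jacobian,
    mean_diffusivities,
)

__all__ = [
    "VAR1Model",
    "discretize_transition",
    "transition_matrix",
    "residual_covariance_closed",
    "residual_covariance_quadrature",
    "sigma_entries",
    "local_var",
    "var1_from_params",
]


@dataclass
class VAR1Model:
    """Bivariate VAR(1) X_t = [[b, d], [c, a]] X_{t-1} + theta_t.

    ``d`` is the driven->driver feedback entry; it is 0 for the
    uni-directionally coupled model but is carried so that general bivariate
    models can be handled by the state-space machinery.
    """

    b: float
    c: float
    a: float
    Sigma: np.ndarray
    h: float
    d: float = 0.0

    def __post_init__(self) -> None:
        self.Sigma = np.asarray(self.Sigma, dtype=float)
        if self.Sigma.shape != (2, 2):
            raise ValueError("Sigma must be 2x2")
        if not np.allclose(self.Sigma, self.Sigma.T, atol=1e-12):
            raise ValueError("Sigma must be symmetric")

    @property
    def transition(self) -> np.ndarray:
        return np.array([[self.b, self.d], [self.c, self.a]])

    @property
    def spectral_radius(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(self.transition))))

    @property
    def is_stable(self) -> bool:
        return self.spectral_radius < 1.0

    def to_json(self) -> str:
        return json.dumps(
            {
                "b": self.b,
                "c": self.c,
                "a": self.a,
                "d": self.d,
                "h": self.h,
                "Sigma": self.Sigma.tolist(),
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "VAR1Model":
        obj = json.loads(s)
        return cls(
            b=obj["b"],
            c=obj["c"],
            a=obj["a"],
            d=obj.get("d", 0.0),
            h=obj["h"],
            Sigma=np.array(obj["Sigma"]),
        )


def discretize_transition(
    params: ModelParams, delta_t: float
) -> tuple[float, float, float]:
    """Transition entries (a, b, c) of the exact stroboscopic map.

    a = e^{-(1+mu)h}, b = e^{-h}, c = b - a with h = p*delta_t; equal to the
    matrix exponential of jacobian(params)*delta_t.
    """
    _require_finite_mu(params)
    if not delta_t > 0:
        raise ValueError(f"delta_t must be > 0, got {delta_t}")
    h = params.p * delta_t
    b = math.exp(-h)
    a = math.exp(-(1.0 + params.mu) * h)
    return a, b, b - a


def transition_matrix(params: ModelParams, delta_t: float) -> np.ndarray:
    a, b, c = discretize_transition(params, delta_t)
    return np.array([[b, 0.0], [c, a]])


def sigma_entries(d1, d2, mu, h, p=1.0):
    """Residual covariance entries for frozen diagonal diffusion (d1, d2).

    Antiderivative form of the Sigma integral, regular for every mu >= 0
    (no removable singularity at mu = 0); vectorised over d1/d2 so that
    per-state local covariances can be evaluated in bulk.

    Returns (Sigma11, Sigma12, Sigma22).
    """
    d1 = np.asarray(d1, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    e2 = np.exp(-2.0 * h)
    em = np.exp(-(2.0 + mu) * h)
    e2m = np.exp(-2.0 * (1.0 + mu) * h)
    i_mm = (1.0 - e2) / (2.0 * p)
    i_mn = (1.0 - em) / (p * (2.0 + mu))
    i_nn = (1.0 - e2m) / (2.0 * p * (1.0 + mu))
    s11 = d1 * i_mm
    s12 = d1 * (i_mm - i_mn)
    s22 = d2 * i_nn + d1 * (i_mm - 2.0 * i_mn + i_nn)
    return s11, s12, s22


def residual_covariance_closed(params: ModelParams, delta_t: float) -> np.ndarray:
    """Closed-form residual covariance with state-averaged diffusivities.

    Sigma11 depends only on the driver noise; Sigma12 vanishes at mu = 0 and
    tends to Sigma11 as mu -> inf; Sigma22 stays finite for mu -> inf because
    the faster follower relaxation compensates the linearly growing
    diffusivity sigma2^2(mu).
    """
    _require_finite_mu(params)
    if not delta_t > 0:
        raise ValueError(f"delta_t must be > 0, got {delta_t}")
    dv = mean_diffusivities(params)
    h = params.p * delta_t
    s11, s12, s22 = sigma_entries(dv.sigma1_sq, dv.sigma2_sq, params.mu, h, params.p)
    return np.array([[s11, s12], [s12, s22]])


def residual_covariance_quadrature(
    Gamma: np.ndarray,
    D: np.ndarray,
    delta_t: float,
    epsrel: float = 1e-10,
) -> np.ndarray:
    """Residual covariance by adaptive quadrature of the matrix integral.

    Serves as the independent oracle for :func:`residual_covariance_closed`.
    ``D`` must be diagonal (the model's diffusion has no cross terms).
    """
    Gamma = np.asarray(Gamma, dtype=float)
    D = np.asarray(D, dtype=float)
    if Gamma.shape != (2, 2) or D.shape != (2, 2):
        raise ValueError("Gamma and D must be 2x2")
    if np.any(D - np.diag(np.diag(D)) != 0.0):
        raise ValueError("D must be diagonal")
    if np.all(np.diag(D) == 0.0):
        return np.zeros((2, 2))
    if np.any(np.real(np.linalg.eigvals(Gamma)) >= 0):
        import warnings

        warnings.warn("Gamma is not strictly stable; Sigma is still finite "
                      "for finite delta_t", stacklevel=2)

    def integrand(t: float) -> np.ndarray:
        E = expm(Gamma * t)
        return E @ D @ E.T

    epsabs = 1e-16 * float(np.abs(np.diag(D)).max())
    out, err = quad_vec(integrand, 0.0, delta_t, epsrel=epsrel, epsabs=epsabs)
    scale = max(float(np.abs(out).max()), epsabs)
    if err > 1e-6 * scale:
        raise RuntimeError(
            f"quadrature did not converge: estimated error {err:g} "
            f"for result scale {scale:g}"
        )
    return 0.5 * (out + out.T)


def var1_from_params(params: ModelParams, delta_t: float) -> VAR1Model:
    """The global VAR(1) twin of the diffusion with average-noise residuals."""
    a, b, c = discretize_transition(params, delta_t)
    Sigma = residual_covariance_closed(params, delta_t)
    return VAR1Model(b=b, c=c, a=a, Sigma=Sigma, h=params.p * delta_t)


def local_var(params: ModelParams, x: State, delta_t: float) -> VAR1Model:
    """VAR(1) with the diffusion frozen at state ``x`` (weakly multiplicative
    noise treated as locally additive); Sigma via the quadrature route."""
    a, b, c = discretize_transition(params, delta_t)
    Sigma = residual_covariance_quadrature(
        jacobian(params), diffusion(x, params), delta_t
    )
    return VAR1Model(b=b, c=c, a=a, Sigma=Sigma, h=params.p * delta_t)
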