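"""Weidlich-type leader/follower opinion dynamics at the diffusion level.

Two groups — ``n1`` leaders and ``n2`` followers — each hold one of two
opinions.  Leaders flip intrinsically (rates ``3p/4`` and ``p/4``); followers
additionally imitate the leaders with coupling strength ``mu``.  In the
large-group (thermodynamic) limit the master equation for the opinion counts
becomes a Fokker-Planck equation for the opinion imbalances

    x_i = y_{i,2} - y_{i,1}  in  [-1, 1],

with linear drift

    D1(x) = -p (x1 - 1/2),
    D2(x) = -p (x2 + 1/2 + mu (x2 - x1)),

and diagonal, weakly state-dependent diffusion

    D11 = (p/n1) (2 - x1),
    D22 = (p/n2) (2 + x2 + 2 mu (1 - x1 x2)).

The coupling enters both the drift (synchronising force) and the diffusion
(noise amplification), which is the mechanism behind the residual predictive
information flow in the tight-coupling limit that this package quantifies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "MU_FINITE_MAX",
    "ModelParams",
    "OpinionConfig",
    "State",
    "Diffusivities",
    "transition_rates",
    "drift",
    "diffusion",
    "jacobian",
    "stationary_means",
    "mean_diffusivities",
]

#: Finite-mu routines reject couplings above this to avoid silent overflow of
#: exp(-mu*h) terms; the mu -> infinity limit has its own dedicated API.
MU_FINITE_MAX = 1e6


@dataclass(frozen=True)
class ModelParams:
    """Parameter set of the leader/follower model.

    Parameters
    ----------
    p : float
        Intrinsic opinion-flip rate (1/time), > 0.
    n1, n2 : int
        Leader / follower group sizes, >= 1.
    mu : float
        Coupling strength (dimensionless), >= 0.  ``math.inf`` is accepted as
        a marker for the tight-coupling limit but is only honoured by the
        dedicated limit operations; every finite-mu routine rejects it.
    """

    p: float = 1.0
    n1: int = 100
    n2: int = 10_000
    mu: float = 0.0

    def __post_init__(self) -> None:
        if not (self.p > 0 and math.isfinite(self.p)):
            raise ValueError(f"p must be finite and > 0, got {self.p}")
        if not (isinstance(self.n1, (int, np.integer)) and self.n1 >= 1):
            raise ValueError(f"n1 must be an integer >= 1, got {self.n1}")
        if not (isinstance(self.n2, (int, np.integer)) and self.n2 >= 1):
            raise ValueError(f"n2 must be an integer >= 1, got {self.n2}")
        if not (self.mu >= 0):
            raise ValueError(f"mu must be >= 0, got {self.mu}")

    @property
    def eps(self) -> float:
        """Leader-to-follower group-size ratio n1/n2."""
        return self.n1 / self.n2

    @property
    def mu_is_finite(self) -> bool:
        return math.isfinite(self.mu)


def _require_finite_mu(params: ModelParams) -> None:
    if not params.mu_is_finite or params.mu > MU_FINITE_MAX:
        raise ValueError(
            f"mu={params.mu} is out of range for finite-coupling routines "
            f"(must be finite and <= {MU_FINITE_MAX}); use the tight-coupling "
            "limit API in resgc.gc_analytic instead"
        )


@dataclass(frozen=True)
class OpinionConfig:
    """Group-opinion fractions y_{i,j}; each group's fractions sum to one."""

    y11: float
    y12: float
    y21: float
    y22: float

    def __post_init__(self) -> None:
        for name in ("y11", "y12", "y21", "y22"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if abs(self.y11 + self.y12 - 1.0) > 1e-12:
            raise ValueError(f"y11 + y12 = {self.y11 + self.y12} != 1")
        if abs(self.y21 + self.y22 - 1.0) > 1e-12:
            raise ValueError(f"y21 + y22 = {self.y21 + self.y22} != 1")


@dataclass(frozen=True)
class State:
    """Opinion imbalances x_i = y_{i,2} - y_{i,1}, each in [-1, 1]."""

    x1: float
    x2: float

    def __post_init__(self) -> None:
        if not (-1.0 <= self.x1 <= 1.0 and -1.0 <= self.x2 <= 1.0):
            raise ValueError(f"state ({self.x1}, {self.x2}) outside [-1, 1]^2")

    def as_array(self) -> np.ndarray:
        return np.array([self.x1, self.x2])


@dataclass(frozen=True)
class Diffusivities:
    """State-averaged diffusivities (1/time); sigma2_sq grows linearly in mu."""

    sigma1_sq: float
    sigma2_sq: float


def transition_rates(
    cfg: OpinionConfig, params: ModelParams
) -> tuple[float, float, float, float]:
    """Per-capita opinion-flip rates (leader 1->2, leader 2->1, follower 1->2,
    follower 2->1).

    Leaders flip independently of the followers; followers imitate leaders,
    their flip rate toward opinion j being boosted by ``mu * p * y1j``.
    """
    _require_finite_mu(params)
    p, mu = params.p, params.mu
    return (
        0.75 * p,
        0.25 * p,
        0.25 * p + mu * p * cfg.y12,
        0.75 * p + mu * p * cfg.y11,
    )


def drift(x: State, params: ModelParams) -> np.ndarray:
    """Drift vector of the Fokker-Planck equation at state ``x``.

    The leader component relaxes toward 1/2 independently of the followers;
    the follower component is pulled toward the leader imbalance with
    strength ``mu``.
    """
    _require_finite_mu(params)
    p, mu = params.p, params.mu
    return np.array(
        [
            -p * (x.x1 - 0.5),
            -p * (x.x2 + 0.5 + mu * (x.x2 - x.x1)),
        ]
    )


def diffusion(x: State, params: ModelParams) -> np.ndarray:
    """Diagonal diffusion matrix at state ``x``.

    Entries scale with 1/n1 and 1/n2 (demographic noise) and the follower
    entry grows linearly with the coupling ``mu``.  Positive definite on
    [-1, 1]^2.
    """
    _require_finite_mu(params)
    p, mu = params.p, params.mu
    d11 = (p / params.n1) * (2.0 - x.x1)
    d22 = (p / params.n2) * (2.0 + x.x2 + 2.0 * mu * (1.0 - x.x1 * x.x2))
    return np.diag([d11, d22])


def jacobian(params: ModelParams) -> np.ndarray:
    """Jacobian of the drift; constant because the drift is linear.

    Gamma = p * [[-1, 0], [mu, -(1+mu)]], lower triangular with eigenvalues
    -p and -p(1+mu): the dynamics is stable for every mu >= 0.
    """
    _require_finite_mu(params)
    p, mu = params.p, params.mu
    return p * np.array([[-1.0, 0.0], [mu, -(1.0 + mu)]])


def stationary_means(params: ModelParams) -> tuple[float, float]:
    """Fixed point of the drift: (<x1>, <x2>) = (1/2, (mu-1)/(2(mu+1))).

    Accepts the ``mu = inf`` marker, for which the follower mean approaches
    the leader mean 1/2 (complete mean-level synchronisation).
    """
    if not params.mu_is_finite:
        return 0.5, 0.5
    mu = params.mu
    return 0.5, 0.5 * (mu - 1.0) / (mu + 1.0)


def mean_diffusivities(params: ModelParams) -> Diffusivities:
    """Diffusivities with the stationary means substituted for the state.

    sigma1^2 = (3/2) p / n1                          (mu-independent),
    sigma2^2 = (p / n2) (3 mu^2 + 10 mu + 3) / (2 (mu + 1)).

    At mu = 0, sigma2^2 = eps * sigma1^2 when p is shared; for large mu,
    sigma2^2 ~ (3/2) (p/n2) mu — the linear noise amplification that
    sustains the residual Granger causality.
    """
    _require_finite_mu(params)
    p, mu = params.p, params.mu
    s1 = 1.5 * p / params.n1
    s2 = (p / params.n2) * 0.5 * (3.0 * mu**2 + 10.0 * mu + 3.0) / (mu + 1.0)
    return Diffusivities(sigma1_sq=s1, sigma2_sq=s2)
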