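"""Closed-form Granger causality of the triangular VAR(1) and its
tight-coupling asymptotics.

For X_t = [[b, 0], [c, a]] X_{t-1} + theta_t with residual covariance Sigma,
the driver->driven Granger causality depends only on the effective
coefficients

    b' = b - (Sigma12 / Sigma22) c,
    c'^2 = (det Sigma / Sigma22^2) c^2,

which absorb the residual correlation, and equals

    GC = ln[ (S + sqrt(S^2 - 4 b'^2)) / 2 ],    S = 1 + b'^2 + c'^2,

a generalisation of Barnett & Seth's identity-covariance formula.  The
equivalent spectral form is the Kolmogorov mean log-spectrum of the driven
component,

    GC = (1/pi) int_0^pi ln[(1 + b'^2 + c'^2 - 2 b' cos w) /
                            (1 + b'^2 - 2 b' cos w)] dw.

In the tight-coupling limit mu -> inf the residual covariance degenerates
toward the rank-one synchronised matrix but keeps a second finite semi-axis
of order eta = eps / (2 (1 - e^{-2h})); the surviving effective coefficients
give a strictly positive residual GC whenever eps = n1/n2 > 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.integrate import quad

from .model_core import ModelParams
from .var_map import VAR1Model, var1_from_params

__all__ = [
    "GCResult",
    "LimitSpectrum",
    "effective_coefficients",
    "gc_closed",
    "gc_spectral",
    "gc_curve",
    "default_mu_grid",
    "limit_covariance",
    "limit_eigenvalues",
    "limit_coefficients",
    "gc_asymptotic",
    "variance_ratio",
    "curve_peak",
    "CurvePeak",
]


@dataclass(frozen=True)
class GCResult:
    """A Granger-causality value together with the coefficients and route
    that produced it."""

    gc: float
    b_eff: float
    c_eff: float
    method: str


@dataclass(frozen=True)
class LimitSpectrum:
    """Eigenvalues (in units of Sigma11) of the mu->inf residual covariance."""

    eta: float
    lambda1: float
    lambda2: float


def effective_coefficients(model: VAR1Model) -> tuple[float, float]:
    """Effective (b', c') absorbing the residual correlation of ``model``.

    Requires the triangular model (d = 0) and a nonsingular Sigma22.
    c' is reported nonnegative; GC depends on c' only through c'^2.
    """
    if model.d != 0.0:
        raise ValueError("effective coefficients are defined for d = 0 only")
    S = model.Sigma
    s22 = S[1, 1]
    if s22 <= 0 or not np.isfinite(s22):
        raise ValueError(f"Sigma22 = {s22} is not positive")
    det = float(np.linalg.det(S))
    if det < 0 and det > -1e-15 * s22 * S[0, 0]:
        det = 0.0  # clip tiny negative round-off of a PSD matrix
    if det < 0:
        raise ValueError("Sigma is not positive semidefinite")
    b_eff = model.b - (S[0, 1] / s22) * model.c
    c_eff = math.sqrt(det) / s22 * abs(model.c)
    return b_eff, c_eff


def gc_closed(b_eff: float, c_eff: float) -> float:
    """Closed-form GC in nats; zero exactly iff c_eff = 0."""
    if abs(b_eff) >= 1.0:
        raise ValueError(f"|b_eff| = {abs(b_eff)} >= 1 violates stationarity")
    if c_eff == 0.0:
        return 0.0
    s = 1.0 + b_eff**2 + c_eff**2
    return math.log(0.5 * (s + math.sqrt(s * s - 4.0 * b_eff**2)))


def gc_spectral(b_eff: float, c_eff: float) -> float:
    """GC by numerical quadrature of the mean log-spectrum (oracle for
    :func:`gc_closed`)."""
    if abs(b_eff) >= 1.0:
        raise ValueError(f"|b_eff| = {abs(b_eff)} >= 1 violates stationarity")
    s_full = 1.0 + b_eff**2 + c_eff**2
    s_red = 1.0 + b_eff**2

    def integrand(w: float) -> float:
        cw = 2.0 * b_eff * math.cos(w)
        return math.log((s_full - cw) / (s_red - cw))

    val, _ = quad(integrand, 0.0, math.pi, epsabs=1e-12, epsrel=1e-12, limit=200)
    return val / math.pi


def default_mu_grid(mu_max: float = 100.0) -> np.ndarray:
    """Hybrid linear+geometric coupling grid on [0, mu_max]."""
    lin = np.linspace(0.0, 10.0, 41)
    geo = np.geomspace(10.0, mu_max, 25)
    return np.unique(np.concatenate([lin, geo]))


def gc_curve(
    params_base: ModelParams,
    delta_t: float,
    mu_grid: Iterable[float] | None = None,
) -> pd.DataFrame:
    """Analytic GC versus coupling strength.

    For each mu the pipeline is: state-averaged diffusivities -> exact VAR(1)
    (transition + closed-form Sigma) -> effective coefficients -> closed-form
    GC.  Returns a DataFrame with columns ``mu``, ``gc``, ``b_eff``,
    ``c_eff``.
    """
    if mu_grid is None:
        mu_grid = default_mu_grid()
    mu_grid = np.asarray(list(mu_grid), dtype=float)
    if mu_grid.size == 0:
        raise ValueError("mu_grid is empty")
    if np.any(~np.isfinite(mu_grid)) or np.any(mu_grid < 0):
        raise ValueError("mu_grid must be finite and non-negative")
    rows = []
    for mu in mu_grid:
        params = ModelParams(p=params_base.p, n1=params_base.n1,
                             n2=params_base.n2, mu=float(mu))
        model = var1_from_params(params, delta_t)
        b_eff, c_eff = effective_coefficients(model)
        rows.append((mu, gc_closed(b_eff, c_eff), b_eff, c_eff))
    return pd.DataFrame(rows, columns=["mu", "gc", "b_eff", "c_eff"])


def limit_covariance(eps: float, h: float, Sigma11: float = 1.0) -> np.ndarray:
    """mu -> inf limit of the residual covariance.

    Sigma11 * [[1, 1], [1, 1 + eps/(1 - e^{-2h})]]: rank one (full residual
    synchronisation) only in the eps -> 0 limit.
    """
    if not (eps > 0 and h > 0):
        raise ValueError("eps and h must be > 0")
    extra = eps / (1.0 - math.exp(-2.0 * h))
    return Sigma11 * np.array([[1.0, 1.0], [1.0, 1.0 + extra]])


def limit_eigenvalues(eta: float) -> LimitSpectrum:
    """Eigenvalues (1 + eta +- sqrt(1 + eta^2)) of the limiting covariance,
    in units of Sigma11; ~ (2 + eta, eta) for small eta."""
    if eta < 0:
        raise ValueError("eta must be >= 0")
    root = math.sqrt(1.0 + eta * eta)
    return LimitSpectrum(eta=eta, lambda1=1.0 + eta + root, lambda2=1.0 + eta - root)


def limit_coefficients(eps: float, h: float) -> tuple[float, float]:
    """Tight-coupling limits of the effective coefficients:

    b' -> eps e^{-h} / (1 + eps - e^{-2h}),
    c' -> sqrt(eps e^{-2h} (1 - e^{-2h})) / (1 + eps - e^{-2h}).

    Group sizes enter only through eps; both vanish as eps -> 0.
    """
    if not (eps > 0 and h > 0):
        raise ValueError("eps and h must be > 0")
    e2 = math.exp(-2.0 * h)
    den = 1.0 + eps - e2
    b_eff = eps * math.exp(-h) / den
    c_eff = math.sqrt(eps * e2 * (1.0 - e2)) / den
    return b_eff, c_eff


def gc_asymptotic(eps: float, h: float) -> float:
    """Residual GC surviving the mu -> inf limit; strictly positive for
    eps > 0."""
    return gc_closed(*limit_coefficients(eps, h))


def variance_ratio(eps: float, h: float | None = None, *,
                   leading_order: bool = False) -> float:
    """Blow-up factor Sigma22(mu->inf) / Sigma22(mu=0).

    Full expression (1/eps)(1 + eps/(1 - e^{-2h})); its dominant term for
    small eps is 1/eps (``leading_order=True``).
    """
    if not eps > 0:
        raise ValueError("eps must be > 0")
    if leading_order:
        return 1.0 / eps
    if h is None or not h > 0:
        raise ValueError("h must be > 0 unless leading_order=True")
    return (1.0 / eps) * (1.0 + eps / (1.0 - math.exp(-2.0 * h)))


@dataclass(frozen=True)
class CurvePeak:
    mu_star: float
    gc_star: float
    interior: bool


def curve_peak(curve: pd.DataFrame) -> CurvePeak:
    """Grid argmax of a GC-vs-mu table (first index wins ties); the peak is
    flagged interior when it exceeds the values at both grid endpoints."""
    if len(curve) == 0:
        raise ValueError("curve table is empty")
    gc = curve["gc"].to_numpy()
    i = int(np.argmax(gc))
    interior = bool(0 < i < len(gc) - 1 and gc[i] > gc[0] and gc[i] > gc[-1])
    return CurvePeak(
        mu_star=float(curve["mu"].iloc[i]), gc_star=float(gc[i]), interior=interior
    )
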