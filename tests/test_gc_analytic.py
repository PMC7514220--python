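"""Closed-form GC, effective coefficients, and tight-coupling asymptotics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from resgc import (
    ModelParams,
    VAR1Model,
    curve_peak,
    effective_coefficients,
    gc_asymptotic,
    gc_closed,
    gc_curve,
    gc_spectral,
    limit_coefficients,
    limit_covariance,
    limit_eigenvalues,
    var1_from_params,
    variance_ratio,
)
from conftest import random_triangular_model


def test_effective_coefficients_identity_sigma():
    m = VAR1Model(b=0.7, c=0.3, a=0.2, Sigma=np.eye(2), h=0.1)
    assert effective_coefficients(m) == pytest.approx((0.7, 0.3))


def test_effective_coefficients_zero_c():
    m = VAR1Model(b=0.7, c=0.0, a=0.2,
                  Sigma=np.array([[2.0, 0.7], [0.7, 1.5]]), h=0.1)
    b_eff, c_eff = effective_coefficients(m)
    assert b_eff == 0.7 and c_eff == 0.0
    assert gc_closed(b_eff, c_eff) == 0.0


def test_effective_coefficients_match_limit_formulas():
    """The mu->inf limit covariance with (b=c=e^{-h}, a=0) reproduces the
    closed-form limiting coefficients."""
    for eps, h in [(0.01, 0.1), (0.01, 0.145), (0.5, 0.2), (1.0, 0.145)]:
        b = math.exp(-h)
        m = VAR1Model(b=b, c=b, a=0.0, Sigma=limit_covariance(eps, h), h=h)
        got = effective_coefficients(m)
        assert got == pytest.approx(limit_coefficients(eps, h), rel=1e-9)


@pytest.mark.parametrize(
    "b_eff, c_eff, expected",
    [(0.7, 0.0, 0.0), (0.0, 1.0, math.log(2.0)), (0.5, 0.5, 0.269276)],
)
def test_gc_closed_values(b_eff, c_eff, expected):
    assert gc_closed(b_eff, c_eff) == pytest.approx(expected, abs=5e-7)


def test_gc_closed_rejects_nonstationary():
    with pytest.raises(ValueError):
        gc_closed(1.0, 0.5)
    with pytest.raises(ValueError):
        gc_spectral(-1.01, 0.5)


def test_gc_spectral_trivial_cases():
    assert gc_spectral(0.9, 0.0) == pytest.approx(0.0, abs=1e-10)
    for c in (0.3, 1.0, 2.5):
        assert gc_spectral(0.0, c) == pytest.approx(math.log(1 + c * c),
                                                    abs=1e-10)


@settings(derandomize=True, max_examples=200, deadline=None)
@given(st.floats(-0.99, 0.99), st.floats(0.0, 3.0))
def test_gc_spectral_equals_closed_form(b_eff, c_eff):
    assert abs(gc_spectral(b_eff, c_eff) - gc_closed(b_eff, c_eff)) < 1e-8


@settings(derandomize=True, max_examples=100, deadline=None)
@given(st.floats(-0.95, 0.95), st.floats(1e-6, 2.0), st.floats(1.01, 3.0))
def test_gc_strictly_increasing_in_c_eff(b_eff, c_eff, factor):
    assert gc_closed(b_eff, factor * c_eff) > gc_closed(b_eff, c_eff)


def test_gc_invariant_under_sigma_rescaling():
    rng = np.random.default_rng(7)
    for _ in range(20):
        m = random_triangular_model(rng)
        b1, c1 = effective_coefficients(m)
        m2 = VAR1Model(b=m.b, c=m.c, a=m.a, Sigma=37.5 * m.Sigma, h=m.h)
        b2, c2 = effective_coefficients(m2)
        assert (b2, c2) == pytest.approx((b1, c1), rel=1e-12)


def test_gc_nonnegative_on_random_models():
    rng = np.random.default_rng(11)
    for _ in range(100):
        m = random_triangular_model(rng)
        assert gc_closed(*effective_coefficients(m)) >= 0.0


def test_curve_zero_at_mu0_and_positive_plateau(base_params, delta_t):
    curve = gc_curve(base_params, delta_t, [0.0, 1.0, 3.0, 10.0, 100.0])
    assert curve["gc"].iloc[0] == 0.0
    assert np.all(curve["gc"].to_numpy()[1:] > 0)


def test_curve_small_eps_has_interior_maximum_above_plateau(base_params, delta_t):
    for h in (0.1, 0.145, 0.2):
        curve = gc_curve(base_params, h / base_params.p)
        peak = curve_peak(curve)
        plateau = gc_asymptotic(base_params.eps, h)
        assert peak.interior
        assert peak.gc_star > plateau > 0


@pytest.mark.parametrize("n1, n2", [(100, 100), (200, 100)])
def test_curve_large_eps_no_interior_maximum(n1, n2, delta_t):
    """Comparable or larger leader group: over the examined coupling window
    (mu up to 10) the GC rises monotonically and never exceeds the
    tight-coupling plateau; in the fine-sampling regime (h = 0.02) the same
    holds on the full default grid up to mu = 100."""
    params = ModelParams(n1=n1, n2=n2)
    window = gc_curve(params, delta_t, np.linspace(0.0, 10.0, 101))
    gc = window["gc"].to_numpy()
    plateau = gc_asymptotic(params.eps, params.p * delta_t)
    assert np.all(np.diff(gc) > 0)
    assert np.all(gc <= plateau + 1e-12)
    assert not curve_peak(window).interior
    h_fine = 0.02
    full = gc_curve(params, h_fine / params.p)
    assert np.all(full["gc"].to_numpy()
                  <= gc_asymptotic(params.eps, h_fine) + 1e-12)
    assert not curve_peak(full).interior


@pytest.mark.parametrize("n1, n2", [(100, 100), (200, 100)])
def test_curve_large_eps_shallow_overshoot_beyond_window(n1, n2, delta_t):
    """Beyond the examined window the eps >= 1 curve overshoots its plateau
    by a shallow maximum near mu ~ O(1/h) before decaying back — the
    suppression of the maximum for comparable group sizes is a property of
    the fine-sampling regime, not of the model at arbitrary coupling."""
    params = ModelParams(n1=n1, n2=n2)
    h = params.p * delta_t
    curve = gc_curve(params, delta_t, np.geomspace(10.0, 100.0, 41))
    plateau = gc_asymptotic(params.eps, h)
    excess = curve["gc"].to_numpy().max() - plateau
    assert 0 < excess < 0.2 * plateau


def test_curve_peak_monotone_curve_flagged_non_interior():
    import pandas as pd

    up = pd.DataFrame({"mu": [0, 1, 2], "gc": [0.0, 0.1, 0.2]})
    assert not curve_peak(up).interior
    assert curve_peak(up).mu_star == 2


def test_curve_rejects_bad_grid(base_params, delta_t):
    with pytest.raises(ValueError):
        gc_curve(base_params, delta_t, [])
    with pytest.raises(ValueError):
        gc_curve(base_params, delta_t, [0.0, -1.0])
    with pytest.raises(ValueError):
        gc_curve(base_params, delta_t, [0.0, math.inf])


def test_limit_covariance_values():
    L = limit_covariance(0.01, 0.1)
    assert L[0, 0] == L[0, 1] == L[1, 0] == 1.0
    assert L[1, 1] == pytest.approx(1.0 + 0.01 / (1 - math.exp(-0.2)))
    assert L[1, 1] == pytest.approx(1.05517, abs=1e-5)
    tiny = limit_covariance(1e-12, 0.1)
    assert np.linalg.det(tiny) == pytest.approx(0.0, abs=1e-10)


def test_limit_eigenvalues_values():
    s = limit_eigenvalues(0.0)
    assert (s.lambda1, s.lambda2) == (2.0, 0.0)
    s = limit_eigenvalues(0.1)
    assert (s.lambda1, s.lambda2) == pytest.approx((2.104988, 0.095012),
                                                   abs=1e-6)
    # small-eta expansion (2 + eta, eta) to first order
    s = limit_eigenvalues(0.01)
    assert s.lambda1 == pytest.approx(2.01, abs=1e-4)
    assert s.lambda2 == pytest.approx(0.01, abs=1e-4)


@pytest.mark.parametrize("h", [0.05, 0.1, 0.2])
def test_limit_eigenvalues_match_limit_covariance(h):
    eps = 0.01
    eta = eps / (2.0 * (1.0 - math.exp(-2 * h)))
    s = limit_eigenvalues(eta)
    eig = np.sort(np.linalg.eigvalsh(limit_covariance(eps, h, 1.0)))[::-1]
    assert eig == pytest.approx((s.lambda1, s.lambda2), abs=1e-12)


def test_limit_coefficients_values():
    assert limit_coefficients(0.01, 0.1) == pytest.approx(
        (0.047307, 0.201412), abs=5e-5
    )
    # group sizes enter only through eps
    assert limit_coefficients(200 / 20_000, 0.1) == limit_coefficients(
        100 / 10_000, 0.1
    )


def test_limit_coefficients_vanish_with_eps():
    b_eff, c_eff = limit_coefficients(1e-12, 0.145)
    assert b_eff < 1e-11 and c_eff < 1e-5
    assert gc_asymptotic(1e-12, 0.145) < 1e-10


@pytest.mark.parametrize("h", np.linspace(0.01, 1.0, 12).tolist())
def test_residual_gc_strictly_positive(h):
    assert gc_asymptotic(0.01, h) > 0.0


@pytest.mark.parametrize("eps, h", [(0.01, 0.1), (0.01, 0.145), (0.1, 0.2)])
def test_asymptote_matches_large_mu_curve(eps, h):
    """The finite-coupling curve approaches the analytic asymptote as O(1/mu)
    (amplified ~30x by the det-Sigma cancellation, hence the strong-coupling
    end of the admissible range)."""
    n2 = 10_000
    params = ModelParams(n1=int(eps * n2), n2=n2, mu=1e6)
    m = var1_from_params(params, h / params.p)
    gc_large = gc_closed(*effective_coefficients(m))
    assert gc_large == pytest.approx(gc_asymptotic(eps, h), rel=1e-3)


def test_variance_ratio_values():
    assert variance_ratio(0.01, leading_order=True) == pytest.approx(100.0)
    assert variance_ratio(0.01, 0.1) == pytest.approx(105.517, abs=5e-3)
    # eps = 1, long sampling interval: ratio -> 2
    assert variance_ratio(1.0, 50.0) == pytest.approx(2.0, rel=1e-12)


def test_variance_ratio_matches_covariance_ends():
    eps, h, n2 = 0.01, 0.145, 10_000
    n1 = int(eps * n2)
    s0 = var1_from_params(ModelParams(n1=n1, n2=n2, mu=0.0), h).Sigma[1, 1]
    sinf = var1_from_params(ModelParams(n1=n1, n2=n2, mu=1e5), h).Sigma[1, 1]
    assert sinf / s0 == pytest.approx(variance_ratio(eps, h), rel=1e-3)


@pytest.mark.parametrize("h", [0.05, 0.1, 0.2])
def test_limit_lag0_correlation_h_independent(h):
    """Lag-0 cross-correlation implied by the limiting covariance equals
    (1+eps)^{-1/2} for every sampling interval."""
    from resgc.crosscorr import ccf_limit

    eps = 0.01
    c = ccf_limit(eps, h, 0)
    assert c.rho[0] == pytest.approx(1.0 / math.sqrt(1.0 + eps), abs=1e-12)
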