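import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from idiovar import dynamics as dyn
from idiovar.synthetic import simulate_var, spectral_radius
from idiovar.var_model import PatientVAR

from .conftest import coupled_pair, random_stable_fit

NAMES = ("sleep", "depression")


def simulated_impulse_response(A, sigma, impulse_idx, horizon):
    """Independent oracle: shock the fitted difference equation with the
    impulse-first orthogonal shock and iterate it deterministically."""
    A = np.asarray(A)
    p, k, _ = A.shape
    perm = [impulse_idx] + [i for i in range(k) if i != impulse_idx]
    A_p = A[:, perm][:, :, perm]
    chol = np.linalg.cholesky(np.asarray(sigma)[np.ix_(perm, perm)])
    shock = chol[:, 0] / chol[0, 0]
    path = np.zeros((horizon + 1 + p, k))
    path[p] = shock
    for h in range(1, horizon + 1):
        acc = np.zeros(k)
        for lag in range(p):
            acc += A_p[lag] @ path[p + h - 1 - lag]
        path[p + h] = acc
    return path[p:]  # rows = horizons, cols = permuted variables


def test_ma_matrices_of_zero_var_are_identity_then_zero():
    phi = dyn.ma_coefficients(np.zeros((1, 2, 2)), horizon=5)
    assert np.array_equal(phi[0], np.eye(2))
    assert np.all(phi[1:] == 0.0)


def test_ma_matrices_of_var1_are_matrix_powers():
    A = np.array([[0.5, 0.2], [0.1, 0.4]])
    phi = dyn.ma_coefficients(A[None], horizon=8)
    for h in range(9):
        assert np.allclose(phi[h], np.linalg.matrix_power(A, h), atol=1e-12)


@pytest.mark.parametrize("p", [1, 2, 3])
def test_irf_equals_deterministic_simulation_oracle(p, rng):
    for _ in range(10):
        A, sigma = random_stable_fit(rng, p=p)
        for imp in (0, 1):
            resp = 1 - imp
            irf = dyn.orthogonalized_irf(
                A, sigma, NAMES, NAMES[imp], NAMES[resp], horizon=10, shock_sd=1.0
            )
            oracle = simulated_impulse_response(A, sigma, imp, 10)
            assert np.abs(irf.point - oracle[:, 1]).max() < 1e-8


def test_zero_cross_dynamics_give_zero_cross_response():
    A = np.array([[0.6, 0.0], [0.0, 0.3]])
    irf = dyn.orthogonalized_irf(
        A[None], np.diag([2.0, 0.5]), NAMES, "sleep", "depression", shock_sd=1.0
    )
    assert np.allclose(irf.point, 0.0, atol=1e-14)


def test_lag1_cross_response_is_the_cross_coefficient():
    b = 0.37
    A = np.array([[0.0, 0.0], [b, 0.0]])
    irf = dyn.orthogonalized_irf(
        A[None], np.eye(2), NAMES, "sleep", "depression", shock_sd=1.0
    )
    assert irf.point[1] == pytest.approx(b, abs=1e-12)
    assert irf.point[0] == 0.0


def test_cumulative_is_running_sum_and_tail_flattens(rng):
    for _ in range(10):
        A, sigma = random_stable_fit(rng)
        irf = dyn.orthogonalized_irf(
            A, sigma, NAMES, "sleep", "depression", horizon=10, shock_sd=1.0
        )
        assert np.allclose(irf.cumulative, np.cumsum(irf.point), atol=1e-12)
        d_early = abs(irf.cumulative[2] - irf.cumulative[1])
        d_late = abs(irf.cumulative[10] - irf.cumulative[9])
        assert d_late <= d_early + 1e-12


def test_cumulative_increments_decay_geometrically(rng):
    A, sigma = random_stable_fit(rng, p=1, max_radius=0.8)
    irf = dyn.orthogonalized_irf(
        A, sigma, NAMES, "sleep", "depression", horizon=20, shock_sd=1.0
    )
    inc = np.abs(np.diff(irf.cumulative))
    rho = spectral_radius(A)
    # beyond a short transient the increments shrink at least like ρ^h
    assert inc[15] <= inc[5] * rho**5 + 1e-10


def test_irf_shock_scaling_is_linear():
    A = np.array([[0.4, 0.1], [0.2, 0.3]])
    sigma = np.array([[1.0, 0.3], [0.3, 2.0]])
    a = dyn.orthogonalized_irf(A[None], sigma, NAMES, "sleep", "depression", shock_sd=1.0)
    b = dyn.orthogonalized_irf(A[None], sigma, NAMES, "sleep", "depression", shock_sd=3.5)
    assert np.allclose(b.point, 3.5 * a.point, atol=1e-12)
    assert b.point[0] == 0.0 if abs(a.point[0]) < 1e-15 else True


def test_fevd_zero_coupling_leaves_all_variance_own():
    A = np.diag([0.5, 0.3])[None]
    out = dyn.fevd(A, np.diag([1.0, 2.0]), NAMES, horizon=10)
    for res in out:
        assert np.allclose(res.share_from(res.target), 1.0, atol=1e-12)


@settings(max_examples=100, derandomize=True)
@given(st.integers(0, 10_000), st.integers(1, 3))
def test_fevd_shares_are_simplex_at_every_horizon(seed, p):
    rng = np.random.default_rng(seed)
    A, sigma = random_stable_fit(rng, p=p)
    for res in dyn.fevd(A, sigma, NAMES, horizon=10):
        assert np.all(res.shares >= -1e-12)
        assert np.abs(res.shares.sum(axis=1) - 1.0).max() < 1e-9


def test_first_ordered_variable_owns_horizon1_variance(rng):
    A, sigma = random_stable_fit(rng)
    res = dyn.fevd(A, sigma, NAMES, horizon=5)[0]
    assert res.shares[0, 0] == pytest.approx(1.0, abs=1e-12)


def test_fevd_matches_statsmodels(rng):
    from statsmodels.tsa.api import VAR as SMVAR

    y = simulate_var([0.5, 1.0], np.array([[[0.4, 0.15], [0.1, 0.35]]]),
                     np.array([[1.0, 0.3], [0.3, 1.5]]), 600, rng)
    fit = PatientVAR(y).fit(lags=1)
    ours = fit.fevd(horizon=10)
    sm = SMVAR(y).fit(1, trend="c").fevd(10)
    for i in range(2):
        assert np.allclose(ours[i].shares, sm.decomp[i], atol=1e-8)


def test_lag1_coupled_process_cross_share_rises_then_plateaus(rng):
    """Qualitative cohort-table shape: the cross share jumps after lag 1 and
    is flat by lag 3–4."""
    y = coupled_pair(4000, 0.4, 0.5, rng)
    fit = PatientVAR(y).fit(lags=1)
    dep_fevd = [f for f in fit.fevd(horizon=10) if f.target == "depression"][0]
    cross = dep_fevd.share_from("sleep")
    assert cross[0] < cross[1] <= cross[2] + 1e-9
    assert abs(cross[9] - cross[3]) < 0.01


def _fitted(rng, n=300, b=0.4):
    y = coupled_pair(n, b, 0.5, rng)
    return PatientVAR(y).fit(lags=1)


def test_bootstrap_bands_deterministic_under_seed(rng):
    fit = _fitted(rng)
    a = fit.irf("sleep", "depression", bands=True, runs=100, seed=5)
    b = fit.irf("sleep", "depression", bands=True, runs=100, seed=5)
    assert np.array_equal(a.lower, b.lower) and np.array_equal(a.upper, b.upper)


def test_band_contains_point_estimate_everywhere(rng):
    fit = _fitted(rng)
    irf = fit.irf("sleep", "depression", bands=True, runs=200, seed=9)
    assert np.all(irf.lower <= irf.point) and np.all(irf.point <= irf.upper)
    assert np.all(irf.cum_lower <= irf.cumulative)
    assert np.all(irf.cumulative <= irf.cum_upper)
    assert 1 in irf.significant_horizons()  # strong lag-1 coupling


def test_band_width_shrinks_with_sample_size():
    rng = np.random.default_rng(77)
    wide = _fitted(rng, n=150).irf("sleep", "depression", bands=True, runs=300, seed=1)
    narrow = _fitted(rng, n=1500).irf("sleep", "depression", bands=True, runs=300, seed=1)
    w_wide = (wide.upper - wide.lower)[1:4].mean()
    w_narrow = (narrow.upper - narrow.lower)[1:4].mean()
    assert w_narrow < w_wide


def test_near_diagonal_covariance_makes_ordering_immaterial():
    A = np.array([[0.4, 0.1], [0.2, 0.3]])
    sigma = np.array([[1.0, 1e-6], [1e-6, 2.0]])
    fwd = dyn.orthogonalized_irf(A[None], sigma, NAMES, "sleep", "depression",
                                 shock_sd=1.0, ordering=("sleep", "depression"))
    rev = dyn.orthogonalized_irf(A[None], sigma, NAMES, "sleep", "depression",
                                 shock_sd=1.0, ordering=("depression", "sleep"))
    assert np.abs(fwd.point - rev.point).max() < 1e-5


def test_nonspd_covariance_rejected():
    with pytest.raises(ValueError, match="positive definite"):
        dyn.orthogonalized_irf(
            np.zeros((1, 2, 2)), np.array([[1.0, 2.0], [2.0, 1.0]]),
            NAMES, "sleep", "depression",
        )


def test_unstable_fit_warns_on_ma_recursion(rng):
    y = coupled_pair(200, 0.3, 0.5, rng)
    fit = PatientVAR(y).fit(lags=1)
    fit.coef_matrices = np.eye(2)[None] * 1.01
    with pytest.warns(UserWarning, match="stable"):
        fit.ma_coefficients(horizon=5)
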