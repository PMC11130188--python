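"""Conjugate conditional samplers, label-switching handling, and the chain."""

import numpy as np
import pytest
from scipy import stats

from sanfilippopred import (
    GibbsConfig,
    GibbsState,
    PosteriorDraws,
    PriorSpec,
    default_priors,
    enforce_weight_order,
    init_state,
    run_gibbs,
    sample_assignments,
    sample_covariances,
    sample_means,
    sample_weights,
    summarize_posterior,
)
from sanfilippopred.errors import ConfigError, DataError
from sanfilippopred.gibbs import load_draws, responsibilities_from_state, save_draws

from conftest import SHORT_CHAIN


# ---------------------------------------------------------------------------
# priors


def test_default_priors_match_data_moments():
    rng = np.random.default_rng(0)
    X = rng.standard_normal((10_000, 2))
    pr = default_priors(X)
    assert np.abs(pr.eta).max() < 0.05
    assert np.abs(pr.psi - np.eye(2)).max() < 0.05
    np.testing.assert_allclose(pr.tau, 10 * pr.psi)
    assert pr.nu == 2
    np.testing.assert_array_equal(pr.alpha, [1.0, 1.0])


def test_default_priors_nu_equals_dimension():
    X = np.random.default_rng(1).random((50, 8))
    assert default_priors(X).nu == 8


def test_default_priors_jitters_singular_covariance():
    rng = np.random.default_rng(2)
    X = np.column_stack([rng.standard_normal(30), np.full(30, 3.0)])
    pr = default_priors(X)
    np.linalg.cholesky(pr.psi)  # must not raise
    pr.validate()


def test_default_priors_requires_more_rows_than_columns():
    with pytest.raises(DataError):
        default_priors(np.zeros((3, 5)))


def test_prior_spec_validation():
    with pytest.raises(ConfigError):
        PriorSpec(
            alpha=np.ones(2), eta=np.zeros(2), tau=np.eye(2), nu=1.0, psi=np.eye(2)
        ).validate()
    with pytest.raises(ConfigError):
        PriorSpec(
            alpha=np.ones(2),
            eta=np.zeros(2),
            tau=-np.eye(2),
            nu=2.0,
            psi=np.eye(2),
        ).validate()


# ---------------------------------------------------------------------------
# conditional samplers vs closed forms


def _state_1d(omega, mus, var):
    return GibbsState(
        z=np.array([1]),
        omega=np.asarray(omega, dtype=float),
        mu=np.array([[mus[0]], [mus[1]]], dtype=float),
        sigma=np.array([[[var]], [[var]]], dtype=float),
    )


def test_assignment_responsibility_closed_form():
    """1D, equal weights, means 0 and 4, unit variance, x=1:
    P(z=1) = 1 / (1 + exp(-4))."""
    st = _state_1d((0.5, 0.5), (0.0, 4.0), 1.0)
    resp = responsibilities_from_state(np.array([[1.0]]), st.omega, st.mu, st.sigma)
    assert resp[0, 0] == pytest.approx(1.0 / (1.0 + np.exp(-4.0)), abs=1e-12)


def test_assignment_symmetry(rng):
    st = _state_1d((0.5, 0.5), (2.0, 2.0), 1.0)
    X = np.full((10_000, 1), 2.0)
    z = sample_assignments(X, st, rng)
    assert (z == 1).mean() == pytest.approx(0.5, abs=0.02)


def test_assignment_near_certain(rng):
    st = _state_1d((0.5, 0.5), (0.0, 100.0), 1e-4)
    X = np.zeros((10_000, 1))
    z = sample_assignments(X, st, rng)
    assert (z == 1).mean() > 0.999


def test_assignment_consumes_one_variate_per_row_in_order():
    st = _state_1d((0.5, 0.5), (0.0, 4.0), 1.0)
    X = np.array([[1.0], [3.0], [2.0]])
    z1 = sample_assignments(X, st, np.random.default_rng(42))
    resp = responsibilities_from_state(X, st.omega, st.mu, st.sigma)
    u = np.random.default_rng(42).random(3)
    np.testing.assert_array_equal(z1, np.where(u < resp[:, 0], 1, 2))


def test_weights_posterior_dirichlet_moment(rng):
    """n = (10, 30), alpha = (1, 1): E[omega_1] = 11/42."""
    z = np.r_[np.ones(10), np.full(30, 2)].astype(int)
    draws = np.array([sample_weights(z, np.ones(2), rng) for _ in range(100_000)])
    assert draws[:, 0].mean() == pytest.approx(11 / 42, abs=0.005)


def test_weights_symmetric_case(rng):
    z = np.r_[np.ones(20), np.full(20, 2)].astype(int)
    draws = np.array([sample_weights(z, np.ones(2), rng) for _ in range(100_000)])
    assert draws[:, 0].mean() == pytest.approx(0.5, abs=0.005)


def test_means_conjugate_closed_form_1d(rng):
    """Prior N(0, 10), n_k=10 observations with mean 5, sigma^2=1:
    posterior mean 50/10.1, variance 1/10.1."""
    pr = PriorSpec(
        alpha=np.ones(2),
        eta=np.zeros(1),
        tau=np.array([[10.0]]),
        nu=1.0,
        psi=np.eye(1),
    )
    X = np.full((10, 1), 5.0)
    z = np.ones(10, dtype=int)  # all in cluster 1; cluster 2 empty
    sigma = np.array([np.eye(1), np.eye(1)])
    draws = np.array(
        [sample_means(X, z, sigma, pr, rng)[0, 0] for _ in range(10_000)]
    )
    assert draws.mean() == pytest.approx(50 / 10.1, abs=4 * np.sqrt(1 / 10.1 / 10_000) * 3)
    assert draws.var() == pytest.approx(1 / 10.1, rel=0.08)


def test_means_empty_cluster_draws_from_prior(rng):
    pr = PriorSpec(
        alpha=np.ones(2),
        eta=np.array([3.0]),
        tau=np.array([[4.0]]),
        nu=1.0,
        psi=np.eye(1),
    )
    X = np.full((10, 1), 5.0)
    z = np.ones(10, dtype=int)
    sigma = np.array([np.eye(1), np.eye(1)])
    draws = np.array(
        [sample_means(X, z, sigma, pr, rng)[1, 0] for _ in range(10_000)]
    )
    # KS test against the prior N(3, 4)
    p = stats.kstest(draws, stats.norm(loc=3.0, scale=2.0).cdf).pvalue
    assert p > 0.01


def test_means_concentrate_with_sample_size(rng):
    pr = PriorSpec(
        alpha=np.ones(2),
        eta=np.zeros(1),
        tau=np.array([[10.0]]),
        nu=1.0,
        psi=np.eye(1),
    )
    sigma = np.array([np.eye(1), np.eye(1)])
    sds = []
    for n_k in (100, 10_000):
        X = np.full((n_k, 1), 2.0)
        z = np.ones(n_k, dtype=int)
        d = np.array(
            [sample_means(X, z, sigma, pr, rng)[0, 0] for _ in range(2000)]
        )
        assert d.mean() == pytest.approx(2.0, abs=0.05)
        sds.append(d.std())
    assert sds[1] < sds[0] / 5  # ~ sqrt(100) shrink, allow MC slack


def test_covariances_prior_moment_and_spd(rng):
    """Empty cluster: E[Sigma] = Psi / (nu - p - 1) for nu > p + 1."""
    psi = np.array([[2.0, 0.3], [0.3, 1.0]])
    pr = PriorSpec(
        alpha=np.ones(2), eta=np.zeros(2), tau=np.eye(2), nu=5.0, psi=psi
    )
    X = np.zeros((6, 2))
    z = np.ones(6, dtype=int)
    mu = np.zeros((2, 2))
    draws = np.stack(
        [sample_covariances(X, z, mu, pr, rng)[1] for _ in range(10_000)]
    )
    np.testing.assert_allclose(draws.mean(axis=0), psi / 2.0, rtol=0.05)
    for s in draws[:200]:
        np.linalg.cholesky(s)


def test_covariances_1d_inverse_gamma_mean(rng):
    """p=1 reduces to InvGamma(nu/2, psi/2): mean psi / (nu - 2)."""
    pr = PriorSpec(
        alpha=np.ones(2),
        eta=np.zeros(1),
        tau=np.eye(1),
        nu=6.0,
        psi=np.array([[3.0]]),
    )
    X = np.zeros((4, 1))
    z = np.ones(4, dtype=int)
    mu = np.zeros((2, 1))
    draws = np.array(
        [sample_covariances(X, z, mu, pr, rng)[1, 0, 0] for _ in range(10_000)]
    )
    assert draws.mean() == pytest.approx(3.0 / 4.0, rel=0.05)


# ---------------------------------------------------------------------------
# label switching


def _draws(omega, mu):
    omega = np.asarray(omega, dtype=float)[None, :]
    mu = np.asarray(mu, dtype=float)[None, :, :]
    sigma = np.stack([np.eye(mu.shape[2])] * 2)[None, :, :, :]
    return PosteriorDraws(omega=omega, mu=mu, sigma=sigma, features=("revel",))


def test_weight_order_swaps_full_block():
    d = _draws([0.7, 0.3], [[1.0], [2.0]])
    out = enforce_weight_order(d)
    np.testing.assert_array_equal(out.omega[0], [0.3, 0.7])
    np.testing.assert_array_equal(out.mu[0], [[2.0], [1.0]])


def test_weight_order_identity_when_ordered():
    d = _draws([0.3, 0.7], [[1.0], [2.0]])
    out = enforce_weight_order(d)
    np.testing.assert_array_equal(out.omega[0], [0.3, 0.7])
    np.testing.assert_array_equal(out.mu[0], [[1.0], [2.0]])


def test_weight_tie_broken_by_anchor_feature():
    # benign must carry the lower anchor (REVEL) mean
    d = _draws([0.5, 0.5], [[0.9], [0.2]])
    out = enforce_weight_order(d)
    np.testing.assert_array_equal(out.mu[0], [[0.2], [0.9]])


# ---------------------------------------------------------------------------
# initialization and the full chain


def test_init_state_deterministic():
    X = np.random.default_rng(3).standard_normal((40, 2))
    pr = default_priors(X)
    cfg = GibbsConfig(seed=5, **SHORT_CHAIN)
    a = init_state(X, pr, cfg, np.random.default_rng(5))
    b = init_state(X, pr, cfg, np.random.default_rng(5))
    np.testing.assert_array_equal(a.z, b.z)
    np.testing.assert_array_equal(a.mu, b.mu)


def test_init_state_both_clusters_populated():
    X = np.random.default_rng(4).standard_normal((10, 1))
    pr = default_priors(X)
    st = init_state(X, pr, GibbsConfig(seed=1, **SHORT_CHAIN))
    assert {1, 2} <= set(st.z)
    assert min((st.z == 1).sum(), (st.z == 2).sum()) >= 3  # p + 2


def test_kmeans_init_recovers_separated_blobs():
    rng = np.random.default_rng(6)
    X = np.vstack(
        [rng.standard_normal((120, 2)), rng.standard_normal((120, 2)) + 8.0]
    )
    truth = np.r_[np.ones(120), np.full(120, 2)]
    pr = default_priors(X)
    cfg = GibbsConfig(seed=0, init="kmeans", **SHORT_CHAIN)
    st = init_state(X, pr, cfg)
    agree = max((st.z == truth).mean(), (st.z == 3 - truth).mean())
    assert agree >= 0.95


def test_run_gibbs_recovers_two_blob_parameters():
    rng = np.random.default_rng(7)
    n = 400
    comp = rng.random(n) < 0.35
    X = np.where(
        comp[:, None], rng.standard_normal((n, 2)), rng.standard_normal((n, 2)) + 6.0
    )
    cfg = GibbsConfig(n_iter=2000, burn_in=500, thin=3, seed=8)
    draws = run_gibbs(X, default_priors(X), cfg)
    om = draws.omega.mean(axis=0)
    mu = draws.mu.mean(axis=0)
    assert om[0] == pytest.approx(comp.mean(), abs=0.05)
    assert np.abs(mu[0] - 0.0).max() < 0.3
    assert np.abs(mu[1] - 6.0).max() < 0.3


def test_run_gibbs_deterministic_under_seed():
    X = np.random.default_rng(9).standard_normal((60, 2)) * 2
    cfg = GibbsConfig(n_iter=300, burn_in=100, thin=2, seed=13)
    a = run_gibbs(X, default_priors(X), cfg)
    b = run_gibbs(X, default_priors(X), cfg)
    np.testing.assert_array_equal(a.omega, b.omega)
    np.testing.assert_array_equal(a.sigma, b.sigma)


def test_retained_draw_invariants(fitted_draws):
    d = fitted_draws
    np.testing.assert_allclose(d.omega.sum(axis=1), 1.0, atol=1e-12)
    assert (d.omega[:, 0] < d.omega[:, 1]).all() or (
        (d.omega[:, 0] <= d.omega[:, 1]).all()
    )
    for m in range(0, d.M, max(1, d.M // 25)):
        for k in range(2):
            np.linalg.cholesky(d.sigma[m, k])


def test_run_gibbs_rejects_missing_and_small_n():
    X = np.random.default_rng(10).standard_normal((30, 2))
    Xm = X.copy()
    Xm[0, 0] = np.nan
    with pytest.raises(DataError, match="impute"):
        run_gibbs(Xm, cfg=GibbsConfig(n_iter=50, burn_in=10, thin=1, seed=0))
    with pytest.raises(DataError):
        run_gibbs(
            X[:8], cfg=GibbsConfig(n_iter=50, burn_in=10, thin=1, seed=0)
        )


def test_row_permutation_leaves_posterior_means_stable():
    rng = np.random.default_rng(11)
    n = 200
    comp = rng.random(n) < 0.4
    X = np.where(
        comp[:, None], rng.standard_normal((n, 2)), rng.standard_normal((n, 2)) + 5.0
    )
    cfg = GibbsConfig(n_iter=1500, burn_in=500, thin=2, seed=3)
    a = run_gibbs(X, default_priors(X), cfg)
    perm = np.random.default_rng(12).permutation(n)
    b = run_gibbs(X[perm], default_priors(X[perm]), cfg)
    # exchangeability up to Monte-Carlo noise
    se = a.mu.std(axis=0, ddof=1) / np.sqrt(a.M / 10)  # autocorrelation slack
    tol = np.maximum(3 * se, 0.05)
    assert (np.abs(a.mu.mean(axis=0) - b.mu.mean(axis=0)) < tol).all()


# ---------------------------------------------------------------------------
# posterior summaries and serialization


def test_summary_degenerate_posterior():
    omega = np.tile([0.3, 0.7], (50, 1))
    mu = np.tile([[1.0], [2.0]], (50, 1, 1))
    sigma = np.tile(np.eye(1), (50, 2, 1, 1))
    d = PosteriorDraws(omega=omega, mu=mu, sigma=sigma, features=("cadd",))
    s = summarize_posterior(d)
    assert s.weight_stats[0, 1] == pytest.approx(0.0, abs=1e-12)  # SD
    assert s.weight_stats[0, 2] == s.weight_stats[0, 3] == s.weight_stats[0, 4] == 0.3


def test_summary_normal_quantiles():
    rng = np.random.default_rng(13)
    M = 100_000
    omega = np.tile([0.4, 0.6], (M, 1))
    mu = np.zeros((M, 2, 1))
    mu[:, 0, 0] = rng.standard_normal(M)
    sigma = np.tile(np.eye(1), (M, 2, 1, 1))
    s = summarize_posterior(
        PosteriorDraws(omega=omega, mu=mu, sigma=sigma, features=("cadd",))
    )
    q = s.mean_stats[0, 0]
    assert q[2] == pytest.approx(-1.96, abs=0.02)
    assert q[3] == pytest.approx(0.0, abs=0.02)
    assert q[4] == pytest.approx(1.96, abs=0.02)


def test_summary_table_layout(fitted_draws):
    s = summarize_posterior(fitted_draws)
    assert set(s.table.columns) == {
        "cluster",
        "parameter",
        "mean",
        "sd",
        "q2.5",
        "q50",
        "q97.5",
    }
    assert set(s.table["cluster"]) == {"benign", "pathogenic"}
    # weight + 8 feature means per cluster
    assert len(s.table) == 2 * (1 + 8)
    assert (s.table["q2.5"] <= s.table["q50"]).all()
    assert (s.table["q50"] <= s.table["q97.5"]).all()


def test_summary_requires_minimum_draws():
    omega = np.tile([0.4, 0.6], (10, 1))
    d = PosteriorDraws(
        omega=omega,
        mu=np.zeros((10, 2, 1)),
        sigma=np.tile(np.eye(1), (10, 2, 1, 1)),
    )
    with pytest.raises(DataError):
        summarize_posterior(d)


def test_draws_round_trip_serialization(tmp_path, fitted_draws):
    path = tmp_path / "post.npz"
    save_draws(fitted_draws, path)
    back = load_draws(path)
    np.testing.assert_array_equal(back.omega, fitted_draws.omega)
    np.testing.assert_array_equal(back.mu, fitted_draws.mu)
    np.testing.assert_array_equal(back.sigma, fitted_draws.sigma)
    assert back.features == fitted_draws.features
    assert back.config.seed == fitted_draws.config.seed
    np.testing.assert_allclose(back.priors.psi, fitted_draws.priors.psi)
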