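"""Two-component Bayesian Gaussian mixture fitted by Gibbs sampling.

Model
-----
Each variant's score vector ``x_i`` (length p) is modelled as a draw from a
two-component multivariate normal mixture,

    x_i | z_i = k  ~  N(mu_k, Sigma_k),      P(z_i = k) = omega_k,

with conjugate priors

    (omega_1, omega_2) ~ Dirichlet(1, 1)
    mu_k               ~ N(eta, tau)
    Sigma_k            ~ Inverse-Wishart(nu, Psi)

where by default ``eta`` is the data mean vector, ``tau`` the data
covariance scaled by 10 (a weak prior on cluster means), ``nu = p`` and
``Psi`` the data covariance. The Gibbs sampler cycles the full
conditionals: component assignments (categorical, proportional to
``omega_k N(x_i; mu_k, Sigma_k)``, computed in log space), weights
(Dirichlet), means (multivariate-normal conjugate update) and covariances
(inverse-Wishart conjugate update).

Mixture likelihoods are invariant to relabelling the components; draws are
made identifiable by enforcing ``omega_1 < omega_2`` in every retained draw
(swapping the full parameter block when violated), under the modelling
assumption that the benign cluster is the smaller one: cluster 1 = benign,
cluster 2 = pathogenic. An exact tie is broken by the posterior mean of an
anchor feature (REVEL by default; benign = lower).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
import numpy as np
from scipy import linalg
from scipy.special import logsumexp
from scipy.stats import invwishart
from sklearn.base import BaseEstimator

from .errors import ConfigError, DataError, NumericalError

_LOG_2PI = float(np.log(2.0 * np.pi))


# ---------------------------------------------------------------------------
# configuration containers


@dataclass
class PriorSpec:
    """Hyperparameters of the conjugate prior.

    alpha : (2,) Dirichlet concentrations for the cluster weights.
    eta : (p,) prior mean of the cluster means.
    tau : (p, p) prior covariance of the cluster means (SPD).
    nu : inverse-Wishart degrees of freedom, nu >= p.
    psi : (p, p) inverse-Wishart scale matrix (SPD).
    """

    alpha: np.ndarray
    eta: np.ndarray
    tau: np.ndarray
    nu: float
    psi: np.ndarray

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.eta = np.asarray(self.eta, dtype=float)
        self.tau = np.asarray(self.tau, dtype=float)
        self.psi = np.asarray(self.psi, dtype=float)

    def validate(self) -> None:
        p = self.eta.shape[0]
        if self.alpha.shape != (2,) or (self.alpha <= 0).any():
            raise ConfigError("alpha must be a length-2 positive vector")
        if self.tau.shape != (p, p) or self.psi.shape != (p, p):
            raise ConfigError("tau and psi must be p x p")
        if self.nu < p:
            raise ConfigError(f"nu={self.nu} must be >= p={p}")
        for name, m in (("tau", self.tau), ("psi", self.psi)):
            if not np.allclose(m, m.T):
                raise ConfigError(f"{name} must be symmetric")
            try:
                np.linalg.cholesky(m)
            except np.linalg.LinAlgError as exc:
                raise ConfigError(f"{name} must be positive definite") from exc

    @property
    def p(self) -> int:
        return self.eta.shape[0]


@dataclass
class GibbsConfig:
    """Chain settings: total sweeps, burn-in, thinning, seed, initialization."""

    n_iter: int = 20000
    burn_in: int = 5000
    thin: int = 5
    seed: int = 0
    init: str = "random"

    def validate(self) -> None:
        if self.burn_in >= self.n_iter:
            raise ConfigError("burn_in must be < n_iter")
        if self.thin < 1:
            raise ConfigError("thin must be >= 1")
        if self.init not in {"random", "kmeans"}:
            raise ConfigError("init must be 'random' or 'kmeans'")

    @property
    def n_retained(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


@dataclass
class GibbsState:
    """One sweep's parameter block: assignments, weights, means, covariances."""

    z: np.ndarray  # (n,) values in {1, 2}
    omega: np.ndarray  # (2,)
    mu: np.ndarray  # (2, p)
    sigma: np.ndarray  # (2, p, p)


@dataclass
class PosteriorDraws:
    """Retained Gibbs draws, already reordered so omega_1 < omega_2.

    Cluster 1 is the benign cluster, cluster 2 the pathogenic cluster.
    """

    omega: np.ndarray  # (M, 2)
    mu: np.ndarray  # (M, 2, p)
    sigma: np.ndarray  # (M, 2, p, p)
    features: tuple[str, ...] = ()
    priors: PriorSpec | None = None
    config: GibbsConfig | None = None

    @property
    def M(self) -> int:
        return self.omega.shape[0]

    @property
    def p(self) -> int:
        return self.mu.shape[2]


@dataclass
class ClusterSummary:
    """Posterior summaries per cluster: mean, SD, 2.5/50/97.5 percentiles.

    ``table`` is a tidy DataFrame with one row per (cluster, parameter) in
    the layout of the published centroid tables; array attributes give the
    same numbers positionally for programmatic use.
    """

    features: tuple[str, ...]
    roles: tuple[str, str]
    weight_stats: np.ndarray  # (2, 5): mean, sd, q2.5, q50, q97.5
    mean_stats: np.ndarray  # (2, p, 5)
    table: "object" = None  # pandas.DataFrame


# ---------------------------------------------------------------------------
# numerics


def _chol_logdet_and_maha(X: np.ndarray, mu: np.ndarray, sigma: np.ndarray):
    """Cholesky-based log|Sigma| and squared Mahalanobis distances of rows."""
    try:
        L = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError as exc:
        raise NumericalError("covariance not positive definite") from exc
    diff = X - mu
    sol = linalg.solve_triangular(L, diff.T, lower=True)
    return 2.0 * np.log(np.diag(L)).sum(), np.einsum("ij,ij->j", sol, sol)


def mvn_logpdf(X: np.ndarray, mu: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """Row-wise multivariate-normal log density."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    p = X.shape[1]
    logdet, maha = _chol_logdet_and_maha(X, mu, sigma)
    return -0.5 * (p * _LOG_2PI + logdet + maha)


def _ensure_spd(m: np.ndarray, ridge: float = 1e-6) -> np.ndarray:
    """Return m, jittered along the diagonal if a Cholesky fails."""
    m = 0.5 * (m + m.T)
    try:
        np.linalg.cholesky(m)
        return m
    except np.linalg.LinAlgError:
        pass
    diag = np.diag(m)
    scale = diag[diag > 0].mean() if (diag > 0).any() else 1.0
    jitter = ridge * scale
    for _ in range(12):
        try:
            np.linalg.cholesky(m + jitter * np.eye(m.shape[0]))
            return m + jitter * np.eye(m.shape[0])
        except np.linalg.LinAlgError:
            jitter *= 10.0
    raise NumericalError("covariance matrix singular even after jitter")


# ---------------------------------------------------------------------------
# priors


def default_priors(
    X: np.ndarray, tau_scale: float = 10.0, ridge: float = 1e-6
) -> PriorSpec:
    """Data-driven conjugate prior.

    alpha = (1, 1); eta = column means; tau = ``tau_scale`` x sample
    covariance (default 10, a wide prior on the means); nu = p; Psi = the
    sample covariance. A singular sample covariance (e.g. a constant
    column) is jittered by ``ridge`` x mean diagonal. No standardization is
    applied: the mixture is fitted on raw score scales.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n <= p:
        raise DataError(f"need n > p, got n={n}, p={p}")
    if np.isnan(X).any():
        raise DataError("X contains missing values; impute first")
    cov = np.cov(X, rowvar=False, ddof=1).reshape(p, p)
    cov = _ensure_spd(cov, ridge)
    return PriorSpec(
        alpha=np.ones(2),
        eta=X.mean(axis=0),
        tau=tau_scale * cov,
        nu=float(p),
        psi=cov,
    )


# ---------------------------------------------------------------------------
# conditional samplers


def sample_assignments(
    X: np.ndarray, state: GibbsState, rng: np.random.Generator
) -> np.ndarray:
    """Draw component assignments from their categorical full conditional.

    Responsibilities are normalized in log space, so simultaneous density
    underflow in both clusters never produces NaN. One uniform variate is
    consumed per row, in row order.
    """
    logp = np.stack(
        [
            np.log(state.omega[k]) + mvn_logpdf(X, state.mu[k], state.sigma[k])
            for k in range(2)
        ],
        axis=1,
    )
    resp = np.exp(logp - logsumexp(logp, axis=1, keepdims=True))
    u = rng.random(X.shape[0])
    return np.where(u < resp[:, 0], 1, 2).astype(np.int64)


def responsibilities_from_state(
    X: np.ndarray, omega: np.ndarray, mu: np.ndarray, sigma: np.ndarray
) -> np.ndarray:
    """(n, 2) posterior membership probabilities for fixed parameters."""
    logp = np.stack(
        [np.log(omega[k]) + mvn_logpdf(X, mu[k], sigma[k]) for k in range(2)],
        axis=1,
    )
    return np.exp(logp - logsumexp(logp, axis=1, keepdims=True))


def sample_weights(
    z: np.ndarray, alpha: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Dirichlet(alpha_1 + n_1, alpha_2 + n_2) draw of the cluster weights."""
    counts = np.array([(z == 1).sum(), (z == 2).sum()], dtype=float)
    return rng.dirichlet(np.asarray(alpha, dtype=float) + counts)


def sample_means(
    X: np.ndarray,
    z: np.ndarray,
    sigma: np.ndarray,
    priors: PriorSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    """Conjugate multivariate-normal draw of both cluster means.

    Posterior precision is ``tau^-1 + n_k Sigma_k^-1``; an empty cluster
    falls back to a prior draw.
    """
    p = priors.p
    tau_inv = np.linalg.inv(priors.tau)
    mu = np.empty((2, p))
    for k in range(2):
        rows = X[z == k + 1]
        n_k = rows.shape[0]
        if n_k == 0:
            L = np.linalg.cholesky(priors.tau)
            mu[k] = priors.eta + L @ rng.standard_normal(p)
            continue
        sig_inv = np.linalg.inv(sigma[k])
        prec = tau_inv + n_k * sig_inv
        cov = np.linalg.inv(prec)
        cov = 0.5 * (cov + cov.T)
        mean = cov @ (tau_inv @ priors.eta + sig_inv @ (n_k * rows.mean(axis=0)))
        L = np.linalg.cholesky(cov)
        mu[k] = mean + L @ rng.standard_normal(p)
    return mu


def sample_covariances(
    X: np.ndarray,
    z: np.ndarray,
    mu: np.ndarray,
    priors: PriorSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    """Inverse-Wishart(nu + n_k, Psi + scatter_k) draw of both covariances."""
    p = priors.p
    sigma = np.empty((2, p, p))
    for k in range(2):
        rows = X[z == k + 1]
        diff = rows - mu[k]
        scale = priors.psi + diff.T @ diff
        draw = invwishart.rvs(
            df=priors.nu + rows.shape[0], scale=scale, random_state=rng
        )
        draw = np.atleast_2d(draw)
        sigma[k] = 0.5 * (draw + draw.T)
    return sigma


# ---------------------------------------------------------------------------
# initialization and the sampler


def init_state(
    X: np.ndarray,
    priors: PriorSpec,
    cfg: GibbsConfig,
    rng: np.random.Generator | None = None,
) -> GibbsState:
    """Initial state from a random or PCA-split assignment plus one sweep.

    ``random`` assigns rows to the two clusters uniformly (redrawn up to 100
    times until both clusters have at least p + 2 members); ``kmeans``
    splits at the median projection on the first principal direction. Given
    the assignment, weights, covariances (around cluster sample means) and
    means are drawn from one pass of their conditionals.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    n, p = X.shape
    min_members = p + 2
    if cfg.init == "kmeans":
        centred = X - X.mean(axis=0)
        _, _, vt = np.linalg.svd(centred, full_matrices=False)
        proj = centred @ vt[0]
        z = np.where(proj <= np.median(proj), 1, 2).astype(np.int64)
        if min((z == 1).sum(), (z == 2).sum()) < min_members:
            raise DataError(
                f"principal-direction split leaves a cluster with fewer than "
                f"{min_members} members"
            )
    else:
        for _ in range(100):
            z = rng.integers(1, 3, size=n).astype(np.int64)
            if min((z == 1).sum(), (z == 2).sum()) >= min_members:
                break
        else:
            raise DataError(
                f"could not initialize clusters with >= {min_members} members "
                f"in 100 attempts (n={n}, p={p})"
            )
    omega = sample_weights(z, priors.alpha, rng)
    mu_hat = np.stack(
        [X[z == k + 1].mean(axis=0) for k in range(2)]
    )
    sigma = sample_covariances(X, z, mu_hat, priors, rng)
    mu = sample_means(X, z, sigma, priors, rng)
    return GibbsState(z=z, omega=omega, mu=mu, sigma=sigma)


def run_gibbs(
    X: np.ndarray,
    priors: PriorSpec | None = None,
    cfg: GibbsConfig | None = None,
    features: tuple[str, ...] = (),
    anchor_feature: str = "revel",
) -> PosteriorDraws:
    """Run the Gibbs sampler and return identifiability-ordered draws.

    Each sweep cycles assignments -> weights -> means -> covariances.
    Burn-in draws are discarded, the rest thinned; finally every retained
    draw is reordered so that omega_1 < omega_2 (see
    :func:`enforce_weight_order`). A cluster that stays empty for more than
    50 consecutive sweeps triggers a warning (its parameters keep being
    refreshed from the prior, which keeps the chain proper).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise DataError("X must be a 2-D matrix")
    if np.isnan(X).any():
        raise DataError("X contains missing values; impute first")
    n, p = X.shape
    if n <= 2 * (p + 2):
        raise DataError(f"need n > 2(p+2) = {2 * (p + 2)}, got n={n}")
    cfg = cfg if cfg is not None else GibbsConfig()
    cfg.validate()
    priors = priors if priors is not None else default_priors(X)
    priors.validate()
    if priors.p != p:
        raise DataError("prior dimension differs from data dimension")

    rng = np.random.default_rng(cfg.seed)
    state = init_state(X, priors, cfg, rng)

    M = cfg.n_retained
    omega_out = np.empty((M, 2))
    mu_out = np.empty((M, 2, p))
    sigma_out = np.empty((M, 2, p, p))
    m = 0
    empty_streak = 0
    warned = False
    for it in range(cfg.n_iter):
        z = sample_assignments(X, state, rng)
        counts = ((z == 1).sum(), (z == 2).sum())
        if min(counts) == 0:
            empty_streak += 1
            if empty_streak > 50 and not warned:
                warnings.warn(
                    "a mixture component has been empty for more than 50 "
                    "consecutive sweeps; its parameters are prior draws",
                    RuntimeWarning,
                )
                warned = True
        else:
            empty_streak = 0
        omega = sample_weights(z, priors.alpha, rng)
        mu = sample_means(X, z, state.sigma, priors, rng)
        sigma = sample_covariances(X, z, mu, priors, rng)
        state = GibbsState(z=z, omega=omega, mu=mu, sigma=sigma)
        if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0 and m < M:
            omega_out[m] = omega
            mu_out[m] = mu
            sigma_out[m] = sigma
            m += 1

    draws = PosteriorDraws(
        omega=omega_out[:m],
        mu=mu_out[:m],
        sigma=sigma_out[:m],
        features=tuple(features),
        priors=priors,
        config=cfg,
    )
    return enforce_weight_order(draws, anchor_feature=anchor_feature)


def enforce_weight_order(
    draws: PosteriorDraws, anchor_feature: str = "revel"
) -> PosteriorDraws:
    """Resolve label switching: reorder every draw so omega_1 < omega_2.

    Draws violating the constraint have their full parameter block (omega,
    mu, Sigma) swapped. An exact weight tie is ordered by the anchor
    feature's means (benign = lower; default anchor REVEL, falling back to
    the last feature when the anchor is absent).
    """
    omega = draws.omega.copy()
    mu = draws.mu.copy()
    sigma = draws.sigma.copy()
    if draws.features and anchor_feature in draws.features:
        a = draws.features.index(anchor_feature)
    else:
        a = mu.shape[2] - 1
    swap = omega[:, 0] > omega[:, 1]
    tie = omega[:, 0] == omega[:, 1]
    swap |= tie & (mu[:, 0, a] > mu[:, 1, a])
    omega[swap] = omega[swap][:, ::-1]
    mu[swap] = mu[swap][:, ::-1, :]
    sigma[swap] = sigma[swap][:, ::-1, :, :]
    return replace(draws, omega=omega, mu=mu, sigma=sigma)


def summarize_posterior(draws: PosteriorDraws, min_draws: int = 40) -> ClusterSummary:
    """Posterior mean, SD and 2.5/50/97.5 percentiles per cluster parameter.

    Requires at least ``min_draws`` retained draws for percentile stability.
    """
    import pandas as pd

    if draws.M < min_draws:
        raise DataError(
            f"need at least {min_draws} retained draws, have {draws.M}"
        )
    qs = (2.5, 50.0, 97.5)

    def stats(samples: np.ndarray) -> np.ndarray:
        out = np.empty(samples.shape[1:] + (5,))
        out[..., 0] = samples.mean(axis=0)
        out[..., 1] = samples.std(axis=0, ddof=1)
        out[..., 2:] = np.moveaxis(np.percentile(samples, qs, axis=0), 0, -1)
        return out

    weight_stats = stats(draws.omega)  # (2, 5)
    mean_stats = stats(draws.mu)  # (2, p, 5)

    features = draws.features or tuple(f"x{j}" for j in range(draws.p))
    roles = ("benign", "pathogenic")
    rows = []
    for k, role in enumerate(roles):
        rows.append(
            {
                "cluster": role,
                "parameter": "weight",
                "mean": weight_stats[k, 0],
                "sd": weight_stats[k, 1],
                "q2.5": weight_stats[k, 2],
                "q50": weight_stats[k, 3],
                "q97.5": weight_stats[k, 4],
            }
        )
        for j, f in enumerate(features):
            rows.append(
                {
                    "cluster": role,
                    "parameter": f,
                    "mean": mean_stats[k, j, 0],
                    "sd": mean_stats[k, j, 1],
                    "q2.5": mean_stats[k, j, 2],
                    "q50": mean_stats[k, j, 3],
                    "q97.5": mean_stats[k, j, 4],
                }
            )
    return ClusterSummary(
        features=features,
        roles=roles,
        weight_stats=weight_stats,
        mean_stats=mean_stats,
        table=pd.DataFrame(rows),
    )


# ---------------------------------------------------------------------------
# serialization


def save_draws(draws: PosteriorDraws, path: str | Path) -> None:
    """Serialize retained draws plus metadata to an NPZ container."""
    meta: dict = {"features": list(draws.features), "version": 1}
    if draws.priors is not None:
        meta["priors"] = {
            "alpha": draws.priors.alpha.tolist(),
            "eta": draws.priors.eta.tolist(),
            "tau": draws.priors.tau.tolist(),
            "nu": draws.priors.nu,
            "psi": draws.priors.psi.tolist(),
        }
    if draws.config is not None:
        meta["config"] = {
            "n_iter": draws.config.n_iter,
            "burn_in": draws.config.burn_in,
            "thin": draws.config.thin,
            "seed": draws.config.seed,
            "init": draws.config.init,
        }
    np.savez_compressed(
        path,
        omega=draws.omega,
        mu=draws.mu,
        sigma=draws.sigma,
        meta=np.frombuffer(json.dumps(meta, sort_keys=True).encode(), dtype=np.uint8),
    )


def load_draws(path: str | Path) -> PosteriorDraws:
    """Inverse of :func:`save_draws`."""
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["meta"]).decode())
        priors = None
        if "priors" in meta:
            pr = meta["priors"]
            priors = PriorSpec(
                alpha=np.array(pr["alpha"]),
                eta=np.array(pr["eta"]),
                tau=np.array(pr["tau"]),
                nu=pr["nu"],
                psi=np.array(pr["psi"]),
            )
        config = GibbsConfig(**meta["config"]) if "config" in meta else None
        return PosteriorDraws(
            omega=npz["omega"],
            mu=npz["mu"],
            sigma=npz["sigma"],
            features=tuple(meta.get("features", ())),
            priors=priors,
            config=config,
        )


# ---------------------------------------------------------------------------
# estimator


class GibbsGaussianMixture(BaseEstimator):
    """Unsupervised two-cluster Bayesian Gaussian mixture estimator.

    ``fit`` runs the Gibbs sampler on a complete score matrix;
    ``predict_proba`` returns posterior-predictive membership probabilities
    averaged over retained draws (column 0 benign, column 1 pathogenic), and
    ``predict`` applies the per-draw argmax / mode-over-draws rule.

    Parameters mirror :class:`GibbsConfig` plus the prior knobs
    ``tau_scale`` and ``ridge``; ``K`` must remain 2 (validated).
    """

    def __init__(
        self,
        n_iter: int = 20000,
        burn_in: int = 5000,
        thin: int = 5,
        init: str = "random",
        tau_scale: float = 10.0,
        ridge: float = 1e-6,
        anchor_feature: str = "revel",
        K: int = 2,
        random_state: int = 0,
    ):
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.thin = thin
        self.init = init
        self.tau_scale = tau_scale
        self.ridge = ridge
        self.anchor_feature = anchor_feature
        self.K = K
        self.random_state = random_state

    def fit(self, X, y=None, features: tuple[str, ...] = ()):
        if self.K != 2:
            raise ConfigError("only the two-cluster model is supported")
        X = np.asarray(X, dtype=float)
        cfg = GibbsConfig(
            n_iter=self.n_iter,
            burn_in=self.burn_in,
            thin=self.thin,
            seed=self.random_state,
            init=self.init,
        )
        priors = default_priors(X, tau_scale=self.tau_scale, ridge=self.ridge)
        self.draws_ = run_gibbs(
            X, priors, cfg, features=features, anchor_feature=self.anchor_feature
        )
        self.priors_ = priors
        self.n_features_in_ = X.shape[1]
        self.summary_ = summarize_posterior(
            self.draws_, min_draws=min(40, self.draws_.M)
        )
        return self

    def _check_fitted(self):
        if not hasattr(self, "draws_"):
            raise DataError("estimator is not fitted")

    def predict_proba(self, X) -> np.ndarray:
        from .classify import classify_variants

        self._check_fitted()
        return classify_variants(X, self.draws_).mean_proba

    def predict(self, X) -> np.ndarray:
        from .classify import classify_variants

        self._check_fitted()
        return classify_variants(X, self.draws_).labels

    def classification_result(self, X):
        from .classify import classify_variants

        self._check_fitted()
        return classify_variants(X, self.draws_)
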