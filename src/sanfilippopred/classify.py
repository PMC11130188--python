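"""Posterior-predictive classification, DIC, and backward feature elimination.

Classification follows the posterior-predictive rule: for each retained
draw m the membership probability of variant i in cluster k is

    p_{i,k,m} ∝ omega_{k,m} |2 pi Sigma_{k,m}|^{-1/2}
                exp(-1/2 (x_i - mu_{k,m})' Sigma_{k,m}^{-1} (x_i - mu_{k,m}))

normalized over k (computed in log space). The per-draw label is the
argmax over k, and the final label the mode over draws; the reported
pathogenicity probability is the mean over draws of the pathogenic-cluster
responsibility. A split vote (even number of draws) is resolved to
"pathogenic" and flagged — in a screening context the sensitive call is
preferred.

Model comparison uses the deviance information criterion with the
observed-data mixture likelihood, D(theta) = -2 sum_i log sum_k omega_k
N(x_i; mu_k, Sigma_k), and Spiegelhalter's effective parameter count
p_D = Dbar - D(theta_bar), where theta_bar is the element-wise posterior
mean (weights renormalized, covariances symmetrized and projected to the
nearest positive-definite matrix if needed). DIC = Dbar + p_D. Backward
elimination greedily removes the feature whose removal most lowers DIC,
stopping when no removal lowers it or one feature remains; DIC values
across feature sets of different dimension live on different likelihood
scales — within a step all candidates share a dimension, and the recorded
trace carries this caveat.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.special import logsumexp

from .errors import DataError
from .gibbs import (
    GibbsConfig,
    PosteriorDraws,
    default_priors,
    mvn_logpdf,
    run_gibbs,
)

#: Score set consumed by the distributed calculator-style scorer.
SANFILIPPO_FEATURES: tuple[str, ...] = (
    "sift",
    "polyphen2",
    "cadd",
    "revel",
    "metalr",
    "mutation_assessor",
)

_DIC_CAVEAT = (
    "DIC values are comparable within a step (same data dimension); "
    "across steps the likelihood dimension changes."
)


@dataclass
class ClassificationResult:
    """Per-variant classification output.

    labels : (n,) int, 0 = benign, 1 = pathogenic (mode over draws).
    mean_proba : (n, 2) mean responsibilities over draws (benign, pathogenic).
    pathogenic_votes : (n,) number of draws whose argmax was pathogenic.
    n_draws : number of retained draws used.
    tie : (n,) bool, True where the vote split exactly in half.
    """

    labels: np.ndarray
    mean_proba: np.ndarray
    pathogenic_votes: np.ndarray
    n_draws: int
    tie: np.ndarray

    @property
    def pathogenicity_probability(self) -> np.ndarray:
        return self.mean_proba[:, 1]


@dataclass
class DICResult:
    mean_deviance: float
    plug_in_deviance: float
    p_d: float
    dic: float
    feature_set: tuple[str, ...] = ()
    note: str = _DIC_CAVEAT


@dataclass
class EliminationStep:
    feature_set: tuple[str, ...]
    dic: DICResult
    removed_feature: str | None


@dataclass
class EliminationTrace:
    steps: list[EliminationStep] = field(default_factory=list)
    note: str = _DIC_CAVEAT

    @property
    def final_features(self) -> tuple[str, ...]:
        return self.steps[-1].feature_set if self.steps else ()


def _log_mixture_components(
    X: np.ndarray, omega: np.ndarray, mu: np.ndarray, sigma: np.ndarray
) -> np.ndarray:
    """(n, 2) matrix of log(omega_k) + log N(x_i; mu_k, Sigma_k)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != mu.shape[1]:
        raise DataError(
            f"dimension mismatch: x has {X.shape[1]} features, model has "
            f"{mu.shape[1]}"
        )
    with np.errstate(divide="ignore"):  # omega_k == 0 -> log 0 = -inf is fine
        return np.stack(
            [np.log(omega[k]) + mvn_logpdf(X, mu[k], sigma[k]) for k in range(2)],
            axis=1,
        )


def posterior_predictive_responsibility(
    x: np.ndarray, omega: np.ndarray, mu: np.ndarray, sigma: np.ndarray
) -> np.ndarray:
    """Membership probabilities of one observation under one draw.

    Log-space normalization: even when both cluster densities underflow,
    the result is finite and sums to 1.
    """
    logp = _log_mixture_components(np.atleast_2d(x), omega, mu, sigma)
    return np.exp(logp - logsumexp(logp, axis=1, keepdims=True))[0]


def classify_variants(X: np.ndarray, draws: PosteriorDraws) -> ClassificationResult:
    """Classify rows of X under every retained draw and take the vote.

    Requires complete rows (impute first) on the model's feature set.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if np.isnan(X).any():
        raise DataError("X contains missing values; run imputation first")
    n = X.shape[0]
    sum_resp = np.zeros((n, 2))
    votes = np.zeros(n, dtype=np.int64)
    for m in range(draws.M):
        logp = _log_mixture_components(
            X, draws.omega[m], draws.mu[m], draws.sigma[m]
        )
        resp = np.exp(logp - logsumexp(logp, axis=1, keepdims=True))
        sum_resp += resp
        votes += (resp[:, 1] > resp[:, 0]).astype(np.int64)
    mean_proba = sum_resp / draws.M
    tie = 2 * votes == draws.M
    labels = np.where(2 * votes >= draws.M, 1, 0)
    return ClassificationResult(
        labels=labels,
        mean_proba=mean_proba,
        pathogenic_votes=votes,
        n_draws=draws.M,
        tie=tie,
    )


def compute_deviance(
    X: np.ndarray, omega: np.ndarray, mu: np.ndarray, sigma: np.ndarray
) -> float:
    """Observed-data mixture deviance -2 log L at one parameter block."""
    logp = _log_mixture_components(X, omega, mu, sigma)
    return float(-2.0 * logsumexp(logp, axis=1).sum())


def _nearest_spd(m: np.ndarray) -> np.ndarray:
    """Project a symmetric matrix to the nearest SPD by eigenvalue clipping."""
    m = 0.5 * (m + m.T)
    try:
        np.linalg.cholesky(m)
        return m
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(m)
        floor = max(1e-10, 1e-10 * w.max())
        return (v * np.maximum(w, floor)) @ v.T


def posterior_mean_parameters(draws: PosteriorDraws):
    """Element-wise posterior-mean parameter block (theta_bar for DIC)."""
    omega = draws.omega.mean(axis=0)
    omega = omega / omega.sum()
    mu = draws.mu.mean(axis=0)
    sigma = np.stack([_nearest_spd(s) for s in draws.sigma.mean(axis=0)])
    return omega, mu, sigma


def posterior_median_parameters(draws: PosteriorDraws):
    """Element-wise posterior-median parameter block (plug-in scoring)."""
    omega = np.median(draws.omega, axis=0)
    omega = omega / omega.sum()
    mu = np.median(draws.mu, axis=0)
    sigma = np.stack([_nearest_spd(s) for s in np.median(draws.sigma, axis=0)])
    return omega, mu, sigma


def compute_dic(X: np.ndarray, draws: PosteriorDraws) -> DICResult:
    """Deviance information criterion of the fitted mixture on X."""
    if draws.M < 2:
        raise DataError("DIC requires at least 2 retained draws")
    X = np.asarray(X, dtype=float)
    devs = np.array(
        [
            compute_deviance(X, draws.omega[m], draws.mu[m], draws.sigma[m])
            for m in range(draws.M)
        ]
    )
    mean_dev = float(devs.mean())
    omega, mu, sigma = posterior_mean_parameters(draws)
    plug_in = compute_deviance(X, omega, mu, sigma)
    p_d = mean_dev - plug_in
    return DICResult(
        mean_deviance=mean_dev,
        plug_in_deviance=plug_in,
        p_d=p_d,
        dic=mean_dev + p_d,
        feature_set=draws.features,
    )


def backward_eliminate(
    X: np.ndarray,
    features: Sequence[str],
    cfg: GibbsConfig,
    priors_builder: Callable[[np.ndarray], "object"] = default_priors,
    min_features: int = 1,
) -> EliminationTrace:
    """Greedy DIC-based backward feature elimination.

    At each step the mixture is refitted on every leave-one-out subset of
    the current feature set; the removal with the lowest DIC is accepted if
    it improves on the current model, otherwise elimination stops (or when
    ``min_features`` remain). Subsets whose refit fails are skipped with a
    warning.
    """
    features = list(features)
    if len(features) < 2:
        raise DataError("elimination requires at least 2 features")
    X = np.asarray(X, dtype=float)
    col = {f: j for j, f in enumerate(features)}

    def fit_dic(subset: list[str]) -> DICResult:
        Xs = X[:, [col[f] for f in subset]]
        draws = run_gibbs(Xs, priors_builder(Xs), cfg, features=tuple(subset))
        return compute_dic(Xs, draws)

    trace = EliminationTrace()
    current = features
    current_dic = fit_dic(current)
    trace.steps.append(EliminationStep(tuple(current), current_dic, None))
    while len(current) > min_features:
        candidates: list[tuple[str, DICResult]] = []
        for f in current:
            subset = [g for g in current if g != f]
            try:
                candidates.append((f, fit_dic(subset)))
            except Exception as exc:  # refit failure: skip subset
                warnings.warn(
                    f"refit without feature {f!r} failed ({exc}); subset skipped",
                    RuntimeWarning,
                )
        if not candidates:
            break
        removed, best = min(candidates, key=lambda t: t[1].dic)
        if best.dic >= current_dic.dic:
            break
        current = [g for g in current if g != removed]
        current_dic = best
        trace.steps.append(EliminationStep(tuple(current), best, removed))
    return trace


def sanfilippo_score(
    x: Mapping[str, float] | np.ndarray,
    model: PosteriorDraws,
    mode: str = "draws",
    threshold: float = 0.5,
) -> tuple[float, str]:
    """Score one variant: (pathogenicity probability, label).

    ``x`` is either a mapping from feature name to score or a vector
    aligned with ``model.features``. ``mode='draws'`` averages per-draw
    responsibilities; ``mode='plug_in'`` evaluates a single responsibility
    at the posterior-median parameters (the calculator-style
    approximation). The label is "pathogenic" iff the probability meets the
    0.5 threshold.
    """
    feats = model.features or SANFILIPPO_FEATURES
    if isinstance(x, Mapping):
        missing = [f for f in feats if f not in x or x[f] is None]
        if missing:
            raise DataError(f"missing score(s) for: {', '.join(missing)}")
        vec = np.array([float(x[f]) for f in feats])
    else:
        vec = np.asarray(x, dtype=float).ravel()
        if vec.shape[0] != len(feats):
            raise DataError(
                f"expected {len(feats)} scores ({', '.join(feats)}), got "
                f"{vec.shape[0]}"
            )
        if np.isnan(vec).any():
            missing = [f for f, v in zip(feats, vec) if np.isnan(v)]
            raise DataError(f"missing score(s) for: {', '.join(missing)}")
    if mode == "draws":
        prob = float(classify_variants(vec[None, :], model).mean_proba[0, 1])
    elif mode == "plug_in":
        omega, mu, sigma = posterior_median_parameters(model)
        prob = float(
            posterior_predictive_responsibility(vec, omega, mu, sigma)[1]
        )
    else:
        raise DataError("mode must be 'draws' or 'plug_in'")
    label = "pathogenic" if prob >= threshold else "benign"
    return prob, label
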