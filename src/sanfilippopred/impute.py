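"""Predictive-mean-matching imputation by chained equations.

Missing score cells are filled column by column: each incomplete column is
regressed (OLS, with intercept) on all other columns of the current
completed matrix; every missing entry then receives the *observed* value of
one of the ``n_donors`` observed rows whose fitted means lie nearest to its
own predicted mean (uniform draw among the donors, deterministic tie-break
by row index). The cycle over columns is repeated ``n_cycles`` times. The
donor mechanism guarantees every imputed value lies within the empirical
support of its column, which matters here because several predictor scores
are hard-bounded ([0, 1] scores, nonnegative distances).

The chain is initialized at column means. With ``n_imputations > 1`` the
chain is run that many times from independent substreams and a list of
completed datasets is returned; pooling across imputations is the caller's
concern (the modeling stage consumes a single completed dataset).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import ConfigError, ImputationError
from .variant_io import Dataset


@dataclass
class PMMConfig:
    """Tuning parameters of the chained-PMM imputer."""

    n_donors: int = 5
    n_cycles: int = 5
    n_imputations: int = 1
    seed: int = 0

    def validate(self) -> None:
        if self.n_donors < 1:
            raise ConfigError("n_donors must be >= 1")
        if self.n_cycles < 1:
            raise ConfigError("n_cycles must be >= 1")
        if self.n_imputations < 1:
            raise ConfigError("n_imputations must be >= 1")


def match_donors(
    predicted_missing: np.ndarray,
    predicted_obs: np.ndarray,
    observed: np.ndarray,
    k: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Donor draw of PMM: observed values of the k nearest predicted means.

    For each entry of ``predicted_missing``, the k observed rows whose
    ``predicted_obs`` are closest (absolute difference; ties broken by row
    index) are candidate donors, and one is chosen uniformly at random.
    """
    predicted_missing = np.asarray(predicted_missing, dtype=float)
    predicted_obs = np.asarray(predicted_obs, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted_obs.shape != observed.shape:
        raise ImputationError("predicted_obs and observed must align")
    n_obs = observed.size
    if k > n_obs:
        raise ImputationError(f"k={k} donors requested but only {n_obs} observed rows")
    out = np.empty(predicted_missing.size)
    idx = np.arange(n_obs)
    for t, v in enumerate(predicted_missing):
        d = np.abs(predicted_obs - v)
        # lexsort: distance first, then row index for deterministic ties
        order = np.lexsort((idx, d))[:k]
        out[t] = observed[order[rng.integers(k)]]
    return out


def _ols_predict(Z: np.ndarray, target: np.ndarray, obs: np.ndarray) -> np.ndarray:
    """Fitted means from OLS of target[obs] on Z[obs]; predictions for all rows."""
    design = np.column_stack([np.ones(Z.shape[0]), Z])
    beta, *_ = np.linalg.lstsq(design[obs], target[obs], rcond=None)
    return design @ beta


def _pmm_complete(
    X: np.ndarray,
    features: tuple[str, ...],
    cfg: PMMConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    mask = np.isnan(X)
    if not mask.any():
        return X.copy()
    n_obs_per_col = (~mask).sum(axis=0)
    for j, f in enumerate(features):
        if n_obs_per_col[j] == 0:
            raise ImputationError(f"column {f!r} has no observed values")
        if mask[:, j].any() and n_obs_per_col[j] < cfg.n_donors:
            raise ImputationError(
                f"column {f!r} has {n_obs_per_col[j]} observed values, fewer "
                f"than n_donors={cfg.n_donors}"
            )
    work = X.copy()
    col_means = np.nanmean(X, axis=0)
    work[mask] = np.take(col_means, np.nonzero(mask)[1])

    incomplete = [j for j in range(X.shape[1]) if mask[:, j].any()]
    for _ in range(cfg.n_cycles):
        for j in incomplete:
            obs = ~mask[:, j]
            others = [c for c in range(X.shape[1]) if c != j]
            if others:
                pred = _ols_predict(work[:, others], X[:, j], obs)
            else:
                pred = np.full(X.shape[0], col_means[j])
            work[mask[:, j], j] = match_donors(
                pred[mask[:, j]], pred[obs], X[obs, j], cfg.n_donors, rng
            )
    return work


def pmm_impute(ds: Dataset, cfg: PMMConfig | None = None):
    """Impute missing scores of a Dataset by chained PMM.

    Returns a completed Dataset (or a list of ``n_imputations`` completed
    datasets when more than one is requested). Observed cells are never
    modified; every imputed value equals some observed value of its column;
    complete input is returned unchanged (identity).
    """
    cfg = cfg if cfg is not None else PMMConfig()
    cfg.validate()
    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.n_imputations)
    completed = [
        ds.with_X(
            _pmm_complete(ds.X, ds.features, cfg, np.random.default_rng(s))
        )
        for s in seeds
    ]
    return completed[0] if cfg.n_imputations == 1 else completed


class PMMImputer(TransformerMixin, BaseEstimator):
    """scikit-learn transformer wrapping chained-PMM imputation.

    By design each split is imputed from its own observed values only (no
    information flows from the fitting data into ``transform``), so ``fit``
    merely validates shape; this avoids leakage between the unlabelled
    training pool and the labelled evaluation sets.
    """

    def __init__(
        self,
        n_donors: int = 5,
        n_cycles: int = 5,
        random_state: int = 0,
    ):
        self.n_donors = n_donors
        self.n_cycles = n_cycles
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ImputationError("X must be 2-dimensional")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        if X.shape[1] != getattr(self, "n_features_in_", X.shape[1]):
            raise ImputationError("feature count differs from fit")
        cfg = PMMConfig(n_donors=self.n_donors, n_cycles=self.n_cycles, seed=self.random_state)
        cfg.validate()
        features = tuple(f"x{j}" for j in range(X.shape[1]))
        return _pmm_complete(X, features, cfg, np.random.default_rng(self.random_state))
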