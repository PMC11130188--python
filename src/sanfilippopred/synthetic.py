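"""Model-faithful synthetic variant-score data.

The study's raw table of 612 NAGLU missense variants is not publicly
deposited, so every stage of the package is exercised on synthetic data
drawn from the model the predictor assumes: a two-component multivariate
Gaussian mixture over the eight predictor scores. Default centroids and
weights are the published posterior centroid estimates for the NAGLU VUS
clusters (benign vs pathogenic); values are clipped to the empirical score
ranges of the study table.

The published centroid table reports posterior SDs of the cluster means
(standard-error scale), not within-cluster spread; defaults scale that SD
column by :data:`WITHIN_SD_SCALE` to obtain plausible within-cluster SDs.
At the default scale the two components are separated by ~6 Mahalanobis
units in 8 dimensions while overlapping per feature, so classification is
easy but estimation is non-trivial.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .errors import ConfigError, DataError
from .variant_io import FEATURE_RANGES, FEATURES, Dataset, harmonize_labels
from .variant_io import partition_validation_test

#: Cluster-1 (benign) posterior-mean centroid per feature.
BENIGN_CENTROID: dict[str, float] = {
    "grantham": 63.4,
    "sneath": 19.7,
    "sift": 0.38,
    "polyphen2": 0.22,
    "cadd": 15.0,
    "revel": 0.39,
    "metalr": 0.81,
    "mutation_assessor": 0.40,
}

#: Cluster-2 (pathogenic) posterior-mean centroid per feature.
PATHOGENIC_CENTROID: dict[str, float] = {
    "grantham": 82.4,
    "sneath": 24.6,
    "sift": 0.03,
    "polyphen2": 0.77,
    "cadd": 24.4,
    "revel": 0.75,
    "metalr": 0.95,
    "mutation_assessor": 0.77,
}

#: Posterior SDs of the centroids (standard-error scale).
POSTERIOR_SD_BENIGN: dict[str, float] = {
    "grantham": 3.09,
    "sneath": 0.76,
    "sift": 0.04,
    "polyphen2": 0.05,
    "cadd": 0.96,
    "revel": 0.03,
    "metalr": 0.01,
    "mutation_assessor": 0.04,
}

POSTERIOR_SD_PATHOGENIC: dict[str, float] = {
    "grantham": 3.61,
    "sneath": 0.70,
    "sift": 0.03,
    "polyphen2": 0.05,
    "cadd": 0.76,
    "revel": 0.03,
    "metalr": 0.01,
    "mutation_assessor": 0.03,
}

#: Factor converting centroid posterior SDs to within-cluster SDs.
WITHIN_SD_SCALE: float = 5.0

#: Cluster weights (benign, pathogenic).
DEFAULT_WEIGHTS: tuple[float, float] = (0.43, 0.57)

#: Study design sizes: unlabelled pool, benign-labelled, pathogenic-labelled.
N_UNLABELLED = 415
N_BENIGN_LABELLED = 101
N_PATHOGENIC_LABELLED = 96


def _default_centroids(features: Sequence[str]) -> np.ndarray:
    return np.array(
        [
            [BENIGN_CENTROID[f] for f in features],
            [PATHOGENIC_CENTROID[f] for f in features],
        ]
    )


def _default_sds(features: Sequence[str]) -> np.ndarray:
    return WITHIN_SD_SCALE * np.array(
        [
            [POSTERIOR_SD_BENIGN[f] for f in features],
            [POSTERIOR_SD_PATHOGENIC[f] for f in features],
        ]
    )


@dataclass
class GeneratorSpec:
    """Parameters of the two-component synthetic score generator.

    ``covariances`` may be a (2, p) array of per-feature SDs (diagonal
    covariance, the default) or a (2, p, p) array of full covariance
    matrices. ``clip_ranges`` defaults to the empirical study ranges.
    ``truncate=True`` resamples out-of-range cells instead of clipping.
    """

    n: int = 612
    features: tuple[str, ...] = FEATURES
    weights: tuple[float, float] = DEFAULT_WEIGHTS
    centroids: np.ndarray | None = None
    covariances: np.ndarray | None = None
    clip_ranges: dict[str, tuple[float, float]] | None = None
    label_fraction: float = 0.0
    missing_rate: float = 0.0
    truncate: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        self.features = tuple(self.features)
        if self.centroids is None:
            self.centroids = _default_centroids(self.features)
        else:
            self.centroids = np.asarray(self.centroids, dtype=float)
        if self.covariances is None:
            self.covariances = _default_sds(self.features)
        else:
            self.covariances = np.asarray(self.covariances, dtype=float)
        if self.clip_ranges is None:
            self.clip_ranges = {
                f: FEATURE_RANGES.get(f, (-np.inf, np.inf)) for f in self.features
            }
        self.validate()

    def validate(self) -> None:
        p = len(self.features)
        if not np.isclose(sum(self.weights), 1.0):
            raise ConfigError("mixture weights must sum to 1")
        if min(self.weights) < 0:
            raise ConfigError("mixture weights must be nonnegative")
        if self.centroids.shape != (2, p):
            raise ConfigError(f"centroids must have shape (2, {p})")
        if self.covariances.shape not in {(2, p), (2, p, p)}:
            raise ConfigError(
                f"covariances must have shape (2, {p}) (SDs) or (2, {p}, {p})"
            )
        if self.covariances.ndim == 3:
            for k in range(2):
                try:
                    np.linalg.cholesky(self.covariances[k])
                except np.linalg.LinAlgError as exc:
                    raise ConfigError(
                        f"component {k} covariance not positive definite"
                    ) from exc
        elif (self.covariances <= 0).any():
            raise ConfigError("per-feature SDs must be positive")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigError("missing_rate must be in [0, 1)")
        if not 0.0 <= self.label_fraction <= 1.0:
            raise ConfigError("label_fraction must be in [0, 1]")

    @property
    def diagonal(self) -> bool:
        return self.covariances.ndim == 2

    def component_sds(self) -> np.ndarray:
        """(2, p) within-cluster SDs (diagonal of the covariance)."""
        if self.diagonal:
            return self.covariances
        return np.sqrt(
            np.stack([np.diag(self.covariances[k]) for k in range(2)])
        )


def component_clipped_means(spec: GeneratorSpec) -> np.ndarray:
    """Analytic per-component means of the *clipped* generator (2, p).

    For diagonal specs, E[clip(X, a, b)] for X ~ N(mu, sd^2) is
    ``a*Phi(alpha) + b*(1 - Phi(beta)) + mu*(Phi(beta) - Phi(alpha))
    + sd*(phi(alpha) - phi(beta))`` with alpha=(a-mu)/sd, beta=(b-mu)/sd.
    This is the actual estimand a Gaussian fit to clipped data targets,
    used by recovery checks at boundary-hugging coordinates.
    """
    if not spec.diagonal:
        raise ConfigError("analytic clipped means require a diagonal spec")
    means = np.empty_like(spec.centroids)
    for k in range(2):
        for j, f in enumerate(spec.features):
            mu = spec.centroids[k, j]
            sd = spec.covariances[k, j]
            a, b = spec.clip_ranges[f]
            alpha = (a - mu) / sd
            beta = (b - mu) / sd
            means[k, j] = (
                (a * norm.cdf(alpha) if np.isfinite(a) else 0.0)
                + (b * norm.sf(beta) if np.isfinite(b) else 0.0)
                + mu * (norm.cdf(beta) - norm.cdf(alpha))
                + sd * (norm.pdf(alpha) - norm.pdf(beta))
            )
    return means


def _draw_component_rows(
    spec: GeneratorSpec, comp: int, size: int, rng: np.random.Generator
) -> np.ndarray:
    p = len(spec.features)
    mu = spec.centroids[comp]
    if spec.diagonal:
        raw = mu + rng.standard_normal((size, p)) * spec.covariances[comp]
    else:
        L = np.linalg.cholesky(spec.covariances[comp])
        raw = mu + rng.standard_normal((size, p)) @ L.T
    return raw


def _apply_ranges(
    raw: np.ndarray,
    comp_labels: np.ndarray,
    spec: GeneratorSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    lo = np.array([spec.clip_ranges[f][0] for f in spec.features])
    hi = np.array([spec.clip_ranges[f][1] for f in spec.features])
    if not spec.truncate:
        return np.clip(raw, lo, hi)
    # truncated-normal alternative: resample out-of-range cells (diagonal only)
    if not spec.diagonal:
        raise ConfigError("truncate=True requires diagonal covariances")
    out = raw.copy()
    for _ in range(1000):
        bad = (out < lo) | (out > hi)
        if not bad.any():
            return out
        rows, cols = np.nonzero(bad)
        mu = spec.centroids[comp_labels[rows], cols]
        sd = spec.covariances[comp_labels[rows], cols]
        out[rows, cols] = mu + sd * rng.standard_normal(rows.size)
    raise DataError("truncated sampling failed to converge in 1000 rounds")


def generate_mixture_dataset(
    spec: GeneratorSpec,
) -> tuple[Dataset, np.ndarray]:
    """Draw a synthetic variant table from the two-component mixture.

    Returns ``(dataset, raw)`` where ``dataset.truth`` holds the generating
    component per row (0 benign, 1 pathogenic) and ``raw`` is the unclipped
    score matrix (for distributional checks). A ``label_fraction`` subset of
    rows carries a clinical label derived from its component; all other rows
    are VUS. MCAR missingness at ``missing_rate`` is applied to scores only.
    """
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n, len(spec.features)
    comp = (rng.random(n) >= spec.weights[0]).astype(int)
    raw = np.empty((n, p))
    for k in (0, 1):
        rows = comp == k
        raw[rows] = _draw_component_rows(spec, k, int(rows.sum()), rng)
    X = _apply_ranges(raw, comp, spec, rng)

    labels = np.array(["VUS"] * n, dtype=object)
    n_lab = int(round(spec.label_fraction * n))
    if n_lab > 0:
        lab_rows = rng.choice(n, size=n_lab, replace=False)
        labels[lab_rows] = np.where(
            comp[lab_rows] == 1, "pathogenic", "benign"
        )
    ds = Dataset(
        variant_ids=np.array([f"synth_{i:05d}" for i in range(n)], dtype=object),
        genes=np.array(["NAGLU"] * n, dtype=object),
        labels=labels,
        features=spec.features,
        X=X,
        truth=comp,
    )
    ds = harmonize_labels(ds)
    if spec.missing_rate > 0:
        ds = inject_missingness(ds, spec.missing_rate, seed=int(rng.integers(2**31)))
    return ds, raw


def inject_missingness(ds: Dataset, rate: float, seed: int) -> Dataset:
    """Mask each score cell independently with probability ``rate`` (MCAR).

    Labels and identifiers are never masked; reproducible under ``seed``.
    """
    if not 0.0 <= rate < 1.0:
        raise ConfigError("missingness rate must be in [0, 1)")
    if rate == 0.0:
        return ds
    rng = np.random.default_rng(seed)
    mask = rng.random(ds.X.shape) < rate
    X = ds.X.copy()
    X[mask] = np.nan
    return replace(ds, X=X)


def make_benchmark_fixture(
    seed: int, spec: GeneratorSpec | None = None
) -> tuple[Dataset, Dataset, Dataset]:
    """Emulate the study design: (train, validation, test) datasets.

    415 unlabelled VUS rows drawn from the mixture form the training pool;
    101 benign-component and 96 pathogenic-component labelled rows are
    partitioned 99/98 into stratified validation and test sets.
    """
    base = spec if spec is not None else GeneratorSpec(seed=seed)
    train_spec = replace(base, n=N_UNLABELLED, label_fraction=0.0, seed=seed)
    train, _ = generate_mixture_dataset(train_spec)

    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    rows = []
    comps = []
    for k, size in ((0, N_BENIGN_LABELLED), (1, N_PATHOGENIC_LABELLED)):
        draw = _draw_component_rows(base, k, size, rng)
        rows.append(draw)
        comps.append(np.full(size, k))
    raw = np.vstack(rows)
    comp = np.concatenate(comps)
    X = _apply_ranges(raw, comp, base, rng)
    labels = np.where(comp == 1, "pathogenic", "benign").astype(object)
    labelled = Dataset(
        variant_ids=np.array(
            [f"synth_lab_{i:05d}" for i in range(len(comp))], dtype=object
        ),
        genes=np.array(["NAGLU"] * len(comp), dtype=object),
        labels=labels,
        features=base.features,
        X=X,
        truth=comp,
    )
    labelled = harmonize_labels(labelled)
    validation, test = partition_validation_test(labelled, seed=seed)
    return train, validation, test
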