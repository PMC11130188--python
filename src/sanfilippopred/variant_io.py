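"""Variant score tables: reading, label harmonization, and partitioning.

A variant table is a CSV/TSV with one row per missense variant carrying a
variant identifier, a clinical-assertion label (VUS / benign / likely benign /
pathogenic / likely pathogenic), an optional gene symbol, and up to eight
numeric in-silico predictor scores. Tables are held in memory as a
:class:`Dataset`: an ``n x p`` score matrix with a missingness mask (NaN),
aligned identifier/label arrays, and — after :func:`harmonize_labels` — a
binary class vector (benign = 0, pathogenic = 1, NaN = unlabelled).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, RangeError, SchemaError, StratificationError

logger = logging.getLogger(__name__)

#: Canonical feature names, in table order.
FEATURES: tuple[str, ...] = (
    "grantham",
    "sneath",
    "sift",
    "polyphen2",
    "cadd",
    "revel",
    "metalr",
    "mutation_assessor",
)

_INF = math.inf

#: Admissible ranges used for input validation. Unit-interval scores are
#: bounded in [0, 1]; substitution distances and CADD are nonnegative.
FEATURE_BOUNDS: dict[str, tuple[float, float]] = {
    "grantham": (0.0, _INF),
    "sneath": (0.0, _INF),
    "sift": (0.0, 1.0),
    "polyphen2": (0.0, 1.0),
    "cadd": (0.0, _INF),
    "revel": (0.0, 1.0),
    "metalr": (0.0, 1.0),
    "mutation_assessor": (0.0, 1.0),
}

#: Empirical score ranges observed across the 612 NAGLU missense variants of
#: the study table; the synthetic generator clips to these.
FEATURE_RANGES: dict[str, tuple[float, float]] = {
    "grantham": (5.0, 215.0),
    "sneath": (5.0, 43.0),
    "sift": (0.0, 1.0),
    "polyphen2": (0.0, 1.0),
    "cadd": (0.0, 32.0),
    "revel": (0.124, 0.995),
    "metalr": (0.0, 0.997),
    "mutation_assessor": (0.0, 0.951),
}

LABELS: tuple[str, ...] = (
    "VUS",
    "benign",
    "likely_benign",
    "pathogenic",
    "likely_pathogenic",
    "unknown",
)

#: Cell contents treated as missing (case-insensitive).
MISSING_TOKENS = frozenset({"", "na", ".", "nan"})

_LABEL_NORMALIZE = {
    "vus": "VUS",
    "uncertain_significance": "VUS",
    "benign": "benign",
    "likely_benign": "likely_benign",
    "pathogenic": "pathogenic",
    "likely_pathogenic": "likely_pathogenic",
    "unknown": "unknown",
}


@dataclass
class Dataset:
    """An ordered collection of variant records with an aligned score matrix.

    Attributes
    ----------
    variant_ids : object array, shape (n,)
    genes : object array, shape (n,)
    labels : object array, shape (n,)
        Clinical-assertion labels from :data:`LABELS`.
    features : tuple of str
        Column order of ``X``.
    X : float array, shape (n, p)
        Score matrix; missing cells are NaN.
    y : float array, shape (n,) or None
        Harmonized class (0 benign, 1 pathogenic, NaN unlabelled); None
        before :func:`harmonize_labels`.
    truth : int array, shape (n,) or None
        Generating mixture component for synthetic data (0/1); None for
        real tables.
    """

    variant_ids: np.ndarray
    genes: np.ndarray
    labels: np.ndarray
    features: tuple[str, ...]
    X: np.ndarray
    y: np.ndarray | None = None
    truth: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.variant_ids)
        if self.X.shape != (n, len(self.features)):
            raise DataError(
                f"score matrix shape {self.X.shape} inconsistent with "
                f"{n} records x {len(self.features)} features"
            )
        for arr, name in ((self.genes, "genes"), (self.labels, "labels")):
            if len(arr) != n:
                raise DataError(f"{name} length {len(arr)} != {n} records")
        if self.y is not None and len(self.y) != n:
            raise DataError("y length inconsistent with records")
        if self.truth is not None and len(self.truth) != n:
            raise DataError("truth length inconsistent with records")

    @property
    def n(self) -> int:
        return len(self.variant_ids)

    @property
    def p(self) -> int:
        return len(self.features)

    def subset(self, idx: np.ndarray | Sequence[int]) -> "Dataset":
        """Row subset preserving order of ``idx``."""
        idx = np.asarray(idx)
        return Dataset(
            variant_ids=self.variant_ids[idx],
            genes=self.genes[idx],
            labels=self.labels[idx],
            features=self.features,
            X=self.X[idx],
            y=None if self.y is None else self.y[idx],
            truth=None if self.truth is None else self.truth[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "variant_id": self.variant_ids,
                "gene": self.genes,
                "label": self.labels,
            }
        )
        for j, f in enumerate(self.features):
            df[f] = self.X[:, j]
        return df

    def with_X(self, X: np.ndarray) -> "Dataset":
        return replace(self, X=np.asarray(X, dtype=float))


def _normalize_label(raw: str) -> str:
    key = str(raw).strip().lower().replace(" ", "_").replace("-", "_")
    if key in _LABEL_NORMALIZE:
        return _LABEL_NORMALIZE[key]
    logger.warning("unrecognized clinical label %r mapped to 'unknown'", raw)
    return "unknown"


def _parse_cell(token: str, feature: str, line: int) -> float:
    text = str(token).strip()
    if text.lower() in MISSING_TOKENS:
        return math.nan
    try:
        value = float(text)
    except ValueError as exc:
        raise SchemaError(
            f"line {line}: cannot parse {feature}={text!r} as a number"
        ) from exc
    if not math.isfinite(value):
        raise SchemaError(f"line {line}: non-finite {feature}={text!r}")
    lo, hi = FEATURE_BOUNDS[feature]
    if not (lo <= value <= hi):
        raise RangeError(
            f"line {line}: {feature}={value} outside admissible range "
            f"[{lo}, {hi}]"
        )
    return value


def read_variant_table(
    path: str | Path,
    features: Sequence[str] = FEATURES,
    dialect: str | None = None,
    aliases: Mapping[str, str] | None = None,
) -> Dataset:
    """Read a variant score table from CSV or TSV.

    Parameters
    ----------
    path : str or Path
    features : sequence of canonical feature names to extract (subsets allowed
        for reduced models).
    dialect : {"csv", "tsv"} or None
        None infers from the file extension (``.tsv``/``.tab`` -> TSV).
    aliases : optional mapping from column names as they appear in the file to
        canonical names (``variant_id``, ``gene``, ``label``, feature names).

    Empty cells and the tokens "NA", ".", "NaN" are parsed as missing.
    Out-of-range or unparseable numeric cells raise row-level errors naming
    the offending line.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such file: {path}")
    features = tuple(features)
    unknown = [f for f in features if f not in FEATURE_BOUNDS]
    if unknown:
        raise SchemaError(f"unrecognized feature name(s): {unknown}")
    if dialect is None:
        dialect = "tsv" if path.suffix.lower() in {".tsv", ".tab"} else "csv"
    if dialect not in {"csv", "tsv"}:
        raise SchemaError(f"dialect must be 'csv' or 'tsv', got {dialect!r}")
    sep = "\t" if dialect == "tsv" else ","

    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if aliases:
        df = df.rename(columns=dict(aliases))
    required = ["variant_id", "label", *features]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise SchemaError(
            f"{path.name}: missing required column(s) {missing_cols}"
        )

    n = len(df)
    X = np.empty((n, len(features)), dtype=float)
    for j, f in enumerate(features):
        col = df[f].to_numpy()
        for i in range(n):
            # header is line 1; data row i is line i + 2
            X[i, j] = _parse_cell(col[i], f, line=i + 2)

    genes = (
        df["gene"].to_numpy(dtype=object)
        if "gene" in df.columns
        else np.array([""] * n, dtype=object)
    )
    labels = np.array([_normalize_label(v) for v in df["label"]], dtype=object)
    return Dataset(
        variant_ids=df["variant_id"].to_numpy(dtype=object),
        genes=genes,
        labels=labels,
        features=features,
        X=X,
    )


def write_variant_table(ds: Dataset, path: str | Path, dialect: str = "csv") -> None:
    """Write a Dataset back to CSV/TSV (inverse of :func:`read_variant_table`)."""
    sep = "\t" if dialect == "tsv" else ","
    df = ds.to_frame()
    df.to_csv(path, sep=sep, index=False, na_rep="NA", float_format="%.10g")


def harmonize_labels(ds: Dataset) -> Dataset:
    """Collapse 5-level clinical assertions to a binary class vector.

    benign / likely benign -> 0; pathogenic / likely pathogenic -> 1;
    VUS / unknown -> NaN (unlabelled).
    """
    mapping = {
        "benign": 0.0,
        "likely_benign": 0.0,
        "pathogenic": 1.0,
        "likely_pathogenic": 1.0,
        "VUS": math.nan,
        "unknown": math.nan,
    }
    y = np.array([mapping[lab] for lab in ds.labels], dtype=float)
    return replace(ds, y=y)


def split_by_label_status(ds: Dataset) -> tuple[Dataset, Dataset]:
    """Partition into (unlabelled, labelled) by harmonized class.

    Row order is preserved within each part; the partition is exhaustive
    and disjoint.
    """
    if ds.y is None:
        raise DataError("dataset must be harmonized before splitting")
    unlab = np.flatnonzero(np.isnan(ds.y))
    lab = np.flatnonzero(~np.isnan(ds.y))
    if unlab.size == 0:
        logger.warning("no unlabelled variants: unsupervised training impossible")
    return ds.subset(unlab), ds.subset(lab)


def partition_validation_test(
    labelled: Dataset, seed: int
) -> tuple[Dataset, Dataset]:
    """Stratified 50/50 split of labelled variants into validation and test.

    Each class is split as evenly as possible between the two sets; when a
    class has an odd count the extra record goes to the validation set first,
    alternating for subsequent odd classes so the total sizes differ by at
    most one. Reproducible under ``seed``.
    """
    if labelled.y is None or np.isnan(labelled.y).any():
        raise DataError("partition requires a fully labelled dataset")
    classes = np.unique(labelled.y)
    if classes.size < 2:
        raise StratificationError(
            "stratified partition requires both classes present"
        )
    rng = np.random.default_rng(seed)
    val_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []
    extra_to_validation = True
    for c in classes:
        idx = np.flatnonzero(labelled.y == c)
        perm = rng.permutation(idx.size)
        n_val = idx.size // 2
        if idx.size % 2 == 1:
            if extra_to_validation:
                n_val += 1
            extra_to_validation = not extra_to_validation
        val_idx.append(idx[perm[:n_val]])
        test_idx.append(idx[perm[n_val:]])
    val = np.sort(np.concatenate(val_idx))
    test = np.sort(np.concatenate(test_idx))
    return labelled.subset(val), labelled.subset(test)


def write_predictions(ds: Dataset, result, path: str | Path) -> None:
    """Write per-variant predictions to CSV.

    Columns: variant_id, p_benign, p_pathogenic, label, tie. Probabilities
    are written with 8 significant digits so they round-trip well beyond the
    6-digit contract.
    """
    if result.labels.shape[0] != ds.n:
        raise DataError(
            f"prediction length {result.labels.shape[0]} != dataset size {ds.n}"
        )
    df = pd.DataFrame(
        {
            "variant_id": ds.variant_ids,
            "p_benign": result.mean_proba[:, 0],
            "p_pathogenic": result.mean_proba[:, 1],
            "label": np.where(result.labels == 1, "pathogenic", "benign"),
            "tie": result.tie.astype(bool),
        }
    )
    df.to_csv(path, index=False, float_format="%.8g")
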