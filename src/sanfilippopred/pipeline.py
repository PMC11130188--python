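"""End-to-end orchestration: simulate -> impute -> train -> select ->
predict -> evaluate, with a manifest for provenance.

A single global seed fans out deterministically to per-stage seeds (stable
hash of ``"<seed>:<stage>"``), so re-running a configuration reproduces
every artifact.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .classify import backward_eliminate, classify_variants, compute_dic
from .errors import ConfigError
from .gibbs import GibbsConfig, default_priors, run_gibbs, save_draws, summarize_posterior
from .impute import PMMConfig, pmm_impute
from .metrics import evaluate_predictions
from .synthetic import GeneratorSpec, make_benchmark_fixture
from .variant_io import (
    FEATURES,
    Dataset,
    harmonize_labels,
    partition_validation_test,
    read_variant_table,
    split_by_label_status,
    write_predictions,
    write_variant_table,
)

_STAGES = ("simulate", "impute", "train", "select", "predict", "evaluate")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    digest = hashlib.blake2b(
        f"{global_seed}:{stage}".encode(), digest_size=4
    ).digest()
    return int.from_bytes(digest, "big") % (2**31)


@dataclass
class RunConfig:
    """Everything a full run needs; YAML-serializable."""

    seed: int = 0
    out_dir: str = "run"
    features: tuple[str, ...] = FEATURES
    # inputs: either one combined table, three per-split tables, or neither
    # (in which case a synthetic benchmark fixture is simulated)
    input_table: str | None = None
    train_table: str | None = None
    validation_table: str | None = None
    test_table: str | None = None
    # imputation
    n_donors: int = 5
    n_cycles: int = 5
    # chain
    n_iter: int = 20000
    burn_in: int = 5000
    thin: int = 5
    init: str = "random"
    # prior knobs
    tau_scale: float = 10.0
    ridge: float = 1e-6
    anchor_feature: str = "revel"
    K: int = 2
    # stages
    select: bool = False
    mode: str = "draws"
    simulate_missing_rate: float = 0.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        if "features" in raw:
            raw["features"] = tuple(raw["features"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["features"] = list(self.features)
        return d

    def gibbs_config(self, seed: int) -> GibbsConfig:
        return GibbsConfig(
            n_iter=self.n_iter,
            burn_in=self.burn_in,
            thin=self.thin,
            seed=seed,
            init=self.init,
        )

    def pmm_config(self, seed: int) -> PMMConfig:
        return PMMConfig(n_donors=self.n_donors, n_cycles=self.n_cycles, seed=seed)


def validate_config(cfg: RunConfig) -> list[str]:
    """Return a list of human-readable invariant violations (empty = valid)."""
    v: list[str] = []
    if cfg.K != 2:
        v.append("K: only the two-cluster model is supported")
    if cfg.burn_in >= cfg.n_iter:
        v.append("burn_in: must be smaller than n_iter")
    if cfg.thin < 1:
        v.append("thin: must be >= 1")
    if cfg.init not in {"random", "kmeans"}:
        v.append("init: must be 'random' or 'kmeans'")
    if cfg.n_donors < 1:
        v.append("n_donors: must be >= 1")
    if cfg.n_cycles < 1:
        v.append("n_cycles: must be >= 1")
    if cfg.mode not in {"draws", "plug_in"}:
        v.append("mode: must be 'draws' or 'plug_in'")
    if not 0.0 <= cfg.simulate_missing_rate < 1.0:
        v.append("simulate_missing_rate: must be in [0, 1)")
    if cfg.tau_scale <= 0:
        v.append("tau_scale: must be positive")
    unknown = [f for f in cfg.features if f not in FEATURES]
    if unknown:
        v.append(f"features: unrecognized name(s) {unknown}")
    given = [
        t
        for t in (cfg.train_table, cfg.validation_table, cfg.test_table)
        if t is not None
    ]
    if given and len(given) != 3:
        v.append("train/validation/test tables must be given together")
    if cfg.input_table is not None and given:
        v.append("give either input_table or per-split tables, not both")
    return v


def _config_hash(cfg: RunConfig) -> str:
    return hashlib.sha256(
        json.dumps(cfg.to_dict(), sort_keys=True).encode()
    ).hexdigest()


def _load_inputs(cfg: RunConfig, seeds: dict) -> tuple[Dataset, Dataset, Dataset]:
    if cfg.input_table is not None:
        ds = harmonize_labels(read_variant_table(cfg.input_table, cfg.features))
        train, labelled = split_by_label_status(ds)
        validation, test = partition_validation_test(labelled, seeds["simulate"])
        return train, validation, test
    if cfg.train_table is not None:
        parts = []
        for path in (cfg.train_table, cfg.validation_table, cfg.test_table):
            parts.append(harmonize_labels(read_variant_table(path, cfg.features)))
        return tuple(parts)  # type: ignore[return-value]
    spec = GeneratorSpec(
        features=cfg.features,
        missing_rate=cfg.simulate_missing_rate,
        seed=seeds["simulate"],
    )
    return make_benchmark_fixture(seeds["simulate"], spec=spec)


def run_full_workflow(cfg: RunConfig) -> Path:
    """Execute the whole pipeline; returns the run directory.

    Artifacts: completed_{split}.csv, posterior_full.npz (and
    posterior_reduced.npz + trace.json when selection is on),
    predictions_{split}.csv, metrics.json, manifest.json. Any stage failure
    is re-raised with the stage name prepended.
    """
    violations = validate_config(cfg)
    if violations:
        raise ConfigError("; ".join(violations))
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = {s: stage_seed(cfg.seed, s) for s in _STAGES}

    stage = "simulate"
    try:
        train, validation, test = _load_inputs(cfg, seeds)
        for name, ds in (
            ("train", train),
            ("validation", validation),
            ("test", test),
        ):
            write_variant_table(ds, out / f"input_{name}.csv")

        stage = "impute"
        completed = {}
        for i, (name, ds) in enumerate(
            (("train", train), ("validation", validation), ("test", test))
        ):
            if np.isnan(ds.X).any():
                ds = pmm_impute(ds, cfg.pmm_config(seeds["impute"] + i))
            completed[name] = ds
            write_variant_table(ds, out / f"completed_{name}.csv")

        stage = "train"
        X_train = completed["train"].X
        priors = default_priors(X_train, tau_scale=cfg.tau_scale, ridge=cfg.ridge)
        draws = run_gibbs(
            X_train,
            priors,
            cfg.gibbs_config(seeds["train"]),
            features=cfg.features,
            anchor_feature=cfg.anchor_feature,
        )
        save_draws(draws, out / "posterior_full.npz")
        summary = summarize_posterior(draws, min_draws=min(40, draws.M))
        summary.table.to_csv(out / "posterior_summary_full.csv", index=False)
        models = {"full": (draws, list(cfg.features))}

        if cfg.select:
            stage = "select"
            trace = backward_eliminate(
                X_train, cfg.features, cfg.gibbs_config(seeds["select"])
            )
            trace_payload = {
                "note": trace.note,
                "steps": [
                    {
                        "feature_set": list(s.feature_set),
                        "removed_feature": s.removed_feature,
                        "dic": s.dic.dic,
                        "mean_deviance": s.dic.mean_deviance,
                        "p_d": s.dic.p_d,
                    }
                    for s in trace.steps
                ],
            }
            (out / "trace.json").write_text(json.dumps(trace_payload, indent=2))
            final = list(trace.final_features)
            cols = [cfg.features.index(f) for f in final]
            X_red = X_train[:, cols]
            red_draws = run_gibbs(
                X_red,
                default_priors(X_red, tau_scale=cfg.tau_scale, ridge=cfg.ridge),
                cfg.gibbs_config(seeds["select"] + 1),
                features=tuple(final),
                anchor_feature=cfg.anchor_feature,
            )
            save_draws(red_draws, out / "posterior_reduced.npz")
            models["reduced"] = (red_draws, final)

        stage = "predict"
        results = {}
        for model_name, (model_draws, feats) in models.items():
            cols = [cfg.features.index(f) for f in feats]
            for split_name, ds in completed.items():
                res = classify_variants(ds.X[:, cols], model_draws)
                results[(model_name, split_name)] = res
                if model_name == "full":
                    write_predictions(ds, res, out / f"predictions_{split_name}.csv")

        stage = "evaluate"
        metrics: dict = {}
        for model_name, (model_draws, feats) in models.items():
            cols = [cfg.features.index(f) for f in feats]
            metrics[model_name] = {
                "dic": compute_dic(
                    completed["train"].X[:, cols], model_draws
                ).dic
            }
            for split_name in ("validation", "test"):
                ds = completed[split_name]
                res = results[(model_name, split_name)]
                metrics[model_name][split_name] = evaluate_predictions(
                    ds.y.astype(int),
                    res.labels,
                    scores=res.pathogenicity_probability,
                )
        (out / "metrics.json").write_text(json.dumps(metrics, indent=2))

        manifest = {
            "package": "sanfilippopred",
            "version": __version__,
            "config": cfg.to_dict(),
            "config_hash": _config_hash(cfg),
            "stage_seeds": seeds,
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    except Exception as exc:
        if isinstance(exc, (ConfigError,)):
            raise
        raise type(exc)(f"stage '{stage}' failed: {exc}") from exc
    return out
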