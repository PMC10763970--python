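"""End-to-end experiment orchestration.

An experiment runs the full protocol on one cohort: optionally balance the
classes, split 80:20, fit every configured model, evaluate each on the
held-out split, run k-fold cross-validation, and compare model pairs with
paired t-tests over their evaluation-score vectors.  With balancing on,
both data settings (original and down-sampled) are processed, so each model
accumulates eight scores — accuracy and the three macro metrics per setting
— which is what the model-comparison t-test pairs (df = 7).

Reports are written twice: JSON for machines (full precision, no wall-clock
entries, so reruns are byte-identical) and Markdown for humans (half-up
rounding at 2 decimals).  Timing goes to the manifest only.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .balancing import BalanceConfig, balance_cohort
from .data_io import (
    Cohort,
    FeatureEncoder,
    read_thyroid_table,
    split_train_test,
)
from .ensembles import (
    BaseLearnerSpec,
    SelfStackingClassifier,
    SelfVotingClassifier,
    StackConfig,
    make_model,
)
from .evaluation import (
    kfold_cv,
    metric_report,
    model_score_vector,
    paired_ttest,
    round_half_up,
)
from .synthetic import GeneratorConfig, generate_cohort, make_separable_cohort

logger = logging.getLogger(__name__)

__all__ = ["ExperimentConfig", "run_experiment", "build_estimator"]

_FAMILY_KINDS = {
    "rf": "RF",
    "gbm": "GBM",
    "ada": "AdaBoost",
    "adaboost": "AdaBoost",
    "lr": "LR",
    "svc": "SVC",
}


def build_estimator(kind: str, seed: int = 0, options: dict | None = None):
    """Construct a fit/predict estimator for a model kind.

    Kinds: the five base families (``rf``, ``gbm``, ``ada``, ``lr``,
    ``svc``), the self-stacking classifier ``ssc``, and the self-voting
    ensembles ``svec-h`` / ``svec-s``.  ``options`` carries hyperparameter
    overrides (single models) or architecture knobs (``m``, ``k``,
    ``meta_mode``, ``n_base``, ``hyperparameters``) for the ensembles.
    """
    options = dict(options or {})
    kind = kind.lower()
    if kind in _FAMILY_KINDS:
        spec = BaseLearnerSpec(_FAMILY_KINDS[kind], options, seed=seed)
        return make_model(spec)
    hyper = options.pop("hyperparameters", {})
    base = BaseLearnerSpec("RF", hyper)
    if kind == "ssc":
        config = StackConfig(
            m=options.pop("m", 4),
            k=options.pop("k", 5),
            meta_mode=options.pop("meta_mode", "label"),
            base_spec=base,
            meta_spec=base,
            master_seed=seed,
        )
        if options:
            raise ValueError(f"unknown ssc options: {sorted(options)}")
        return SelfStackingClassifier(config)
    if kind in ("svec-h", "svec-s"):
        est = SelfVotingClassifier(
            n_base=options.pop("n_base", 3),
            spec=base,
            criterion="hard" if kind == "svec-h" else "soft",
            master_seed=seed,
        )
        if options:
            raise ValueError(f"unknown svec options: {sorted(options)}")
        return est
    raise ValueError(f"unknown model kind {kind!r}")


@dataclass
class ExperimentConfig:
    """Declarative description of one experiment run."""

    source: dict[str, Any]
    models: list[dict[str, Any]]
    balance: dict[str, Any] | None = None
    split: dict[str, Any] = field(
        default_factory=lambda: {"ratio": 0.2, "seed": 0, "shuffle": True}
    )
    cv: dict[str, Any] | None = field(
        default_factory=lambda: {"k": 10, "seed": 0}
    )
    comparisons: list[list[str]] = field(default_factory=list)
    output_dir: str = "selfstack-out"
    model_seed: int = 0

    def __post_init__(self) -> None:
        names = [m["name"] for m in self.models]
        if len(set(names)) != len(names):
            raise ValueError("model names must be unique")
        for pair in self.comparisons:
            for name in pair:
                if name not in names:
                    raise ValueError(f"comparison references unknown model {name!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_dict(self) -> dict[str, Any]:
        return {
            "source": self.source,
            "models": self.models,
            "balance": self.balance,
            "split": self.split,
            "cv": self.cv,
            "comparisons": self.comparisons,
            "output_dir": self.output_dir,
            "model_seed": self.model_seed,
        }


def _load_cohort(source: dict[str, Any]) -> Cohort:
    if "path" in source:
        return read_thyroid_table(source["path"])
    preset = source.get("preset")
    seed = source.get("seed", 0)
    if preset == "separable":
        return make_separable_cohort(
            n_per_class=source.get("n_per_class", 230),
            n_classes=source.get("n_classes", 5),
            seed=seed,
        )
    if preset == "thyroid-skew":
        kwargs = {
            k: source[k]
            for k in (
                "class_counts",
                "effect_size",
                "flip_rate",
                "missing_rate",
                "n_continuous",
                "n_binary",
            )
            if k in source
        }
        return generate_cohort(GeneratorConfig(seed=seed, **kwargs))
    raise ValueError("source must give a 'path' or a known 'preset'")


def _evaluate_setting(
    cohort: Cohort, config: ExperimentConfig, setting: str
) -> dict[str, Any]:
    encoded = FeatureEncoder().fit_transform(cohort)
    split = split_train_test(
        encoded,
        ratio=config.split.get("ratio", 0.2),
        seed=config.split.get("seed", 0),
        shuffle=config.split.get("shuffle", True),
    )
    out: dict[str, Any] = {"setting": setting, "models": {}}
    for mspec in config.models:
        name, kind = mspec["name"], mspec["kind"]
        options = mspec.get("options", {})
        logger.info("[%s] fitting %s", setting, name)
        est = build_estimator(kind, seed=config.model_seed, options=options)
        est.fit(split.train.X, split.train.y)
        pred = est.predict(split.test.X)
        report = metric_report(split.test.y, pred, encoded.class_map)
        entry: dict[str, Any] = {"report": report}
        if config.cv:
            entry["cv"] = kfold_cv(
                lambda k=kind, o=options: build_estimator(
                    k, seed=config.model_seed, options=o
                ),
                encoded,
                k=config.cv.get("k", 10),
                seed=config.cv.get("seed", 0),
            )
        out["models"][name] = entry
    return out


def run_experiment(config: ExperimentConfig) -> dict[str, Any]:
    """Run the full protocol and write the report bundle.

    Returns the in-memory result: per-setting per-model MetricReports and
    CVResults plus TTestResults for the configured comparisons.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = _load_cohort(config.source)

    settings: list[tuple[str, Cohort]] = [("original", cohort)]
    if config.balance is not None:
        bc = BalanceConfig(
            min_class_size=config.balance.get("min_class_size", 200),
            per_class_n=config.balance.get("per_class_n", 230),
        )
        balanced, plan = balance_cohort(
            cohort, bc, allow_short=config.balance.get("allow_short", False)
        )
        settings.append(("balanced", balanced))
        (outdir / "balance_plan.json").write_text(
            json.dumps(
                {
                    "selected_classes": plan.selected_classes,
                    "dropped_classes": plan.dropped_classes,
                    "kept_counts": {
                        c: len(ix) for c, ix in plan.kept_indices.items()
                    },
                },
                indent=2,
            )
        )

    results = {name: _evaluate_setting(c, config, name) for name, c in settings}

    comparisons: dict[str, Any] = {}
    for a, b in config.comparisons:
        va = model_score_vector(
            [results[s]["models"][a]["report"] for s, _ in settings]
        )
        vb = model_score_vector(
            [results[s]["models"][b]["report"] for s, _ in settings]
        )
        comparisons[f"{a}_vs_{b}"] = paired_ttest(va, vb)

    _write_bundle(outdir, config, results, comparisons)
    return {"settings": results, "comparisons": comparisons}


def _cv_dict(cv) -> dict[str, Any]:
    return {
        "fold_accuracies": cv.fold_accuracies,
        "mean_accuracy": cv.mean_accuracy,
        "sd": cv.sd,
        "k": cv.k,
        "seed": cv.seed,
    }


def _write_bundle(outdir: Path, config, results, comparisons) -> None:
    timings: dict[str, float] = {}
    md = ["# Experiment report", ""]
    for setting, res in results.items():
        sdir = outdir / setting
        for name, entry in res["models"].items():
            mdir = sdir / name
            mdir.mkdir(parents=True, exist_ok=True)
            report = entry["report"]
            (mdir / "report.json").write_text(
                json.dumps(report.to_dict(), indent=2)
            )
            md += [f"## {name} ({setting})", "", report.to_markdown(), ""]
            if "cv" in entry:
                cv = entry["cv"]
                (mdir / "cv.json").write_text(
                    json.dumps(_cv_dict(cv), indent=2)
                )
                timings[f"{setting}/{name}/cv_seconds"] = cv.elapsed_seconds
                md += [
                    f"{cv.k}-fold CV accuracy: "
                    f"{round_half_up(cv.mean_accuracy)} "
                    f"+/- {round_half_up(cv.sd)}",
                    "",
                ]
    if comparisons:
        comp_json = {
            key: {
                "t_statistic": t.t_statistic,
                "df": t.df,
                "p_value": t.p_value,
                "alpha": t.alpha,
                "reject_null": t.reject_null,
            }
            for key, t in comparisons.items()
        }
        (outdir / "comparisons.json").write_text(json.dumps(comp_json, indent=2))
        md += ["## Model comparisons (paired t-test)", ""]
        md += ["| Pair | t | df | p | reject H0 |", "|---|---|---|---|---|"]
        for key, t in comparisons.items():
            md.append(
                f"| {key} | {round_half_up(t.t_statistic, 3)} | {t.df} "
                f"| {round_half_up(t.p_value, 4)} | {t.reject_null} |"
            )
        md.append("")
    (outdir / "report.md").write_text("\n".join(md))

    cfg = config.to_dict()
    manifest = {
        "config": cfg,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest(),
        "selfstack_version": __version__,
        "timings_seconds": timings,
    }
    try:
        import sklearn
        import numpy

        manifest["library_versions"] = {
            "scikit-learn": sklearn.__version__,
            "numpy": numpy.__version__,
        }
    except Exception:  # pragma: no cover
        pass
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
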