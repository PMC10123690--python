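"""Staged end-to-end experiment pipeline on synthetic data.

Stages: ``synth`` (feature table) -> ``select`` (feature selection runs) ->
``tune`` (classifier hyperparameter tuning on the best mask) -> ``evaluate``
(stratified k-fold of the tuned classifier) -> ``report`` (summary tables).
Each stage persists a JSON/CSV artifact and reads its inputs from the output
directory, so the pipeline can be resumed from any stage. Stage seeds are
derived as ``seed_base + stage offset``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .classify import (
    default_classifier_factory,
    default_hyperparam_space,
    kfold_evaluate,
    tune_classifier,
)
from .feature_selection import (
    FSConfig,
    random_mask_select,
    run_fs_experiment,
    select_features,
)
from .io import load_feature_csv, load_mask_json, save_feature_csv, save_mask_json
from .metrics import fs_run_statistics
from .optimizers import ConfigurationError, OptimizerConfig
from .reports import descriptive_table, run_statistics_table, wilcoxon_table, write_table
from .synthetic import SyntheticSpec, gen_feature_dataset

__all__ = ["ExperimentConfig", "PipelineError", "STAGES", "run_pipeline"]

STAGES = ("synth", "select", "tune", "evaluate", "report")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class ExperimentConfig:
    out_dir: str = "results"
    seed_base: int = 0
    n_runs: int = 5
    label_col: str = "label"
    synth: SyntheticSpec = field(default_factory=SyntheticSpec)
    fs: FSConfig = field(default_factory=FSConfig)
    tuning_optimizer: OptimizerConfig = field(
        default_factory=lambda: OptimizerConfig(n_agents=5, n_iterations=10)
    )
    kfold: int = 5

    ALLOWED_KEYS = {
        "out_dir",
        "seed_base",
        "n_runs",
        "label_col",
        "synth",
        "fs",
        "optimizer",
        "tuning_optimizer",
        "kfold",
    }

    @classmethod
    def from_dict(cls, data: dict) -> "ExperimentConfig":
        unknown = set(data) - cls.ALLOWED_KEYS
        if unknown:
            raise ConfigurationError(f"unknown configuration keys {sorted(unknown)}")
        kwargs = {}
        for key in ("out_dir", "seed_base", "n_runs", "label_col", "kfold"):
            if key in data:
                kwargs[key] = data[key]
        if "synth" in data:
            kwargs["synth"] = SyntheticSpec(**data["synth"])
        optimizer = OptimizerConfig(**data.get("optimizer", {}))
        fs_kwargs = dict(data.get("fs", {}))
        kwargs["fs"] = FSConfig(optimizer=optimizer, **fs_kwargs)
        if "tuning_optimizer" in data:
            kwargs["tuning_optimizer"] = OptimizerConfig(**data["tuning_optimizer"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        out = asdict(self)
        return out


def _stage_synth(config: ExperimentConfig, out: Path) -> None:
    from dataclasses import replace

    spec = replace(config.synth, seed=config.seed_base)
    dataset, informative = gen_feature_dataset(spec)
    save_feature_csv(dataset, out / "features.csv", config.label_col)
    (out / "synth.json").write_text(
        json.dumps(
            {
                "schema_version": 1,
                "spec": asdict(spec),
                "informative_indices": informative.tolist(),
            },
            indent=2,
        )
    )


def _stage_select(config: ExperimentConfig, out: Path) -> None:
    dataset = load_feature_csv(out / "features.csv", config.label_col)
    seed = config.seed_base + 1
    methods = {
        "bDDTPSO": lambda ds, cfg, s: select_features(ds, cfg, s),
        "random_mask": lambda ds, cfg, s: random_mask_select(ds, cfg, s),
    }
    results = run_fs_experiment(dataset, methods, config.n_runs, seed, config.fs)
    best = min(results["bDDTPSO"], key=lambda r: r.best_fitness)
    save_mask_json(
        best.best_mask,
        out / "fsresult.json",
        dataset.feature_names,
        extra={
            "best_fitness": best.best_fitness,
            "error_rate": best.error_rate,
            "seed": best.seed,
            "per_method_runs": {
                name: [r.to_dict(dataset.feature_names) for r in runs]
                for name, runs in results.items()
            },
        },
    )


def _stage_tune(config: ExperimentConfig, out: Path) -> None:
    dataset = load_feature_csv(out / "features.csv", config.label_col)
    mask = load_mask_json(out / "fsresult.json")
    from dataclasses import replace

    opt = replace(config.tuning_optimizer, seed=config.seed_base + 2)
    tuned = tune_classifier(
        dataset, mask.bits, default_hyperparam_space(), opt, default_classifier_factory
    )
    (out / "tuned.json").write_text(
        json.dumps({"schema_version": 1, **tuned.to_dict()}, indent=2)
    )


def _stage_evaluate(config: ExperimentConfig, out: Path) -> None:
    dataset = load_feature_csv(out / "features.csv", config.label_col)
    mask = load_mask_json(out / "fsresult.json")
    tuned = json.loads((out / "tuned.json").read_text())
    params = tuned["best_params"]
    report, counts, _folds = kfold_evaluate(
        dataset,
        mask.bits,
        lambda: default_classifier_factory(params),
        k=config.kfold,
        seed=config.seed_base + 3,
    )
    (out / "evaluation.json").write_text(
        json.dumps(
            {"schema_version": 1, "kfold": config.kfold, "counts": asdict(counts), "metrics": asdict(report)},
            indent=2,
        )
    )


def _stage_report(config: ExperimentConfig, out: Path) -> None:
    from .feature_selection import FeatureMask, FSRunResult

    payload = json.loads((out / "fsresult.json").read_text())
    stats = {}
    errors = {}
    for name, runs in payload["per_method_runs"].items():
        parsed = [
            FSRunResult(
                best_mask=FeatureMask(np.asarray(r["best_mask"]["bits"], dtype=np.int8)),
                best_fitness=r["best_fitness"],
                error_rate=r["error_rate"],
                fitness_history=r["fitness_history"],
                seed=r["seed"],
            )
            for r in runs
        ]
        stats[name] = fs_run_statistics(parsed)
        errors[name] = [r.error_rate for r in parsed]
    write_table(run_statistics_table(stats), out / "report.csv")
    write_table(descriptive_table(errors), out / "report_descriptive.csv")
    if all(len(v) >= 1 and all(x != 0 for x in v) for v in errors.values()):
        write_table(wilcoxon_table(errors), out / "report_wilcoxon.csv")
    summary = {
        "schema_version": 1,
        "run_statistics": {k: asdict(v) for k, v in stats.items()},
        "evaluation": json.loads((out / "evaluation.json").read_text()),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))


_STAGE_FUNCS = {
    "synth": _stage_synth,
    "select": _stage_select,
    "tune": _stage_tune,
    "evaluate": _stage_evaluate,
    "report": _stage_report,
}


def run_pipeline(config: ExperimentConfig, start_stage: str = "synth") -> Path:
    """Run the staged pipeline; artifacts land in ``config.out_dir``.

    A stage failure raises :class:`PipelineError` naming the stage; artifacts
    from completed stages remain on disk.
    """
    if start_stage not in STAGES:
        raise ConfigurationError(f"unknown stage {start_stage!r}; choose from {STAGES}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "effective_config.json").write_text(
        json.dumps({"schema_version": 1, **config.to_dict()}, indent=2, default=str)
    )
    for stage in STAGES[STAGES.index(start_stage):]:
        try:
            _STAGE_FUNCS[stage](config, out)
        except (ConfigurationError, PipelineError):
            raise
        except Exception as exc:  # noqa: BLE001 - halt with the stage name
            raise PipelineError(stage, str(exc)) from exc
    return out
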