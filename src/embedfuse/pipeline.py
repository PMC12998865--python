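"""End-to-end orchestration of the six-step evaluate-a-fusion workflow.

1. load the dataset splits (through registered providers and the cache);
2. exhaustive (or singles-only) subset search on train/valid;
3. build the fusion model and emit train/valid embeddings;
4. tune the probe's hyperparameters on train, selecting by validation
   accuracy;
5. generate test embeddings with the fusion model;
6. score the tuned probe on test, averaging accuracy and AUC over
   ``n_final_runs`` probe seeds (default 3).

Each stage persists its artifact (``leaderboard.csv``, ``search.json``,
``trials.csv``, ``tuned.json``, ``metrics.json``, ``config.resolved.yaml``)
into the run directory; with ``resume=True`` a stage whose artifact already
exists is skipped and its result reloaded, so deleting one artifact re-runs
the pipeline from that stage only.  A run is fully reproducible from its
persisted config and seed.

Ordinal-regression label sets are handled as plain multi-class tasks.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cache import EmbeddingCache
from .errors import EmbedFuseError
from .fusion import AttentionFusionConfig
from .probe import ProbeConfig, TunerConfig, score_multi_seed, tune_probe
from .registry import Registry
from .search import FusionModel, SearchResult, build_fusion_model, run_search


@dataclass
class RunConfig:
    """Everything needed to reproduce one run."""

    dataset_id: str = "dataset"
    cache_root: str | None = None
    mode: str = "exhaustive"  # or "singles_only"
    fusion: dict = field(default_factory=lambda: {"strategy": "concat"})
    probe: dict = field(default_factory=dict)  # overrides of ProbeConfig fields
    tuner: dict = field(default_factory=dict)  # overrides of TunerConfig fields
    n_final_runs: int = 3
    seed: int = 0
    output_dir: str = "run"

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def probe_config(self) -> ProbeConfig:
        return ProbeConfig(seed=self.seed, **self.probe)

    def tuner_config(self) -> TunerConfig:
        return TunerConfig(seed=self.seed, **self.tuner)

    def attention_config(self) -> AttentionFusionConfig:
        kwargs = {k: v for k, v in self.fusion.items() if k != "strategy"}
        kwargs.setdefault("seed", self.seed)
        return AttentionFusionConfig(**kwargs)


@dataclass
class RunReport:
    """Outcome of a workflow run."""

    selected: tuple[str, ...]
    fused_dim: int
    valid_accuracy: float
    tuned_params: dict
    test_metrics: dict
    stages: dict  # stage -> "computed" | "resumed" | "failed: ..."
    timings: dict  # stage -> seconds

    def to_dict(self) -> dict:
        return {
            "selected": list(self.selected),
            "fused_dim": self.fused_dim,
            "valid_accuracy": self.valid_accuracy,
            "tuned_params": self.tuned_params,
            "test_metrics": self.test_metrics,
            "stages": self.stages,
            "timings": self.timings,
        }


def run_workflow(
    config: RunConfig, registry: Registry, resume: bool = False
) -> RunReport:
    """Execute the six-step workflow; artifacts land in ``config.output_dir``."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.resolved.yaml")
    cache = EmbeddingCache(config.cache_root) if config.cache_root else None
    strategy = config.fusion.get("strategy", "concat")
    stages: dict[str, str] = {}
    timings: dict[str, float] = {}

    # -- stage 2: subset search ------------------------------------------
    search_json = outdir / "search.json"
    t0 = time.perf_counter()
    if resume and search_json.exists():
        state = json.loads(search_json.read_text())
        selected = tuple(state["selected"])
        valid_acc = state["selected_accuracy"]
        result = None
        stages["search"] = "resumed"
    else:
        result = run_search(
            registry,
            dataset_id=config.dataset_id,
            probe_config=config.probe_config(),
            mode=config.mode,
            seed=config.seed,
            cache=cache,
            fusion=strategy,
            attention_config=(
                config.attention_config() if strategy == "self_attention" else None
            ),
        )
        selected = result.selected
        valid_acc = result.selected_accuracy
        result.to_dataframe().to_csv(outdir / "leaderboard.csv", index=False)
        search_json.write_text(json.dumps({
            "selected": list(selected),
            "selected_accuracy": valid_acc,
            "mode": result.mode,
            "n_evaluated": result.n_evaluated,
            "seed": result.seed,
            "fusion": result.fusion,
        }))
        stages["search"] = "computed"
    timings["search"] = time.perf_counter() - t0

    # -- stage 3: fusion model + train/valid embeddings -------------------
    t0 = time.perf_counter()
    if result is not None:
        model = build_fusion_model(result, registry, cache)
    else:  # resumed: rebuild from the persisted selection (concat only)
        if strategy == "self_attention":
            raise EmbedFuseError(
                "cannot resume a self-attention run past the search stage; "
                "re-run the search to refit the fusion block"
            )
        model = FusionModel(registry=registry, selected=selected,
                             dataset_id=config.dataset_id, cache=cache)
    train_fused = model.transform("train")
    valid_fused = model.transform("valid")
    stages["embed"] = "computed"
    timings["embed"] = time.perf_counter() - t0

    # -- stage 4: probe tuning --------------------------------------------
    tuned_json = outdir / "tuned.json"
    t0 = time.perf_counter()
    if resume and tuned_json.exists():
        tuned_params = json.loads(tuned_json.read_text())
        best_cfg = ProbeConfig(
            n_estimators=int(tuned_params["n_estimators"]),
            learning_rate=float(tuned_params["learning_rate"]),
            max_depth=int(tuned_params["max_depth"]),
            seed=config.seed,
            extra={k: v for k, v in tuned_params.items()
                   if k not in ("n_estimators", "learning_rate", "max_depth")},
        )
        stages["tune"] = "resumed"
    else:
        best_cfg, trials = tune_probe(
            train_fused, train_fused.labels, valid_fused, valid_fused.labels,
            config.tuner_config(),
        )
        trials.to_csv(outdir / "trials.csv", index=False)
        tuned_params = best_cfg.flat_params()
        tuned_json.write_text(json.dumps(tuned_params))
        stages["tune"] = "computed"
    timings["tune"] = time.perf_counter() - t0

    # -- stages 5-6: test embeddings + final scoring ----------------------
    t0 = time.perf_counter()
    test_fused = model.transform("test")
    report = score_multi_seed(
        train_fused, train_fused.labels, test_fused, test_fused.labels,
        best_cfg, n_runs=config.n_final_runs,
    )
    metrics = {
        "selected": list(selected),
        "fused_dim": model.fused_dim,
        "valid_accuracy": valid_acc,
        "test": report.to_dict(),
    }
    (outdir / "metrics.json").write_text(json.dumps(metrics, indent=2))
    stages["evaluate"] = "computed"
    timings["evaluate"] = time.perf_counter() - t0

    return RunReport(
        selected=selected,
        fused_dim=model.fused_dim,
        valid_accuracy=valid_acc,
        tuned_params=tuned_params,
        test_metrics=report.to_dict(),
        stages=stages,
        timings=timings,
    )


def report(run_dir: str | Path) -> dict:
    """Summarise a completed or partial run; writes ``summary.json`` beside
    the artifacts and returns the summary dict."""
    run_dir = Path(run_dir)
    if not run_dir.is_dir():
        raise FileNotFoundError(f"no run directory at {run_dir}")
    summary: dict = {"run_dir": str(run_dir), "missing_stages": []}

    search_json = run_dir / "search.json"
    if search_json.exists():
        state = json.loads(search_json.read_text())
        summary["selected"] = state["selected"]
        summary["valid_accuracy"] = state["selected_accuracy"]
        summary["n_evaluated"] = state["n_evaluated"]
    else:
        summary["missing_stages"].append("search")

    trials_csv = run_dir / "trials.csv"
    if trials_csv.exists():
        trials = pd.read_csv(trials_csv)
        summary["n_trials"] = int(len(trials))
        summary["best_valid_accuracy"] = float(trials["valid_accuracy"].max())
    else:
        summary["missing_stages"].append("tune")

    metrics_json = run_dir / "metrics.json"
    if metrics_json.exists():
        metrics = json.loads(metrics_json.read_text())
        summary["fused_dim"] = metrics["fused_dim"]
        summary["test_accuracy"] = metrics["test"]["accuracy"]
        summary["test_auc"] = metrics["test"]["auc"]
    else:
        summary["missing_stages"].append("evaluate")

    (run_dir / "summary.json").write_text(json.dumps(summary, indent=2))
    return summary


def format_summary(summary: dict) -> str:
    lines = [f"run: {summary['run_dir']}"]
    if "selected" in summary:
        lines.append(f"  selected subset : {'+'.join(summary['selected'])}")
        lines.append(f"  valid accuracy  : {summary['valid_accuracy']:.4f}")
        lines.append(f"  subsets scored  : {summary['n_evaluated']}")
    if "fused_dim" in summary:
        lines.append(f"  fused dim       : {summary['fused_dim']}")
        lines.append(f"  test accuracy   : {summary['test_accuracy']:.4f}")
        lines.append(f"  test AUC        : {summary['test_auc']:.4f}")
    if summary["missing_stages"]:
        lines.append(f"  missing stages  : {', '.join(summary['missing_stages'])}")
    return "\n".join(lines)
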