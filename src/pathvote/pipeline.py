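"""End-to-end orchestration: simulate-or-load, split, fit, evaluate, write.

This is the programmatic equivalent of the ``run-all`` CLI subcommand; the
CLI is a thin wrapper around :func:`run_all`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import io
from ._seeds import derive_int
from .config import RunConfig
from .containers import ExpressionDataset, GeneSetCollection
from .learners import CVProtocol
from .metrics import MetricsReport, evaluate_on_test
from .optimizer import EnsembleModel, fit_ensemble
from .simulate import SimulationConfig, simulate, split_dataset

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run_all"]


@dataclass
class PipelineResult:
    model: EnsembleModel
    metrics: MetricsReport
    train: ExpressionDataset
    test: ExpressionDataset
    pathways: GeneSetCollection
    ground_truth: frozenset[str] | None = None


def run_all(
    config: RunConfig,
    expression: str | Path | None = None,
    labels: str | Path | None = None,
    gmt: str | Path | None = None,
    positive_label: str | None = None,
    sim_config: SimulationConfig | None = None,
    train_fraction: float = 0.5,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Load (or simulate) a cohort, split it, fit the ensemble, evaluate it.

    Either all three input paths are given, or a :class:`SimulationConfig`
    is; artifacts (model/trace JSON, metrics TSV, accuracy-curve TSV) are
    written to ``out_dir`` when provided.
    """
    ground_truth = None
    if sim_config is not None:
        dataset, pathways, ground_truth = simulate(sim_config)
    else:
        if expression is None or labels is None or gmt is None:
            raise io.FormatError("need expression, labels and GMT paths (or a simulation config)")
        if positive_label is None:
            raise io.FormatError("need the positive class label")
        dataset = io.read_expression(expression)
        dataset = dataset.with_labels(io.read_labels(labels, positive_label), positive_label)
        pathways = io.read_gmt(gmt)

    train, test = split_dataset(dataset, train_fraction, seed=derive_int(config.seed, "split"))
    logger.info(
        "split: train %s, test %s", train.class_counts(), test.class_counts()
    )
    model = fit_ensemble(train, pathways, config)
    protocol = CVProtocol(
        n_runs=config.n_runs,
        n_folds=config.n_folds,
        balance=True,
        seed=derive_int(config.seed, "test"),
    )
    metrics = evaluate_on_test(model, test, protocol)
    logger.info("test metrics (mean over %d runs): %s", metrics.n_runs, metrics.mean)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        io.write_results(model, metrics, out / "model.json")
        with open(out / "trace.json", "w", encoding="utf-8") as fh:
            json.dump(model.trace.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
        pd.DataFrame(
            list(model.trace.prefix_accuracies), columns=["n_base_classifiers", "cv_accuracy"]
        ).to_csv(out / "accuracy_curve.tsv", sep="\t", index=False)
        rows = [{"metric": k, "mean": metrics.mean[k], "sd": metrics.sd[k]} for k in metrics.mean]
        pd.DataFrame(rows).to_csv(out / "metrics.tsv", sep="\t", index=False)
        if ground_truth is not None:
            with open(out / "ground_truth.json", "w", encoding="utf-8") as fh:
                json.dump(sorted(ground_truth), fh)
                fh.write("\n")
    return PipelineResult(
        model=model,
        metrics=metrics,
        train=train,
        test=test,
        pathways=pathways,
        ground_truth=ground_truth,
    )
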