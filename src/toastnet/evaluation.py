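"""Evaluation: imbalance-aware metrics, cross-validation, experiment grids.

Multiclass metrics follow the support-weighted convention: per-class
precision, recall and F1 (from the confusion matrix's TP/FP/FN/TN) are
averaged with weights proportional to class frequency. Under that
convention weighted recall is algebraically identical to overall accuracy
— ``sum_c (n_c/N)(TP_c/n_c) = sum_c TP_c / N`` — which is why accuracy and
recall columns coincide in every report. AUC is one-vs-rest area under the
ROC curve, support-weighted by default.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import (
    confusion_matrix as sk_confusion,
    precision_recall_fscore_support,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold, KFold, train_test_split

from . import preprocessing as prep
from .active_loop import CycleConfig, run_active_cycle
from .causal_net import CausalCNN, NetworkSpec, build_network, predict_proba, train
from .losses import LOSS_NAMES, LossConfig
from .synthetic_cohort import CohortTable
from .uncertainty import STRATEGIES


@dataclass
class MetricsReport:
    """Overall and per-class classification metrics."""

    accuracy: float
    auc: float
    precision: float
    recall: float
    f1: float
    per_class: pd.DataFrame
    confusion: np.ndarray
    n_samples: int = 0

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "auc": self.auc,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "per_class": self.per_class.to_dict(orient="index"),
            "confusion": self.confusion.tolist(),
            "n_samples": self.n_samples,
        }


def compute_metrics(
    y_true: np.ndarray,
    proba: np.ndarray,
    class_names: Sequence[str] | None = None,
    auc_average: str = "weighted",
) -> MetricsReport:
    """Score a probability matrix against true labels.

    The predicted class is the row argmax (ties to the lowest index).
    Classes absent from ``y_true`` are excluded from averaging with a
    warning. Raises if any probability row is not normalized.
    """
    y_true = np.asarray(y_true, dtype=int)
    proba = np.atleast_2d(np.asarray(proba, dtype=float))
    if len(y_true) != len(proba):
        raise ValueError("y_true and proba length mismatch")
    if not np.allclose(proba.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("probability rows must sum to 1")
    k = proba.shape[1]
    y_pred = proba.argmax(axis=1)
    present = np.unique(y_true)
    if len(present) < k:
        missing = sorted(set(range(k)) - set(present.tolist()))
        warnings.warn(
            f"classes {missing} absent from y_true; excluded from averages",
            stacklevel=2,
        )
    prec, rec, f1, support = precision_recall_fscore_support(
        y_true, y_pred, labels=present, zero_division=0
    )
    weights = support / support.sum()
    names = class_names or [f"class_{c}" for c in range(k)]
    per_class = pd.DataFrame(
        {"precision": prec, "recall": rec, "f1": f1, "support": support},
        index=[names[c] for c in present],
    )
    accuracy = float((y_pred == y_true).mean())
    aucs = []
    for c in present:
        binary = (y_true == c).astype(int)
        if binary.all() or not binary.any():
            aucs.append(np.nan)
        else:
            aucs.append(roc_auc_score(binary, proba[:, c]))
    aucs = np.asarray(aucs)
    ok = ~np.isnan(aucs)
    if not ok.any():
        auc = float("nan")
    elif auc_average == "weighted":
        auc = float(np.average(aucs[ok], weights=weights[ok]))
    else:
        auc = float(np.mean(aucs[ok]))
    return MetricsReport(
        accuracy=accuracy,
        auc=auc,
        precision=float(np.average(prec, weights=weights)),
        recall=float(np.average(rec, weights=weights)),
        f1=float(np.average(f1, weights=weights)),
        per_class=per_class,
        confusion=sk_confusion(y_true, y_pred, labels=np.arange(k)),
        n_samples=len(y_true),
    )


def report_delta(report_a: MetricsReport, report_b: MetricsReport) -> dict:
    """Signed differences (b minus a), overall and per class."""
    if list(report_a.per_class.index) != list(report_b.per_class.index):
        raise ValueError("reports cover different class sets")
    overall = {
        m: getattr(report_b, m) - getattr(report_a, m)
        for m in ("accuracy", "auc", "precision", "recall", "f1")
    }
    cols = ["precision", "recall", "f1"]
    per_class = report_b.per_class[cols] - report_a.per_class[cols]
    return {"overall": overall, "per_class": per_class}


def _mean_report(reports: list[MetricsReport]) -> MetricsReport:
    per_class = sum(r.per_class.fillna(0.0) for r in reports) / len(reports)
    return MetricsReport(
        accuracy=float(np.mean([r.accuracy for r in reports])),
        auc=float(np.nanmean([r.auc for r in reports])),
        precision=float(np.mean([r.precision for r in reports])),
        recall=float(np.mean([r.recall for r in reports])),
        f1=float(np.mean([r.f1 for r in reports])),
        per_class=per_class,
        confusion=np.sum([r.confusion for r in reports], axis=0),
        n_samples=int(sum(r.n_samples for r in reports)),
    )


def fit_fold(
    table_train: CohortTable,
    table_test: CohortTable,
    model_factory: Callable[[int], CausalCNN],
    loss: LossConfig,
    epochs: int,
    batch_size: int,
    seed: int,
    importance_threshold: float = prep.DEFAULT_IMPORTANCE_THRESHOLD,
) -> tuple[CausalCNN, MetricsReport, prep.RankedFeatureMatrix]:
    """Preprocess (fit on train only), train, and score one split."""
    train_i, test_i = prep.impute_mode(table_train, [table_test])
    report = prep.compute_importance(train_i, seed=seed)
    try:
        ordering, _ = prep.filter_and_rank(report, importance_threshold)
    except ValueError:
        # degenerate split (e.g. no split gained anything): keep all features
        try:
            ordering, _ = prep.filter_and_rank(report, 0.0)
        except ValueError:
            ordering = list(report.importances)
    seq_train = prep.to_sequence(train_i, ordering)
    seq_test = prep.to_sequence(test_i, ordering)
    model = model_factory(seq_train.sequence_length)
    train(
        model,
        seq_train.values,
        train_i.labels,
        loss=loss,
        epochs=epochs,
        batch_size=batch_size,
        seed=seed,
    )
    metrics = compute_metrics(test_i.labels, predict_proba(model, seq_test.values))
    return model, metrics, seq_train


def cross_validate(
    model_factory: Callable[[int], CausalCNN],
    cohort: CohortTable,
    k: int = 10,
    stratified: bool = True,
    seed: int = 0,
    loss: LossConfig | None = None,
    epochs: int = 100,
    batch_size: int = 32,
) -> tuple[list[MetricsReport], MetricsReport]:
    """k-fold cross-validation with preprocessing fitted inside each fold.

    Folds are stratified by default (the cohort is severely imbalanced);
    a class with fewer than k members raises with a pointer to
    non-stratified mode.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    loss = loss or LossConfig()
    y = cohort.labels
    if stratified:
        counts = np.bincount(y)
        small = np.flatnonzero((counts > 0) & (counts < k))
        if small.size:
            raise ValueError(
                f"classes {small.tolist()} have fewer than {k} members; "
                "use stratified=False"
            )
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    reports = []
    for fold, (tr, te) in enumerate(splitter.split(cohort.data, y)):
        t_train = CohortTable(
            cohort.data.iloc[tr].reset_index(drop=True), y[tr], dict(cohort.kinds)
        )
        t_test = CohortTable(
            cohort.data.iloc[te].reset_index(drop=True), y[te], dict(cohort.kinds)
        )
        _, metrics, _ = fit_fold(
            t_train, t_test, model_factory, loss, epochs, batch_size, seed + fold
        )
        reports.append(metrics)
    return reports, _mean_report(reports)


def run_experiment(config: dict, cohort: CohortTable, out_dir: str | Path | None = None):
    """Grid harness: one report per (variant, loss, strategy) cell.

    ``config`` keys: ``variants`` (list of V1..V4), ``losses`` (names from
    the loss menu), ``strategies`` (``none`` for no active cycle, or a
    query-criterion name), plus optional ``alpha``, ``fraction``,
    ``epochs``, ``batch_size``, ``test_size``, ``seed``. Names are checked
    before any training. Results go to CSV + JSON when ``out_dir`` is set.
    """
    variants = config.get("variants", ["V4"])
    losses = config.get("losses", ["kl_focal"])
    strategies = config.get("strategies", ["none"])
    if not variants or not losses or not strategies:
        raise ValueError("empty experiment grid")
    from .causal_net import VARIANTS

    for v in variants:
        if v not in VARIANTS:
            raise ValueError(f"unknown variant '{v}'")
    for name in losses:
        if name not in LOSS_NAMES:
            raise ValueError(f"unknown loss '{name}'")
    for s in strategies:
        if s != "none" and s not in STRATEGIES:
            raise ValueError(f"unknown strategy '{s}'")

    seed = int(config.get("seed", 0))
    epochs = int(config.get("epochs", 100))
    batch_size = int(config.get("batch_size", 32))
    test_size = float(config.get("test_size", 0.2))
    idx = np.arange(cohort.n_patients)
    tr, te = train_test_split(
        idx, test_size=test_size, stratify=cohort.labels, random_state=seed
    )
    t_train = CohortTable(
        cohort.data.iloc[tr].reset_index(drop=True),
        cohort.labels[tr],
        dict(cohort.kinds),
    )
    t_test = CohortTable(
        cohort.data.iloc[te].reset_index(drop=True),
        cohort.labels[te],
        dict(cohort.kinds),
    )
    rows, results = [], {}
    for variant in variants:
        for loss_name in losses:
            loss = LossConfig(
                name=loss_name,
                gamma=float(config.get("gamma", 2.0)),
                label_smoothing=float(config.get("label_smoothing", 0.05)),
            )
            for strategy in strategies:
                factory = lambda L, v=variant: build_network(
                    NetworkSpec(variant=v, sequence_length=L, seed=seed)
                )
                model, metrics, seq_train = fit_fold(
                    t_train, t_test, factory, loss, epochs, batch_size, seed
                )
                if strategy != "none":
                    cc = CycleConfig(
                        strategy=strategy,
                        alpha=float(config.get("alpha", 0.3)),
                        fraction=float(config.get("fraction", 0.5)),
                        finetune_epochs=int(config.get("finetune_epochs", epochs)),
                        batch_size=batch_size,
                        seed=seed,
                        loss=loss,
                    )
                    run_active_cycle(seq_train.values, t_train.labels, model, cc)
                    seq_test = prep.to_sequence(
                        prep.impute_mode(t_train, [t_test])[1], seq_train.ordering
                    )
                    metrics = compute_metrics(
                        t_test.labels, predict_proba(model, seq_test.values)
                    )
                cell = f"{variant}|{loss_name}|{strategy}"
                results[cell] = metrics
                rows.append(
                    {
                        "variant": variant,
                        "loss": loss_name,
                        "strategy": strategy,
                        "accuracy": metrics.accuracy,
                        "auc": metrics.auc,
                        "precision": metrics.precision,
                        "recall": metrics.recall,
                        "f1": metrics.f1,
                    }
                )
    frame = pd.DataFrame(rows)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        frame.to_csv(out / "grid.csv", index=False)
        with open(out / "grid.json", "w") as fh:
            json.dump({k: v.to_dict() for k, v in results.items()}, fh, indent=2)
    return results, frame
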