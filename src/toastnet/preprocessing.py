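"""Data preparation for the causal classifier.

The pipeline mirrors how a neurologist triages information: a
gradient-boosted tree ensemble scores every feature's importance, weak
features (importance <= 0.005 by default) are dropped, the survivors are
ranked most-important-first, and each patient becomes an ordered feature
sequence read left to right by the causal network. Missing cells are filled
with the per-feature mode estimated on the training split; feature values
are deliberately left unscaled so every cell of the sequence equals a raw
table value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from xgboost import XGBClassifier

from .synthetic_cohort import CohortTable

DEFAULT_IMPORTANCE_THRESHOLD = 0.005


@dataclass
class ImportanceReport:
    """Normalized per-feature importances from the tree ensemble."""

    importances: dict[str, float]
    method: str = "xgboost-gain"
    fitted_on: int = 0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.importances.values()):
            raise ValueError("importances must be non-negative")


@dataclass
class RankedFeatureMatrix:
    """Per-patient feature sequences ordered by descending importance.

    Column ``i`` of ``values`` is the feature ranked ``i``-th (position 0 is
    the most important). Cell values are raw table values — no scaling.
    """

    values: np.ndarray
    ordering: list[str]
    dropped: list[str] = field(default_factory=list)

    @property
    def sequence_length(self) -> int:
        return self.values.shape[1]


def compute_importance(
    table: CohortTable,
    *,
    n_estimators: int = 100,
    max_depth: int = 6,
    learning_rate: float = 0.3,
    seed: int = 0,
) -> ImportanceReport:
    """Fit a gradient-boosted tree ensemble and return gain importances.

    Importances are normalized to sum to 1; features the ensemble never
    splits on (e.g. constants) get importance 0. Deterministic for a fixed
    seed. Raises if the labels contain a single class.
    """
    y = np.asarray(table.labels)
    if len(np.unique(y)) < 2:
        raise ValueError("feature importance is undefined for single-class labels")
    clf = XGBClassifier(
        n_estimators=n_estimators,
        max_depth=max_depth,
        learning_rate=learning_rate,
        random_state=seed,
        n_jobs=1,
        tree_method="hist",
        verbosity=0,
    )
    clf.fit(table.data.to_numpy(dtype=np.float64), y)
    booster = clf.get_booster()
    raw = booster.get_score(importance_type="gain")
    names = table.feature_names
    # booster keys are f0, f1, ... in column order
    gains = np.zeros(len(names))
    for key, value in raw.items():
        gains[int(key[1:])] = value
    total = gains.sum()
    if total > 0:
        gains = gains / total
    return ImportanceReport(
        importances=dict(zip(names, gains.tolist())),
        method="xgboost-gain",
        fitted_on=table.n_patients,
    )


def filter_and_rank(
    report: ImportanceReport,
    threshold: float = DEFAULT_IMPORTANCE_THRESHOLD,
) -> tuple[list[str], list[str]]:
    """Drop features with importance <= threshold; rank the rest.

    Survivors are sorted by descending importance with ties broken by
    original column order (stable sort). Returns ``(kept, dropped)``.
    """
    if not report.importances:
        raise ValueError("empty importance report")
    names = list(report.importances)
    kept = [n for n in names if report.importances[n] > threshold]
    dropped = [n for n in names if report.importances[n] <= threshold]
    if not kept:
        raise ValueError(
            f"all {len(names)} features fall at or below the importance "
            f"threshold {threshold}; lower the threshold or check the labels"
        )
    kept.sort(key=lambda n: -report.importances[n])  # stable: ties keep column order
    return kept, dropped


def impute_mode(
    train: CohortTable, apply_to: list[CohortTable] | None = None
) -> list[CohortTable]:
    """Fill missing cells with the per-feature mode of the training split.

    The mode is computed from observed training values only (ties resolved
    to the smallest value) and applied to the training table and every
    table in ``apply_to``. Returns the imputed tables, train first.
    """
    apply_to = apply_to or []
    modes: dict[str, float] = {}
    for name in train.feature_names:
        observed = train.data[name].dropna()
        if observed.empty:
            raise ValueError(f"feature '{name}' has no observed values in train")
        counts = observed.value_counts()
        top = counts.max()
        modes[name] = min(v for v, c in counts.items() if c == top)
    out = []
    for table in [train, *apply_to]:
        filled = table.data.fillna(value=modes)
        out.append(CohortTable(data=filled, labels=table.labels, kinds=dict(table.kinds)))
    return out


def to_sequence(table: CohortTable, ordering: list[str]) -> RankedFeatureMatrix:
    """Reorder columns into the ranked sequence the causal network reads.

    Position 0 carries the most important feature. Requires every name in
    ``ordering`` to exist in the table and no missing cells.
    """
    unknown = [n for n in ordering if n not in table.data.columns]
    if unknown:
        raise KeyError(f"unknown features in ordering: {unknown}")
    sub = table.data[ordering]
    if sub.isna().any().any():
        raise ValueError("sequence conversion requires a fully imputed table")
    dropped = [n for n in table.feature_names if n not in set(ordering)]
    return RankedFeatureMatrix(
        values=sub.to_numpy(dtype=np.float64),
        ordering=list(ordering),
        dropped=dropped,
    )


def write_importance_csv(report: ImportanceReport, path) -> None:
    """Two-column CSV (feature, importance) sorted by rank."""
    items = sorted(report.importances.items(), key=lambda kv: -kv[1])
    pd.DataFrame(items, columns=["feature", "importance"]).to_csv(path, index=False)
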