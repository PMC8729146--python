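"""The TRAIN -> QUERY -> APPEND -> FINETUNE adaptation cycle.

Starting from a model trained on the original data, each cycle scores a
query pool with an uncertainty criterion, appends the most uncertain
``floor(fraction * n)`` samples to the training set, and fine-tunes the
model from its current weights (no re-initialization) with the KL-focal
loss on the augmented set. The default pool is the training partition
itself, so selected samples are effectively re-weighted by duplication;
a conventional held-out pool policy is also available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .causal_net import CausalCNN, predict_proba, train
from .losses import LossConfig
from .synthetic_cohort import addition_rates
from .uncertainty import (
    DEFAULT_ALPHA,
    DEFAULT_FRACTION,
    select_top_fraction,
    strategy_scores_and_direction,
)


@dataclass(frozen=True)
class CycleConfig:
    """Settings of the active-adaptation loop."""

    strategy: str = "mixed"
    alpha: float = DEFAULT_ALPHA
    fraction: float = DEFAULT_FRACTION
    mixed_variant: str = "literal"
    pool_policy: str = "self"
    n_cycles: int = 1
    finetune_epochs: int = 100
    batch_size: int = 32
    seed: int = 0
    loss: LossConfig = field(default_factory=LossConfig)

    def validate(self) -> None:
        if self.n_cycles < 0:
            raise ValueError("n_cycles must be >= 0")
        if self.pool_policy not in ("self", "holdout"):
            raise ValueError("pool_policy must be 'self' or 'holdout'")
        self.loss.validate()


@dataclass
class CycleRecord:
    """Bookkeeping for one cycle."""

    selected: np.ndarray
    class_counts: np.ndarray
    rates_pct: np.ndarray
    size_before: int
    size_after: int


@dataclass
class CycleReport:
    cycles: list[CycleRecord] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "cycles": [
                {
                    "selected": r.selected.tolist(),
                    "class_counts": r.class_counts.tolist(),
                    "rates_pct": r.rates_pct.tolist(),
                    "size_before": r.size_before,
                    "size_after": r.size_after,
                }
                for r in self.cycles
            ]
        }


def query_pool(
    X_train: np.ndarray,
    y_train: np.ndarray,
    policy: str = "self",
    holdout: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Materialize the query pool under the given policy.

    ``"self"`` returns the training partition itself; ``"holdout"``
    returns the provided withheld split. Rows are value-identical views of
    their source.
    """
    if len(X_train) == 0:
        raise ValueError("empty training partition")
    if policy == "self":
        return X_train, y_train
    if policy == "holdout":
        if holdout is None or len(holdout[0]) == 0:
            raise ValueError("holdout policy requires a non-empty holdout split")
        return holdout
    raise ValueError(f"unknown pool policy '{policy}'")


def run_active_cycle(
    X_train: np.ndarray,
    y_train: np.ndarray,
    model: CausalCNN,
    config: CycleConfig | None = None,
    holdout: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[CausalCNN, np.ndarray, np.ndarray, CycleReport]:
    """Run ``config.n_cycles`` adaptation cycles.

    Returns ``(model, X_augmented, y_augmented, report)``. With
    ``n_cycles = 0`` the model and data come back unchanged.
    """
    config = config or CycleConfig()
    config.validate()
    if len(X_train) == 0:
        raise ValueError("empty training partition")
    X_cur = np.asarray(X_train, dtype=np.float64)
    y_cur = np.asarray(y_train, dtype=int)
    report = CycleReport()
    n_classes = model.spec.n_classes
    base_counts = np.bincount(y_cur, minlength=n_classes)
    for cycle in range(config.n_cycles):
        X_pool, y_pool = query_pool(X_cur, y_cur, config.pool_policy, holdout)
        P = predict_proba(model, X_pool)
        scores, direction = strategy_scores_and_direction(
            P, config.strategy, config.alpha, config.mixed_variant
        )
        sel = select_top_fraction(
            scores, direction, config.fraction, labels=y_pool, n_classes=n_classes
        )
        size_before = len(X_cur)
        X_cur = np.vstack([X_cur, X_pool[sel.selected]])
        y_cur = np.concatenate([y_cur, y_pool[sel.selected]])
        safe_base = np.maximum(base_counts, 1)
        rates = addition_rates(sel.class_counts, safe_base)
        report.cycles.append(
            CycleRecord(
                selected=sel.selected,
                class_counts=sel.class_counts,
                rates_pct=rates,
                size_before=size_before,
                size_after=len(X_cur),
            )
        )
        train(
            model,
            X_cur,
            y_cur,
            loss=config.loss,
            epochs=config.finetune_epochs,
            batch_size=config.batch_size,
            seed=config.seed + cycle + 1,
        )
    return model, X_cur, y_cur, report
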