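"""Pool-based uncertainty scoring and sample selection.

Three query criteria over a matrix of predicted class probabilities:

* entropy — ``-sum_j p_j ln p_j`` per sample; high = uncertain.
* margin — top-1 minus top-2 probability; low = uncertain.
* mixed — ``alpha * (p1 ln p1) + (1 - alpha) * (p1 - p2)``, minimized;
  a trade-off (default alpha = 0.3) between a confidence-entropy term and
  the margin. An alternative form substituting the full negative entropy
  for the first term is available as ``variant="entropy_full"``.

Natural logarithms throughout. Selection takes the most uncertain
``floor(fraction * n)`` samples with stable (lowest-index-first) ties.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

STRATEGIES = ("entropy", "margin", "mixed")
DEFAULT_ALPHA = 0.3
DEFAULT_FRACTION = 0.5


@dataclass
class QueryScores:
    """Per-sample uncertainty scores for one pool."""

    entropy: np.ndarray
    margin: np.ndarray
    mixed: np.ndarray
    alpha: float
    n: int


@dataclass
class SelectionResult:
    """Indices chosen by a query, most uncertain first."""

    selected: np.ndarray
    fraction: float
    class_counts: np.ndarray | None = field(default=None)


def _check_proba(P: np.ndarray) -> np.ndarray:
    P = np.atleast_2d(np.asarray(P, dtype=float))
    if P.ndim != 2:
        raise ValueError("probability matrix must be 2-D")
    return P


def entropy_score(P: np.ndarray) -> np.ndarray:
    """Shannon entropy (nats) per row; 0 for one-hot, ln K at uniform."""
    P = _check_proba(P)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(P > 0, P * np.log(P), 0.0)
    return -terms.sum(axis=1)


def margin_score(P: np.ndarray) -> np.ndarray:
    """Top-1 minus top-2 probability per row; small margin = uncertain."""
    P = _check_proba(P)
    if P.shape[1] < 2:
        raise ValueError("margin requires at least 2 classes")
    part = np.partition(P, -2, axis=1)
    return part[:, -1] - part[:, -2]


def mixed_score(
    P: np.ndarray, alpha: float = DEFAULT_ALPHA, variant: str = "literal"
) -> np.ndarray:
    """Mixed criterion, minimized to pick uncertain samples.

    ``literal`` uses the top-1 confidence-entropy term ``p1 ln p1``;
    ``entropy_full`` replaces it with the negative full entropy.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    P = _check_proba(P)
    if P.shape[1] < 2:
        raise ValueError("mixed criterion requires at least 2 classes")
    part = np.partition(P, -2, axis=1)
    p1, p2 = part[:, -1], part[:, -2]
    if variant == "literal":
        first = np.where(p1 > 0, p1 * np.log(p1), 0.0)
    elif variant == "entropy_full":
        first = -entropy_score(P)
    else:
        raise ValueError("variant must be 'literal' or 'entropy_full'")
    return alpha * first + (1.0 - alpha) * (p1 - p2)


def score_pool(
    P: np.ndarray, alpha: float = DEFAULT_ALPHA, variant: str = "literal"
) -> QueryScores:
    P = _check_proba(P)
    return QueryScores(
        entropy=entropy_score(P),
        margin=margin_score(P),
        mixed=mixed_score(P, alpha, variant),
        alpha=alpha,
        n=len(P),
    )


def select_top_fraction(
    scores: np.ndarray,
    direction: str,
    fraction: float = DEFAULT_FRACTION,
    labels: np.ndarray | None = None,
    n_classes: int = 5,
) -> SelectionResult:
    """Pick the ``floor(fraction * n)`` most uncertain samples.

    ``direction="desc"`` treats high scores as uncertain (entropy);
    ``"asc"`` treats low scores as uncertain (margin, mixed). Ties go to
    the smaller index. If ``labels`` is given, per-class counts of the
    selection are reported for addition-rate bookkeeping.
    """
    scores = np.asarray(scores, dtype=float)
    n = len(scores)
    if n == 0:
        raise ValueError("empty pool")
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    if direction not in ("asc", "desc"):
        raise ValueError("direction must be 'asc' or 'desc'")
    m = int(np.floor(fraction * n))
    key = scores if direction == "asc" else -scores
    order = np.argsort(key, kind="stable")
    selected = order[:m]
    counts = None
    if labels is not None:
        counts = np.bincount(np.asarray(labels)[selected], minlength=n_classes)
    return SelectionResult(selected=selected, fraction=fraction, class_counts=counts)


def strategy_scores_and_direction(
    P: np.ndarray,
    strategy: str,
    alpha: float = DEFAULT_ALPHA,
    variant: str = "literal",
) -> tuple[np.ndarray, str]:
    """Map a strategy name to its score vector and selection direction."""
    if strategy == "entropy":
        return entropy_score(P), "desc"
    if strategy == "margin":
        return margin_score(P), "asc"
    if strategy == "mixed":
        return mixed_score(P, alpha, variant), "asc"
    raise ValueError(f"unknown strategy '{strategy}'; choose from {STRATEGIES}")
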