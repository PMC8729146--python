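"""Synthetic stroke-cohort generation.

Real TOAST-subtyped registries are rarely shareable, so this module builds
cohort tables with the same statistical skeleton as a typical single-centre
ischemic-stroke registry: five etiologic subtypes (LAA, CE, SAO, OC, UND)
with severe class imbalance, a wide mixed categorical/continuous feature
panel, a configurable informative subset carrying class signal, and sparse
completely-at-random missingness.

The default :class:`CohortSpec` mirrors a 2,310-patient cohort with class
counts 1290/107/550/81/282 and 122 features, of which a configurable number
are class-informative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

SUBTYPES = ("LAA", "CE", "SAO", "OC", "UND")

#: per-subtype patient counts of the default cohort
DEFAULT_CLASS_COUNTS = (1290, 107, 550, 81, 282)

#: column name carrying the subtype label in the CSV dialect
LABEL_COLUMN = "toast"


def _round_half_up(x: float) -> int:
    """Round to nearest integer, ties away from zero (half-up for x >= 0)."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort.

    Parameters
    ----------
    n_patients:
        Total number of rows; must equal ``sum(class_counts)``.
    class_counts:
        Exact per-subtype row counts, ordered LAA, CE, SAO, OC, UND.
    n_features:
        Total feature columns (categorical + continuous).
    n_informative:
        How many features carry class signal; the rest are pure noise.
    categorical_fraction:
        Fraction of features generated as small-cardinality categorical
        codes; the remainder are continuous.
    effect_size:
        Scale of the class separation. Continuous informative features get
        per-class location shifts proportional to this; categorical
        informative features get per-class logit perturbations of this
        scale. Zero means no feature carries any class information.
    missing_rate:
        Probability that any feature cell is blanked out (missing
        completely at random). The default 0.0047 reproduces an average
        data integrity of 99.53 %.
    seed:
        Generator seed; the table is a pure function of (spec, seed).
    """

    n_patients: int = sum(DEFAULT_CLASS_COUNTS)
    class_counts: tuple[int, ...] = DEFAULT_CLASS_COUNTS
    n_features: int = 122
    n_informative: int = 30
    categorical_fraction: float = 0.5
    effect_size: float = 1.0
    missing_rate: float = 0.0047
    seed: int = 0

    def validate(self) -> None:
        if len(self.class_counts) != len(SUBTYPES):
            raise ValueError(
                f"class_counts must have {len(SUBTYPES)} entries, "
                f"got {len(self.class_counts)}"
            )
        if any(c < 0 for c in self.class_counts):
            raise ValueError("class_counts must be non-negative")
        if sum(self.class_counts) != self.n_patients:
            raise ValueError(
                f"sum(class_counts)={sum(self.class_counts)} != "
                f"n_patients={self.n_patients}"
            )
        if not 0 <= self.n_informative <= self.n_features:
            raise ValueError("need 0 <= n_informative <= n_features")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must lie in [0, 1]")
        if not 0.0 <= self.categorical_fraction <= 1.0:
            raise ValueError("categorical_fraction must lie in [0, 1]")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")


@dataclass
class CohortTable:
    """A patients x features table with subtype labels.

    ``data`` holds numeric codes for categorical features and reals for
    continuous ones, with ``NaN`` marking missing cells. ``kinds`` maps each
    feature column to ``"categorical"`` or ``"continuous"``.
    """

    data: pd.DataFrame
    labels: np.ndarray
    kinds: dict[str, str] = field(default_factory=dict)
    informative: list[str] = field(default_factory=list)

    @property
    def n_patients(self) -> int:
        return len(self.data)

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    def class_counts(self, n_classes: int = len(SUBTYPES)) -> np.ndarray:
        return np.bincount(self.labels, minlength=n_classes)

    def to_frame(self) -> pd.DataFrame:
        out = self.data.copy()
        out[LABEL_COLUMN] = self.labels
        return out


def _feature_name(index: int, kind: str) -> str:
    prefix = "cat" if kind == "categorical" else "num"
    return f"{prefix}_{index:03d}"


def generate_cohort(spec: CohortSpec) -> CohortTable:
    """Draw a cohort table from the spec's generative model.

    Informative continuous features are unit-scale normal draws whose
    location is shifted per class by an offset proportional to
    ``effect_size``; informative categorical features are multinomial draws
    whose category logits are perturbed per class at the same scale.
    Non-informative features are class-independent. Missing cells are
    injected uniformly at random at ``missing_rate``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n, p, k = spec.n_patients, spec.n_features, len(spec.class_counts)

    labels = np.repeat(np.arange(k), spec.class_counts)
    rng.shuffle(labels)

    n_cat = int(round(spec.categorical_fraction * p))
    kind_flags = np.array(["categorical"] * n_cat + ["continuous"] * (p - n_cat))
    rng.shuffle(kind_flags)
    informative = np.zeros(p, dtype=bool)
    informative[rng.choice(p, size=spec.n_informative, replace=False)] = True

    columns: dict[str, np.ndarray] = {}
    kinds: dict[str, str] = {}
    for j in range(p):
        kind = str(kind_flags[j])
        name = _feature_name(j, kind)
        kinds[name] = kind
        if kind == "continuous":
            base = rng.standard_normal(n)
            if informative[j] and spec.effect_size > 0:
                offsets = spec.effect_size * rng.standard_normal(k)
                base = base + offsets[labels]
            elif informative[j]:
                # effect_size 0: still consume the draw so column values do
                # not depend on the informative flag
                rng.standard_normal(k)
            columns[name] = base
        else:
            n_levels = int(rng.integers(2, 7))
            base_logits = rng.standard_normal(n_levels)
            if informative[j] and spec.effect_size > 0:
                logits = base_logits[None, :] + spec.effect_size * rng.standard_normal(
                    (k, n_levels)
                )
            else:
                if informative[j]:
                    rng.standard_normal((k, n_levels))
                logits = np.broadcast_to(base_logits, (k, n_levels))
            probs = np.exp(logits - logits.max(axis=1, keepdims=True))
            probs = probs / probs.sum(axis=1, keepdims=True)
            u = rng.random(n)
            cdf = np.cumsum(probs, axis=1)
            columns[name] = np.float64(
                (u[:, None] > cdf[labels]).sum(axis=1)
            )

    data = pd.DataFrame(columns)
    if spec.missing_rate > 0:
        mask = rng.random((n, p)) < spec.missing_rate
        values = data.to_numpy()
        values[mask] = np.nan
        data = pd.DataFrame(values, columns=data.columns)

    informative_names = [
        _feature_name(j, str(kind_flags[j])) for j in range(p) if informative[j]
    ]
    return CohortTable(
        data=data, labels=labels, kinds=kinds, informative=informative_names
    )


def summarize_distribution(
    table: CohortTable, n_classes: int = len(SUBTYPES)
) -> tuple[np.ndarray, np.ndarray]:
    """Per-class counts and integer percentages (half-up rounding).

    Returns ``(counts, percentages)`` where percentages are
    ``100 * count / total`` rounded half-up. Raises on an empty table.
    """
    if table.n_patients == 0:
        raise ValueError("cannot summarize an empty cohort")
    counts = table.class_counts(n_classes)
    total = counts.sum()
    pct = np.array([_round_half_up(100.0 * c / total) for c in counts])
    return counts, pct


def addition_rates(
    added: Sequence[int], base: Sequence[int]
) -> np.ndarray:
    """Per-class growth of a training set, as integer percentages of base.

    ``100 * added / base`` rounded half-up; every base count must be
    strictly positive.
    """
    added_a = np.asarray(added, dtype=float)
    base_a = np.asarray(base, dtype=float)
    if added_a.shape != base_a.shape:
        raise ValueError("added and base must have the same length")
    if np.any(base_a <= 0):
        raise ValueError("base counts must be strictly positive")
    return np.array([_round_half_up(100.0 * a / b) for a, b in zip(added_a, base_a)])


def write_cohort_csv(table: CohortTable, path: str | Path) -> None:
    """Write the cohort CSV dialect: feature columns + final ``toast``
    label column, missing cells as empty strings, UTF-8, comma-separated."""
    frame = table.to_frame()
    frame.to_csv(path, index=False, na_rep="", encoding="utf-8")


def read_cohort_csv(path: str | Path) -> CohortTable:
    """Read a cohort CSV written by :func:`write_cohort_csv`.

    Feature kind is recovered from the column-name prefix (``cat_`` /
    ``num_``); unknown prefixes default to continuous.
    """
    frame = pd.read_csv(path, encoding="utf-8")
    if LABEL_COLUMN not in frame.columns:
        raise ValueError(f"cohort CSV must contain a '{LABEL_COLUMN}' column")
    labels = frame[LABEL_COLUMN].to_numpy(dtype=int)
    data = frame.drop(columns=[LABEL_COLUMN])
    kinds = {
        name: ("categorical" if name.startswith("cat_") else "continuous")
        for name in data.columns
    }
    return CohortTable(data=data, labels=labels, kinds=kinds)
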