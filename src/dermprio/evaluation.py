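"""Confusion matrices and the triage metric suite.

Metrics follow the conventions of imbalanced-class medical-imaging
evaluation: per-class sensitivity (recall), precision and F1, plus
accuracy, macro F1 (unweighted mean over classes) and weighted F1
(support-weighted mean).  All metrics are kept unrounded internally and
reported as percentages with 2-decimal half-up rounding; undefined
ratios (zero denominators) are defined as 0.

`naive_gt_from_counts` is the deterministic harness that maps every
case's true diagnosis through the knowledge map's modal priority and
scores the result against the true priority — the upper bound any
diagnosis-then-map pipeline can reach.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from os import PathLike
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .fusion import KnowledgeMap, km_modal_priority
from .taxonomy import (
    DEFAULT_PRIORITIES,
    DEFAULT_TAXONOMY,
    DiagnosisTaxonomy,
    PriorityLevels,
)

__all__ = [
    "CountTable",
    "ConfusionMatrix",
    "MetricsReport",
    "round_half_up",
    "load_count_table",
    "confusion",
    "metrics_from_confusion",
    "naive_gt_from_counts",
    "evaluate_predictions",
]

#: Display order mirrors the reported per-class tables (most severe first).
DISPLAY_ORDER = ("HP", "P", "N")


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (0.005 -> 0.01), as in the reported tables."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CountTable:
    """Diagnosis x priority case counts for one dataset partition."""

    counts: np.ndarray
    taxonomy: DiagnosisTaxonomy = DEFAULT_TAXONOMY
    priorities: PriorityLevels = DEFAULT_PRIORITIES
    partition: str = ""

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        object.__setattr__(self, "counts", counts)
        if counts.shape != (len(self.taxonomy), len(self.priorities)):
            raise ValueError(
                f"counts must be {len(self.taxonomy)}x{len(self.priorities)}, got {counts.shape}"
            )
        if np.any(counts < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def expand(self) -> pd.DataFrame:
        """Case-level expansion: one row per counted case."""
        rows: List[Tuple[str, str]] = []
        for i, code in enumerate(self.taxonomy.codes):
            for j, level in enumerate(self.priorities):
                rows.extend([(code, level)] * int(self.counts[i, j]))
        return pd.DataFrame(rows, columns=["diagnosis", "priority"])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.counts, index=list(self.taxonomy.codes), columns=list(self.priorities)
        )
        df["Tot"] = df.sum(axis=1)
        return df


def load_count_table(
    source: Union[str, PathLike, pd.DataFrame, None] = None,
    partition: str = "test1",
    taxonomy: DiagnosisTaxonomy = DEFAULT_TAXONOMY,
    priorities: PriorityLevels = DEFAULT_PRIORITIES,
) -> CountTable:
    """Load a partition's counts from long CSV (code, partition, N, P, HP).

    ``source=None`` reads the packaged referral-dataset distribution
    (train / test1 / test2 partitions).
    """
    if source is None:
        with resources.files("dermprio.data").joinpath("dermai_counts.csv").open() as fh:
            df = pd.read_csv(fh)
    elif isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source)
    if "partition" in df.columns:
        df = df[df["partition"] == partition]
    if df.empty:
        raise ValueError(f"no rows for partition {partition!r}")
    unknown = set(df["code"]) - set(taxonomy.codes)
    if unknown:
        raise ValueError(f"unknown diagnosis codes: {sorted(unknown)}")
    if len(df) != len(taxonomy):
        raise ValueError(f"expected {len(taxonomy)} class rows, got {len(df)}")
    df = df.set_index("code").loc[list(taxonomy.codes)]
    counts = df[list(priorities)].to_numpy(dtype=int)
    return CountTable(counts=counts, taxonomy=taxonomy, priorities=priorities, partition=partition)


@dataclass(frozen=True)
class ConfusionMatrix:
    """K x K counts; rows are true labels, columns predicted."""

    matrix: np.ndarray
    labels: Tuple[str, ...]

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=int)
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "labels", tuple(self.labels))
        k = len(self.labels)
        if m.shape != (k, k):
            raise ValueError(f"matrix must be {k}x{k}, got {m.shape}")
        if np.any(m < 0):
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.matrix.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=list(self.labels), columns=list(self.labels))


def confusion(
    y_true: Sequence[str],
    y_pred: Sequence[str],
    labels: Sequence[str],
) -> ConfusionMatrix:
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must have equal length")
    index = {lab: i for i, lab in enumerate(labels)}
    m = np.zeros((len(labels), len(labels)), dtype=int)
    for t, p in zip(y_true, y_pred):
        if t not in index:
            raise ValueError(f"unknown true label: {t!r}")
        if p not in index:
            raise ValueError(f"unknown predicted label: {p!r}")
        m[index[t], index[p]] += 1
    return ConfusionMatrix(matrix=m, labels=tuple(labels))


@dataclass(frozen=True)
class MetricsReport:
    """Per-class and aggregate metrics, all on the percent scale."""

    labels: Tuple[str, ...]
    sensitivity: Dict[str, float]
    precision: Dict[str, float]
    f1: Dict[str, float]
    support: Dict[str, int]
    accuracy: float
    macro_f1: float
    weighted_f1: float

    def rounded(self, ndigits: int = 2) -> "MetricsReport":
        r = lambda d: {k: round_half_up(v, ndigits) for k, v in d.items()}
        return MetricsReport(
            labels=self.labels,
            sensitivity=r(self.sensitivity),
            precision=r(self.precision),
            f1=r(self.f1),
            support=dict(self.support),
            accuracy=round_half_up(self.accuracy, ndigits),
            macro_f1=round_half_up(self.macro_f1, ndigits),
            weighted_f1=round_half_up(self.weighted_f1, ndigits),
        )

    def per_class_frame(self, order: Optional[Sequence[str]] = None) -> pd.DataFrame:
        order = list(order) if order is not None else list(self.labels)
        return pd.DataFrame(
            {
                "sensitivity": [self.sensitivity[c] for c in order],
                "precision": [self.precision[c] for c in order],
                "f1": [self.f1[c] for c in order],
                "support": [self.support[c] for c in order],
            },
            index=order,
        )

    def to_dict(self) -> Dict:
        return {
            "accuracy": self.accuracy,
            "macro_f1": self.macro_f1,
            "weighted_f1": self.weighted_f1,
            "per_class": {
                c: {
                    "sensitivity": self.sensitivity[c],
                    "precision": self.precision[c],
                    "f1": self.f1[c],
                    "support": self.support[c],
                }
                for c in self.labels
            },
        }


def metrics_from_confusion(cm: ConfusionMatrix) -> MetricsReport:
    """Sensitivity/precision/F1 per class plus accuracy and F1 aggregates.

    Zero denominators yield 0.  Aggregates use the unrounded per-class
    values (rounding first shifts the weighted F1 in the second decimal).
    """
    m = cm.matrix.astype(float)
    total = m.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    tp = np.diag(m)
    row = m.sum(axis=1)
    col = m.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        sens = np.where(row > 0, tp / row, 0.0)
        prec = np.where(col > 0, tp / col, 0.0)
        denom = sens + prec
        f1 = np.where(denom > 0, 2 * sens * prec / denom, 0.0)
    support = row
    accuracy = tp.sum() / total
    macro = f1.mean()
    weighted = float(f1 @ support / total)
    pct = lambda a: {lab: 100.0 * a[i] for i, lab in enumerate(cm.labels)}
    return MetricsReport(
        labels=cm.labels,
        sensitivity=pct(sens),
        precision=pct(prec),
        f1=pct(f1),
        support={lab: int(support[i]) for i, lab in enumerate(cm.labels)},
        accuracy=100.0 * accuracy,
        macro_f1=100.0 * macro,
        weighted_f1=100.0 * weighted,
    )


def naive_gt_from_counts(
    table: CountTable, km: KnowledgeMap
) -> Tuple[MetricsReport, ConfusionMatrix]:
    """Score the knowledge-map modal priority of each true diagnosis.

    Every case counted under diagnosis ``c`` is predicted the modal
    priority of ``c``'s knowledge-map row; the confusion over true
    priorities follows directly from the count table, with no sampling.
    """
    if table.taxonomy.codes != km.taxonomy.codes:
        raise ValueError("count table and knowledge map use different taxonomies")
    levels = tuple(table.priorities)
    index = {lab: i for i, lab in enumerate(levels)}
    m = np.zeros((len(levels), len(levels)), dtype=int)
    for i, code in enumerate(table.taxonomy.codes):
        j = index[km_modal_priority(km, code)]
        for t, level in enumerate(levels):
            m[t, j] += int(table.counts[i, t])
    cm = ConfusionMatrix(matrix=m, labels=levels)
    return metrics_from_confusion(cm), cm


def evaluate_predictions(
    cases: pd.DataFrame,
    true_col: str = "priority",
    pred_col: str = "predicted",
    labels: Sequence[str] = tuple(DEFAULT_PRIORITIES.levels),
) -> Tuple[MetricsReport, ConfusionMatrix]:
    """Generic wrapper: confusion + metrics over a labelled prediction table."""
    if cases.empty:
        raise ValueError("no cases to evaluate")
    cm = confusion(cases[true_col].tolist(), cases[pred_col].tolist(), labels)
    return metrics_from_confusion(cm), cm
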