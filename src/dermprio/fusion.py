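"""Expert knowledge map and score-fusion rules.

The knowledge map is a 13x3 table elicited from dermatologists: for each
differential diagnosis it gives the expected percentage of cases at each
triage priority (mean and standard deviation across experts).  The
fusion rules here turn diagnosis scores (from any classifier, or a
ground-truth label) into priority scores:

* **naive fusion** — multiply each diagnosis score by its knowledge-map
  row and aggregate per priority level by summing or taking the max;
* **naive GT** — shortcut for a ground-truth diagnosis label, equivalent
  to reading off the modal priority of that label's row;
* **simple fusion** — weighted addition ``alpha * priority_scores +
  beta * naive_scores`` combining a dedicated priority classifier with
  the knowledge-map route.

Argmax decisions break ties toward the higher-severity level, the
clinically conservative choice.  The std columns are validated on load
but deliberately unused by fusion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from os import PathLike
from typing import Optional, Union

import numpy as np
import pandas as pd

from .taxonomy import (
    DEFAULT_PRIORITIES,
    DEFAULT_TAXONOMY,
    DiagnosisTaxonomy,
    PriorityLevels,
)

__all__ = [
    "KnowledgeMap",
    "ScoreVector",
    "FusionConfig",
    "load_knowledge_map",
    "default_knowledge_map",
    "km_modal_priority",
    "naive_fuse",
    "naive_gt",
    "simple_fuse",
    "predict_priority",
]

_ROW_SUM_TOL = 1e-9


@dataclass(frozen=True)
class KnowledgeMap:
    """Expert priority priors: 13x3 mean and std percentage matrices."""

    mean: np.ndarray
    std: np.ndarray
    taxonomy: DiagnosisTaxonomy = DEFAULT_TAXONOMY
    priorities: PriorityLevels = DEFAULT_PRIORITIES

    def __post_init__(self) -> None:
        mean = np.asarray(self.mean, dtype=float)
        std = np.asarray(self.std, dtype=float)
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "std", std)
        n_dx, n_pr = len(self.taxonomy), len(self.priorities)
        if mean.shape != (n_dx, n_pr) or std.shape != (n_dx, n_pr):
            raise ValueError(
                f"knowledge map must be {n_dx}x{n_pr}; got mean {mean.shape}, std {std.shape}"
            )
        if np.any(mean < 0) or np.any(mean > 100):
            raise ValueError("mean percentages must lie in [0, 100]")
        if np.any(std < 0):
            raise ValueError("std percentages must be nonnegative")
        sums = mean.sum(axis=1)
        bad = np.nonzero(np.abs(sums - 100.0) > _ROW_SUM_TOL)[0]
        if bad.size:
            rows = ", ".join(
                f"{self.taxonomy.codes[i]} (sum={sums[i]:g})" for i in bad
            )
            raise ValueError(f"knowledge map rows must sum to 100: {rows}")

    def row(self, code: str) -> np.ndarray:
        """Mean percentage row for one diagnosis code."""
        return self.mean[self.taxonomy.position(code)]


@dataclass(frozen=True)
class ScoreVector:
    """Nonnegative score vector over diagnoses (13) or priorities (3)."""

    values: np.ndarray
    semantics: str = "unnormalized"  # "probability" | "unnormalized"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.shape[0] not in (3, 13):
            raise ValueError("score vector must be 1-D of length 3 or 13")
        if np.any(values < 0):
            raise ValueError("scores must be nonnegative")
        if self.semantics not in ("probability", "unnormalized"):
            raise ValueError(f"unknown semantics flag: {self.semantics!r}")
        if self.semantics == "probability" and abs(values.sum() - 1.0) > 1e-9:
            raise ValueError("probability-flagged vector must sum to 1")

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class FusionConfig:
    """Weights for simple fusion: alpha on priority, beta on diagnosis.

    Defaults follow the best setting reported for this task
    (alpha=2, beta=1).
    """

    mode: str = "sum"
    alpha: float = 2.0
    beta: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in ("sum", "max"):
            raise ValueError(f"mode must be 'sum' or 'max', got {self.mode!r}")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be nonnegative")
        if self.alpha + self.beta <= 0:
            raise ValueError("alpha + beta must be positive")


def load_knowledge_map(
    source: Union[str, PathLike, pd.DataFrame, None] = None,
    taxonomy: DiagnosisTaxonomy = DEFAULT_TAXONOMY,
    priorities: PriorityLevels = DEFAULT_PRIORITIES,
) -> KnowledgeMap:
    """Load and validate a knowledge map.

    ``source`` is a CSV path (columns ``code,name,mean_N,mean_P,mean_HP,
    std_N,std_P,std_HP``), a DataFrame with those columns, or ``None``
    for the packaged default.
    """
    if source is None:
        with resources.files("dermprio.data").joinpath("knowledge_map.csv").open() as fh:
            df = pd.read_csv(fh)
    elif isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source)

    required = {"code"} | {f"{kind}_{p}" for kind in ("mean", "std") for p in priorities}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"knowledge map table missing columns: {sorted(missing)}")
    if len(df) != len(taxonomy):
        raise ValueError(f"expected {len(taxonomy)} rows, got {len(df)}")
    unknown = set(df["code"]) - set(taxonomy.codes)
    if unknown:
        raise ValueError(f"unknown diagnosis codes in table: {sorted(unknown)}")

    df = df.set_index("code").loc[list(taxonomy.codes)]
    mean = df[[f"mean_{p}" for p in priorities]].to_numpy(dtype=float)
    std = df[[f"std_{p}" for p in priorities]].to_numpy(dtype=float)
    return KnowledgeMap(mean=mean, std=std, taxonomy=taxonomy, priorities=priorities)


def default_knowledge_map() -> KnowledgeMap:
    """The packaged expert knowledge map."""
    return load_knowledge_map(None)


def predict_priority(
    scores: Union[ScoreVector, np.ndarray],
    priorities: PriorityLevels = DEFAULT_PRIORITIES,
) -> str:
    """Argmax priority with ties broken toward the higher-severity level.

    An all-zero vector is degenerate; the lowest-severity level is
    returned with a warning so pipelines never crash on a dead head.
    """
    values = scores.values if isinstance(scores, ScoreVector) else np.asarray(scores, dtype=float)
    if values.shape != (len(priorities),):
        raise ValueError(f"expected length-{len(priorities)} scores, got shape {values.shape}")
    if np.all(values == 0):
        warnings.warn("all-zero priority scores; defaulting to lowest severity", stacklevel=2)
        return priorities.levels[0]
    # reversed scan keeps the highest-severity index on ties
    best = len(values) - 1 - int(np.argmax(values[::-1]))
    return priorities.levels[best]


def km_modal_priority(km: KnowledgeMap, dx: str) -> str:
    """Modal (most expected) priority of a diagnosis under the map."""
    return predict_priority(km.row(dx), km.priorities)


def _as_dx_scores(scores: Union[ScoreVector, np.ndarray], km: KnowledgeMap) -> np.ndarray:
    values = scores.values if isinstance(scores, ScoreVector) else np.asarray(scores, dtype=float)
    if values.shape != (len(km.taxonomy),):
        raise ValueError(f"expected length-{len(km.taxonomy)} diagnosis scores")
    if np.any(values < 0):
        raise ValueError("diagnosis scores must be nonnegative")
    return values


def naive_fuse(
    dx_scores: Union[ScoreVector, np.ndarray],
    km: KnowledgeMap,
    mode: str = "sum",
) -> ScoreVector:
    """Fuse diagnosis scores with the knowledge map into priority scores.

    Each class score is multiplied by that class's mean percentage row;
    per-priority aggregation is a sum over classes (``mode="sum"``,
    equivalent to the vector-matrix product ``s @ M``) or a max over
    classes (``mode="max"``).  Output is on the percent scale and
    flagged unnormalized.
    """
    s = _as_dx_scores(dx_scores, km)
    if mode == "sum":
        fused = s @ km.mean
    elif mode == "max":
        fused = (s[:, None] * km.mean).max(axis=0)
    else:
        raise ValueError(f"mode must be 'sum' or 'max', got {mode!r}")
    return ScoreVector(values=fused, semantics="unnormalized")


def naive_gt(dx_label: str, km: KnowledgeMap) -> str:
    """Priority implied by a ground-truth diagnosis label.

    One-hot input makes sum and max aggregation coincide, so this is
    exactly the modal priority of the label's knowledge-map row.
    """
    return km_modal_priority(km, dx_label)


def simple_fuse(
    priority_scores: Union[ScoreVector, np.ndarray],
    naive_scores: Union[ScoreVector, np.ndarray],
    cfg: Optional[FusionConfig] = None,
) -> ScoreVector:
    """Weighted addition ``alpha * priority + beta * naive``.

    The knowledge-map (naive) scores are normalized to unit sum first so
    that alpha and beta weight comparable vectors; a zero naive vector
    is left as zeros.
    """
    cfg = cfg or FusionConfig()
    p = priority_scores.values if isinstance(priority_scores, ScoreVector) else np.asarray(priority_scores, dtype=float)
    n = naive_scores.values if isinstance(naive_scores, ScoreVector) else np.asarray(naive_scores, dtype=float)
    if p.shape != (3,) or n.shape != (3,):
        raise ValueError("simple fusion expects two length-3 score vectors")
    if np.any(p < 0) or np.any(n < 0):
        raise ValueError("scores must be nonnegative")
    total = n.sum()
    n_norm = n / total if total > 0 else n
    return ScoreVector(values=cfg.alpha * p + cfg.beta * n_norm, semantics="unnormalized")
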