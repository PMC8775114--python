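"""Training-schedule generators for the triage learning schemes.

All schedules are pure functions of their specs: frozen-block
fine-tuning (progressive unfreezing of backbone block groups, three
epochs per phase, separate head/body learning rates), coarse-to-fine
loss-weight schedules for branch (B-CNN) hierarchies, curriculum class
introduction ordered by per-class difficulty, class-balanced stratified
batch sampling with oversampling of rare classes, and late metadata
fusion.  A backend-agnostic trainer consumes the emitted
:class:`ScheduleState` stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import yaml

from .taxonomy import DEFAULT_TAXONOMY, DiagnosisTaxonomy

__all__ = [
    "BackboneSpec",
    "HierarchyLevel",
    "HierarchySpec",
    "LossWeightSchedule",
    "CurriculumSpec",
    "ScheduleState",
    "AugmentationConfig",
    "TWO_LEVEL_SCHEDULE",
    "THREE_LEVEL_SCHEDULE",
    "frozen_block_schedule",
    "bcnn_loss_weights",
    "hierarchical_loss",
    "curriculum_order",
    "curriculum_schedule",
    "stratified_batches",
    "fuse_metadata",
]

#: Learning rates used at full scale: head vs. unfrozen body blocks.
HEAD_LR = 1e-4
BODY_LR = 1e-5


@dataclass(frozen=True)
class BackboneSpec:
    """Ordered feature-extractor block groups with branch tap points."""

    blocks: Tuple[str, ...]
    feature_dim: int
    insertion_points: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "blocks", tuple(self.blocks))
        if len(self.blocks) < 2:
            raise ValueError("backbone needs at least 2 blocks")
        if len(set(self.blocks)) != len(self.blocks):
            raise ValueError("block identifiers must be unique")
        for name, idx in self.insertion_points.items():
            if not 0 <= idx < len(self.blocks):
                raise ValueError(f"insertion point {name!r} references missing block {idx}")

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)


@dataclass(frozen=True)
class HierarchyLevel:
    name: str
    categories: Tuple[str, ...]
    mapping: Mapping[str, str]
    overridable: Tuple[str, ...] = ()
    override_values: Mapping[str, str] = field(default_factory=dict)


@dataclass(frozen=True)
class HierarchySpec:
    """Coarse-level groupings above the 13 fine diagnosis classes.

    ``levels`` are ordered coarse -> fine-adjacent; the fine 13-way
    level itself is implicit.  A per-sample override (e.g. a
    dermatologist's pigmentation call for BCC or ActKer) may replace
    the default coarse label on levels that declare the class
    overridable.
    """

    levels: Tuple[HierarchyLevel, ...]
    taxonomy: DiagnosisTaxonomy = DEFAULT_TAXONOMY

    def __post_init__(self) -> None:
        if len(self.levels) not in (1, 2):
            raise ValueError("hierarchies have 1 or 2 coarse levels (2- or 3-level total)")
        for level in self.levels:
            missing = set(self.taxonomy.codes) - set(level.mapping)
            if missing:
                raise ValueError(f"level {level.name!r} misses classes: {sorted(missing)}")
            bad = set(level.mapping.values()) - set(level.categories)
            if bad:
                raise ValueError(f"level {level.name!r} maps to unknown categories: {sorted(bad)}")

    @property
    def n_levels(self) -> int:
        """Total prediction levels including the fine diagnosis level."""
        return len(self.levels) + 1

    def coarse_label(self, code: str, level: int = 0, override: Optional[str] = None) -> str:
        lev = self.levels[level]
        if override is not None:
            if code not in lev.overridable:
                raise ValueError(f"{code!r} is not overridable at level {lev.name!r}")
            if override in lev.override_values:
                return lev.override_values[override]
            if override in lev.categories:
                return override
            raise ValueError(f"unknown override {override!r} for level {lev.name!r}")
        return lev.mapping[code]

    @classmethod
    def two_level_default(cls, taxonomy: DiagnosisTaxonomy = DEFAULT_TAXONOMY) -> "HierarchySpec":
        """Benign vs malignant; neoplasms of unclear behaviour sit with
        the malignant group because their categorisation is not clear."""
        malignant = {"UncNeop", "OtMalNeop", "BCC", "MM"}
        mapping = {c: ("malignant" if c in malignant else "benign") for c in taxonomy.codes}
        level = HierarchyLevel(
            name="benign-malignant", categories=("benign", "malignant"), mapping=mapping
        )
        return cls(levels=(level,), taxonomy=taxonomy)

    @classmethod
    def three_level_default(cls, taxonomy: DiagnosisTaxonomy = DEFAULT_TAXONOMY) -> "HierarchySpec":
        """Melanocytic/pigmentation hierarchy loaded from the packaged,
        editable config (a best-effort clinical reading)."""
        with resources.files("dermprio.data").joinpath("hierarchy_three_level.yaml").open() as fh:
            raw = yaml.safe_load(fh)
        levels = tuple(
            HierarchyLevel(
                name=entry["name"],
                categories=tuple(entry["categories"]),
                mapping=dict(entry["mapping"]),
                overridable=tuple(entry.get("overridable", ())),
                override_values=dict(entry.get("override_values", {})),
            )
            for entry in raw["levels"]
        )
        return cls(levels=levels, taxonomy=taxonomy)


@dataclass(frozen=True)
class LossWeightSchedule:
    """Piecewise-constant per-level loss weights keyed by start epoch."""

    entries: Tuple[Tuple[int, Tuple[float, ...]], ...]

    def __post_init__(self) -> None:
        entries = tuple((int(e), tuple(float(x) for x in w)) for e, w in self.entries)
        object.__setattr__(self, "entries", entries)
        if not entries or entries[0][0] != 0:
            raise ValueError("schedule must start at epoch 0")
        starts = [e for e, _ in entries]
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("start epochs must be strictly increasing")
        n = len(entries[0][1])
        for e, w in entries:
            if len(w) != n:
                raise ValueError("all weight vectors must have the same length")
            if abs(sum(w) - 1.0) > 1e-9:
                raise ValueError(f"weights at epoch {e} must sum to 1, got {sum(w)}")

    @property
    def n_levels(self) -> int:
        return len(self.entries[0][1])


#: Coarse-to-fine weight handover for the two-level hierarchy.
TWO_LEVEL_SCHEDULE = LossWeightSchedule(
    entries=((0, (0.98, 0.02)), (6, (0.3, 0.7)), (12, (0.1, 0.9)), (18, (0.0, 1.0)))
)
#: And for the three-level hierarchy.
THREE_LEVEL_SCHEDULE = LossWeightSchedule(
    entries=(
        (0, (0.97, 0.02, 0.01)),
        (6, (0.1, 0.8, 0.1)),
        (12, (0.1, 0.2, 0.7)),
        (18, (0.0, 0.0, 1.0)),
    )
)


def bcnn_loss_weights(schedule: LossWeightSchedule, epoch: int) -> Tuple[float, ...]:
    """Loss-weight vector in force at ``epoch`` (piecewise lookup)."""
    if epoch < 0:
        raise ValueError("epoch must be nonnegative")
    current = schedule.entries[0][1]
    for start, weights in schedule.entries:
        if epoch >= start:
            current = weights
        else:
            break
    return current


def hierarchical_loss(per_level_losses: Sequence[float], weights: Sequence[float]) -> float:
    """Weighted sum of the per-level prediction losses."""
    if len(per_level_losses) != len(weights):
        raise ValueError("losses and weights must have matching lengths")
    return float(np.dot(per_level_losses, weights))


@dataclass(frozen=True)
class ScheduleState:
    """Training state for one epoch of any scheme."""

    epoch: int
    phase: int
    active_classes: Tuple[str, ...]
    trainable_blocks: Tuple[str, ...]
    learning_rates: Mapping[str, float]
    loss_weights: Tuple[float, ...] = (1.0,)
    batch_size: int = 0
    samples_per_batch_per_class: int = 1


@dataclass(frozen=True)
class CurriculumSpec:
    """Easiest-to-hardest class introduction schedule."""

    ordered_classes: Tuple[str, ...]
    initial_count: int = 4
    epochs_per_phase: int = 3
    blocks_per_cycle: int = 6
    taxonomy: DiagnosisTaxonomy = DEFAULT_TAXONOMY

    def __post_init__(self) -> None:
        object.__setattr__(self, "ordered_classes", tuple(self.ordered_classes))
        if sorted(self.ordered_classes) != sorted(self.taxonomy.codes):
            raise ValueError("ordered_classes must be a permutation of the taxonomy")
        if not 1 <= self.initial_count <= len(self.ordered_classes):
            raise ValueError("initial_count must be within the class count")


@dataclass(frozen=True)
class AugmentationConfig:
    """Photometric/geometric augmentation ranges used during training."""

    rotation_range: Tuple[float, float] = (1.0, 30.0)
    horizontal_flip: bool = True
    vertical_flip: bool = True
    shear: bool = True
    zoom: bool = True
    shift_range: Tuple[float, float] = (0.0, 0.2)
    channel_shift_range: Tuple[float, float] = (0.0, 10.0)
    brightness_range: Tuple[float, float] = (0.2, 0.8)
    fill_mode: str = "reflect"

    def __post_init__(self) -> None:
        if self.fill_mode not in ("reflect", "constant", "nearest"):
            raise ValueError(f"unknown fill mode: {self.fill_mode!r}")
        for name in ("rotation_range", "shift_range", "channel_shift_range", "brightness_range"):
            lo, hi = getattr(self, name)
            if hi < lo:
                raise ValueError(f"{name} must be (lo, hi) with lo <= hi")


def frozen_block_schedule(
    backbone: BackboneSpec,
    cycles: int,
    epochs_per_cycle: int = 3,
    initial_unfrozen: int = 1,
    active_classes: Optional[Sequence[str]] = None,
    head_lr: float = HEAD_LR,
    body_lr: float = BODY_LR,
    epoch_offset: int = 0,
    samples_per_batch_per_class: int = 1,
) -> List[ScheduleState]:
    """Progressive-unfreezing schedule over backbone block groups.

    Phase ``k`` (0-indexed) trains the last ``initial_unfrozen + k``
    block groups (capped at the backbone depth) plus the head, for
    ``epochs_per_cycle`` epochs, with distinct head and body learning
    rates.  Total epochs = ``epochs_per_cycle * cycles``.
    """
    if cycles < 1:
        raise ValueError("cycles must be >= 1")
    if cycles > backbone.n_blocks:
        raise ValueError(
            f"cycles ({cycles}) cannot exceed the number of blocks ({backbone.n_blocks})"
        )
    if not 1 <= initial_unfrozen <= backbone.n_blocks:
        raise ValueError("initial_unfrozen must be within the block count")
    classes = tuple(active_classes) if active_classes is not None else DEFAULT_TAXONOMY.codes
    states: List[ScheduleState] = []
    epoch = epoch_offset
    for k in range(cycles):
        n_open = min(initial_unfrozen + k, backbone.n_blocks)
        trainable = backbone.blocks[backbone.n_blocks - n_open :]
        lrs = {"head": head_lr, **{b: body_lr for b in trainable}}
        for _ in range(epochs_per_cycle):
            states.append(
                ScheduleState(
                    epoch=epoch,
                    phase=k,
                    active_classes=classes,
                    trainable_blocks=trainable,
                    learning_rates=lrs,
                    batch_size=len(classes) * samples_per_batch_per_class,
                    samples_per_batch_per_class=samples_per_batch_per_class,
                )
            )
            epoch += 1
    return states


def curriculum_order(
    per_class_f1: Mapping[str, float],
    forced_last: Sequence[str] = ("SLent",),
    taxonomy: DiagnosisTaxonomy = DEFAULT_TAXONOMY,
) -> List[str]:
    """Class order from easiest (highest flat-model F1) to hardest.

    ``forced_last`` classes are appended in the given order regardless
    of score (the rarest class is hardest whatever its F1 says); ties
    break alphabetically.
    """
    missing = set(taxonomy.codes) - set(per_class_f1)
    if missing:
        raise ValueError(f"missing F1 scores for: {sorted(missing)}")
    tail = list(forced_last)
    head = [c for c in taxonomy.codes if c not in tail]
    head.sort(key=lambda c: (-float(per_class_f1[c]), c))
    return head + tail


def curriculum_schedule(
    spec: CurriculumSpec,
    backbone: BackboneSpec,
    head_lr: float = HEAD_LR,
    body_lr: float = BODY_LR,
) -> List[ScheduleState]:
    """Curriculum: grow the active-class set one class per outer cycle.

    Each outer cycle runs a full frozen-block unfreeze
    (``blocks_per_cycle`` phases of ``epochs_per_phase`` epochs); when a
    new class is introduced all blocks are refrozen and unfreezing
    restarts.  Batches hold one sample of each active class, so the
    batch size equals the number of active classes.
    """
    states: List[ScheduleState] = []
    epoch = 0
    for n_classes in range(spec.initial_count, len(spec.ordered_classes) + 1):
        active = spec.ordered_classes[:n_classes]
        inner = frozen_block_schedule(
            backbone,
            cycles=spec.blocks_per_cycle,
            epochs_per_cycle=spec.epochs_per_phase,
            active_classes=active,
            head_lr=head_lr,
            body_lr=body_lr,
            epoch_offset=epoch,
        )
        states.extend(inner)
        epoch += len(inner)
    return states


def stratified_batches(
    labels: Sequence,
    samples_per_class: int = 200,
    seed: int = 0,
    per_class_per_batch: int = 1,
) -> List[np.ndarray]:
    """Class-balanced batches for one epoch.

    Each class contributes exactly ``samples_per_class`` indices per
    epoch — a random subset when the class is large enough, sampling
    with replacement (oversampling) when it is under-represented.
    Batches are transversals holding ``per_class_per_batch`` samples of
    every class, so the batch size is ``n_classes *
    per_class_per_batch``.  Deterministic given the seed.
    """
    if samples_per_class % per_class_per_batch != 0:
        raise ValueError("samples_per_class must be divisible by per_class_per_batch")
    labels = np.asarray(labels)
    classes = sorted(np.unique(labels).tolist())
    if not classes:
        raise ValueError("no labels given")
    rng = np.random.default_rng(seed)
    per_class_indices = {}
    for c in classes:
        idx = np.nonzero(labels == c)[0]
        if idx.size == 0:
            raise ValueError(f"class {c!r} has no samples")
        if idx.size >= samples_per_class:
            chosen = rng.choice(idx, size=samples_per_class, replace=False)
        else:
            chosen = rng.choice(idx, size=samples_per_class, replace=True)
        rng.shuffle(chosen)
        per_class_indices[c] = chosen
    n_batches = samples_per_class // per_class_per_batch
    batches = []
    for b in range(n_batches):
        chunk = np.concatenate(
            [
                per_class_indices[c][b * per_class_per_batch : (b + 1) * per_class_per_batch]
                for c in classes
            ]
        )
        rng.shuffle(chunk)
        batches.append(chunk)
    return batches


SEX_ENCODING = {"male": 1.0, "female": 0.0, "M": 1.0, "F": 0.0}


def fuse_metadata(features: np.ndarray, age: float, sex: str) -> np.ndarray:
    """Late fusion: append normalised age and a sex indicator.

    Age is scaled by 1/100 so it is commensurate with unit-scale
    features; sex is a 0/1 indicator.  Output dimension is D + 2.
    """
    if age < 0:
        raise ValueError("age must be nonnegative")
    if sex not in SEX_ENCODING:
        raise ValueError(f"unknown sex category: {sex!r}")
    features = np.asarray(features, dtype=float).ravel()
    return np.concatenate([features, [age / 100.0, SEX_ENCODING[sex]]])
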