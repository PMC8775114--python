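"""Backend trainers that execute the schedule streams.

The trainers consume :class:`~dermprio.schedules.ScheduleState`
sequences and drive a :class:`~dermprio.nn.MultiHeadModel`:

* flat 13-way diagnosis training (optionally under the curriculum
  schedule, which simply varies the active-class set per epoch);
* hierarchical (branch) training with epoch-scheduled per-level loss
  weights;
* the combined two-head trainer whose final priority score fuses the
  priority head with the knowledge-map route *during* training, so the
  loss sees both the diagnosis and the fused priority.

Images are NHWC float arrays in [0, 1]; labels are integer indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .fusion import FusionConfig, KnowledgeMap
from .nn import Adam, MultiHeadModel, cross_entropy, softmax
from .schedules import (
    AugmentationConfig,
    LossWeightSchedule,
    ScheduleState,
    bcnn_loss_weights,
    stratified_batches,
)
from .taxonomy import DEFAULT_TAXONOMY

__all__ = [
    "TrainConfig",
    "augment_batch",
    "train_flat",
    "train_hierarchical",
    "train_combined",
    "predict_probs",
    "combined_priority_scores",
]


@dataclass
class TrainConfig:
    """Trainer knobs.

    Learning rates default to ``None``, meaning "use the rates carried
    by each schedule state" (the full-scale defaults); tiny randomly
    initialised backbones train with explicitly larger rates.
    """

    head_lr: Optional[float] = None
    body_lr: Optional[float] = None
    samples_per_class: int = 200
    seed: int = 0
    lambda_dx: float = 0.5
    lambda_pr: float = 0.5
    augment: Optional[AugmentationConfig] = None


def augment_batch(
    images: np.ndarray, cfg: AugmentationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Light geometric/photometric augmentation of an NHWC batch."""
    out = np.empty_like(images)
    lo_r, hi_r = cfg.rotation_range
    lo_s, hi_s = cfg.shift_range
    lo_b, hi_b = cfg.brightness_range
    lo_c, hi_c = cfg.channel_shift_range
    for i, img in enumerate(images):
        x = img
        angle = rng.uniform(lo_r, hi_r) * rng.choice([-1, 1])
        x = ndimage.rotate(x, angle, axes=(0, 1), reshape=False, order=1, mode=cfg.fill_mode)
        if cfg.horizontal_flip and rng.random() < 0.5:
            x = x[:, ::-1]
        if cfg.vertical_flip and rng.random() < 0.5:
            x = x[::-1]
        shift = rng.uniform(lo_s, hi_s, size=2) * np.array(x.shape[:2]) * rng.choice([-1, 1], 2)
        x = ndimage.shift(x, (*shift, 0), order=1, mode=cfg.fill_mode)
        # brightness as a multiplicative factor around 1, channel shift on the 0-255 scale
        x = x * rng.uniform(lo_b + 0.5, hi_b + 0.5)
        x = x + rng.uniform(lo_c, hi_c, size=x.shape[-1]) / 255.0 * rng.choice([-1, 1])
        out[i] = np.clip(x, 0.0, 1.0)
    return out


def _state_lrs(state: ScheduleState, cfg: TrainConfig) -> Tuple[float, float]:
    head = cfg.head_lr if cfg.head_lr is not None else state.learning_rates.get("head", 1e-4)
    body_defaults = [v for k, v in state.learning_rates.items() if k != "head"]
    body = cfg.body_lr if cfg.body_lr is not None else (body_defaults[0] if body_defaults else head / 10)
    return head, body


def _epoch_batches(
    labels: np.ndarray,
    active_idx: Sequence[int],
    state: ScheduleState,
    cfg: TrainConfig,
    epoch_seed: int,
) -> List[np.ndarray]:
    """Stratified batches over the samples of the active classes."""
    keep = np.isin(labels, list(active_idx))
    pool = np.nonzero(keep)[0]
    sub = stratified_batches(
        labels[pool],
        samples_per_class=cfg.samples_per_class,
        seed=epoch_seed,
        per_class_per_batch=state.samples_per_batch_per_class,
    )
    return [pool[b] for b in sub]


def _run_epochs(
    model: MultiHeadModel,
    states: Sequence[ScheduleState],
    images: np.ndarray,
    labels_for_batching: np.ndarray,
    cfg: TrainConfig,
    step_fn,
) -> List[Dict]:
    """Shared epoch loop: freezing, batching, optimisation, bookkeeping."""
    optimizer = Adam()
    rng = np.random.default_rng(cfg.seed)
    taxonomy_index = {c: i for i, c in enumerate(DEFAULT_TAXONOMY.codes)}
    history: List[Dict] = []
    for state in states:
        model.set_trainable(state.trainable_blocks)
        head_lr, body_lr = _state_lrs(state, cfg)
        active_idx = [taxonomy_index[c] for c in state.active_classes if c in taxonomy_index]
        if not active_idx:  # non-diagnosis label space (e.g. priority branch)
            active_idx = sorted(set(labels_for_batching.tolist()))
        batches = _epoch_batches(labels_for_batching, active_idx, state, cfg, int(rng.integers(2**31)))
        epoch_loss = 0.0
        for batch in batches:
            x = images[batch]
            if cfg.augment is not None:
                x = augment_batch(x, cfg.augment, rng)
            model.zero_grad()
            loss = step_fn(model, x, batch, state)
            optimizer.step(model.param_groups(head_lr, body_lr))
            epoch_loss += loss
        history.append(
            {
                "epoch": state.epoch,
                "phase": state.phase,
                "n_active_classes": len(active_idx),
                "trainable_blocks": list(state.trainable_blocks),
                "loss": epoch_loss / max(len(batches), 1),
            }
        )
    return history


def train_flat(
    model: MultiHeadModel,
    states: Sequence[ScheduleState],
    images: np.ndarray,
    labels: np.ndarray,
    cfg: Optional[TrainConfig] = None,
    head: str = "dx",
) -> List[Dict]:
    """Single-head cross-entropy training (flat scheme or curriculum)."""
    cfg = cfg or TrainConfig()
    labels = np.asarray(labels)

    def step(model: MultiHeadModel, x: np.ndarray, batch: np.ndarray, state: ScheduleState) -> float:
        y = labels[batch]
        logits = model.forward(x, train=True)[head]
        probs = softmax(logits)
        n = len(batch)
        grad = probs.copy()
        grad[np.arange(n), y] -= 1.0
        model.backward({head: grad / n})
        return cross_entropy(probs, y)

    return _run_epochs(model, states, images, labels, cfg, step)


def train_hierarchical(
    model: MultiHeadModel,
    states: Sequence[ScheduleState],
    images: np.ndarray,
    level_labels: Mapping[str, np.ndarray],
    schedule: LossWeightSchedule,
    level_heads: Sequence[str],
    cfg: Optional[TrainConfig] = None,
    fine_labels_key: Optional[str] = None,
) -> List[Dict]:
    """Branch (B-CNN) training: weighted sum of per-level losses.

    ``level_heads`` lists head names coarse -> fine; ``level_labels``
    maps each head name to its integer label array.  Per-epoch level
    weights come from the loss-weight schedule.
    """
    cfg = cfg or TrainConfig()
    fine_key = fine_labels_key or level_heads[-1]
    batch_labels = np.asarray(level_labels[fine_key])

    def step(model: MultiHeadModel, x: np.ndarray, batch: np.ndarray, state: ScheduleState) -> float:
        weights = bcnn_loss_weights(schedule, state.epoch)
        logits = model.forward(x, train=True)
        n = len(batch)
        grads, total = {}, 0.0
        for w, head in zip(weights, level_heads):
            y = np.asarray(level_labels[head])[batch]
            probs = softmax(logits[head])
            g = probs.copy()
            g[np.arange(n), y] -= 1.0
            grads[head] = w * g / n
            total += w * cross_entropy(probs, y)
        model.backward(grads)
        return total

    return _run_epochs(model, states, images, batch_labels, cfg, step)


def combined_priority_scores(
    dx_probs: np.ndarray,
    pr_probs: np.ndarray,
    km: KnowledgeMap,
    fusion: FusionConfig,
) -> np.ndarray:
    """Fused priority scores alpha*priority + beta*(naive normalised).

    The sum-mode naive output of a unit-sum diagnosis vector always
    totals 100, so normalisation is division by 100.
    """
    naive = dx_probs @ km.mean
    return fusion.alpha * pr_probs + fusion.beta * naive / naive.sum(axis=1, keepdims=True)


def train_combined(
    model: MultiHeadModel,
    states: Sequence[ScheduleState],
    images: np.ndarray,
    dx_labels: np.ndarray,
    pr_labels: np.ndarray,
    km: KnowledgeMap,
    fusion: Optional[FusionConfig] = None,
    cfg: Optional[TrainConfig] = None,
) -> List[Dict]:
    """Two-head trainer with in-training knowledge-map fusion.

    Total loss = lambda_dx * CE(diagnosis head) + lambda_pr *
    CE(softmax of the fused priority score).  Both gradients flow: the
    fused loss reaches the diagnosis head through the knowledge map.
    """
    cfg = cfg or TrainConfig()
    fusion = fusion or FusionConfig()
    dx_labels = np.asarray(dx_labels)
    pr_labels = np.asarray(pr_labels)
    M = km.mean

    def step(model: MultiHeadModel, x: np.ndarray, batch: np.ndarray, state: ScheduleState) -> float:
        n = len(batch)
        y_dx = dx_labels[batch]
        y_pr = pr_labels[batch]
        logits = model.forward(x, train=True)
        s = softmax(logits["dx"])
        p = softmax(logits["pr"])
        u = s @ M  # row sums are exactly 100 for unit-sum s
        f = fusion.alpha * p + fusion.beta * u / 100.0
        q = softmax(f)

        loss = cfg.lambda_dx * cross_entropy(s, y_dx) + cfg.lambda_pr * cross_entropy(q, y_pr)

        dq = q.copy()
        dq[np.arange(n), y_pr] -= 1.0
        df = cfg.lambda_pr * dq / n
        # priority head: through softmax p
        dp = fusion.alpha * df
        g_pr = p * (dp - (dp * p).sum(axis=1, keepdims=True))
        # diagnosis head: fused route through the knowledge map + direct CE
        ds = (fusion.beta / 100.0) * (df @ M.T)
        g_dx = s * (ds - (ds * s).sum(axis=1, keepdims=True))
        direct = s.copy()
        direct[np.arange(n), y_dx] -= 1.0
        g_dx = g_dx + cfg.lambda_dx * direct / n
        model.backward({"dx": g_dx, "pr": g_pr})
        return loss

    return _run_epochs(model, states, images, dx_labels, cfg, step)


def predict_probs(
    model: MultiHeadModel, images: np.ndarray, head: str = "dx", batch_size: int = 64
) -> np.ndarray:
    """Softmax probabilities of one head in evaluation mode."""
    chunks = []
    for start in range(0, len(images), batch_size):
        logits = model.forward(images[start : start + batch_size], train=False)[head]
        chunks.append(softmax(logits))
    return np.concatenate(chunks, axis=0)
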