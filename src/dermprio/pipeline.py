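"""End-to-end orchestration and the table-reproduction harness.

`run_reproduce` ties the packaged referral count tables to the expert
knowledge map and checks the ground-truth-diagnosis (Naive GT)
prioritization metrics cell by cell against the packaged reference
values.  `run_pipeline` chains the stages (simulate -> crop -> train ->
fuse -> evaluate) on a working directory, with every stage reading the
previous stage's declared outputs and all randomness seeded.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from PIL import Image

from . import evaluation as ev
from .cropping import CropConfig, LesionMask, crop_and_resize, square_patch
from .fusion import (
    FusionConfig,
    KnowledgeMap,
    default_knowledge_map,
    naive_fuse,
    naive_gt,
    predict_priority,
    simple_fuse,
)
from .synthetic import GeneratorConfig, cases_to_frame, counts_from_cases, generate_cases
from .taxonomy import DEFAULT_PRIORITIES, DEFAULT_TAXONOMY

logger = logging.getLogger("dermprio")

APPROACHES = ("baseline", "naive_sum", "naive_max", "simple", "combined", "naive_gt")


@dataclass
class PipelineConfig:
    """Configuration for `run_pipeline`."""

    out_dir: Path
    stages: Sequence[str] = ("simulate", "crop", "evaluate")
    approach: str = "naive_gt"
    n_per_class: int = 10
    image_size: int = 32
    tolerance_pct: float = 30.0
    output_size: int = 32
    fusion: FusionConfig = field(default_factory=FusionConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        if self.approach not in APPROACHES:
            raise ValueError(f"approach must be one of {APPROACHES}, got {self.approach!r}")
        unknown = set(self.stages) - {"simulate", "crop", "train-dx", "train-priority", "fuse", "evaluate"}
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")


def _reference() -> Dict:
    with resources.files("dermprio.data").joinpath("naive_gt_reference.json").open() as fh:
        return json.load(fh)


def run_reproduce(
    km: Optional[KnowledgeMap] = None,
    counts_source=None,
    tolerance: float = 0.01,
) -> Dict:
    """Recompute every Naive-GT reference cell and compare.

    Returns a report dict with computed and reference values and a
    per-cell pass flag at ``tolerance`` (absolute, after 2-decimal
    rounding); ``report["all_pass"]`` aggregates them.
    """
    km = km or default_knowledge_map()
    reference = _reference()
    report: Dict = {"tolerance": tolerance, "partitions": {}, "all_pass": True}
    for partition in ("test1", "test2"):
        table = ev.load_count_table(counts_source, partition=partition)
        metrics, cm = ev.naive_gt_from_counts(table, km)
        rounded = metrics.rounded()
        ref = reference[partition]
        cells: Dict[str, Dict] = {}

        def check(name: str, got: float, want: float) -> None:
            ok = abs(got - want) <= tolerance
            cells[name] = {"computed": got, "reference": want, "pass": ok}
            if not ok:
                report["all_pass"] = False

        check("accuracy", rounded.accuracy, ref["accuracy"])
        check("weighted_f1", rounded.weighted_f1, ref["weighted_f1"])
        check("macro_f1", rounded.macro_f1, ref["macro_f1"])
        for level, vals in ref["per_class"].items():
            check(f"{level}_sensitivity", rounded.sensitivity[level], vals["sensitivity"])
            check(f"{level}_precision", rounded.precision[level], vals["precision"])
            check(f"{level}_f1", rounded.f1[level], vals["f1"])
        if "hp_correct" in ref:
            hp = cm.labels.index("HP")
            got_hp = int(cm.matrix[hp, hp])
            ok = got_hp == ref["hp_correct"]
            cells["hp_correct"] = {"computed": got_hp, "reference": ref["hp_correct"], "pass": ok}
            if not ok:
                report["all_pass"] = False
        report["partitions"][partition] = {
            "cells": cells,
            "confusion": cm.to_frame().to_dict(),
            "total": table.total,
        }
    return report


def _save_png(path: Path, array: np.ndarray) -> None:
    if array.dtype != np.uint8:
        array = np.clip(np.asarray(array, dtype=float) * 255, 0, 255).astype(np.uint8)
    Image.fromarray(array).save(path)


def _stage_simulate(cfg: PipelineConfig) -> None:
    gen = GeneratorConfig(image_size=cfg.image_size, seed=cfg.seed)
    cases = generate_cases(gen, n_per_class=cfg.n_per_class)
    img_dir = cfg.out_dir / "images"
    mask_dir = cfg.out_dir / "masks"
    img_dir.mkdir(parents=True, exist_ok=True)
    mask_dir.mkdir(parents=True, exist_ok=True)
    for case in cases:
        _save_png(img_dir / f"{case.case_id}.png", case.image)
        _save_png(mask_dir / f"{case.case_id}.png", case.mask.astype(np.uint8) * 255)
    cases_to_frame(cases).to_csv(cfg.out_dir / "cases.csv", index=False)
    counts = counts_from_cases(cases)
    frame = counts.to_frame().rename_axis("code").reset_index()
    frame.to_csv(cfg.out_dir / "counts.csv", index=False)


def _stage_crop(cfg: PipelineConfig) -> None:
    cases = pd.read_csv(cfg.out_dir / "cases.csv")
    crop_cfg = CropConfig(tolerance_pct=cfg.tolerance_pct, output_size=cfg.output_size)
    out_dir = cfg.out_dir / "cropped"
    out_dir.mkdir(parents=True, exist_ok=True)
    log_rows = []
    for case_id in cases["case_id"]:
        image = np.asarray(Image.open(cfg.out_dir / "images" / f"{case_id}.png"), dtype=float) / 255.0
        mask_arr = np.asarray(Image.open(cfg.out_dir / "masks" / f"{case_id}.png")) > 127
        mask = (
            LesionMask(grid=mask_arr, provenance="deeplab")
            if mask_arr.any()
            else LesionMask.empty(mask_arr.shape)
        )
        box = square_patch(mask, crop_cfg, image.shape[:2])
        cropped = crop_and_resize(image, box, crop_cfg)
        _save_png(out_dir / f"{case_id}.png", cropped)
        coords = box.as_tuple() if box is not None else ("", "", "", "")
        log_rows.append([case_id, mask.provenance, *coords])
    pd.DataFrame(
        log_rows, columns=["case_id", "chosen_mask", "row_start", "row_stop", "col_start", "col_stop"]
    ).to_csv(cfg.out_dir / "crop_log.csv", index=False)


def _load_images(cfg: PipelineConfig, case_ids: Sequence[str]) -> np.ndarray:
    folder = cfg.out_dir / ("cropped" if (cfg.out_dir / "cropped").is_dir() else "images")
    return np.stack(
        [np.asarray(Image.open(folder / f"{cid}.png"), dtype=float) / 255.0 for cid in case_ids]
    )


def _stage_train_dx(cfg: PipelineConfig) -> None:
    from .nn import make_tiny_cnn
    from .schedules import frozen_block_schedule
    from .training import TrainConfig, predict_probs, train_flat

    cases = pd.read_csv(cfg.out_dir / "cases.csv")
    images = _load_images(cfg, cases["case_id"])
    labels = np.array([DEFAULT_TAXONOMY.position(c) for c in cases["diagnosis"]])
    model, spec = make_tiny_cnn(n_classes=13, seed=cfg.seed)
    states = frozen_block_schedule(spec, cycles=spec.n_blocks)
    n_min = int(np.bincount(labels, minlength=13).min())
    tc = TrainConfig(head_lr=0.01, body_lr=0.002, samples_per_class=max(n_min, 4), seed=cfg.seed)
    train_flat(model, states, images, labels, tc)
    probs = predict_probs(model, images)
    out = pd.DataFrame(probs, columns=list(DEFAULT_TAXONOMY.codes))
    out.insert(0, "case_id", cases["case_id"])
    out.to_csv(cfg.out_dir / "dx_scores.csv", index=False)


def _stage_train_priority(cfg: PipelineConfig) -> None:
    from .nn import make_tiny_cnn
    from .schedules import frozen_block_schedule
    from .training import TrainConfig, predict_probs, train_flat

    cases = pd.read_csv(cfg.out_dir / "cases.csv")
    images = _load_images(cfg, cases["case_id"])
    labels = np.array([DEFAULT_PRIORITIES.severity(p) for p in cases["priority"]])
    model, spec = make_tiny_cnn(n_classes=3, seed=cfg.seed + 1)
    states = frozen_block_schedule(
        spec, cycles=spec.n_blocks, initial_unfrozen=min(3, spec.n_blocks),
        samples_per_batch_per_class=4, active_classes=(),
    )
    n_min = int(np.bincount(labels, minlength=3).min())
    tc = TrainConfig(head_lr=0.01, body_lr=0.002, samples_per_class=max(n_min - n_min % 4, 4), seed=cfg.seed)
    train_flat(model, states, images, labels, tc)
    probs = predict_probs(model, images)
    out = pd.DataFrame(probs, columns=list(DEFAULT_PRIORITIES.levels))
    out.insert(0, "case_id", cases["case_id"])
    out.to_csv(cfg.out_dir / "priority_scores.csv", index=False)


def _stage_fuse(cfg: PipelineConfig, km: KnowledgeMap) -> None:
    cases = pd.read_csv(cfg.out_dir / "cases.csv")
    preds: List[str] = []
    if cfg.approach == "naive_gt":
        preds = [naive_gt(dx, km) for dx in cases["diagnosis"]]
    else:
        dx_path = cfg.out_dir / "dx_scores.csv"
        pr_path = cfg.out_dir / "priority_scores.csv"
        dx = pd.read_csv(dx_path).set_index("case_id") if dx_path.exists() else None
        pr = pd.read_csv(pr_path).set_index("case_id") if pr_path.exists() else None
        for case_id in cases["case_id"]:
            if cfg.approach == "baseline":
                if pr is None:
                    raise FileNotFoundError("stage 'fuse' (baseline) needs train-priority outputs")
                preds.append(predict_priority(pr.loc[case_id].to_numpy()))
                continue
            if dx is None:
                raise FileNotFoundError(f"stage 'fuse' ({cfg.approach}) needs train-dx outputs")
            mode = "max" if cfg.approach == "naive_max" else "sum"
            fused = naive_fuse(dx.loc[case_id].to_numpy(), km, mode=mode)
            if cfg.approach in ("simple", "combined"):
                if pr is None:
                    raise FileNotFoundError(f"stage 'fuse' ({cfg.approach}) needs train-priority outputs")
                fused = simple_fuse(pr.loc[case_id].to_numpy(), fused, cfg.fusion)
            preds.append(predict_priority(fused))
    pd.DataFrame({"case_id": cases["case_id"], "predicted": preds}).to_csv(
        cfg.out_dir / "predictions.csv", index=False
    )


def _stage_evaluate(cfg: PipelineConfig) -> Dict:
    cases = pd.read_csv(cfg.out_dir / "cases.csv")
    preds = pd.read_csv(cfg.out_dir / "predictions.csv")
    merged = cases.merge(preds, on="case_id", validate="one_to_one")
    metrics, cm = ev.evaluate_predictions(merged)
    payload = {
        "approach": cfg.approach,
        "metrics": metrics.rounded().to_dict(),
        "confusion": cm.to_frame().to_dict(),
    }
    with open(cfg.out_dir / "metrics.json", "w") as fh:
        json.dump(payload, fh, indent=2)
    return payload


def run_pipeline(cfg: PipelineConfig, km: Optional[KnowledgeMap] = None) -> Dict:
    """Execute the enabled stages in order; returns the final payload."""
    km = km or default_knowledge_map()
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    order = ["simulate", "crop", "train-dx", "train-priority", "fuse", "evaluate"]
    result: Dict = {}
    for stage in order:
        if stage not in cfg.stages:
            continue
        t0 = time.perf_counter()
        logger.info("stage %s: starting", stage)
        try:
            if stage == "simulate":
                _stage_simulate(cfg)
            elif stage == "crop":
                _require(cfg.out_dir / "cases.csv", stage, "simulate")
                _stage_crop(cfg)
            elif stage == "train-dx":
                _require(cfg.out_dir / "cases.csv", stage, "simulate")
                _stage_train_dx(cfg)
            elif stage == "train-priority":
                _require(cfg.out_dir / "cases.csv", stage, "simulate")
                _stage_train_priority(cfg)
            elif stage == "fuse":
                _require(cfg.out_dir / "cases.csv", stage, "simulate")
                _stage_fuse(cfg, km)
            elif stage == "evaluate":
                if not (cfg.out_dir / "predictions.csv").exists():
                    _stage_fuse(cfg, km)
                result = _stage_evaluate(cfg)
        except FileNotFoundError as exc:
            raise FileNotFoundError(f"stage {stage!r}: missing upstream artifact ({exc})") from exc
        logger.info("stage %s: done in %.2fs", stage, time.perf_counter() - t0)
    return result


def _require(path: Path, stage: str, upstream: str) -> None:
    if not path.exists():
        raise FileNotFoundError(f"{path} (produced by stage {upstream!r}) is required by {stage!r}")
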