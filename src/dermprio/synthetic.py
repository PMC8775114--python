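"""Synthetic referral-case generator.

The real referral dataset is private, so this module renders
class-conditional lesion fixtures that mirror its structure: 13
diagnosis classes with visually distinct lesion appearance (hue,
texture, border irregularity, size), exact ground-truth masks, patient
metadata (age ~ 55.84 +/- 22.18 years truncated to [0, 100], male
fraction 1406/3427), and priority labels drawn from the expert
knowledge-map row of each diagnosis.  Appearance is deliberately
separable — the point is testing pipelines and recovering known
relationships, not photorealism.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from skimage import color as skcolor

from .evaluation import CountTable
from .fusion import KnowledgeMap, default_knowledge_map
from .taxonomy import DEFAULT_PRIORITIES, DEFAULT_TAXONOMY, DiagnosisTaxonomy, PriorityLevels

__all__ = [
    "ClassAppearance",
    "GeneratorConfig",
    "CaseRecord",
    "generate_cases",
    "counts_from_cases",
    "cases_to_frame",
    "make_test2_subset",
]

#: Dataset-level metadata statistics being emulated.
AGE_MEAN = 55.84
AGE_SD = 22.18
MALE_FRACTION = 1406 / 3427


@dataclass(frozen=True)
class ClassAppearance:
    """Rendering parameters of one diagnosis class."""

    hue: float
    saturation: float = 0.75
    value: float = 0.45
    texture_amplitude: float = 0.03
    border_irregularity: float = 0.08
    size_range: Tuple[float, float] = (0.18, 0.30)  # radius as fraction of image side


def _default_appearances(taxonomy: DiagnosisTaxonomy) -> Dict[str, ClassAppearance]:
    """Pairwise-distinct appearances: one hue per class plus small
    systematic differences in texture, border and size."""
    out = {}
    n = len(taxonomy)
    for i, code in enumerate(taxonomy.codes):
        out[code] = ClassAppearance(
            hue=i / n,
            saturation=0.6 + 0.3 * ((i % 3) / 2),
            value=0.35 + 0.25 * ((i % 2)),
            texture_amplitude=0.02 + 0.015 * (i % 4),
            border_irregularity=0.04 + 0.04 * (i % 3),
            size_range=(0.16 + 0.02 * (i % 2), 0.26 + 0.03 * (i % 2)),
        )
    return out


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic cohort."""

    image_size: int = 64
    appearances: Optional[Dict[str, ClassAppearance]] = None
    hair_artifacts: bool = True
    hair_probability: float = 0.3
    ruler_artifacts: bool = False
    age_mean: float = AGE_MEAN
    age_sd: float = AGE_SD
    male_fraction: float = MALE_FRACTION
    km: Optional[KnowledgeMap] = None
    taxonomy: DiagnosisTaxonomy = DEFAULT_TAXONOMY
    priorities: PriorityLevels = DEFAULT_PRIORITIES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size < 16:
            raise ValueError("image_size must be >= 16")
        if not 0 <= self.male_fraction <= 1:
            raise ValueError("male_fraction must be a probability")
        if self.age_sd <= 0:
            raise ValueError("age_sd must be positive")

    def resolved_appearances(self) -> Dict[str, ClassAppearance]:
        app = self.appearances or _default_appearances(self.taxonomy)
        missing = set(self.taxonomy.codes) - set(app)
        if missing:
            raise ValueError(f"missing appearances for: {sorted(missing)}")
        return app

    def resolved_km(self) -> KnowledgeMap:
        return self.km if self.km is not None else default_knowledge_map()


@dataclass
class CaseRecord:
    """One synthetic referral case."""

    case_id: str
    image: Optional[np.ndarray]  # HxWx3 float in [0,1], None when not rendered
    mask: Optional[np.ndarray]  # HxW bool ground-truth lesion mask
    age: float
    sex: str
    diagnosis: str
    priority: str


def _sample_age(rng: np.random.Generator, mean: float, sd: float) -> float:
    a, b = (0.0 - mean) / sd, (100.0 - mean) / sd
    return float(stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def _render_lesion(
    rng: np.random.Generator, app: ClassAppearance, size: int, hair: bool
) -> Tuple[np.ndarray, np.ndarray]:
    """Render one lesion on a skin-tone background; mask is exact."""
    # skin-tone background with mild vignette-free noise
    base_hsv = np.array([0.07 + rng.uniform(-0.01, 0.01), 0.35 + rng.uniform(-0.05, 0.05), 0.85])
    img = np.ones((size, size, 3)) * skcolor.hsv2rgb(base_hsv[None, None, :])
    img += rng.normal(0, 0.015, img.shape)

    cy, cx = (size - 1) / 2 + rng.uniform(-0.08, 0.08, 2) * size
    radius = rng.uniform(*app.size_range) * size
    aspect = rng.uniform(0.75, 1.0)
    theta0 = rng.uniform(0, 2 * np.pi)
    yy, xx = np.mgrid[0:size, 0:size]
    dy, dx = yy - cy, xx - cx
    ang = np.arctan2(dy, dx)
    # irregular border: radius modulated by low-order harmonics
    amp = app.border_irregularity
    wobble = 1.0 + amp * (
        np.sin(3 * ang + theta0) * rng.uniform(0.5, 1.0)
        + 0.5 * np.sin(5 * ang + 2 * theta0) * rng.uniform(0.5, 1.0)
    )
    # elliptical distance in a rotated frame
    u = np.cos(theta0) * dx + np.sin(theta0) * dy
    v = -np.sin(theta0) * dx + np.cos(theta0) * dy
    mask = np.hypot(u, v / aspect) <= radius * wobble

    lesion_hsv = np.array([app.hue, app.saturation, app.value])
    lesion_rgb = skcolor.hsv2rgb(lesion_hsv[None, None, :])[0, 0]
    texture = rng.normal(0, app.texture_amplitude, (size, size, 1))
    img[mask] = lesion_rgb + texture[mask]

    if hair:
        # dark strokes strictly outside the lesion so the mask stays exact
        for _ in range(rng.integers(1, 4)):
            x0, y0 = rng.uniform(0, size, 2)
            angle = rng.uniform(0, np.pi)
            length = rng.uniform(0.3, 0.8) * size
            t = np.linspace(0, 1, int(length * 2))
            xs = np.clip((x0 + t * length * np.cos(angle)).astype(int), 0, size - 1)
            ys = np.clip((y0 + t * length * np.sin(angle)).astype(int), 0, size - 1)
            keep = ~mask[ys, xs]
            img[ys[keep], xs[keep]] = img[ys[keep], xs[keep]] * 0.35
    return np.clip(img, 0, 1), mask


def generate_cases(
    cfg: GeneratorConfig,
    n_per_class: int,
    render_images: bool = True,
) -> List[CaseRecord]:
    """Generate ``n_per_class`` cases per diagnosis class.

    Priorities are multinomial draws from each diagnosis's
    knowledge-map mean row (percent / 100).  ``render_images=False``
    skips image synthesis (labels and metadata only), which keeps
    large statistical checks cheap.  Deterministic given ``cfg.seed``.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(cfg.seed)
    km = cfg.resolved_km()
    apps = cfg.resolved_appearances()
    records: List[CaseRecord] = []
    for code in cfg.taxonomy.codes:
        probs = km.row(code) / 100.0
        priorities = rng.choice(len(cfg.priorities), size=n_per_class, p=probs)
        for j in range(n_per_class):
            image = mask = None
            if render_images:
                hair = cfg.hair_artifacts and rng.random() < cfg.hair_probability
                image, mask = _render_lesion(rng, apps[code], cfg.image_size, hair)
                if not mask.any():  # degenerate draw; retry once with a round lesion
                    image, mask = _render_lesion(
                        rng, ClassAppearance(hue=apps[code].hue, border_irregularity=0.0),
                        cfg.image_size, False,
                    )
            records.append(
                CaseRecord(
                    case_id=f"{code}_{j:05d}",
                    image=image,
                    mask=mask,
                    age=_sample_age(rng, cfg.age_mean, cfg.age_sd),
                    sex="male" if rng.random() < cfg.male_fraction else "female",
                    diagnosis=code,
                    priority=cfg.priorities.levels[int(priorities[j])],
                )
            )
    return records


def counts_from_cases(
    cases: Sequence[CaseRecord],
    taxonomy: DiagnosisTaxonomy = DEFAULT_TAXONOMY,
    priorities: PriorityLevels = DEFAULT_PRIORITIES,
    partition: str = "synthetic",
) -> CountTable:
    """Tally cases into a diagnosis x priority count table."""
    if not cases:
        raise ValueError("no cases to tally")
    counts = np.zeros((len(taxonomy), len(priorities)), dtype=int)
    for case in cases:
        counts[taxonomy.position(case.diagnosis), priorities.severity(case.priority)] += 1
    return CountTable(counts=counts, taxonomy=taxonomy, priorities=priorities, partition=partition)


def cases_to_frame(cases: Sequence[CaseRecord]):
    import pandas as pd

    return pd.DataFrame(
        {
            "case_id": [c.case_id for c in cases],
            "age": [c.age for c in cases],
            "sex": [c.sex for c in cases],
            "diagnosis": [c.diagnosis for c in cases],
            "priority": [c.priority for c in cases],
        }
    )


def make_test2_subset(
    test1_counts: CountTable, n_normal: int = 81, seed: int = 0
) -> CountTable:
    """Balanced-evaluation subset: keep every high-priority and priority
    case, subsample the normal cases to ``n_normal`` uniformly without
    replacement across classes."""
    priorities = test1_counts.priorities
    n_idx = priorities.severity("N")
    normals = test1_counts.counts[:, n_idx]
    available = int(normals.sum())
    if n_normal > available:
        raise ValueError(f"requested {n_normal} normals but only {available} available")
    rng = np.random.default_rng(seed)
    pool = np.repeat(np.arange(len(test1_counts.taxonomy)), normals)
    chosen = rng.choice(pool, size=n_normal, replace=False)
    new_counts = test1_counts.counts.copy()
    new_counts[:, n_idx] = np.bincount(chosen, minlength=len(test1_counts.taxonomy))
    return CountTable(
        counts=new_counts,
        taxonomy=test1_counts.taxonomy,
        priorities=priorities,
        partition="test2",
    )
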