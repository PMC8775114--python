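"""Label taxonomies for the referral-triage problem.

Two fixed label sets are used throughout the package: the 13-way
differential diagnosis assigned after the specialist consultation, and
the 3-level triage priority used to book that consultation (normal,
priority, high priority).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence, Tuple

#: Diagnosis codes in canonical order (matches the knowledge-map rows).
DIAGNOSIS_CODES: Tuple[str, ...] = (
    "SebKer", "ActKer", "Nev", "MolCont", "Haem", "UncNeop", "Drmfib",
    "SLent", "PenFib", "VWart", "OtMalNeop", "BCC", "MM",
)

DIAGNOSIS_NAMES: Mapping[str, str] = {
    "SebKer": "Seborrheic Keratosis",
    "ActKer": "Actinic Keratosis",
    "Nev": "Nevus, Non-neoplastic",
    "MolCont": "Molluscum Contagiosum",
    "Haem": "Haemangioma",
    "UncNeop": "Neoplasm Unc. Behavior",
    "Drmfib": "Dermatofibroma",
    "SLent": "Solar Lentigo",
    "PenFib": "Pendulum Fibroma",
    "VWart": "Viral Warts",
    "OtMalNeop": "Other Malignant Neoplasm",
    "BCC": "Basal Cell Carcinoma",
    "MM": "Malignant Melanoma",
}

#: Priority levels ordered by increasing clinical severity.
PRIORITY_LEVELS: Tuple[str, ...] = ("N", "P", "HP")


@dataclass(frozen=True)
class DiagnosisTaxonomy:
    """Ordered set of diagnosis codes with name and index lookup."""

    codes: Tuple[str, ...] = DIAGNOSIS_CODES
    long_names: Mapping[str, str] = field(default_factory=lambda: dict(DIAGNOSIS_NAMES))

    def __post_init__(self) -> None:
        if len(self.codes) != len(set(self.codes)):
            raise ValueError("diagnosis codes must be unique")
        if len(self.codes) != 13:
            raise ValueError(f"expected 13 diagnosis codes, got {len(self.codes)}")

    @property
    def index(self) -> Mapping[str, int]:
        return {c: i for i, c in enumerate(self.codes)}

    def __len__(self) -> int:
        return len(self.codes)

    def __contains__(self, code: str) -> bool:
        return code in self.codes

    def position(self, code: str) -> int:
        try:
            return self.codes.index(code)
        except ValueError:
            raise KeyError(f"unknown diagnosis code: {code!r}") from None


@dataclass(frozen=True)
class PriorityLevels:
    """Triage levels with a strict severity order (N < P < HP)."""

    levels: Tuple[str, ...] = PRIORITY_LEVELS

    def __post_init__(self) -> None:
        if len(self.levels) != 3 or len(set(self.levels)) != 3:
            raise ValueError("exactly 3 distinct priority levels required")

    def severity(self, level: str) -> int:
        try:
            return self.levels.index(level)
        except ValueError:
            raise KeyError(f"unknown priority level: {level!r}") from None

    def __len__(self) -> int:
        return len(self.levels)

    def __contains__(self, level: str) -> bool:
        return level in self.levels

    def __iter__(self):
        return iter(self.levels)


DEFAULT_TAXONOMY = DiagnosisTaxonomy()
DEFAULT_PRIORITIES = PriorityLevels()


def one_hot(code: str, taxonomy: DiagnosisTaxonomy = DEFAULT_TAXONOMY) -> "list[float]":
    """Length-13 indicator vector for a diagnosis code."""
    v = [0.0] * len(taxonomy)
    v[taxonomy.position(code)] = 1.0
    return v
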