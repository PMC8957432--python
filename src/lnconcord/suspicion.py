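"""The size-conditional CT suspicion rule and enhancement-pattern vocabulary.

A CT-visible node is called suspicious depending on its short-axis size bin
and how many of the three morphologic criteria (roundness, heterogeneous
density, irregular border) it carries:

* ``< 5 mm``   -- suspicious only with all three criteria;
* ``5-10 mm``  -- suspicious with at least two of three;
* ``> 10 mm``  -- always suspicious.

The 5 mm and 10 mm boundaries belong to the middle bin: reading the bins
"<5", "5-10", ">10" makes [5, 10] inclusive at both ends the only
consistent partition of (0, inf).

Enhancement on the venous phase of contrast-enhanced CT is a closed
five-value vocabulary: homogenous, dotted (small <3 mm bright spots),
linear (low-enhancement belts), central (bright central spot) and
peripheral (hypodense centre with hyperdense rim).  Patterns are
categorical radiologist readings; nothing here touches pixels.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

from .errors import DomainError, VocabularyError


class SizeBin(enum.IntEnum):
    """Short-axis size bin of a node; integers order small < mid < large."""

    small = 0   # (0, 5) mm
    mid = 1     # [5, 10] mm
    large = 2   # (10, inf) mm

    def __str__(self) -> str:
        return self.name


class EnhancementPattern(enum.Enum):
    """Venous-phase enhancement pattern of a node on CECT."""

    homogenous = "homogenous"
    dotted = "dotted"
    linear = "linear"
    central = "central"
    peripheral = "peripheral"

    def __str__(self) -> str:
        return self.value


#: Canonical order used for prevalence / odds-ratio vectors everywhere.
PATTERN_ORDER: tuple[EnhancementPattern, ...] = (
    EnhancementPattern.homogenous,
    EnhancementPattern.dotted,
    EnhancementPattern.linear,
    EnhancementPattern.central,
    EnhancementPattern.peripheral,
)

# "homogeneous" is accepted as a read-alias of the canonical spelling;
# "spotted" (the older name for the dotted pattern) deliberately is not.
_PATTERN_ALIASES = {"homogeneous": EnhancementPattern.homogenous}


def validate_pattern(label: str | EnhancementPattern) -> EnhancementPattern:
    """Resolve a pattern label case-insensitively.

    Raises VocabularyError listing the allowed values for unknown labels.
    """
    if isinstance(label, EnhancementPattern):
        return label
    key = str(label).strip().lower()
    if key in _PATTERN_ALIASES:
        return _PATTERN_ALIASES[key]
    try:
        return EnhancementPattern(key)
    except ValueError:
        allowed = ", ".join(p.value for p in EnhancementPattern)
        raise VocabularyError(
            f"unknown enhancement pattern {label!r}; allowed: {allowed}"
        ) from None


@dataclass(frozen=True)
class SuspicionCriteria:
    """The three morphologic suspicion criteria of one CT node."""

    roundness: bool
    heterogeneous_density: bool
    irregular_border: bool

    @property
    def count(self) -> int:
        return int(self.roundness) + int(self.heterogeneous_density) + int(self.irregular_border)


def classify_size_bin(short_axis_mm: float) -> SizeBin:
    """Bin a short-axis diameter (mm): (0,5) small, [5,10] mid, (10,inf) large.

    Raises DomainError for non-positive or non-finite sizes.
    """
    if not isinstance(short_axis_mm, (int, float)) or isinstance(short_axis_mm, bool):
        raise DomainError(f"size must be a real number, got {short_axis_mm!r}")
    if not math.isfinite(short_axis_mm) or short_axis_mm <= 0:
        raise DomainError(
            f"short-axis size must be finite and positive, got {short_axis_mm!r}"
        )
    if short_axis_mm < 5.0:
        return SizeBin.small
    if short_axis_mm <= 10.0:
        return SizeBin.mid
    return SizeBin.large


#: Minimum criteria count per size bin for a node to be suspicious.
_REQUIRED_CRITERIA = {SizeBin.small: 3, SizeBin.mid: 2, SizeBin.large: 0}


def is_suspicious(short_axis_mm: float, criteria: SuspicionCriteria) -> bool:
    """Apply the size-conditional suspicion rule to one node."""
    return criteria.count >= _REQUIRED_CRITERIA[classify_size_bin(short_axis_mm)]


@dataclass(frozen=True)
class CTNodeObservation:
    """One CT-visible node.

    ``suspicious`` is always derived from the rule; construction rejects an
    inconsistent stored value so the concordance statistics can never be fed
    flags that contradict the protocol.
    """

    node_id: str
    patient_id: str
    station_code: str
    short_axis_mm: float
    criteria: SuspicionCriteria
    pattern: EnhancementPattern
    suspicious: bool | None = None

    def __post_init__(self) -> None:
        derived = is_suspicious(self.short_axis_mm, self.criteria)
        if self.suspicious is not None and bool(self.suspicious) != derived:
            raise DomainError(
                f"node {self.node_id!r}: stored suspicious flag "
                f"{self.suspicious!r} contradicts the suspicion rule "
                f"(size {self.short_axis_mm} mm, {self.criteria.count} criteria)"
            )
        object.__setattr__(self, "suspicious", derived)
        object.__setattr__(self, "pattern", validate_pattern(self.pattern))
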