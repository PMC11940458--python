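"""Registry of rated variables and the eight semantic dimensions.

The norming study rates every word on 15 variables: five psycholinguistic
scales (concreteness CNC, imageability IMG, familiarity FAM, age of
acquisition AoA, semantic diversity SEM_DIV), two affective scales
(valence VAL, arousal ARO) and eight semantic dimensions (introspection
INTRO, mental states MENT_ST, quantity QUANT, space SPACE, social SOC,
moral MOR, theoretical THEOR, economic ECO).  The eight dimensions are the
distinguished subset consumed by the exclusivity analysis; every
downstream module takes them from :data:`SEMANTIC_DIMENSIONS`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable, Optional, Sequence

__all__ = [
    "VariableSpec",
    "ItemMeta",
    "SEMANTIC_DIMENSIONS",
    "default_registry",
    "registry_by_name",
    "semantic_dimension_names",
    "likert_names",
    "registry_to_dicts",
    "registry_from_dicts",
]

KIND_PSYCHOLINGUISTIC = "psycholinguistic"
KIND_AFFECTIVE = "affective"
KIND_SEMANTIC_DIMENSION = "semantic_dimension"
KIND_AGE_NUMERIC = "age_numeric"

_VALID_KINDS = frozenset(
    {KIND_PSYCHOLINGUISTIC, KIND_AFFECTIVE, KIND_SEMANTIC_DIMENSION, KIND_AGE_NUMERIC}
)

#: Canonical order of the eight semantic dimensions.
SEMANTIC_DIMENSIONS: tuple[str, ...] = (
    "INTRO",
    "MENT_ST",
    "QUANT",
    "SPACE",
    "SOC",
    "MOR",
    "THEOR",
    "ECO",
)


@dataclass(frozen=True)
class VariableSpec:
    """One rated variable: its name, scale bounds and kind.

    ``scale_max`` may be ``None`` for open-ended numeric responses (age of
    acquisition in years), in which case only the lower bound is enforced.
    """

    name: str
    scale_min: int
    scale_max: Optional[int]
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in _VALID_KINDS:
            raise ValueError(f"unknown variable kind {self.kind!r}")
        if self.scale_max is not None and not self.scale_min < self.scale_max:
            raise ValueError(
                f"{self.name}: scale_min ({self.scale_min}) must be < "
                f"scale_max ({self.scale_max})"
            )

    @property
    def is_likert(self) -> bool:
        """True for bounded integer rating scales (everything except AoA)."""
        return self.scale_max is not None

    def in_bounds(self, value: float) -> bool:
        if self.scale_max is None:
            return value >= self.scale_min
        return self.scale_min <= value <= self.scale_max


@dataclass(frozen=True)
class ItemMeta:
    """Per-word metadata: abstract/concrete flag and optional a priori label.

    The a priori category is kept for provenance only; no computation uses it.
    """

    word: str
    is_abstract: bool
    a_priori_category: Optional[str] = None


def default_registry() -> list[VariableSpec]:
    """The study's 15 variables.

    7-point scales for CNC, IMG, FAM, SEM_DIV and the 8 semantic dimensions;
    9-point scales for valence and arousal; AoA is an age in years
    (nonnegative, unbounded above).
    """
    seven = [("CNC", KIND_PSYCHOLINGUISTIC), ("IMG", KIND_PSYCHOLINGUISTIC),
             ("FAM", KIND_PSYCHOLINGUISTIC), ("SEM_DIV", KIND_PSYCHOLINGUISTIC)]
    specs = [VariableSpec(name, 1, 7, kind) for name, kind in seven]
    specs.append(VariableSpec("AoA", 0, None, KIND_AGE_NUMERIC))
    specs.append(VariableSpec("VAL", 1, 9, KIND_AFFECTIVE))
    specs.append(VariableSpec("ARO", 1, 9, KIND_AFFECTIVE))
    specs.extend(
        VariableSpec(dim, 1, 7, KIND_SEMANTIC_DIMENSION) for dim in SEMANTIC_DIMENSIONS
    )
    return specs


def registry_by_name(specs: Iterable[VariableSpec]) -> dict[str, VariableSpec]:
    """Index a registry by name, rejecting duplicates."""
    out: dict[str, VariableSpec] = {}
    for spec in specs:
        if spec.name in out:
            raise ValueError(f"duplicate variable name {spec.name!r} in registry")
        out[spec.name] = spec
    return out


def semantic_dimension_names(specs: Iterable[VariableSpec]) -> tuple[str, ...]:
    """The semantic-dimension subset of a registry, in canonical order."""
    dims = [s.name for s in specs if s.kind == KIND_SEMANTIC_DIMENSION]
    canonical = [d for d in SEMANTIC_DIMENSIONS if d in dims]
    extras = sorted(d for d in dims if d not in SEMANTIC_DIMENSIONS)
    return tuple(canonical + extras)


def likert_names(specs: Iterable[VariableSpec]) -> tuple[str, ...]:
    """Names of all bounded Likert variables (AoA excluded)."""
    return tuple(s.name for s in specs if s.is_likert)


def registry_to_dicts(specs: Sequence[VariableSpec]) -> list[dict]:
    """Serialize a registry to plain dicts (JSON/YAML-ready)."""
    registry_by_name(specs)  # validate uniqueness
    return [asdict(s) for s in specs]


def registry_from_dicts(items: Sequence[dict]) -> list[VariableSpec]:
    """Inverse of :func:`registry_to_dicts`; validates names and kinds."""
    specs = [VariableSpec(**item) for item in items]
    registry_by_name(specs)
    return specs
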