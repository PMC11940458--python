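"""Representative-dimension labels and exact set-intersection tables.

A word represents a dimension when its mean rating on that dimension is
strictly greater than 3.5 (the scale midpoint region's upper edge); a
word can represent several dimensions at once. The intersection table
counts words per exact dimension combination — the tabulation behind an
UpSet plot — and can be crossed with exclusivity levels.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd

from .variables import SEMANTIC_DIMENSIONS

__all__ = [
    "DimensionLabelSet",
    "IntersectionTable",
    "representative_labels",
    "dimension_counts",
    "intersection_table",
    "crosstab_by_level",
]


@dataclass(frozen=True)
class DimensionLabelSet:
    """The subset of the 8 dimensions a word scores > threshold on."""

    word: str
    dims: frozenset[str]

    @property
    def cardinality(self) -> int:
        return len(self.dims)


def _canonical_combo(dims: frozenset[str]) -> tuple[str, ...]:
    return tuple(d for d in SEMANTIC_DIMENSIONS if d in dims)


@dataclass(frozen=True)
class IntersectionTable:
    """Exact-combination word counts plus per-dimension marginals.

    ``rows`` lists non-empty combinations (canonical dimension order)
    sorted by descending count, then ascending cardinality, then
    lexicographically. Words with an empty label set are excluded from the
    rows but available as ``n_unlabelled``.
    """

    rows: tuple[tuple[tuple[str, ...], int], ...]
    marginals: Mapping[str, int]
    n_words: int
    n_unlabelled: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"combination": "|".join(combo), "cardinality": len(combo),
              "count": count} for combo, count in self.rows]
        )


def representative_labels(norms: pd.DataFrame, threshold: float = 3.5
                          ) -> list[DimensionLabelSet]:
    """Label each word with the dimensions whose mean exceeds ``threshold``.

    Strict inequality: a mean of exactly 3.5 does not qualify. Words
    exceeding the threshold on no dimension are retained with an empty
    label set (they are reported separately downstream).
    """
    cols = [f"{d}_mean" for d in SEMANTIC_DIMENSIONS]
    missing = [c for c in cols if c not in norms.columns]
    if missing:
        raise ValueError(f"norms table missing dimension means: {missing}")
    sub = norms[cols]
    if sub.isna().any().any():
        bad = sub.index[sub.isna().any(axis=1)]
        raise ValueError(f"missing dimension mean for words: {list(bad[:5])}")
    labels = []
    for word, row in sub.iterrows():
        dims = frozenset(d for d in SEMANTIC_DIMENSIONS
                         if row[f"{d}_mean"] > threshold)
        labels.append(DimensionLabelSet(word=str(word), dims=dims))
    return labels


def dimension_counts(labels: Sequence[DimensionLabelSet]) -> dict[str, int]:
    """Words per dimension (a word counts once in every dimension it holds)."""
    counts = {d: 0 for d in SEMANTIC_DIMENSIONS}
    for lab in labels:
        for d in lab.dims:
            counts[d] += 1
    return counts


def intersection_table(labels: Sequence[DimensionLabelSet]) -> IntersectionTable:
    """Exact-combination counts over the 2^8 possible label sets.

    Conservation: the counts over non-empty combinations sum to the number
    of representative (non-empty-label) words, and each dimension's
    marginal equals the sum of counts of combinations containing it.
    """
    combo_counts: Counter[tuple[str, ...]] = Counter()
    n_unlabelled = 0
    for lab in labels:
        if not lab.dims:
            n_unlabelled += 1
            continue
        combo_counts[_canonical_combo(lab.dims)] += 1
    rows = tuple(sorted(
        combo_counts.items(),
        key=lambda kv: (-kv[1], len(kv[0]), kv[0]),
    ))
    marginals = {d: sum(c for combo, c in combo_counts.items() if d in combo)
                 for d in SEMANTIC_DIMENSIONS}
    return IntersectionTable(
        rows=rows, marginals=marginals,
        n_words=len(labels), n_unlabelled=n_unlabelled,
    )


def crosstab_by_level(labels: Sequence[DimensionLabelSet],
                      levels: Mapping[str, str]
                      ) -> tuple[dict[str, IntersectionTable], pd.DataFrame]:
    """One intersection table per exclusivity level, plus the
    level x cardinality histogram.

    ``labels`` and ``levels`` must cover exactly the same words. The
    histogram has one row per level present and columns 0..8; row sums
    equal level sizes (cardinality-0 words are counted in column 0).
    """
    label_words = {lab.word for lab in labels}
    level_words = set(levels)
    if label_words != level_words:
        only_l = sorted(label_words - level_words)[:5]
        only_v = sorted(level_words - label_words)[:5]
        raise ValueError(
            f"labels and levels cover different words "
            f"(labels only: {only_l}, levels only: {only_v})")
    by_level: dict[str, list[DimensionLabelSet]] = {}
    for lab in labels:
        by_level.setdefault(levels[lab.word], []).append(lab)
    tables = {lvl: intersection_table(labs)
              for lvl, labs in sorted(by_level.items())}
    hist = pd.DataFrame(
        0, index=sorted(by_level), columns=range(len(SEMANTIC_DIMENSIONS) + 1)
    )
    for lvl, labs in by_level.items():
        for lab in labs:
            hist.loc[lvl, lab.cardinality] += 1
    hist.index.name = "level"
    hist.columns.name = "cardinality"
    return tables, hist
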