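"""Exclusivity statistic E, percentile levels and the validity correlation.

E quantifies how uni- vs multidimensional an abstract concept is: for each
word, E = (max − min) / sum × 100 over its eight semantic-dimension means.
A word rated equally on all dimensions has E = 0 (fully multidimensional);
a word rated 7 on one dimension and 1 elsewhere reaches the scale maximum
(7 − 1)/(7 + 7·1) × 100 ≈ 42.857 on a 1–7 scale with eight dimensions.

Words are stratified into low/medium/high exclusivity by the 25th and 75th
percentiles of the E distribution, with the medium band closed on both
sides (low: E < p25, medium: p25 ≤ E ≤ p75, high: E > p75).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .variables import SEMANTIC_DIMENSIONS

__all__ = [
    "ExclusivityResult",
    "LevelCutoffs",
    "exclusivity_score",
    "exclusivity_scores",
    "max_exclusivity",
    "assign_levels",
    "validity_correlation",
    "LEVELS",
]

LEVELS = ("low", "medium", "high")


@dataclass(frozen=True)
class LevelCutoffs:
    """Percentile cutoffs used to stratify E into low/medium/high."""

    p25: float
    p75: float
    method: str

    def __post_init__(self) -> None:
        if not self.p25 <= self.p75:
            raise ValueError("p25 must be <= p75")


@dataclass(frozen=True)
class ExclusivityResult:
    """Per-word exclusivity: the score, its level, and the dimension means."""

    word: str
    E: float
    level: str
    dimension_means: Mapping[str, float]


def max_exclusivity(scale_min: float = 1.0, scale_max: float = 7.0,
                    n_dims: int = 8) -> float:
    """Upper bound of E: one dimension at the scale maximum, the rest at
    the minimum, i.e. 100·(U − L)/(U + (d − 1)·L)."""
    return 100.0 * (scale_max - scale_min) / (scale_max + (n_dims - 1) * scale_min)


def exclusivity_score(dimension_means: Sequence[float], *,
                      scale_min: float = 1.0, scale_max: float = 7.0,
                      n_dims: int = 8) -> float:
    """E = (max − min) / sum × 100 over the eight dimension means.

    Raises ``ValueError`` on wrong arity or values outside the rating scale.
    """
    values = np.asarray(dimension_means, dtype=float)
    if values.shape != (n_dims,):
        raise ValueError(
            f"expected exactly {n_dims} dimension means, got shape {values.shape}"
        )
    if np.any(np.isnan(values)):
        raise ValueError("dimension means contain NaN")
    if np.any((values < scale_min) | (values > scale_max)):
        raise ValueError(
            f"dimension means must lie within [{scale_min}, {scale_max}]"
        )
    return float((values.max() - values.min()) / values.sum() * 100.0)


def exclusivity_scores(dimension_means: pd.DataFrame, *,
                       scale_min: float = 1.0,
                       scale_max: float = 7.0) -> pd.Series:
    """Vectorised E over a words × dimensions frame (one row per word).

    Columns must be exactly the eight semantic dimensions (any order).
    """
    missing = [d for d in SEMANTIC_DIMENSIONS if d not in dimension_means.columns]
    if missing:
        raise ValueError(f"missing dimension means: {missing}")
    mat = dimension_means[list(SEMANTIC_DIMENSIONS)].to_numpy(dtype=float)
    if np.isnan(mat).any():
        bad = dimension_means.index[np.isnan(mat).any(axis=1)]
        raise ValueError(f"NaN dimension means for words: {list(bad[:5])}")
    if ((mat < scale_min) | (mat > scale_max)).any():
        raise ValueError(f"dimension means outside [{scale_min}, {scale_max}]")
    scores = (mat.max(axis=1) - mat.min(axis=1)) / mat.sum(axis=1) * 100.0
    return pd.Series(scores, index=dimension_means.index, name="E")


_PERCENTILE_METHODS = {
    # default: linear interpolation between order statistics at (n-1)p + 1
    "linear": "linear",
    # SPSS EXAMINE/FREQUENCIES "weighted average" convention at (n+1)p
    "spss": "weibull",
}


def assign_levels(E_values: pd.Series | Sequence[float], *,
                  percentiles: tuple[float, float] = (25.0, 75.0),
                  method: str = "linear") -> tuple[LevelCutoffs, pd.Series]:
    """Stratify E scores at the 25th/75th percentiles.

    ``method`` selects the percentile convention: ``"linear"`` (interpolation
    between order statistics) or ``"spss"`` (the weighted-average convention
    at position (n+1)p used by SPSS). Boundary values fall in the medium
    band, which is closed on both sides.

    Returns the cutoffs and a level per word. If all scores are identical
    every word is medium and a warning is issued.
    """
    if method not in _PERCENTILE_METHODS:
        raise ValueError(f"unknown percentile method {method!r}")
    E = pd.Series(E_values, dtype=float)
    if len(E) < 4:
        raise ValueError("need at least 4 E values to form quartile levels")
    lo_q, hi_q = percentiles
    p25, p75 = np.percentile(
        E.to_numpy(), [lo_q, hi_q], method=_PERCENTILE_METHODS[method]
    )
    cutoffs = LevelCutoffs(p25=float(p25), p75=float(p75), method=method)
    if E.nunique() == 1:
        warnings.warn("all E values identical; every word assigned 'medium'")
        return cutoffs, pd.Series("medium", index=E.index, name="level")
    levels = pd.Series("medium", index=E.index, name="level")
    levels[E < cutoffs.p25] = "low"
    levels[E > cutoffs.p75] = "high"
    return cutoffs, levels


def validity_correlation(E_values: Sequence[float],
                         semdiv_means: Sequence[float]) -> tuple[float, float]:
    """Pearson correlation (r, two-sided p) between E and semantic diversity.

    The study's validity check: semantic diversity (how many contexts a word
    occurs in) should correlate negatively with exclusivity. Returns
    (nan, nan) with a warning if either input has zero variance.
    """
    x = np.asarray(E_values, dtype=float)
    y = np.asarray(semdiv_means, dtype=float)
    if x.shape != y.shape:
        raise ValueError("E and SEM_DIV inputs must be paired (same length)")
    if x.size < 3:
        raise ValueError("need at least 3 pairs for a correlation")
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn("zero variance in E or SEM_DIV; correlation undefined")
        return float("nan"), float("nan")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
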