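"""Inter-rater reliability: Cronbach's alpha per variable.

Raters play the role of the scale's "items" and words the role of cases,
the standard convention for quantifying rater consistency in norming
studies. Because raters see disjoint word lists, alpha is computed within
each list (where a complete word x rater block exists) and pooled as the
unweighted mean across lists; a variable is acceptable when its pooled
alpha exceeds 0.6.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .ratings_io import records_to_frame
from .variables import VariableSpec, default_registry

__all__ = ["ReliabilityReport", "cronbach_alpha", "reliability_report"]

logger = logging.getLogger(__name__)


@dataclass
class ReliabilityReport:
    """Per-variable alpha by list, pooled alpha, and acceptability."""

    alpha_by_list: dict[str, dict[str, float]] = field(default_factory=dict)
    pooled_alpha: dict[str, float] = field(default_factory=dict)
    acceptable: dict[str, bool] = field(default_factory=dict)
    alpha_floor: float = 0.6

    def to_dict(self) -> dict:
        return {
            "alpha_floor": self.alpha_floor,
            "pooled_alpha": {k: round(v, 6) for k, v in self.pooled_alpha.items()},
            "acceptable": dict(self.acceptable),
            "alpha_by_list": {
                v: {l: round(a, 6) for l, a in per.items()}
                for v, per in self.alpha_by_list.items()
            },
        }


def cronbach_alpha(matrix: pd.DataFrame | np.ndarray) -> float:
    """Cronbach's alpha for a complete words x raters response block.

    alpha = k/(k−1) · (1 − Σᵢ s²ᵢ / s²_total) with k raters, s²ᵢ the
    variance of rater i across words and s²_total the variance of per-word
    sums (sample variances, n−1). Returns NaN with a warning when the
    per-word sums have zero variance; missing cells are an error (compute
    per list instead).
    """
    mat = np.asarray(matrix, dtype=float)
    if mat.ndim != 2 or mat.shape[0] < 2 or mat.shape[1] < 2:
        raise ValueError("need a 2-D block with >=2 words and >=2 raters")
    if np.isnan(mat).any():
        raise ValueError(
            "matrix has missing cells; alpha requires a complete block — "
            "compute within each list")
    k = mat.shape[1]
    item_vars = mat.var(axis=0, ddof=1)
    total_var = mat.sum(axis=1).var(ddof=1)
    if total_var == 0:
        warnings.warn("zero variance of per-word sums; alpha undefined")
        return float("nan")
    return float(k / (k - 1) * (1.0 - item_vars.sum() / total_var))


def reliability_report(records, alpha_floor: float = 0.6,
                       registry: Optional[Sequence[VariableSpec]] = None
                       ) -> ReliabilityReport:
    """Alpha per variable, computed within lists and pooled.

    Within each list x variable the word x rater block is pivoted; raters
    with missing cells in that block (e.g. responses lost to trimming) are
    dropped from it. Lists left with fewer than 2 raters or 2 words are
    skipped with a warning. The pooled alpha is the unweighted mean of the
    per-list alphas; acceptability compares it to ``alpha_floor`` (strict).
    """
    if registry is None:
        registry = default_registry()
    frame = records_to_frame(records)
    report = ReliabilityReport(alpha_floor=alpha_floor)
    for var in (s.name for s in registry):
        sub = frame[frame["variable"] == var]
        per_list: dict[str, float] = {}
        for list_id, grp in sub.groupby("list_id", sort=True):
            block = grp.pivot(index="word", columns="rater_id", values="value")
            block = block.dropna(axis=1)  # raters with holes in this block
            if block.shape[1] < 2 or block.shape[0] < 2:
                warnings.warn(
                    f"list {list_id}, variable {var}: fewer than 2 complete "
                    f"raters/words; skipped")
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                a = cronbach_alpha(block)
            if np.isfinite(a):
                per_list[str(list_id)] = a
        if not per_list:
            warnings.warn(f"variable {var}: no list yielded an alpha")
            pooled = float("nan")
        else:
            pooled = float(np.mean(list(per_list.values())))
        report.alpha_by_list[var] = per_list
        report.pooled_alpha[var] = pooled
        report.acceptable[var] = bool(np.isfinite(pooled) and pooled > alpha_floor)
        logger.info("variable %s pooled alpha %.3f (%d lists)",
                    var, pooled, len(per_list))
    return report
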