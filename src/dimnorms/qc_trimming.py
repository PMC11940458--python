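"""Two-stage data cleaning: rater exclusion, then 3-SD response trimming.

Stage 1 removes raters who gave (near-)constant responses — one Likert
value accounting for strictly more than 85% of all their Likert responses
pooled across variables — and raters who did not complete their lists.
Stage 2 sweeps every word x variable cell once and removes responses more
than 3 sample SDs from the cell mean. Both thresholds are configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .ratings_io import records_to_frame
from .variables import VariableSpec, default_registry, registry_by_name

__all__ = [
    "QCReport",
    "flag_careless",
    "flag_incomplete",
    "trim_responses",
    "drop_raters",
    "expected_counts_from_lists",
]

logger = logging.getLogger(__name__)


@dataclass
class QCReport:
    """What the cleaning removed and why."""

    excluded_raters: list[tuple[str, str]] = field(default_factory=list)
    removed_responses: list[tuple[str, str, str]] = field(default_factory=list)
    pct_removed_by_variable: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "excluded_raters": [list(t) for t in self.excluded_raters],
            "n_removed_responses": len(self.removed_responses),
            "removed_responses": [list(t) for t in self.removed_responses],
            "pct_removed_by_variable": dict(self.pct_removed_by_variable),
        }


def flag_careless(records, threshold: float = 0.85,
                  registry: Optional[Sequence[VariableSpec]] = None
                  ) -> frozenset[str]:
    """Raters whose modal Likert response exceeds ``threshold`` of their
    responses (strict inequality; AoA excluded from the pool).

    A rater with zero Likert responses cannot be judged careless and is
    left to the completeness check.
    """
    if registry is None:
        registry = default_registry()
    by_name = registry_by_name(registry)
    frame = records_to_frame(records)
    likert = frame[frame["variable"].map(lambda v: by_name[v].is_likert)]
    flagged = []
    for rater, grp in likert.groupby("rater_id", sort=True):
        share = grp["value"].value_counts(normalize=True).iloc[0]
        if share > threshold:
            flagged.append(str(rater))
            logger.info("rater %s flagged careless (modal share %.3f)", rater, share)
    return frozenset(flagged)


def expected_counts_from_lists(records,
                               registry: Optional[Sequence[VariableSpec]] = None
                               ) -> dict[str, int]:
    """Expected responses per rater from the observed list design:
    (words in the rater's lists) x (number of variables)."""
    if registry is None:
        registry = default_registry()
    frame = records_to_frame(records)
    n_vars = len(list(registry))
    words_per_list = frame.groupby("list_id")["word"].nunique()
    rater_lists = frame.groupby("rater_id")["list_id"].unique()
    return {
        str(r): int(sum(words_per_list[l] for l in lists) * n_vars)
        for r, lists in rater_lists.items()
    }


def flag_incomplete(records, expected_counts: Mapping[str, int],
                    completeness_fraction: float = 1.0) -> frozenset[str]:
    """Raters with fewer than ``completeness_fraction`` of their expected
    responses. Raters expected but absent from the records are flagged."""
    frame = records_to_frame(records)
    observed = frame.groupby("rater_id").size()
    flagged = []
    for rater, expected in expected_counts.items():
        got = int(observed.get(rater, 0))
        if got < completeness_fraction * expected:
            flagged.append(str(rater))
            logger.info("rater %s flagged incomplete (%d/%d responses)",
                        rater, got, expected)
    return frozenset(flagged)


def drop_raters(records, rater_ids) -> pd.DataFrame:
    frame = records_to_frame(records)
    return frame[~frame["rater_id"].isin(set(rater_ids))].reset_index(drop=True)


def trim_responses(records, trim_sd: float = 3.0,
                   leave_one_out: bool = False,
                   registry: Optional[Sequence[VariableSpec]] = None
                   ) -> tuple[pd.DataFrame, QCReport]:
    """Single-pass 3-SD trimming per word x variable cell.

    A response is removed when |value − cell mean| > trim_sd × cell SD,
    with mean and SD (sample SD, n−1) computed once over the whole cell,
    candidate included. ``leave_one_out`` recomputes mean/SD excluding the
    candidate instead. Cells with zero SD lose nothing; a rule that would
    empty a cell raises (cannot occur for the inclusive variant).
    """
    frame = records_to_frame(records).reset_index(drop=True)
    grp = frame.groupby(["word", "variable"])["value"]
    n = grp.transform("count")
    if leave_one_out:
        s = grp.transform("sum")
        ss = frame["value"].pow(2).groupby(
            [frame["word"], frame["variable"]]).transform("sum")
        n1 = n - 1
        mean = (s - frame["value"]) / n1.where(n1 > 0)
        var = ((ss - frame["value"] ** 2) - n1 * mean**2) / (n1 - 1).where(n1 > 1)
        sd = np.sqrt(var.clip(lower=0.0))
        dev = (frame["value"] - mean).abs()
        # a candidate deviating from a zero-variance remainder is an outlier
        remove = (dev > trim_sd * sd) & sd.notna() & (n >= 3)
    else:
        mean = grp.transform("mean")
        sd = grp.transform("std")  # ddof=1; NaN for singleton cells
        dev = (frame["value"] - mean).abs()
        remove = (dev > trim_sd * sd) & sd.gt(0).fillna(False) & (n >= 2)

    removed_per_cell = remove.groupby([frame["word"], frame["variable"]]).sum()
    cell_sizes = frame.groupby(["word", "variable"])["value"].size()
    emptied = removed_per_cell[removed_per_cell >= cell_sizes]
    if len(emptied):
        raise ValueError(
            f"trimming would empty {len(emptied)} word x variable cells, "
            f"e.g. {emptied.index[0]}")

    removed = frame[remove]
    kept = frame[~remove].reset_index(drop=True)
    total_by_var = frame.groupby("variable").size()
    removed_by_var = removed.groupby("variable").size()
    pct = {
        str(var): float(100.0 * removed_by_var.get(var, 0) / total)
        for var, total in total_by_var.items()
    }
    report = QCReport(
        removed_responses=[
            (str(r), str(w), str(v))
            for r, w, v in removed[["rater_id", "word", "variable"]]
            .itertuples(index=False)
        ],
        pct_removed_by_variable=pct,
    )
    for r, w, v in report.removed_responses:
        logger.info("trimmed response rater=%s word=%s variable=%s", r, w, v)
    return kept, report
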