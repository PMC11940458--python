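"""Word-level norms: aggregation, concreteness comparison, correlations.

Aggregation turns trimmed rater-level records into the wide norms table
(mean, sample SD, n per word x variable). The concreteness comparison
contrasts concrete fillers with abstract words on CNC and IMG (Welch
t-test; the groups' variances differ strongly since concrete words sit
near the scale ceiling) and counts abstract words falling inside the
concrete group's observed CNC range. The correlation matrix gives
pairwise Pearson r and p over word-level means for all 15 variables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ratings_io import records_to_frame
from .variables import ItemMeta, VariableSpec, default_registry

__all__ = [
    "ConcretenessComparison",
    "aggregate",
    "concreteness_comparison",
    "correlation_matrix",
]


@dataclass(frozen=True)
class ConcretenessComparison:
    """Concrete vs abstract group contrast on CNC and IMG word means."""

    concrete_mean: dict[str, float]
    abstract_mean: dict[str, float]
    concrete_range: dict[str, tuple[float, float]]
    abstract_range: dict[str, tuple[float, float]]
    t_statistic: dict[str, float]
    p_value: dict[str, float]
    n_abstract_in_concrete_range: int
    range_split: dict[str, dict[str, int]]
    pct_above_6: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "concrete_mean": self.concrete_mean,
            "abstract_mean": self.abstract_mean,
            "concrete_range": {k: list(v) for k, v in self.concrete_range.items()},
            "abstract_range": {k: list(v) for k, v in self.abstract_range.items()},
            "welch_t": self.t_statistic,
            "p_value": self.p_value,
            "n_abstract_in_concrete_range": self.n_abstract_in_concrete_range,
            "range_split": self.range_split,
            "pct_above_6": self.pct_above_6,
        }


def aggregate(records, meta: Optional[Sequence[ItemMeta]] = None,
              registry: Optional[Sequence[VariableSpec]] = None,
              min_n_warn: int = 20) -> pd.DataFrame:
    """Aggregate trimmed records into the wide norms table.

    One row per word; columns ``<VAR>_mean``, ``<VAR>_sd`` (sample SD,
    NaN for n = 1), ``<VAR>_n`` and ``is_abstract``. Warns when any cell
    has fewer than ``min_n_warn`` responses; a word missing a registry
    variable entirely is an error.
    """
    if registry is None:
        registry = default_registry()
    frame = records_to_frame(records)
    if frame.empty:
        raise ValueError("no records to aggregate")
    agg = (frame.groupby(["word", "variable"])["value"]
           .agg(["mean", "std", "count"]))
    wide = agg.unstack("variable")
    var_names = [s.name for s in registry]
    missing_vars = [v for v in var_names if v not in wide["mean"].columns]
    if missing_vars:
        raise ValueError(f"no responses at all for variables: {missing_vars}")
    counts = wide["count"]
    holes = counts[var_names].isna()
    if holes.any().any():
        bad_word = holes.any(axis=1).idxmax()
        bad_var = holes.loc[bad_word].idxmax()
        raise ValueError(
            f"word {bad_word!r} has zero responses on required variable "
            f"{bad_var!r}")
    low = counts[var_names] < min_n_warn
    if low.any().any():
        warnings.warn(
            f"{int(low.sum().sum())} word x variable cells have fewer than "
            f"{min_n_warn} responses")
    out = pd.DataFrame(index=wide.index)
    for var in var_names:
        out[f"{var}_mean"] = wide["mean"][var]
        out[f"{var}_sd"] = wide["std"][var]
        out[f"{var}_n"] = wide["count"][var].astype(int)
    if meta is not None:
        flags = {m.word: m.is_abstract for m in meta}
        unknown = [w for w in out.index if w not in flags]
        if unknown:
            raise ValueError(f"words missing from metadata: {unknown[:5]}")
        out.insert(0, "is_abstract", [flags[w] for w in out.index])
    out.index.name = "word"
    return out.sort_index()


def concreteness_comparison(norms: pd.DataFrame,
                            split_at: float = 6.0) -> ConcretenessComparison:
    """Concrete vs abstract contrast on CNC and IMG.

    Welch's two-sample t-test on word-level means; the count of abstract
    words whose CNC mean falls inside the closed interval spanned by the
    concrete group's CNC means; the concrete range split at ``split_at``
    with per-group counts in each part; and the percentage of each group
    with CNC mean above 6.
    """
    if "is_abstract" not in norms.columns:
        raise ValueError("norms table lacks is_abstract flags")
    concrete = norms[~norms["is_abstract"]]
    abstract = norms[norms["is_abstract"]]
    if concrete.empty or abstract.empty:
        raise ValueError("both a concrete and an abstract group are required")

    mean_c, mean_a, range_c, range_a, tstat, pval = {}, {}, {}, {}, {}, {}
    for var in ("CNC", "IMG"):
        col = f"{var}_mean"
        c, a = concrete[col].to_numpy(), abstract[col].to_numpy()
        mean_c[var] = float(c.mean())
        mean_a[var] = float(a.mean())
        range_c[var] = (float(c.min()), float(c.max()))
        range_a[var] = (float(a.min()), float(a.max()))
        if np.array_equal(np.sort(c), np.sort(a)):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(c, a, equal_var=False)
        tstat[var], pval[var] = float(t), float(p)

    cmin, cmax = range_c["CNC"]
    cnc_a = abstract["CNC_mean"]
    cnc_c = concrete["CNC_mean"]
    in_range = cnc_a.between(cmin, cmax)  # closed interval
    split = {
        "lower": {  # [cmin, split_at)
            "concrete": int(((cnc_c >= cmin) & (cnc_c < split_at)).sum()),
            "abstract": int((in_range & (cnc_a < split_at)).sum()),
        },
        "upper": {  # [split_at, cmax]
            "concrete": int(((cnc_c >= split_at) & (cnc_c <= cmax)).sum()),
            "abstract": int((in_range & (cnc_a >= split_at)).sum()),
        },
    }
    pct6 = {
        "concrete": float(100.0 * (cnc_c > 6.0).mean()),
        "abstract": float(100.0 * (cnc_a > 6.0).mean()),
    }
    return ConcretenessComparison(
        concrete_mean=mean_c, abstract_mean=mean_a,
        concrete_range=range_c, abstract_range=range_a,
        t_statistic=tstat, p_value=pval,
        n_abstract_in_concrete_range=int(in_range.sum()),
        range_split=split, pct_above_6=pct6,
    )


def correlation_matrix(norms: pd.DataFrame,
                       words_subset: Optional[Sequence[str]] = None,
                       registry: Optional[Sequence[VariableSpec]] = None
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations over word-level means.

    Returns (r, p) frames over all registry variables, symmetric with a
    unit diagonal. A zero-variance variable yields NaN for its off-diagonal
    pairs, with a warning.
    """
    if registry is None:
        registry = default_registry()
    var_names = [s.name for s in registry]
    data = norms.loc[words_subset] if words_subset is not None else norms
    cols = [f"{v}_mean" for v in var_names]
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise ValueError(f"norms table missing mean columns: {missing}")
    mat = data[cols].to_numpy(dtype=float)
    if mat.shape[0] < 3:
        raise ValueError("need at least 3 words for a correlation matrix")
    k = len(var_names)
    r = np.eye(k)
    p = np.zeros((k, k))
    sds = mat.std(axis=0)
    for i in range(k):
        for j in range(i + 1, k):
            if sds[i] == 0 or sds[j] == 0:
                warnings.warn(
                    f"zero variance in {var_names[i] if sds[i] == 0 else var_names[j]}; "
                    f"correlation undefined")
                r[i, j] = r[j, i] = np.nan
                p[i, j] = p[j, i] = np.nan
                continue
            rij, pij = stats.pearsonr(mat[:, i], mat[:, j])
            r[i, j] = r[j, i] = rij
            p[i, j] = p[j, i] = pij
    r_df = pd.DataFrame(r, index=var_names, columns=var_names)
    p_df = pd.DataFrame(p, index=var_names, columns=var_names)
    return r_df, p_df
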