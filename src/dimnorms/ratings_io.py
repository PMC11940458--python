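"""On-disk formats: raw ratings CSV, norms TSV, labels TSV, run config.

Raw ratings travel long (tidy): one row per rater x word x variable, the
shape in which list-based rating studies are collected. Norms travel wide:
one row per word with <VAR>_mean, <VAR>_sd, <VAR>_n columns, the shape in
which norm databases are distributed. All writers are deterministic.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .variables import VariableSpec, default_registry, registry_by_name

__all__ = [
    "RatingRecord",
    "Config",
    "read_ratings",
    "write_ratings",
    "records_to_frame",
    "frame_to_records",
    "read_norms",
    "write_norms",
    "write_labels",
    "load_config",
]

RATINGS_COLUMNS = ("rater_id", "list_id", "word", "variable", "value")


class RatingRecord(NamedTuple):
    """One rater's response to one word on one variable."""

    rater_id: str
    list_id: str
    word: str
    variable: str
    value: float


@dataclass(frozen=True)
class Config:
    """Analysis thresholds; defaults are the study's stated values.

    careless_threshold: a rater is dropped when one response value exceeds
        this share of their Likert responses (strictly more than 85%).
    trim_sd: responses farther than this many SDs from the item mean are
        removed (3 SD, single pass).
    representative_threshold: a word represents a dimension when its mean
        exceeds this value (strictly more than 3.5).
    level_percentiles: E percentile cutoffs for low/medium/high (25, 75).
    alpha_floor: Cronbach's alpha above this is acceptable (0.6).
    """

    careless_threshold: float = 0.85
    completeness_fraction: float = 1.0
    trim_sd: float = 3.0
    trim_leave_one_out: bool = False
    representative_threshold: float = 3.5
    level_percentiles: tuple[float, float] = (25.0, 75.0)
    percentile_method: str = "linear"
    alpha_floor: float = 0.6
    round_norms_decimals: Optional[int] = None
    decimal: str = "."
    seed: int = 0
    aliases: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("careless_threshold", "completeness_fraction"):
            v = getattr(self, name)
            if not isinstance(v, (int, float)) or not 0 <= v <= 1:
                raise ValueError(f"{name} must be a number in [0, 1]")
        if not isinstance(self.trim_sd, (int, float)) or self.trim_sd <= 0:
            raise ValueError("trim_sd must be a positive number")
        if not isinstance(self.representative_threshold, (int, float)):
            raise ValueError("representative_threshold must be numeric")
        lo, hi = self.level_percentiles
        if not (0 <= lo <= hi <= 100):
            raise ValueError("level_percentiles must satisfy 0 <= lo <= hi <= 100")
        if self.percentile_method not in ("linear", "spss"):
            raise ValueError("percentile_method must be 'linear' or 'spss'")


def records_to_frame(records: Sequence[RatingRecord] | pd.DataFrame) -> pd.DataFrame:
    """Coerce a record list (or an already-tidy frame) to the tidy frame."""
    if isinstance(records, pd.DataFrame):
        missing = [c for c in RATINGS_COLUMNS if c not in records.columns]
        if missing:
            raise ValueError(f"ratings frame missing columns: {missing}")
        return records
    return pd.DataFrame.from_records(records, columns=RATINGS_COLUMNS)


def frame_to_records(frame: pd.DataFrame) -> list[RatingRecord]:
    return [RatingRecord(str(r), str(l), str(w), str(v), float(x))
            for r, l, w, v, x in frame[list(RATINGS_COLUMNS)].itertuples(index=False)]


def read_ratings(path, registry: Optional[Sequence[VariableSpec]] = None,
                 decimal: str = ".") -> list[RatingRecord]:
    """Read and validate a long-format ratings CSV.

    Rejects unknown variables, out-of-range values (naming the rater and
    word) and malformed rows (naming the line number). Duplicate
    (rater, word, variable) triples are an error.
    """
    if registry is None:
        registry = default_registry()
    by_name = registry_by_name(registry)
    records: list[RatingRecord] = []
    seen: set[tuple[str, str, str]] = set()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header] != list(RATINGS_COLUMNS):
            raise ValueError(
                f"{path}: expected header {','.join(RATINGS_COLUMNS)}, got {header}")
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != 5:
                raise ValueError(f"{path}:{lineno}: malformed row ({len(row)} fields)")
            rater, list_id, word, variable, raw = (c.strip() for c in row)
            if variable not in by_name:
                raise ValueError(f"{path}:{lineno}: unknown variable {variable!r}")
            try:
                value = float(raw.replace(decimal, ".") if decimal != "." else raw)
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric value {raw!r}") from None
            spec = by_name[variable]
            if not spec.in_bounds(value):
                raise ValueError(
                    f"{path}:{lineno}: value {value} for {variable} out of range "
                    f"(rater {rater}, word {word})")
            key = (rater, word, variable)
            if key in seen:
                raise ValueError(
                    f"{path}:{lineno}: duplicate response (rater {rater}, "
                    f"word {word}, variable {variable})")
            seen.add(key)
            records.append(RatingRecord(rater, list_id, word, variable, value))
    return records


def write_ratings(records: Sequence[RatingRecord] | pd.DataFrame, path) -> None:
    """Write the long-format ratings CSV (deterministic, UTF-8)."""
    frame = records_to_frame(records)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(RATINGS_COLUMNS)
        for r, l, w, v, x in frame[list(RATINGS_COLUMNS)].itertuples(index=False):
            writer.writerow([r, l, w, v, f"{float(x):g}"])


def _norms_columns(variables: Sequence[str]) -> list[str]:
    cols = []
    for var in variables:
        cols.extend([f"{var}_mean", f"{var}_sd", f"{var}_n"])
    return cols


def write_norms(norms: pd.DataFrame, path,
                registry: Optional[Sequence[VariableSpec]] = None) -> None:
    """Write a wide norms table to TSV, one row per word.

    Expects a frame indexed by word with <VAR>_mean/_sd/_n columns and an
    is_abstract column; floats printed with 6 decimals (round-trip stable).
    """
    if registry is None:
        registry = default_registry()
    var_names = [s.name for s in registry]
    cols = ["is_abstract"] + [c for c in _norms_columns(var_names)
                              if c in norms.columns]
    missing = [c for c in cols if c not in norms.columns]
    if missing:
        raise ValueError(f"norms table missing columns: {missing}")
    out = norms[cols].sort_index()
    out.to_csv(path, sep="\t", index=True, index_label="word",
               float_format="%.6f", lineterminator="\n")


def read_norms(path, registry: Optional[Sequence[VariableSpec]] = None,
               column_map: Optional[dict[str, str]] = None,
               decimal: str = ".") -> pd.DataFrame:
    """Read a norms TSV back into the wide frame.

    ``column_map`` renames external column names to the canonical
    ``<VAR>_mean``/``_sd``/``_n`` scheme before validation, so deposited
    norms with different headers can be ingested. Missing mean columns
    for registry variables are an error; missing _sd/_n are tolerated.
    """
    if registry is None:
        registry = default_registry()
    frame = pd.read_csv(path, sep="\t", index_col="word", decimal=decimal)
    if column_map:
        frame = frame.rename(columns=column_map)
    required = [f"{s.name}_mean" for s in registry]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required norm columns: {missing}")
    if "is_abstract" not in frame.columns:
        raise ValueError(f"{path}: missing required column is_abstract")
    frame["is_abstract"] = frame["is_abstract"].astype(bool)
    return frame


def write_labels(labels_frame: pd.DataFrame, path) -> None:
    """Write the word/E/level/dimension-set table (dims pipe-joined)."""
    out = labels_frame.sort_index()
    out.to_csv(path, sep="\t", index=True, index_label="word",
               float_format="%.6f", lineterminator="\n")


_CONFIG_KEYS = {f.name for f in dc_fields(Config)}


def load_config(path) -> Config:
    """Load analysis thresholds from a YAML or JSON file.

    An empty file yields all defaults. Unknown keys warn and are ignored;
    invalid threshold types raise.
    """
    text = Path(path).read_text(encoding="utf-8")
    data = yaml.safe_load(text) if text.strip() else {}
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    unknown = sorted(set(data) - _CONFIG_KEYS)
    if unknown:
        warnings.warn(f"{path}: ignoring unknown config keys: {unknown}")
    kwargs = {k: v for k, v in data.items() if k in _CONFIG_KEYS}
    if "level_percentiles" in kwargs:
        lp = kwargs["level_percentiles"]
        if not (isinstance(lp, (list, tuple)) and len(lp) == 2):
            raise ValueError("level_percentiles must be a pair")
        kwargs["level_percentiles"] = (float(lp[0]), float(lp[1]))
    return Config(**kwargs)
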