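"""End-to-end orchestration: qc -> reliability -> norms -> exclusivity ->
classification -> co-occurrence network, plus a reproduction mode that
starts from an already-aggregated norms table.

Every stage is a pure function of its inputs plus the config; a fixed
seed makes the simulated run fully deterministic. The run report collects
the quantities a reader of the study would check first: exclusion counts,
pooled alphas, E cutoffs and level counts, per-dimension word counts, the
largest intersections, the 2-cluster partition and the E-SEM_DIV
validity correlation.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from . import __version__ as _version
from .classification import (DimensionLabelSet, crosstab_by_level,
                             dimension_counts, intersection_table,
                             representative_labels)
from .conetwork import bipartite_edges, cluster_dimensions, cooccurrence
from .exclusivity import (assign_levels, exclusivity_scores,
                          validity_correlation)
from .norms import aggregate, concreteness_comparison, correlation_matrix
from .qc_trimming import (drop_raters, expected_counts_from_lists,
                          flag_careless, flag_incomplete, trim_responses)
from .ratings_io import (Config, read_norms, read_ratings, records_to_frame,
                         write_labels, write_norms, write_ratings)
from .reliability import reliability_report
from .synthetic_ratings import GeneratorConfig, generate_dataset
from .variables import ItemMeta, SEMANTIC_DIMENSIONS, default_registry

__all__ = ["run_pipeline", "reproduce", "analyze_norms"]

logger = logging.getLogger(__name__)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


class StageError(RuntimeError):
    """An analysis stage failed; carries the stage name for context."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def analyze_norms(norms: pd.DataFrame, config: Optional[Config] = None,
                  with_comparison: bool = True) -> dict:
    """Norms-level analyses shared by the full run and the reproduce mode.

    Computes E over the abstract words, percentile levels, the validity
    correlation with semantic diversity, representative labels,
    per-dimension counts, the intersection table (global and by level),
    the co-occurrence network and its 2-cluster partition, and (optionally)
    the concreteness comparison. Returns everything in one dict, with
    non-serialisable objects (labels, tables, network) under ``objects``.
    """
    cfg = config or Config()
    abstract = norms[norms["is_abstract"]]
    if abstract.empty:
        raise ValueError("no abstract words in norms table")
    dim_means = abstract[[f"{d}_mean" for d in SEMANTIC_DIMENSIONS]].rename(
        columns=lambda c: c[:-5])
    if cfg.round_norms_decimals is not None:
        dim_means = dim_means.round(cfg.round_norms_decimals)
    E = exclusivity_scores(dim_means)
    cutoffs, levels = assign_levels(
        E, percentiles=cfg.level_percentiles, method=cfg.percentile_method)
    r, p = validity_correlation(E, abstract["SEM_DIV_mean"])

    labelled_norms = dim_means.add_suffix("_mean")
    labels = representative_labels(labelled_norms,
                                   threshold=cfg.representative_threshold)
    counts = dimension_counts(labels)
    table = intersection_table(labels)
    tables_by_level, cardinality_hist = crosstab_by_level(
        labels, levels.to_dict())
    net = cooccurrence(labels)
    clusters = cluster_dimensions(net, k=2)

    report = {
        "n_words": int(len(norms)),
        "n_abstract": int(len(abstract)),
        "exclusivity": {
            "min": float(E.min()),
            "max": float(E.max()),
            "mean": float(E.mean()),
            "sd": float(E.std(ddof=1)),
            "word_max_E": str(E.idxmax()),
            "word_min_E": str(E.idxmin()),
            "cutoffs": {"p25": cutoffs.p25, "p75": cutoffs.p75,
                        "method": cutoffs.method},
            "level_counts": {lvl: int((levels == lvl).sum())
                             for lvl in ("low", "medium", "high")},
        },
        "validity_correlation": {"r": r, "p": p},
        "dimension_counts": counts,
        "n_representative": int(table.n_words - table.n_unlabelled),
        "n_unlabelled": int(table.n_unlabelled),
        "pct_single_dimension": float(
            100.0 * sum(c for combo, c in table.rows if len(combo) == 1)
            / max(1, table.n_words - table.n_unlabelled)),
        "top_intersections": [
            {"combination": "|".join(combo), "count": int(c)}
            for combo, c in table.rows[:10]
        ],
        "clusters": [list(part) for part in clusters],
        "objects": {
            "E": E, "levels": levels, "labels": labels, "table": table,
            "tables_by_level": tables_by_level,
            "cardinality_hist": cardinality_hist, "network": net,
        },
    }
    has_both_groups = norms["is_abstract"].nunique() == 2
    if with_comparison and has_both_groups:
        report["concreteness_comparison"] = concreteness_comparison(
            norms).to_dict()
    return report


def _write_outputs(out_dir: Path, norms: pd.DataFrame, analysis: dict,
                   report: dict) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    objs = analysis["objects"]
    write_norms(norms, out_dir / "norms.tsv")
    labels_frame = pd.DataFrame({
        "E": objs["E"],
        "level": objs["levels"],
        "dims": ["|".join(d for d in SEMANTIC_DIMENSIONS if d in lab.dims)
                 for lab in objs["labels"]],
    }, index=objs["E"].index)
    write_labels(labels_frame, out_dir / "labels.tsv")
    objs["table"].to_frame().to_csv(
        out_dir / "intersections.tsv", sep="\t", index=False,
        lineterminator="\n")
    net = objs["network"]
    edges = pd.DataFrame(
        [{"dim_a": a, "dim_b": b, "shared": s,
          "jaccard": round(net.jaccard[(a, b)], 6)}
         for (a, b), s in sorted(net.shared.items())])
    edges.to_csv(out_dir / "network_edges.tsv", sep="\t", index=False,
                 lineterminator="\n")
    nx.write_graphml(net.to_graph(), out_dir / "network.graphml")
    with open(out_dir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(_jsonable(report), fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_pipeline(ratings=None, meta: Optional[Sequence[ItemMeta]] = None,
                 simulate: Optional[GeneratorConfig] = None,
                 config: Optional[Config] = None,
                 out_dir=None) -> dict:
    """Run the full rater-level analysis.

    Input is either ``ratings`` (a path to the long CSV, a tidy frame or a
    record list) plus ``meta`` with abstract/concrete flags, or
    ``simulate`` (a generator config) to run on synthetic data. Stages:
    careless/incomplete rater exclusion, 3-SD trimming, per-list
    reliability, aggregation, exclusivity and levels, representative
    labels, intersections, co-occurrence clustering. Writes norms TSV,
    labels TSV, intersections TSV, network exports and report JSON when
    ``out_dir`` is given; returns the report dict (with an ``objects``
    entry holding in-memory results).
    """
    cfg = config or Config()
    registry = default_registry()
    if (ratings is None) == (simulate is None):
        raise ValueError("provide exactly one of ratings or simulate")

    stage = "input"
    try:
        if simulate is not None:
            frame, meta, _truth = generate_dataset(simulate, registry)
        else:
            if isinstance(ratings, (str, Path)):
                frame = records_to_frame(read_ratings(ratings, registry,
                                                      decimal=cfg.decimal))
            else:
                frame = records_to_frame(ratings)
            if meta is None:
                raise ValueError("meta with is_abstract flags is required")
        n_raters_in = frame["rater_id"].nunique()

        stage = "qc_raters"
        careless = flag_careless(frame, cfg.careless_threshold, registry)
        expected = expected_counts_from_lists(frame, registry)
        incomplete = flag_incomplete(frame, expected, cfg.completeness_fraction)
        incomplete -= careless
        frame = drop_raters(frame, careless | incomplete)

        stage = "qc_trim"
        frame, qc_report = trim_responses(
            frame, trim_sd=cfg.trim_sd,
            leave_one_out=cfg.trim_leave_one_out, registry=registry)
        qc_report.excluded_raters = (
            [(r, "careless") for r in sorted(careless)]
            + [(r, "incomplete") for r in sorted(incomplete)])

        stage = "reliability"
        rel = reliability_report(frame, alpha_floor=cfg.alpha_floor,
                                 registry=registry)

        stage = "aggregate"
        norms = aggregate(frame, meta=meta, registry=registry)

        stage = "norms_analysis"
        analysis = analyze_norms(norms, cfg)
    except (ValueError, KeyError) as exc:
        raise StageError(stage, exc) from exc

    report = {k: v for k, v in analysis.items() if k != "objects"}
    report.update({
        "version": _version,
        "seed": simulate.seed if simulate is not None else cfg.seed,
        "config": {
            "careless_threshold": cfg.careless_threshold,
            "trim_sd": cfg.trim_sd,
            "representative_threshold": cfg.representative_threshold,
            "level_percentiles": list(cfg.level_percentiles),
            "percentile_method": cfg.percentile_method,
            "alpha_floor": cfg.alpha_floor,
        },
        "qc": {
            "n_raters_input": int(n_raters_in),
            "n_excluded_careless": len(careless),
            "n_excluded_incomplete": len(incomplete),
            "n_trimmed_responses": len(qc_report.removed_responses),
            "pct_removed_by_variable": qc_report.pct_removed_by_variable,
            "max_pct_removed": max(qc_report.pct_removed_by_variable.values(),
                                   default=0.0),
        },
        "reliability": rel.to_dict(),
    })
    report["objects"] = {**analysis["objects"], "norms": norms,
                         "qc_report": qc_report, "reliability": rel}
    if out_dir is not None:
        clean = {k: v for k, v in report.items() if k != "objects"}
        _write_outputs(Path(out_dir), norms, analysis, clean)
    return report


#: The study's printed values, for the side-by-side table the reproduce
#: mode prints next to its own recomputed numbers.
PUBLISHED = {
    "E_min": 5.52, "E_max": 35.76, "p25": 15.24, "p75": 20.29,
    "level_counts": {"low": 202, "medium": 404, "high": 201},
    "validity_r": -0.47,
    "dimension_counts": {"THEOR": 272, "ECO": 233, "QUANT": 245,
                         "SPACE": 135, "INTRO": 417, "MENT_ST": 420,
                         "SOC": 462, "MOR": 321},
    "n_representative": 802, "n_unlabelled": 5,
    "abstract_CNC_mean": 3.02,
    "n_abstract_in_concrete_range": 117,
    "clusters": [["INTRO", "MENT_ST", "SOC", "MOR"],
                 ["QUANT", "SPACE", "THEOR", "ECO"]],
}


def reproduce(norms_path, column_map: Optional[Mapping[str, str]] = None,
              config: Optional[Config] = None, out_dir=None,
              published: Optional[dict] = None) -> dict:
    """Reproduction mode: run the norms-level analyses on a deposited
    word x variable norms table, skipping the rater-level stages.

    ``column_map`` renames the deposit's columns to the canonical
    ``<VAR>_mean`` scheme. Both percentile conventions are computed so the
    one matching the printed cutoffs can be identified. The report gains a
    ``comparison`` block putting recomputed values next to the published
    ones.
    """
    cfg = config or Config()
    norms = read_norms(norms_path, column_map=dict(column_map or {}),
                       decimal=cfg.decimal)
    analysis = analyze_norms(norms, cfg)
    E = analysis["objects"]["E"]
    both = {}
    for method in ("linear", "spss"):
        c, _ = assign_levels(E, percentiles=cfg.level_percentiles,
                             method=method)
        both[method] = {"p25": c.p25, "p75": c.p75}
    report = {k: v for k, v in analysis.items() if k != "objects"}
    report["cutoffs_by_method"] = both
    pub = PUBLISHED if published is None else published
    report["comparison"] = {
        "E_min": {"ours": report["exclusivity"]["min"], "published": pub["E_min"]},
        "E_max": {"ours": report["exclusivity"]["max"], "published": pub["E_max"]},
        "p25": {"ours": report["exclusivity"]["cutoffs"]["p25"],
                "published": pub["p25"]},
        "p75": {"ours": report["exclusivity"]["cutoffs"]["p75"],
                "published": pub["p75"]},
        "validity_r": {"ours": report["validity_correlation"]["r"],
                       "published": pub["validity_r"]},
        "n_representative": {"ours": report["n_representative"],
                             "published": pub["n_representative"]},
        "clusters": {"ours": report["clusters"], "published": pub["clusters"]},
    }
    report["version"] = _version
    report["objects"] = analysis["objects"]
    if out_dir is not None:
        clean = {k: v for k, v in report.items() if k != "objects"}
        _write_outputs(Path(out_dir), norms, analysis, clean)
    return report
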