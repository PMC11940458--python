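"""Synthetic rater-level data with the structure the analysis assumes.

Emulates the norming study's design: 964 Italian nouns (807 abstract, 157
concrete fillers) split into 24 lists, each rater assigned a pair of lists
and rating every variable for the words on them, so that every word is
rated by >= 20 raters. Each abstract word has 1-8 "relevant" semantic
dimensions with high latent means; the remaining dimensions sit in the
low, irrelevant band. Latent semantic diversity is coupled negatively to
latent exclusivity so the pipeline's validity correlation has a known
population value. Careless (constant-response) raters and rare extreme
outlier responses can be injected, with ground truth returned for
recovery tests.

All randomness flows from ``GeneratorConfig.seed``; every function here is
deterministic given the config.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .exclusivity import exclusivity_score
from .variables import (
    SEMANTIC_DIMENSIONS,
    ItemMeta,
    VariableSpec,
    default_registry,
    registry_by_name,
)

__all__ = [
    "GeneratorConfig",
    "LatentProfile",
    "make_profiles",
    "simulate_ratings",
    "inject_careless",
    "inject_outliers",
    "generate_dataset",
    "GroundTruth",
    "write_ground_truth",
]

#: Default distribution of the number of relevant dimensions per abstract
#: word (1..8). Chosen to mirror a norming sample where single-dimension
#: words are a small minority (~9%) and most words recruit 2-5 dimensions.
DEFAULT_DIM_COUNT_PMF: tuple[float, ...] = (
    0.09, 0.17, 0.21, 0.24, 0.15, 0.08, 0.04, 0.02
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic study; defaults reproduce the study design.

    ``noise_sd`` is the within-rater response noise in rating-scale units;
    rater-level offsets are drawn with SD ``noise_sd/2`` to create
    inter-rater spread. ``semdiv_coupling`` is the target population
    correlation between latent exclusivity and latent semantic diversity.
    ``integer_levels`` restricts latent dimension means to integer scale
    points, the only profiles exactly representable after Likert rounding;
    used by noiseless-recovery tests.
    """

    n_items: int = 964
    n_concrete: int = 157
    n_lists: int = 24
    raters_per_list: int = 22
    noise_sd: float = 1.0
    careless_rate: float = 0.0
    outlier_rate: float = 0.0
    relevant_dim_count_distribution: tuple[float, ...] = DEFAULT_DIM_COUNT_PMF
    relevant_level_range: tuple[float, float] = (4.5, 6.5)
    irrelevant_level_range: tuple[float, float] = (1.2, 3.2)
    semdiv_coupling: float = -0.47
    integer_levels: bool = False
    dim_families: Optional[tuple[tuple[str, ...], tuple[str, ...]]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_items <= 0 or self.n_lists <= 0 or self.raters_per_list < 1:
            raise ValueError("n_items, n_lists and raters_per_list must be positive")
        if self.n_lists % 2:
            raise ValueError("n_lists must be even (raters take a pair of lists)")
        if not 0 <= self.n_concrete < self.n_items:
            raise ValueError("n_concrete must be in [0, n_items)")
        for name in ("careless_rate", "outlier_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        pmf = np.asarray(self.relevant_dim_count_distribution, dtype=float)
        if pmf.size == 0 or pmf.size > len(SEMANTIC_DIMENSIONS):
            raise ValueError("relevant_dim_count_distribution must cover 1..8")
        if (pmf < 0).any() or not math.isclose(pmf.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("relevant_dim_count_distribution must be a pmf")
        lo, hi = self.relevant_level_range
        if not (3.5 < lo <= hi <= 7.0):
            raise ValueError("relevant_level_range must lie within (3.5, 7]")
        lo, hi = self.irrelevant_level_range
        if not (1.0 <= lo <= hi <= 3.5):
            raise ValueError("irrelevant_level_range must lie within [1, 3.5]")
        if not -1.0 <= self.semdiv_coupling <= 0.0:
            raise ValueError("semdiv_coupling must be in [-1, 0]")
        if self.dim_families is not None:
            flat = [d for fam in self.dim_families for d in fam]
            if sorted(flat) != sorted(SEMANTIC_DIMENSIONS) or len(self.dim_families) != 2:
                raise ValueError("dim_families must partition the 8 dimensions in two")


@dataclass(frozen=True)
class LatentProfile:
    """Ground-truth generating profile for one word."""

    word: str
    is_abstract: bool
    true_means: Mapping[str, float]
    relevant_dims: frozenset[str]
    latent_E: float


@dataclass(frozen=True)
class GroundTruth:
    """What was planted: profiles, careless rater ids, outlier triples."""

    profiles: tuple[LatentProfile, ...]
    careless_raters: frozenset[str]
    outlier_triples: tuple[tuple[str, str, str], ...]


def _uniform(rng: np.random.Generator, rng_range: tuple[float, float],
             size: int, integer: bool) -> np.ndarray:
    lo, hi = rng_range
    if integer:
        lo_i, hi_i = math.ceil(lo), math.floor(hi)
        if hi_i < lo_i:  # degenerate integer window: snap to nearest point
            lo_i = hi_i = round((lo + hi) / 2)
        return rng.integers(lo_i, hi_i + 1, size=size).astype(float)
    return rng.uniform(lo, hi, size=size)


def make_profiles(config: GeneratorConfig,
                  registry: Optional[Sequence[VariableSpec]] = None
                  ) -> list[LatentProfile]:
    """Draw latent per-word profiles for all 15 variables.

    Abstract words draw k relevant dimensions from the configured count
    distribution (restricted to one dimension family when ``dim_families``
    is set); relevant dimensions get true means in the relevant band,
    the rest in the irrelevant band. Latent SEM_DIV is a linear-Gaussian
    function of standardised latent E calibrated so the population
    correlation equals ``semdiv_coupling``. Concrete fillers score low on
    all dimensions and high on concreteness/imageability.
    """
    if registry is None:
        registry = default_registry()
    registry_by_name(registry)
    dims = list(SEMANTIC_DIMENSIONS)
    if not dims:
        raise ValueError("empty semantic dimension set")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))

    n_abs = config.n_items - config.n_concrete
    pmf = np.asarray(config.relevant_dim_count_distribution, dtype=float)
    profiles: list[LatentProfile] = []
    words_abs = [f"w{idx:04d}" for idx in range(n_abs)]
    words_con = [f"c{idx:04d}" for idx in range(config.n_concrete)]

    # semantic-dimension means for abstract items
    dim_means = np.empty((n_abs, len(dims)))
    relevant_sets: list[frozenset[str]] = []
    for i in range(n_abs):
        if config.dim_families is not None:
            family = list(config.dim_families[int(rng.integers(2))])
            k = int(rng.integers(1, len(family) + 1))
            chosen = rng.choice(family, size=k, replace=False)
        else:
            k = int(rng.choice(np.arange(1, pmf.size + 1), p=pmf))
            chosen = rng.choice(dims, size=k, replace=False)
        rel = set(chosen.tolist())
        relevant_sets.append(frozenset(rel))
        for j, d in enumerate(dims):
            band = (config.relevant_level_range if d in rel
                    else config.irrelevant_level_range)
            dim_means[i, j] = _uniform(rng, band, 1, config.integer_levels)[0]

    latent_E = np.array([
        exclusivity_score(dim_means[i]) for i in range(n_abs)
    ])

    # SEM_DIV: rho * z(E) + sqrt(1 - rho^2) * eps, mapped to the 1-7 scale
    rho = config.semdiv_coupling
    zE = (latent_E - latent_E.mean()) / (latent_E.std() or 1.0)
    eps = rng.standard_normal(n_abs)
    s = rho * zE + math.sqrt(max(0.0, 1.0 - rho * rho)) * eps
    semdiv_abs = np.clip(4.0 + 1.0 * s, 1.0, 7.0)
    if config.integer_levels:
        semdiv_abs = np.round(semdiv_abs)

    def _psy(rng_range, n):  # psycholinguistic latents
        return _uniform(rng, rng_range, n, config.integer_levels)

    cnc_abs = _psy((1.5, 4.8), n_abs)
    img_abs = _psy((1.5, 5.0), n_abs)
    fam_abs = _psy((3.0, 7.0), n_abs)
    val_abs = _psy((2.0, 8.0), n_abs)
    aro_abs = _psy((2.0, 8.0), n_abs)
    aoa_abs = np.round(rng.uniform(3.0, 13.0, n_abs))

    for i, word in enumerate(words_abs):
        means = {d: float(dim_means[i, j]) for j, d in enumerate(dims)}
        means.update(CNC=float(cnc_abs[i]), IMG=float(img_abs[i]),
                     FAM=float(fam_abs[i]), SEM_DIV=float(semdiv_abs[i]),
                     VAL=float(val_abs[i]), ARO=float(aro_abs[i]),
                     AoA=float(aoa_abs[i]))
        profiles.append(LatentProfile(
            word=word, is_abstract=True, true_means=means,
            relevant_dims=relevant_sets[i], latent_E=float(latent_E[i]),
        ))

    n_con = config.n_concrete
    if n_con:
        dim_con = _uniform(rng, config.irrelevant_level_range,
                           n_con * len(dims), config.integer_levels
                           ).reshape(n_con, len(dims))
        cnc_con = _psy((6.0, 7.0), n_con)
        img_con = _psy((6.0, 7.0), n_con)
        fam_con = _psy((4.0, 7.0), n_con)
        sd_con = _psy((1.5, 5.0), n_con)
        val_con = _psy((3.0, 7.0), n_con)
        aro_con = _psy((2.0, 7.0), n_con)
        aoa_con = np.round(rng.uniform(2.0, 8.0, n_con))
        for i, word in enumerate(words_con):
            means = {d: float(dim_con[i, j]) for j, d in enumerate(dims)}
            means.update(CNC=float(cnc_con[i]), IMG=float(img_con[i]),
                         FAM=float(fam_con[i]), SEM_DIV=float(sd_con[i]),
                         VAL=float(val_con[i]), ARO=float(aro_con[i]),
                         AoA=float(aoa_con[i]))
            profiles.append(LatentProfile(
                word=word, is_abstract=False, true_means=means,
                relevant_dims=frozenset(),
                latent_E=float(exclusivity_score(dim_con[i])),
            ))
    return profiles


def profiles_meta(profiles: Sequence[LatentProfile]) -> list[ItemMeta]:
    """ItemMeta rows for a profile set."""
    return [ItemMeta(p.word, p.is_abstract) for p in profiles]


def _round_half_away(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer, ties away from zero (documented convention)."""
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def simulate_ratings(profiles: Sequence[LatentProfile], config: GeneratorConfig,
                     registry: Optional[Sequence[VariableSpec]] = None
                     ) -> pd.DataFrame:
    """Simulate the rater-level long table.

    Words go round-robin into ``n_lists`` lists; lists are paired, and each
    pair receives ``raters_per_list`` raters who rate every variable for
    every word on their two lists. A Likert response is
    ``clamp(round(true_mean + rater_offset + noise), lo, hi)``; AoA gets
    uniform +-2-year noise, floored at zero, with no rater offset.

    Returns a tidy frame with columns rater_id, list_id, word, variable,
    value, sorted deterministically.
    """
    if registry is None:
        registry = default_registry()
    by_name = registry_by_name(registry)
    if not profiles:
        raise ValueError("no profiles to simulate from")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))

    words = [p.word for p in profiles]
    list_of_word = {w: i % config.n_lists for i, w in enumerate(words)}
    n_pairs = config.n_lists // 2

    rater_rows = []  # (rater_id, list_index)
    rid = 0
    for pair in range(n_pairs):
        for _ in range(config.raters_per_list):
            rater = f"r{rid:04d}"
            rater_rows.append((rater, 2 * pair))
            rater_rows.append((rater, 2 * pair + 1))
            rid += 1
    offsets = {f"r{i:04d}": off for i, off in enumerate(
        rng.normal(0.0, config.noise_sd / 2.0, rid))}

    lists_words: dict[int, list[str]] = {i: [] for i in range(config.n_lists)}
    for w in words:
        lists_words[list_of_word[w]].append(w)
    prof_by_word = {p.word: p for p in profiles}
    var_names = [s.name for s in registry]

    recs_rater, recs_list, recs_word, recs_var, recs_val = [], [], [], [], []
    for rater, li in rater_rows:
        wlist = lists_words[li]
        off = offsets[rater]
        for var in var_names:
            spec = by_name[var]
            true = np.array([prof_by_word[w].true_means[var] for w in wlist])
            if spec.is_likert:
                noise = rng.normal(0.0, config.noise_sd, len(wlist)) \
                    if config.noise_sd > 0 else 0.0
                vals = _round_half_away(true + off + noise)
                vals = np.clip(vals, spec.scale_min, spec.scale_max)
            else:  # AoA: uniform +-2y noise, floored at 0
                noise = rng.uniform(-2.0, 2.0, len(wlist)) \
                    if config.noise_sd > 0 else 0.0
                vals = np.maximum(_round_half_away(true + noise), 0.0)
            recs_rater.extend([rater] * len(wlist))
            recs_list.extend([f"L{li:02d}"] * len(wlist))
            recs_word.extend(wlist)
            recs_var.extend([var] * len(wlist))
            recs_val.append(vals)
    frame = pd.DataFrame({
        "rater_id": recs_rater,
        "list_id": recs_list,
        "word": recs_word,
        "variable": recs_var,
        "value": np.concatenate(recs_val),
    })
    frame.sort_values(["rater_id", "word", "variable"], inplace=True,
                      kind="mergesort", ignore_index=True)
    return frame


def inject_careless(records: pd.DataFrame, config: GeneratorConfig
                    ) -> tuple[pd.DataFrame, frozenset[str]]:
    """Replace a ``careless_rate`` fraction of raters' responses by a
    per-rater constant scale value; returns (records, altered rater ids)."""
    if config.careless_rate == 0:
        return records, frozenset()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 303]))
    raters = np.sort(records["rater_id"].unique())
    n_careless = round(config.careless_rate * len(raters))
    chosen = rng.choice(raters, size=n_careless, replace=False)
    out = records.copy()
    for rater in chosen:
        const = float(rng.integers(1, 8))  # valid on every Likert scale here
        out.loc[out["rater_id"] == rater, "value"] = const
    return out, frozenset(str(r) for r in chosen)


def inject_outliers(records: pd.DataFrame, config: GeneratorConfig,
                    registry: Optional[Sequence[VariableSpec]] = None
                    ) -> tuple[pd.DataFrame, tuple[tuple[str, str, str], ...]]:
    """Push an ``outlier_rate`` fraction of Likert responses to the scale
    extreme opposite their item mean; returns (records, altered triples)."""
    if registry is None:
        registry = default_registry()
    by_name = registry_by_name(registry)
    if config.outlier_rate == 0:
        return records, ()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 404]))
    out = records.copy()
    likert = out["variable"].map(lambda v: by_name[v].is_likert)
    idx_pool = out.index[likert].to_numpy()
    n_out = round(config.outlier_rate * idx_pool.size)
    chosen = rng.choice(idx_pool, size=n_out, replace=False)
    cell_mean = out.groupby(["word", "variable"])["value"].transform("mean")
    for i in chosen:
        spec = by_name[out.at[i, "variable"]]
        mid = (spec.scale_min + spec.scale_max) / 2.0
        out.at[i, "value"] = float(
            spec.scale_min if cell_mean.at[i] > mid else spec.scale_max)
    triples = tuple(sorted(
        (str(out.at[i, "rater_id"]), str(out.at[i, "word"]),
         str(out.at[i, "variable"])) for i in chosen))
    return out, triples


def generate_dataset(config: GeneratorConfig,
                     registry: Optional[Sequence[VariableSpec]] = None
                     ) -> tuple[pd.DataFrame, list[ItemMeta], GroundTruth]:
    """Full generator: profiles -> ratings -> careless -> outliers."""
    profiles = make_profiles(config, registry)
    frame = simulate_ratings(profiles, config, registry)
    frame, careless = inject_careless(frame, config)
    frame, outliers = inject_outliers(frame, config, registry)
    truth = GroundTruth(tuple(profiles), careless, outliers)
    return frame, profiles_meta(profiles), truth


def write_ground_truth(truth: GroundTruth, path) -> None:
    """TSV of the latent truth: word, latent_E, pipe-joined relevant dims."""
    rows = [
        {"word": p.word, "is_abstract": p.is_abstract,
         "latent_E": f"{p.latent_E:.6f}",
         "relevant_dims": "|".join(sorted(p.relevant_dims))}
        for p in truth.profiles
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
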