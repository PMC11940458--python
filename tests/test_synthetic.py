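"""Generator contracts: latent structure, determinism, injections."""

import numpy as np
import pandas as pd
import pytest

from dimnorms.exclusivity import exclusivity_score
from dimnorms.synthetic_ratings import (GeneratorConfig, inject_careless,
                                        inject_outliers, make_profiles,
                                        simulate_ratings)
from dimnorms.variables import (SEMANTIC_DIMENSIONS, default_registry,
                                registry_by_name)


def test_latent_E_matches_formula_edge_cases():
    # one relevant dimension at 7, rest at 1 -> (7-1)/14 * 100
    assert exclusivity_score([7, 1, 1, 1, 1, 1, 1, 1]) == pytest.approx(
        42.857142857142854)
    # all equal -> zero range
    assert exclusivity_score([5.5] * 8) == 0.0


def test_profiles_respect_config_structure(small_config):
    profiles = make_profiles(small_config)
    assert len(profiles) == small_config.n_items
    n_abs = small_config.n_items - small_config.n_concrete
    assert sum(p.is_abstract for p in profiles) == n_abs
    rel_lo, rel_hi = small_config.relevant_level_range
    irr_lo, irr_hi = small_config.irrelevant_level_range
    for p in profiles:
        if p.is_abstract:
            assert 1 <= len(p.relevant_dims) <= 8
        for d in SEMANTIC_DIMENSIONS:
            band = (rel_lo, rel_hi) if d in p.relevant_dims else (irr_lo, irr_hi)
            assert band[0] <= p.true_means[d] <= band[1]
        assert p.latent_E == pytest.approx(exclusivity_score(
            [p.true_means[d] for d in SEMANTIC_DIMENSIONS]), abs=1e-12)


def test_semdiv_coupling_calibration():
    """Monte-Carlo check: population corr(E, SEM_DIV) ~= the target."""
    cfg = GeneratorConfig(n_items=2000, n_concrete=0, n_lists=50,
                          raters_per_list=25, semdiv_coupling=-0.47, seed=11)
    profiles = make_profiles(cfg)
    E = np.array([p.latent_E for p in profiles])
    sd = np.array([p.true_means["SEM_DIV"] for p in profiles])
    assert np.corrcoef(E, sd)[0, 1] == pytest.approx(-0.47, abs=0.05)


def test_all_values_within_scale_bounds(small_dataset):
    frame, _, _ = small_dataset
    by_name = registry_by_name(default_registry())
    for var, grp in frame.groupby("variable"):
        spec = by_name[var]
        assert grp["value"].ge(spec.scale_min).all()
        if spec.scale_max is not None:
            assert grp["value"].le(spec.scale_max).all()
        assert (grp["value"] == grp["value"].round()).all()


def test_noiseless_means_equal_rounded_truth():
    cfg = GeneratorConfig(n_items=40, n_concrete=8, n_lists=4,
                          raters_per_list=20, noise_sd=0.0, seed=2)
    profiles = make_profiles(cfg)
    frame = simulate_ratings(profiles, cfg)
    means = frame.groupby(["word", "variable"])["value"].mean()
    by_name = registry_by_name(default_registry())
    for p in profiles:
        for var in by_name:
            if not by_name[var].is_likert:
                continue
            true = p.true_means[var]
            expected = np.sign(true) * np.floor(abs(true) + 0.5)
            assert means[(p.word, var)] == expected


def test_observed_means_track_truth_with_noise():
    """CLT bound: with 25 raters and unit noise, >=99% of item x dimension
    cells sit within 3 standard errors of the latent mean (the discrete
    scale's rounding adds a sub-SE bias, absorbed by a rounding margin)."""
    cfg = GeneratorConfig(n_items=200, n_concrete=0, n_lists=4,
                          raters_per_list=25, noise_sd=1.0, seed=9)
    profiles = make_profiles(cfg)
    frame = simulate_ratings(profiles, cfg)
    dims = frame[frame["variable"].isin(SEMANTIC_DIMENSIONS)]
    means = dims.groupby(["word", "variable"])["value"].mean()
    truth = {(p.word, d): p.true_means[d] for p in profiles
             for d in SEMANTIC_DIMENSIONS}
    # per-response SD combines noise and rater offsets (sd = noise_sd/2)
    per_resp_sd = np.sqrt(1.0**2 + 0.5**2)
    tol = 3 * per_resp_sd / np.sqrt(25) + 0.15  # + clamp/rounding margin
    within = np.array([abs(means[k] - truth[k]) <= tol for k in means.index])
    assert within.mean() >= 0.99


def test_simulation_deterministic(small_config):
    a = simulate_ratings(make_profiles(small_config), small_config)
    b = simulate_ratings(make_profiles(small_config), small_config)
    pd.testing.assert_frame_equal(a, b)


class TestInjections:
    def test_zero_rates_are_identity(self, small_config, small_dataset):
        frame, _, _ = small_dataset
        cfg = GeneratorConfig(n_items=20, n_concrete=0, n_lists=2,
                              raters_per_list=5, careless_rate=0.0,
                              outlier_rate=0.0, seed=1)
        out, careless = inject_careless(frame, cfg)
        assert careless == frozenset() and out is frame
        out, triples = inject_outliers(frame, cfg)
        assert triples == () and out is frame

    def test_careless_count_and_constancy(self, small_dataset):
        frame, _, _ = small_dataset
        cfg = GeneratorConfig(n_items=120, n_concrete=20, n_lists=4,
                              raters_per_list=22, careless_rate=0.1, seed=3)
        out, careless = inject_careless(frame, cfg)
        n_raters = frame["rater_id"].nunique()
        assert len(careless) == round(0.1 * n_raters)
        for rater in careless:
            assert out.loc[out["rater_id"] == rater, "value"].nunique() == 1

    def test_outliers_in_bounds_and_extreme(self, small_dataset):
        frame, _, _ = small_dataset
        cfg = GeneratorConfig(n_items=120, n_concrete=20, n_lists=4,
                              raters_per_list=22, outlier_rate=0.02, seed=3)
        out, triples = inject_outliers(frame, cfg)
        by_name = registry_by_name(default_registry())
        indexed = out.set_index(["rater_id", "word", "variable"])
        n_likert = frame["variable"].map(
            lambda v: by_name[v].is_likert).sum()
        assert len(triples) == round(0.02 * n_likert)
        for rater, word, var in triples:
            spec = by_name[var]
            v = indexed.loc[(rater, word, var), "value"]
            assert v in (spec.scale_min, spec.scale_max)


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        GeneratorConfig(n_items=0)
    with pytest.raises(ValueError):
        GeneratorConfig(careless_rate=1.5)
    with pytest.raises(ValueError):
        GeneratorConfig(relevant_level_range=(2.0, 6.0))  # below 3.5
    with pytest.raises(ValueError):
        GeneratorConfig(semdiv_coupling=0.3)  # must be nonpositive
    with pytest.raises(ValueError):
        GeneratorConfig(dim_families=(("INTRO",), ("MENT_ST",)))
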