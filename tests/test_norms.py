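"""Aggregation arithmetic, group comparison, correlation matrix."""

import warnings

import numpy as np
import pandas as pd
import pytest

from dimnorms.norms import (aggregate, concreteness_comparison,
                            correlation_matrix)
from dimnorms.qc_trimming import trim_responses
from dimnorms.ratings_io import RatingRecord
from dimnorms.variables import ItemMeta, default_registry


def _full_word(word, rater_values):
    """Records covering every registry variable for one word."""
    recs = []
    for var in (s.name for s in default_registry()):
        for rater, value in rater_values:
            recs.append(RatingRecord(rater, "L0", word, var, float(value)))
    return recs


def test_two_point_cell_arithmetic():
    recs = _full_word("w0", [("r1", 1), ("r2", 7)])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        norms = aggregate(recs)
    assert norms.loc["w0", "SOC_mean"] == pytest.approx(4.0)
    assert norms.loc["w0", "SOC_sd"] == pytest.approx(4.242640687, abs=1e-6)
    assert norms.loc["w0", "SOC_n"] == 2


def test_n_bookkeeping_after_trimming():
    values = [("r%d" % i, 6) for i in range(24)] + [("r24", 1)]
    recs = _full_word("w0", values)
    trimmed, report = trim_responses(recs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        before = aggregate(recs)
        after = aggregate(trimmed)
    n_removed_soc = sum(1 for _, w, v in report.removed_responses
                        if v == "SOC")
    assert after.loc["w0", "SOC_n"] == before.loc["w0", "SOC_n"] - n_removed_soc


def test_missing_variable_is_error():
    recs = [RatingRecord("r1", "L0", "w0", "SOC", 4.0),
            RatingRecord("r2", "L0", "w0", "SOC", 5.0)]
    with pytest.raises(ValueError, match="no responses"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            aggregate(recs)


def test_aggregation_order_invariant(small_dataset):
    frame, meta, _ = small_dataset
    shuffled = frame.sample(frac=1.0, random_state=0).reset_index(drop=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        a = aggregate(frame, meta=meta)
        b = aggregate(shuffled, meta=meta)
    pd.testing.assert_frame_equal(a, b)


class TestConcretenessComparison:
    def test_identical_groups(self):
        rng = np.random.default_rng(7)
        base = rng.uniform(2, 6, 10)
        rows = {}
        for i, v in enumerate(base):
            rows[f"a{i}"] = {"is_abstract": True, "CNC_mean": v, "IMG_mean": v}
            rows[f"c{i}"] = {"is_abstract": False, "CNC_mean": v, "IMG_mean": v}
        norms = pd.DataFrame.from_dict(rows, orient="index")
        cmp = concreteness_comparison(norms)
        assert cmp.t_statistic["CNC"] == 0.0
        # identical groups: every abstract word is inside the concrete range
        assert cmp.n_abstract_in_concrete_range == 10

    def test_groups_separate(self, small_norms):
        cmp = concreteness_comparison(small_norms)
        assert cmp.concrete_mean["CNC"] > cmp.abstract_mean["CNC"]
        assert cmp.p_value["CNC"] < 0.001
        lo, hi = cmp.concrete_range["CNC"]
        in_range = small_norms[small_norms["is_abstract"]]["CNC_mean"] \
            .between(lo, hi).sum()
        assert cmp.n_abstract_in_concrete_range == int(in_range)
        # the range split partitions the in-range counts
        assert (cmp.range_split["lower"]["abstract"]
                + cmp.range_split["upper"]["abstract"]) == int(in_range)
        assert (cmp.range_split["lower"]["concrete"]
                + cmp.range_split["upper"]["concrete"]) == (
                    (~small_norms["is_abstract"]).sum())

    def test_empty_group_is_error(self, small_norms):
        only_abstract = small_norms[small_norms["is_abstract"]]
        with pytest.raises(ValueError):
            concreteness_comparison(only_abstract)


class TestCorrelationMatrix:
    def test_oracle_agreement_on_fixture(self, small_norms):
        r, p = correlation_matrix(small_norms.head(10))
        cols = [f"{v}_mean" for v in r.columns]
        mat = small_norms.head(10)[cols].to_numpy()
        # brute-force covariance / sd oracle
        for i in range(len(r)):
            for j in range(len(r)):
                xi, xj = mat[:, i], mat[:, j]
                cov = ((xi - xi.mean()) * (xj - xj.mean())).sum() / (len(xi) - 1)
                oracle = cov / (xi.std(ddof=1) * xj.std(ddof=1))
                assert r.iloc[i, j] == pytest.approx(oracle, abs=1e-12)

    def test_symmetric_unit_diagonal(self, small_norms):
        r, p = correlation_matrix(small_norms)
        assert np.allclose(r, r.T, equal_nan=True)
        assert np.allclose(np.diag(r), 1.0)
        assert r.shape == (15, 15)

    def test_row_permutation_invariant(self, small_norms):
        r1, _ = correlation_matrix(small_norms)
        shuffled = small_norms.sample(frac=1.0, random_state=1)
        r2, _ = correlation_matrix(shuffled)
        pd.testing.assert_frame_equal(r1, r2)

    def test_constructed_anticorrelated_pair(self):
        n = 12
        rng = np.random.default_rng(8)
        norms = pd.DataFrame(index=[f"w{i}" for i in range(n)])
        x = np.linspace(2, 6, n)
        for var in (s.name for s in default_registry()):
            norms[f"{var}_mean"] = rng.uniform(1, 7, n)
        norms["SOC_mean"] = x
        norms["MOR_mean"] = 8 - x  # exact mirror
        r, _ = correlation_matrix(norms)
        assert r.loc["SOC", "MOR"] == pytest.approx(-1.0, abs=1e-12)

    def test_zero_variance_gives_nan(self):
        norms = pd.DataFrame(index=["w0", "w1", "w2"])
        rng = np.random.default_rng(9)
        for var in (s.name for s in default_registry()):
            norms[f"{var}_mean"] = rng.uniform(1, 7, 3)
        norms["SOC_mean"] = 4.0
        with pytest.warns(UserWarning, match="zero variance"):
            r, p = correlation_matrix(norms)
        assert np.isnan(r.loc["SOC", "MOR"])
        assert r.loc["SOC", "SOC"] == 1.0
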