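import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phoscoreg.cooccurrence import (
    PatternCounts,
    cooccurrence_matrix,
    coregulation_ratios,
    count_patterns,
)
from phoscoreg.model import ValidationError

from conftest import corpus_from_calls


class TestCountPatterns:
    def test_direct_tally(self):
        corpus = corpus_from_calls(
            {
                "d1": {"CAV1_Y14": "U", "CAV1_S37": "U"},
                "d2": {"CAV1_Y14": "U", "CAV1_S37": "U"},
                "d3": {"CAV1_Y14": "D", "CAV1_S37": "D"},
                "d4": {"CAV1_Y14": "U", "CAV1_S37": "D"},
            }
        )
        c = count_patterns("CAV1_Y14", "CAV1_S37", corpus)
        assert (c.nUU, c.nDD, c.nUD, c.nDU) == (2, 1, 1, 0)

    def test_no_co_detected_datasets_all_zero(self):
        corpus = corpus_from_calls(
            {"d1": {"CAV1_Y14": "U"}, "d2": {"CAV1_S37": "D"}}
        )
        c = count_patterns("CAV1_Y14", "CAV1_S37", corpus)
        assert c.n_both == 0

    def test_uncalled_records_do_not_count(self):
        corpus = corpus_from_calls(
            {"d1": {"CAV1_Y14": "U", "CAV1_S37": "none"}}
        )
        assert count_patterns("CAV1_Y14", "CAV1_S37", corpus).n_both == 0

    def test_identical_sites_rejected(self):
        corpus = corpus_from_calls({"d1": {"CAV1_Y14": "U"}})
        with pytest.raises(ValidationError):
            count_patterns("CAV1_Y14", "CAV1_Y14", corpus)

    def test_swap_symmetry(self):
        corpus = corpus_from_calls(
            {
                "d1": {"CAV1_Y14": "U", "CAV1_S37": "D"},
                "d2": {"CAV1_Y14": "D", "CAV1_S37": "U"},
                "d3": {"CAV1_Y14": "D", "CAV1_S37": "U"},
                "d4": {"CAV1_Y14": "U", "CAV1_S37": "U"},
            }
        )
        fwd = count_patterns("CAV1_Y14", "CAV1_S37", corpus)
        rev = count_patterns("CAV1_S37", "CAV1_Y14", corpus)
        assert (rev.nUU, rev.nDD, rev.nUD, rev.nDU) == (fwd.nUU, fwd.nDD, fwd.nDU, fwd.nUD)
        assert rev == fwd.swapped()


class TestRatios:
    @pytest.mark.parametrize(
        "counts, pos, neg",
        [
            ((3, 2, 1, 0), 5.0, 0.2),
            ((0, 0, 2, 2), 0.0, math.inf),
            ((2, 2, 0, 0), math.inf, 0.0),
        ],
    )
    def test_examples_and_sentinels(self, counts, pos, neg):
        res = coregulation_ratios(PatternCounts("A_S1", "B_S2", *counts))
        assert res.positive_ratio == pos and res.negative_ratio == neg

    def test_no_data_sentinel(self):
        res = coregulation_ratios(PatternCounts("A_S1", "B_S2", 0, 0, 0, 0))
        assert math.isnan(res.positive_ratio) and math.isnan(res.negative_ratio)
        assert res.no_data

    @given(
        nUU=st.integers(0, 50),
        nDD=st.integers(0, 50),
        nUD=st.integers(0, 50),
        nDU=st.integers(0, 50),
    )
    @settings(max_examples=200, derandomize=True)
    def test_reciprocal_identity(self, nUU, nDD, nUD, nDU):
        res = coregulation_ratios(PatternCounts("A_S1", "B_S2", nUU, nDD, nUD, nDU))
        if math.isfinite(res.positive_ratio) and res.positive_ratio > 0:
            assert res.positive_ratio * res.negative_ratio == pytest.approx(1.0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            PatternCounts("A_S1", "B_S2", -1, 0, 0, 0)


class TestMatrix:
    def test_symmetric_positive_ratio_no_diagonal(self):
        corpus = corpus_from_calls(
            {
                "d1": {"CAV1_Y14": "U", "CAV1_S37": "U", "CAV1_Y25": "D"},
                "d2": {"CAV1_Y14": "D", "CAV1_S37": "D"},
                "d3": {"CAV1_Y14": "U", "CAV1_Y25": "U"},
            }
        )
        mat = cooccurrence_matrix(corpus, "CAV1")
        assert not (mat["site1"] == mat["site2"]).any()
        wide = mat.set_index(["site1", "site2"])["positive_ratio"]
        for (s1, s2) in wide.index:
            a, b = wide.loc[(s1, s2)], wide.loc[(s2, s1)]
            assert (a == b) or (math.isnan(a) and math.isnan(b))

    def test_conservation_against_raw_frame(self):
        corpus = corpus_from_calls(
            {
                "d1": {"CAV1_Y14": "U", "CAV1_S37": "D"},
                "d2": {"CAV1_Y14": "D", "CAV1_S37": "D"},
                "d3": {"CAV1_S37": "U"},
            }
        )
        mat = cooccurrence_matrix(corpus, "CAV1").set_index(["site1", "site2"])
        row = mat.loc[("CAV1_Y14", "CAV1_S37")]
        called = corpus.differential[corpus.differential["call"] != "none"]
        per_ds = called.groupby("dataset_id")["site"].nunique()
        n_codetected = int((per_ds == 2).sum())
        assert row[["nUU", "nDD", "nUD", "nDU"]].sum() == n_codetected

    def test_single_site_warns_empty(self):
        corpus = corpus_from_calls({"d1": {"CAV1_Y14": "U"}})
        with pytest.warns(UserWarning):
            mat = cooccurrence_matrix(corpus, "CAV1")
        assert len(mat) == 0
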