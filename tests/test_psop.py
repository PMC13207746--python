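import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from phoscoreg.model import ValidationError
from phoscoreg.psop import (
    ContingencyTable,
    build_contingency,
    classify_pattern,
    fisher_one_sided,
    psop_screen,
)

from conftest import corpus_from_calls
from oracles import enumeration_fisher


class TestClassifyPattern:
    @pytest.mark.parametrize(
        "pred, other, code",
        [("U", "U", "UU"), ("D", "D", "DD"), ("U", "D", "UD"), ("D", "U", "DU")],
    )
    def test_first_letter_is_predominant_site_status(self, pred, other, code):
        assert classify_pattern(pred, other) == code

    def test_reversing_the_pair_swaps_the_letters(self):
        for x in "UD":
            for y in "UD":
                assert classify_pattern(x, y) == classify_pattern(y, x)[::-1]

    def test_uncalled_input_rejected(self):
        with pytest.raises(ValidationError):
            classify_pattern("U", "none")


class TestBuildContingency:
    def test_direct_tally_over_ten_datasets(self):
        call_map = {}
        for i in range(4):  # neither called
            call_map[f"a{i}"] = {"CAV1_Y14": "none"}
        for i in range(3):  # only one called
            call_map[f"b{i}"] = {"CAV1_Y14": "U", "EGFR_Y1068": "none"}
        call_map["c0"] = {"CAV1_Y14": "U", "EGFR_Y1068": "D"}  # discordant
        call_map["d0"] = {"CAV1_Y14": "U", "EGFR_Y1068": "U"}  # concordant
        call_map["d1"] = {"CAV1_Y14": "D", "EGFR_Y1068": "D"}
        corpus = corpus_from_calls(call_map)
        t = build_contingency("CAV1_Y14", "EGFR_Y1068", corpus)
        assert (t.a, t.b, t.c, t.d) == (4, 3, 1, 2)
        assert t.n == 10 == corpus.n_differential_datasets

    def test_never_codetected_pair(self):
        corpus = corpus_from_calls(
            {"d1": {"CAV1_Y14": "U"}, "d2": {"EGFR_Y1068": "D"}},
            extra_differential=3,
        )
        t = build_contingency("CAV1_Y14", "EGFR_Y1068", corpus)
        assert t.c == 0 and t.d == 0
        assert t.a + t.b == t.n == 5

    def test_same_protein_pair_rejected(self):
        corpus = corpus_from_calls({"d1": {"CAV1_Y14": "U", "CAV1_S37": "U"}})
        with pytest.raises(ValidationError):
            build_contingency("CAV1_Y14", "CAV1_S37", corpus)

    def test_negative_cells_rejected(self):
        with pytest.raises(ValidationError):
            ContingencyTable(1, 1, -1, 1)


class TestFisherOneSided:
    def test_no_codetection_gives_p_one(self):
        t = ContingencyTable(5, 5, 0, 0)
        assert fisher_one_sided(t, "positive") == 1.0
        assert fisher_one_sided(t, "negative") == 1.0

    def test_known_table_matches_enumeration(self):
        t = ContingencyTable(8, 2, 2, 8)
        for direction in ("positive", "negative"):
            assert fisher_one_sided(t, direction) == pytest.approx(
                enumeration_fisher(8, 2, 2, 8, direction), abs=1e-14
            )

    def test_empty_table_is_p_one(self):
        assert fisher_one_sided(ContingencyTable(0, 0, 0, 0), "positive") == 1.0

    def test_invalid_direction_rejected(self):
        with pytest.raises(ValidationError):
            fisher_one_sided(ContingencyTable(1, 1, 1, 1), "sideways")

    @given(
        a=st.integers(0, 25),
        b=st.integers(0, 25),
        c=st.integers(0, 25),
        d=st.integers(0, 25),
    )
    @settings(max_examples=150, derandomize=True)
    def test_cross_check_against_scipy(self, a, b, c, d):
        # toward-large-d extremeness on [[a,b],[c,d]] coincides with the
        # odds-ratio-greater one-sided test of the same 2x2 (a = c1 - r2 + d
        # grows with d at fixed margins), and toward-large-c with 'less'
        t = ContingencyTable(a, b, c, d)
        _, p_greater = scipy.stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        _, p_less = scipy.stats.fisher_exact([[a, b], [c, d]], alternative="less")
        assert fisher_one_sided(t, "positive") == pytest.approx(p_greater, abs=1e-9)
        assert fisher_one_sided(t, "negative") == pytest.approx(p_less, abs=1e-9)

    @pytest.mark.parametrize("a, b, total_cd", [(10, 5, 8), (3, 12, 10), (0, 7, 6)])
    def test_p_nonincreasing_in_d_at_fixed_margins(self, a, b, total_cd):
        ps = [
            fisher_one_sided(ContingencyTable(a, b, total_cd - d, d), "positive")
            for d in range(total_cd + 1)
        ]
        assert all(p1 >= p2 - 1e-15 for p1, p2 in zip(ps, ps[1:]))


class TestScreen:
    def _screen_corpus(self, n_studies=4):
        """CAV1_Y14 vs one concordant partner across datasets from n_studies studies."""
        call_map, pmids = {}, {}
        for i in range(8):
            call_map[f"d{i}"] = {"CAV1_Y14": "U", "EGFR_Y1068": "U"}
            pmids[f"d{i}"] = f"PM{i % n_studies}"
        for i in range(8, 16):
            call_map[f"d{i}"] = {"CAV1_Y14": "none", "EGFR_Y1068": "none"}
            pmids[f"d{i}"] = f"PM{i % n_studies}"
        return corpus_from_calls(call_map, pmids=pmids)

    def test_contingency_and_pattern_counts_are_consistent(self):
        corpus = self._screen_corpus()
        res = psop_screen("CAV1_Y14", corpus)
        assert len(res) == 1
        row = res.iloc[0]
        assert row["c"] + row["d"] == row[["nUU", "nDD", "nUD", "nDU"]].sum()
        assert row[["a", "b", "c", "d"]].sum() == corpus.n_differential_datasets

    def test_significant_concordant_pair_passes(self):
        res = psop_screen("CAV1_Y14", self._screen_corpus())
        row = res.iloc[0]
        assert row["category"] == "UUDD"
        assert row["fet_p"] < 0.05
        assert bool(row["passes"]) is True

    def test_two_study_support_fails_pmid_filter(self):
        res = psop_screen("CAV1_Y14", self._screen_corpus(n_studies=2))
        row = res.iloc[0]
        assert row["fet_p"] < 0.05 and row["pmid_count"] == 2
        assert bool(row["passes"]) is False

    def test_freq_ratio_uses_predominant_site_total(self):
        corpus = self._screen_corpus()
        res = psop_screen("CAV1_Y14", corpus)
        row = res.iloc[0]
        pred_count = (
            (corpus.differential["site"] == "CAV1_Y14") & (corpus.differential["call"] != "none")
        ).sum()
        assert row["freq_ratio"] == pytest.approx(row["coreg_freq"] / pred_count)

    def test_uncalled_predominant_site_warns_empty(self):
        corpus = corpus_from_calls({"d1": {"EGFR_Y1068": "U"}})
        with pytest.warns(UserWarning):
            res = psop_screen("CAV1_Y14", corpus)
        assert len(res) == 0

    def test_bh_column_monotone_with_raw_p(self):
        from phoscoreg.simulate import default_study_config, generate_corpus

        corpus, _ = generate_corpus(default_study_config(seed=3))
        res = psop_screen("CAV1_Y14", corpus)
        assert (res["fet_bh"] >= res["fet_p"] - 1e-12).all()
        srt = res.sort_values("fet_p")
        assert (srt["fet_bh"].diff().dropna() >= -1e-12).all()
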