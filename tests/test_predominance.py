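import numpy as np
import pandas as pd
import pytest

from phoscoreg.model import Corpus, ValidationError
from phoscoreg.predominance import (
    export_lollipop_table,
    predominant_sites,
    rank_predominant,
    site_frequencies,
)
from phoscoreg.simulate import SyntheticConfig, generate_corpus

from conftest import add_profiling, corpus_from_calls


@pytest.fixture
def mixed_corpus():
    """CAV1 with two sites across 3 differential + 2 profiling datasets, 3 studies."""
    corpus = corpus_from_calls(
        {
            "d1": {"CAV1_Y14": "U", "CAV1_S37": "U", "EGFR_Y1068": "U"},
            "d2": {"CAV1_Y14": "D", "CAV1_S37": "none"},
            "d3": {"CAV1_S37": "D"},
        },
        pmids={"d1": "PM1", "d2": "PM2", "d3": "PM3"},
    )
    return add_profiling(
        corpus,
        {"p1": ["CAV1_Y14", "CAV1_S37"], "p2": ["CAV1_Y14"]},
        pmids={"p1": "PM1", "p2": "PM4"},
    )


class TestSiteFrequencies:
    def test_counts(self, mixed_corpus, fcfg):
        freqs = site_frequencies(mixed_corpus, "CAV1", fcfg).set_index("site")
        y14 = freqs.loc["CAV1_Y14"]
        assert (y14["profiling_count"], y14["differential_count"]) == (2, 2)
        assert (y14["up_count"], y14["down_count"]) == (1, 1)
        assert y14["study_count"] == 3  # {PM1, PM2} differential + {PM1, PM4} profiling
        s37 = freqs.loc["CAV1_S37"]
        assert (s37["profiling_count"], s37["differential_count"]) == (1, 2)
        assert s37["study_count"] == 2  # {PM1, PM3}; sub-threshold d2 record does not count

    def test_other_proteins_excluded(self, mixed_corpus, fcfg):
        freqs = site_frequencies(mixed_corpus, "CAV1", fcfg)
        assert set(freqs["gene"]) == {"CAV1"}

    def test_absent_protein_warns_and_returns_empty(self, mixed_corpus, fcfg):
        with pytest.warns(UserWarning):
            freqs = site_frequencies(mixed_corpus, "NOPE", fcfg)
        assert len(freqs) == 0

    def test_duplicate_rows_count_once_per_dataset(self, fcfg):
        corpus = corpus_from_calls({"d1": {"CAV1_Y14": "U"}})
        dup = Corpus(
            corpus.datasets,
            corpus.profiling,
            pd.concat([corpus.differential] * 3, ignore_index=True),
        )
        freqs = site_frequencies(dup, "CAV1", fcfg).set_index("site")
        assert freqs.loc["CAV1_Y14", "differential_count"] == 1

    def test_row_order_invariance(self, mixed_corpus, fcfg):
        base = site_frequencies(mixed_corpus, "CAV1", fcfg)
        rng = np.random.default_rng(0)
        shuffled = Corpus(
            mixed_corpus.datasets.sample(frac=1, random_state=1),
            mixed_corpus.profiling.sample(frac=1, random_state=2),
            mixed_corpus.differential.sample(frac=1, random_state=3),
        )
        assert site_frequencies(shuffled, "CAV1", fcfg).equals(base)

    def test_profiling_count_conservation(self, mixed_corpus, fcfg):
        freqs = site_frequencies(mixed_corpus, "CAV1", fcfg)
        prof = mixed_corpus.profiling
        pairs = prof[prof["gene"] == "CAV1"].drop_duplicates(["site", "dataset_id"])
        assert freqs["profiling_count"].sum() == len(pairs)


class TestRanking:
    def test_sorted_by_total_then_differential(self):
        freqs = pd.DataFrame(
            {
                "site": ["G_S1", "G_S2", "G_S3"],
                "gene": "G",
                "residue": "S",
                "position": [1, 2, 3],
                "profiling_count": [5, 3, 4],
                "differential_count": [1, 3, 2],
                "up_count": [1, 3, 2],
                "down_count": [0, 0, 0],
                "study_count": [3, 3, 3],
            }
        )
        ranked = rank_predominant(freqs)
        assert ranked["site"].tolist() == ["G_S2", "G_S3", "G_S1"]  # ties: differential wins

    def test_predominance_requires_both_types_and_min_pmids(self, fcfg):
        freqs = pd.DataFrame(
            {
                "site": ["G_S1", "G_S2", "G_S3"],
                "gene": "G",
                "residue": "S",
                "position": [1, 2, 3],
                "profiling_count": [10, 0, 10],
                "differential_count": [5, 5, 5],
                "up_count": [5, 5, 5],
                "down_count": [0, 0, 0],
                "study_count": [3, 3, 2],
            }
        )
        ranked = rank_predominant(freqs, fcfg).set_index("site")
        assert bool(ranked.loc["G_S1", "predominant"]) is True
        assert bool(ranked.loc["G_S2", "predominant"]) is False  # never profiled
        assert bool(ranked.loc["G_S3", "predominant"]) is False  # only 2 studies

    def test_empty_table_raises(self):
        with pytest.raises(ValidationError):
            rank_predominant(pd.DataFrame(columns=["site"]))

    def test_ranking_recovers_planted_high_frequency_site(self, fcfg):
        cfg = SyntheticConfig(
            n_studies=5,
            conditions_per_study=(100, 100),
            n_proteins=0,
            base_detect_prob=0.0,
            predominant_sites=[("CAV1_Y14", 0.9), ("CAV1_S37", 0.1)],
            seed=12,
        )
        corpus, _ = generate_corpus(cfg)
        freqs = site_frequencies(corpus, "CAV1", fcfg)
        ranked = rank_predominant(freqs, fcfg)
        assert ranked["site"].iloc[0] == "CAV1_Y14"
        assert "CAV1_Y14" in predominant_sites(freqs, fcfg)


class TestLollipopExport:
    def test_down_heights_negative_and_domains_labelled(self, mixed_corpus, fcfg):
        freqs = site_frequencies(mixed_corpus, "CAV1", fcfg)
        domains = pd.DataFrame(
            {"domain": ["scaffolding"], "start": [10], "end": [20]}
        )
        table = export_lollipop_table(freqs, domains).set_index("site")
        assert table.loc["CAV1_Y14", "down_height"] == -1
        assert table.loc["CAV1_Y14", "domain"] == "scaffolding"
        assert table.loc["CAV1_S37", "domain"] == ""

    def test_invalid_domain_interval_raises(self, mixed_corpus, fcfg):
        freqs = site_frequencies(mixed_corpus, "CAV1", fcfg)
        bad = pd.DataFrame({"domain": ["x"], "start": [20], "end": [10]})
        with pytest.raises(ValidationError):
            export_lollipop_table(freqs, bad)
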