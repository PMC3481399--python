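"""Document-frequency enrichment statistic, its p-values and pair selection.

Independent oracle for the full enrichment path: scipy's Welch t-test on
the per-sample document-frequency vectors.
"""

import math

import numpy as np
import pytest
from scipy import stats

import dgconnect as dg
from dgconnect.errors import ValidationError
from dgconnect.literature_mining import (
    co_mention_counts,
    document_frequency,
    drug_pvalue,
    enrich_drugs,
    enrichment_statistic,
    partition_corpus,
    sample_corpus,
    select_top_pairs,
    welch_df,
)


def _docs(flags, term="tam"):
    return [
        dg.DocRecord(doc_id=f"d{i}", drug_terms=frozenset([term] if f else []))
        for i, f in enumerate(flags)
    ]


class TestDocumentFrequency:
    def test_term_in_all_docs(self):
        assert document_frequency("tam", _docs([1] * 10)) == 1.0

    def test_term_absent(self):
        assert document_frequency("tam", _docs([0] * 10)) == 0.0

    def test_three_of_eight(self):
        assert document_frequency("tam", _docs([1, 1, 1, 0, 0, 0, 0, 0])) == 0.375

    def test_empty_docs_rejected(self):
        with pytest.raises(ValidationError):
            document_frequency("tam", [])


class TestSampleCorpus:
    @pytest.fixture
    def corpus(self):
        return dg.Corpus(_docs([1, 0] * 10), label="retrieved")

    def test_deterministic_per_seed(self, corpus):
        a = sample_corpus(corpus, 5, 8, seed=42)
        b = sample_corpus(corpus, 5, 8, seed=42)
        assert [[d.doc_id for d in s] for s in a] == [[d.doc_id for d in s] for s in b]

    def test_without_replacement_full_size_is_permutation(self, corpus):
        (sample,) = sample_corpus(corpus, 1, len(corpus), seed=0, replace=False)
        assert sorted(d.doc_id for d in sample) == sorted(d.doc_id for d in corpus)

    def test_with_replacement_duplicates_at_binomial_rate(self, corpus):
        # P(some duplicate in a sample of 5 from 20) = 1 - 19*18*17*16/20^4
        expected = 1 - (19 * 18 * 17 * 16) / 20**4
        hits = sum(
            len({d.doc_id for d in sample_corpus(corpus, 1, 5, seed=s)[0]}) < 5
            for s in range(1000)
        )
        se = math.sqrt(expected * (1 - expected) / 1000)
        assert abs(hits / 1000 - expected) < 4 * se

    def test_oversized_sample_without_replacement_rejected(self, corpus):
        with pytest.raises(ValidationError):
            sample_corpus(corpus, 1, len(corpus) + 1, replace=False)

    def test_partition_blocks_are_disjoint_and_cover(self, corpus):
        blocks = partition_corpus(corpus, 4, seed=1)
        ids = [d.doc_id for b in blocks for d in b]
        assert len(ids) == len(set(ids)) == 20
        assert {len(b) for b in blocks} == {5}

    def test_partition_more_blocks_than_docs_rejected(self, corpus):
        with pytest.raises(ValidationError):
            partition_corpus(corpus, 21, seed=1)


class TestEnrichmentStatistic:
    def test_identical_means_give_zero(self):
        assert enrichment_statistic(0.3, 0.3, 0.01, 0.02, 50, 50) == 0.0

    def test_worked_example(self):
        # (0.3-0.1)/sqrt(0.01/50 + 0.01/50) = 0.2/0.02 = 10
        assert enrichment_statistic(0.3, 0.1, 0.01, 0.01, 50, 50) == pytest.approx(10.0)

    def test_antisymmetric_under_corpus_swap(self):
        a = enrichment_statistic(0.3, 0.1, 0.01, 0.03, 40, 60)
        b = enrichment_statistic(0.1, 0.3, 0.03, 0.01, 60, 40)
        assert a == -b

    def test_zero_variance_equal_means_is_zero(self):
        assert enrichment_statistic(0.2, 0.2, 0.0, 0.0, 50, 50) == 0.0

    def test_zero_variance_different_means_is_signed_infinity(self):
        assert enrichment_statistic(0.3, 0.1, 0.0, 0.0, 50, 50) == math.inf
        assert enrichment_statistic(0.1, 0.3, 0.0, 0.0, 50, 50) == -math.inf

    def test_small_counts_rejected(self):
        with pytest.raises(ValidationError):
            enrichment_statistic(0.3, 0.1, 0.01, 0.01, 1, 50)


class TestDrugPvalue:
    def test_zero_delta_gives_p_one(self):
        assert drug_pvalue(0.0, 50, 50, 0.01, 0.01) == 1.0

    def test_infinite_delta_gives_p_zero(self):
        assert drug_pvalue(math.inf, 50, 50, 0.0, 0.0) == 0.0
        assert drug_pvalue(-math.inf, 50, 50, 0.0, 0.0) == 0.0

    def test_large_delta_tiny_p(self):
        # df = 98 for equal n and variances; t=10 tail is < 1e-12
        p = drug_pvalue(10.0, 50, 50, 0.01, 0.01)
        assert 0 < p < 1e-12
        assert p == pytest.approx(2 * stats.t.sf(10.0, 98), rel=1e-9)

    def test_welch_df_equal_variances(self):
        assert welch_df(0.01, 0.01, 50, 50) == pytest.approx(98.0)

    def test_p_symmetric_in_sign(self):
        assert drug_pvalue(3.0, 30, 40, 0.01, 0.02) == drug_pvalue(
            -3.0, 30, 40, 0.01, 0.02
        )


class TestEnrichDrugs:
    def test_null_self_comparison_is_exactly_flat(self):
        # identical corpora: the partition means coincide exactly
        ret, _ = dg.gen_corpus_pair(50, [f"t{i}" for i in range(10)], {}, 0.3, seed=3)
        results = enrich_drugs(ret, dg.Corpus(ret.records, label="background"),
                               {f"t{i}" for i in range(10)}, n_samples=10, seed=5)
        assert all(r.p_value == 1.0 and r.delta == 0.0 for r in results)

    def test_planted_term_recovered_and_matches_scipy_oracle(self):
        vocab = [f"d{i}" for i in range(20)]
        ret, bg = dg.gen_corpus_pair(
            200, vocab, {"d7": (0.6, 0.05)}, base_rate=0.1, seed=17
        )
        results = enrich_drugs(ret, bg, set(vocab), n_samples=100, seed=17)
        assert results[0].drug == "d7"
        assert results[0].p_value < 1e-3
        # oracle: take the same blocks, compute dfs by counting, and hand
        # the two df vectors to scipy's Welch test
        dfs = []
        for corpus in (ret, bg):
            blocks = partition_corpus(corpus, 100, seed=17)
            dfs.append(
                np.array([document_frequency("d7", block) for block in blocks])
            )
        t, p = stats.ttest_ind(dfs[0], dfs[1], equal_var=False)
        assert results[0].delta == pytest.approx(t)
        assert results[0].p_value == pytest.approx(p)

    def test_term_in_neither_corpus_is_null(self):
        ret, bg = dg.gen_corpus_pair(40, ["a"], {}, 0.5, seed=1)
        results = enrich_drugs(ret, bg, {"ghost"}, n_samples=10, seed=1)
        (r,) = results
        assert r.delta == 0.0 and r.p_value == 1.0 and r.rel_freq == 0.0

    def test_empty_vocabulary_gives_empty_result(self, caplog):
        ret, bg = dg.gen_corpus_pair(10, ["a"], {}, 0.5, seed=1)
        with caplog.at_level("WARNING"):
            assert enrich_drugs(ret, bg, set(), seed=1, n_samples=5) == []

    def test_swapping_corpora_negates_delta_and_preserves_p(self):
        vocab = [f"d{i}" for i in range(5)]
        ret, bg = dg.gen_corpus_pair(60, vocab, {"d2": (0.5, 0.1)}, 0.2, seed=9)
        fwd = {r.drug: r for r in enrich_drugs(ret, bg, set(vocab), n_samples=20, seed=9)}
        # swap roles but keep the same partition draws per corpus position
        rev_ret = dg.Corpus(bg.records, label="retrieved")
        rev_bg = dg.Corpus(ret.records, label="background")
        rev = {r.drug: r for r in enrich_drugs(rev_ret, rev_bg, set(vocab),
                                               n_samples=20, seed=9)}
        for term in vocab:
            assert fwd[term].delta == pytest.approx(-rev[term].delta)
            assert fwd[term].p_value == pytest.approx(rev[term].p_value)

    def test_bit_reproducible_for_fixed_seed(self):
        vocab = [f"d{i}" for i in range(8)]
        ret, bg = dg.gen_corpus_pair(50, vocab, {}, 0.25, seed=2)
        a = enrich_drugs(ret, bg, set(vocab), n_samples=10, seed=123)
        b = enrich_drugs(ret, bg, set(vocab), n_samples=10, seed=123)
        assert a == b


class TestSelectTopPairs:
    @pytest.fixture
    def inputs(self):
        ranked = [
            dg.RankedProtein("P1", 3.0),
            dg.RankedProtein("P2", 2.0),
            dg.RankedProtein("P3", 1.0),
            dg.RankedProtein("P4", 0.5),
        ]
        enriched = [
            self._enr("dA", 0.001),
            self._enr("dB", 0.01),
            self._enr("dC", 0.01),
        ]
        counts = {
            (d, p): 1
            for d in ("dA", "dB", "dC")
            for p in ("P1", "P2", "P3", "P4")
        }
        return ranked, enriched, counts

    @staticmethod
    def _enr(drug, p):
        return dg.DrugEnrichment(
            drug=drug, delta=1.0, p_value=p, mean_df_net=0.2, mean_df_bg=0.1,
            var_df_net=0.01, var_df_bg=0.01, n_net=10, n_bg=10, rel_freq=0.2,
        )

    def test_truncation_matches_brute_force_sort(self, inputs):
        ranked, enriched, counts = inputs
        pvals = {e.drug: e.p_value for e in enriched}
        rps = {r.protein_id: r.r_p for r in ranked}
        oracle = sorted(
            counts, key=lambda dp: (pvals[dp[0]], -rps[dp[1]], dp[0], dp[1])
        )[:5]
        assert select_top_pairs(ranked, enriched, counts, 5) == oracle

    def test_n_larger_than_pair_count_returns_all(self, inputs):
        ranked, enriched, counts = inputs
        assert len(select_top_pairs(ranked, enriched, counts, 999)) == len(counts)

    def test_equal_p_drugs_interleave_by_protein_score(self, inputs):
        ranked, enriched, counts = inputs
        pairs = select_top_pairs(ranked, enriched, counts, 8)
        # dB and dC share p=0.01: their pairs alternate by r_p then drug name
        tail = pairs[4:]
        assert tail == [
            ("dB", "P1"), ("dC", "P1"), ("dB", "P2"), ("dC", "P2"),
        ]

    def test_pairs_without_co_mention_excluded(self, inputs):
        ranked, enriched, _ = inputs
        counts = {("dA", "P1"): 1, ("dA", "P2"): 0}
        assert select_top_pairs(ranked, enriched, counts, 10) == [("dA", "P1")]

    def test_co_mention_counts(self):
        corpus = dg.Corpus(
            [
                dg.DocRecord("1", frozenset({"dA"}), frozenset({"P1", "P2"})),
                dg.DocRecord("2", frozenset({"dA"}), frozenset({"P1"})),
            ]
        )
        assert co_mention_counts(corpus) == {("dA", "P1"): 2, ("dA", "P2"): 1}


class TestStatisticalBehaviour:
    def test_type_one_error_calibrated_under_null(self):
        # one corpus pair, 500 exchangeable null terms at base rate 0.1
        vocab = [f"n{i:03d}" for i in range(500)]
        ret, bg = dg.gen_corpus_pair(200, vocab, {}, base_rate=0.1, seed=101)
        results = enrich_drugs(ret, bg, set(vocab), n_samples=100, seed=101)
        for alpha in (0.01, 0.05):
            frac = sum(r.p_value < alpha for r in results) / len(results)
            se = math.sqrt(alpha * (1 - alpha) / len(results))
            assert abs(frac - alpha) <= 3 * se, (alpha, frac)

    @pytest.mark.parametrize("seed", range(20))
    def test_planted_enrichment_power_over_seed_panel(self, seed):
        vocab = [f"d{i}" for i in range(30)]
        ret, bg = dg.gen_corpus_pair(
            200, vocab, {"d0": (0.6, 0.05)}, base_rate=0.1, seed=seed
        )
        results = enrich_drugs(ret, bg, set(vocab), n_samples=100, seed=seed)
        assert results[0].drug == "d0" and results[0].p_value < 1e-3
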