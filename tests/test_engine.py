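"""Counting engine: dedup counts, co-occurrence, ranking, breadth, trends."""

import random

import pytest
from hypothesis import given, strategies as st

from mirlit.engine import (
    Ranking,
    aggregate_counts,
    breadth,
    count_cooccurrence,
    count_mirna_articles,
    run_pipeline,
    top_k,
    yearly_trend,
)
from mirlit.fixtures import FixtureSpec, generate_corpus_object
from mirlit.medline import CitationRecord, Corpus


def _corpus(texts, label="c", years=None, pub_types=None):
    records = []
    for i, text in enumerate(texts):
        records.append(CitationRecord(
            pmid=str(i + 1), title=text,
            year=None if years is None else years[i],
            pub_types=["Journal Article"] if pub_types is None else list(pub_types[i]),
        ))
    return Corpus(label=label, records=records)


class TestCountMirnaArticles:
    def test_once_per_article(self):
        c = _corpus([
            "miR-155 regulates miR-155 targets",   # two mentions, one article
            "a study of miR-155",
            "no mention here",
        ])
        assert count_mirna_articles(c) == {"miR-155": 2}

    def test_empty_corpus(self):
        assert count_mirna_articles(Corpus(label="e")) == {}

    def test_matches_generator_truth(self, small_corpus):
        corpus, truth = small_corpus
        assert count_mirna_articles(corpus) == truth.family_counts(include_reviews=True)


class TestCooccurrence:
    def test_single_record_pairs(self, dicts):
        c = _corpus(["miR-146 suppresses inflammation in fibroblasts"])
        m = count_cooccurrence(c, dicts)
        assert m.cell("miR-146", "process", "inflammation") == 1
        assert m.cell("miR-146", "cell_type", "fibroblast") == 1
        assert m.cell("miR-146", "cytokine", "IL-6") == 0

    def test_empty_corpus_all_zero(self, dicts):
        m = count_cooccurrence(Corpus(label="e"), dicts)
        assert m.counts.values.sum() == 0 if m.counts.size else True
        assert m.row_families == []

    def test_family_restriction_limits_rows(self, dicts):
        c = _corpus(["miR-146 and miR-21 in inflammation"])
        m = count_cooccurrence(c, dicts, families=["miR-146"])
        assert m.row_families == ["miR-146"]
        assert m.cell("miR-146", "process", "inflammation") == 1

    def test_cells_bounded_by_marginals(self, dicts, small_corpus):
        corpus, _ = small_corpus
        m = count_cooccurrence(corpus, dicts)
        fam_counts = count_mirna_articles(corpus)
        from mirlit.dictionaries import match_all

        term_counts = {}
        for rec in corpus:
            for col in match_all(rec.mining_text(), dicts):
                term_counts[col] = term_counts.get(col, 0) + 1
        for f in m.row_families:
            for col in m.col_terms:
                cell = int(m.counts.loc[f, col])
                assert cell <= min(fam_counts[f], term_counts.get(col, 0))
                assert cell <= len(corpus)

    def test_matches_generator_truth(self, dicts, small_corpus):
        corpus, truth = small_corpus
        m = count_cooccurrence(corpus, dicts)
        want = truth.cooccurrence_counts(include_reviews=True)
        got = {
            (f, cat, term): int(m.counts.loc[f, (cat, term)])
            for f in m.row_families for cat, term in m.col_terms
            if int(m.counts.loc[f, (cat, term)])
        }
        assert got == want

    def test_long_form_table_round(self, dicts):
        c = _corpus(["miR-21 and IL-6 in fibroblasts"])
        m = count_cooccurrence(c, dicts)
        long = m.to_long()
        assert set(long.columns) == {"family", "category", "term", "count"}
        row = long[(long.family == "miR-21") & (long.term == "IL-6")]
        assert row["count"].tolist() == [1]


class TestTopK:
    def test_paper_shaped_ordering(self):
        counts = {"miR-146": 94, "miR-155": 77, "miR-223": 37, "miR-21": 29}
        r = top_k(counts, k=2)
        assert r.families == ["miR-146", "miR-155"]
        assert r.entries == [("miR-146", 94), ("miR-155", 77)]

    def test_tie_broken_by_ascending_family_index(self):
        r = top_k({"miR-5": 3, "miR-2": 3}, k=1)
        assert r.families == ["miR-2"]

    def test_empty_counts(self):
        assert top_k({}, k=4).entries == []

    def test_zero_counts_never_appear(self):
        r = top_k({"miR-1": 0, "miR-2": 2}, k=5)
        assert r.families == ["miR-2"]

    def test_k_below_one_rejected(self):
        with pytest.raises(ValueError):
            top_k({"miR-1": 1}, k=0)

    def test_stable_under_removal_outside_top_k_plus_one(self):
        counts = {"miR-1": 10, "miR-2": 8, "miR-3": 6, "miR-4": 4, "miR-5": 2}
        k = 2
        reduced = {f: c for f, c in counts.items() if f != "miR-5"}
        assert top_k(counts, k).entries == top_k(reduced, k).entries


class TestBreadth:
    def _ranking(self, label, families, k=7):
        return Ranking(corpus_label=label, k=k,
                       entries=[(f, 1) for f in families])

    def test_present_in_all(self):
        rankings = [self._ranking(str(i), ["miR-146", "miR-155"]) for i in range(9)]
        assert breadth(rankings)["miR-146"] == 9

    def test_absent_family_not_reported(self):
        rankings = [self._ranking("a", ["miR-1"]), self._ranking("b", ["miR-2"])]
        assert "miR-3" not in breadth(rankings)

    def test_partial_membership(self):
        rankings = [self._ranking("a", ["miR-1"]), self._ranking("b", ["miR-1"]),
                    self._ranking("c", ["miR-2"])]
        assert breadth(rankings) == {"miR-1": 2, "miR-2": 1}

    def test_mixed_k_rejected(self):
        with pytest.raises(ValueError):
            breadth([self._ranking("a", ["miR-1"], k=7),
                     self._ranking("b", ["miR-1"], k=5)])


class TestAggregateAndTrend:
    def test_elementwise_sum(self):
        total = aggregate_counts([{"miR-21": 29}, {"miR-21": 39, "miR-9": 1}])
        assert total == {"miR-21": 68, "miR-9": 1}

    def test_single_corpus_identity(self):
        assert aggregate_counts([{"miR-1": 3}]) == {"miR-1": 3}

    def test_all_empty(self):
        assert aggregate_counts([{}, {}]) == {}

    def test_yearly_trend_counts(self):
        c = _corpus(["a", "b", "c"], years=[2020, 2020, 2022])
        assert yearly_trend(c).year_counts == {2020: 2, 2022: 1}

    def test_records_without_year_excluded(self):
        c = _corpus(["a", "b"], years=[None, 1999])
        series = yearly_trend(c)
        assert series.year_counts == {1999: 1}
        assert sum(series.year_counts.values()) == 1

    def test_empty_corpus(self):
        assert yearly_trend(Corpus(label="e")).year_counts == {}

    def test_matches_generator_truth(self, small_corpus):
        corpus, truth = small_corpus
        assert yearly_trend(corpus).year_counts == truth.year_counts(include_reviews=True)


class TestInvariants:
    @given(seed=st.integers(min_value=0, max_value=2**31 - 1))
    def test_permutation_invariance(self, dicts, seed):
        spec = FixtureSpec(
            seed=seed, n_records=30,
            family_probs={"miR-146": 0.5, "miR-21": 0.3, "miR-9": 0.2},
            term_probs={("cytokine", "IL-1"): 0.3, ("process", "pain"): 0.3},
            review_prob=0.2, surface_noise=True,
        )
        corpus, _ = generate_corpus_object(spec)
        shuffled = Corpus(label=corpus.label, records=list(corpus.records))
        random.Random(seed ^ 0x5A5A).shuffle(shuffled.records)

        assert count_mirna_articles(corpus) == count_mirna_articles(shuffled)
        m1 = count_cooccurrence(corpus, dicts)
        m2 = count_cooccurrence(shuffled, dicts)
        assert m1.counts.sort_index().equals(m2.counts.sort_index())
        assert yearly_trend(corpus).year_counts == yearly_trend(shuffled).year_counts

    def test_duplicating_mention_changes_nothing(self):
        base = _corpus(["miR-21 in fibroblasts"])
        doubled = _corpus(["miR-21 and miR-21 again in fibroblasts"])
        assert count_mirna_articles(base) == count_mirna_articles(doubled)

    def test_duplicating_record_increments_by_one(self, dicts):
        text = "miR-21 drives inflammation"
        one = _corpus([text])
        two = _corpus([text, text])
        assert count_mirna_articles(two)["miR-21"] == count_mirna_articles(one)["miR-21"] + 1
        m1 = count_cooccurrence(one, dicts)
        m2 = count_cooccurrence(two, dicts)
        assert (m2.cell("miR-21", "process", "inflammation")
                == m1.cell("miR-21", "process", "inflammation") + 1)


class TestRunPipeline:
    def test_requires_a_corpus(self):
        with pytest.raises(ValueError):
            run_pipeline([])

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError):
            run_pipeline([Corpus(label="x"), Corpus(label="x")])

    def test_bundle_structure_and_determinism(self, dicts, nine_corpora):
        corpora, _ = nine_corpora
        b1 = run_pipeline(corpora, dicts=dicts)
        b2 = run_pipeline(corpora, dicts=dicts)
        assert len(b1.rankings) == len(b1.matrices) == len(b1.trends) == 9
        assert all(len(r.entries) <= 7 for r in b1.rankings.values())
        for label in b1.corpus_labels:
            assert b1.rankings[label].entries == b2.rankings[label].entries
            assert b1.matrices[label].counts.equals(b2.matrices[label].counts)
        assert b1.aggregate == b2.aggregate
        assert b1.breadth_map == b2.breadth_map

    def test_reviews_filtered_by_default(self, small_corpus):
        corpus, truth = small_corpus
        bundle = run_pipeline([corpus])
        assert bundle.counts["small"] == truth.family_counts(include_reviews=False)
        kept = run_pipeline([corpus], keep_reviews=True)
        assert kept.counts["small"] == truth.family_counts(include_reviews=True)

    def test_matrix_rows_are_top_k_families(self, nine_corpora, dicts):
        corpora, _ = nine_corpora
        bundle = run_pipeline(corpora, dicts=dicts)
        for label in bundle.corpus_labels:
            assert bundle.matrices[label].row_families == bundle.rankings[label].families

    def test_shared_pmid_diagnostic(self):
        a = _corpus(["miR-1 one"], label="a")
        b = _corpus(["miR-1 one"], label="b")  # same pmid "1" in both
        bundle = run_pipeline([a, b])
        assert bundle.shared_pmids == {"1": 2}
        assert bundle.aggregate["miR-1"] == 2  # counted once per corpus

    def test_bundle_write_is_deterministic(self, tmp_path, nine_corpora, dicts):
        corpora, _ = nine_corpora
        bundle = run_pipeline(corpora, dicts=dicts)
        out1, out2 = tmp_path / "r1", tmp_path / "r2"
        paths1 = bundle.write(str(out1))
        bundle.write(str(out2))
        assert len(paths1) == 9 * 3 + 3
        for p1 in paths1:
            p2 = str(p1).replace(str(out1), str(out2))
            assert open(p1, "rb").read() == open(p2, "rb").read()
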