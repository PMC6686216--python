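import math

import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_bundle, lexicon_of, ontology_of, sent
from ontorisk.corpus import CASE, Corpus, PatientRecord, Section, Sentence
from ontorisk.enrichment import (
    NegationLexicon,
    OntologyTermRanker,
    consistency,
    consistency_moments,
    count_statements,
    neighbor_entropy,
    rank_terms,
    term_weight,
)
from ontorisk.ontology import OntologyTerm, merge

LEX = NegationLexicon()
EN_LEX = NegationLexicon(cues=frozenset({"no", "denies"}))


def section_of(*clauses):
    return Section(
        name="S",
        sentences=[Sentence(tokens=tuple(c.split()), raw=c) for c in clauses],
    )


class TestCountStatements:
    def test_cue_before_term_is_negative(self):
        assert count_statements([section_of("无 发热")], "发热", LEX) == (0, 1)

    def test_no_cue_is_positive(self):
        assert count_statements([section_of("发热 3 天")], "发热", LEX) == (1, 0)

    def test_three_clause_enumeration(self):
        sec = section_of("无 发热", "发热", "否认 发热")
        assert count_statements([sec], "发热", LEX) == (1, 2)

    def test_cue_after_term_does_not_negate(self):
        assert count_statements([section_of("发热 无 咳嗽")], "发热", LEX) == (1, 0)

    def test_negation_does_not_cross_clauses(self):
        sec = Section(
            name="S",
            sentences=[
                Sentence(tokens=("无", "咳嗽"), raw="无 咳嗽"),
                Sentence(tokens=("发热",), raw="发热"),
            ],
        )
        assert count_statements([sec], "发热", LEX) == (1, 0)


class TestConsistency:
    @pytest.mark.parametrize(
        "n_pos,n_neg,expected",
        [(5, 0, 1.0), (2, 2, 0.0), (3, 1, 2 / 3), (0, 0, 0.0), (0, 4, 1.0)],
    )
    def test_values(self, n_pos, n_neg, expected):
        assert consistency(n_pos, n_neg) == pytest.approx(expected, abs=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            consistency(-1, 0)

    @settings(derandomize=True, max_examples=100)
    @given(n_pos=st.integers(0, 50), n_neg=st.integers(0, 50))
    def test_sign_symmetric_and_bounded(self, n_pos, n_neg):
        c = consistency(n_pos, n_neg)
        assert 0.0 <= c <= 1.0
        # flipping every statement from positive to negative changes nothing
        assert c == consistency(n_neg, n_pos)


class TestConsistencyMoments:
    def test_all_ones(self):
        assert consistency_moments([1, 1, 1]) == (1.0, 0.0)

    def test_two_values_sample_sd(self):
        mean, sd = consistency_moments([1, 0])
        assert mean == pytest.approx(0.5)
        assert sd == pytest.approx(math.sqrt(0.5), abs=1e-4)  # 0.7071

    def test_single_patient_sd_zero(self):
        assert consistency_moments([0.6]) == (0.6, 0.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            consistency_moments([])


class TestNeighborEntropy:
    def test_single_neighbor(self):
        assert neighbor_entropy({"a": 1}) == (0.0, 1.0)

    def test_uniform_two_outcomes(self):
        s, pen = neighbor_entropy({"a": 1, "b": 1})
        assert s == pytest.approx(math.log(2), abs=1e-12)
        assert pen == pytest.approx(1 / (1 + math.log(2)), abs=1e-4)  # 0.5906

    def test_three_outcomes(self):
        s, pen = neighbor_entropy({"a": 2, "b": 1, "c": 1})
        expected = -(0.5 * math.log(0.5) + 0.25 * math.log(0.25) * 2)
        assert s == pytest.approx(expected, abs=1e-12)  # 1.0397
        assert pen == pytest.approx(1 / (1 + expected), abs=1e-4)  # 0.4903

    def test_no_neighbors(self):
        assert neighbor_entropy({}) == (0.0, 1.0)

    @settings(derandomize=True, max_examples=60)
    @given(st.dictionaries(st.text("ab", min_size=1, max_size=2), st.integers(1, 9), max_size=6))
    def test_entropy_nonnegative_penalty_in_unit_interval(self, counts):
        s, pen = neighbor_entropy(counts)
        assert s >= 0.0
        assert 0.0 < pen <= 1.0


class TestTermWeight:
    def test_worked_product(self):
        assert term_weight(0.01, 0.1, 0.5, 1.0, 0.0) == pytest.approx(0.005)

    def test_fdoc_one_zeroes_weight(self):
        assert term_weight(0.9, 1.0, 0.3, 1.0, 2.0) == 0.0

    def test_second_worked_product(self):
        assert term_weight(0.02, 0.01, 1.0, 0.5, 0.5) == pytest.approx(0.03)

    @pytest.mark.parametrize("bad", [0.0, -0.2, 1.5])
    def test_fdoc_out_of_range(self, bad):
        with pytest.raises(ValueError):
            term_weight(0.1, bad, 1.0, 1.0, 0.0)

    def test_penalty_monotonicity(self):
        # more diverse neighbors -> larger entropy -> never a larger weight
        s_lo, pen_lo = neighbor_entropy({"a": 4})
        s_hi, pen_hi = neighbor_entropy({"a": 1, "b": 1, "c": 1, "d": 1})
        assert s_hi > s_lo
        w_lo = term_weight(0.01, 0.2, pen_lo, 0.8, 0.1)
        w_hi = term_weight(0.01, 0.2, pen_hi, 0.8, 0.1)
        assert w_hi < w_lo


def _record(pid, label, clauses):
    return PatientRecord(
        patient_id=pid,
        label=label,
        documents={},
        sections={"S": [section_of(*clauses)]},
    )


class TestRankTerms:
    def test_planted_term_ranks_top5(self, small_corpus, small_ontology, small_lexicon):
        ranked = rank_terms(
            small_corpus, small_ontology, "Admitting Diagnosis", CASE, small_lexicon
        )
        assert "embolus" in ranked.top(5)

    def test_k_larger_than_vocabulary(self, small_corpus, small_ontology, small_lexicon):
        full = rank_terms(
            small_corpus, small_ontology, "Chief Complaint", CASE, small_lexicon, top_k=10**6
        )
        clipped = rank_terms(
            small_corpus, small_ontology, "Chief Complaint", CASE, small_lexicon, top_k=5
        )
        assert len(clipped.entries) == 5
        assert full.terms()[:5] == clipped.terms()

    def test_ubiquitous_word_gets_zero_weight(self):
        # a filler in every section instance has F_doc = 1 hence W_o = 0
        onto = merge([[OntologyTerm("filler", frozenset({"X"})), OntologyTerm("rare", frozenset({"X"}))]])
        records = [
            _record("a", "case", ["filler x rare"]),
            _record("b", "case", ["filler y"]),
            _record("c", "control", ["filler z"]),
        ]
        ranked = rank_terms(Corpus(records=records), onto, "S", CASE, EN_LEX)
        by_term = {e.term: e for e in ranked.entries}
        assert by_term["filler"].w_o == 0.0
        assert by_term["rare"].w_o > 0.0
        assert ranked.terms()[0] == "rare"

    def test_common_word_demoted_relative_to_tfidf(self):
        # "maybe"-style filler: decent TF-IDF but promiscuous neighbors and
        # inconsistent statements; the professional term wins under W_o
        # while losing under bare TF-IDF.
        onto = merge(
            [[OntologyTerm("maybe", frozenset({"X"})), OntologyTerm("embolism", frozenset({"X"}))]]
        )
        records = []
        for i in range(8):
            if i == 7:  # one instance without the filler keeps F_doc < 1
                clauses = ["alpha beta gamma delta epsilon"]
            else:
                clauses = ["alpha maybe beta maybe gamma", "no maybe epsilon zeta eta"]
            if i == 0:  # embolism: rare, stereotyped, always positive
                clauses.append("embolism")
            records.append(_record(f"p{i}", "case" if i < 4 else "control", clauses))
        ranked = rank_terms(Corpus(records=records), onto, "S", CASE, EN_LEX)
        by_term = {e.term: e for e in ranked.entries}
        tfidf = {t: e.f_word * math.log10(1 / e.f_doc) for t, e in by_term.items()}
        assert tfidf["maybe"] > tfidf["embolism"]
        assert by_term["maybe"].w_o < by_term["embolism"].w_o

    def test_progress_note_instances_pool_as_one_section(
        self, small_corpus, small_ontology, small_lexicon
    ):
        ranked = rank_terms(
            small_corpus, small_ontology, "Progress Note", CASE, small_lexicon
        )
        # F_doc denominator counts every dated entry as an instance
        n_instances = sum(
            len(r.sections.get("Progress Note", [])) for r in small_corpus.records
        )
        for e in ranked.entries:
            assert 0 < e.f_doc <= 1
            assert round(e.f_doc * n_instances) == pytest.approx(e.f_doc * n_instances)


class TestRanker:
    def test_fit_produces_both_cohorts(self, small_corpus, small_ontology, small_lexicon):
        ranker = OntologyTermRanker(
            ontology=small_ontology, lexicon=small_lexicon, top_k=50
        ).fit(small_corpus)
        assert set(ranker.sections_) >= {"Admitting Diagnosis", "Progress Note"}
        case_list = ranker.rankings_[("Admitting Diagnosis", "case")]
        ctrl_list = ranker.rankings_[("Admitting Diagnosis", "control")]
        assert case_list.terms() != ctrl_list.terms()

    def test_ranker_matches_rank_terms(self, small_corpus, small_ontology, small_lexicon):
        ranker = OntologyTermRanker(
            ontology=small_ontology, lexicon=small_lexicon, top_k=30
        ).fit(small_corpus)
        direct = rank_terms(
            small_corpus, small_ontology, "Admitting Diagnosis", CASE, small_lexicon, top_k=30
        )
        assert ranker.rankings_[("Admitting Diagnosis", CASE)].terms() == direct.terms()
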