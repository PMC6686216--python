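import pickle

import numpy as np
import pytest

from conftest import lexicon_of, make_bundle, ontology_of
from ontorisk.corpus import CASE
from ontorisk.embedding import SkipGramEmbedding
from ontorisk.enrichment import OntologyTermRanker
from ontorisk.risk import (
    EvalProtocol,
    GreedySectionSelector,
    GreedyTermSelector,
    RiskModel,
    evaluate,
    pooled_vectors,
    score_sections,
    term_presence,
)
from ontorisk.synthetic import GeneratorSpec, PlantedTerm, generate

LR = EvalProtocol(classifier="lr", seed=0)


def pipeline_fixture(bundle, dim=8, top_k=30, seed=0):
    corpus = bundle.parsed_corpus()
    ranker = OntologyTermRanker(
        ontology=ontology_of(bundle), lexicon=lexicon_of(bundle), top_k=top_k
    ).fit(corpus)
    emb = SkipGramEmbedding(vector_size=dim, epochs=2, seed=seed).fit(corpus)
    term_sets = {s: ranker.top_terms(s, CASE) for s in ranker.sections_}
    term_sets = {s: t for s, t in term_sets.items() if t}
    return corpus, emb, term_sets


class TestEvaluate:
    def test_separable_features_reach_auc_one(self):
        rng = np.random.default_rng(0)
        y = np.array([0, 1] * 100)
        X = np.c_[y + 0.01 * rng.standard_normal(200), rng.standard_normal(200)]
        mean, sd = evaluate(X, y, LR)
        assert mean == pytest.approx(1.0, abs=1e-9)
        assert sd == pytest.approx(0.0, abs=1e-9)

    def test_independent_labels_near_half(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((600, 6))
        y = np.array([0, 1] * 300)
        mean, _ = evaluate(X, y, LR)
        assert 0.35 < mean < 0.65

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((200, 4))
        y = np.array([0, 1] * 100)
        assert evaluate(X, y, LR) == evaluate(X, y, LR)

    def test_gbdt_protocol_runs(self):
        rng = np.random.default_rng(3)
        y = np.array([0, 1] * 60)
        X = np.c_[y + 0.1 * rng.standard_normal(120)]
        mean, _ = evaluate(X, y, EvalProtocol(classifier="gbdt", seed=0))
        assert mean > 0.95

    def test_unknown_classifier_rejected(self):
        with pytest.raises(ValueError):
            evaluate(np.zeros((10, 1)), [0, 1] * 5, EvalProtocol(classifier="nope"))


@pytest.fixture(scope="module")
def single_signal():
    bundle = generate(
        GeneratorSpec(
            n_case=75,
            n_control=75,
            seed=4,
            planted_terms=[PlantedTerm("embolus", "Admitting Diagnosis", 0.9, 0.1, 0.0)],
        )
    )
    return pipeline_fixture(bundle)


@pytest.fixture(scope="module")
def double_signal():
    return pipeline_fixture(make_bundle(seed=11, n_case=75, n_control=75))


class TestScoreSections:
    def test_planted_section_wins_only_and_loses_exclusion(self, single_signal):
        corpus, emb, term_sets = single_signal
        scores = score_sections(corpus, term_sets, emb, LR)
        assert scores[0].section == "Admitting Diagnosis"
        worst_excl = min(scores, key=lambda s: s.auc_exclusion[0])
        assert worst_excl.section == "Admitting Diagnosis"

    def test_sorted_by_auc_only(self, single_signal):
        corpus, emb, term_sets = single_signal
        scores = score_sections(corpus, term_sets, emb, LR)
        onlys = [s.auc_only[0] for s in scores]
        assert onlys == sorted(onlys, reverse=True)

    def test_needs_two_sections(self, single_signal):
        corpus, emb, term_sets = single_signal
        with pytest.raises(ValueError):
            score_sections(corpus, {"X": ["t"]}, emb, LR)


class TestSectionSelection:
    def test_single_informative_section(self, single_signal):
        corpus, emb, term_sets = single_signal
        sel = GreedySectionSelector(embedding=emb, term_sets=term_sets, protocol=LR).fit(corpus)
        assert sel.selected_sections_[0] == "Admitting Diagnosis"
        assert len(sel.trace_.steps) == len(sel.selected_sections_)

    def test_both_signal_sections_found(self, double_signal):
        corpus, emb, term_sets = double_signal
        sel = GreedySectionSelector(embedding=emb, term_sets=term_sets, protocol=LR).fit(corpus)
        assert {"Admitting Diagnosis", "Progress Note"} <= set(sel.selected_sections_)

    def test_trace_auc_is_monotone_under_mean_stopping(self, double_signal):
        corpus, emb, term_sets = double_signal
        sel = GreedySectionSelector(embedding=emb, term_sets=term_sets, protocol=LR).fit(corpus)
        means = [m for _, m, _ in sel.trace_.steps]
        assert all(b > a for a, b in zip(means, means[1:]))

    def test_deterministic(self, double_signal):
        corpus, emb, term_sets = double_signal
        a = GreedySectionSelector(embedding=emb, term_sets=term_sets, protocol=LR).fit(corpus)
        b = GreedySectionSelector(embedding=emb, term_sets=term_sets, protocol=LR).fit(corpus)
        assert a.trace_.steps == b.trace_.steps


@pytest.fixture(scope="module")
def small_pool():
    bundle = generate(
        GeneratorSpec(
            n_case=60,
            n_control=60,
            seed=6,
            n_background=9,
            planted_terms=[PlantedTerm("embolus", "Admitting Diagnosis", 1.0, 0.0, 0.0)],
        )
    )
    corpus, emb, term_sets = pipeline_fixture(bundle, top_k=20)
    return corpus, emb, term_sets["Admitting Diagnosis"]


class TestTermSelection:
    def test_perfect_term_chosen_first_and_kept(self, small_pool):
        corpus, emb, pool = small_pool
        sel = GreedyTermSelector(
            embedding=emb, sections=["Admitting Diagnosis"], term_pool=pool, protocol=LR
        ).fit(corpus)
        assert sel.order_[0] == "embolus"
        assert "embolus" in sel.optimal_terms_
        assert len(sel.order_) == len(pool)

    def test_singleton_pool(self, small_pool):
        corpus, emb, _ = small_pool
        sel = GreedyTermSelector(
            embedding=emb, sections=["Admitting Diagnosis"], term_pool=["embolus"], protocol=LR
        ).fit(corpus)
        assert sel.optimal_terms_ == ["embolus"]

    def test_deterministic_path(self, small_pool):
        corpus, emb, pool = small_pool
        a = GreedyTermSelector(
            embedding=emb, sections=["Admitting Diagnosis"], term_pool=pool, protocol=LR
        ).fit(corpus)
        b = GreedyTermSelector(
            embedding=emb, sections=["Admitting Diagnosis"], term_pool=pool, protocol=LR
        ).fit(corpus)
        assert a.order_ == b.order_
        np.testing.assert_array_equal(a.path_auc_, b.path_auc_)

    def test_empty_pool_rejected(self, small_pool):
        corpus, emb, _ = small_pool
        with pytest.raises(ValueError):
            GreedyTermSelector(embedding=emb, sections=["X"], term_pool=[], protocol=LR).fit(corpus)


class TestPooledVectors:
    def test_matches_vectorizer_semantics(self, single_signal):
        corpus, emb, term_sets = single_signal
        from ontorisk.representation import represent_patient

        terms = sorted(term_sets["Admitting Diagnosis"])[:10]
        terms = [t for t in terms if t in emb]
        present = term_presence(corpus, ["Admitting Diagnosis"], terms)
        vecs = np.vstack([emb[t] for t in terms])
        X = pooled_vectors(present, vecs, list(range(len(terms))))
        for i, rec in enumerate(corpus.records[:20]):
            expected = represent_patient(rec, {"Admitting Diagnosis": terms}, emb)
            np.testing.assert_allclose(X[i], expected, rtol=1e-12, atol=1e-15)


class TestRiskModel:
    def test_separable_corpus_perfect_metrics(self):
        bundle = generate(
            GeneratorSpec(
                n_case=60,
                n_control=60,
                seed=8,
                planted_terms=[PlantedTerm("embolus", "Admitting Diagnosis", 1.0, 0.0, 0.0)],
            )
        )
        corpus, emb, _ = pipeline_fixture(bundle)
        model = RiskModel(
            embedding=emb,
            sections=["Admitting Diagnosis"],
            terms=["embolus"],
            protocol=EvalProtocol(classifier="gbdt", seed=0),
        ).fit(corpus)
        assert model.auroc_ == pytest.approx(1.0)
        assert model.sensitivity_ == pytest.approx(1.0)
        assert model.specificity_ == pytest.approx(1.0)

    def test_pickle_round_trip_scores_identical(self, single_signal):
        corpus, emb, term_sets = single_signal
        model = RiskModel(
            embedding=emb,
            sections=["Admitting Diagnosis"],
            terms=term_sets["Admitting Diagnosis"][:10],
            protocol=LR,
        ).fit(corpus)
        clone = pickle.loads(pickle.dumps(model))
        np.testing.assert_array_equal(
            model.predict_proba(corpus), clone.predict_proba(corpus)
        )

    def test_label_permutation_destroys_signal(self, single_signal):
        corpus, emb, term_sets = single_signal
        X = None
        rng = np.random.default_rng(12)
        y = np.asarray(corpus.labels())
        y_perm = rng.permutation(y)
        from ontorisk.representation import PatientVectorizer

        X = (
            PatientVectorizer(embedding=emb, term_sets={"Admitting Diagnosis": term_sets["Admitting Diagnosis"]})
            .fit(corpus)
            .transform(corpus)
        )
        mean_true, _ = evaluate(X, y, LR)
        mean_perm, _ = evaluate(X, y_perm, LR)
        assert mean_true > 0.8
        assert 0.3 < mean_perm < 0.7
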