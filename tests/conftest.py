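import pytest

from ontorisk.corpus import Sentence
from ontorisk.enrichment import NegationLexicon
from ontorisk.embedding import SkipGramEmbedding
from ontorisk.ontology import OntologyTerm, merge
from ontorisk.synthetic import GeneratorSpec, PlantedTerm, generate


def make_bundle(seed=7, n_case=30, n_control=30, **kw):
    spec = GeneratorSpec(
        n_case=n_case,
        n_control=n_control,
        seed=seed,
        planted_terms=[
            PlantedTerm("embolus", "Admitting Diagnosis", 0.9, 0.1, 0.0),
            PlantedTerm("dyspnea", "Progress Note", 0.8, 0.2, 0.3),
        ],
        **kw,
    )
    return generate(spec)


def ontology_of(bundle):
    return merge(
        [[OntologyTerm(t, frozenset({"synthetic"})) for t in bundle.ontology_terms]]
    )


def lexicon_of(bundle):
    return NegationLexicon(cues=frozenset(bundle.negation_cues))


@pytest.fixture(scope="session")
def small_bundle():
    return make_bundle()


@pytest.fixture(scope="session")
def small_corpus(small_bundle):
    return small_bundle.parsed_corpus()


@pytest.fixture(scope="session")
def small_ontology(small_bundle):
    return ontology_of(small_bundle)


@pytest.fixture(scope="session")
def small_lexicon(small_bundle):
    return lexicon_of(small_bundle)


@pytest.fixture(scope="session")
def small_embedding(small_corpus):
    return SkipGramEmbedding(vector_size=8, epochs=2, seed=3).fit(small_corpus)


def sent(*tokens):
    return Sentence(tokens=tuple(tokens), raw=" ".join(tokens))
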