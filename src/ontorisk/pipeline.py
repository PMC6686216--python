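"""End-to-end orchestration: ranking -> embedding -> selection -> model.

One call runs the whole construction on a parsed corpus: rank ontology
terms per section from the case cohort, train the universal skip-gram
embedding, score sections by AUC(Only)/AUC(Exclusion), greedily select
sections then terms, and fit the final risk classifier on the optimal term
subset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ontorisk.corpus import CASE, Corpus
from ontorisk.embedding import SkipGramEmbedding
from ontorisk.enrichment import NegationLexicon, OntologyTermRanker
from ontorisk.ontology import OntologySet
from ontorisk.risk import (
    EvalProtocol,
    GreedySectionSelector,
    GreedyTermSelector,
    RiskModel,
    SectionScore,
    score_sections,
)

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    ranker: OntologyTermRanker
    embedding: SkipGramEmbedding
    term_sets: dict[str, list[str]]
    section_scores: list[SectionScore]
    section_selector: GreedySectionSelector
    term_selector: GreedyTermSelector | None
    model: RiskModel | None
    metrics: dict[str, float] = field(default_factory=dict)


def run_pipeline(
    corpus: Corpus,
    ontology: OntologySet,
    lexicon: NegationLexicon | None = None,
    *,
    vector_size: int = 100,
    epochs: int = 3,
    window: int = 5,
    top_k: int = 300,
    selection_protocol: EvalProtocol | None = None,
    final_protocol: EvalProtocol | None = None,
    embed_seed: int = 0,
    select_terms: bool = True,
    train_final: bool = True,
) -> PipelineResult:
    """Run the full model construction and return every fitted stage.

    ``selection_protocol`` drives section scoring and both greedy searches;
    ``final_protocol`` (GBDT by default) drives the held-out final model.
    """
    selection_protocol = selection_protocol or EvalProtocol()
    final_protocol = final_protocol or EvalProtocol(seed=selection_protocol.seed)
    ranker = OntologyTermRanker(
        ontology=ontology, lexicon=lexicon, window=window, top_k=top_k
    ).fit(corpus)
    embedding = SkipGramEmbedding(
        vector_size=vector_size, epochs=epochs, seed=embed_seed
    ).fit(corpus)
    term_sets = {s: ranker.top_terms(s, CASE) for s in ranker.sections_}
    term_sets = {s: t for s, t in term_sets.items() if t}
    scores = score_sections(corpus, term_sets, embedding, selection_protocol)
    section_selector = GreedySectionSelector(
        embedding=embedding, term_sets=term_sets, protocol=selection_protocol
    ).fit(corpus)
    chosen = section_selector.selected_sections_

    term_selector = None
    model = None
    metrics: dict[str, float] = {}
    if select_terms:
        pool = sorted({t for s in chosen for t in term_sets[s]})
        term_selector = GreedyTermSelector(
            embedding=embedding,
            sections=chosen,
            term_pool=pool,
            protocol=selection_protocol,
        ).fit(corpus)
    if train_final:
        terms = (
            term_selector.optimal_terms_
            if term_selector is not None
            else sorted({t for s in chosen for t in term_sets[s]})
        )
        model = RiskModel(
            embedding=embedding,
            sections=chosen,
            terms=terms,
            protocol=final_protocol,
        ).fit(corpus)
        metrics = model.metrics()
    return PipelineResult(
        ranker=ranker,
        embedding=embedding,
        term_sets=term_sets,
        section_scores=scores,
        section_selector=section_selector,
        term_selector=term_selector,
        model=model,
        metrics=metrics,
    )
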