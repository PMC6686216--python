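"""Distributed patient representations from term embeddings.

A patient is represented by the concatenation ``X = [V  M]`` where ``V`` is
the mean and ``M`` the elementwise maximum of the embedding vectors of the
patient's matched ontology terms (the terms of the chosen section set that
occur in the patient's text and have a vector).  When several sections are
combined, one pooled mean/max is taken over all their terms together.  A
patient matching no term at all is the zero vector of length 2P.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from ontorisk.corpus import Corpus, PatientRecord
from ontorisk.embedding import SkipGramEmbedding
from ontorisk.ontology import normalize_term

__all__ = ["represent_patient", "PatientVectorizer"]


def _matched_vectors(
    record: PatientRecord,
    term_sets: Mapping[str, Iterable[str]],
    model: SkipGramEmbedding,
    unique: bool,
) -> list[np.ndarray]:
    vecs: list[np.ndarray] = []
    seen: set[str] = set()
    for section in sorted(term_sets):
        terms = {normalize_term(t) for t in term_sets[section]}
        for sec in record.sections.get(section, []):
            for sent in sec.sentences:
                for tok in sent.tokens:
                    key = normalize_term(tok)
                    if key not in terms:
                        continue
                    if unique:
                        if key in seen:
                            continue
                        seen.add(key)
                    v = model.get_vector(key)
                    if v is not None:
                        vecs.append(v)
    return vecs


def represent_patient(
    record: PatientRecord,
    term_sets: Mapping[str, Iterable[str]],
    model: SkipGramEmbedding,
    unique: bool = True,
) -> np.ndarray:
    """Build the length-2P vector ``[V  M]`` for one patient.

    ``term_sets`` maps section name -> terms of interest for that section.
    With ``unique=True`` (default) each distinct term contributes one
    vector; otherwise every occurrence contributes to the mean.
    """
    p = model.vector_size
    vecs = _matched_vectors(record, term_sets, model, unique)
    if not vecs:
        return np.zeros(2 * p)
    arr = np.asarray(vecs)
    return np.concatenate([arr.mean(axis=0), arr.max(axis=0)])


class PatientVectorizer(BaseEstimator, TransformerMixin):
    """Transform patient records into ``[mean  max]`` embedding vectors.

    Parameters
    ----------
    embedding : SkipGramEmbedding
        A fitted embedding model.
    term_sets : mapping section -> iterable of terms
        Which terms of which sections feed the representation.
    unique : bool, default True
        Count each distinct matched term once (term-set semantics) rather
        than once per occurrence.
    """

    def __init__(self, embedding=None, term_sets=None, unique=True):
        self.embedding = embedding
        self.term_sets = term_sets
        self.unique = unique

    def fit(self, X: Corpus | Sequence[PatientRecord], y=None):
        if self.embedding is None or self.term_sets is None:
            raise ValueError("PatientVectorizer requires an embedding and term_sets")
        self.n_features_out_ = 2 * self.embedding.vector_size
        return self

    def transform(self, X: Corpus | Sequence[PatientRecord]) -> np.ndarray:
        records = X.records if isinstance(X, Corpus) else list(X)
        return np.vstack(
            [
                represent_patient(rec, self.term_sets, self.embedding, self.unique)
                for rec in records
            ]
        )
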