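"""Skip-gram word embeddings with negative sampling.

One "universal" embedding model is trained on all sentences of both cohorts
combined.  Words with corpus frequency below ``min_count`` (default 2) are
omitted, the context window is 5, and training is the continuous skip-gram
objective with negative sampling (unigram^0.75 noise distribution).  The
inner SGD loop is numba-compiled, single-threaded and fully seeded, so two
runs with the same seed produce identical vectors.
"""

from __future__ import annotations

from collections import Counter
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from numba import njit
from sklearn.base import BaseEstimator

from ontorisk.corpus import Corpus

__all__ = ["SkipGramEmbedding", "corpus_sentences"]


@njit(cache=True)
def _sgns_epoch(w_in, w_out, centers, contexts, negatives, lr_start, lr_end):
    """One sequential pass of skip-gram negative-sampling SGD."""
    n, k = negatives.shape
    p = w_in.shape[1]
    for i in range(n):
        lr = lr_start + (lr_end - lr_start) * i / n
        c = centers[i]
        for t in range(k + 1):
            tgt = contexts[i] if t == 0 else negatives[i, t - 1]
            label = 1.0 if t == 0 else 0.0
            dot = 0.0
            for d in range(p):
                dot += w_in[c, d] * w_out[tgt, d]
            if dot > 16.0:
                dot = 16.0
            elif dot < -16.0:
                dot = -16.0
            g = (label - 1.0 / (1.0 + np.exp(-dot))) * lr
            for d in range(p):
                tmp = w_in[c, d]
                w_in[c, d] += g * w_out[tgt, d]
                w_out[tgt, d] += g * tmp


def corpus_sentences(corpus: Corpus) -> list[list[str]]:
    """All tokenized sentences of every section of every record, one pool."""
    out: list[list[str]] = []
    for rec in corpus:
        for secs in rec.sections.values():
            for sec in secs:
                for sent in sec.sentences:
                    out.append(list(sent.tokens))
    return out


class SkipGramEmbedding(BaseEstimator):
    """Train skip-gram word vectors on tokenized sentences.

    Parameters
    ----------
    vector_size : int, default 100
        Embedding dimension P.
    window : int, default 5
        Context half-width in tokens (fixed, clipped at sentence bounds).
    min_count : int, default 2
        Words rarer than this are dropped from the vocabulary.
    negative : int, default 5
        Negative samples per (center, context) pair.
    epochs : int, default 3
    alpha, min_alpha : float
        Initial and final learning rate (linear decay over updates).
    seed : int, default 0

    Attributes
    ----------
    vocab_ : dict[str, int]
        Word to row index.
    vectors_ : ndarray of shape (V, P)
        Input ("center") vectors; these are the word representations.
    counts_ : dict[str, int]
        Corpus frequency of each vocabulary word.
    """

    def __init__(
        self,
        vector_size: int = 100,
        window: int = 5,
        min_count: int = 2,
        negative: int = 5,
        epochs: int = 3,
        alpha: float = 0.025,
        min_alpha: float = 1e-4,
        seed: int = 0,
    ):
        self.vector_size = vector_size
        self.window = window
        self.min_count = min_count
        self.negative = negative
        self.epochs = epochs
        self.alpha = alpha
        self.min_alpha = min_alpha
        self.seed = seed

    # -- vocabulary ---------------------------------------------------------
    def _build_vocab(self, sentences: Sequence[Sequence[str]]) -> None:
        counts = Counter()
        for sent in sentences:
            counts.update(sent)
        kept = {w: c for w, c in counts.items() if c >= self.min_count}
        if not kept:
            raise ValueError(
                f"no word reaches min_count={self.min_count}; corpus too small"
            )
        # frequency-descending then lexicographic: deterministic indexing
        order = sorted(kept, key=lambda w: (-kept[w], w))
        self.vocab_ = {w: i for i, w in enumerate(order)}
        self.counts_ = {w: kept[w] for w in order}

    def _pairs(self, sentences: Sequence[Sequence[str]]) -> np.ndarray:
        centers: list[int] = []
        contexts: list[int] = []
        vocab = self.vocab_
        w = self.window
        for sent in sentences:
            idx = [vocab[t] for t in sent if t in vocab]
            n = len(idx)
            for i, c in enumerate(idx):
                lo = max(0, i - w)
                hi = min(n, i + w + 1)
                for j in range(lo, hi):
                    if j != i:
                        centers.append(c)
                        contexts.append(idx[j])
        return np.array([centers, contexts], dtype=np.int64).T

    # -- training -----------------------------------------------------------
    def fit(self, X: Corpus | Iterable[Sequence[str]], y=None):
        sentences = corpus_sentences(X) if isinstance(X, Corpus) else [list(s) for s in X]
        self._build_vocab(sentences)
        rng = np.random.default_rng(self.seed)
        v, p = len(self.vocab_), self.vector_size
        if p < 2:
            raise ValueError("vector_size must be >= 2")
        w_in = (rng.random((v, p)) - 0.5) / p
        w_out = np.zeros((v, p))

        counts = np.array(list(self.counts_.values()), dtype=float)
        noise = counts**0.75
        noise /= noise.sum()

        pairs = self._pairs(sentences)
        n_pairs = len(pairs)
        if n_pairs == 0:
            raise ValueError("no (center, context) pairs; corpus too small")
        k = self.negative
        for epoch in range(self.epochs):
            perm = rng.permutation(n_pairs)
            centers = np.ascontiguousarray(pairs[perm, 0])
            contexts = np.ascontiguousarray(pairs[perm, 1])
            negatives = rng.choice(v, size=(n_pairs, k), p=noise).astype(np.int64)
            lr_start = self.alpha + (self.min_alpha - self.alpha) * (epoch / self.epochs)
            lr_end = self.alpha + (self.min_alpha - self.alpha) * ((epoch + 1) / self.epochs)
            _sgns_epoch(w_in, w_out, centers, contexts, negatives, lr_start, lr_end)
        self.vectors_ = w_in
        return self

    # -- lookup -------------------------------------------------------------
    def __contains__(self, word: str) -> bool:
        return word in self.vocab_

    def __getitem__(self, word: str) -> np.ndarray:
        return self.vectors_[self.vocab_[word]]

    def get_vector(self, word: str) -> np.ndarray | None:
        i = self.vocab_.get(word)
        return None if i is None else self.vectors_[i]

    # -- persistence (word2vec text format) ---------------------------------
    def save_word2vec(self, path: str | Path) -> None:
        """``V P`` header then one ``word v1 ... vP`` line per word."""
        with Path(path).open("w", encoding="utf-8") as fh:
            fh.write(f"{len(self.vocab_)} {self.vector_size}\n")
            for word, i in self.vocab_.items():
                vec = " ".join(repr(float(x)) for x in self.vectors_[i])
                fh.write(f"{word} {vec}\n")

    @classmethod
    def load_word2vec(cls, path: str | Path) -> "SkipGramEmbedding":
        with Path(path).open(encoding="utf-8") as fh:
            v, p = (int(x) for x in fh.readline().split())
            model = cls(vector_size=p)
            vocab: dict[str, int] = {}
            vectors = np.empty((v, p))
            for i, line in enumerate(fh):
                parts = line.rstrip("\n").split(" ")
                vocab[parts[0]] = i
                vectors[i] = [float(x) for x in parts[1 : p + 1]]
        model.vocab_ = vocab
        model.vectors_ = vectors
        model.counts_ = {}
        return model
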