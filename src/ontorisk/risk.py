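"""Classifier harness, section importance and greedy section/term selection.

Model quality is always the cross-validated AUROC: a stratified 20% test
split is held out, and 5-fold cross-validation on the remaining 80% yields
the mean and standard deviation of AUC reported during selection.  A
section's direct value is AUC(Only) — a model on its terms alone — and its
marginal value AUC(Exclusion) — a model on the pooled terms of all other
sections.  Sections, then terms, are added greedily: each round every
remaining candidate is scored and the best improver kept.  The term path is
run to exhaustion, the (size -> mean AUC) curve smoothed with a centered
moving average, and the prefix at the smoothed maximum returned as the
optimal term subset.  The final model is a gradient-boosted tree classifier
on that subset, reported with held-out AUROC, sensitivity and specificity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.svm import SVC

from ontorisk.corpus import Corpus, PatientRecord
from ontorisk.embedding import SkipGramEmbedding
from ontorisk.ontology import normalize_term
from ontorisk.representation import PatientVectorizer

__all__ = [
    "EvalProtocol",
    "SectionScore",
    "SelectionTrace",
    "make_classifier",
    "evaluate",
    "score_sections",
    "GreedySectionSelector",
    "GreedyTermSelector",
    "RiskModel",
    "term_presence",
    "pooled_vectors",
]


@dataclass(frozen=True)
class EvalProtocol:
    """Fixed evaluation protocol: split, folds, metric, classifier, seed."""

    test_fraction: float = 0.2
    n_folds: int = 5
    classifier: str = "gbdt"  # gbdt | rf | lr | svm
    seed: int = 0
    # frozen GBDT hyperparameters (library defaults scaled for small corpora)
    gbdt_n_estimators: int = 100
    gbdt_max_depth: int = 3

    def with_seed(self, seed: int) -> "EvalProtocol":
        return replace(self, seed=seed)


def make_classifier(protocol: EvalProtocol):
    kind = protocol.classifier.lower()
    if kind == "gbdt":
        return GradientBoostingClassifier(
            n_estimators=protocol.gbdt_n_estimators,
            max_depth=protocol.gbdt_max_depth,
            random_state=protocol.seed,
        )
    if kind == "rf":
        return RandomForestClassifier(n_estimators=200, random_state=protocol.seed)
    if kind == "lr":
        return LogisticRegression(max_iter=1000, random_state=protocol.seed)
    if kind == "svm":
        return SVC(probability=True, random_state=protocol.seed)
    raise ValueError(f"unknown classifier kind {protocol.classifier!r}")


def train_pool_split(
    X: np.ndarray, y: np.ndarray, protocol: EvalProtocol
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Stratified (train pool, test) split at the protocol's test fraction."""
    return train_test_split(
        X,
        y,
        test_size=protocol.test_fraction,
        stratify=y,
        random_state=protocol.seed,
    )


def evaluate(
    X: np.ndarray,
    y: Sequence[int],
    protocol: EvalProtocol | None = None,
    holdout_test: bool = True,
) -> tuple[float, float]:
    """Cross-validated AUROC mean and sd under the protocol's fixed seed.

    With ``holdout_test`` (default) the stratified test fraction is split
    off first and cross-validation runs on the remaining training pool, so
    selection never sees the held-out patients.
    """
    if protocol is None:
        protocol = EvalProtocol()
    X = np.asarray(X)
    y = np.asarray(y)
    if holdout_test:
        X, _, y, _ = train_pool_split(X, y, protocol)
    skf = StratifiedKFold(n_splits=protocol.n_folds, shuffle=True, random_state=protocol.seed)
    aucs = []
    for tr, va in skf.split(X, y):
        if len(np.unique(y[va])) < 2:  # pragma: no cover - stratification prevents it
            raise ValueError("single-class validation fold; increase cohort sizes")
        clf = make_classifier(protocol)
        clf.fit(X[tr], y[tr])
        score = clf.predict_proba(X[va])[:, 1]
        aucs.append(roc_auc_score(y[va], score))
    aucs = np.asarray(aucs)
    return float(aucs.mean()), float(aucs.std(ddof=1))


# ---------------------------------------------------------------------------
# section importance

@dataclass(frozen=True)
class SectionScore:
    section: str
    auc_only: tuple[float, float]  # (mean, sd)
    auc_exclusion: tuple[float, float]


def _vectorize(
    corpus: Corpus,
    term_sets: Mapping[str, Iterable[str]],
    embedding: SkipGramEmbedding,
) -> np.ndarray:
    return PatientVectorizer(embedding=embedding, term_sets=dict(term_sets)).fit(corpus).transform(corpus)


def score_sections(
    corpus: Corpus,
    term_sets: Mapping[str, Sequence[str]],
    embedding: SkipGramEmbedding,
    protocol: EvalProtocol | None = None,
) -> list[SectionScore]:
    """AUC(Only) and AUC(Exclusion) per section, sorted by AUC(Only) desc.

    ``term_sets`` maps each section to its (top-K) terms.  Sections with an
    empty term list are skipped with a warning.
    """
    if protocol is None:
        protocol = EvalProtocol()
    if len(term_sets) < 2:
        raise ValueError("section scoring needs at least two sections")
    y = np.asarray(corpus.labels())
    scores: list[SectionScore] = []
    for section in sorted(term_sets):
        terms = list(term_sets[section])
        if not terms:
            import warnings

            warnings.warn(f"section {section!r} has no terms; skipped")
            continue
        only = evaluate(_vectorize(corpus, {section: terms}, embedding), y, protocol)
        others = {s: list(t) for s, t in term_sets.items() if s != section and len(t)}
        excl = evaluate(_vectorize(corpus, others, embedding), y, protocol)
        scores.append(SectionScore(section=section, auc_only=only, auc_exclusion=excl))
    scores.sort(key=lambda s: (-s.auc_only[0], s.section))
    return scores


# ---------------------------------------------------------------------------
# greedy selection

@dataclass
class SelectionTrace:
    """Ordered record of greedy additions with the AUC at each step."""

    steps: list[tuple[str, float, float]] = field(default_factory=list)  # (unit, mean, sd)
    chosen: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"step": i + 1, "unit": u, "mean_auc": m, "sd_auc": s}
                for i, (u, m, s) in enumerate(self.steps)
            ]
        )


class GreedySectionSelector(BaseEstimator):
    """Forward selection of sections by cross-validated AUROC.

    Each round re-pools the representation over the current section set plus
    one candidate, keeps the best improver, and stops when the stopping rule
    fires: ``stopping="mean"`` (default) stops when the best candidate does
    not increase the mean AUC; ``stopping="mean_or_sd"`` keeps adding while
    either the mean increases or the sd decreases.

    Attributes
    ----------
    selected_sections_ : list of str
    trace_ : SelectionTrace
    """

    def __init__(self, embedding=None, term_sets=None, protocol=None, stopping="mean"):
        self.embedding = embedding
        self.term_sets = term_sets
        self.protocol = protocol
        self.stopping = stopping

    def fit(self, corpus: Corpus, y=None):
        protocol = self.protocol or EvalProtocol()
        term_sets = {s: list(t) for s, t in self.term_sets.items() if len(t)}
        labels = np.asarray(corpus.labels())
        chosen: list[str] = []
        remaining = sorted(term_sets)
        trace = SelectionTrace()
        cur_mean, cur_sd = -np.inf, np.inf
        while remaining:
            best = None  # (-mean, section, sd)
            for section in remaining:
                pool = {s: term_sets[s] for s in chosen + [section]}
                mean, sd = evaluate(_vectorize(corpus, pool, self.embedding), labels, protocol)
                key = (-mean, section)
                if best is None or key < best[0]:
                    best = (key, section, mean, sd)
            _, section, mean, sd = best
            if self.stopping == "mean":
                stop = mean <= cur_mean
            elif self.stopping == "mean_or_sd":
                stop = mean <= cur_mean and sd >= cur_sd
            else:
                raise ValueError(f"unknown stopping rule {self.stopping!r}")
            if chosen and stop:
                break
            chosen.append(section)
            remaining.remove(section)
            trace.steps.append((section, mean, sd))
            cur_mean, cur_sd = mean, sd
        trace.chosen = list(chosen)
        self.trace_ = trace
        self.selected_sections_ = chosen
        return self


def term_presence(
    corpus: Corpus,
    sections: Sequence[str],
    terms: Sequence[str],
) -> np.ndarray:
    """Boolean (n_patients, n_terms) matrix: term occurs in the patient's
    instances of the given sections."""
    index = {normalize_term(t): j for j, t in enumerate(terms)}
    out = np.zeros((len(corpus.records), len(terms)), dtype=bool)
    for i, rec in enumerate(corpus.records):
        for section in sections:
            for sec in rec.sections.get(section, []):
                for sent in sec.sentences:
                    for tok in sent.tokens:
                        j = index.get(normalize_term(tok))
                        if j is not None:
                            out[i, j] = True
    return out


def pooled_vectors(
    present: np.ndarray, term_vectors: np.ndarray, subset: Sequence[int]
) -> np.ndarray:
    """``[mean  max]`` patient vectors for a term subset, from the presence
    matrix — equivalent to re-pooling the representation per patient."""
    sub = np.asarray(subset, dtype=int)
    mask = present[:, sub]  # (n, m)
    vecs = term_vectors[sub]  # (m, P)
    counts = mask.sum(axis=1)
    safe = np.maximum(counts, 1)[:, None]
    mean = (mask @ vecs) / safe
    neg_inf = np.where(mask[:, :, None], vecs[None, :, :], -np.inf)
    mx = neg_inf.max(axis=1) if len(sub) else np.zeros((present.shape[0], vecs.shape[1]))
    mx[counts == 0] = 0.0
    mean[counts == 0] = 0.0
    return np.concatenate([mean, mx], axis=1)


class GreedyTermSelector(BaseEstimator):
    """Exhaustive forward path over a term pool, then pick the smoothed optimum.

    Every round scores adding each remaining term to the current set (ties
    broken lexicographically) and appends the best; the path runs until the
    pool is exhausted.  The (size -> mean AUC) curve is smoothed with a
    centered moving average of width ``smooth_window`` and the prefix at the
    smoothed maximum (smallest size on ties) is the optimal subset.

    Terms without an embedding vector are dropped from the pool up front.

    Attributes
    ----------
    order_ : list of str — terms in addition order (the full path)
    path_auc_ : ndarray — mean CV AUC at each prefix size
    path_sd_ : ndarray
    optimal_terms_ : list of str
    optimal_size_ : int
    trace_ : SelectionTrace
    """

    def __init__(self, embedding=None, sections=None, term_pool=None, protocol=None, smooth_window=5):
        self.embedding = embedding
        self.sections = sections
        self.term_pool = term_pool
        self.protocol = protocol
        self.smooth_window = smooth_window

    def fit(self, corpus: Corpus, y=None):
        protocol = self.protocol or EvalProtocol()
        if not self.term_pool:
            raise ValueError("term pool must be non-empty")
        pool = sorted(dict.fromkeys(normalize_term(t) for t in self.term_pool))
        pool = [t for t in pool if t in self.embedding]
        if not pool:
            raise ValueError("no pooled term has an embedding vector")
        vecs = np.vstack([self.embedding[t] for t in pool])
        present = term_presence(corpus, self.sections, pool)
        labels = np.asarray(corpus.labels())

        chosen_idx: list[int] = []
        remaining = list(range(len(pool)))
        means, sds = [], []
        trace = SelectionTrace()
        while remaining:
            best = None  # ((-mean, term), idx, mean, sd)
            for j in remaining:
                X = pooled_vectors(present, vecs, chosen_idx + [j])
                mean, sd = evaluate(X, labels, protocol)
                key = (-mean, pool[j])
                if best is None or key < best[0]:
                    best = (key, j, mean, sd)
            _, j, mean, sd = best
            chosen_idx.append(j)
            remaining.remove(j)
            means.append(mean)
            sds.append(sd)
            trace.steps.append((pool[j], mean, sd))
        self.order_ = [pool[j] for j in chosen_idx]
        self.path_auc_ = np.asarray(means)
        self.path_sd_ = np.asarray(sds)
        smoothed = _moving_average(self.path_auc_, self.smooth_window)
        self.optimal_size_ = int(np.argmax(smoothed)) + 1
        self.optimal_terms_ = self.order_[: self.optimal_size_]
        trace.chosen = list(self.optimal_terms_)
        self.trace_ = trace
        return self


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; the window shrinks at the edges."""
    half = window // 2
    out = np.empty_like(x, dtype=float)
    for i in range(len(x)):
        lo, hi = max(0, i - half), min(len(x), i + half + 1)
        out[i] = x[lo:hi].mean()
    return out


# ---------------------------------------------------------------------------
# final model

class RiskModel(BaseEstimator, ClassifierMixin):
    """Risk classifier on the pooled representation of a chosen term subset.

    ``fit`` splits off the protocol's stratified test fraction, trains the
    protocol's classifier (GBDT by default) on the training pool, and
    records held-out AUROC plus sensitivity and specificity at the 0.5
    probability threshold.

    Attributes
    ----------
    classifier_ : fitted sklearn classifier
    auroc_, sensitivity_, specificity_ : float — held-out test metrics
    """

    def __init__(self, embedding=None, sections=None, terms=None, protocol=None):
        self.embedding = embedding
        self.sections = sections
        self.terms = terms
        self.protocol = protocol

    def _X(self, corpus: Corpus) -> np.ndarray:
        term_sets = {s: list(self.terms) for s in self.sections}
        return _vectorize(corpus, term_sets, self.embedding)

    def fit(self, corpus: Corpus, y=None):
        protocol = self.protocol or EvalProtocol()
        X = self._X(corpus)
        yv = np.asarray(corpus.labels()) if y is None else np.asarray(y)
        X_tr, X_te, y_tr, y_te = train_pool_split(X, yv, protocol)
        clf = make_classifier(protocol)
        clf.fit(X_tr, y_tr)
        prob = clf.predict_proba(X_te)[:, 1]
        pred = (prob >= 0.5).astype(int)
        tp = int(((pred == 1) & (y_te == 1)).sum())
        tn = int(((pred == 0) & (y_te == 0)).sum())
        fp = int(((pred == 1) & (y_te == 0)).sum())
        fn = int(((pred == 0) & (y_te == 1)).sum())
        self.classifier_ = clf
        self.auroc_ = float(roc_auc_score(y_te, prob))
        self.sensitivity_ = tp / (tp + fn) if tp + fn else float("nan")
        self.specificity_ = tn / (tn + fp) if tn + fp else float("nan")
        self.classes_ = np.array([0, 1])
        return self

    def predict_proba(self, corpus: Corpus) -> np.ndarray:
        return self.classifier_.predict_proba(self._X(corpus))

    def predict(self, corpus: Corpus) -> np.ndarray:
        return (self.predict_proba(corpus)[:, 1] >= 0.5).astype(int)

    def metrics(self) -> dict[str, float]:
        return {
            "auroc": self.auroc_,
            "sensitivity": self.sensitivity_,
            "specificity": self.specificity_,
        }
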