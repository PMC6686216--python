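"""Term enrichment: negation-aware importance weighting of ontology terms.

For every (section, cohort) stratum, each ontology term found among the
segmented words receives the importance weight

    W_o = F_word * log10(1 / F_doc) * Penalty * mean(C) * (1 + sd(C))

where ``F_word * log10(1/F_doc)`` is TF-IDF over section instances,
``Penalty = 1 / (1 + S_neighbor)`` down-weights promiscuous words via the
Shannon entropy (nats) of the word distribution inside a ±L-token window
around the term, and ``C`` is the per-patient statement consistency

    C = |N_pos - N_neg| / max(N_pos, N_neg)

computed from counts of positive versus negated statements of the term.  A
statement is negated when a negation cue precedes the term inside the same
punctuation-delimited clause.  Terms are ranked by W_o descending per
section and cohort, and the top K kept.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from sklearn.base import BaseEstimator

from ontorisk.corpus import CASE, CONTROL, Corpus, PatientRecord, Section, Sentence
from ontorisk.ontology import OntologySet, normalize_term

__all__ = [
    "NegationLexicon",
    "DEFAULT_NEGATION_CUES",
    "TermStats",
    "TermWeight",
    "RankedTermList",
    "count_statements",
    "consistency",
    "consistency_moments",
    "neighbor_entropy",
    "term_weight",
    "collect_term_stats",
    "rank_terms",
    "OntologyTermRanker",
    "ranking_to_frame",
]

#: Negation cues of the source records: 无 (not have), 未见 (not see),
#: 没有 (no), 不像 (not like), 不似 (not similar), 否认 (deny),
#: 不可能 (not possible).
DEFAULT_NEGATION_CUES = frozenset({"无", "未见", "没有", "不像", "不似", "否认", "不可能"})


@dataclass(frozen=True)
class NegationLexicon:
    cues: frozenset[str] = DEFAULT_NEGATION_CUES

    def __post_init__(self) -> None:
        if not self.cues:
            raise ValueError("negation lexicon must be non-empty")

    @classmethod
    def from_file(cls, path: str | Path) -> "NegationLexicon":
        cues = set()
        with Path(path).open(encoding="utf-8") as fh:
            for line in fh:
                cue = line.strip()
                if cue:
                    cues.add(cue)
        return cls(cues=frozenset(cues))


@dataclass
class TermStats:
    """Accumulators for one term within one (section, cohort) stratum."""

    section: str
    term: str
    occurrences: int = 0
    instances_containing: int = 0
    per_patient: dict[str, tuple[int, int]] = field(default_factory=dict)  # id -> (N_pos, N_neg)
    neighbor_counts: Counter = field(default_factory=Counter)


@dataclass(frozen=True)
class TermWeight:
    term: str
    f_word: float
    f_doc: float
    s_neighbor: float
    penalty: float
    consistency_mean: float
    consistency_sd: float
    w_o: float


@dataclass
class RankedTermList:
    section: str
    cohort: str
    entries: list[TermWeight]

    def terms(self) -> list[str]:
        return [e.term for e in self.entries]

    def top(self, k: int) -> list[str]:
        return [e.term for e in self.entries[:k]]


# ---------------------------------------------------------------------------
# elementary statistics

def count_statements(
    sections: Iterable[Section],
    term: str,
    lexicon: NegationLexicon,
) -> tuple[int, int]:
    """Count positive and negated statements of ``term`` for one patient.

    An occurrence is negated iff a cue token occurs earlier in the same
    punctuation-delimited clause; otherwise it is positive.
    """
    n_pos = n_neg = 0
    for sec in sections:
        for sent in sec.sentences:
            cue_at = -1
            for i, tok in enumerate(sent.tokens):
                if tok in lexicon.cues and cue_at < 0:
                    cue_at = i
                if tok == term:
                    if 0 <= cue_at < i:
                        n_neg += 1
                    else:
                        n_pos += 1
    return n_pos, n_neg


def consistency(n_pos: int, n_neg: int) -> float:
    """|N_pos - N_neg| / max(N_pos, N_neg); 0 when the term never occurs."""
    if n_pos < 0 or n_neg < 0:
        raise ValueError("statement counts must be non-negative")
    if n_pos == 0 and n_neg == 0:
        return 0.0
    return abs(n_pos - n_neg) / max(n_pos, n_neg)


def consistency_moments(values: Sequence[float]) -> tuple[float, float]:
    """Mean and sample standard deviation (N-1 denominator; sd=0 at N=1)."""
    n = len(values)
    if n == 0:
        raise ValueError("consistency moments need at least one patient")
    mean = sum(values) / n
    if n == 1:
        return mean, 0.0
    sd = math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1))
    return mean, sd


def neighbor_entropy(neighbor_counts: Mapping[str, int]) -> tuple[float, float]:
    """Shannon entropy (nats) of the neighbor distribution and its penalty.

    ``P_k = N_k / sum(N_i)``; ``S = -sum P_k ln P_k``; ``penalty =
    1/(1+S)``.  With no neighbors at all, S = 0 and penalty = 1.
    """
    total = sum(neighbor_counts.values())
    if total == 0:
        return 0.0, 1.0
    s = 0.0
    for n_k in neighbor_counts.values():
        if n_k > 0:
            p = n_k / total
            s -= p * math.log(p)
    s = max(s, 0.0)
    return s, 1.0 / (1.0 + s)


def term_weight(
    f_word: float,
    f_doc: float,
    penalty: float,
    consistency_mean: float,
    consistency_sd: float,
) -> float:
    """W_o = F_word * log10(1/F_doc) * penalty * mean * (1 + sd)."""
    if not 0.0 < f_doc <= 1.0:
        raise ValueError(f"F_doc must be in (0, 1], got {f_doc}")
    return f_word * math.log10(1.0 / f_doc) * penalty * consistency_mean * (1.0 + consistency_sd)


# ---------------------------------------------------------------------------
# corpus-level accumulation

def _iter_instances(records: Iterable[PatientRecord], section: str):
    for rec in records:
        for sec in rec.sections.get(section, []):
            yield rec.patient_id, sec


def collect_term_stats(
    records: Sequence[PatientRecord],
    onto: OntologySet,
    section: str,
    lexicon: NegationLexicon,
    window: int = 5,
) -> tuple[dict[str, TermStats], int, int]:
    """Accumulate per-term statistics over one cohort's section instances.

    All dated progress-note entries count as instances of the same section
    kind.  Returns ``(stats by term, total token count, instance count)``.
    """
    stats: dict[str, TermStats] = {}
    total_tokens = 0
    n_instances = 0
    for pid, sec in _iter_instances(records, section):
        n_instances += 1
        present: set[str] = set()
        for sent in sec.sentences:
            total_tokens += len(sent.tokens)
            cue_at = -1
            norm = [normalize_term(t) for t in sent.tokens]
            for i, tok in enumerate(sent.tokens):
                if tok in lexicon.cues and cue_at < 0:
                    cue_at = i
                key = norm[i]
                if key not in onto.terms:
                    continue
                st = stats.get(key)
                if st is None:
                    st = stats[key] = TermStats(section=section, term=key)
                st.occurrences += 1
                present.add(key)
                negated = 0 <= cue_at < i
                p, n = st.per_patient.get(pid, (0, 0))
                st.per_patient[pid] = (p + (not negated), n + negated)
                lo = max(0, i - window)
                hi = min(len(sent.tokens), i + window + 1)
                for j in range(lo, hi):
                    if j != i:
                        st.neighbor_counts[sent.tokens[j]] += 1
        for key in present:
            stats[key].instances_containing += 1
    return stats, total_tokens, n_instances


def _rank_from_stats(
    stats: Mapping[str, TermStats],
    total_tokens: int,
    n_instances: int,
    cohort_patients: set[str],
    section: str,
    cohort: str,
    top_k: int,
) -> RankedTermList:
    entries: list[TermWeight] = []
    for term, st in stats.items():
        if st.occurrences == 0 or total_tokens == 0:
            continue
        cons = [
            consistency(p, n)
            for pid, (p, n) in st.per_patient.items()
            if pid in cohort_patients
        ]
        if not cons:  # term absent from this cohort
            continue
        f_word = st.occurrences / total_tokens
        f_doc = st.instances_containing / n_instances
        s_nb, penalty = neighbor_entropy(st.neighbor_counts)
        c_mean, c_sd = consistency_moments(cons)
        w = term_weight(f_word, f_doc, penalty, c_mean, c_sd)
        entries.append(
            TermWeight(
                term=term,
                f_word=f_word,
                f_doc=f_doc,
                s_neighbor=s_nb,
                penalty=penalty,
                consistency_mean=c_mean,
                consistency_sd=c_sd,
                w_o=w,
            )
        )
    entries.sort(key=lambda e: (-e.w_o, -e.f_word, e.term))
    return RankedTermList(section=section, cohort=cohort, entries=entries[:top_k])


def rank_terms(
    corpus: Corpus,
    onto: OntologySet,
    section: str,
    cohort: str,
    lexicon: NegationLexicon | None = None,
    window: int = 5,
    top_k: int = 300,
) -> RankedTermList:
    """Rank a section's ontology terms by W_o descending, truncated to top K.

    F_word, F_doc and the neighbor entropy are corpus-wide statistics (both
    cohorts pooled — a term concentrated in the small case cohort keeps a
    low document frequency and hence a high IDF); the consistency moments
    are taken over the requested cohort's patients in which the term occurs,
    which is what distinguishes the case from the control list.  Ties are
    broken by F_word descending then term lexicographically, so the ranking
    is deterministic.
    """
    if lexicon is None:
        lexicon = NegationLexicon()
    stats, total_tokens, n_instances = collect_term_stats(
        corpus.records, onto, section, lexicon, window
    )
    cohort_patients = {r.patient_id for r in corpus.cohort(cohort)}
    ranked = _rank_from_stats(
        stats, total_tokens, n_instances, cohort_patients, section, cohort, top_k
    )
    if not ranked.entries:
        import warnings

        warnings.warn(f"no ontology terms found in section {section!r} ({cohort})")
    return ranked


class OntologyTermRanker(BaseEstimator):
    """Rank ontology terms per section and cohort by the W_o weight.

    Parameters
    ----------
    ontology : OntologySet
        Flat term vocabulary matched token-exactly against segmented words.
    lexicon : NegationLexicon, optional
        Negation cues; defaults to the built-in Chinese cue set.
    window : int, default 5
        Half-width L of the neighbor-entropy window, in tokens, clipped at
        clause boundaries.
    top_k : int, default 300
        Number of terms kept per (section, cohort) list.
    sections : sequence of str, optional
        Sections to rank; all sections present in the corpus by default.

    Attributes
    ----------
    rankings_ : dict[(section, cohort), RankedTermList]
    sections_ : list of section names actually ranked
    """

    def __init__(self, ontology=None, lexicon=None, window=5, top_k=300, sections=None):
        self.ontology = ontology
        self.lexicon = lexicon
        self.window = window
        self.top_k = top_k
        self.sections = sections

    def fit(self, corpus: Corpus, y=None):
        if self.ontology is None:
            raise ValueError("OntologyTermRanker requires an ontology")
        lexicon = self.lexicon if self.lexicon is not None else NegationLexicon()
        if self.sections is None:
            names: set[str] = set()
            for rec in corpus:
                names.update(rec.sections)
            sections = sorted(names)
        else:
            sections = list(self.sections)
        self.sections_ = sections
        self.rankings_ = {}
        cohort_ids = {
            cohort: {r.patient_id for r in corpus.cohort(cohort)} for cohort in (CASE, CONTROL)
        }
        for section in sections:
            stats, total_tokens, n_instances = collect_term_stats(
                corpus.records, self.ontology, section, lexicon, self.window
            )
            for cohort in (CASE, CONTROL):
                self.rankings_[(section, cohort)] = _rank_from_stats(
                    stats, total_tokens, n_instances, cohort_ids[cohort], section, cohort, self.top_k
                )
        return self

    def top_terms(self, section: str, cohort: str = CASE, k: int | None = None) -> list[str]:
        lst = self.rankings_[(section, cohort)]
        return lst.top(k if k is not None else self.top_k)


def ranking_to_frame(ranked: RankedTermList) -> pd.DataFrame:
    """Export one ranked list as a DataFrame (TSV-ready, rank starts at 1)."""
    rows = [
        {
            "section": ranked.section,
            "cohort": ranked.cohort,
            "rank": i + 1,
            "term": e.term,
            "F_word": e.f_word,
            "F_doc": e.f_doc,
            "S_neighbor": e.s_neighbor,
            "penalty": e.penalty,
            "consistency_mean": e.consistency_mean,
            "consistency_sd": e.consistency_sd,
            "W_o": e.w_o,
        }
        for i, e in enumerate(ranked.entries)
    ]
    return pd.DataFrame(rows)
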