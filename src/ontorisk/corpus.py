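"""Data model and I/O for sectioned clinical notes.

A :class:`Corpus` holds one :class:`PatientRecord` per patient.  Each record
carries the raw documents as read from disk (``title -> text``) plus, after
section extraction, named :class:`Section` objects whose sentences are
punctuation-delimited clauses of tokens.  Tokenization is a pluggable
contract: a whitespace splitter for synthetic/English corpora and a
dictionary-driven maximum-matching segmenter for Chinese text.
"""

from __future__ import annotations

import json
import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

__all__ = [
    "Sentence",
    "Section",
    "PatientRecord",
    "Corpus",
    "WhitespaceTokenizer",
    "MaxMatchTokenizer",
    "DEFAULT_PUNCTUATION",
    "split_clauses",
    "tokenize",
    "read_corpus",
    "write_corpus",
]

#: Clause delimiters: Chinese and ASCII sentence/clause marks plus newline.
DEFAULT_PUNCTUATION = "。，；！？,.;!?\n"

CASE, CONTROL = "case", "control"

_LABEL_ALIASES = {
    "case": CASE,
    "vte": CASE,
    "1": CASE,
    "control": CONTROL,
    "non-vte": CONTROL,
    "0": CONTROL,
}


@dataclass(frozen=True)
class Sentence:
    """One punctuation-delimited clause: its tokens and the raw text."""

    tokens: tuple[str, ...]
    raw: str = ""

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.tokens)


@dataclass
class Section:
    """A titled sub-document (or one dated progress-note entry)."""

    name: str
    sentences: list[Sentence] = field(default_factory=list)
    date: _dt.date | None = None
    raw: str = ""


@dataclass
class PatientRecord:
    patient_id: str
    label: str  # "case" (VTE) or "control"
    documents: dict[str, str] = field(default_factory=dict)
    #: section name -> list of instances (progress notes have one per date)
    sections: dict[str, list[Section]] = field(default_factory=dict)

    @property
    def is_case(self) -> bool:
        return self.label == CASE


@dataclass
class Corpus:
    records: list[PatientRecord]

    @property
    def n_case(self) -> int:
        return sum(1 for r in self.records if r.label == CASE)

    @property
    def n_control(self) -> int:
        return sum(1 for r in self.records if r.label == CONTROL)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def cohort(self, label: str) -> list[PatientRecord]:
        return [r for r in self.records if r.label == label]

    def labels(self) -> list[int]:
        """0/1 vector (1 = case), aligned with ``records``."""
        return [1 if r.label == CASE else 0 for r in self.records]


# ---------------------------------------------------------------------------
# tokenizers

class WhitespaceTokenizer:
    """Split a clause on whitespace; for synthetic and space-delimited text."""

    def __call__(self, clause: str) -> list[str]:
        return clause.split()


class MaxMatchTokenizer:
    """Greedy forward maximum-matching word segmenter.

    Segments a clause by repeatedly taking the longest prefix found in the
    supplied vocabulary; characters not starting any known word become
    single-character tokens.  ASCII alphanumeric runs are kept whole so that
    numerals and latin abbreviations survive as tokens.
    """

    def __init__(self, vocabulary: Iterable[str]):
        self.vocabulary = set(w for w in vocabulary if w)
        self._max_len = max((len(w) for w in self.vocabulary), default=1)

    def __call__(self, clause: str) -> list[str]:
        tokens: list[str] = []
        i, n = 0, len(clause)
        while i < n:
            ch = clause[i]
            if ch.isspace():
                i += 1
                continue
            if ch.isascii() and ch.isalnum():
                j = i + 1
                while j < n and clause[j].isascii() and clause[j].isalnum():
                    j += 1
                tokens.append(clause[i:j])
                i = j
                continue
            match = ch
            for length in range(min(self._max_len, n - i), 1, -1):
                cand = clause[i : i + length]
                if cand in self.vocabulary:
                    match = cand
                    break
            tokens.append(match)
            i += len(match)
        return tokens


Tokenizer = Callable[[str], list[str]]


def split_clauses(text: str, punctuation: str = DEFAULT_PUNCTUATION) -> list[str]:
    """Split ``text`` at any delimiter character; empty clauses are dropped."""
    clauses: list[str] = []
    buf: list[str] = []
    for ch in text:
        if ch in punctuation:
            clause = "".join(buf).strip()
            if clause:
                clauses.append(clause)
            buf = []
        else:
            buf.append(ch)
    clause = "".join(buf).strip()
    if clause:
        clauses.append(clause)
    return clauses


def tokenize(
    text: str,
    tokenizer: Tokenizer | None = None,
    punctuation: str = DEFAULT_PUNCTUATION,
) -> list[Sentence]:
    """Split ``text`` into punctuation-delimited clauses and tokenize each.

    A :class:`Sentence` never spans a delimiter; clauses whose tokenization
    is empty are dropped.  Deterministic: repeated calls give identical
    token sequences.
    """
    if tokenizer is None:
        tokenizer = WhitespaceTokenizer()
    sentences = []
    for clause in split_clauses(text, punctuation):
        tokens = tokenizer(clause)
        if tokens:
            sentences.append(Sentence(tokens=tuple(tokens), raw=clause))
    return sentences


# ---------------------------------------------------------------------------
# JSON-lines corpus I/O

def read_corpus(path: str | Path) -> Corpus:
    """Read a JSON-lines corpus: one object per patient.

    Each line must provide ``patient_id``, ``label`` (case/VTE/1 vs
    control/non-VTE/0) and ``documents`` (mapping document title -> raw
    text).  Raw text is retained for section extraction.

    Raises
    ------
    ValueError
        on an empty file, a duplicate patient id, or an unknown label.
    """
    path = Path(path)
    records: list[PatientRecord] = []
    seen: set[str] = set()
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            obj = json.loads(line)
            pid = str(obj["patient_id"])
            if pid in seen:
                raise ValueError(f"duplicate patient_id {pid!r} at line {lineno}")
            seen.add(pid)
            raw_label = str(obj["label"]).strip().lower()
            if raw_label not in _LABEL_ALIASES:
                raise ValueError(f"unknown label {obj['label']!r} for patient {pid!r}")
            documents = {str(k): str(v) for k, v in obj.get("documents", {}).items()}
            records.append(
                PatientRecord(patient_id=pid, label=_LABEL_ALIASES[raw_label], documents=documents)
            )
    if not records:
        raise ValueError("empty corpus")
    return Corpus(records=records)


def write_corpus(corpus: Corpus, path: str | Path) -> None:
    """Write a corpus back to JSON-lines (inverse of :func:`read_corpus`)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for rec in corpus.records:
            fh.write(
                json.dumps(
                    {
                        "patient_id": rec.patient_id,
                        "label": rec.label,
                        "documents": rec.documents,
                    },
                    ensure_ascii=False,
                    sort_keys=True,
                )
                + "\n"
            )
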