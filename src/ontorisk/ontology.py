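"""Flat ontology vocabulary: load, normalize, merge and match term lists.

Terms from several vocabularies (ICD-10, HPO, MeSH, SNOMED-CT, ...) are
merged into one deduplicated set keyed by the normalized surface form and
used as a flat vocabulary — terms are matched token-exactly against the
segmented words of a sentence, not as substrings.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from ontorisk.corpus import Sentence

__all__ = [
    "OntologyTerm",
    "OntologySet",
    "normalize_term",
    "load_term_list",
    "merge",
    "match_terms",
]


def normalize_term(surface: str) -> str:
    """NFKC-normalize, strip, and lowercase ASCII letters (CJK untouched)."""
    s = unicodedata.normalize("NFKC", surface).strip()
    return "".join(c.lower() if c.isascii() else c for c in s)


@dataclass(frozen=True)
class OntologyTerm:
    surface: str
    sources: frozenset[str]


@dataclass
class OntologySet:
    """Deduplicated term set; a shared surface accumulates source tags."""

    terms: dict[str, OntologyTerm] = field(default_factory=dict)

    def __contains__(self, surface: str) -> bool:
        return normalize_term(surface) in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def surfaces(self) -> set[str]:
        return set(self.terms)

    def add(self, term: OntologyTerm) -> None:
        prev = self.terms.get(term.surface)
        if prev is None:
            self.terms[term.surface] = term
        else:
            self.terms[term.surface] = OntologyTerm(
                surface=term.surface, sources=prev.sources | term.sources
            )


def load_term_list(path: str | Path, source_tag: str) -> list[OntologyTerm]:
    """Read one term per line (an optional leading ``code<TAB>`` is ignored).

    Whitespace is trimmed, empty lines dropped, and duplicates within the
    file collapsed.  A missing file raises.
    """
    path = Path(path)
    seen: set[str] = set()
    out: list[OntologyTerm] = []
    with path.open(encoding="utf-8") as fh:
        for line in fh:
            if "\t" in line:
                line = line.split("\t", 1)[1]
            surface = normalize_term(line)
            if not surface or surface in seen:
                continue
            seen.add(surface)
            out.append(OntologyTerm(surface=surface, sources=frozenset({source_tag})))
    return out


def merge(term_lists: Iterable[Iterable[OntologyTerm]]) -> OntologySet:
    """Union of term lists keyed by normalized surface."""
    term_lists = list(term_lists)
    if not term_lists:
        raise ValueError("merge requires at least one term list")
    onto = OntologySet()
    for terms in term_lists:
        for t in terms:
            onto.add(OntologyTerm(surface=normalize_term(t.surface), sources=t.sources))
    return onto


def match_terms(sentence: Sentence, onto: OntologySet) -> list[tuple[str, int]]:
    """Token-exact ontology matches: ``(term, token position)`` pairs.

    A term matches iff it equals a token produced by segmentation; a token
    occurring twice yields two matches at distinct positions.
    """
    out = []
    for pos, tok in enumerate(sentence.tokens):
        key = normalize_term(tok)
        if key in onto.terms:
            out.append((key, pos))
    return out
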