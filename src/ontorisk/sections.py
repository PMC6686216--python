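"""Greedy rule-based section extraction.

Admission notes in the source records open each section with a known title
(chief complaint, present history, ...).  Because clinicians may delete
sections or reorder them, extraction is a greedy scan: from the current
position, find the title occurrence with the smallest character offset,
close the pending section there, and continue after the matched title.
Progress notes are instead split at date headers, one section instance per
dated daily entry.
"""

from __future__ import annotations

import datetime as _dt
import re
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

from ontorisk.corpus import (
    DEFAULT_PUNCTUATION,
    Corpus,
    Section,
    Tokenizer,
    tokenize,
)

__all__ = [
    "TitleConfig",
    "SectionSpan",
    "extract_sections",
    "split_progress_note",
    "parse_corpus",
    "DEFAULT_TITLES",
    "PROGRESS_NOTE",
]

PROGRESS_NOTE = "Progress Note"

#: The 11 admission-note sections with default Chinese title patterns.
#: Obstetrical history, menstrual history and the physician's signature are
#: recognised (so their text is not glued onto a neighbour) but dropped.
DEFAULT_TITLES: list[tuple[str, list[str]]] = [
    ("Chief Complaint", ["主诉"]),
    ("Present History", ["现病史"]),
    ("Previous History", ["既往史"]),
    ("Personal History", ["个人史"]),
    ("Family History", ["家族史"]),
    ("Obstetrical History", ["婚育史", "生育史"]),
    ("Menstrual History", ["月经史"]),
    ("Physical Examination", ["体格检查", "查体"]),
    ("Laboratory Examination", ["实验室检查", "辅助检查"]),
    ("Admitting Diagnosis", ["入院诊断", "初步诊断"]),
    ("Signature", ["医师签名"]),
]

DEFAULT_DROP = frozenset({"Obstetrical History", "Menstrual History", "Signature"})

#: ISO-ish and Chinese date headers of daily progress-note entries.
DEFAULT_DATE_PATTERN = r"(\d{4})[-/年.](\d{1,2})[-/月.](\d{1,2})日?"


@dataclass
class TitleConfig:
    """Ordered title patterns plus the progress-note date pattern."""

    titles: list[tuple[str, list[str]]] = field(default_factory=lambda: list(DEFAULT_TITLES))
    date_pattern: str = DEFAULT_DATE_PATTERN
    drop: frozenset[str] = DEFAULT_DROP

    def __post_init__(self) -> None:
        names = [name for name, _ in self.titles]
        if len(names) != len(set(names)):
            raise ValueError("section names in TitleConfig must be unique")
        for name, patterns in self.titles:
            if not patterns:
                raise ValueError(f"section {name!r} has no title patterns")

    @property
    def kept_names(self) -> list[str]:
        return [name for name, _ in self.titles if name not in self.drop]


class SectionSpan(NamedTuple):
    """One extracted span: ``name`` is None for an unnamed (title-less) span."""

    name: str | None
    body: str
    title: str  # the matched title text ("" for unnamed spans)


def extract_sections(raw: str, cfg: TitleConfig | None = None) -> list[SectionSpan]:
    """Split one whole document into titled spans by greedy title matching.

    Scanning from the current position, the nearest occurrence of any
    still-unmatched title opens a new section; the text between consecutive
    matched titles belongs to the first title.  Ties at the same offset go
    to the longest matching title.  A matched section is consumed and cannot
    match again.  Sections absent from the document are simply missing, and
    the output follows document order, not config order.

    Concatenating ``title + body`` over the returned spans reconstructs the
    input exactly.
    """
    if cfg is None:
        cfg = TitleConfig()
    # (config_rank, name, pattern) for every pattern of every section
    candidates: list[tuple[int, str, str]] = [
        (rank, name, pat)
        for rank, (name, patterns) in enumerate(cfg.titles)
        for pat in patterns
    ]
    spans: list[SectionSpan] = []
    pos = 0
    pending: tuple[str | None, str, int] | None = None  # (name, title, body_start)

    def close(end: int) -> None:
        nonlocal pending
        if pending is not None:
            name, title, start = pending
            spans.append(SectionSpan(name=name, body=raw[start:end], title=title))
            pending = None

    while True:
        best: tuple[int, int, int, str, str] | None = None  # offset, -len, rank, name, pat
        for rank, name, pat in candidates:
            off = raw.find(pat, pos)
            if off < 0:
                continue
            key = (off, -len(pat), rank, name, pat)
            if best is None or key < best:
                best = key
        if best is None:
            break
        off, _, _, name, pat = best
        if pending is None and off > 0:
            spans.append(SectionSpan(name=None, body=raw[:off], title=""))
        close(off)
        pending = (name, pat, off + len(pat))
        pos = off + len(pat)
        candidates = [c for c in candidates if c[1] != name]
    if pending is None:
        if raw:
            warnings.warn("no section title matched; returning a single unnamed span")
            spans.append(SectionSpan(name=None, body=raw, title=""))
    else:
        close(len(raw))
    return spans


def _parse_date(match: re.Match) -> _dt.date | None:
    try:
        y, m, d = (int(g) for g in match.groups()[:3])
        return _dt.date(y, m, d)
    except (ValueError, TypeError):
        return None


def split_progress_note(raw: str, cfg: TitleConfig | None = None) -> list[Section]:
    """Split a progress note into dated entries, one :class:`Section` each.

    Entries open at date headers matching ``cfg.date_pattern``; a header
    whose date does not parse is merged into the previous entry, and text
    before the first header is merged into the first entry.  With no date
    at all, a single undated section is returned with a warning.
    """
    if cfg is None:
        cfg = TitleConfig()
    pat = re.compile(cfg.date_pattern)
    matches = list(pat.finditer(raw))
    entries: list[Section] = []
    for i, m in enumerate(matches):
        date = _parse_date(m)
        end = matches[i + 1].start() if i + 1 < len(matches) else len(raw)
        body = raw[m.end() : end]
        if date is None and entries:
            prev = entries[-1]
            prev.raw += raw[m.start() : end]
            continue
        start_body = body if entries or m.start() == 0 else raw[: m.start()] + body
        entries.append(Section(name=PROGRESS_NOTE, date=date, raw=start_body))
    if not entries:
        warnings.warn("no date header found in progress note; keeping one undated entry")
        return [Section(name=PROGRESS_NOTE, date=None, raw=raw)]
    return entries


def parse_corpus(
    corpus: Corpus,
    cfg: TitleConfig | None = None,
    tokenizer: Tokenizer | None = None,
    punctuation: str = DEFAULT_PUNCTUATION,
    progress_doc_titles: tuple[str, ...] = ("progress", "progress_note", PROGRESS_NOTE),
) -> Corpus:
    """Fill ``record.sections`` for every record, in place.

    Documents whose title is in ``progress_doc_titles`` are split by date
    into instances of the single section kind ``"Progress Note"``; all other
    documents go through greedy title extraction, keeping only the
    configured non-dropped sections.  Section bodies are tokenized into
    punctuation-delimited sentences.
    """
    if cfg is None:
        cfg = TitleConfig()
    progress_keys = {t.lower() for t in progress_doc_titles}
    for rec in corpus:
        rec.sections = {}
        for doc_title, text in rec.documents.items():
            if doc_title.lower() in progress_keys:
                for sec in split_progress_note(text, cfg):
                    sec.sentences = tokenize(sec.raw, tokenizer, punctuation)
                    rec.sections.setdefault(PROGRESS_NOTE, []).append(sec)
            else:
                for span in extract_sections(text, cfg):
                    if span.name is None or span.name in cfg.drop:
                        continue
                    sec = Section(name=span.name, raw=span.body)
                    sec.sentences = tokenize(span.body, tokenizer, punctuation)
                    rec.sections.setdefault(span.name, []).append(sec)
    return corpus
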