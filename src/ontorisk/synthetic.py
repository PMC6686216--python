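"""Synthetic sectioned two-cohort corpora with planted discriminative terms.

The generator emulates the shape of the clinical source data — an admission
note with titled sections plus a progress note split by date, for a case
(VTE) and a control cohort — without attempting realistic clinical prose.
Background sentences are random draws from a token vocabulary; each planted
term is inserted into its target section with a cohort-specific occurrence
probability, and an insertion is negated by prefixing a cue token inside
the same clause.  Everything is driven by one seed, so identical seeds give
byte-identical output files.  Padua risk-factor flags are sampled with
cohort-specific prevalences (defaults follow the factor prevalences
reported for VTE vs non-VTE inpatient cohorts).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from ontorisk.corpus import Corpus, PatientRecord, WhitespaceTokenizer
from ontorisk.sections import PROGRESS_NOTE, TitleConfig, parse_corpus

__all__ = ["PlantedTerm", "GeneratorSpec", "GeneratedBundle", "generate"]

DEFAULT_SECTIONS = ["Chief Complaint", "Present History", "Admitting Diagnosis", PROGRESS_NOTE]
DEFAULT_CUES = ("no", "denies", "without")

#: Per-factor prevalence (case, control): the inpatient cohort rates used as
#: realistic defaults for flag sampling.
DEFAULT_PADUA_PREVALENCE: dict[str, tuple[float, float]] = {
    "active_cancer_chemo": (0.3125, 0.2800),
    "previous_vte": (0.1518, 0.0059),
    "reduced_mobility": (0.7054, 0.3574),
    "thrombophilic": (0.1116, 0.0184),
    "recent_trauma_surgery": (0.0625, 0.0302),
    "age_ge_70": (0.2009, 0.1450),
    "heart_resp_failure": (0.2902, 0.0389),
    "ami_ischemic_stroke": (0.0357, 0.0153),
    "infection_rheumatologic": (0.5848, 0.2464),
    "bmi_ge_30": (0.0580, 0.0573),
    "glucocorticoid": (0.6071, 0.3373),
}


@dataclass(frozen=True)
class PlantedTerm:
    term: str
    section: str
    p_case: float
    p_control: float
    p_negated: float = 0.0

    def __post_init__(self) -> None:
        for p in (self.p_case, self.p_control, self.p_negated):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability out of [0,1] for term {self.term!r}")


@dataclass
class GeneratorSpec:
    n_case: int = 100
    n_control: int = 100
    sections: list[str] = field(default_factory=lambda: list(DEFAULT_SECTIONS))
    n_background: int = 50
    planted_terms: list[PlantedTerm] = field(default_factory=list)
    negation_cues: tuple[str, ...] = DEFAULT_CUES
    sentences_per_section: tuple[int, int] = (3, 6)  # inclusive range
    progress_entries: tuple[int, int] = (2, 4)
    mean_extra_occurrences: float = 1.0  # Poisson extra insertions per positive patient
    zipf_exponent: float = 1.1  # background word frequencies are Zipf-like
    background_negation_rate: float = 0.15  # share of clauses opening with a cue
    template_rate: float = 0.5  # share of insertions preceded by a collocate
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_case < 1 or self.n_control < 1:
            raise ValueError("both cohorts must be non-empty")
        cues = set(self.negation_cues)
        for pt in self.planted_terms:
            if pt.term in cues:
                raise ValueError(f"planted term {pt.term!r} collides with a negation cue")
            if pt.section not in self.sections:
                raise ValueError(f"planted term {pt.term!r} targets unknown section {pt.section!r}")


@dataclass
class GeneratedBundle:
    corpus: Corpus
    title_config: TitleConfig
    ontology_terms: list[str]
    negation_cues: list[str]
    padua_flags: pd.DataFrame
    manifest: dict

    def parsed_corpus(self) -> Corpus:
        """Section-extract and tokenize the raw documents (whitespace)."""
        return parse_corpus(self.corpus, self.title_config, WhitespaceTokenizer())

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        from ontorisk.corpus import write_corpus

        write_corpus(self.corpus, out / "corpus.jsonl")
        (out / "ontology.txt").write_text(
            "".join(t + "\n" for t in self.ontology_terms), encoding="utf-8"
        )
        (out / "cues.txt").write_text(
            "".join(c + "\n" for c in self.negation_cues), encoding="utf-8"
        )
        self.padua_flags.to_csv(out / "padua.csv", index=False)
        (out / "manifest.json").write_text(
            json.dumps(self.manifest, indent=2, sort_keys=True), encoding="utf-8"
        )


def _sentence_length(rng: np.random.Generator) -> int:
    # bounded geometric: 2..15 tokens keeps clauses realistic for the
    # entropy window
    return int(min(2 + rng.geometric(0.35) - 1, 15))


def _background_sentence(
    rng: np.random.Generator,
    vocab: list[str],
    weights: np.ndarray,
    cues: tuple[str, ...],
    negation_rate: float,
) -> list[str]:
    """One clause of Zipf-weighted background words; some clauses open with
    a negation cue, emulating 'denies X' review-of-systems boilerplate."""
    n = _sentence_length(rng)
    toks = [vocab[i] for i in rng.choice(len(vocab), size=n, p=weights)]
    if rng.random() < negation_rate:
        toks.insert(0, cues[int(rng.integers(0, len(cues)))])
    return toks


def generate(spec: GeneratorSpec, out_dir: str | Path | None = None) -> GeneratedBundle:
    """Draw a corpus bundle from the generator spec (deterministic per seed).

    The emitted ontology list contains the planted terms plus the whole
    background vocabulary, so ranking and selection face realistic
    competition.  Raw documents carry section titles (``Name: ...``) and
    dated progress-note entries, exercising the section extractor.
    """
    rng = np.random.default_rng(spec.seed)
    vocab = [f"w{i:03d}" for i in range(spec.n_background)]
    weights = 1.0 / np.arange(1, spec.n_background + 1) ** spec.zipf_exponent
    weights /= weights.sum()
    # two dedicated collocate tokens per planted term emulate the
    # stereotyped contexts medical terms occur in
    companions = {
        pt.term: [f"c_{pt.term}_{k}" for k in range(2)] for pt in spec.planted_terms
    }
    planted_by_section: dict[str, list[PlantedTerm]] = {}
    for pt in spec.planted_terms:
        if pt.term in vocab:
            raise ValueError(f"planted term {pt.term!r} collides with background vocabulary")
        planted_by_section.setdefault(pt.section, []).append(pt)

    admission_sections = [s for s in spec.sections if s != PROGRESS_NOTE]
    records: list[PatientRecord] = []
    labels = ["case"] * spec.n_case + ["control"] * spec.n_control
    lo_s, hi_s = spec.sentences_per_section
    lo_p, hi_p = spec.progress_entries
    for idx, label in enumerate(labels):
        pid = f"p{idx:05d}"
        section_sentences: dict[str, list[list[list[str]]]] = {}
        for name in admission_sections:
            n_sent = int(rng.integers(lo_s, hi_s + 1))
            section_sentences[name] = [
                [_background_sentence(
                    rng, vocab, weights, spec.negation_cues, spec.background_negation_rate
                ) for _ in range(n_sent)]
            ]
        if PROGRESS_NOTE in spec.sections:
            n_entries = int(rng.integers(lo_p, hi_p + 1))
            section_sentences[PROGRESS_NOTE] = [
                [
                    _background_sentence(
                    rng, vocab, weights, spec.negation_cues, spec.background_negation_rate
                )
                    for _ in range(int(rng.integers(lo_s, hi_s + 1)))
                ]
                for _ in range(n_entries)
            ]
        # plant terms
        for name, planted in planted_by_section.items():
            instances = section_sentences.get(name)
            if not instances:
                continue
            for pt in planted:
                p = pt.p_case if label == "case" else pt.p_control
                if rng.random() >= p:
                    continue
                n_occ = 1 + int(rng.poisson(spec.mean_extra_occurrences))
                for _ in range(n_occ):
                    entry = instances[int(rng.integers(0, len(instances)))]
                    # a planted mention is its own short clause, the way a
                    # diagnosis line reads: "[cue] [collocate] term."
                    clause: list[str] = []
                    if rng.random() < pt.p_negated:
                        clause.append(
                            spec.negation_cues[int(rng.integers(0, len(spec.negation_cues)))]
                        )
                    if rng.random() < spec.template_rate:
                        comp = companions[pt.term]
                        clause.append(comp[int(rng.integers(0, len(comp)))])
                    clause.append(pt.term)
                    entry.insert(int(rng.integers(0, len(entry) + 1)), clause)
        # render raw documents
        adm_parts = []
        for name in admission_sections:
            body = " ".join(" ".join(s) + "." for s in section_sentences[name][0])
            adm_parts.append(f"{name}: {body}")
        documents = {"admission": "\n".join(adm_parts)}
        if PROGRESS_NOTE in spec.sections:
            day = 1
            entries = []
            for entry in section_sentences[PROGRESS_NOTE]:
                body = " ".join(" ".join(s) + "." for s in entry)
                entries.append(f"2014-01-{day:02d} {body}")
                day += 1
            documents["progress"] = "\n".join(entries)
        records.append(PatientRecord(patient_id=pid, label=label, documents=documents))

    corpus = Corpus(records=records)
    title_cfg = TitleConfig(
        titles=[(name, [f"{name}:"]) for name in admission_sections],
        drop=frozenset(),
    )
    flags = _sample_padua(rng, labels)
    flags.insert(0, "patient_id", [r.patient_id for r in records])
    ontology_terms = [pt.term for pt in spec.planted_terms] + vocab
    manifest = {
        "n_case": spec.n_case,
        "n_control": spec.n_control,
        "seed": spec.seed,
        "sections": spec.sections,
        "planted_terms": [asdict(pt) for pt in spec.planted_terms],
    }
    bundle = GeneratedBundle(
        corpus=corpus,
        title_config=title_cfg,
        ontology_terms=ontology_terms,
        negation_cues=list(spec.negation_cues),
        padua_flags=flags,
        manifest=manifest,
    )
    if out_dir is not None:
        bundle.write(out_dir)
    return bundle


def _sample_padua(rng: np.random.Generator, labels: list[str]) -> pd.DataFrame:
    rows = []
    for label in labels:
        row = {"cohort": label}
        for factor, (p_case, p_control) in DEFAULT_PADUA_PREVALENCE.items():
            p = p_case if label == "case" else p_control
            row[factor] = bool(rng.random() < p)
        rows.append(row)
    return pd.DataFrame(rows)
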