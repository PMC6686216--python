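# ontorisk

Ontology-based construction of clinical risk models from free-text medical
records, with venous thromboembolism (VTE) risk assessment as the target
application and the Padua linear score as the baseline.

Inpatient VTE is common and preventable, but the standard 11-factor Padua
score transfers poorly across populations. Clinical notes — admission notes
with titled sections (chief complaint, present history, admitting
diagnosis, ...) plus a dated progress note — contain far richer signals.
`ontorisk` implements a complete workflow that turns such notes into a risk
classifier while surfacing interpretable candidate risk factors:

1. **Section extraction** — greedy title matching splits each note into its
   sections, tolerant of deleted or reordered sections; progress notes are
   split at date headers.
2. **Term enrichment** — every ontology term (ICD-10 / MeSH / HPO /
   SNOMED-style flat vocabularies) found among the segmented words is scored
   per section with

   `W_o = F_word · log10(1/F_doc) · 1/(1+S_neighbor) · mean(C) · (1 + σ(C))`

   where `F_word · log10(1/F_doc)` is TF-IDF over section instances,
   `S_neighbor` is the Shannon entropy (nats) of the words inside a ±L token
   window around the term (promiscuous filler words get large entropy and a
   small `1/(1+S)` penalty), and `C = |N_pos − N_neg| / max(N_pos, N_neg)`
   is the per-patient consistency of positive versus negated statements of
   the term (a cue such as 无 / 否认 / "denies" earlier in the same clause
   marks an occurrence negated). Terms are ranked per section per cohort.
3. **Patient representation** — a skip-gram embedding (min_count = 2,
   window = 5, negative sampling) is trained on all sentences of both
   cohorts; a patient is `X = [V M]`, the concatenated mean and
   element-wise max of the vectors of their matched top-K terms.
4. **Greedy selection and model** — sections are scored by cross-validated
   AUROC using their terms alone (AUC *Only*) or everything but them
   (AUC *Exclusion*), then selected greedily; a full forward path over the
   chosen sections' terms is smoothed to find the optimal term subset; a
   gradient-boosted tree classifier on that subset is the final model,
   reported with held-out AUROC, sensitivity and specificity.
5. **Padua baseline** — the 11-factor linear score (high risk at ≥ 4) and
   per-cohort summary tables from structured flags.

Because real hospital records cannot ship with the package, a synthetic
corpus generator produces sectioned two-cohort corpora with Zipf background
text, negated boilerplate, and planted discriminative terms with known
cohort probabilities, so every stage is testable end to end.

## Worked example

```python
from ontorisk import NegationLexicon, OntologyTerm, merge, rank_terms
from ontorisk.corpus import CASE
from ontorisk.enrichment import ranking_to_frame
from ontorisk.pipeline import run_pipeline
from ontorisk.risk import EvalProtocol
from ontorisk.synthetic import GeneratorSpec, PlantedTerm, generate

spec = GeneratorSpec(
    n_case=100, n_control=100, seed=0,
    planted_terms=[PlantedTerm("embolus", "Admitting Diagnosis", 0.9, 0.1, 0.0)],
)
bundle = generate(spec)
corpus = bundle.parsed_corpus()
ontology = merge([[OntologyTerm(t, frozenset({"synthetic"})) for t in bundle.ontology_terms]])
lexicon = NegationLexicon(cues=frozenset(bundle.negation_cues))

ranked = rank_terms(corpus, ontology, "Admitting Diagnosis", CASE, lexicon)
print(ranking_to_frame(ranked).head(3)[
    ["rank", "term", "F_word", "F_doc", "penalty", "consistency_mean", "W_o"]
].round(4).to_string(index=False))

res = run_pipeline(
    corpus, ontology, lexicon,
    vector_size=10, epochs=2, top_k=50,
    selection_protocol=EvalProtocol(classifier="lr", seed=0),
    final_protocol=EvalProtocol(classifier="gbdt", seed=0),
)
print("selected sections:", res.section_selector.selected_sections_)
print("held-out metrics:", {k: round(v, 3) for k, v in res.metrics.items()})
```

prints

```
 rank    term  F_word  F_doc  penalty  consistency_mean    W_o
    1 embolus  0.0461  0.475   0.5909            1.0000 0.0088
    2    w003  0.0500  0.615   0.2503            0.9412 0.0030
    3    w005  0.0290  0.435   0.2460            0.9186 0.0030
selected sections: ['Admitting Diagnosis', 'Progress Note', 'Present History']
held-out metrics: {'auroc': 0.917, 'sensitivity': 0.85, 'specificity': 0.85}
```

The planted term `embolus` (present in 90% of cases, 10% of controls) tops
the case ranking with a ~3× weight margin: it keeps a high IDF because it is
rare corpus-wide, a mild neighbor penalty because it occurs in short
stereotyped clauses, and perfect statement consistency — while filler words
lose on all three factors. The greedy search then selects the signal-bearing
sections and the final classifier reaches AUROC ≈ 0.92 on the held-out 20%.

A command-line interface covers the same flow on bundle directories:

```bash
ontorisk simulate --spec spec.json --out bundle/
ontorisk enrich --dir bundle/ --window 5 --top-k 300 --out ranked.tsv
ontorisk evaluate-sections --dir bundle/ --out sections.tsv
ontorisk select --dir bundle/ --level term --out trace.tsv
ontorisk train --dir bundle/ --out metrics.json
ontorisk padua-summary --flags bundle/padua.csv --out summary.tsv
```

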