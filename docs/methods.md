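# Methods

## The model

`ontorisk` builds a binary risk classifier for a two-cohort corpus of
sectioned clinical notes (cases vs controls) in five stages. The modelling
assumptions are:

- **Notes are section-structured.** An admission note is a concatenation of
  titled sections; clinicians may delete or reorder sections but do not nest
  them. A progress note is a sequence of dated daily entries, all of which
  are instances of one section kind. Section extraction is therefore a
  greedy left-to-right scan: from the current position, the title occurrence
  with the smallest character offset (ties to the longest title, then config
  order) opens the next section, and the text between consecutive matched
  titles belongs to the first. A matched section is consumed so a title
  word recurring inside prose cannot re-trigger it.
- **Clauses are the unit of meaning.** Text is split at punctuation
  (default `。，；！？,.;!?` plus the newline, since line ends close clauses
  in notes); a sentence never spans a delimiter. Negation scope and the
  neighbor window never cross a clause boundary.
- **The ontology is a flat vocabulary.** Terms are matched token-exactly
  against segmented words, not as substrings; multi-token terms that the
  segmenter splits are not matched. No hierarchy traversal.
- **Word use, not chart structure, carries the signal.** Patients are
  represented through embeddings of their matched terms only.

## Term importance weight

For each section, statistics are accumulated over all patients of both
cohorts:

- `F_word` — occurrences of the term in that section across the corpus,
  divided by the total token count of the section (dimensionless).
- `F_doc` — fraction of the section's instances (every dated progress-note
  entry counts separately) containing the term; `F_word · log10(1/F_doc)`
  is TF-IDF. A term present in every instance gets weight exactly 0.
- `S_neighbor` — Shannon entropy in nats of the pooled word counts within
  ±L tokens (default L = 5) of each occurrence, clipped at the clause
  boundary, the centre token excluded (other occurrences of the same word
  inside the window do count). `Penalty = 1/(1+S)`; a term with no
  neighbors at all has S = 0, penalty 1.
- Per patient, `N_pos`/`N_neg` — occurrences asserted vs negated, where an
  occurrence is negated iff a cue token (无, 未见, 没有, 不像, 不似, 否认,
  不可能 by default; configurable) appears earlier in the same clause.
  `C = |N_pos − N_neg| / max(N_pos, N_neg)`, defined as 0 at 0/0.

The cohort enters only through the consistency moments: `mean(C)` and the
sample standard deviation `σ(C)` (denominator N−1, σ = 0 for a single
patient) are taken over the patients of one cohort in which the term occurs
at least once, giving each section a case list and a control list. The
final weight is the product

```
W_o = F_word · log10(1/F_doc) · 1/(1+S_neighbor) · mean(C) · (1+σ(C))
```

ranked descending with deterministic tie-breaks (F_word descending, then
term lexicographic), truncated to the top K (default 300). Computing
F_word/F_doc corpus-wide rather than per cohort is deliberate: a term
concentrated in a small case cohort then keeps a low document frequency and
a large IDF, which is precisely what lets cohort-specific terms surface.

## Embedding and patient representation

One "universal" skip-gram model is trained on all sentences of both cohorts
pooled: dimension P (default 100; the synthetic suites use 10), context
window 5, min_count 2, 5 negative samples from the unigram^0.75 noise
distribution, learning rate decaying linearly 0.025 → 1e-4 over a default
3 epochs. The SGD inner loop is numba-compiled but strictly sequential and
fully seeded, so training is reproducible bit-for-bit; vectors persist in
the word2vec text format. Test-set patients' text is included in embedding
training (the embedding is unsupervised; still a potential source of mild
leakage, noted as a limitation).

A patient's representation for a chosen section/term set is
`X = [V M] ∈ R^{2P}`: `V` the mean and `M` the element-wise max of the
embedding vectors of the patient's matched terms. By default each distinct
matched term contributes once (term-set semantics; a flag switches to
per-occurrence pooling). Combining sections pools one mean/max over all
their terms, not per-section concatenation. A patient matching nothing is
the zero vector, keeping the classifier input well defined.

## Evaluation protocol and greedy selection

A stratified 20% test split is reserved up front; all selection quality is
the mean ± sd AUROC of 5-fold cross-validation on the remaining 80%, under
a fixed seed (folds are identical across candidates, so comparisons are
paired). Classifier kinds: gradient-boosted trees (default; 100 trees,
depth 3), random forest, logistic regression, SVM — hyperparameters are
frozen defaults since the goal is a reproducible harness, not tuning.

- **Section scoring.** AUC(Only) uses a section's top-K terms alone;
  AUC(Exclusion) pools every other section's terms. Sections are reported
  sorted by AUC(Only).
- **Section selection.** Forward greedy: each round re-pools the
  representation with each remaining section added and keeps the best
  improver. Default stopping: the best candidate fails to increase the mean
  AUC. The alternative reading — continue while either the mean rises or
  the sd falls — is available as `stopping="mean_or_sd"`; mean-based
  stopping is the conservative choice.
- **Term selection.** The forward path runs to exhaustion over the pooled
  top-K terms of the chosen sections (candidates evaluated serially in
  deterministic order, ties to the lexicographically smaller term), giving
  a size → mean-AUC curve. The curve is smoothed with a centered moving
  average (window 5, shrinking at the edges — parameter-free and
  monotone-respecting, standing in for an unspecified curve fit) and the
  prefix at the smoothed maximum (smallest size on ties) is the optimal
  subset. Internally the per-candidate representation is recomputed from a
  precomputed term-presence matrix; this is algebraically identical to
  re-pooling per patient and is covered by an equivalence test.
- **Final model.** The protocol's classifier trained on the 80% pool with
  the optimal terms; held-out AUROC plus sensitivity and specificity at the
  0.5 probability threshold (the operating point is otherwise unspecified).

## Padua baseline

Eleven boolean factors with weights 3 (active cancer/chemotherapy, previous
VTE, reduced mobility, thrombophilic condition), 2 (recent trauma/surgery)
and 1 (age ≥ 70, heart/respiratory failure, AMI/ischemic stroke,
infection/rheumatologic disorder, BMI ≥ 30, glucocorticoids); high risk at
score ≥ 4, maximum 20. Flags are consumed as structured per-patient columns
(clinician-scored), never extracted from text. The cohort summary reports
per-factor counts and percentages, score mean ± sd, and high-risk rates.

## Synthetic corpus generator

The generator emulates the *structure* of a two-cohort inpatient corpus,
not clinical language: per patient an admission document with titled
sections and a progress document with 2–4 dated entries; clause lengths
bounded-geometric (2–15 tokens); background words drawn from a Zipf
distribution (exponent 1.1 over 50 words by default) so common fillers
appear in nearly every instance; 15% of background clauses open with a
negation cue, emulating "denies X" boilerplate. Each planted term is
inserted, with cohort probability `p_case`/`p_control` per patient and
1 + Poisson(1) occurrences when present, as its own short clause with an
optional dedicated collocate token (rate 0.5) — the diagnosis-line style
that gives professional terms their low neighbor entropy; a negated
insertion is prefixed by a cue inside the clause. Padua flags are sampled
with cohort-specific prevalences defaulting to reported VTE vs non-VTE
inpatient rates. Everything derives from one seed; identical seeds yield
byte-identical output files.

What passing tests on this corpus do show: the weighting separates planted
cohort-specific, consistently-asserted, stereotyped terms from Zipf filler;
the greedy search recovers planted sections and terms; the harness is
calibrated under label permutation. What they do not show: robustness to
real segmentation errors, template diversity, section-title typos, or
distribution shift between hospitals — the generator has none of these.

## Numerical and design choices

- Entropy uses the natural log; IDF uses log10 (matching the two printed
  conventions). Consistency 0/0 → 0; σ at N = 1 → 0; empty neighbor set →
  penalty 1; `F_doc ∉ (0,1]` is a hard error.
- Consistency moments run over patients with ≥ 1 occurrence only — including
  absent patients would conflate prevalence with consistency, and prevalence
  is already TF-IDF's job.
- Negation is rule-based by design (cue-before-term within the clause); the
  cue list is a config so richer templates can be added. No dependency
  parsing or learned negation.
- The Chinese segmenter built-in is dictionary-driven forward maximum
  matching with single-character fallback and whole ASCII alphanumeric
  runs; synthetic corpora use the whitespace tokenizer. Numerals and units
  are kept as tokens.
- Test-suite problem sizes: the oracle suite uses ≤ 20 patients; recovery
  suites use n = 1,000 (five seeds) with P = 10, 2 epochs and a logistic
  selection classifier; the null suite uses n = 2,000. These sizes make the
  planted effects detectable while keeping the full greedy paths small
  enough to run routinely.

## Known limitations

- Embeddings are trained on the full corpus including later test patients
  (unsupervised leakage, flagged above).
- Token-exact matching misses multi-word ontology terms split by the
  segmenter; recall is traded for fidelity to the segmentation contract.
- The greedy searches are one-step lookahead; redundant-but-jointly-useful
  term pairs can be missed.
- Padua factor extraction from text is out of scope; flags must be
  supplied.
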