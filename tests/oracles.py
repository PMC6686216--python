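"""Independent brute-force recomputations used as test oracles.

These deliberately share no code with the implementation: every quantity is
recounted from raw sentences with naive loops and the formulas written out
directly.
"""

from __future__ import annotations

import math
import statistics


def instances_of(corpus, section, cohort=None):
    out = []
    for rec in corpus.records:
        if cohort is not None and rec.label != cohort:
            continue
        for sec in rec.sections.get(section, []):
            out.append((rec.patient_id, sec))
    return out


def brute_force_weights(corpus, terms, cues, section, cohort, window=5):
    """term -> dict of every W_o ingredient, recounted naively.

    F_word, F_doc and neighbor counts run over both cohorts; the
    consistency moments over the requested cohort only.
    """
    all_inst = instances_of(corpus, section)
    cohort_ids = {r.patient_id for r in corpus.records if r.label == cohort}
    total_tokens = sum(
        len(s.tokens) for _, sec in all_inst for s in sec.sentences
    )
    n_instances = len(all_inst)
    out = {}
    for term in terms:
        occ = 0
        containing = 0
        neighbors: dict[str, int] = {}
        pos_neg: dict[str, list[int]] = {}
        for pid, sec in all_inst:
            found = False
            for s in sec.sentences:
                toks = list(s.tokens)
                for i, tok in enumerate(toks):
                    if tok != term:
                        continue
                    found = True
                    occ += 1
                    for j in range(i - window, i + window + 1):
                        if j == i or j < 0 or j >= len(toks):
                            continue
                        neighbors[toks[j]] = neighbors.get(toks[j], 0) + 1
                    negated = any(t in cues for t in toks[:i])
                    pn = pos_neg.setdefault(pid, [0, 0])
                    pn[1 if negated else 0] += 1
            if found:
                containing += 1
        if occ == 0:
            continue
        cons = []
        for pid, (np_, nn) in pos_neg.items():
            if pid in cohort_ids:
                cons.append(abs(np_ - nn) / max(np_, nn))
        if not cons:
            continue
        f_word = occ / total_tokens
        f_doc = containing / n_instances
        total_nb = sum(neighbors.values())
        s_nb = 0.0
        for c in neighbors.values():
            p = c / total_nb
            s_nb += -p * math.log(p)
        penalty = 1.0 / (1.0 + s_nb)
        c_mean = statistics.fmean(cons)
        c_sd = statistics.stdev(cons) if len(cons) > 1 else 0.0
        w_o = f_word * math.log10(1.0 / f_doc) * penalty * c_mean * (1.0 + c_sd)
        out[term] = {
            "f_word": f_word,
            "f_doc": f_doc,
            "s_neighbor": s_nb,
            "penalty": penalty,
            "consistency_mean": c_mean,
            "consistency_sd": c_sd,
            "w_o": w_o,
        }
    return out


def brute_force_patient_vector(record, term_sets, model):
    """[mean | max] over the distinct matched terms, recomputed naively."""
    matched = set()
    for section, terms in term_sets.items():
        terms = set(terms)
        for sec in record.sections.get(section, []):
            for s in sec.sentences:
                for tok in s.tokens:
                    if tok in terms and tok in model:
                        matched.add(tok)
    p = model.vector_size
    if not matched:
        return [0.0] * (2 * p)
    vecs = [model[t] for t in sorted(matched)]
    mean = [sum(v[d] for v in vecs) / len(vecs) for d in range(p)]
    mx = [max(v[d] for v in vecs) for d in range(p)]
    return mean + mx
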