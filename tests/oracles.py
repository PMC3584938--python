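"""Independent brute-force oracles used to cross-check the implementation.

Everything here works on plain dicts (term -> parent set, protein -> term
set, hit tuples) with naive recursion/enumeration, deliberately sharing no
code with the package.
"""

from __future__ import annotations

import math
from collections import deque


# -- ontology -----------------------------------------------------------------


def naive_ancestors(parents: dict, term: str, include_self: bool = False) -> set:
    out = set()

    def walk(t):
        for p in parents.get(t, ()):
            if p not in out:
                out.add(p)
                walk(p)

    walk(term)
    if include_self:
        out.add(term)
    return out


def naive_propagate(parents: dict, terms) -> set:
    out = set()
    for t in terms:
        out |= naive_ancestors(parents, t, include_self=True)
    return out


def naive_edge_distance(parents: dict, t1: str, t2: str) -> int:
    """Breadth-first search over the undirected is_a skeleton."""
    adjacency: dict[str, set] = {t: set() for t in parents}
    for child, ps in parents.items():
        for p in ps:
            adjacency[child].add(p)
            adjacency.setdefault(p, set()).add(child)
    seen = {t1: 0}
    queue = deque([t1])
    while queue:
        node = queue.popleft()
        if node == t2:
            return seen[node]
        for nxt in adjacency.get(node, ()):
            if nxt not in seen:
                seen[nxt] = seen[node] + 1
                queue.append(nxt)
    raise ValueError("no path")


def n_paths_up(parents: dict, src: str, dst: str) -> int:
    """Number of distinct directed parent-paths from src up to dst."""
    if src == dst:
        return 1
    return sum(n_paths_up(parents, p, dst) for p in parents.get(src, ()))


def naive_freq(parents: dict, annot: dict, term: str) -> float:
    """Unrolled recursive frequency: every annotation of a descendant is
    counted once per distinct upward path (the multi-parent double-count)."""
    return float(sum(a * n_paths_up(parents, t, term) for t, a in annot.items()))


def naive_ic(parents: dict, annot: dict, term: str, root: str) -> float:
    p = naive_freq(parents, annot, term) / naive_freq(parents, annot, root)
    return -math.log10(p)


def naive_msa_ic(parents: dict, ic: dict, t1: str, t2: str) -> float:
    common = naive_ancestors(parents, t1, True) & naive_ancestors(parents, t2, True)
    values = [ic[c] for c in common if c in ic and not math.isnan(ic[c])]
    return max(values) if values else 0.0


# -- annotations --------------------------------------------------------------


def naive_cooccurrence(protein_terms: dict, fa: str, fj: str) -> float:
    """Double loop over proteins with direct annotations."""
    n_fj = sum(1 for terms in protein_terms.values() if fj in terms)
    if n_fj == 0:
        return 0.0
    n_both = sum(1 for terms in protein_terms.values() if fj in terms and fa in terms)
    return n_both / n_fj


# -- predictors ---------------------------------------------------------------


def naive_pfp(hits, protein_terms: dict, all_terms, b=2.0, ceiling=100.0,
              floor=1e-180) -> dict:
    """Literal triple loop over hits, hit annotations and candidate terms."""
    scores = {}
    for fa in all_terms:
        s = 0.0
        for hit in hits:
            if hit.evalue >= ceiling:
                continue
            w = -math.log10(max(hit.evalue, floor)) + b
            for fj in protein_terms.get(hit.subject, ()):
                s += w * naive_cooccurrence(protein_terms, fa, fj)
        if s != 0.0:
            scores[fa] = s
    return scores


def naive_transfer(raw: dict, parents: dict, annot: dict) -> dict:
    out = dict(raw)
    for fa, s in raw.items():
        fa_freq = naive_freq(parents, annot, fa)
        for fp in naive_ancestors(parents, fa):
            fp_freq = naive_freq(parents, annot, fp)
            if fp_freq > 0:
                out[fp] = out.get(fp, 0.0) + s * fa_freq / fp_freq
    return out


def _naive_weights(hits, floor):
    masses = [
        -math.log10(max(h.evalue, floor)) if h.evalue < 1 else 0.0 for h in hits
    ]
    total = sum(masses)
    return [m / total if total > 0 else 0.0 for m in masses]


def naive_esg(level1, level2: dict, protein_terms: dict, a=0.5, ceiling=100.0,
              floor=1e-180) -> dict:
    """Direct two-level enumeration of the weighted annotation transfer."""
    l1 = [h for h in level1 if h.evalue < ceiling]
    w1 = _naive_weights(l1, floor)
    scores: dict[str, float] = {}

    def add(term, value):
        scores[term] = scores.get(term, 0.0) + value

    for hit, w in zip(l1, w1):
        if w <= 0:
            continue
        seconds = [h for h in level2.get(hit.subject, ()) if h.evalue < ceiling]
        w2 = _naive_weights(seconds, floor)
        if sum(w2) > 0:
            for term in protein_terms.get(hit.subject, ()):
                add(term, w * a)
            for h2, wj in zip(seconds, w2):
                for term in protein_terms.get(h2.subject, ()):
                    add(term, w * (1 - a) * wj)
        else:
            for term in protein_terms.get(hit.subject, ()):
                add(term, w)
    return scores


def naive_gotcha(hits, protein_terms: dict, parents: dict, root: str,
                 floor=1e-180) -> dict:
    raw: dict[str, float] = {}
    for hit in hits:
        mass = -math.log10(max(hit.evalue, floor))
        if mass <= 0:
            continue
        terms = protein_terms.get(hit.subject, set())
        if not terms:
            continue
        for term in naive_propagate(parents, terms):
            raw[term] = raw.get(term, 0.0) + mass
    if raw.get(root, 0.0) <= 0:
        return {}
    return {t: v / raw[root] for t, v in raw.items()}


def naive_blast(hits, protein_terms: dict) -> dict:
    scores: dict[str, float] = {}
    for hit in hits:
        for term in protein_terms.get(hit.subject, ()):
            scores[term] = max(scores.get(term, 0.0), hit.pident / 100.0)
    return scores


def naive_prior(parents: dict, annot: dict, terms, root: str, n_max: int):
    root_freq = naive_freq(parents, annot, root)
    scored = {
        t: (naive_freq(parents, annot, t) + 1.0) / (root_freq + 1.0) for t in terms
    }
    return sorted(scored.items(), key=lambda kv: (-kv[1], kv[0]))[:n_max]


# -- evaluation ---------------------------------------------------------------


def naive_confusion(pred_items, truth, parents: dict, tau: float, root: str,
                    all_terms) -> tuple:
    pred = naive_propagate(parents, [t for t, s in pred_items if s >= tau]) - {root}
    true = naive_propagate(parents, truth) - {root}
    universe = set(all_terms) - {root}
    tp = len(pred & true)
    fp = len(pred - true)
    fn = len(true - pred)
    tn = len(universe - pred - true)
    return tp, fp, fn, tn


def naive_weighted(pred_items, truth, parents: dict, ic: dict, tau: float,
                   root: str) -> tuple:
    pred = naive_propagate(parents, [t for t, s in pred_items if s >= tau]) - {root}
    true = naive_propagate(parents, truth) - {root}

    def ic_sum(terms):
        return sum(ic[t] for t in terms if t in ic and not math.isnan(ic[t]))

    tp = ic_sum(pred & true)
    wprec = tp / ic_sum(pred) if ic_sum(pred) > 0 else None
    wrec = tp / ic_sum(true) if ic_sum(true) > 0 else None
    return wprec, wrec


def naive_semantic(pred_terms, truth_terms, parents: dict, ic: dict) -> tuple:
    pairs = [naive_msa_ic(parents, ic, p, t) for p in pred_terms for t in truth_terms]
    similarity = sum(pairs) / len(pairs)
    sprec = sum(
        ic[p] - max(naive_msa_ic(parents, ic, p, t) for t in truth_terms)
        for p in pred_terms
    ) / len(pred_terms)
    srec = sum(
        ic[t] - max(naive_msa_ic(parents, ic, p, t) for p in pred_terms)
        for t in truth_terms
    ) / len(truth_terms)
    return similarity, sprec, srec


def naive_target_fmax(pred_items, truth, parents: dict, root: str, all_terms,
                      taus) -> float:
    best = 0.0
    true = naive_propagate(parents, truth) - {root}
    for tau in taus:
        selected = [t for t, s in pred_items if s >= tau]
        pred = naive_propagate(parents, selected) - {root}
        tp = len(pred & true)
        precision = tp / len(pred) if pred else 0.0
        recall = tp / len(true)
        if precision + recall > 0:
            best = max(best, 2 * precision * recall / (precision + recall))
    return best
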