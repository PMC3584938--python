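"""CAFA-style assessment of GO term predictions against truth sets.

Four metric families over :class:`~gopred.predictors.PredictionSet` objects:

* threshold sweep — score cutoffs from 0.01 to 1.00; predicted and true term
  sets are propagated to the namespace root before counting TP/FP/FN/TN;
* top-N sweep — rank cutoffs (ties at the boundary included), either N = 1..20
  or the 1..1000-by-5 rank sweep used for unbounded raw scores;
* IC-weighted threshold sweep — precision/recall with every term weighted by
  its information content;
* semantic similarity — per-pair maximum shared-ancestor IC between
  unpropagated predicted and true terms, with semantic precision/recall as
  the mean IC excess/deficit relative to the best shared ancestor.

Plus the term-centric analysis: for a single GO term, targets annotated with
it (after propagation) are positives and the per-term F1 is the maximum over
cutoffs of the harmonic mean of precision and recall.

Conventions (configurable where noted): the namespace root is excluded from
all counted sets, since every non-empty prediction implies it; "above the
threshold" means ``score >= tau``; precision is averaged only over targets
with a non-empty prediction set at the cutoff while recall counts such
targets as zeros.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .ontology import OntologyDAG, TermStats, max_shared_ancestor_ic
from .predictors import PredictionSet

logger = logging.getLogger(__name__)


def default_taus() -> np.ndarray:
    """Score thresholds 0.01, 0.02, ..., 1.00."""
    return np.round(np.arange(1, 101) / 100.0, 2)


@dataclass
class TruthSet:
    """Target -> set of true GO terms (pre-propagation), with namespace tag."""

    truths: dict[str, set[str]] = field(default_factory=dict)
    namespace: str | None = None

    @property
    def targets(self) -> list[str]:
        return sorted(self.truths)

    def __getitem__(self, target: str) -> set[str]:
        return self.truths.get(target, set())

    def write_tsv(self, stream: IO[str]) -> None:
        for target in self.targets:
            for term in sorted(self.truths[target]):
                stream.write(f"{target}\t{term}\n")

    @classmethod
    def read_tsv(cls, stream: IO[str], namespace: str | None = None) -> "TruthSet":
        truths: dict[str, set[str]] = {}
        for lineno, line in enumerate(stream, start=1):
            line = line.strip()
            if not line or line.startswith("!"):
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                raise ValueError(f"truth line {lineno}: expected 2 columns")
            truths.setdefault(cols[0], set()).add(cols[1])
        return cls(truths=truths, namespace=namespace)


@dataclass
class EvalPoint:
    """Confusion counts and derived rates at one cutoff."""

    threshold: float
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else math.nan

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else math.nan

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if (self.tn + self.fp) else math.nan

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        if math.isnan(p) or math.isnan(r) or (p + r) == 0:
            return 0.0
        return 2 * p * r / (p + r)


def _roots(dag: OntologyDAG) -> set[str]:
    return set(dag.roots.values())


def propagated_truth(dag: OntologyDAG, truth: Iterable[str]) -> set[str]:
    """Ancestral closure of the truth set, minus the namespace root(s)."""
    return dag.propagate(t for t in truth if t in dag) - _roots(dag)


class _PredCache:
    """Propagated prediction sets for one ranked list, cached per prefix.

    The selected set changes only at distinct score values, so the closure is
    computed once per prefix length and shared across nearby cutoffs.
    """

    def __init__(self, dag: OntologyDAG, items: Sequence[tuple[str, float]]):
        self._dag = dag
        self._items = sorted(items, key=lambda kv: (-kv[1], kv[0]))
        self._scores = [s for _, s in self._items]
        self._cache: dict[int, frozenset[str]] = {0: frozenset()}

    def at_prefix(self, n: int) -> frozenset[str]:
        n = max(0, min(n, len(self._items)))
        if n not in self._cache:
            terms = [t for t, _ in self._items[:n] if t in self._dag]
            self._cache[n] = frozenset(self._dag.propagate(terms) - _roots(self._dag))
        return self._cache[n]

    def at_threshold(self, tau: float) -> frozenset[str]:
        # number of items with score >= tau (list is sorted descending)
        n = int(np.searchsorted(-np.asarray(self._scores), -tau, side="right"))
        return self.at_prefix(n)

    def at_rank(self, n: int, include_ties: bool = True) -> frozenset[str]:
        if n < 1 or not self._items:
            return self.at_prefix(min(max(n, 0), len(self._items)))
        if n >= len(self._items):
            return self.at_prefix(len(self._items))
        if not include_ties:
            return self.at_prefix(n)
        cutoff = self._scores[n - 1]
        m = n
        while m < len(self._items) and self._scores[m] == cutoff:
            m += 1
        return self.at_prefix(m)


def _counts(
    pred: frozenset[str] | set[str],
    truth: frozenset[str] | set[str],
    universe_size: int,
) -> tuple[int, int, int, int]:
    tp = len(pred & truth)
    fp = len(pred) - tp
    fn = len(truth) - tp
    tn = universe_size - len(pred | truth)
    return tp, fp, fn, tn


def _universe_size(
    dag: OntologyDAG, namespace: str, universe: Iterable[str] | None
) -> int:
    if universe is not None:
        return len(set(universe))
    return len(dag.namespace_terms(namespace)) - 1  # minus the root


def _namespace_of_truth(dag: OntologyDAG, truth: Iterable[str]) -> str:
    for term in truth:
        if term in dag:
            return dag.namespace_of(term)
    raise ValueError("no truth term is present in the ontology")


def confusion_at_threshold(
    pred_items: Sequence[tuple[str, float]],
    truth_terms: set[str],
    dag: OntologyDAG,
    tau: float,
    universe: Iterable[str] | None = None,
) -> EvalPoint:
    """Confusion counts for one target at one score cutoff.

    Both the selected predictions (``score >= tau``) and the truth are
    propagated to the root, which is then excluded; the negative universe
    defaults to all namespace terms minus the root.
    """
    if not truth_terms:
        raise ValueError("empty truth set: recall is undefined")
    namespace = _namespace_of_truth(dag, truth_terms)
    truth = propagated_truth(dag, truth_terms)
    pred = _PredCache(dag, pred_items).at_threshold(tau)
    tp, fp, fn, tn = _counts(pred, truth, _universe_size(dag, namespace, universe))
    return EvalPoint(threshold=tau, tp=tp, fp=fp, fn=fn, tn=tn)


def _evaluable(
    predset: PredictionSet, truthset: TruthSet, dag: OntologyDAG
) -> list[tuple[str, _PredCache, frozenset[str]]]:
    out = []
    for target in truthset.targets:
        truth_terms = truthset[target]
        truth = frozenset(propagated_truth(dag, truth_terms))
        if not truth:
            logger.info("target %s has empty (or unknown) truth; skipped", target)
            continue
        out.append((target, _PredCache(dag, predset[target]), truth))
    return out


def _average_points(
    per_target_sets: list[tuple[frozenset[str], frozenset[str]]],
    universe_size: int,
    cutoff: float,
) -> dict[str, float]:
    precisions, recalls, specificities = [], [], []
    for pred, truth in per_target_sets:
        tp, fp, fn, tn = _counts(pred, truth, universe_size)
        if pred:
            precisions.append(tp / (tp + fp))
        recalls.append(tp / (tp + fn))
        if tn + fp:
            specificities.append(tn / (tn + fp))
    return {
        "threshold": cutoff,
        "precision": float(np.mean(precisions)) if precisions else math.nan,
        "recall": float(np.mean(recalls)) if recalls else math.nan,
        "specificity": float(np.mean(specificities)) if specificities else math.nan,
        "n_targets": len(per_target_sets),
        "n_targets_precision": len(precisions),
    }


def threshold_curves(
    predset: PredictionSet,
    truthset: TruthSet,
    dag: OntologyDAG,
    taus: Sequence[float] | None = None,
    universe: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Average precision/recall/specificity across targets per score cutoff."""
    taus = default_taus() if taus is None else np.asarray(taus)
    entries = _evaluable(predset, truthset, dag)
    if not entries:
        return pd.DataFrame()
    namespace = dag.namespace_of(next(iter(entries[0][2])))
    usize = _universe_size(dag, namespace, universe)
    rows = []
    for tau in taus:
        sets = [(cache.at_threshold(float(tau)), truth) for _, cache, truth in entries]
        rows.append(_average_points(sets, usize, float(tau)))
    return pd.DataFrame(rows)


def topn_curves(
    predset: PredictionSet,
    truthset: TruthSet,
    dag: OntologyDAG,
    n_grid: Sequence[int] | None = None,
    include_ties: bool = True,
    universe: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Average metrics at rank cutoffs N (default 1..20, ties included)."""
    n_grid = list(range(1, 21)) if n_grid is None else list(n_grid)
    entries = _evaluable(predset, truthset, dag)
    if not entries:
        return pd.DataFrame()
    namespace = dag.namespace_of(next(iter(entries[0][2])))
    usize = _universe_size(dag, namespace, universe)
    rows = []
    for n in n_grid:
        sets = [(cache.at_rank(n, include_ties), truth) for _, cache, truth in entries]
        row = _average_points(sets, usize, float(n))
        row["n"] = n
        rows.append(row)
    return pd.DataFrame(rows)


def topk_curves(
    predset: PredictionSet,
    truthset: TruthSet,
    dag: OntologyDAG,
    n_max: int = 1000,
    step: int = 5,
    **kwargs,
) -> pd.DataFrame:
    """Rank sweep for unbounded raw scores: N = 1, then 5..n_max by ``step``."""
    grid = [1] + list(range(step, n_max + 1, step))
    return topn_curves(predset, truthset, dag, n_grid=grid, **kwargs)


def weighted_curves(
    predset: PredictionSet,
    truthset: TruthSet,
    stats: TermStats,
    dag: OntologyDAG,
    taus: Sequence[float] | None = None,
) -> pd.DataFrame:
    """IC-weighted precision and recall per score cutoff.

    wPrec = sum IC(TP) / sum IC(TP u FP) and wRec = sum IC(TP) / sum IC(TP u
    FN), with the same propagated sets as the threshold method; terms with
    undefined IC are dropped from the sets (logged once).
    """
    taus = default_taus() if taus is None else np.asarray(taus)
    entries = _evaluable(predset, truthset, dag)
    if not entries:
        return pd.DataFrame()

    def ic_sum(terms: Iterable[str]) -> float:
        return sum(stats.ic[t] for t in terms if stats.is_defined(t))

    rows = []
    for tau in taus:
        wprec, wrec = [], []
        for _, cache, truth in entries:
            pred = cache.at_threshold(float(tau))
            tp_ic = ic_sum(pred & truth)
            p_ic = ic_sum(pred)
            t_ic = ic_sum(truth)
            if pred and p_ic > 0:
                wprec.append(tp_ic / p_ic)
            if t_ic > 0:
                wrec.append(tp_ic / t_ic)
        rows.append(
            {
                "threshold": float(tau),
                "weighted_precision": float(np.mean(wprec)) if wprec else math.nan,
                "weighted_recall": float(np.mean(wrec)) if wrec else math.nan,
                "n_targets": len(entries),
                "n_targets_precision": len(wprec),
            }
        )
    return pd.DataFrame(rows)


def semantic_curves(
    predset: PredictionSet,
    truthset: TruthSet,
    stats: TermStats,
    dag: OntologyDAG,
    taus: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Shared-ancestor IC similarity and semantic precision/recall per cutoff.

    Operates on *unpropagated* predicted and true term sets.  Per target:
    similarity is the mean over all (true, predicted) pairs of the maximum
    shared-ancestor IC; semantic precision is the mean over predicted terms p
    of ``IC(p) - max over true t of sharedIC(p, t)`` (deficit of specificity
    support), semantic recall the analogue over true terms.  Targets with an
    empty prediction set at a cutoff are excluded from that cutoff's means.
    """
    taus = default_taus() if taus is None else np.asarray(taus)
    pair_cache: dict[tuple[str, str], float] = {}

    def shared(p: str, t: str) -> float:
        key = (p, t) if p <= t else (t, p)
        if key not in pair_cache:
            pair_cache[key] = max_shared_ancestor_ic(dag, stats, key[0], key[1])
        return pair_cache[key]

    entries = []
    for target in truthset.targets:
        truth = sorted(
            t for t in truthset[target] if t in dag and stats.is_defined(t)
        )
        if not truth:
            logger.info("target %s has no truth terms with defined IC; skipped", target)
            continue
        items = sorted(predset[target], key=lambda kv: (-kv[1], kv[0]))
        entries.append((target, items, truth))

    rows = []
    for tau in taus:
        sims, sprecs, srecs = [], [], []
        for _, items, truth in entries:
            pred = [
                t for t, s in items if s >= tau and t in dag and stats.is_defined(t)
                and dag.namespace_of(t) == dag.namespace_of(truth[0])
            ]
            if not pred:
                continue
            sims.append(
                float(np.mean([shared(p, t) for p in pred for t in truth]))
            )
            sprecs.append(
                float(np.mean([stats.ic[p] - max(shared(p, t) for t in truth)
                               for p in pred]))
            )
            srecs.append(
                float(np.mean([stats.ic[t] - max(shared(p, t) for p in pred)
                               for t in truth]))
            )
        rows.append(
            {
                "threshold": float(tau),
                "semantic_similarity": float(np.mean(sims)) if sims else math.nan,
                "semantic_precision": float(np.mean(sprecs)) if sprecs else math.nan,
                "semantic_recall": float(np.mean(srecs)) if srecs else math.nan,
                "n_targets": len(sims),
            }
        )
    return pd.DataFrame(rows)


def evaluable_terms(
    truthset: TruthSet, dag: OntologyDAG, min_targets: int = 25
) -> list[str]:
    """Terms contained in the propagated truth of >= ``min_targets`` targets."""
    if min_targets < 1:
        raise ValueError("min_targets must be >= 1")
    counts: dict[str, int] = {}
    for target in truthset.targets:
        for term in propagated_truth(dag, truthset[target]):
            counts[term] = counts.get(term, 0) + 1
    selected = [t for t, n in counts.items() if n >= min_targets]
    return sorted(selected, key=lambda t: (-counts[t], t))


def per_term_f1(
    predset: PredictionSet,
    truthset: TruthSet,
    dag: OntologyDAG,
    term: str,
    taus: Sequence[float] | None = None,
) -> float:
    """Term-centric max-F1: targets whose propagated truth contains ``term``
    are positives; per cutoff a target is TP when its propagated prediction
    set contains the term; the returned value is the maximum over cutoffs of
    the harmonic mean of precision and recall."""
    taus = default_taus() if taus is None else np.asarray(taus)
    entries = _evaluable(predset, truthset, dag)
    positives = [(c, True) for _, c, truth in entries if term in truth]
    negatives = [(c, False) for _, c, truth in entries if term not in truth]
    if not positives:
        raise ValueError(f"no target is annotated with {term!r}")
    best = 0.0
    for tau in taus:
        tp = sum(1 for c, _ in positives if term in c.at_threshold(float(tau)))
        fn = len(positives) - tp
        fp = sum(1 for c, _ in negatives if term in c.at_threshold(float(tau)))
        precision = tp / (tp + fp) if (tp + fp) else 0.0
        recall = tp / (tp + fn)
        if precision + recall > 0:
            best = max(best, 2 * precision * recall / (precision + recall))
    return best


def target_fmax(
    pred_items: Sequence[tuple[str, float]],
    truth_terms: set[str],
    dag: OntologyDAG,
    taus: Sequence[float] | None = None,
    universe: Iterable[str] | None = None,
) -> float:
    """Per-target F1: max over cutoffs of the harmonic mean of precision and
    recall on propagated sets (an empty prediction set scores 0)."""
    taus = default_taus() if taus is None else np.asarray(taus)
    if not truth_terms:
        raise ValueError("empty truth set")
    namespace = _namespace_of_truth(dag, truth_terms)
    truth = frozenset(propagated_truth(dag, truth_terms))
    cache = _PredCache(dag, pred_items)
    usize = _universe_size(dag, namespace, universe)
    best = 0.0
    for tau in taus:
        pred = cache.at_threshold(float(tau))
        tp, fp, fn, _ = _counts(pred, truth, usize)
        precision = tp / (tp + fp) if pred else 0.0
        recall = tp / (tp + fn)
        if precision + recall > 0:
            best = max(best, 2 * precision * recall / (precision + recall))
    return best


# -- ranking quality ----------------------------------------------------------


def ranking_auc(
    scores: Mapping[str, float],
    positive_terms: set[str],
    dag: OntologyDAG,
    namespace: str,
) -> float:
    """ROC AUC of a score map against a positive term set.

    The universe is every namespace term except the root; unscored terms get
    score 0.  Positives are intended to be a target's *direct* truth terms:
    with propagated labels any depth-correlated scorer beats chance for
    structural reasons alone, whereas direct labels give an uninformed
    ranking an expected AUC of 1/2.  Returns nan when the positives are
    empty or cover the whole universe.
    """
    from sklearn.metrics import roc_auc_score

    universe = sorted(dag.namespace_terms(namespace) - {dag.root(namespace)})
    y = np.array([1 if t in positive_terms else 0 for t in universe])
    if y.sum() == 0 or y.sum() == len(y):
        return math.nan
    s = np.array([scores.get(t, 0.0) for t in universe])
    return float(roc_auc_score(y, s))


def mean_ranking_auc(
    predset: PredictionSet,
    truthset: TruthSet,
    dag: OntologyDAG,
    namespace: str,
) -> float:
    """Mean per-target :func:`ranking_auc` over all targets with usable truth."""
    values = []
    for target in truthset.targets:
        pos = {t for t in truthset[target] if t in dag}
        auc = ranking_auc(predset.scores(target), pos, dag, namespace)
        if not math.isnan(auc):
            values.append(auc)
    if not values:
        return math.nan
    return float(np.mean(values))
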