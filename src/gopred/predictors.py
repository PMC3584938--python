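"""Homology-based GO term scoring methods and prediction-set handling.

Five scorers plus an enrichment combiner, all producing ranked
:class:`PredictionSet` objects:

``pfp``
    Accumulates, over every search hit i and every direct annotation f_j of
    that hit, the quantity ``(-log10(E_i) + b) * P(fa | f_j)`` for every term
    fa co-occurring with f_j (a double sum with b = log10 of the E-value
    ceiling so the log term stays positive).  Raw scores are then
    shared root-ward: each scored term adds ``s(fa) * freq(fa)/freq(fp)`` to
    every proper ancestor fp.  Optionally, raw scores are converted to
    confidences via term-specific empirical p-values and the per-bin fraction
    of correct benchmark predictions within edge distance k of a true term.

``esg``
    Iterative-search scoring: each level-1 hit carries a normalized
    -log10(E) weight; a hit with a second-level search splits its weight
    between its own annotations (fraction ``a``) and its level-2 hits'
    annotations (fraction ``1 - a``, spread by the level-2 weights).  Scores
    lie in [0, 1].

``gotcha``
    Sums max(0, -log10 E) over hits onto each hit's propagated annotation
    set and normalizes by the root's total (the I-score).

``blast``
    Max percent identity over hits directly annotated with a term, / 100.

``prior``
    Target-independent ranking by database frequency with a pseudocount of
    1: ``(freq(c) + 1) / (freq(root) + 1)``.

Prediction lists are truncated to the 1000 highest-scoring terms.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Sequence

import numpy as np

from .annotations import AnnotationDB, CooccurrenceTable
from .ontology import OntologyDAG, TermStats
from .search_io import (
    DEFAULT_E_CEILING,
    DEFAULT_E_FLOOR,
    Hit,
    HitGraph,
    build_hit_graph,
)

logger = logging.getLogger(__name__)

MAX_PREDICTIONS = 1000

#: Header keywords tolerated (and skipped) when reading prediction files.
_SKIP_PREFIXES = ("AUTHOR", "MODEL", "KEYWORDS", "END")


def rank_terms(
    scores: Mapping[str, float], max_terms: int | None = MAX_PREDICTIONS
) -> list[tuple[str, float]]:
    """Sort by score descending, ties by term id ascending; truncate."""
    ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    if max_terms is not None:
        ranked = ranked[:max_terms]
    return ranked


@dataclass
class PredictionSet:
    """Per-target ranked (term, score) lists produced by one method."""

    method: str
    predictions: dict[str, list[tuple[str, float]]] = field(default_factory=dict)

    @classmethod
    def from_scores(
        cls,
        method: str,
        per_target: Mapping[str, Mapping[str, float]],
        max_terms: int | None = MAX_PREDICTIONS,
    ) -> "PredictionSet":
        return cls(
            method=method,
            predictions={
                target: rank_terms(scores, max_terms)
                for target, scores in per_target.items()
            },
        )

    @property
    def targets(self) -> list[str]:
        return sorted(self.predictions)

    def __getitem__(self, target: str) -> list[tuple[str, float]]:
        return self.predictions.get(target, [])

    def scores(self, target: str) -> dict[str, float]:
        return dict(self[target])

    def write_tsv(self, stream: IO[str]) -> None:
        for target in self.targets:
            for term, score in self.predictions[target]:
                stream.write(f"{target}\t{term}\t{score:.6f}\n")

    @classmethod
    def read_tsv(cls, stream: IO[str], method: str = "file") -> "PredictionSet":
        predictions: dict[str, list[tuple[str, float]]] = {}
        for lineno, line in enumerate(stream, start=1):
            line = line.strip()
            if not line or line.split(maxsplit=1)[0] in _SKIP_PREFIXES:
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ValueError(f"prediction line {lineno}: expected 3 columns")
            predictions.setdefault(cols[0], []).append((cols[1], float(cols[2])))
        out = cls(method=method)
        for target, items in predictions.items():
            out.predictions[target] = rank_terms(dict(items), None)
        return out


def truncate_predictions(preds: PredictionSet, k: int = MAX_PREDICTIONS) -> PredictionSet:
    """Keep the k highest-scoring terms per target (ties: smaller id first)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return PredictionSet(
        method=preds.method,
        predictions={
            target: rank_terms(dict(items), k)
            for target, items in preds.predictions.items()
        },
    )


# -- PFP ----------------------------------------------------------------------


@dataclass
class PFPParams:
    """Constants of the PFP accumulation.

    ``b`` keeps the log term positive up to the E-value ceiling; with the
    default ceiling of 100, b = log10(100) = 2.
    """

    b: float = 2.0
    e_ceiling: float = DEFAULT_E_CEILING
    e_floor: float = DEFAULT_E_FLOOR


def pfp_raw_scores(
    hits: Iterable[Hit],
    db: AnnotationDB,
    cooc: CooccurrenceTable,
    dag: OntologyDAG,
    namespace: str,
    params: PFPParams | None = None,
) -> dict[str, float]:
    """Direct PFP accumulation: s(fa) = sum_i sum_j (-log10 E_i + b) P(fa|fj).

    Scores are produced for every term with nonzero co-occurrence against any
    observed annotation.  Hits at or above the E-value ceiling are ignored.
    """
    params = params or PFPParams()
    scores: dict[str, float] = defaultdict(float)
    for hit in hits:
        if hit.evalue >= params.e_ceiling:
            continue
        weight = -math.log10(max(hit.evalue, params.e_floor)) + params.b
        for fj in db.terms_of(hit.subject, dag, namespace):
            for fa, p in cooc.conditional_given(fj).items():
                scores[fa] += weight * p
    return dict(scores)


def pfp_parent_transfer(
    raw_scores: Mapping[str, float],
    dag: OntologyDAG,
    stats: TermStats,
) -> dict[str, float]:
    """Share each raw score root-ward in proportion to term frequencies.

    Every directly scored term fa adds ``s(fa) * freq(fa) / freq(fp)`` to each
    proper ancestor fp; the result per term is its direct score plus all
    received transfers (ancestors absent from the input appear in the output).
    """
    out: dict[str, float] = defaultdict(float, raw_scores)
    for fa, score in raw_scores.items():
        freq_a = stats.freq.get(fa)
        if freq_a is None:
            logger.warning("term %s missing from stats; transfer skipped", fa)
            continue
        for fp in dag.ancestors(fa):
            freq_p = stats.freq.get(fp, 0.0)
            if freq_p > 0:
                out[fp] += score * freq_a / freq_p
    return dict(out)


@dataclass
class CalibrationTable:
    """Background raw-score samples and binned correctness fractions.

    ``fractions[k]`` holds, per empirical-p-value bin, the fraction of
    benchmark predictions whose term lay within edge distance ``k`` of a true
    term, pooled isotonically so confidence never increases with p.
    """

    backgrounds: dict[str, np.ndarray]
    pooled: np.ndarray
    bin_edges: np.ndarray
    fractions: dict[int, np.ndarray]
    min_background: int = 5

    def background_for(self, term: str) -> np.ndarray:
        bg = self.backgrounds.get(term)
        if bg is None or len(bg) < self.min_background:
            return self.pooled
        return bg

    def pvalue(self, term: str, score: float) -> float:
        return empirical_pvalue(self.background_for(term), score)

    def confidence(self, term: str, score: float, k: int = 0) -> float:
        if k not in self.fractions:
            raise KeyError(f"no calibration at edge distance k={k}")
        p = self.pvalue(term, score)
        idx = int(np.clip(np.searchsorted(self.bin_edges, p, side="right") - 1,
                          0, len(self.bin_edges) - 2))
        return float(self.fractions[k][idx])


def empirical_pvalue(background: np.ndarray, score: float) -> float:
    """Inclusive upper-tail empirical p-value P[X >= score].

    With n background samples the p-value is (number >= score) / n; a score
    strictly above every sample gets the add-one floor 1 / (n + 1).
    """
    n = len(background)
    if n == 0:
        return 1.0
    n_ge = int(n - np.searchsorted(background, score, side="left"))
    if n_ge == 0:
        return 1.0 / (n + 1)
    return n_ge / n


def build_calibration(
    predictions: Iterable[tuple[str, str, float]],
    truths: Mapping[str, set[str]],
    dag: OntologyDAG,
    k_values: Sequence[int] = (0, 2, 4),
    n_bins: int = 10,
    min_background: int = 5,
) -> CalibrationTable:
    """Build the p-value -> fraction-correct table from benchmark predictions.

    Parameters
    ----------
    predictions:
        (target, term, raw score) records for benchmark targets.
    truths:
        Benchmark target -> true term set; a prediction is correct at edge
        distance k when its term lies within k is_a edges of some true term.
    """
    from sklearn.isotonic import IsotonicRegression

    records = [
        (target, term, float(score))
        for target, term, score in predictions
        if target in truths and truths[target]
    ]
    if not records:
        raise ValueError("no benchmark predictions overlap the truth set")

    per_term: dict[str, list[float]] = defaultdict(list)
    for _, term, score in records:
        per_term[term].append(score)
    backgrounds = {t: np.sort(np.asarray(v)) for t, v in per_term.items()}
    pooled = np.sort(np.asarray([s for _, _, s in records]))
    n_small = sum(1 for v in backgrounds.values() if len(v) < min_background)
    if n_small:
        logger.info(
            "%d terms have < %d background samples; pooled background used",
            n_small, min_background,
        )

    table = CalibrationTable(
        backgrounds=backgrounds,
        pooled=pooled,
        bin_edges=np.linspace(0.0, 1.0, n_bins + 1),
        fractions={},
        min_background=min_background,
    )

    pvals: list[float] = []
    dists: list[float] = []
    for target, term, score in records:
        truth = [t for t in truths[target]
                 if t in dag and dag.namespace_of(t) == dag.namespace_of(term)]
        if not truth:
            continue
        pvals.append(table.pvalue(term, score))
        dists.append(min(dag.edge_distance(term, t) for t in truth))
    if not pvals:
        raise ValueError("no benchmark prediction shares a namespace with its truth")
    p_arr = np.asarray(pvals)
    d_arr = np.asarray(dists)
    centers = (table.bin_edges[:-1] + table.bin_edges[1:]) / 2
    for k in k_values:
        iso = IsotonicRegression(y_min=0.0, y_max=1.0, increasing=False,
                                 out_of_bounds="clip")
        iso.fit(p_arr, (d_arr <= k).astype(float))
        table.fractions[int(k)] = iso.predict(centers)
    return table


def pfp_confidence(
    raw_scores: Mapping[str, float],
    calibration: CalibrationTable | None,
    k: int = 0,
) -> dict[str, float]:
    """Map raw scores (after parent transfer) to [0, 1] confidences.

    Each term's raw score is converted to a term-specific empirical p-value
    and looked up in the calibration table at edge distance ``k``.
    """
    if calibration is None:
        raise ValueError(
            "no calibration table available; rank predictions by raw score instead"
        )
    return {
        term: calibration.confidence(term, score, k)
        for term, score in raw_scores.items()
    }


# -- ESG ----------------------------------------------------------------------


def esg_scores(
    hit_graph: HitGraph,
    db: AnnotationDB,
    dag: OntologyDAG,
    namespace: str,
    a: float = 0.5,
) -> dict[str, float]:
    """Two-level iterative-search scores in [0, 1].

    A level-1 hit with weight w and a level-2 search contributes
    ``w * a`` to its own annotations and ``w * (1 - a) * w_j`` to the
    annotations of each level-2 hit j; without a level-2 search (or with one
    carrying no positive weight) its full weight goes to its own annotations.
    """
    if not 0 <= a <= 1:
        raise ValueError("mixing parameter a must lie in [0, 1]")
    scores: dict[str, float] = defaultdict(float)
    for hit, weight in zip(hit_graph.hits, hit_graph.weights):
        if weight <= 0:
            continue
        own = db.terms_of(hit.subject, dag, namespace)
        level2 = hit_graph.level2.get(hit.subject)
        if level2 is not None and sum(level2[1]) > 0:
            for term in own:
                scores[term] += weight * a
            hits2, weights2 = level2
            for hit2, w2 in zip(hits2, weights2):
                if w2 <= 0:
                    continue
                for term in db.terms_of(hit2.subject, dag, namespace):
                    scores[term] += weight * (1 - a) * w2
        else:
            for term in own:
                scores[term] += weight
    return dict(scores)


# -- GOtcha -------------------------------------------------------------------


def gotcha_scores(
    hits: Iterable[Hit],
    db: AnnotationDB,
    dag: OntologyDAG,
    namespace: str,
    e_floor: float = DEFAULT_E_FLOOR,
) -> dict[str, float]:
    """I-scores: summed max(0, -log10 E) over propagated hit annotations,
    normalized by the root's total.  Empty when no positive-scoring hit has a
    usable annotation."""
    raw: dict[str, float] = defaultdict(float)
    for hit in hits:
        mass = -math.log10(max(hit.evalue, e_floor))
        if mass <= 0:
            continue
        terms = db.terms_of(hit.subject, dag, namespace)
        if not terms:
            continue
        for term in dag.propagate(terms):
            raw[term] += mass
    root = dag.root(namespace)
    root_mass = raw.get(root, 0.0)
    if root_mass <= 0:
        return {}
    return {term: value / root_mass for term, value in raw.items()}


# -- BLAST baseline -----------------------------------------------------------


def blast_baseline(
    hits: Iterable[Hit],
    db: AnnotationDB,
    dag: OntologyDAG,
    namespace: str,
) -> dict[str, float]:
    """Max percent identity (scaled to [0, 1]) over hits directly annotated
    with each term; hits without usable annotations yield no predictions."""
    scores: dict[str, float] = {}
    for hit in hits:
        value = hit.pident / 100.0
        for term in db.terms_of(hit.subject, dag, namespace):
            if value > scores.get(term, -1.0):
                scores[term] = value
    return scores


# -- Prior --------------------------------------------------------------------


def prior_predictions(
    stats: TermStats,
    dag: OntologyDAG,
    namespace: str,
    n_max: int = MAX_PREDICTIONS,
) -> list[tuple[str, float]]:
    """Target-independent ranking by pseudocounted database frequency:
    score(c) = (freq(c) + 1) / (freq(root) + 1)."""
    root_freq = stats.freq[dag.root(namespace)]
    scores = {
        term: (stats.freq.get(term, 0.0) + 1.0) / (root_freq + 1.0)
        for term in dag.namespace_terms(namespace)
    }
    return rank_terms(scores, n_max)


def prior_prediction_set(
    stats: TermStats,
    dag: OntologyDAG,
    namespace: str,
    targets: Iterable[str],
    n_max: int = MAX_PREDICTIONS,
) -> PredictionSet:
    """Assign the identical prior list to every target."""
    prior = prior_predictions(stats, dag, namespace, n_max)
    return PredictionSet(
        method="prior", predictions={target: list(prior) for target in targets}
    )


def enrich_with_prior(
    preds: PredictionSet,
    prior: Sequence[tuple[str, float]],
    mode: str,
) -> PredictionSet:
    """Merge prior terms absent from a method's predictions into its lists.

    ``mode="pfp"``: imported scores are linearly rescaled from the prior
    list's [min, max] onto the target's own [min, max] (the method's scores
    are confidences / expected accuracies).  ``mode="esg"``: imported scores
    are kept as-is, since both scales already live in [0, 1].  A target with
    an empty prediction list receives the prior list unrescaled (logged).
    """
    if mode not in {"pfp", "esg"}:
        raise ValueError(f"mode must be 'pfp' or 'esg', got {mode!r}")
    if not prior:
        raise ValueError("empty prior list")
    prior_scores = [s for _, s in prior]
    pmin, pmax = min(prior_scores), max(prior_scores)
    merged: dict[str, list[tuple[str, float]]] = {}
    for target, items in preds.predictions.items():
        if not items:
            logger.info(
                "target %s has no %s predictions; prior used unrescaled",
                target, preds.method,
            )
            merged[target] = rank_terms(dict(prior), MAX_PREDICTIONS)
            continue
        combined = dict(items)
        have = set(combined)
        own_scores = [s for _, s in items]
        omin, omax = min(own_scores), max(own_scores)
        for term, score in prior:
            if term in have:
                continue
            if mode == "pfp":
                if pmax > pmin:
                    score = omin + (score - pmin) * (omax - omin) / (pmax - pmin)
                else:
                    logger.info("degenerate prior score range; imports mapped to min")
                    score = omin
            combined[term] = score
        merged[target] = rank_terms(combined, MAX_PREDICTIONS)
    return PredictionSet(method=f"{preds.method}+prior", predictions=merged)


# -- dispatch -----------------------------------------------------------------

METHODS = (
    "pfp", "pfp-raw", "esg", "gotcha", "blast", "prior", "pfp+prior", "esg+prior",
)


def run_predictor(
    method: str,
    dag: OntologyDAG,
    db: AnnotationDB,
    namespace: str,
    hits: Mapping[str, Sequence[Hit]],
    level2: Mapping[str, Sequence[Hit]] | None = None,
    targets: Iterable[str] | None = None,
    esg_a: float = 0.5,
    params: PFPParams | None = None,
    calibration_truth: Mapping[str, set[str]] | None = None,
    confidence_k: int = 0,
    stats: TermStats | None = None,
    max_terms: int = MAX_PREDICTIONS,
) -> PredictionSet:
    """Run one scoring method over per-target hit lists.

    This is the single entry point the command line and the end-to-end tests
    use; it wires together term statistics, co-occurrence tables, hit graphs
    and (for the confidence-scored variant) the empirical calibration built
    from ``calibration_truth``.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    params = params or PFPParams()
    target_list = sorted(targets) if targets is not None else sorted(hits)
    if stats is None and method in {"pfp", "pfp-raw", "prior", "pfp+prior", "esg+prior"}:
        counts = db.direct_counts(dag, namespace)
        from .ontology import compute_term_stats

        stats = compute_term_stats(dag, counts)

    def pfp_raw_all() -> dict[str, dict[str, float]]:
        cooc = CooccurrenceTable.build(db, dag, namespace)
        out = {}
        for target in target_list:
            raw = pfp_raw_scores(hits.get(target, []), db, cooc, dag, namespace, params)
            out[target] = pfp_parent_transfer(raw, dag, stats)
        return out

    if method == "pfp-raw":
        return PredictionSet.from_scores("pfp-raw", pfp_raw_all(), max_terms)

    if method in {"pfp", "pfp+prior"}:
        if calibration_truth is None:
            raise ValueError(
                "method 'pfp' needs calibration_truth to build the confidence "
                "calibration; use 'pfp-raw' for raw-score ranking"
            )
        raw_all = pfp_raw_all()
        records = [
            (target, term, score)
            for target, scores in raw_all.items()
            if target in calibration_truth
            for term, score in scores.items()
        ]
        calibration = build_calibration(records, calibration_truth, dag)
        per_target = {
            target: pfp_confidence(scores, calibration, k=confidence_k)
            for target, scores in raw_all.items()
        }
        preds = PredictionSet.from_scores("pfp", per_target, max_terms)
        if method == "pfp":
            return preds
        prior = prior_predictions(stats, dag, namespace, max_terms)
        return enrich_with_prior(preds, prior, mode="pfp")

    if method in {"esg", "esg+prior"}:
        per_target = {}
        for target in target_list:
            graph = build_hit_graph(
                target, hits.get(target, []), level2,
                e_ceiling=params.e_ceiling, e_floor=params.e_floor,
            )
            per_target[target] = esg_scores(graph, db, dag, namespace, a=esg_a)
        preds = PredictionSet.from_scores("esg", per_target, max_terms)
        if method == "esg":
            return preds
        if stats is None:
            raise ValueError("esg+prior needs term stats")
        prior = prior_predictions(stats, dag, namespace, max_terms)
        return enrich_with_prior(preds, prior, mode="esg")

    if method == "gotcha":
        per_target = {
            target: gotcha_scores(hits.get(target, []), db, dag, namespace,
                                  e_floor=params.e_floor)
            for target in target_list
        }
        return PredictionSet.from_scores("gotcha", per_target, max_terms)

    if method == "blast":
        per_target = {
            target: blast_baseline(hits.get(target, []), db, dag, namespace)
            for target in target_list
        }
        return PredictionSet.from_scores("blast", per_target, max_terms)

    # prior
    return prior_prediction_set(stats, dag, namespace, target_list, max_terms)
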