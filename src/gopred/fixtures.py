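"""Synthetic desk-scale benchmarks and the hand-checked D0 micro-dataset.

The generator emulates the study setting the predictors assume: a searchable
annotation database, a set of prediction targets with held-out truth, and
per-target sequence-search results whose E-value structure carries a planted
homology signal.

Truth for each synthetic target is derived from a hidden "donor" protein that
is excluded from the searchable database: the donor's direct annotations are
the target's specific truth and their ancestral closure (minus the root) is
written to the truth file.  Signal hits are database proteins sharing at
least one direct truth term with the donor (E-values drawn log-uniform from a
strong range); noise hits are arbitrary database proteins with weak E-values,
some above 1 to exercise the clamping rules.  Every draw is governed by a
single integer seed; one independent stream per artifact (ontology /
annotations / searches) so components can be regenerated separately.

What this emulates — and what it does not: hit lists have realistic E-value
contrast between homologous and spurious hits, but there are no sequences, no
alignment coordinates, and only a two-range log-uniform E-value model.
"""

from __future__ import annotations

import io
import json
import logging
from dataclasses import asdict, dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np

from .annotations import AnnotationDB, parse_gaf, write_gaf
from .evaluation import TruthSet
from .ontology import NAMESPACE_NAMES, OntologyDAG, TermRecord, parse_obo, write_obo
from .search_io import Hit, write_blast_tabular

logger = logging.getLogger(__name__)

# -- D0: the fixed worked-example micro-dataset -------------------------------

#: Symbolic names for the five D0 terms.
D0_TERMS = {
    "R": "GO:0000001",
    "A": "GO:0000002",
    "B": "GO:0000003",
    "A1": "GO:0000004",
    "A2": "GO:0000005",
}


def d0_obo_text() -> str:
    return resources.files("gopred.data").joinpath("d0.obo").read_text()


def d0_gaf_text() -> str:
    return resources.files("gopred.data").joinpath("d0.gaf").read_text()


def d0_dag() -> OntologyDAG:
    """The five-term ontology R; A,B is_a R; A1,A2 is_a A."""
    return parse_obo(io.StringIO(d0_obo_text()))


def d0_db() -> AnnotationDB:
    """Proteins p1:{A1}, p2:{A1,B}, p3:{A2} (all experimental evidence)."""
    return parse_gaf(io.StringIO(d0_gaf_text()))


# -- configurable generator ---------------------------------------------------


@dataclass
class FixtureConfig:
    """Study conditions of the synthetic benchmark.

    The defaults are the conditions used throughout the test suite: a
    balanced branching-3 depth-4 BP ontology (121 terms), 200 database
    proteins with 1-3 leaf-biased annotations each, 50 targets with 10 hits
    apiece, signal strength 0.9 and strong E-values log-uniform in
    [1e-50, 1e-10] against weak ones in [1e-2, 10].
    """

    seed: int = 7
    namespace: str = "BP"
    depth: int = 4
    branching: int = 3
    multi_parent_fraction: float = 0.1
    n_proteins: int = 200
    annotations_min: int = 1
    annotations_max: int = 3
    leaf_bias: float = 0.7
    iea_fraction: float = 0.1
    n_targets: int = 50
    hits_per_target: int = 10
    signal: float = 0.9
    strong_log10_evalue: tuple[float, float] = (-50.0, -10.0)
    weak_log10_evalue: tuple[float, float] = (-2.0, 1.0)
    level2_fanout: int = 3
    with_level2: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.signal <= 1.0:
            raise ValueError("signal strength must lie in [0, 1]")
        if not 0.0 <= self.leaf_bias <= 1.0:
            raise ValueError("leaf_bias must lie in [0, 1]")
        if not 0.0 <= self.iea_fraction <= 1.0:
            raise ValueError("iea_fraction must lie in [0, 1]")
        if self.depth < 1 or self.branching < 1:
            raise ValueError("depth and branching must be >= 1")
        if self.annotations_min < 1 or self.annotations_max < self.annotations_min:
            raise ValueError("invalid annotations-per-protein range")


def _rng(config: FixtureConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def make_ontology(config: FixtureConfig) -> OntologyDAG:
    """Balanced is_a tree of the configured depth/branching, optionally
    rewired into a DAG by giving a fraction of deep nodes a second parent
    from a strictly shallower level (which preserves acyclicity)."""
    rng = _rng(config, 1)
    ns = config.namespace
    counter = 0

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"GO:{7000000 + counter:07d}"

    root = new_id()
    terms = {root: TermRecord(root, NAMESPACE_NAMES.get(ns, ns), ns)}
    parents: dict[str, set[str]] = {root: set()}
    levels: list[list[str]] = [[root]]
    for depth in range(1, config.depth + 1):
        level = []
        for parent in levels[-1]:
            for _ in range(config.branching):
                tid = new_id()
                terms[tid] = TermRecord(tid, f"synthetic term {tid[-7:]}", ns)
                parents[tid] = {parent}
                level.append(tid)
        levels.append(level)
    # extra parents: only from levels strictly above the node's own
    for depth in range(2, config.depth + 1):
        shallower = [t for lvl in levels[1:depth] for t in lvl]
        for tid in levels[depth]:
            if shallower and rng.random() < config.multi_parent_fraction:
                extra = shallower[int(rng.integers(len(shallower)))]
                if extra not in parents[tid]:
                    parents[tid].add(extra)
    return OntologyDAG(terms, parents)


def _sample_terms(
    dag: OntologyDAG, config: FixtureConfig, rng: np.random.Generator
) -> set[str]:
    leaves = sorted(dag.leaves(config.namespace))
    internal = sorted(
        dag.namespace_terms(config.namespace)
        - dag.leaves(config.namespace)
        - {dag.root(config.namespace)}
    )
    k = int(rng.integers(config.annotations_min, config.annotations_max + 1))
    terms: set[str] = set()
    for _ in range(k):
        if internal and rng.random() >= config.leaf_bias:
            terms.add(internal[int(rng.integers(len(internal)))])
        else:
            terms.add(leaves[int(rng.integers(len(leaves)))])
    return terms


def make_annotation_db(
    dag: OntologyDAG,
    config: FixtureConfig,
    protein_ids: list[str] | None = None,
    iea_fraction: float | None = None,
) -> AnnotationDB:
    """Annotate proteins with leaf-biased random terms; a configurable
    fraction of annotations carries IEA evidence to exercise filtering."""
    rng = _rng(config, 2)
    if protein_ids is None:
        protein_ids = [f"P{i:06d}" for i in range(1, config.n_proteins + 1)]
    iea = config.iea_fraction if iea_fraction is None else iea_fraction
    data: dict[str, dict[str, set[str]]] = {}
    for protein in protein_ids:
        terms = _sample_terms(dag, config, rng)
        data[protein] = {
            term: {"IEA" if rng.random() < iea else "EXP"} for term in sorted(terms)
        }
    return AnnotationDB(data)


def simulate_search(
    db: AnnotationDB,
    dag: OntologyDAG,
    truth_direct: Mapping[str, set[str]],
    config: FixtureConfig,
) -> tuple[dict[str, list[Hit]], dict[str, list[Hit]]]:
    """Per-target level-1 hit lists plus one shared level-2 map.

    Each of ``hits_per_target`` draws is a signal hit with probability
    ``signal`` — a database protein whose non-IEA annotations overlap the
    target's direct truth, with a strong E-value — and a noise hit otherwise.
    Level-2 searches are generated once per level-1 subject (their queries
    are level-1 subject ids), seeded by that subject's own annotations.
    """
    rng = _rng(config, 3)
    ns = config.namespace
    usable = db.filtered()
    proteins = sorted(db.proteins)
    by_term: dict[str, list[str]] = {}
    for protein in proteins:
        for term in usable.terms_of(protein, dag, ns):
            by_term.setdefault(term, []).append(protein)

    def draw_evalue(strong: bool) -> float:
        lo, hi = (
            config.strong_log10_evalue if strong else config.weak_log10_evalue
        )
        return float(10.0 ** rng.uniform(lo, hi))

    def draw_hits(query: str, truth: set[str], n: int) -> list[Hit]:
        pool = sorted({p for t in truth for p in by_term.get(t, ())} - {query})
        hits: list[Hit] = []
        used: set[str] = set()
        for _ in range(n):
            is_signal = bool(pool) and rng.random() < config.signal
            candidates = pool if is_signal else proteins
            subject = candidates[int(rng.integers(len(candidates)))]
            if subject in used or subject == query:
                continue  # duplicates would be collapsed at parse time anyway
            used.add(subject)
            pident = float(rng.uniform(60, 95) if is_signal else rng.uniform(20, 40))
            hits.append(
                Hit(query=query, subject=subject, pident=round(pident, 2),
                    evalue=draw_evalue(is_signal))
            )
        return hits

    level1 = {
        target: draw_hits(target, truth_direct[target], config.hits_per_target)
        for target in sorted(truth_direct)
    }
    level2: dict[str, list[Hit]] = {}
    if config.with_level2:
        subjects = sorted({h.subject for hits in level1.values() for h in hits})
        for subject in subjects:
            seed_terms = usable.terms_of(subject, dag, ns)
            level2[subject] = draw_hits(subject, seed_terms, config.level2_fanout)
    return level1, level2


@dataclass
class Bundle:
    """In-memory fixture bundle plus (optionally) its on-disk file layout."""

    config: FixtureConfig
    dag: OntologyDAG
    db: AnnotationDB
    truth: TruthSet
    truth_direct: TruthSet
    level1: dict[str, list[Hit]]
    level2: dict[str, list[Hit]]
    out_dir: Path | None = None

    @property
    def targets(self) -> list[str]:
        return sorted(self.truth.truths)


def make_bundle(config: FixtureConfig, out_dir: str | Path | None = None) -> Bundle:
    """Generate ontology, annotations, targets with held-out truth and search
    results; optionally write the whole bundle (OBO, GAF, BLAST tabular,
    truth TSVs, JSON manifest) under ``out_dir``."""
    dag = make_ontology(config)
    ns = config.namespace
    protein_ids = [f"P{i:06d}" for i in range(1, config.n_proteins + 1)]
    donor_ids = [f"D{i:06d}" for i in range(1, config.n_targets + 1)]
    db_all = make_annotation_db(dag, config, protein_ids + donor_ids)
    # donors are hidden: their annotations become target truth (always
    # experimental) and they are removed from the searchable database
    data = {p: {t: db_all.evidence(p, t) for t in db_all.terms_of(p)}
            for p in protein_ids}
    db = AnnotationDB(data)
    root = dag.root(ns)
    truth_direct: dict[str, set[str]] = {}
    truth: dict[str, set[str]] = {}
    for i, donor in enumerate(donor_ids, start=1):
        target = f"T{i:06d}"
        direct = db_all.terms_of(donor, dag, ns)
        truth_direct[target] = direct
        truth[target] = dag.propagate(direct) - {root}
    level1, level2 = simulate_search(db, dag, truth_direct, config)
    bundle = Bundle(
        config=config,
        dag=dag,
        db=db,
        truth=TruthSet(truths=truth, namespace=ns),
        truth_direct=TruthSet(truths=truth_direct, namespace=ns),
        level1=level1,
        level2=level2,
    )
    if out_dir is not None:
        bundle.out_dir = Path(out_dir)
        _write_bundle(bundle)
    return bundle


def _write_bundle(bundle: Bundle) -> None:
    out = bundle.out_dir
    assert out is not None
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "ontology.obo", "w") as fh:
        write_obo(bundle.dag, fh)
    with open(out / "annotations.gaf", "w") as fh:
        write_gaf(bundle.db, fh, bundle.dag)
    with open(out / "hits.tsv", "w") as fh:
        write_blast_tabular(bundle.level1, fh)
    with open(out / "hits_level2.tsv", "w") as fh:
        write_blast_tabular(bundle.level2, fh)
    with open(out / "truth.tsv", "w") as fh:
        bundle.truth.write_tsv(fh)
    with open(out / "truth_direct.tsv", "w") as fh:
        bundle.truth_direct.write_tsv(fh)
    manifest = {
        "config": asdict(bundle.config),
        "seed": bundle.config.seed,
        "files": [
            "ontology.obo", "annotations.gaf", "hits.tsv", "hits_level2.tsv",
            "truth.tsv", "truth_direct.tsv",
        ],
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("fixture bundle written to %s", out)
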