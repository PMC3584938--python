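"""Shared fixtures: the D0 worked-example dataset and random small instances.

Random instances (DAG <= 20 terms, <= 10 proteins, <= 8 hits) are generated
from a numpy Generator so every test run is reproducible; the helper returns
both the package objects and the plain-dict views the brute-force oracles
consume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from gopred.annotations import AnnotationDB, CooccurrenceTable
from gopred.fixtures import D0_TERMS, d0_dag, d0_db
from gopred.ontology import OntologyDAG, TermRecord, compute_term_stats
from gopred.search_io import Hit


@pytest.fixture(scope="session")
def d0():
    dag = d0_dag()
    db = d0_db()
    stats = compute_term_stats(dag, db.direct_counts(dag, "BP"))
    cooc = CooccurrenceTable.build(db, dag, "BP")
    return {"dag": dag, "db": db, "stats": stats, "cooc": cooc, "T": D0_TERMS}


@dataclass
class Instance:
    """One random small problem plus plain-dict views for the oracles."""

    dag: OntologyDAG
    parents: dict[str, set[str]]
    root: str
    db: AnnotationDB
    protein_terms: dict[str, set[str]]
    annot: dict[str, int]
    hits: list[Hit]
    all_terms: list[str]


def random_dag(rng: np.random.Generator, max_terms: int = 20):
    """Random rooted is_a DAG: term i > 0 gets 1-2 parents among terms < i."""
    n = int(rng.integers(4, max_terms + 1))
    ids = [f"GO:{i + 1:07d}" for i in range(n)]
    terms = {t: TermRecord(t, f"t{i}", "BP") for i, t in enumerate(ids)}
    parents: dict[str, set[str]] = {ids[0]: set()}
    for i in range(1, n):
        k = 1 if i == 1 or rng.random() < 0.7 else 2
        choice = rng.choice(i, size=min(k, i), replace=False)
        parents[ids[i]] = {ids[int(j)] for j in choice}
    return OntologyDAG(terms, parents), parents, ids[0], ids


def random_instance(rng: np.random.Generator) -> Instance:
    dag, parents, root, ids = random_dag(rng)
    n_prot = int(rng.integers(2, 11))
    protein_terms: dict[str, set[str]] = {}
    for i in range(n_prot):
        k = int(rng.integers(1, 4))
        terms = {ids[int(j)] for j in rng.integers(1, len(ids), size=k)}
        protein_terms[f"q{i + 1}"] = terms
    db = AnnotationDB(
        {p: {t: {"EXP"} for t in terms} for p, terms in protein_terms.items()}
    )
    annot: dict[str, int] = {t: 0 for t in ids}
    for terms in protein_terms.values():
        for t in terms:
            annot[t] += 1
    proteins = sorted(protein_terms)
    n_hits = int(rng.integers(0, 9))
    hits = [
        Hit(
            query="T1",
            subject=proteins[int(rng.integers(len(proteins)))],
            pident=float(np.round(rng.uniform(10, 100), 2)),
            evalue=float(10.0 ** rng.uniform(-10, 1)),
        )
        for _ in range(n_hits)
    ]
    # collapse duplicate subjects the way the parser would (lowest E wins)
    best: dict[str, Hit] = {}
    order: list[str] = []
    for h in hits:
        if h.subject not in best:
            order.append(h.subject)
            best[h.subject] = h
        elif h.evalue < best[h.subject].evalue:
            best[h.subject] = h
    hits = [best[s] for s in order]
    return Instance(
        dag=dag,
        parents=parents,
        root=root,
        db=db,
        protein_terms=protein_terms,
        annot=annot,
        hits=hits,
        all_terms=ids,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
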