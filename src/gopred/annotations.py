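"""Protein -> GO annotation databases (GAF parsing) and term co-occurrence.

Annotations are read from GAF 2.x files, with evidence-code filtering (IEA
excluded by default, matching the convention that only experimentally
supported annotations count) and NOT-qualified rows dropped.

Co-occurrence conditional probabilities P(fa | fj) — the fraction of proteins
annotated with ``fj`` that are also annotated with ``fa`` — are computed over
*direct* annotations within a single namespace.  Propagated sets would drive
every ancestor probability toward 1, which is not what the association score
intends.
"""

from __future__ import annotations

import logging
from collections import Counter
from typing import IO, Iterable, Mapping

from .ontology import OntologyDAG

logger = logging.getLogger(__name__)

DEFAULT_EXCLUDED_EVIDENCE = frozenset({"IEA"})

_ASPECT = {"BP": "P", "MF": "F", "CC": "C"}


class AnnotationDB:
    """Protein -> {term -> evidence codes} with per-term count helpers."""

    def __init__(self, data: Mapping[str, Mapping[str, Iterable[str]]]) -> None:
        self._data: dict[str, dict[str, frozenset[str]]] = {
            protein: {term: frozenset(codes) for term, codes in terms.items()}
            for protein, terms in data.items()
        }

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotationDB):
            return NotImplemented
        return self._data == other._data

    def __len__(self) -> int:
        return len(self._data)

    def __contains__(self, protein: str) -> bool:
        return protein in self._data

    @property
    def proteins(self) -> list[str]:
        return sorted(self._data)

    @property
    def n_annotations(self) -> int:
        return sum(len(terms) for terms in self._data.values())

    def evidence(self, protein: str, term: str) -> frozenset[str]:
        return self._data.get(protein, {}).get(term, frozenset())

    def terms_of(
        self,
        protein: str,
        dag: OntologyDAG | None = None,
        namespace: str | None = None,
    ) -> set[str]:
        """Direct annotation terms of a protein, optionally namespace-filtered.

        Terms absent from ``dag`` are dropped when a dag is supplied.
        """
        terms = set(self._data.get(protein, ()))
        if dag is not None:
            terms = {t for t in terms if t in dag}
            if namespace is not None:
                terms = {t for t in terms if dag.namespace_of(t) == namespace}
        return terms

    def nfunc(self, protein: str, dag: OntologyDAG, namespace: str) -> int:
        """Number of GO annotations of a protein in the given namespace."""
        return len(self.terms_of(protein, dag, namespace))

    def direct_counts(
        self, dag: OntologyDAG | None = None, namespace: str | None = None
    ) -> Counter[str]:
        """Direct per-term protein counts (input to term statistics)."""
        counts: Counter[str] = Counter()
        for protein in self._data:
            for term in self.terms_of(protein, dag, namespace):
                counts[term] += 1
        return counts

    def term_proteins(
        self, dag: OntologyDAG | None = None, namespace: str | None = None
    ) -> dict[str, frozenset[str]]:
        index: dict[str, set[str]] = {}
        for protein in self._data:
            for term in self.terms_of(protein, dag, namespace):
                index.setdefault(term, set()).add(protein)
        return {t: frozenset(p) for t, p in index.items()}

    def protein_terms(
        self, dag: OntologyDAG | None = None, namespace: str | None = None
    ) -> dict[str, frozenset[str]]:
        return {
            protein: frozenset(self.terms_of(protein, dag, namespace))
            for protein in self._data
        }

    def filtered(
        self, exclude_evidence: Iterable[str] = DEFAULT_EXCLUDED_EVIDENCE
    ) -> "AnnotationDB":
        """Drop evidence codes in ``exclude_evidence``; annotations left with
        no remaining code are removed, as are proteins left with no terms."""
        excluded = frozenset(exclude_evidence)
        data: dict[str, dict[str, frozenset[str]]] = {}
        for protein, terms in self._data.items():
            kept = {
                term: codes - excluded
                for term, codes in terms.items()
                if codes - excluded
            }
            if kept:
                data[protein] = kept
        return AnnotationDB(data)


def parse_gaf(
    stream: IO[str],
    exclude_evidence: Iterable[str] = DEFAULT_EXCLUDED_EVIDENCE,
    strict: bool = True,
) -> AnnotationDB:
    """Read a GAF 2.x file into an :class:`AnnotationDB`.

    Rows with an evidence code in ``exclude_evidence`` (default ``{IEA}``) and
    rows carrying a NOT qualifier are dropped.  Comment lines (``!``) are
    skipped.  Rows with fewer than 15 columns raise a :class:`ValueError`
    naming the line number in strict mode (default) and are skipped with a log
    message otherwise.
    """
    excluded = frozenset(exclude_evidence)
    data: dict[str, dict[str, set[str]]] = {}
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("!"):
            continue
        cols = line.split("\t")
        if len(cols) < 15:
            msg = f"GAF line {lineno}: expected >=15 columns, found {len(cols)}"
            if strict:
                raise ValueError(msg)
            logger.warning("%s (skipped)", msg)
            continue
        protein, qualifier, term, evidence = cols[1], cols[3], cols[4], cols[6]
        if "NOT" in qualifier.split("|"):
            continue
        if evidence in excluded:
            continue
        data.setdefault(protein, {}).setdefault(term, set()).add(evidence)
    return AnnotationDB(data)


def write_gaf(
    db: AnnotationDB, stream: IO[str], dag: OntologyDAG | None = None
) -> None:
    """Write 17-column GAF 2.1 rows, one per (protein, term, evidence code).

    ``parse_gaf(write_gaf(db), exclude_evidence=())`` round-trips exactly.
    The aspect column is derived from ``dag`` when given, else ``P``.
    """
    stream.write("!gaf-version: 2.1\n")
    for protein in db.proteins:
        for term in sorted(db.terms_of(protein)):
            aspect = "P"
            if dag is not None and term in dag:
                aspect = _ASPECT.get(dag.namespace_of(term), "P")
            for code in sorted(db.evidence(protein, term)):
                cols = [
                    "UniProtKB", protein, protein, "", term,
                    "GO_REF:0000002", code, "", aspect, "", "",
                    "protein", "taxon:0", "20110901", "SYN", "", "",
                ]
                stream.write("\t".join(cols) + "\n")


def cooccurrence_probability(
    db: AnnotationDB,
    fa: str,
    fj: str,
    dag: OntologyDAG | None = None,
    namespace: str | None = None,
) -> float:
    """P(fa | fj): proteins directly annotated with both, over those with fj.

    Cross-namespace pairs and unannotated ``fj`` return 0 (logged).
    """
    index = db.term_proteins(dag, namespace)
    with_fj = index.get(fj, frozenset())
    if not with_fj:
        logger.debug("term %s has no (namespace) annotation; P(%s|%s)=0", fj, fa, fj)
        return 0.0
    with_fa = index.get(fa, frozenset())
    return len(with_fa & with_fj) / len(with_fj)


class CooccurrenceTable:
    """Sparse conditional probabilities P(fa | fj) over direct annotations.

    Built once per (db, namespace); serves both single lookups and the full
    conditional distribution given an observed term, which is what the PFP
    accumulation iterates over.
    """

    def __init__(
        self,
        term_proteins: Mapping[str, frozenset[str]],
        protein_terms: Mapping[str, frozenset[str]],
    ) -> None:
        self.term_proteins = dict(term_proteins)
        self.protein_terms = dict(protein_terms)
        self._given: dict[str, dict[str, float]] = {}

    @classmethod
    def build(
        cls,
        db: AnnotationDB,
        dag: OntologyDAG | None = None,
        namespace: str | None = None,
    ) -> "CooccurrenceTable":
        return cls(db.term_proteins(dag, namespace), db.protein_terms(dag, namespace))

    @property
    def terms(self) -> set[str]:
        return set(self.term_proteins)

    def conditional_given(self, fj: str) -> dict[str, float]:
        """All nonzero P(fa | fj) for a fixed conditioning term ``fj``."""
        cached = self._given.get(fj)
        if cached is not None:
            return cached
        with_fj = self.term_proteins.get(fj, frozenset())
        if not with_fj:
            self._given[fj] = {}
            return self._given[fj]
        counts: Counter[str] = Counter()
        for protein in with_fj:
            counts.update(self.protein_terms.get(protein, ()))
        table = {fa: n / len(with_fj) for fa, n in counts.items()}
        self._given[fj] = table
        return table

    def prob(self, fa: str, fj: str) -> float:
        return self.conditional_given(fj).get(fa, 0.0)
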