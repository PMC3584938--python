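"""Gene Ontology DAG handling: OBO parsing, ancestor closure, term statistics.

The ontology is modelled as a directed acyclic graph over ``is_a`` edges with
one rooted component per namespace (biological_process, molecular_function).
Annotation with a term implies annotation with every ancestor, so the central
operations are the transitive ancestor closure (:meth:`OntologyDAG.ancestors`,
:meth:`OntologyDAG.propagate`) and the minimum undirected edge distance
between terms (:meth:`OntologyDAG.edge_distance`).

Term usage statistics follow the recursive frequency definition

    freq(c) = annot(c) + sum over children h of freq(h)

where ``annot(c)`` is the number of gene products directly annotated with
``c``.  The probability of a term is ``p(c) = freq(c) / freq(root)`` within
its namespace and its information content is ``IC(c) = -log10(p(c))``.  Note
that the recursion counts a gene product once per parent path under
multi-parent descendants; an alternative unique-protein mode is available
(see :func:`compute_term_stats`).

Only ``is_a`` edges are used; ``part_of`` and other relationship types are
ignored at parse time (with a log message).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import IO, Iterable, Mapping

import networkx as nx
import obonet

logger = logging.getLogger(__name__)

#: Mapping from namespace code to the full OBO namespace name.
NAMESPACE_NAMES = {
    "BP": "biological_process",
    "MF": "molecular_function",
    "CC": "cellular_component",
}
NAMESPACE_CODES = {v: k for k, v in NAMESPACE_NAMES.items()}


@dataclass(frozen=True)
class TermRecord:
    """A single ontology term: identifier, human-readable name, namespace code."""

    id: str
    name: str
    namespace: str  # "BP" or "MF" (or "CC" if explicitly requested)


class OntologyDAG:
    """The is_a DAG of one or more GO namespaces.

    Parameters
    ----------
    terms:
        Mapping from term id to :class:`TermRecord`.
    parents:
        Mapping from term id to the set of its direct ``is_a`` parents.

    Raises
    ------
    ValueError
        If an edge references an unknown term, crosses namespaces, if the
        graph contains a cycle, or if a namespace root cannot be identified.
    """

    def __init__(
        self,
        terms: Mapping[str, TermRecord],
        parents: Mapping[str, Iterable[str]],
    ) -> None:
        self._terms: dict[str, TermRecord] = dict(terms)
        self._parents: dict[str, frozenset[str]] = {
            t: frozenset(parents.get(t, ())) for t in self._terms
        }
        graph = nx.DiGraph()
        graph.add_nodes_from(self._terms)
        for child, ps in self._parents.items():
            for parent in ps:
                if parent not in self._terms:
                    raise ValueError(
                        f"term {child!r} has is_a parent {parent!r} "
                        "which is not a known term"
                    )
                if self._terms[parent].namespace != self._terms[child].namespace:
                    raise ValueError(
                        f"is_a edge {child!r} -> {parent!r} crosses namespaces"
                    )
                graph.add_edge(child, parent)
        if not nx.is_directed_acyclic_graph(graph):
            member = nx.find_cycle(graph)[0][0]
            raise ValueError(f"is_a cycle detected involving term {member!r}")
        self._graph = graph
        self._undirected = graph.to_undirected(as_view=True)
        children: dict[str, set[str]] = {t: set() for t in self._terms}
        for child, ps in self._parents.items():
            for parent in ps:
                children[parent].add(child)
        self._children = {t: frozenset(c) for t, c in children.items()}
        self._roots = self._find_roots()
        self._check_reachability()

    # -- construction helpers -------------------------------------------------

    def _find_roots(self) -> dict[str, str]:
        parentless: dict[str, list[str]] = {}
        for tid, rec in self._terms.items():
            if not self._parents[tid]:
                parentless.setdefault(rec.namespace, []).append(tid)
        roots: dict[str, str] = {}
        for ns, candidates in parentless.items():
            if len(candidates) == 1:
                roots[ns] = candidates[0]
                continue
            ns_name = NAMESPACE_NAMES.get(ns, ns)
            named = [t for t in candidates if self._terms[t].name == ns_name]
            if len(named) != 1:
                raise ValueError(
                    f"namespace {ns}: {len(candidates)} parentless terms and "
                    f"none/multiple named {ns_name!r}; cannot identify the root"
                )
            roots[ns] = named[0]
        return roots

    def _check_reachability(self) -> None:
        for tid, rec in self._terms.items():
            root = self._roots.get(rec.namespace)
            if root is None:
                raise ValueError(f"namespace {rec.namespace} has no root")
            if tid != root and root not in nx.descendants(self._graph, tid):
                raise ValueError(
                    f"term {tid!r} does not reach its namespace root {root!r}"
                )

    # -- basic queries --------------------------------------------------------

    def __contains__(self, term: str) -> bool:
        return term in self._terms

    def __len__(self) -> int:
        return len(self._terms)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OntologyDAG):
            return NotImplemented
        return self._terms == other._terms and self._parents == other._parents

    def __iter__(self):
        return iter(self._terms)

    @property
    def terms(self) -> Mapping[str, TermRecord]:
        return self._terms

    @property
    def namespaces(self) -> tuple[str, ...]:
        return tuple(sorted(self._roots))

    @property
    def roots(self) -> Mapping[str, str]:
        return self._roots

    def root(self, namespace: str) -> str:
        if namespace not in self._roots:
            raise KeyError(f"no namespace {namespace!r} in this ontology")
        return self._roots[namespace]

    def name_of(self, term: str) -> str:
        return self._require(term).name

    def namespace_of(self, term: str) -> str:
        return self._require(term).namespace

    def _require(self, term: str) -> TermRecord:
        try:
            return self._terms[term]
        except KeyError:
            raise KeyError(f"unknown term {term!r}") from None

    def parents_of(self, term: str) -> frozenset[str]:
        self._require(term)
        return self._parents[term]

    def children_of(self, term: str) -> frozenset[str]:
        self._require(term)
        return self._children[term]

    def namespace_terms(self, namespace: str) -> set[str]:
        return {t for t, rec in self._terms.items() if rec.namespace == namespace}

    def leaves(self, namespace: str | None = None) -> set[str]:
        return {
            t
            for t in self._terms
            if not self._children[t]
            and (namespace is None or self._terms[t].namespace == namespace)
        }

    # -- closure operations ---------------------------------------------------

    def ancestors(self, term: str, include_self: bool = False) -> set[str]:
        """Transitive is_a closure of ``term`` up to its namespace root."""
        self._require(term)
        out = set(nx.descendants(self._graph, term))
        if include_self:
            out.add(term)
        return out

    def propagate(self, terms: Iterable[str]) -> set[str]:
        """Union of ancestors-with-self over ``terms`` (idempotent)."""
        out: set[str] = set()
        for term in terms:
            out |= self.ancestors(term, include_self=True)
        return out

    def edge_distance(self, t1: str, t2: str) -> int:
        """Minimum number of is_a edges on any undirected path between terms."""
        r1, r2 = self._require(t1), self._require(t2)
        if r1.namespace != r2.namespace:
            raise ValueError(
                f"terms {t1!r} ({r1.namespace}) and {t2!r} ({r2.namespace}) "
                "are in different namespaces"
            )
        return nx.shortest_path_length(self._undirected, t1, t2)


# -- OBO I/O ------------------------------------------------------------------


def parse_obo(stream: IO[str] | str, namespaces: Iterable[str] = ("BP", "MF")) -> OntologyDAG:
    """Read an OBO 1.2 file into an :class:`OntologyDAG`.

    Only non-obsolete ``[Term]`` stanzas of the requested namespaces are kept
    (obsolete terms are dropped by the reader).  Relationship types other than
    ``is_a`` (e.g. ``part_of``) are ignored.  An ``is_a`` reference to a term
    never defined in the file (or defined only as obsolete) is a hard error,
    as is a cycle.

    Parameters
    ----------
    stream:
        Open text handle or path to an OBO file.
    namespaces:
        Namespace codes to retain, default ``("BP", "MF")``.
    """
    wanted = set(namespaces)
    graph = obonet.read_obo(stream)
    terms: dict[str, TermRecord] = {}
    dropped_ns = 0
    for node, data in graph.nodes(data=True):
        if "namespace" not in data:  # referenced but never defined as a live term
            continue
        code = NAMESPACE_CODES.get(data["namespace"], data["namespace"])
        if code not in wanted:
            dropped_ns += 1
            continue
        terms[node] = TermRecord(id=node, name=data.get("name", node), namespace=code)
    parents: dict[str, set[str]] = {t: set() for t in terms}
    cross_ns = 0
    other_rel = 0
    for child, parent, key in graph.edges(keys=True):
        if key != "is_a":
            other_rel += 1
            continue
        if child not in terms:
            continue
        if parent not in graph.nodes or "namespace" not in graph.nodes[parent]:
            raise ValueError(
                f"term {child!r} has is_a parent {parent!r} which is not "
                "defined as a live term in the file"
            )
        if parent not in terms:
            cross_ns += 1  # parent in a namespace that was not requested
            continue
        if terms[parent].namespace != terms[child].namespace:
            cross_ns += 1
            continue
        parents[child].add(parent)
    if other_rel:
        logger.info("ignored %d non-is_a relationship edges", other_rel)
    if cross_ns:
        logger.info("dropped %d cross-namespace or out-of-namespace edges", cross_ns)
    if dropped_ns:
        logger.info("dropped %d terms outside requested namespaces", dropped_ns)
    return OntologyDAG(terms, parents)


def write_obo(dag: OntologyDAG, stream: IO[str]) -> None:
    """Emit the minimal OBO 1.2 subset (id, name, namespace, is_a).

    ``parse_obo(write_obo(dag))`` round-trips exactly.
    """
    stream.write("format-version: 1.2\nontology: gopred\n")
    for tid in sorted(dag.terms):
        rec = dag.terms[tid]
        stream.write("\n[Term]\n")
        stream.write(f"id: {tid}\n")
        stream.write(f"name: {rec.name}\n")
        stream.write(f"namespace: {NAMESPACE_NAMES.get(rec.namespace, rec.namespace)}\n")
        for parent in sorted(dag.parents_of(tid)):
            stream.write(f"is_a: {parent} ! {dag.name_of(parent)}\n")


# -- term statistics ----------------------------------------------------------


@dataclass
class TermStats:
    """Per-term annotation counts, recursive frequencies and information content.

    ``prob`` and ``ic`` are ``nan`` for terms with zero frequency (or in a
    namespace without any annotation); such terms are excluded from IC-based
    metrics.
    """

    annot: dict[str, int]
    freq: dict[str, float]
    prob: dict[str, float]
    ic: dict[str, float]

    def is_defined(self, term: str) -> bool:
        value = self.ic.get(term)
        return value is not None and not math.isnan(value)


def compute_term_stats(
    dag: OntologyDAG,
    annot_counts: Mapping[str, int],
    mode: str = "recursive",
    protein_terms: Mapping[str, Iterable[str]] | None = None,
) -> TermStats:
    """Compute frequency, probability and information content per term.

    Parameters
    ----------
    dag:
        The ontology.
    annot_counts:
        Direct (unpropagated) per-term gene-product counts.
    mode:
        ``"recursive"`` (default) applies the literal recursion
        ``freq(c) = annot(c) + sum(freq(child))`` which double-counts gene
        products under multi-parent descendants.  ``"unique"`` instead counts
        distinct proteins annotated at or below each term and requires
        ``protein_terms`` (protein id -> direct term ids).
    """
    for term, count in annot_counts.items():
        if term not in dag:
            raise ValueError(f"annotated term {term!r} is not in the ontology")
        if count < 0:
            raise ValueError(f"negative annotation count for {term!r}")
    if sum(annot_counts.values()) == 0:
        raise ValueError("no annotations: every namespace root has frequency 0")

    annot = {t: int(annot_counts.get(t, 0)) for t in dag}
    freq: dict[str, float] = {}
    if mode == "recursive":
        # children precede parents in a topological order of the child->parent graph
        for term in nx.topological_sort(dag._graph):
            freq[term] = annot[term] + sum(freq[c] for c in dag.children_of(term))
    elif mode == "unique":
        if protein_terms is None:
            raise ValueError("mode='unique' requires protein_terms")
        below: dict[str, set[str]] = {t: set() for t in dag}
        for protein, terms in protein_terms.items():
            for term in terms:
                for anc in dag.ancestors(term, include_self=True):
                    below[anc].add(protein)
        freq = {t: float(len(below[t])) for t in dag}
    else:
        raise ValueError(f"unknown mode {mode!r}")

    prob: dict[str, float] = {}
    ic: dict[str, float] = {}
    for ns in dag.namespaces:
        root_freq = freq[dag.root(ns)]
        for term in dag.namespace_terms(ns):
            if root_freq == 0 or freq[term] == 0:
                prob[term] = math.nan
                ic[term] = math.nan
            else:
                p = freq[term] / root_freq
                prob[term] = p
                ic[term] = -math.log10(p)
        if root_freq == 0:
            logger.info("namespace %s has no annotations; IC undefined", ns)
    return TermStats(annot=annot, freq=freq, prob=prob, ic=ic)


def max_shared_ancestor_ic(
    dag: OntologyDAG, stats: TermStats, t1: str, t2: str
) -> float:
    """Maximum information content over common ancestors of two terms.

    The common-ancestor sets include the terms themselves, so the value equals
    ``IC(t1)`` when ``t1 == t2`` or when ``t1`` is an ancestor of ``t2``.
    Returns 0 (with a warning) when no common ancestor has defined IC.
    """
    if dag.namespace_of(t1) != dag.namespace_of(t2):
        raise ValueError(f"terms {t1!r} and {t2!r} are in different namespaces")
    common = dag.ancestors(t1, include_self=True) & dag.ancestors(t2, include_self=True)
    values = [stats.ic[c] for c in common if stats.is_defined(c)]
    if not values:
        logger.warning(
            "no common ancestor of %s and %s has defined IC; returning 0", t1, t2
        )
        return 0.0
    return max(values)
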