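"""Sequence-search result parsing (BLAST tabular) and the two-level hit graph.

The artifact never runs BLAST/PSI-BLAST itself: it consumes 12-column
tabular output (``outfmt 6``: qseqid sseqid pident length mismatch gapopen
qstart qend sstart send evalue bitscore).  Hits are grouped per query in
file order; self-hits are dropped and duplicate (query, subject) pairs keep
the lowest E-value.

For the iterative-search predictor, level-1 hits may each carry a level-2
hit list (a second search seeded from the level-1 subject).  Within a single
search every hit receives the weight

    w_i = -log10(E_i) / sum over hits in the same search of -log10(E)

restricted to hits with positive -log10(E) (i.e. E < 1); E-values of 0 are
clamped at a configurable floor before taking the logarithm.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping

logger = logging.getLogger(__name__)

DEFAULT_E_CEILING = 100.0
DEFAULT_E_FLOOR = 1e-180


@dataclass(frozen=True)
class Hit:
    """One search hit: query, subject, percent identity, E-value."""

    query: str
    subject: str
    pident: float
    evalue: float


def parse_blast_tabular(stream: IO[str]) -> dict[str, list[Hit]]:
    """Parse BLAST ``outfmt 6`` lines into per-query hit lists.

    Original order is preserved; self-hits (qseqid == sseqid) are dropped;
    duplicate (query, subject) pairs keep the hit with the lowest E-value
    (at the position of its first occurrence).  Non-numeric identity or
    E-value raises :class:`ValueError` naming the line number.
    """
    hits: dict[str, list[Hit]] = {}
    index: dict[tuple[str, str], int] = {}
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 12:
            raise ValueError(
                f"BLAST tabular line {lineno}: expected 12 columns, found {len(cols)}"
            )
        query, subject = cols[0], cols[1]
        try:
            pident = float(cols[2])
            evalue = float(cols[10])
        except ValueError:
            raise ValueError(
                f"BLAST tabular line {lineno}: non-numeric identity or E-value"
            ) from None
        if not math.isfinite(evalue) or evalue < 0:
            raise ValueError(f"BLAST tabular line {lineno}: invalid E-value {evalue}")
        if not 0 <= pident <= 100:
            raise ValueError(f"BLAST tabular line {lineno}: identity {pident} outside [0, 100]")
        if query == subject:
            continue
        hit = Hit(query=query, subject=subject, pident=pident, evalue=evalue)
        key = (query, subject)
        if key in index:
            pos = index[key]
            if evalue < hits[query][pos].evalue:
                hits[query][pos] = hit
            continue
        index[key] = len(hits.setdefault(query, []))
        hits[query].append(hit)
    return hits


def write_blast_tabular(hits: Mapping[str, Iterable[Hit]], stream: IO[str]) -> None:
    """Write hits back as 12-column outfmt-6 lines (placeholder coordinates)."""
    for query in hits:
        for hit in hits[query]:
            cols = [
                hit.query, hit.subject, f"{hit.pident:.2f}",
                "100", "0", "0", "1", "100", "1", "100",
                repr(hit.evalue), "50.0",
            ]
            stream.write("\t".join(cols) + "\n")


@dataclass
class HitGraph:
    """Per-target level-1 hits plus optional per-hit level-2 hit lists.

    ``weights`` is aligned with ``hits``; within each search the weights of
    hits with E < 1 sum to 1 (or are all 0 when no hit has positive
    -log10(E) mass).  ``level2`` maps a level-1 subject id to its own
    (hits, weights) pair.
    """

    target: str
    hits: list[Hit] = field(default_factory=list)
    weights: list[float] = field(default_factory=list)
    level2: dict[str, tuple[list[Hit], list[float]]] = field(default_factory=dict)

    @property
    def n_hits(self) -> int:
        return len(self.hits)


def _search_weights(hits: list[Hit], e_floor: float) -> list[float]:
    masses = [
        -math.log10(max(h.evalue, e_floor)) if h.evalue < 1 else 0.0 for h in hits
    ]
    total = sum(masses)
    if total <= 0:
        return [0.0] * len(hits)
    return [m / total for m in masses]


def build_hit_graph(
    target: str,
    level1: Iterable[Hit],
    level2: Mapping[str, Iterable[Hit]] | None = None,
    e_ceiling: float = DEFAULT_E_CEILING,
    e_floor: float = DEFAULT_E_FLOOR,
) -> HitGraph:
    """Assemble the two-level hit graph for one target.

    Hits with ``E >= e_ceiling`` are removed at both levels.  Level-2 lists
    whose key is not a retained level-1 subject are dropped (logged).
    """
    if e_ceiling <= 0:
        raise ValueError("e_ceiling must be positive")
    kept = [h for h in level1 if h.evalue < e_ceiling]
    graph = HitGraph(target=target, hits=kept, weights=_search_weights(kept, e_floor))
    subjects = {h.subject for h in kept}
    if level2:
        for seed, seed_hits in level2.items():
            if seed not in subjects:
                logger.debug(
                    "level-2 search for %s ignored: not a level-1 subject of %s",
                    seed, target,
                )
                continue
            kept2 = [h for h in seed_hits if h.evalue < e_ceiling]
            graph.level2[seed] = (kept2, _search_weights(kept2, e_floor))
    return graph
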