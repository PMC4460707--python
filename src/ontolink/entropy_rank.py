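"""Entropy-weighted popularity ranking over the knowledge graph.

Two quantities are computed here.  First, the Shannon entropy of each
relation,

    H(p) = - sum_{o in O_p} psi(o) log psi(o),

where ``psi(o)`` is the empirical frequency of object value ``o`` among all
triples with property ``p`` (natural log; the base only rescales every H(p)
uniformly and cancels in rankings).  A relation whose objects are spread
over many values carries more information about its subject than one that
always points at the same object, so H(p) serves as the weight of edges
typed ``p``.

Second, the recursive EntropyRank salience score

    ER(c) = sum_{p in P^c} H(p) sum_{o in O_pc} ER(o) / L(o),

where ``P^c`` are the properties on out-edges of ``c``, ``O_pc`` their
entity-valued objects and ``L(o)`` the number of distinct entities with an
out-edge to ``o`` (a sharing penalty analogous to PageRank's out-degree
division).  Scores start at 1 and are updated synchronously; after each
sweep the vector is rescaled to sum to the number of entities, which pins
down a bounded fixed point without changing within-sweep order.  Entities
with a zero update (no entity-valued out-edges, or only zero-entropy
properties) retain their previous value so that leaves keep the
initialization as a popularity floor instead of collapsing to zero.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .kb_graph import KnowledgeGraph

DEFAULT_TOLERANCE = 1e-8
DEFAULT_MAX_ITERATIONS = 100


class UnusedPropertyError(KeyError):
    """The property occurs in no triple of the graph."""


@dataclass
class PropertyEntropyTable:
    """Per-property Shannon entropies H(p), in nats."""

    entropy: dict[str, float] = field(default_factory=dict)

    def __getitem__(self, p: str) -> float:
        return self.entropy[p]

    def get(self, p: str, default: float = 0.0) -> float:
        return self.entropy.get(p, default)

    def __len__(self) -> int:
        return len(self.entropy)

    def __contains__(self, p: str) -> bool:
        return p in self.entropy


@dataclass
class EntropyRankState:
    """Converged (or truncated) EntropyRank vector plus iteration metadata."""

    rank: dict[str, float]
    iterations_run: int
    converged: bool
    residual: float

    def __getitem__(self, e: str) -> float:
        return self.rank[e]

    def get(self, e: str, default: float | None = None) -> float | None:
        return self.rank.get(e, default)


def property_entropy(kg: KnowledgeGraph, p: str) -> float:
    """Shannon entropy (nats) of the object distribution of property ``p``.

    The distribution is the maximum-likelihood frequency of each distinct
    object value over all triples with property ``p``, literals included
    when present.
    """
    counts = Counter(t.object for t in kg.triples if t.property == p)
    if not counts:
        raise UnusedPropertyError(p)
    total = sum(counts.values())
    return -sum((c / total) * math.log(c / total) for c in counts.values())


def compute_all_entropies(
    kg: KnowledgeGraph, exclude: Iterable[str] = ()
) -> PropertyEntropyTable:
    """H(p) for every property occurring in ``kg``.

    Surface-form properties are passed via ``exclude``: label strings are
    near-unique, so including them would make their entropies dominate the
    relation weights artificially.
    """
    excluded = set(exclude)
    table = PropertyEntropyTable()
    for p in sorted(kg.properties()):
        if p in excluded:
            continue
        table.entropy[p] = property_entropy(kg, p)
    return table


def _propagation_structure(
    kg: KnowledgeGraph, entropies: PropertyEntropyTable
) -> dict[str, list[tuple[float, str]]]:
    """Per-entity update terms: c -> [(H(p)/L(o), o), ...].

    Only entity-valued objects whose property has a (positive) entry in the
    entropy table take part; L(o) counts distinct entities with any
    entity-valued out-edge to o.
    """
    in_sources: dict[str, set[str]] = {}
    for t in kg.triples:
        if t.object_is_entity:
            in_sources.setdefault(t.object, set()).add(t.subject)
    terms: dict[str, list[tuple[float, str]]] = {e: [] for e in kg.entities}
    for t in sorted(kg.triples, key=lambda t: (t.subject, t.property, t.object)):
        if not t.object_is_entity:
            continue
        h = entropies.get(t.property, 0.0)
        if h <= 0.0:
            continue
        load = len(in_sources[t.object])
        terms[t.subject].append((h / load, t.object))
    return terms


def entropy_rank(
    kg: KnowledgeGraph,
    entropies: PropertyEntropyTable,
    tolerance: float = DEFAULT_TOLERANCE,
    max_iterations: int = DEFAULT_MAX_ITERATIONS,
) -> EntropyRankState:
    """Power-iterate the rescaled EntropyRank operator to its fixed point.

    Convergence is declared when the L-infinity change of the rescaled
    vector drops to ``tolerance`` or below; otherwise iteration stops at
    ``max_iterations`` with ``converged=False``.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    if max_iterations < 1:
        raise ValueError("max_iterations must be >= 1")

    entities = sorted(kg.entities)
    n = len(entities)
    if n == 0:
        return EntropyRankState(rank={}, iterations_run=0, converged=True, residual=0.0)

    terms = _propagation_structure(kg, entropies)
    rank = {e: 1.0 for e in entities}
    residual = math.inf
    iterations = 0
    for iterations in range(1, max_iterations + 1):
        new = {}
        for e in entities:
            contribs = terms[e]
            if contribs:
                new[e] = sum(w * rank[o] for w, o in contribs)
            else:
                # zero-update entity: hold previous value
                new[e] = rank[e]
        total = sum(new.values())
        if total <= 0.0:
            # degenerate: nothing propagates anywhere; keep previous vector
            residual = 0.0
            break
        scale = n / total
        new = {e: v * scale for e, v in new.items()}
        residual = max(abs(new[e] - rank[e]) for e in entities)
        rank = new
        if residual <= tolerance:
            break
    return EntropyRankState(
        rank=rank,
        iterations_run=iterations,
        converged=residual <= tolerance,
        residual=residual,
    )


# ---------------------------------------------------------------------------
# Serialization (rank-vector cache)
# ---------------------------------------------------------------------------


def write_rank_tsv(state: EntropyRankState, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# iterations={state.iterations_run} converged={state.converged} "
                 f"residual={state.residual:.3e}\n")
        for e in sorted(state.rank):
            fh.write(f"{e}\t{state.rank[e]:.17g}\n")


def read_rank_tsv(path: str | Path) -> EntropyRankState:
    rank: dict[str, float] = {}
    iterations, converged, residual = 0, True, 0.0
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                meta = dict(kv.split("=") for kv in line[1:].split())
                iterations = int(meta.get("iterations", 0))
                converged = meta.get("converged", "True") == "True"
                residual = float(meta.get("residual", 0.0))
                continue
            if not line.strip():
                continue
            entity, value = line.split("\t")
            rank[entity] = float(value)
    return EntropyRankState(rank, iterations, converged, residual)


def write_entropy_tsv(table: PropertyEntropyTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for p in sorted(table.entropy):
            fh.write(f"{p}\t{table.entropy[p]:.17g}\n")


def read_entropy_tsv(path: str | Path) -> PropertyEntropyTable:
    table = PropertyEntropyTable()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            p, value = line.split("\t")
            table.entropy[p] = float(value)
    return table
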