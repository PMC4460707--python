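"""Candidate retrieval and (non-)collective disambiguation scoring.

Each mention's candidates come from the surface-form dictionary: exact
normalized matches plus partial matches scored by Jaccard similarity on
token sets and kept above ``min_js``.  Candidates are pre-ranked by the
non-collective score

    ER*(m, c) = JS(m, c) * ER(c),

string similarity times the EntropyRank popularity prior.  Collective
inference then rewards candidates whose knowledge-graph neighborhood
echoes the mention's document-graph neighborhood:

    SimF(m, c) = alpha * ER*(m, c)
               + beta * sum_p H(p) * sum_{n in O_pc ∩ O_m} ER(n),

where ``O_pc ∩ O_m`` is the set of KB neighbors of ``c`` (either edge
direction) whose registered surface form exactly matches, after
normalization, the surface of some mention adjacent to ``m`` in the
document graph.  A neighbor reachable through two properties contributes
under both.  The defaults alpha=15 and beta=8 weight the popularity prior
against the context agreement term.  With beta=0, or on an edgeless
(mention-level) document graph, SimF ranking reduces exactly to the
non-collective ranking.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

from .entropy_rank import EntropyRankState, PropertyEntropyTable
from .kb_graph import (
    KnowledgeGraph,
    SurfaceFormDictionary,
    neighbors,
    normalize_surface,
    tokenize,
)
from .mentions import Document, DocumentGraph, Level, Mention, build_document_graph, extract_mentions

DEFAULT_ALPHA = 15.0
DEFAULT_BETA = 8.0
DEFAULT_MIN_JS = 0.5


class MissingRankError(KeyError):
    """A candidate entity has no EntropyRank entry."""


@dataclass(frozen=True)
class Candidate:
    entity: str
    matched_form: str
    js: float
    er: float = 0.0
    er_star: float = 0.0


@dataclass
class LinkResult:
    mention: Mention
    ranked: list[tuple[Candidate, float]]  # (candidate, simf), descending
    chosen: str | None

    def to_row(self) -> dict:
        top = self.ranked[0] if self.ranked else None
        return {
            "start": self.mention.start,
            "end": self.mention.end,
            "surface": self.mention.surface,
            "chosen": self.chosen,
            "simf": top[1] if top else None,
            "er_star": top[0].er_star if top else None,
            "js": top[0].js if top else None,
        }


def jaccard_similarity(a: str, b: str) -> float:
    """Jaccard similarity of normalized token sets, in [0, 1]."""
    ta = set(tokenize(normalize_surface(a)))
    tb = set(tokenize(normalize_surface(b)))
    if not ta or not tb:
        raise ValueError("input is empty after normalization")
    return len(ta & tb) / len(ta | tb)


def retrieve_candidates(
    sfd: SurfaceFormDictionary, mention: Mention | str, min_js: float = DEFAULT_MIN_JS
) -> list[Candidate]:
    """Entities whose best surface form matches the mention exactly or with
    Jaccard similarity at least ``min_js``.

    Partial matches are located through the token index (any shared
    token); per entity the best-scoring form is recorded.  The result is
    sorted by descending similarity, then entity id.
    """
    if not (0 < min_js <= 1):
        raise ValueError("require 0 < min_js <= 1")
    surface = mention.surface if isinstance(mention, Mention) else mention
    norm = normalize_surface(surface)
    toks = set(tokenize(norm))
    if not toks:
        return []
    best: dict[str, tuple[float, str]] = {}
    for key in sfd.candidate_keys(toks):
        key_toks = set(tokenize(key))
        js = len(toks & key_toks) / len(toks | key_toks)
        if js < min_js and key != norm:
            continue
        for entity in sfd.forms[key]:
            prev = best.get(entity)
            if prev is None or js > prev[0]:
                best[entity] = (js, key)
    out = [Candidate(entity=e, matched_form=form, js=js)
           for e, (js, form) in best.items()]
    out.sort(key=lambda c: (-c.js, c.entity))
    return out


def score_noncollective(
    candidates: Sequence[Candidate], ranks: EntropyRankState
) -> list[Candidate]:
    """Populate ER and ER* = JS x ER; sort by ER* descending, entity id
    ascending on ties."""
    scored = []
    for c in candidates:
        er = ranks.get(c.entity)
        if er is None:
            raise MissingRankError(c.entity)
        scored.append(replace(c, er=er, er_star=c.js * er))
    scored.sort(key=lambda c: (-c.er_star, c.entity))
    return scored


def context_overlap(
    kg: KnowledgeGraph,
    candidate: str,
    mention_vertex: int,
    dg: DocumentGraph,
    sfd: SurfaceFormDictionary,
) -> set[str]:
    """KB neighbors of ``candidate`` surface-matching the mention's
    document-graph neighborhood.

    A neighbor ``n`` (either edge direction) is in the overlap iff some
    mention adjacent to ``mention_vertex`` has a normalized surface that
    is a registered surface form of ``n`` (exact match — partial matching
    here would compound noise).
    """
    adjacent_surfaces = {
        normalize_surface(dg.vertices[j].surface) for j in dg.adjacent(mention_vertex)
    }
    if not adjacent_surfaces:
        return set()
    overlap: set[str] = set()
    for _prop, n in neighbors(kg, candidate, "both"):
        if n in overlap:
            continue
        for surf in adjacent_surfaces:
            if n in sfd.forms.get(surf, ()):
                overlap.add(n)
                break
    return overlap


def overlap_properties(
    kg: KnowledgeGraph, candidate: str, overlap: set[str]
) -> dict[str, set[str]]:
    """Group overlap members by the properties connecting them to the
    candidate (both directions); a neighbor linked via two properties
    appears under both."""
    by_prop: dict[str, set[str]] = {}
    for prop, n in neighbors(kg, candidate, "both"):
        if n in overlap:
            by_prop.setdefault(prop, set()).add(n)
    return by_prop


def simf(
    candidate: Candidate,
    overlap_by_property: Mapping[str, set[str]],
    entropies: PropertyEntropyTable,
    ranks: EntropyRankState,
    alpha: float = DEFAULT_ALPHA,
    beta: float = DEFAULT_BETA,
) -> float:
    """Collective similarity score alpha*ER* + beta*sum_p H(p) sum_n ER(n)."""
    if alpha < 0 or beta < 0:
        raise ValueError("alpha and beta must be non-negative")
    context = 0.0
    if beta > 0:
        for prop, members in overlap_by_property.items():
            h = entropies.get(prop, 0.0)
            if h <= 0:
                continue
            context += h * sum(ranks.get(n, 0.0) for n in members)
    return alpha * candidate.er_star + beta * context


def link_mentions(
    mentions: Sequence[Mention],
    kg: KnowledgeGraph,
    sfd: SurfaceFormDictionary,
    entropies: PropertyEntropyTable,
    ranks: EntropyRankState,
    level: Level = "sentence",
    alpha: float = DEFAULT_ALPHA,
    beta: float = DEFAULT_BETA,
    min_js: float = DEFAULT_MIN_JS,
    simf_threshold: float | None = None,
) -> list[LinkResult]:
    """Disambiguate pre-extracted mentions against the knowledge graph.

    Every mention with at least one candidate receives a link (the system
    has no nil-detection by default); ``simf_threshold``, when set, nils
    out links scoring below it.
    """
    dg = build_document_graph(mentions, level)
    results: list[LinkResult] = []
    for idx, mention in enumerate(mentions):
        candidates = retrieve_candidates(sfd, mention, min_js=min_js)
        candidates = score_noncollective(candidates, ranks)
        ranked: list[tuple[Candidate, float]] = []
        for cand in candidates:
            overlap = context_overlap(kg, cand.entity, idx, dg, sfd)
            by_prop = overlap_properties(kg, cand.entity, overlap)
            score = simf(cand, by_prop, entropies, ranks, alpha=alpha, beta=beta)
            ranked.append((cand, score))
        ranked.sort(key=lambda pair: (-pair[1], pair[0].entity))
        chosen = ranked[0][0].entity if ranked else None
        if chosen is not None and simf_threshold is not None and ranked[0][1] < simf_threshold:
            chosen = None
        results.append(LinkResult(mention=mention, ranked=ranked, chosen=chosen))
    return results


def link_document(
    doc: Document,
    kg: KnowledgeGraph,
    sfd: SurfaceFormDictionary,
    entropies: PropertyEntropyTable,
    ranks: EntropyRankState,
    level: Level = "sentence",
    alpha: float = DEFAULT_ALPHA,
    beta: float = DEFAULT_BETA,
    min_js: float = DEFAULT_MIN_JS,
    min_chunks: int = 1,
    max_chunks: int = 5,
    allow_overlap: bool = False,
    simf_threshold: float | None = None,
) -> list[LinkResult]:
    """Full pipeline for one document: extract mentions, build G_d at the
    requested level, and link every mention (argmax SimF, lexicographic
    tie-break; nil when no candidate is retrieved)."""
    mentions = extract_mentions(doc, sfd, min_chunks=min_chunks,
                                max_chunks=max_chunks, allow_overlap=allow_overlap)
    return link_mentions(mentions, kg, sfd, entropies, ranks, level=level,
                         alpha=alpha, beta=beta, min_js=min_js,
                         simf_threshold=simf_threshold)


# ---------------------------------------------------------------------------
# Output serialization
# ---------------------------------------------------------------------------


def links_to_tsv(results: Sequence[LinkResult]) -> str:
    lines = ["start\tend\tsurface\tchosen\tsimf\ter_star\tjs"]
    for r in results:
        row = r.to_row()
        fmt = lambda v: "" if v is None else (f"{v:.8g}" if isinstance(v, float) else str(v))
        lines.append("\t".join(fmt(row[k]) for k in
                               ("start", "end", "surface", "chosen", "simf", "er_star", "js")))
    return "\n".join(lines) + "\n"


def links_to_json(results: Sequence[LinkResult]) -> str:
    payload = []
    for r in results:
        payload.append({
            "mention": {
                "surface": r.mention.surface,
                "start": r.mention.start,
                "end": r.mention.end,
                "sentence_index": r.mention.sentence_index,
                "paragraph_index": r.mention.paragraph_index,
            },
            "chosen": r.chosen,
            "candidates": [
                {"entity": c.entity, "matched_form": c.matched_form,
                 "js": c.js, "er": c.er, "er_star": c.er_star, "simf": s}
                for c, s in r.ranked
            ],
        })
    return json.dumps(payload, indent=2)
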