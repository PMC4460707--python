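"""Knowledge-graph construction from ontology triples.

The knowledge base is a set of subject--property--object triples aggregated
from one or more ontologies.  Every subject, and every object that names an
entity rather than a literal string, becomes a vertex of the knowledge graph
``G_k``; the triples are its typed edges.  Literal-valued triples carry the
surface forms (labels, synonyms, aliases, symbols) from which the
surface-form dictionary used for candidate retrieval is built.

Two serializations are supported: a subset of N-Triples (parsed with rdflib;
datatype and language tags are stripped, blank-node ids are kept as opaque
identifiers) and a plain 3-column tab-separated dialect with ``#`` comments.
"""

from __future__ import annotations

import logging
import re
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import rdflib

logger = logging.getLogger("ontolink")

#: Properties treated as surface-form carriers when no config is given.
#: Real aggregated ontologies expose far more (label/synonym/alias/symbol
#: variants per namespace); the list is always user-overridable.
DEFAULT_SURFACE_PROPERTIES = ("rdfs:label", "synonym", "alias", "symbol")

Direction = Literal["out", "in", "both"]


class TripleParseError(ValueError):
    """A record in a triple file could not be parsed."""


class EmptyGraphError(ValueError):
    """A triple file yielded no triples."""


class UnknownEntityError(KeyError):
    """An entity identifier is not a vertex of the knowledge graph."""


@dataclass(frozen=True)
class Triple:
    """One ``(subject, property, object)`` assertion.

    ``object_is_entity`` distinguishes edges of the knowledge graph
    (entity-valued objects) from attribute assertions whose object is a
    literal string; a literal never occurs as a subject.
    """

    subject: str
    property: str
    object: str
    object_is_entity: bool

    def __post_init__(self) -> None:
        if not self.subject or not self.property:
            raise ValueError("triple subject and property must be non-empty")


class KnowledgeGraph:
    """Entity vertices plus typed triples, with out/in adjacency indexes.

    Duplicate triples collapse to a single stored copy so that property
    statistics are not inflated by redundant assertions from merged
    ontologies.
    """

    def __init__(self, triples: Iterable[Triple] = ()) -> None:
        self.entities: set[str] = set()
        self.triples: set[Triple] = set()
        self.out_index: dict[str, list[tuple[str, str, bool]]] = {}
        self.in_index: dict[str, list[tuple[str, str]]] = {}
        for t in triples:
            self.add(t)

    def add(self, t: Triple) -> None:
        if t in self.triples:
            return
        self.triples.add(t)
        self.entities.add(t.subject)
        self.out_index.setdefault(t.subject, []).append(
            (t.property, t.object, t.object_is_entity)
        )
        if t.object_is_entity:
            self.entities.add(t.object)
            self.in_index.setdefault(t.object, []).append((t.property, t.subject))

    def __len__(self) -> int:
        return len(self.triples)

    def __contains__(self, entity: str) -> bool:
        return entity in self.entities

    # -- adjacency -----------------------------------------------------

    def properties(self) -> set[str]:
        return {t.property for t in self.triples}

    def out_edges(self, e: str) -> list[tuple[str, str, bool]]:
        """All ``(property, object, object_is_entity)`` with subject ``e``."""
        if e not in self.entities:
            raise UnknownEntityError(e)
        return list(self.out_index.get(e, ()))


def neighbors(
    kg: KnowledgeGraph, e: str, direction: Direction = "both"
) -> list[tuple[str, str]]:
    """Entity-valued neighbors of ``e`` as sorted ``(property, entity)`` pairs.

    Literal-valued objects are excluded; pairs are deduplicated and returned
    in sorted order for determinism.
    """
    if e not in kg.entities:
        raise UnknownEntityError(e)
    pairs: set[tuple[str, str]] = set()
    if direction in ("out", "both"):
        for prop, obj, is_entity in kg.out_index.get(e, ()):
            if is_entity:
                pairs.add((prop, obj))
    if direction in ("in", "both"):
        for prop, subj in kg.in_index.get(e, ()):
            pairs.add((prop, subj))
    return sorted(pairs)


# ---------------------------------------------------------------------------
# Parsing and serialization
# ---------------------------------------------------------------------------


def _parse_tsv(path: Path) -> list[tuple[str, str, str]]:
    records: list[tuple[str, str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip("\n")
            if not stripped.strip() or stripped.lstrip().startswith("#"):
                continue
            fields = stripped.split("\t")
            if len(fields) != 3 or not all(f.strip() for f in fields[:2]):
                raise TripleParseError(
                    f"{path}:{lineno}: expected 3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            records.append((fields[0].strip(), fields[1].strip(), fields[2].strip()))
    return records


def _rdflib_term_to_id(term: rdflib.term.Node) -> tuple[str, bool]:
    """Map an rdflib term to an (identifier, is_entity) pair.

    Blank nodes keep their opaque ``_:`` prefix; URIs are used verbatim;
    literals drop datatype/language tags and keep the lexical form only.
    """
    if isinstance(term, rdflib.Literal):
        return str(term), False
    if isinstance(term, rdflib.BNode):
        return f"_:{term}", True
    return str(term), True


def load_triples(path: str | Path, dialect: Literal["ntriples", "tsv"] = "tsv") -> KnowledgeGraph:
    """Parse a triple file into a :class:`KnowledgeGraph`.

    In the TSV dialect an object is taken to be an entity reference iff it
    is prefixed ``_:`` or also occurs somewhere as a subject; anything else
    is a literal.  Malformed records raise :class:`TripleParseError` naming
    the line; a file with no triples raises :class:`EmptyGraphError`.
    """
    path = Path(path)
    if dialect == "ntriples":
        graph = rdflib.Graph()
        try:
            graph.parse(path, format="nt")
        except Exception as exc:  # rdflib raises several parser exceptions
            raise TripleParseError(f"{path}: {exc}") from exc
        kg = KnowledgeGraph()
        for s, p, o in graph:
            subj, _ = _rdflib_term_to_id(s)
            prop, _ = _rdflib_term_to_id(p)
            obj, is_entity = _rdflib_term_to_id(o)
            kg.add(Triple(subj, prop, obj, is_entity))
        if not kg.triples:
            raise EmptyGraphError(f"{path}: no triples parsed")
        return kg

    if dialect != "tsv":
        raise ValueError(f"unknown dialect: {dialect!r}")
    records = _parse_tsv(path)
    if not records:
        raise EmptyGraphError(f"{path}: no triples parsed")
    subjects = {s for s, _, _ in records}
    kg = KnowledgeGraph()
    for s, p, o in records:
        is_entity = o.startswith("_:") or o in subjects
        kg.add(Triple(s, p, o, is_entity))
    return kg


def write_triples(kg: KnowledgeGraph, path: str | Path, dialect: Literal["ntriples", "tsv"] = "tsv") -> None:
    """Serialize the graph; ``load_triples`` round-trips the result."""
    path = Path(path)
    ordered = sorted(kg.triples, key=lambda t: (t.subject, t.property, t.object))
    if dialect == "tsv":
        with open(path, "w", encoding="utf-8") as fh:
            for t in ordered:
                fh.write(f"{t.subject}\t{t.property}\t{t.object}\n")
        return
    if dialect != "ntriples":
        raise ValueError(f"unknown dialect: {dialect!r}")

    def term(identifier: str, is_entity: bool) -> str:
        if not is_entity:
            escaped = identifier.replace("\\", "\\\\").replace('"', '\\"')
            return f'"{escaped}"'
        # "_:" ids are kept as opaque IRIs rather than blank nodes: N-Triples
        # forbids blank-node predicates, and parsers relabel blank nodes,
        # which would break identifier round-trips
        if identifier.startswith("_:") and not re.search(r"[\s<>\"{}|^`\\]", identifier):
            return f"<{identifier}>"
        # scheme:rest identifiers (URIs, CURIEs) are valid absolute IRIs
        if re.match(r"^[a-zA-Z][a-zA-Z0-9+.-]*:\S+$", identifier) \
                and not re.search(r"[<>\"{}|^`\\]", identifier):
            return f"<{identifier}>"
        # bare names get a blank-node id so the file stays valid N-Triples
        return f"_:{re.sub(r'[^A-Za-z0-9]', '_', identifier)}"

    with open(path, "w", encoding="utf-8") as fh:
        for t in ordered:
            fh.write(
                f"{term(t.subject, True)} {term(t.property, True)} "
                f"{term(t.object, t.object_is_entity)} .\n"
            )


# ---------------------------------------------------------------------------
# Surface-form dictionary
# ---------------------------------------------------------------------------

_WS_RE = re.compile(r"\s+")
_EDGE_PUNCT_RE = re.compile(r"^[\W_]+|[\W_]+$", re.UNICODE)


def normalize_surface(form: str) -> str:
    """Normalize a surface string: NFC, casefold, collapse whitespace,
    strip leading/trailing punctuation.  Idempotent by construction."""
    s = unicodedata.normalize("NFC", form).casefold()
    s = _WS_RE.sub(" ", s).strip()
    # strip edge punctuation per token-free whole string, then re-collapse
    s = _EDGE_PUNCT_RE.sub("", s)
    return _WS_RE.sub(" ", s).strip()


def tokenize(normalized: str) -> list[str]:
    """Whitespace tokens of an already-normalized string."""
    return normalized.split()


class SurfaceFormDictionary:
    """Map from normalized surface string to the entities sharing it.

    ``token_index`` inverts the keys token-by-token so that partial
    (Jaccard) candidate retrieval only scores forms sharing at least one
    token with the query mention.
    """

    def __init__(self) -> None:
        self.forms: dict[str, set[str]] = {}
        self.token_index: dict[str, set[str]] = {}

    def add(self, form: str, entity: str) -> None:
        key = normalize_surface(form)
        if not key:
            return
        self.forms.setdefault(key, set()).add(entity)
        for tok in tokenize(key):
            self.token_index.setdefault(tok, set()).add(key)

    def lookup(self, surface: str) -> set[str]:
        """Entities registered under the normalized form of ``surface``."""
        return set(self.forms.get(normalize_surface(surface), ()))

    def __len__(self) -> int:
        return len(self.forms)

    def __contains__(self, surface: str) -> bool:
        return normalize_surface(surface) in self.forms

    def candidate_keys(self, tokens: Iterable[str]) -> set[str]:
        """All dictionary keys sharing at least one token with ``tokens``."""
        keys: set[str] = set()
        for tok in tokens:
            keys |= self.token_index.get(tok, set())
        return keys


def build_surface_form_dictionary(
    kg: KnowledgeGraph, surface_properties: Iterable[str]
) -> SurfaceFormDictionary:
    """Collect ``(entity, surface-property, literal)`` triples into a
    :class:`SurfaceFormDictionary`.

    Entity-valued objects of surface properties are skipped with a warning:
    a label edge pointing at another entity is an ontology modelling slip,
    not a surface form.
    """
    props = set(surface_properties)
    if not props:
        raise ValueError("surface_properties must be non-empty")
    sfd = SurfaceFormDictionary()
    for t in kg.triples:
        if t.property not in props:
            continue
        if t.object_is_entity:
            logger.warning(
                "surface property %s of %s has entity-valued object %s; skipped",
                t.property, t.subject, t.object,
            )
            continue
        sfd.add(t.object, t.subject)
    return sfd


def surface_triples(kg: KnowledgeGraph, surface_properties: Iterable[str]) -> list[Triple]:
    """Literal-valued triples whose property carries surface forms."""
    props = set(surface_properties)
    return [t for t in kg.triples if t.property in props and not t.object_is_entity]
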