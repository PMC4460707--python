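"""Synthetic knowledge bases, documents, and gold annotations.

Real inputs for this task — hundreds of merged ontologies and an
expert-annotated corpus — are large and not redistributable, so every test
and demonstration runs on generated data.  ``generate_kb`` emits a small
ontology-like triple file: entities with labels/synonyms/aliases, typed
relation edges whose object distributions differ per property (so relation
entropies H(p) differ), and a configurable fraction of entities planted to
share an ambiguous surface form with a partner.  Each member of an
ambiguous pair is wired to a distinct "context" neighbor so that the
ambiguity is resolvable by collective inference but not by the popularity
prior alone.

``generate_document`` writes prose mentioning those entities, one unit
paragraph per target, with gold annotations; distractor sentences placed in
the same paragraph mention the *wrong* member's context neighbor, making
paragraph-level context strictly noisier than sentence-level.

``figure2_fixture`` is a fixed, hand-built scenario: an ambiguous
"nucleus" mention whose popularity prior favours a neural-anatomy entity,
flipped to the cell-biology entity when a co-occurring STAT3 mention
surface-matches the cell nucleus's knowledge-graph neighborhood.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from pathlib import Path

import yaml

from .evaluation import GoldAnnotation, write_gold_tsv
from .kb_graph import KnowledgeGraph, Triple, write_triples

SURFACE_PROPERTIES = ("rdfs:label", "synonym", "alias")

#: Filler vocabulary guaranteed disjoint from generated surface-form tokens.
_FILLERS = ("We observed", "interacting with", "as well as", "and",
            "under basal conditions")


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic knowledge base.

    Defaults describe a small but structured ontology: 40 entities, 4
    relation types with distinct object spreads, 30% of entities sharing a
    surface form with a partner, and roughly 1.5 random relation edges per
    core entity.
    """

    n_entities: int = 40
    n_properties: int = 4
    surface_ambiguity: float = 0.3
    edge_density: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_entities < 2:
            raise ValueError("n_entities must be >= 2")
        if self.n_properties < 1:
            raise ValueError("n_properties must be >= 1")
        if not 0.0 <= self.surface_ambiguity <= 1.0:
            raise ValueError("surface_ambiguity must be in [0, 1]")
        if self.edge_density < 0:
            raise ValueError("edge_density must be >= 0")


@dataclass
class KBFixture:
    """A generated KB plus the metadata needed to write documents about it."""

    spec: FixtureSpec
    kb_path: Path
    config_path: Path
    kg: KnowledgeGraph
    surface_properties: tuple[str, ...]
    labels: dict[str, str]                      # entity -> unique label
    ambiguous_pairs: list[tuple[str, str, str]]  # (shared form, member a, member b)
    friends: dict[str, str]                     # pair member -> context neighbor
    core: list[str]                             # unambiguous filler entities


def generate_kb(spec: FixtureSpec, out_dir: str | Path) -> KBFixture:
    """Write ``kb.tsv`` and ``surface_properties.yaml`` under ``out_dir``.

    Byte-identical output for identical (spec, seed).  Raises
    ``ValueError`` when the requested ambiguity rate cannot be realized
    (fewer than two entities left to serve as context neighbors).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = random.Random(spec.seed)
    n = spec.n_entities
    entities = [f"_:E{i:04d}" for i in range(n)]
    labels = {e: f"term{i:04d}" for i, e in enumerate(entities)}

    k = round(spec.surface_ambiguity * n)
    if spec.surface_ambiguity > 0 and k < 2:
        k = 2
    if k % 2:
        k += 1
    if k > n:
        raise ValueError("infeasible surface_ambiguity: not enough entities to pair")
    plain = entities[k:]
    if k and len(plain) < 2:
        raise ValueError("infeasible surface_ambiguity: no entities left for context")

    triples: list[Triple] = []
    for e in entities:
        triples.append(Triple(e, "rdfs:label", labels[e], False))

    # ambiguous pairs share a synonym; each member gets its own context
    # neighbor via _:relatedTo so collective inference can tell them apart
    ambiguous_pairs: list[tuple[str, str, str]] = []
    friends: dict[str, str] = {}
    m = len(plain)
    for j in range(k // 2):
        a, b = entities[2 * j], entities[2 * j + 1]
        form = f"shared{j:03d}"
        ambiguous_pairs.append((form, a, b))
        triples.append(Triple(a, "synonym", form, False))
        triples.append(Triple(b, "synonym", form, False))
        friends[a] = plain[(2 * j) % m]
        friends[b] = plain[(2 * j + 1) % m]
        triples.append(Triple(a, "_:relatedTo", friends[a], True))
        triples.append(Triple(b, "_:relatedTo", friends[b], True))

    used_friends = set(friends.values())
    core = [e for e in plain if e not in used_friends]
    for i, e in enumerate(core):
        if i % 3 == 0:
            triples.append(Triple(e, "alias", f"alias{i:04d}", False))

    # random typed edges among core entities; property j draws objects from
    # a pool of size j+1 so the relation entropies are heterogeneous
    if len(core) >= 2:
        n_edges = max(2, round(spec.edge_density * len(core)))
        for j in range(1, spec.n_properties):
            prop = f"_:rel{j}"
            pool = core[: min(len(core), j + 1)]
            for _ in range(n_edges):
                subj = rng.choice(core)
                obj = rng.choice(pool)
                if obj != subj:
                    triples.append(Triple(subj, prop, obj, True))

    kg = KnowledgeGraph(triples)
    kb_path = out_dir / "kb.tsv"
    write_triples(kg, kb_path, dialect="tsv")
    config_path = out_dir / "surface_properties.yaml"
    with open(config_path, "w", encoding="utf-8") as fh:
        yaml.safe_dump({"surface_properties": list(SURFACE_PROPERTIES)}, fh)
    return KBFixture(
        spec=spec, kb_path=kb_path, config_path=config_path, kg=kg,
        surface_properties=SURFACE_PROPERTIES, labels=labels,
        ambiguous_pairs=ambiguous_pairs, friends=friends, core=core,
    )


@dataclass
class DocumentFixture:
    text: str
    gold: list[GoldAnnotation]
    doc_path: Path
    gold_path: Path


def generate_document(
    kb: KBFixture,
    n_sentences: int = 8,
    mentions_per_sentence: int = 3,
    distractor_rate: float = 0.0,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> DocumentFixture:
    """Write a document mentioning KB entities, with gold annotations.

    Each sentence is its own paragraph.  While ambiguous pairs exist they
    are targeted round-robin, alternating which member is intended
    (starting with the lexicographically larger one, so the popularity /
    tie-break prior is wrong for it); the intended member's context
    neighbor is mentioned in the same sentence.  With probability
    ``distractor_rate`` an ambiguous unit gains a second sentence, in the
    same paragraph, mentioning the *other* member's context neighbor —
    KB-unrelated to the first sentence's content — so paragraph-level
    context is noisier than sentence-level.
    """
    if n_sentences < 1 or mentions_per_sentence < 1:
        raise ValueError("n_sentences and mentions_per_sentence must be positive")
    rng = random.Random(seed)
    label_of = kb.labels
    core_cycle = list(kb.core) or list(kb.labels)
    pieces: list[str] = []
    gold: list[GoldAnnotation] = []
    offset = 0

    def emit(text_piece: str) -> None:
        nonlocal offset
        pieces.append(text_piece)
        offset += len(text_piece)

    def emit_mention(surface: str, entity: str) -> None:
        nonlocal offset
        gold.append(GoldAnnotation(offset, offset + len(surface), surface, entity))
        emit(surface)

    for t in range(n_sentences):
        if t:
            emit("\n\n")
        unit_mentions: list[tuple[str, str]] = []  # (surface, gold entity)
        distractor_entity: str | None = None
        if kb.ambiguous_pairs:
            form, a, b = kb.ambiguous_pairs[t % len(kb.ambiguous_pairs)]
            lo, hi = sorted((a, b))
            target = hi if t % 2 == 0 else lo
            other = a if target == b else b
            unit_mentions.append((form, target))
            unit_mentions.append((label_of[kb.friends[target]], kb.friends[target]))
            extra = mentions_per_sentence - 2
            if rng.random() < distractor_rate:
                distractor_entity = kb.friends[other]
        else:
            extra = mentions_per_sentence
        for _ in range(max(0, extra)):
            e = rng.choice(core_cycle)
            unit_mentions.append((label_of[e], e))

        emit(_FILLERS[0] + " ")
        for i, (surface, entity) in enumerate(unit_mentions):
            if i == 1:
                emit(" " + _FILLERS[1] + " ")
            elif i > 1:
                emit(" " + _FILLERS[3] + " ")
            emit_mention(surface, entity)
        emit(" " + _FILLERS[4] + ".")
        if distractor_entity is not None:
            emit(" Separately, ")
            emit_mention(label_of[distractor_entity], distractor_entity)
            emit(" was monitored.")

    text = "".join(pieces) + "\n"
    out_dir = Path(out_dir) if out_dir is not None else kb.kb_path.parent
    doc_path = out_dir / "document.txt"
    gold_path = out_dir / "gold.tsv"
    doc_path.write_text(text, encoding="utf-8")
    write_gold_tsv(gold, gold_path)
    return DocumentFixture(text=text, gold=gold, doc_path=doc_path, gold_path=gold_path)


# ---------------------------------------------------------------------------
# Hand-built illustrative scenario
# ---------------------------------------------------------------------------

_FIG2_TRIPLES: tuple[tuple[str, str, str, bool], ...] = (
    # surface forms
    ("_:STAT3", "rdfs:label", "STAT3", False),
    ("_:Activated-STAT3", "rdfs:label", "Activated STAT3", False),
    ("_:Cell-Nucleus", "rdfs:label", "Cell Nucleus", False),
    ("_:Cell-Nucleus", "synonym", "nucleus", False),
    ("_:Neural-Nucleus", "rdfs:label", "Neural Nucleus", False),
    ("_:Neural-Nucleus", "synonym", "nucleus", False),
    ("_:Nervous-Tissue", "rdfs:label", "nervous tissue", False),
    ("_:Nerve-Impulse", "rdfs:label", "nerve impulse", False),
    ("_:Transcription", "rdfs:label", "transcription", False),
    ("_:Cell-Component", "rdfs:label", "cell component", False),
    ("_:Cytokine-Signaling", "rdfs:label", "cytokine signaling", False),
    # STAT3 side of the knowledge graph; STAT3 touches the cell nucleus
    # through two properties, so both feed the context-overlap term
    ("_:STAT3", "_:locatedIn", "_:Cell-Nucleus", True),
    ("_:STAT3", "_:relatedTo", "_:Cell-Nucleus", True),
    ("_:STAT3", "_:relatedTo", "_:Cytokine-Signaling", True),
    ("_:Activated-STAT3", "_:subClassOf", "_:STAT3", True),
    ("_:Activated-STAT3", "_:locatedIn", "_:Cell-Nucleus", True),
    ("_:Activated-STAT3", "_:relatedTo", "_:Transcription", True),
    ("_:Transcription", "_:locatedIn", "_:Cell-Nucleus", True),
    # cell-biology nucleus: modest out-connectivity
    ("_:Cell-Nucleus", "_:partOf", "_:Cell-Component", True),
    # neuroanatomy nucleus: well-connected, hence the higher prior
    ("_:Neural-Nucleus", "_:partOf", "_:Nervous-Tissue", True),
    ("_:Neural-Nucleus", "_:relatedTo", "_:Nerve-Impulse", True),
    ("_:Nerve-Impulse", "_:relatedTo", "_:Nervous-Tissue", True),
)

FIG2_TEXT = "STAT3 translocates to the nucleus during signal transduction.\n"

FIG2_GOLD: tuple[tuple[int, int, str, str], ...] = (
    (0, 5, "STAT3", "_:STAT3"),
    (26, 33, "nucleus", "_:Cell-Nucleus"),
)


@dataclass
class Figure2Fixture:
    kg: KnowledgeGraph
    surface_properties: tuple[str, ...]
    text: str
    gold: list[GoldAnnotation]
    kb_path: Path | None = None
    config_path: Path | None = None
    doc_path: Path | None = None
    gold_path: Path | None = None


def figure2_fixture(out_dir: str | Path | None = None) -> Figure2Fixture:
    """The fixed rank-flip scenario; optionally also written to disk.

    The ambiguous mention "nucleus" has two candidates sharing the synonym:
    the neuroanatomical nucleus carries the higher EntropyRank prior, but
    only the cell nucleus has a knowledge-graph neighbor (STAT3) whose
    surface form occurs in the same sentence, so sentence-level collective
    inference flips the link.
    """
    kg = KnowledgeGraph(Triple(*t) for t in _FIG2_TRIPLES)
    gold = [GoldAnnotation(*row) for row in FIG2_GOLD]
    fixture = Figure2Fixture(
        kg=kg, surface_properties=SURFACE_PROPERTIES, text=FIG2_TEXT, gold=gold,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        fixture.kb_path = out_dir / "kb.tsv"
        write_triples(kg, fixture.kb_path, dialect="tsv")
        fixture.config_path = out_dir / "surface_properties.yaml"
        with open(fixture.config_path, "w", encoding="utf-8") as fh:
            yaml.safe_dump({"surface_properties": list(SURFACE_PROPERTIES)}, fh)
        fixture.doc_path = out_dir / "document.txt"
        fixture.doc_path.write_text(FIG2_TEXT, encoding="utf-8")
        fixture.gold_path = out_dir / "gold.tsv"
        write_gold_tsv(gold, fixture.gold_path)
    return fixture
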