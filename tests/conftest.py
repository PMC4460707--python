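import random
from dataclasses import dataclass

import pytest

from ontolink import (
    KnowledgeGraph,
    Triple,
    build_surface_form_dictionary,
    compute_all_entropies,
    entropy_rank,
    extract_mentions,
    segment,
)
from ontolink.fixtures import SURFACE_PROPERTIES, figure2_fixture


def random_entity_graph(seed: int, n_entities: int = 10, n_properties: int = 3,
                        n_edges: int | None = None) -> KnowledgeGraph:
    """Random knowledge graph with heterogeneous per-property object pools
    (so relation entropies differ), used by the rank-oracle tests."""
    rng = random.Random(seed)
    entities = [f"_:N{i}" for i in range(n_entities)]
    n_edges = n_edges if n_edges is not None else 2 * n_entities
    triples = []
    for _ in range(n_edges):
        p = rng.randrange(n_properties)
        pool = entities[: max(2, n_entities // (p + 1))]
        s = rng.choice(entities)
        o = rng.choice(pool)
        if s != o:
            triples.append(Triple(s, f"_:p{p}", o, True))
    if not triples:  # ensure non-empty
        triples.append(Triple(entities[0], "_:p0", entities[1], True))
    return KnowledgeGraph(triples)


@dataclass
class Pipeline:
    """Precomputed linking state for one KB fixture."""

    kg: KnowledgeGraph
    sfd: object
    entropies: object
    ranks: object


def build_pipeline(kg: KnowledgeGraph, surface_properties=SURFACE_PROPERTIES,
                   tolerance: float = 1e-10) -> Pipeline:
    sfd = build_surface_form_dictionary(kg, surface_properties)
    entropies = compute_all_entropies(kg, exclude=surface_properties)
    ranks = entropy_rank(kg, entropies, tolerance=tolerance, max_iterations=500)
    return Pipeline(kg=kg, sfd=sfd, entropies=entropies, ranks=ranks)


@pytest.fixture(scope="session")
def fig2():
    return figure2_fixture()


@pytest.fixture(scope="session")
def fig2_pipeline(fig2):
    return build_pipeline(fig2.kg, fig2.surface_properties)


@pytest.fixture(scope="session")
def fig2_mentions(fig2, fig2_pipeline):
    doc = segment(fig2.text)
    return doc, extract_mentions(doc, fig2_pipeline.sfd)
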