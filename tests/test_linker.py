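import random

import pytest
from hypothesis import given, settings, strategies as st

from conftest import build_pipeline, random_entity_graph
from ontolink import (
    Candidate,
    KnowledgeGraph,
    SurfaceFormDictionary,
    Triple,
    build_document_graph,
    context_overlap,
    jaccard_similarity,
    link_mentions,
    retrieve_candidates,
    score_noncollective,
    segment,
    simf,
)
from ontolink.entropy_rank import EntropyRankState, PropertyEntropyTable
from ontolink.kb_graph import normalize_surface, tokenize
from ontolink.linker import MissingRankError, link_document, links_to_tsv, overlap_properties
from ontolink.mentions import Mention, extract_mentions


def ranks_of(**kv):
    return EntropyRankState(rank=dict(kv), iterations_run=1, converged=True, residual=0.0)


# ---------------------------------------------------------------------------
# Jaccard similarity
# ---------------------------------------------------------------------------


def test_jaccard_partial_and_identity():
    assert jaccard_similarity("nucleus", "neural nucleus") == pytest.approx(0.5)
    assert jaccard_similarity("IκB kinase", "iκb KINASE") == 1.0


def test_jaccard_empty_after_normalization():
    with pytest.raises(ValueError):
        jaccard_similarity("...", "abc")


word = st.text(alphabet="abcdefg", min_size=1, max_size=4)


@settings(max_examples=300, derandomize=True)
@given(st.lists(word, min_size=1, max_size=6), st.lists(word, min_size=1, max_size=6))
def test_jaccard_matches_set_algebra_oracle(ws_a, ws_b):
    a, b = " ".join(ws_a), " ".join(ws_b)
    sa = set(tokenize(normalize_surface(a)))
    sb = set(tokenize(normalize_surface(b)))
    expected = len(sa & sb) / len(sa | sb)
    assert jaccard_similarity(a, b) == pytest.approx(expected)


# ---------------------------------------------------------------------------
# Candidate retrieval
# ---------------------------------------------------------------------------


def _dictionary(entries):
    sfd = SurfaceFormDictionary()
    for form, entity in entries:
        sfd.add(form, entity)
    return sfd


def test_exact_match_candidate():
    sfd = _dictionary([("iκb kinase", "_:IKK")])
    cands = retrieve_candidates(sfd, "IκB kinase")
    assert [(c.entity, c.js) for c in cands] == [("_:IKK", 1.0)]


def test_no_token_overlap_gives_empty():
    sfd = _dictionary([("alpha beta", "_:AB")])
    assert retrieve_candidates(sfd, "gamma") == []


def test_min_js_validation():
    sfd = _dictionary([("a", "_:A")])
    with pytest.raises(ValueError):
        retrieve_candidates(sfd, "a", min_js=0.0)


def test_retrieval_matches_exhaustive_scan():
    rng = random.Random(13)
    vocab = [f"w{i}" for i in range(12)]
    entries = []
    for i in range(50):
        form = " ".join(rng.sample(vocab, rng.randint(1, 3)))
        entries.append((form, f"_:E{i % 20}"))
    sfd = _dictionary(entries)
    for query in ("w0", "w1 w2", "w3 w4 w5", "w11 w0 w7"):
        got = {(c.entity, c.js) for c in retrieve_candidates(sfd, query, min_js=0.5)}
        # oracle: score every key exhaustively, keep best js >= 0.5 per entity
        qt = set(query.split())
        best = {}
        for key, entities in sfd.forms.items():
            kt = set(key.split())
            js = len(qt & kt) / len(qt | kt)
            if js >= 0.5:
                for e in entities:
                    best[e] = max(best.get(e, 0.0), js)
        assert got == set(best.items())


# ---------------------------------------------------------------------------
# Non-collective scoring
# ---------------------------------------------------------------------------


def test_er_star_is_js_times_rank():
    cands = [Candidate("_:A", "a", js=1.0), Candidate("_:B", "b", js=0.5)]
    scored = score_noncollective(cands, ranks_of(**{"_:A": 2.0, "_:B": 2.0}))
    assert [(c.entity, c.er_star) for c in scored] == [("_:A", 2.0), ("_:B", 1.0)]


def test_partial_match_with_higher_rank_wins():
    cands = [Candidate("_:exact", "x", js=1.0), Candidate("_:partial", "p", js=0.5)]
    scored = score_noncollective(
        cands, ranks_of(**{"_:exact": 1.0, "_:partial": 4.0}))
    assert scored[0].entity == "_:partial"
    assert scored[0].er_star == pytest.approx(2.0)
    assert scored[1].er_star == pytest.approx(1.0)


def test_missing_rank_entry_raises():
    with pytest.raises(MissingRankError):
        score_noncollective([Candidate("_:A", "a", js=1.0)], ranks_of())


def test_tie_broken_lexicographically():
    cands = [Candidate("_:B", "b", js=1.0), Candidate("_:A", "a", js=1.0)]
    scored = score_noncollective(cands, ranks_of(**{"_:A": 1.0, "_:B": 1.0}))
    assert [c.entity for c in scored] == ["_:A", "_:B"]


# ---------------------------------------------------------------------------
# Context overlap
# ---------------------------------------------------------------------------


def test_figure2_overlap_supports_cell_nucleus(fig2, fig2_pipeline, fig2_mentions):
    doc, mentions = fig2_mentions
    dg = build_document_graph(mentions, "sentence")
    nucleus_idx = next(i for i, m in enumerate(mentions) if m.surface == "nucleus")
    cn = context_overlap(fig2.kg, "_:Cell-Nucleus", nucleus_idx, dg, fig2_pipeline.sfd)
    nn = context_overlap(fig2.kg, "_:Neural-Nucleus", nucleus_idx, dg, fig2_pipeline.sfd)
    assert "_:STAT3" in cn
    assert nn == set()


def test_mention_level_graph_gives_empty_overlap(fig2, fig2_pipeline, fig2_mentions):
    doc, mentions = fig2_mentions
    dg = build_document_graph(mentions, "mention")
    for i in range(len(mentions)):
        assert context_overlap(fig2.kg, "_:Cell-Nucleus", i, dg, fig2_pipeline.sfd) == set()


def test_overlap_matches_brute_force_pairing():
    """Planted overlaps equal a brute-force cross-product of all
    (KB neighbor, adjacent mention) pairs."""
    kg = KnowledgeGraph([
        Triple("_:C", "_:p", "_:N1", True),
        Triple("_:N2", "_:q", "_:C", True),
        Triple("_:C", "_:p", "_:N3", True),
        Triple("_:N1", "rdfs:label", "alpha protein", False),
        Triple("_:N2", "rdfs:label", "beta", False),
        Triple("_:N3", "rdfs:label", "gamma", False),
        Triple("_:C", "rdfs:label", "center", False),
    ])
    sfd = _dictionary([("alpha protein", "_:N1"), ("beta", "_:N2"),
                       ("gamma", "_:N3"), ("center", "_:C")])
    ms = [Mention("center", 0, 6, 0, 0), Mention("beta", 7, 11, 0, 0),
          Mention("alpha protein", 12, 25, 0, 0)]
    dg = build_document_graph(ms, "sentence")
    got = context_overlap(kg, "_:C", 0, dg, sfd)
    # brute force over neighbor x adjacent-mention pairs
    from ontolink import neighbors
    expected = set()
    for _, n in neighbors(kg, "_:C", "both"):
        for j in dg.adjacent(0):
            if n in sfd.lookup(ms[j].surface):
                expected.add(n)
    assert got == expected == {"_:N1", "_:N2"}


# ---------------------------------------------------------------------------
# SimF
# ---------------------------------------------------------------------------


def test_beta_zero_reduces_to_alpha_er_star():
    cand = Candidate("_:A", "a", js=0.5, er=2.0, er_star=1.0)
    table = PropertyEntropyTable({"_:p": 1.0})
    score = simf(cand, {"_:p": {"_:N"}}, table, ranks_of(**{"_:N": 0.7}),
                 alpha=15.0, beta=0.0)
    assert score == pytest.approx(15.0 * 1.0)


def test_hand_evaluated_collective_flip():
    # A: er_star 0.2, no overlap -> 15*0.2 = 3.0
    # B: er_star 0.1, one overlap neighbor ER 0.5 via H=1.0 -> 1.5 + 4.0 = 5.5
    table = PropertyEntropyTable({"_:p": 1.0})
    ranks = ranks_of(**{"_:N": 0.5})
    a = Candidate("_:A", "a", js=1.0, er=0.2, er_star=0.2)
    b = Candidate("_:B", "b", js=1.0, er=0.1, er_star=0.1)
    score_a = simf(a, {}, table, ranks)
    score_b = simf(b, {"_:p": {"_:N"}}, table, ranks)
    assert score_a == pytest.approx(3.0)
    assert score_b == pytest.approx(5.5)
    assert score_b > score_a


def test_neighbor_via_two_properties_counts_twice():
    table = PropertyEntropyTable({"_:p": 1.0, "_:q": 0.5})
    cand = Candidate("_:A", "a", js=1.0, er=0.0, er_star=0.0)
    score = simf(cand, {"_:p": {"_:N"}, "_:q": {"_:N"}}, table,
                 ranks_of(**{"_:N": 1.0}), alpha=15, beta=1)
    assert score == pytest.approx(1.5)


def test_simf_scale_covariance():
    """Multiplying every ER by k multiplies every SimF by k."""
    table = PropertyEntropyTable({"_:p": 0.8})
    for k in (2.0, 10.0):
        base = simf(Candidate("_:A", "a", 1.0, er=1.2, er_star=1.2),
                    {"_:p": {"_:N"}}, table, ranks_of(**{"_:N": 0.4}))
        scaled = simf(Candidate("_:A", "a", 1.0, er=k * 1.2, er_star=k * 1.2),
                      {"_:p": {"_:N"}}, table, ranks_of(**{"_:N": k * 0.4}))
        assert scaled == pytest.approx(k * base)


def test_negative_weights_rejected():
    with pytest.raises(ValueError):
        simf(Candidate("_:A", "a", 1.0), {}, PropertyEntropyTable({}),
             ranks_of(), alpha=-1.0)


def test_overlap_monotonicity(fig2, fig2_pipeline, fig2_mentions):
    """Adding an overlap neighbor with ER>0 via H>0 strictly increases simf."""
    doc, mentions = fig2_mentions
    pipe = fig2_pipeline
    cand = Candidate("_:Cell-Nucleus", "nucleus", js=1.0,
                     er=pipe.ranks["_:Cell-Nucleus"],
                     er_star=pipe.ranks["_:Cell-Nucleus"])
    without = simf(cand, {}, pipe.entropies, pipe.ranks)
    by_prop = overlap_properties(fig2.kg, "_:Cell-Nucleus", {"_:STAT3"})
    with_overlap = simf(cand, by_prop, pipe.entropies, pipe.ranks)
    assert with_overlap > without


# ---------------------------------------------------------------------------
# link_document
# ---------------------------------------------------------------------------


def test_figure2_sentence_links(fig2, fig2_pipeline):
    doc = segment(fig2.text)
    pipe = fig2_pipeline
    results = link_document(doc, fig2.kg, pipe.sfd, pipe.entropies, pipe.ranks,
                            level="sentence")
    by_surface = {r.mention.surface: r.chosen for r in results}
    assert by_surface["nucleus"] == "_:Cell-Nucleus"
    assert by_surface["STAT3"] == "_:STAT3"


def test_document_without_hits_is_all_nil(fig2_pipeline):
    doc = segment("Totally unrelated words only.")
    pipe = fig2_pipeline
    from ontolink.fixtures import figure2_fixture
    kg = figure2_fixture().kg
    results = link_document(doc, kg, pipe.sfd, pipe.entropies, pipe.ranks)
    assert all(r.chosen is None for r in results)


@pytest.mark.parametrize("seed", range(5))
def test_mention_level_equals_noncollective_argmax(seed, tmp_path):
    from ontolink.fixtures import FixtureSpec, generate_document, generate_kb

    kb = generate_kb(FixtureSpec(n_entities=20, surface_ambiguity=0.4, seed=seed),
                     tmp_path)
    docfx = generate_document(kb, n_sentences=5, seed=seed)
    pipe = build_pipeline(kb.kg, kb.surface_properties)
    doc = segment(docfx.text)
    mentions = extract_mentions(doc, pipe.sfd)
    results = link_mentions(mentions, kb.kg, pipe.sfd, pipe.entropies, pipe.ranks,
                            level="mention")
    for r in results:
        cands = score_noncollective(
            retrieve_candidates(pipe.sfd, r.mention), pipe.ranks)
        expected = cands[0].entity if cands else None
        assert r.chosen == expected


def test_simf_threshold_nils_low_scores(fig2, fig2_pipeline):
    doc = segment(fig2.text)
    pipe = fig2_pipeline
    results = link_document(doc, fig2.kg, pipe.sfd, pipe.entropies, pipe.ranks,
                            simf_threshold=1e9)
    assert all(r.chosen is None for r in results)
    assert all(r.ranked for r in results)  # candidates still reported


def test_links_tsv_has_expected_columns(fig2, fig2_pipeline):
    doc = segment(fig2.text)
    pipe = fig2_pipeline
    results = link_document(doc, fig2.kg, pipe.sfd, pipe.entropies, pipe.ranks)
    tsv = links_to_tsv(results)
    header, *rows = tsv.strip().split("\n")
    assert header.split("\t") == ["start", "end", "surface", "chosen",
                                  "simf", "er_star", "js"]
    assert len(rows) == len(results)
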