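# Methods

This note records the modelling choices behind `ontolink`, the parameters
that matter, and what the synthetic test bed does and does not establish.

## Model

The system links mentions *m ∈ M* extracted from a document *d* to
reference entities *e ∈ E* of a knowledge graph *G_k* built from
subject–property–object triples.  Disambiguation combines three signals:

1. **String similarity** — Jaccard similarity JS(m, c) between normalized
   token sets of the mention and the candidate's best-matching surface
   form.  Normalization is Unicode NFC + casefold + whitespace collapse +
   edge-punctuation stripping; it is idempotent and applied identically on
   the KB side and the text side.
2. **Popularity prior (EntropyRank)** — a recursive salience score over
   *G_k* in which an edge typed *p* carries weight H(p), the Shannon
   entropy (natural log) of *p*'s object distribution.  Rank flows from
   objects to their subjects: ER(c) = Σ_p H(p) Σ_o ER(o)/L(o), with L(o)
   the number of distinct entities having an out-edge to o.
3. **Context agreement** — for a candidate c of mention m, the set
   O_pc ∩ O_m of KB neighbors of c (either edge direction) whose
   registered surface form exactly matches (after normalization) a
   mention adjacent to m in the document graph.  The combined score is
   SimF = α·JS·ER + β·Σ_p H(p)·Σ_n ER(n) over the properties p actually
   connecting c to overlap members; a neighbor reachable via two
   properties contributes under both.

### Assumptions

* Mentions co-occurring in a sentence (or paragraph) are semantically
  related, so their reference entities should be connected in *G_k*.
  This is the core collective-inference assumption; it is deliberately
  coarse and is exactly what the paragraph-level noise experiments probe.
* Ontology structure is informative: relations with diverse objects say
  more about an entity's salience than near-constant ones.
* Every mention with at least one candidate receives a link; the system
  does not decide linkability.  An optional `simf_threshold` exists but
  defaults to off.

## Numerical choices

* **Log base**: natural log throughout.  The base rescales all H(p)
  uniformly; rankings are unaffected, though the α/β trade-off is tied to
  the chosen base.
* **Ψ(o_p)**: maximum-likelihood frequency of each distinct object value
  of p over the whole KB.
* **Normalization of the rank vector**: the raw recursion has no
  guaranteed bounded nontrivial fixed point (the H(p) weights are not
  stochastic), so after every synchronous sweep the vector is rescaled to
  sum |E|.  This turns the iteration into standard power iteration on a
  non-negative operator: the fixed point is its dominant eigendirection,
  and within-sweep ordering is unchanged.  SimF is homogeneous of degree
  one in ER, so rankings are invariant to this scale choice.
* **Zero-update entities** (no entity-valued out-edges, or only
  zero-entropy properties) hold their previous value instead of dropping
  to 0, keeping the ER = 1 initialization meaningful as a floor for leaf
  entities.
* **Convergence**: L∞ change of the rescaled vector ≤ 1e-8 (default), cap
  100 sweeps.  The packaged fixtures converge in well under 30.
* **Surface properties are excluded** from both the entropy statistics and
  the propagation: label strings are near-unique and would dominate H
  artificially; the rank is a graph quantity.
* **Ties** anywhere in candidate ranking break lexicographically by
  entity identifier, for determinism.
* **Defaults**: α = 15, β = 8 (the operative weighting of prior versus
  context agreement); min_js = 0.5 (admits a one-token mention against a
  two-token form, e.g. "nucleus" vs "neural nucleus", while pruning
  single-token hits on long forms); mention windows of 1–5 chunks.

## Mention extraction

Extraction is deliberately upstream plumbing: the default tagger is a
dictionary longest-match-first scanner over sentence token windows,
accepting a window whose normalized form is a dictionary key or a
whole-token subset of one (so "nucleus" is tagged when only "neural
nucleus" is registered).  Matched spans are consumed unless
`allow_overlap` is set; chunk bounds (1..5 tokens) cap the window.  Any
external NER can be plugged in; its output is validated against the
document bounds.  A rule-based sentence splitter avoids breaking on
common abbreviations, decimals, and periods inside parentheses.  The
optional post-pass merging mentions separated only by
prepositions/articles/punctuation is off by default — it presumes a
fragmenting NER front-end.

## Synthetic data

`fixtures.generate_kb` emulates the *structure* that the method exploits:
unique labels, a configurable fraction of entities sharing an ambiguous
synonym, per-property object pools of different sizes (heterogeneous
H(p)), and for each ambiguous entity a distinct context neighbor
reachable by a positive-entropy relation.  `generate_document` writes
unit paragraphs whose sentences mention a target plus its context
neighbor, alternating which pair member is intended so that the prior
(and the deterministic tie-break) is wrong on roughly half the ambiguous
mentions; distractor sentences inject the wrong member's context neighbor
into the same paragraph.  Study sizes used by the tests and the
acceptance script: 40 entities, 4 relation types, 30% ambiguity, 8–12
sentences with 3 mentions each — small enough to audit by hand, large
enough that every code path (partial matches, shared forms, all three
inference levels, distractor noise) is exercised.

What passing these tests shows: the scoring machinery behaves exactly as
specified — the collective term resolves planted, context-resolvable
ambiguity that the prior cannot, and paragraph-wide noise degrades it.
What it does not show: performance on real ontologies and real prose.
Generated fixtures have clean tokenization, exhaustive dictionaries, and
perfectly reliable co-occurrence cues; real corpora have none of these,
and real mention extraction (here replaced by the dictionary tagger) is a
major error source in its own right.

## Design decisions that were genuinely open

* **Direction of rank flow**: the recursion is read literally — a subject
  accumulates the rank of its objects.  An in-neighbor variant would be a
  different (also defensible) model; the literal reading is the default
  and the only one shipped.
* **TSV entity/literal discrimination**: an object is an entity iff
  prefixed `_:` or occurring as a subject; everything else is a literal.
  N-Triples input distinguishes these syntactically.
* **Duplicate triples collapse**; merged ontologies frequently repeat
  assertions and repeats would inflate both Ψ and the propagation.
* **Overlap matching is exact** (normalized equality), not Jaccard:
  partial matching inside the context term compounds noise from two
  directions at once.
* **Accuracy denominator**: correctly-extracted mentions that carry a
  gold entity and received a non-nil link.  Mentions the extractor missed
  are an extraction error (scored by P/R/F), not a linking error.

## Limitations

* The entropy weights and the α/β trade-off are coupled to the log base
  and to the per-sweep rescaling; the shipped defaults are meaningful as
  a pair, not individually.
* No nil-link decision: precision on corpora with unlinkable mentions is
  bounded by the candidate generator.
* The document graph is built from co-occurrence only; dependency-path or
  role-based context selection is out of scope.
* The ranker is dense-dictionary, in-memory; million-entity KBs would
  need sparse/out-of-core structures that are deliberately not built.
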