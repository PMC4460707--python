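"""Document segmentation, mention extraction, and the document graph.

A document is split into paragraphs (blank-line separated) and sentences
(rule-based splitter).  Candidate entity mentions are found by a
dictionary tagger: at each token position the longest window of up to
``max_chunks`` tokens whose normalized form is known to the surface-form
dictionary becomes a mention.  The tagger is deliberately pluggable —
mention extraction is upstream plumbing here, and any external NER whose
spans lie inside the text can be substituted — while the chunk-bound and
overlap parameters it honours are first-class.

Mentions then become the vertices of the document graph ``G_d``.  At
``mention`` level the graph has no edges (each mention is disambiguated in
isolation); at ``sentence`` / ``paragraph`` level two mentions are
connected iff they co-occur in the same sentence / paragraph.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from typing import Callable, Iterable, Literal, Sequence

from .kb_graph import SurfaceFormDictionary, normalize_surface, tokenize

Level = Literal["mention", "sentence", "paragraph"]
LEVELS: tuple[Level, ...] = ("mention", "sentence", "paragraph")

DEFAULT_MIN_CHUNKS = 1
DEFAULT_MAX_CHUNKS = 5


class EmptyDocumentError(ValueError):
    pass


@dataclass(frozen=True)
class Document:
    """Raw text plus paragraph and sentence character spans (0-based,
    half-open); every sentence lies inside exactly one paragraph."""

    text: str
    paragraphs: tuple[tuple[int, int], ...]
    sentences: tuple[tuple[int, int, int], ...]  # (start, end, paragraph_idx)


@dataclass(frozen=True)
class Mention:
    surface: str
    start: int
    end: int
    sentence_index: int
    paragraph_index: int

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class DocumentGraph:
    """Mention co-occurrence graph G_d at a fixed context level."""

    vertices: list[Mention]
    edges: set[tuple[int, int]]  # symmetric; stored as (min, max)
    level: Level

    def adjacent(self, i: int) -> list[int]:
        if not 0 <= i < len(self.vertices):
            raise IndexError(f"vertex {i} out of range")
        out = [b if a == i else a for a, b in self.edges if i in (a, b)]
        return sorted(out)


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

_ABBREVIATIONS = {
    "e.g", "i.e", "cf", "al", "et al", "fig", "figs", "eq", "eqs", "ref",
    "refs", "vs", "dr", "mr", "mrs", "ms", "prof", "no", "approx", "ca",
    "resp", "sec", "vol",
}

_BOUNDARY_RE = re.compile(r"[.!?]+")


def _sentence_bounds(paragraph: str, offset: int) -> list[tuple[int, int]]:
    """Sentence spans inside one paragraph, absolute coordinates.

    A ``.!?`` run ends a sentence unless it sits inside parentheses or
    directly follows a known abbreviation or a single letter (initials).
    """
    spans: list[tuple[int, int]] = []
    depth = 0
    start = 0
    i = 0
    n = len(paragraph)
    while i < n:
        ch = paragraph[i]
        if ch in "([{":
            depth += 1
        elif ch in ")]}":
            depth = max(0, depth - 1)
        elif ch in ".!?" and depth == 0:
            m = _BOUNDARY_RE.match(paragraph, i)
            end = m.end()
            if ch == ".":
                word = re.search(r"([\w.]*)$", paragraph[start:i]).group(1)
                word = word.rstrip(".").rsplit(".", 1)[-1].lower()
                prev_two = paragraph[max(0, i - 6):i].lower()
                if (word in _ABBREVIATIONS or len(word) == 1
                        or prev_two.endswith("et al")):
                    i = end
                    continue
            # require following whitespace (or end) to avoid decimals/ids
            if end < n and not paragraph[end].isspace():
                i = end
                continue
            spans.append((start, end))
            i = end
            while i < n and paragraph[i].isspace():
                i += 1
            start = i
            continue
        i += 1
    if start < n and paragraph[start:].strip():
        spans.append((start, n))
    # trim whitespace at span edges
    out = []
    for s, e in spans:
        while s < e and paragraph[s].isspace():
            s += 1
        while e > s and paragraph[e - 1].isspace():
            e -= 1
        if s < e:
            out.append((s + offset, e + offset))
    return out


def segment(text: str) -> Document:
    """Split text into paragraphs on blank lines, then into sentences."""
    if not text or not text.strip():
        raise EmptyDocumentError("document text is empty")
    paragraphs: list[tuple[int, int]] = []
    for m in re.finditer(r"(?:[^\n]+\n?)+", text):
        chunk = m.group(0)
        if chunk.strip():
            s, e = m.start(), m.end()
            while s < e and text[s].isspace():
                s += 1
            while e > s and text[e - 1].isspace():
                e -= 1
            paragraphs.append((s, e))
    sentences: list[tuple[int, int, int]] = []
    for p_idx, (ps, pe) in enumerate(paragraphs):
        for ss, se in _sentence_bounds(text[ps:pe], ps):
            sentences.append((ss, se, p_idx))
    return Document(text=text, paragraphs=tuple(paragraphs), sentences=tuple(sentences))


def document_from_json(payload: str | dict) -> Document:
    """Load the JSON document form; segmentation is computed for any
    field left absent.  Schema: {"text", "paragraphs": [[s,e],...],
    "sentences": [[s,e,p],...]}."""
    obj = json.loads(payload) if isinstance(payload, str) else payload
    text = obj["text"]
    if "paragraphs" not in obj or "sentences" not in obj:
        auto = segment(text)
        paragraphs = obj.get("paragraphs", auto.paragraphs)
        sentences = obj.get("sentences", auto.sentences)
    else:
        paragraphs, sentences = obj["paragraphs"], obj["sentences"]
    return Document(
        text=text,
        paragraphs=tuple((int(s), int(e)) for s, e in paragraphs),
        sentences=tuple((int(s), int(e), int(p)) for s, e, p in sentences),
    )


# ---------------------------------------------------------------------------
# Mention extraction
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\S+")
_EDGE_CHAR_RE = re.compile(r"[^\w]|_", re.UNICODE)

Extractor = Callable[[Document], Sequence[Mention]]


def _sentence_tokens(doc: Document, start: int, end: int) -> list[tuple[int, int]]:
    return [(m.start() + start, m.end() + start)
            for m in _TOKEN_RE.finditer(doc.text[start:end])]


def extract_mentions(
    doc: Document,
    sfd: SurfaceFormDictionary,
    min_chunks: int = DEFAULT_MIN_CHUNKS,
    max_chunks: int = DEFAULT_MAX_CHUNKS,
    allow_overlap: bool = False,
) -> list[Mention]:
    """Dictionary longest-match-first tagger.

    Scans each sentence token-by-token; at every position the longest
    window of ``min_chunks``..``max_chunks`` tokens known to the
    dictionary — either as an exact normalized key, or as a whole-token
    subset of a key (so "nucleus" is tagged even when only "neural
    nucleus" is registered) — becomes a mention.  With
    ``allow_overlap=False`` matched spans are consumed and scanning
    resumes after them.
    """
    if not (1 <= min_chunks <= max_chunks):
        raise ValueError("require 1 <= min_chunks <= max_chunks")

    def known(normalized: str) -> bool:
        if normalized in sfd.forms:
            return True
        toks = set(tokenize(normalized))
        if not toks:
            return False
        return any(toks <= set(tokenize(key)) for key in sfd.candidate_keys(toks))

    mentions: list[Mention] = []
    for s_idx, (s_start, s_end, p_idx) in enumerate(doc.sentences):
        tokens = _sentence_tokens(doc, s_start, s_end)
        i = 0
        while i < len(tokens):
            matched_len = 0
            hi = min(len(tokens), i + max_chunks)
            for j in range(hi, i + min_chunks - 1, -1):
                span_start, span_end = tokens[i][0], tokens[j - 1][1]
                # trim edge punctuation so spans align with gold annotations
                while span_start < span_end and _EDGE_CHAR_RE.match(doc.text[span_start]):
                    span_start += 1
                while span_end > span_start and _EDGE_CHAR_RE.match(doc.text[span_end - 1]):
                    span_end -= 1
                if span_start >= span_end:
                    continue
                window = doc.text[span_start:span_end]
                norm = normalize_surface(window)
                if norm and known(norm):
                    mentions.append(Mention(
                        surface=window, start=span_start, end=span_end,
                        sentence_index=s_idx, paragraph_index=p_idx,
                    ))
                    matched_len = j - i
                    break
            if matched_len and not allow_overlap:
                i += matched_len
            else:
                i += 1
    return mentions


_JOINER_WORDS = {"of", "the", "a", "an", "in", "on", "for", "to", "and"}


def _is_joiner_gap(gap: str) -> bool:
    """True when the text between two mentions is only prepositions,
    articles, or punctuation."""
    for token in gap.split():
        stripped = re.sub(r"[\W_]+", "", token)
        if stripped and stripped.lower() not in _JOINER_WORDS:
            return False
    return True


def merge_adjacent_mentions(doc: Document, mentions: Sequence[Mention],
                            sfd: SurfaceFormDictionary) -> list[Mention]:
    """Optional post-pass joining mentions separated only by prepositions,
    articles, or punctuation, when the joined span is itself a dictionary
    form.  Off by default in the pipeline; exists for NER front-ends that
    fragment multi-word names."""
    if not mentions:
        return []
    ordered = sorted(mentions, key=lambda m: m.start)
    merged: list[Mention] = [ordered[0]]
    for m in ordered[1:]:
        prev = merged[-1]
        gap = doc.text[prev.end:m.start]
        joined = doc.text[prev.start:m.end]
        if (m.sentence_index == prev.sentence_index and gap and
                _is_joiner_gap(gap) and normalize_surface(joined) in sfd.forms):
            merged[-1] = Mention(joined, prev.start, m.end,
                                 prev.sentence_index, prev.paragraph_index)
        else:
            merged.append(m)
    return merged


def validate_extractor_output(doc: Document, mentions: Sequence[Mention]) -> list[Mention]:
    """Plugin contract: spans must lie inside the text and reproduce their
    surfaces; violations are rejected."""
    for m in mentions:
        if not (0 <= m.start < m.end <= len(doc.text)):
            raise ValueError(f"mention span {m.span} outside document bounds")
        if doc.text[m.start:m.end] != m.surface:
            raise ValueError(f"mention surface mismatch at {m.span}")
    return list(mentions)


# ---------------------------------------------------------------------------
# Document graph
# ---------------------------------------------------------------------------


def build_document_graph(mentions: Sequence[Mention], level: Level) -> DocumentGraph:
    """Connect mentions co-occurring at the chosen context level."""
    if level not in LEVELS:
        raise ValueError(f"unknown level: {level!r}")
    edges: set[tuple[int, int]] = set()
    if level != "mention":
        key = (lambda m: m.sentence_index) if level == "sentence" \
            else (lambda m: m.paragraph_index)
        for i in range(len(mentions)):
            for j in range(i + 1, len(mentions)):
                if key(mentions[i]) == key(mentions[j]):
                    edges.add((i, j))
    return DocumentGraph(vertices=list(mentions), edges=edges, level=level)


def mentions_to_tsv(mentions: Iterable[Mention]) -> str:
    lines = ["start\tend\tsurface\tsentence_idx\tparagraph_idx"]
    for m in mentions:
        lines.append(f"{m.start}\t{m.end}\t{m.surface}\t"
                     f"{m.sentence_index}\t{m.paragraph_index}")
    return "\n".join(lines) + "\n"
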