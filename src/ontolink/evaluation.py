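"""Scoring against gold annotations: extraction P/R/F, linking accuracy,
and the inference-level ablation.

Mention extraction is scored by exact span match with one-to-one pairing.
Linking accuracy follows the standard convention for this task: among the
correctly extracted mentions that carry a gold entity and received a
non-nil link, the fraction whose chosen entity equals the gold entity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .entropy_rank import EntropyRankState, PropertyEntropyTable
from .kb_graph import KnowledgeGraph, SurfaceFormDictionary
from .linker import LinkResult, link_document
from .mentions import Document, Level, Mention

logger = logging.getLogger("ontolink")


class UndefinedAccuracyError(ZeroDivisionError):
    """No mention qualifies for the accuracy denominator."""


@dataclass(frozen=True)
class GoldAnnotation:
    start: int
    end: int
    surface: str
    gold_entity: str | None

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


def load_gold_tsv(path: str | Path) -> list[GoldAnnotation]:
    """Gold file: TSV columns start, end, surface, gold_entity_ID;
    ``#`` comments; empty entity field means an unlinkable (nil) mention."""
    gold: list[GoldAnnotation] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            start, end, surface = int(fields[0]), int(fields[1]), fields[2]
            entity = fields[3] if len(fields) > 3 and fields[3].strip() else None
            gold.append(GoldAnnotation(start, end, surface, entity))
    return gold


def write_gold_tsv(gold: Iterable[GoldAnnotation], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# start\tend\tsurface\tgold_entity\n")
        for g in gold:
            fh.write(f"{g.start}\t{g.end}\t{g.surface}\t{g.gold_entity or ''}\n")


def mention_prf(
    extracted: Sequence[Mention], gold: Sequence[GoldAnnotation]
) -> tuple[float, float, float]:
    """Precision, recall, F1 of extraction under exact-span one-to-one
    matching.  Empty gold with empty extraction scores (1, 1, 1) by
    convention (logged)."""
    if not extracted and not gold:
        logger.info("mention_prf: empty gold and extraction; scoring (1, 1, 1)")
        return (1.0, 1.0, 1.0)
    gold_spans = [g.span for g in gold]
    tp = 0
    for m in extracted:
        if m.span in gold_spans:
            gold_spans.remove(m.span)  # one-to-one pairing
            tp += 1
    precision = tp / len(extracted) if extracted else 0.0
    recall = tp / len(gold) if gold else 0.0
    f1 = (2 * precision * recall / (precision + recall)) if (precision + recall) else 0.0
    return (precision, recall, f1)


def f_measure(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall."""
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def linking_accuracy(
    results: Sequence[LinkResult], gold: Sequence[GoldAnnotation]
) -> tuple[float, int, int]:
    """(accuracy, correct, total) over correctly extracted gold mentions.

    ``total`` counts results whose span exactly matches a gold annotation
    that has a gold entity and whose link is non-nil; ``correct`` counts
    those linked to the gold entity.
    """
    by_span = {g.span: g for g in gold}
    total = 0
    correct = 0
    for r in results:
        g = by_span.get(r.mention.span)
        if g is None or g.gold_entity is None or r.chosen is None:
            continue
        total += 1
        if r.chosen == g.gold_entity:
            correct += 1
    if total == 0:
        raise UndefinedAccuracyError("no correctly-extracted linked mention to score")
    return (correct / total, correct, total)


def accuracy_from_counts(correct: int, total: int) -> float:
    """Plain correct/total arithmetic used for reporting printed counts."""
    if total == 0:
        raise UndefinedAccuracyError("total is zero")
    return correct / total


def ablation(
    doc: Document,
    kg: KnowledgeGraph,
    sfd: SurfaceFormDictionary,
    entropies: PropertyEntropyTable,
    ranks: EntropyRankState,
    gold: Sequence[GoldAnnotation],
    levels: Sequence[Level] = ("mention", "sentence", "paragraph"),
    **link_kwargs,
) -> list[tuple[Level, float, int, int]]:
    """Run the linker per inference level on identical upstream state and
    report (level, accuracy, correct, total) rows."""
    if not levels:
        raise ValueError("levels must be non-empty")
    rows: list[tuple[Level, float, int, int]] = []
    for level in levels:
        results = link_document(doc, kg, sfd, entropies, ranks, level=level, **link_kwargs)
        acc, correct, total = linking_accuracy(results, gold)
        rows.append((level, acc, correct, total))
    return rows


def ablation_to_tsv(rows: Sequence[tuple[Level, float, int, int]]) -> str:
    lines = ["level\taccuracy\tcorrect\ttotal"]
    for level, acc, correct, total in rows:
        lines.append(f"{level}\t{acc:.4f}\t{correct}\t{total}")
    return "\n".join(lines) + "\n"
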