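"""Entity-level scoring: P/R/F1, per-split recall, relaxed recall.

Precision and F1 are only meaningful corpus-wide; the three recognition
abilities are compared by recall within each split because false positives
cannot be attributed to a split.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .corpus_io import Corpus, Mention
from .partitioner import PartitionResult, Split

logger = logging.getLogger(__name__)

MentionKey = tuple[str, int, int, str]  # doc, start, end, entity_type


def mention_key(doc_id: str, mention: Mention) -> MentionKey:
    return (doc_id, mention.start, mention.end, mention.entity_type)


def _pred_keys(pred_mentions: Iterable[tuple[str, Mention]]) -> set[MentionKey]:
    keys: set[MentionKey] = set()
    duplicates = 0
    for doc_id, m in pred_mentions:
        key = mention_key(doc_id, m)
        if key in keys:
            duplicates += 1
        keys.add(key)
    if duplicates:
        logger.warning("deduplicated %d identical predictions", duplicates)
    return keys


@dataclass
class EvalReport:
    tp: int
    fp: int
    fn: int
    precision_defined: bool = True
    per_split_recall: dict[str, float] = field(default_factory=dict)
    n_per_split: dict[str, int] = field(default_factory=dict)

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0

    def as_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "precision_defined": self.precision_defined,
            "per_split_recall": dict(self.per_split_recall),
            "n_per_split": dict(self.n_per_split),
        }


def entity_prf(
    gold_mentions: Iterable[tuple[str, Mention]],
    pred_mentions: Iterable[tuple[str, Mention]],
) -> EvalReport:
    """Exact span+type matching, one-to-one; duplicates deduplicated."""
    gold_keys = {mention_key(d, m) for d, m in gold_mentions}
    pred_keys = _pred_keys(pred_mentions)
    tp = len(gold_keys & pred_keys)
    fp = len(pred_keys - gold_keys)
    fn = len(gold_keys - pred_keys)
    return EvalReport(tp=tp, fp=fp, fn=fn, precision_defined=bool(tp + fp))


def split_recall(
    partition: PartitionResult,
    pred_mentions: Iterable[tuple[str, Mention]],
) -> tuple[dict[Split, float], dict[Split, int]]:
    """Recall within each split; false positives are never attributed."""
    pred_keys = _pred_keys(pred_mentions)
    hits: dict[Split, int] = {s: 0 for s in Split}
    totals: dict[Split, int] = {s: 0 for s in Split}
    for a in partition.assignments:
        totals[a.split] += 1
        if mention_key(a.doc_id, a.mention) in pred_keys:
            hits[a.split] += 1
    recalls = {
        s: (hits[s] / totals[s]) if totals[s] else 0.0 for s in Split
    }
    return recalls, totals


def find_occurrences(corpus: Corpus, target: str) -> list[tuple[str, int, int]]:
    """Exact (non-overlapping) occurrences of ``target`` in document text."""
    occurrences: list[tuple[str, int, int]] = []
    for doc in corpus.documents:
        text = doc.text
        i = text.find(target)
        while i != -1:
            occurrences.append((doc.doc_id, i, i + len(target)))
            i = text.find(target, i + len(target))
    return occurrences


def relaxed_recall(
    corpus: Corpus,
    pred_mentions: Iterable[tuple[str, Mention]],
    target: str,
) -> float:
    """An occurrence counts as recovered if any predicted span contains it.

    Counting is per occurrence: a document with two target occurrences
    contributes two units.
    """
    occurrences = find_occurrences(corpus, target)
    if not occurrences:
        raise ValueError(f"target {target!r} does not occur in the corpus")
    preds_by_doc: dict[str, list[tuple[int, int]]] = {}
    for doc_id, m in pred_mentions:
        preds_by_doc.setdefault(doc_id, []).append((m.start, m.end))
    tp = 0
    for doc_id, s, e in occurrences:
        for p_s, p_e in preds_by_doc.get(doc_id, ()):
            if p_s <= s and p_e >= e:
                tp += 1
                break
    return tp / len(occurrences)


_ABBREV_RE = re.compile(r"[A-Z0-9\-]{2,}")


def is_abbreviation(surface: str) -> bool:
    """Heuristic: one token, length >= 2, only uppercase/digits/hyphens,
    with at least one uppercase letter."""
    return bool(_ABBREV_RE.fullmatch(surface)) and any(c.isupper() for c in surface)


def abbreviation_recall(
    partition: PartitionResult,
    pred_mentions: Iterable[tuple[str, Mention]],
    detector=is_abbreviation,
) -> tuple[float | None, float]:
    """Recall over abbreviation mentions in the Con split.

    Returns (recall, flagged_fraction); recall is None (undefined) when no
    Con mention is flagged.
    """
    con = partition.of(Split.CON)
    flagged = [a for a in con if detector(a.mention.surface)]
    fraction = len(flagged) / len(con) if con else 0.0
    if not flagged:
        return None, fraction
    pred_keys = _pred_keys(pred_mentions)
    hits = sum(1 for a in flagged if mention_key(a.doc_id, a.mention) in pred_keys)
    return hits / len(flagged), fraction


def overall_recall_from_splits(
    recalls: dict[Split, float], totals: dict[Split, int]
) -> float:
    """Split-size-weighted mean of per-split recalls (identity check helper)."""
    n = sum(totals.values())
    if not n:
        return 0.0
    return sum(recalls[s] * totals[s] for s in Split) / n


def exact_recall_on_occurrences(
    corpus: Corpus,
    pred_mentions: Iterable[tuple[str, Mention]],
    target: str,
) -> float:
    """Exact span-match recall over the same target occurrences (for
    comparison against relaxed_recall; type is ignored on both sides)."""
    occurrences = find_occurrences(corpus, target)
    if not occurrences:
        raise ValueError(f"target {target!r} does not occur in the corpus")
    pred_spans = {(d, m.start, m.end) for d, m in pred_mentions}
    tp = sum(1 for occ in occurrences if occ in pred_spans)
    return tp / len(occurrences)
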