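"""Assign test mentions to Mem / Syn / Con splits by train-set overlap.

A test mention whose (surface, concept) were both seen during training is
memorizable (Mem); an unseen surface of a seen concept is a synonym (Syn);
an unseen surface of an unseen concept is a new concept (Con). The fourth
combination — seen surface, unseen concept — is reported as a separate
Homonym bucket and excluded from the three split metrics.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable

from .corpus_io import UNKNOWN_CONCEPT, Corpus, Mention
from .normalize import DEFAULT_POLICY, NormalizationPolicy


class Split(str, Enum):
    MEM = "Mem"
    SYN = "Syn"
    CON = "Con"
    HOMONYM = "Homonym"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class TrainInventory:
    """Deduplicated training surfaces and concept IDs plus the policy used."""

    surfaces: frozenset[str]
    concepts: frozenset[str]
    policy: NormalizationPolicy = DEFAULT_POLICY
    concept_match: str = "any"  # 'any' or 'all' over a mention's concept_ids

    def surface_seen(self, mention: Mention) -> bool:
        return self.policy.normalize(mention.surface) in self.surfaces

    def concept_seen(self, mention: Mention) -> bool:
        ids = [c for c in mention.concept_ids if c != UNKNOWN_CONCEPT]
        if not ids:
            return False
        if self.concept_match == "all":
            return all(c in self.concepts for c in ids)
        return any(c in self.concepts for c in ids)


@dataclass(frozen=True)
class SplitAssignment:
    doc_id: str
    mention: Mention
    split: Split
    surface_seen: bool
    concept_seen: bool


@dataclass
class PartitionResult:
    assignments: list[SplitAssignment]
    counts: Counter = field(default_factory=Counter)

    def of(self, split: Split) -> list[SplitAssignment]:
        return [a for a in self.assignments if a.split == split]

    def summary(self) -> dict[str, int]:
        return {s.value: self.counts.get(s, 0) for s in Split}


_SPLIT_TABLE = {
    (True, True): Split.MEM,
    (False, True): Split.SYN,
    (False, False): Split.CON,
    (True, False): Split.HOMONYM,
}


def build_inventory(
    train_corpus: Corpus,
    policy: NormalizationPolicy = DEFAULT_POLICY,
    concept_match: str = "any",
) -> TrainInventory:
    """Collect every normalized gold surface and every concept ID seen in training."""
    if concept_match not in ("any", "all"):
        raise ValueError(f"concept_match must be 'any' or 'all', got {concept_match!r}")
    mentions = train_corpus.all_mentions()
    if not mentions:
        raise ValueError("training corpus contains no mentions")
    surfaces = frozenset(policy.normalize(m.surface) for _, m in mentions)
    concepts = frozenset(
        c for _, m in mentions for c in m.concept_ids if c != UNKNOWN_CONCEPT
    )
    return TrainInventory(
        surfaces=surfaces, concepts=concepts, policy=policy, concept_match=concept_match
    )


def assign_split(
    doc_id: str, mention: Mention, inventory: TrainInventory
) -> SplitAssignment:
    surface_seen = inventory.surface_seen(mention)
    concept_seen = inventory.concept_seen(mention)
    return SplitAssignment(
        doc_id=doc_id,
        mention=mention,
        split=_SPLIT_TABLE[(surface_seen, concept_seen)],
        surface_seen=surface_seen,
        concept_seen=concept_seen,
    )


def partition_corpus(test_corpus: Corpus, inventory: TrainInventory) -> PartitionResult:
    """Assign every test mention to exactly one of Mem/Syn/Con/Homonym."""
    assignments = [
        assign_split(doc_id, mention, inventory)
        for doc_id, mention in test_corpus.all_mentions()
    ]
    counts = Counter(a.split for a in assignments)
    return PartitionResult(assignments=assignments, counts=counts)


def partition_to_rows(result: PartitionResult) -> list[tuple]:
    """TSV-friendly rows: doc, start, end, surface, concepts, split."""
    return [
        (
            a.doc_id,
            a.mention.start,
            a.mention.end,
            a.mention.surface,
            "|".join(a.mention.concept_ids),
            a.split.value,
        )
        for a in result.assignments
    ]


def iter_assignment_keys(
    assignments: Iterable[SplitAssignment],
) -> Iterable[tuple[str, int, int, str]]:
    for a in assignments:
        yield (a.doc_id, a.mention.start, a.mention.end, a.mention.entity_type)
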