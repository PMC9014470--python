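"""Dictionary baselines: longest-match extraction from training surfaces.

DICT_train uses the gold training surfaces as its dictionary; DICT_syn adds
database synonyms of every concept observed in training. Matching is over
token-boundary-aligned spans; overlapping candidates are resolved longest
first (in characters), leftmost on ties.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, TextIO

from .corpus_io import UNKNOWN_CONCEPT, Corpus, Mention, Sentence
from .normalize import DEFAULT_POLICY, NormalizationPolicy

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EntityDictionary:
    entries: frozenset[str]  # normalized surfaces
    entity_type: str
    provenance: str  # 'train_mentions' or 'train_plus_synonyms'
    policy: NormalizationPolicy = DEFAULT_POLICY

    def __post_init__(self) -> None:
        if any(not e for e in self.entries):
            raise ValueError("dictionary contains an empty entry")

    @property
    def max_tokens(self) -> int:
        return max((len(e.split()) for e in self.entries), default=0)


def read_synonym_map(stream: TextIO | Iterable[str]) -> dict[str, list[str]]:
    """TSV 'conceptID TAB synonym', one pair per line."""
    out: dict[str, list[str]] = {}
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"line {lineno}: expected 'concept\\tsynonym', got {line!r}")
        out.setdefault(parts[0], []).append(parts[1])
    return out


def write_synonym_map(synonym_map: Mapping[str, Iterable[str]], stream: TextIO) -> None:
    for concept in synonym_map:
        for synonym in synonym_map[concept]:
            stream.write(f"{concept}\t{synonym}\n")


def build_dict_train(
    train_corpus: Corpus, policy: NormalizationPolicy = DEFAULT_POLICY
) -> EntityDictionary:
    mentions = train_corpus.all_mentions()
    if not mentions:
        raise ValueError("training corpus contains no mentions")
    entries = frozenset(policy.normalize(m.surface) for _, m in mentions)
    return EntityDictionary(
        entries=entries,
        entity_type=train_corpus.entity_types[0],
        provenance="train_mentions",
        policy=policy,
    )


def build_dict_syn(
    train_corpus: Corpus,
    synonym_map: Mapping[str, Iterable[str]],
    policy: NormalizationPolicy = DEFAULT_POLICY,
) -> EntityDictionary:
    """Training surfaces plus synonyms of every concept seen in training."""
    base = build_dict_train(train_corpus, policy)
    train_concepts = {
        c
        for _, m in train_corpus.all_mentions()
        for c in m.concept_ids
        if c != UNKNOWN_CONCEPT
    }
    entries = set(base.entries)
    missing = []
    for concept in sorted(train_concepts):
        synonyms = synonym_map.get(concept)
        if synonyms is None:
            missing.append(concept)
            continue
        entries.update(policy.normalize(s) for s in synonyms if s.strip())
    if missing:
        logger.warning(
            "synonym map missing %d training concept(s), e.g. %s",
            len(missing),
            missing[:3],
        )
    return EntityDictionary(
        entries=frozenset(entries),
        entity_type=base.entity_type,
        provenance="train_plus_synonyms",
        policy=policy,
    )


def tag_sentence(sentence: Sentence, dictionary: EntityDictionary) -> list[Mention]:
    """All dictionary matches over token-aligned spans, longest-wins overlaps.

    Candidates are ordered by (character length desc, start asc) and accepted
    greedily when disjoint from everything already accepted, which realizes
    the longest-match rule with a deterministic leftmost tie-break.
    """
    spans = sentence.token_spans
    n = len(spans)
    max_tok = dictionary.max_tokens
    off = sentence.start
    candidates: list[tuple[int, int]] = []
    for i in range(n):
        for j in range(i + 1, min(i + max_tok, n) + 1):
            s, e = spans[i][0], spans[j - 1][1]
            surface = sentence.text[s - off : e - off]
            if dictionary.policy.normalize(surface) in dictionary.entries:
                candidates.append((s, e))
    candidates.sort(key=lambda se: (-(se[1] - se[0]), se[0]))
    accepted: list[tuple[int, int]] = []
    for s, e in candidates:
        if all(e <= a_s or s >= a_e for a_s, a_e in accepted):
            accepted.append((s, e))
    accepted.sort()
    return [
        Mention(
            surface=sentence.text[s - off : e - off],
            start=s,
            end=e,
            entity_type=dictionary.entity_type,
            concept_ids=(UNKNOWN_CONCEPT,),
        )
        for s, e in accepted
    ]


def tag_corpus(
    corpus: Corpus, dictionary: EntityDictionary
) -> list[tuple[str, Mention]]:
    out: list[tuple[str, Mention]] = []
    for sentence in corpus.sentences():
        out.extend((sentence.doc_id, m) for m in tag_sentence(sentence, dictionary))
    return out
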