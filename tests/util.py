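"""Shared test helpers: tiny corpus builders and independent brute-force
oracles (deliberately naive nested-loop implementations)."""

from __future__ import annotations

from splitner.corpus_io import Corpus, Document, Mention
from splitner.normalize import DEFAULT_POLICY


def doc_with(doc_id, title, abstract="", anns=()):
    """Build a Document, locating each annotation surface left-to-right.

    ``anns``: iterables of (surface, entity_type, concept_ids); each surface
    is matched at its first not-yet-annotated occurrence.
    """
    doc = Document(doc_id=doc_id, title=title, abstract=abstract)
    text = doc.text
    taken: list[tuple[int, int]] = []
    for surface, etype, concepts in anns:
        pos = 0
        while True:
            i = text.find(surface, pos)
            if i == -1:
                raise AssertionError(f"{surface!r} not found in {text!r}")
            span = (i, i + len(surface))
            if all(span[1] <= s or span[0] >= e for s, e in taken):
                break
            pos = i + 1
        taken.append(span)
        doc.mentions.append(
            Mention(
                surface=surface,
                start=span[0],
                end=span[1],
                entity_type=etype,
                concept_ids=tuple(concepts),
            )
        )
    doc.mentions.sort(key=lambda m: m.start)
    doc.validate()
    return doc


def corpus_of(docs, entity_types=("Disease",), split_role="train"):
    return Corpus(documents=list(docs), entity_types=entity_types, split_role=split_role)


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------


def oracle_partition(train_mentions, test_mentions, policy=DEFAULT_POLICY):
    """Nested-loop split assignment over raw mention lists, no set types.

    ``train_mentions``/``test_mentions``: lists of (doc_id, Mention).
    Returns {(doc_id, start, end): split-name}.
    """
    out = {}
    for doc_id, m in test_mentions:
        surface_seen = False
        for _, tm in train_mentions:
            if policy.normalize(tm.surface) == policy.normalize(m.surface):
                surface_seen = True
        concept_seen = False
        for c in m.concept_ids:
            if c == "UNKNOWN":
                continue
            for _, tm in train_mentions:
                for tc in tm.concept_ids:
                    if tc != "UNKNOWN" and tc == c:
                        concept_seen = True
        if surface_seen and concept_seen:
            split = "Mem"
        elif concept_seen:
            split = "Syn"
        elif surface_seen:
            split = "Homonym"
        else:
            split = "Con"
        out[(doc_id, m.start, m.end)] = split
    return out


def oracle_dict_tag(sentence, dictionary):
    """All candidate spans, then repeated select-longest (leftmost ties),
    dropping overlaps. Returns sorted (start, end) character spans."""
    spans = sentence.token_spans
    off = sentence.start
    candidates = []
    for i in range(len(spans)):
        for j in range(i, len(spans)):
            s, e = spans[i][0], spans[j][1]
            surface = sentence.text[s - off : e - off]
            if dictionary.policy.normalize(surface) in dictionary.entries:
                candidates.append((s, e))
    selected = []
    while candidates:
        best = max(candidates, key=lambda se: (se[1] - se[0], -se[0]))
        selected.append(best)
        candidates = [
            (s, e) for s, e in candidates if e <= best[0] or s >= best[1]
        ]
    return sorted(selected)


def oracle_bias_counts(tagged_sentences, k):
    """Per-word tag frequency by explicit counting."""
    totals = {}
    per_tag = {}
    for sent in tagged_sentences:
        for word, tag in sent:
            w = word.casefold()
            totals[w] = totals.get(w, 0) + 1
            per_tag[(w, tag)] = per_tag.get((w, tag), 0) + 1
    return {
        w: [per_tag.get((w, t), 0) / totals[w] for t in range(k)] for w in totals
    }
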