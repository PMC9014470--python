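"""Corpus containers and readers/writers for span- and token-level NER data.

The module owns the document model used everywhere else: character-offset
mentions over reconstructed document text, whitespace/punctuation
tokenization, BIO conversion in both directions, and the two plain-text
dialects the toolkit exchanges data in (PubTator-style abstracts and
two-column CoNLL).
"""

from __future__ import annotations

import logging
import re
import string
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence, TextIO

logger = logging.getLogger(__name__)

UNKNOWN_CONCEPT = "UNKNOWN"

_EDGE_PUNCT = set(string.punctuation)
_TOKEN_RE = re.compile(r"\S+")


class CorpusError(ValueError):
    """Raised for malformed corpus files or inconsistent annotations."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Mention:
    """A single annotated entity occurrence.

    Offsets are 0-based, half-open, relative to the full document text.
    ``concept_ids`` is never empty; unmapped mentions carry the sentinel
    ``UNKNOWN``.
    """

    surface: str
    start: int
    end: int
    entity_type: str
    concept_ids: tuple[str, ...] = (UNKNOWN_CONCEPT,)

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise CorpusError(f"empty mention span [{self.start}, {self.end})")
        if not self.concept_ids:
            raise CorpusError("concept_ids must be non-empty")
        if len(self.surface) != self.end - self.start:
            raise CorpusError(
                f"surface length {len(self.surface)} != span length "
                f"{self.end - self.start} for {self.surface!r}"
            )

    @property
    def key(self) -> tuple[int, int, str]:
        return (self.start, self.end, self.entity_type)


@dataclass(frozen=True)
class Sentence:
    """A sentence slice of a document, tokenized, with its mentions.

    ``token_spans`` and mention offsets stay in document coordinates so
    sentence segmentation never invalidates annotations.
    """

    doc_id: str
    text: str
    start: int
    end: int
    token_spans: tuple[tuple[int, int], ...]
    mentions: tuple[Mention, ...] = ()

    @property
    def tokens(self) -> list[str]:
        off = self.start
        return [self.text[s - off : e - off] for s, e in self.token_spans]


@dataclass
class Document:
    doc_id: str
    title: str
    abstract: str = ""
    mentions: list[Mention] = field(default_factory=list)

    @property
    def text(self) -> str:
        if self.abstract:
            return self.title + " " + self.abstract
        return self.title

    def validate(self) -> None:
        text = self.text
        for m in self.mentions:
            if text[m.start : m.end] != m.surface:
                raise CorpusError(
                    f"doc {self.doc_id}: span [{m.start}, {m.end}) reads "
                    f"{text[m.start:m.end]!r}, annotation says {m.surface!r}"
                )

    def sentences(self) -> list[Sentence]:
        """Segment on period+space and tokenize each sentence."""
        text = self.text
        out: list[Sentence] = []
        for s, e in split_sentence_spans(text):
            sent_mentions = tuple(m for m in self.mentions if s <= m.start and m.end <= e)
            for m in self.mentions:
                if (s < m.end and m.start < e) and m not in sent_mentions:
                    raise CorpusError(
                        f"doc {self.doc_id}: mention {m.surface!r} crosses a "
                        "sentence boundary"
                    )
            spans = tuple(tokenize(text[s:e], offset=s))
            out.append(
                Sentence(
                    doc_id=self.doc_id,
                    text=text[s:e],
                    start=s,
                    end=e,
                    token_spans=spans,
                    mentions=sent_mentions,
                )
            )
        return out


@dataclass
class Corpus:
    documents: list[Document] = field(default_factory=list)
    entity_types: tuple[str, ...] = ("Disease",)
    split_role: str = "train"

    def __post_init__(self) -> None:
        ids = [d.doc_id for d in self.documents]
        if len(ids) != len(set(ids)):
            raise CorpusError("duplicate document IDs")

    def validate(self) -> None:
        allowed = set(self.entity_types)
        for doc in self.documents:
            doc.validate()
            for m in doc.mentions:
                if m.entity_type not in allowed:
                    raise CorpusError(
                        f"doc {doc.doc_id}: entity type {m.entity_type!r} not in "
                        f"{sorted(allowed)}"
                    )

    def all_mentions(self) -> list[tuple[str, Mention]]:
        return [(d.doc_id, m) for d in self.documents for m in d.mentions]

    def sentences(self) -> Iterator[Sentence]:
        for doc in self.documents:
            yield from doc.sentences()

    def doc(self, doc_id: str) -> Document:
        for d in self.documents:
            if d.doc_id == doc_id:
                return d
        raise KeyError(doc_id)


@dataclass(frozen=True)
class LabelScheme:
    """Ordered BIO tag classes; plain B/I/O for a single entity type."""

    entity_types: tuple[str, ...] = ("Disease",)

    @property
    def classes(self) -> tuple[str, ...]:
        if len(self.entity_types) == 1:
            return ("B", "I", "O")
        tags: list[str] = []
        for t in self.entity_types:
            tags.extend((f"B-{t}", f"I-{t}"))
        tags.append("O")
        return tuple(tags)

    @property
    def k(self) -> int:
        return len(self.classes)

    @property
    def outside(self) -> str:
        return "O"

    def b_tag(self, entity_type: str) -> str:
        self._check(entity_type)
        return "B" if len(self.entity_types) == 1 else f"B-{entity_type}"

    def i_tag(self, entity_type: str) -> str:
        self._check(entity_type)
        return "I" if len(self.entity_types) == 1 else f"I-{entity_type}"

    def index(self, tag: str) -> int:
        try:
            return self.classes.index(tag)
        except ValueError:
            raise CorpusError(f"tag {tag!r} not in scheme {self.classes}") from None

    def parse(self, tag: str) -> tuple[str, str | None]:
        """Return (kind, entity_type) where kind is 'B', 'I' or 'O'."""
        if tag == "O":
            return "O", None
        if len(self.entity_types) == 1 and tag in ("B", "I"):
            return tag, self.entity_types[0]
        if "-" in tag:
            kind, etype = tag.split("-", 1)
            if kind in ("B", "I") and etype in self.entity_types:
                return kind, etype
        raise CorpusError(f"tag {tag!r} not in scheme {self.classes}")

    def _check(self, entity_type: str) -> None:
        if entity_type not in self.entity_types:
            raise CorpusError(f"unknown entity type {entity_type!r}")


# ---------------------------------------------------------------------------
# tokenization and sentence segmentation
# ---------------------------------------------------------------------------


def tokenize(text: str, offset: int = 0) -> list[tuple[int, int]]:
    """Split on whitespace, then peel leading/trailing punctuation.

    Internal hyphens are untouched, so "COVID-19" and "MK-486" stay single
    tokens while "(COVID-19)" yields three.
    """
    spans: list[tuple[int, int]] = []
    for m in _TOKEN_RE.finditer(text):
        s, e = m.start(), m.end()
        while e - s > 1 and text[s] in _EDGE_PUNCT:
            spans.append((offset + s, offset + s + 1))
            s += 1
        trailing: list[tuple[int, int]] = []
        while e - s > 1 and text[e - 1] in _EDGE_PUNCT:
            trailing.append((offset + e - 1, offset + e))
            e -= 1
        spans.append((offset + s, offset + e))
        spans.extend(reversed(trailing))
    return spans


def split_sentence_spans(text: str) -> list[tuple[int, int]]:
    """Cut after every ". " occurrence; returns non-empty spans."""
    spans: list[tuple[int, int]] = []
    start = 0
    i = 0
    n = len(text)
    while i < n - 1:
        if text[i] == "." and text[i + 1] == " ":
            spans.append((start, i + 1))
            start = i + 2
            i += 2
        else:
            i += 1
    if start < n:
        spans.append((start, n))
    return [(s, e) for s, e in spans if e > s]


# ---------------------------------------------------------------------------
# BIO conversion
# ---------------------------------------------------------------------------


def mentions_to_bio(sentence: Sentence, scheme: LabelScheme) -> list[str]:
    """Token tags for a sentence: first mention token B, rest I, others O.

    Mentions that do not align with token boundaries are expanded to the
    smallest covering token span (with a warning); overlapping gold mentions
    are an error.
    """
    tags = [scheme.outside] * len(sentence.token_spans)
    for m in sentence.mentions:
        covered = [
            i
            for i, (s, e) in enumerate(sentence.token_spans)
            if s < m.end and e > m.start
        ]
        if not covered:
            raise CorpusError(f"mention {m.surface!r} covers no tokens")
        first, last = covered[0], covered[-1]
        if (
            sentence.token_spans[first][0] != m.start
            or sentence.token_spans[last][1] != m.end
        ):
            logger.warning(
                "mention %r at [%d, %d) not token-aligned; expanding to covering span",
                m.surface,
                m.start,
                m.end,
            )
        if any(tags[i] != scheme.outside for i in covered):
            raise CorpusError(f"overlapping gold mentions at {m.surface!r}")
        tags[first] = scheme.b_tag(m.entity_type)
        for i in covered[1:]:
            tags[i] = scheme.i_tag(m.entity_type)
    return tags


def bio_to_mentions(
    sentence: Sentence, tags: Sequence[str], scheme: LabelScheme
) -> list[Mention]:
    """Decode maximal B(-I)* runs into mentions.

    An I without a compatible preceding tag starts a new mention (lenient
    repair), so decoding is total on any tag sequence from the scheme.
    """
    if len(tags) != len(sentence.token_spans):
        raise CorpusError("tag sequence length != token count")
    mentions: list[Mention] = []
    run_start: int | None = None
    run_end: int | None = None
    run_type: str | None = None

    def flush() -> None:
        nonlocal run_start, run_end, run_type
        if run_start is not None:
            assert run_end is not None and run_type is not None
            surface = sentence.text[run_start - sentence.start : run_end - sentence.start]
            mentions.append(
                Mention(
                    surface=surface,
                    start=run_start,
                    end=run_end,
                    entity_type=run_type,
                )
            )
        run_start = run_end = run_type = None

    for (s, e), tag in zip(sentence.token_spans, tags):
        kind, etype = scheme.parse(tag)
        if kind == "O":
            flush()
        elif kind == "B":
            flush()
            run_start, run_end, run_type = s, e, etype
        else:  # I: continue the open run of the same type, else start fresh
            if run_start is not None and run_type == etype:
                run_end = e
            else:
                flush()
                run_start, run_end, run_type = s, e, etype
    flush()
    return mentions


# ---------------------------------------------------------------------------
# PubTator dialect
# ---------------------------------------------------------------------------

_TITLE_RE = re.compile(r"^(?P<pmid>[^|]+)\|t\|(?P<text>.*)$")
_ABSTRACT_RE = re.compile(r"^(?P<pmid>[^|]+)\|a\|(?P<text>.*)$")


def _parse_concepts(raw: str) -> tuple[str, ...]:
    parts = [p.strip() for p in raw.split("|")]
    out = tuple(p if p and p != "-1" else UNKNOWN_CONCEPT for p in parts)
    return out if out else (UNKNOWN_CONCEPT,)


def read_pubtator(
    stream: TextIO | Iterable[str],
    entity_types: tuple[str, ...] | None = None,
    split_role: str = "train",
) -> Corpus:
    """Parse PubTator blocks: title line, abstract line, TSV annotations.

    Every annotation is verified against the reconstructed document text
    (title + single space + abstract); a mismatch is a hard error carrying
    the PMID and offsets.
    """
    documents: list[Document] = []
    title: str | None = None
    abstract = ""
    pmid: str | None = None
    annotations: list[tuple[int, str]] = []
    seen_types: set[str] = set()

    def flush(lineno: int) -> None:
        nonlocal title, abstract, pmid, annotations
        if pmid is None:
            return
        if title is None:
            raise CorpusError(f"line {lineno}: document {pmid} has no title line")
        doc = Document(doc_id=pmid, title=title, abstract=abstract)
        text = doc.text
        for ln, raw in annotations:
            fields = raw.split("\t")
            if len(fields) < 6:
                raise CorpusError(f"line {ln}: malformed annotation {raw!r}")
            a_pmid, s_raw, e_raw, surface, etype, concept = fields[:6]
            if a_pmid != pmid:
                raise CorpusError(f"line {ln}: annotation PMID {a_pmid} != block {pmid}")
            try:
                s, e = int(s_raw), int(e_raw)
            except ValueError as exc:
                raise CorpusError(f"line {ln}: bad offsets {s_raw!r}/{e_raw!r}") from exc
            if text[s:e] != surface:
                raise CorpusError(
                    f"doc {pmid} line {ln}: text[{s}:{e}] = {text[s:e]!r} "
                    f"but annotation says {surface!r}"
                )
            seen_types.add(etype)
            doc.mentions.append(
                Mention(
                    surface=surface,
                    start=s,
                    end=e,
                    entity_type=etype,
                    concept_ids=_parse_concepts(concept),
                )
            )
        documents.append(doc)
        title, abstract, pmid, annotations = None, "", None, []

    lineno = 0
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line.strip():
            flush(lineno)
            continue
        m = _TITLE_RE.match(line)
        if m and "\t" not in line:
            if pmid is not None and title is not None:
                flush(lineno)
            pmid = m.group("pmid")
            title = m.group("text")
            continue
        m = _ABSTRACT_RE.match(line)
        if m and "\t" not in line:
            if m.group("pmid") != pmid:
                raise CorpusError(f"line {lineno}: abstract PMID mismatch")
            abstract = m.group("text")
            continue
        if "\t" in line:
            annotations.append((lineno, line))
            continue
        raise CorpusError(f"line {lineno}: unrecognized line {line!r}")
    flush(lineno + 1)

    if entity_types is None:
        entity_types = tuple(sorted(seen_types)) or ("Disease",)
    corpus = Corpus(documents=documents, entity_types=entity_types, split_role=split_role)
    corpus.validate()
    return corpus


def write_pubtator(corpus: Corpus, stream: TextIO) -> None:
    for doc in corpus.documents:
        stream.write(f"{doc.doc_id}|t|{doc.title}\n")
        stream.write(f"{doc.doc_id}|a|{doc.abstract}\n")
        for m in doc.mentions:
            concepts = "|".join(m.concept_ids)
            stream.write(
                f"{doc.doc_id}\t{m.start}\t{m.end}\t{m.surface}\t{m.entity_type}\t{concepts}\n"
            )
        stream.write("\n")


# ---------------------------------------------------------------------------
# CoNLL dialect
# ---------------------------------------------------------------------------


def read_conll(stream: TextIO | Iterable[str]) -> list[list[tuple[str, str]]]:
    """Two-column token TAB tag sentences separated by blank lines."""
    sentences: list[list[tuple[str, str]]] = []
    current: list[tuple[str, str]] = []
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line.strip():
            if current:
                sentences.append(current)
                current = []
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise CorpusError(f"line {lineno}: expected 'token\\ttag', got {line!r}")
        current.append((parts[0], parts[1]))
    if current:
        sentences.append(current)
    return sentences


def write_conll_sentences(
    sentences: Iterable[Sequence[tuple[str, str]]], stream: TextIO
) -> None:
    for sent in sentences:
        for token, tag in sent:
            stream.write(f"{token}\t{tag}\n")
        stream.write("\n")


def corpus_to_tagged_sentences(
    corpus: Corpus, scheme: LabelScheme
) -> list[list[tuple[str, str]]]:
    out = []
    for sentence in corpus.sentences():
        tags = mentions_to_bio(sentence, scheme)
        out.append(list(zip(sentence.tokens, tags)))
    return out


def write_conll(corpus: Corpus, scheme: LabelScheme, stream: TextIO) -> None:
    write_conll_sentences(corpus_to_tagged_sentences(corpus, scheme), stream)
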