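"""Synthetic corpus generator with a ground-truth ledger.

Builds paired train/test corpora whose test mentions realize configured
Mem/Syn/Con/Homonym proportions exactly, together with a synonym map and a
per-mention ledger, so partitioning, dictionary baselines, evaluation and
debiasing are all testable offline. Concept IDs are synthetic ("SYN:000123");
synonymy means shared concept, distinct generated surfaces.

Generation is a pure function of the config: the same seed yields
byte-identical corpora.
"""

from __future__ import annotations

import json
import random
import string
from dataclasses import dataclass, field, asdict
from math import floor
from typing import Sequence

from .corpus_io import Corpus, Document, Mention
from .evaluation import is_abbreviation
from .normalize import DEFAULT_POLICY
from .partitioner import Split

# Context templates carry disambiguating cues ("Patients with", "diagnosis
# of") so failures on novel surface forms are attributable to the surface,
# not to missing context.
ENTITY_TEMPLATES: tuple[tuple[str, str], ...] = (
    ("Patients with", "were treated promptly ."),
    ("Early diagnosis of", "remains difficult ."),
    ("The registry recorded", "in the cohort ."),
    ("Patients with", "received supportive care ."),
    ("Screening for", "was recommended by the panel ."),
    ("Clinicians managed", "throughout the admission ."),
)

# Numeric tokens here give digit/hyphen shapes an outside-entity prior.
FILLER_SENTENCES: tuple[str, ...] = (
    "The trial protocol was approved by the review board .",
    "Samples were processed within 12 hours of collection .",
    "Follow-up visits occurred every 6-8 weeks during the study .",
    "Participants received 5-10 mg doses for 14 days .",
    "Enrollment continued across 3 regional centers .",
)

DISTRACTOR_WORDS: tuple[str, ...] = (
    "placebo",
    "controls",
    "vitamins",
    "fluids",
    "antibiotics",
)

# Non-entity slots for ABBREV-NUMBER-shaped code tokens (reagent lots,
# identifiers): gives digit/hyphen/caps shapes an outside-entity prior.
CODE_TEMPLATES: tuple[tuple[str, str], ...] = (
    ("Batch", "was stored under refrigeration ."),
    ("Reagent lot", "was logged by the technician ."),
    ("Specimens were labeled", "before shipment ."),
)

O_USAGE_TEMPLATES: tuple[tuple[str, str], ...] = (
    ("The", "subgroup completed the protocol ."),
    ("Reviewers audited the", "records yesterday ."),
    ("The", "cohort returned for assessment ."),
)

UNANNOTATED_TEMPLATE: tuple[str, str] = (
    "The term",
    "appeared frequently in prior reports .",
)

_HEADS = ("disease", "syndrome", "disorder")
_CONSONANTS = "bcdfglmnprstvz"
_VOWELS = "aeiou"

PATTERN_CONVENTIONAL = "conventional"
PATTERN_ABBREV = "abbrev"
PATTERN_ABBREV_NUMBER = "abbrev_number"
PATTERN_PLAIN = "plain"


# ---------------------------------------------------------------------------
# config and ledger
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int = 0
    n_train_docs: int = 60
    n_test_docs: int = 40
    sentences_per_doc: int = 3
    entity_type: str = "Disease"
    # target split proportions of test mentions
    p_mem: float = 0.6
    p_syn: float = 0.25
    p_con: float = 0.15
    p_homonym: float = 0.0
    n_concepts: int = 30
    synonyms_per_concept: int = 3
    # name-pattern mix; the remainder is single lowercase stems ("plain")
    frac_conventional: float = 0.5
    frac_abbrev: float = 0.3
    frac_abbrev_number: float = 0.0
    con_pattern: str | None = None  # force a pattern for Con concepts
    # fraction of test mentions matched by an extra unannotated occurrence
    # of a dictionary surface (label inconsistency)
    inconsistency_rate: float = 0.0
    inconsistency_synonym_fraction: float = 0.5
    # train-sentence composition
    bias_strength: float = 0.0  # fraction of entity-slot contexts given a non-entity word
    mixed_usage_rate: float = 0.0  # fraction of sentences using an entity word outside a mention
    filler_rate: float = 0.1
    code_filler_rate: float = 0.0  # fraction with ABBREV-NUMBER code tokens tagged O

    def validate(self) -> None:
        total = self.p_mem + self.p_syn + self.p_con + self.p_homonym
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"split proportions sum to {total}, expected 1")
        for name in (
            "p_mem",
            "p_syn",
            "p_con",
            "p_homonym",
            "frac_conventional",
            "frac_abbrev",
            "frac_abbrev_number",
            "inconsistency_rate",
            "inconsistency_synonym_fraction",
            "bias_strength",
            "mixed_usage_rate",
            "filler_rate",
            "code_filler_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.frac_conventional + self.frac_abbrev + self.frac_abbrev_number > 1 + 1e-9:
            raise ValueError("pattern-mix fractions exceed 1")
        if (
            self.bias_strength
            + self.mixed_usage_rate
            + self.filler_rate
            + self.code_filler_rate
            > 0.9
        ):
            raise ValueError("non-entity sentence rates leave too few entity sentences")
        if self.n_train_docs < 1 or self.n_test_docs < 1 or self.sentences_per_doc < 1:
            raise ValueError("document counts must be positive")


@dataclass
class LedgerMention:
    doc_id: str
    start: int
    end: int
    surface: str
    concept_id: str
    split: str
    pattern: str
    is_abbreviation: bool


@dataclass
class GeneratorLedger:
    """Generator-side ground truth for every emitted annotation."""

    mentions: list[LedgerMention] = field(default_factory=list)
    split_counts: dict[str, int] = field(default_factory=dict)
    unannotated: list[dict] = field(default_factory=list)
    bias_words: list[str] = field(default_factory=list)
    distractor_words: list[str] = field(default_factory=list)
    synonym_pool_size: int = 0

    def to_json(self) -> str:
        return json.dumps(
            {
                "mentions": [asdict(m) for m in self.mentions],
                "split_counts": self.split_counts,
                "unannotated": self.unannotated,
                "bias_words": self.bias_words,
                "distractor_words": self.distractor_words,
                "synonym_pool_size": self.synonym_pool_size,
            },
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "GeneratorLedger":
        data = json.loads(text)
        return cls(
            mentions=[LedgerMention(**m) for m in data["mentions"]],
            split_counts=data["split_counts"],
            unannotated=data["unannotated"],
            bias_words=data["bias_words"],
            distractor_words=data["distractor_words"],
            synonym_pool_size=data["synonym_pool_size"],
        )


@dataclass
class GeneratedData:
    train: Corpus
    test: Corpus
    synonym_map: dict[str, list[str]]
    ledger: GeneratorLedger


# ---------------------------------------------------------------------------
# surface makers
# ---------------------------------------------------------------------------


def make_pseudo_entity(rng: random.Random) -> str:
    """3-5 capital letters, hyphen, 1-3 digits (e.g. IST-5, CHF-113)."""
    n_letters = rng.choice((3, 4, 5))
    letters = "".join(rng.choice(string.ascii_uppercase) for _ in range(n_letters))
    n_digits = rng.choice((1, 2, 3))
    digits = str(rng.randint(1, 9)) + "".join(
        rng.choice(string.digits) for _ in range(n_digits - 1)
    )
    return f"{letters}-{digits}"


def _make_stem(rng: random.Random) -> str:
    n_syll = rng.choice((2, 3))
    return "".join(
        rng.choice(_CONSONANTS) + rng.choice(_VOWELS) for _ in range(n_syll)
    )


def _make_abbrev(rng: random.Random) -> str:
    n = rng.choice((3, 4, 5))
    return "".join(rng.choice(string.ascii_uppercase) for _ in range(n))


@dataclass
class _Concept:
    cid: str
    pattern: str
    surfaces: list[str]  # surfaces[0] is the primary (train) surface


class _SurfaceFactory:
    """Draws globally unique surfaces; stems and full surfaces are both
    reserved so no surface is a token-aligned piece of another."""

    def __init__(self, rng: random.Random) -> None:
        self.rng = rng
        self.used: set[str] = set()
        for sentence in FILLER_SENTENCES:
            self.used.update(w.casefold() for w in sentence.split())
        for pre, post in ENTITY_TEMPLATES + O_USAGE_TEMPLATES + (UNANNOTATED_TEMPLATE,):
            self.used.update(w.casefold() for w in (pre + " " + post).split())
        self.used.update(DISTRACTOR_WORDS)
        self.used.update(_HEADS)

    def new_surface(self, pattern: str) -> str:
        for _ in range(10_000):
            if pattern == PATTERN_CONVENTIONAL:
                stem = _make_stem(self.rng)
                surface = f"{stem} {self.rng.choice(_HEADS)}"
                keys = {stem, DEFAULT_POLICY.normalize(surface)}
            elif pattern == PATTERN_ABBREV:
                surface = _make_abbrev(self.rng)
                keys = {DEFAULT_POLICY.normalize(surface)}
            elif pattern == PATTERN_ABBREV_NUMBER:
                surface = make_pseudo_entity(self.rng)
                keys = {DEFAULT_POLICY.normalize(surface)}
            elif pattern == PATTERN_PLAIN:
                surface = _make_stem(self.rng)
                keys = {DEFAULT_POLICY.normalize(surface)}
            else:
                raise ValueError(f"unknown pattern {pattern!r}")
            if not keys & self.used:
                self.used.update(keys)
                return surface
        raise RuntimeError("surface space exhausted")


def _sample_pattern(rng: random.Random, cfg: GeneratorConfig) -> str:
    r = rng.random()
    if r < cfg.frac_conventional:
        return PATTERN_CONVENTIONAL
    if r < cfg.frac_conventional + cfg.frac_abbrev:
        return PATTERN_ABBREV
    if r < cfg.frac_conventional + cfg.frac_abbrev + cfg.frac_abbrev_number:
        return PATTERN_ABBREV_NUMBER
    return PATTERN_PLAIN


def _largest_remainder(proportions: Sequence[float], total: int) -> list[int]:
    raw = [p * total for p in proportions]
    counts = [floor(x) for x in raw]
    short = total - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: (-(raw[i] - counts[i]), i))
    for i in order[:short]:
        counts[i] += 1
    return counts


# ---------------------------------------------------------------------------
# sentence planning / document assembly
# ---------------------------------------------------------------------------


@dataclass
class _Planned:
    text: str
    # (rel_start, rel_end, surface, cid, split, pattern) — annotated mention
    mention: tuple[int, int, str, str, str, str] | None = None
    # (rel_start, rel_end, surface, source) — deliberately unannotated
    unannotated: tuple[int, int, str, str] | None = None


def _slot_sentence(rng: random.Random, templates, slot_text: str) -> tuple[str, int]:
    pre, post = rng.choice(templates)
    text = f"{pre} {slot_text} {post}"
    return text, len(pre) + 1


def _assemble(
    prefix: str,
    groups: list[list[_Planned]],
    entity_type: str,
    ledger: GeneratorLedger,
    split_role: str,
) -> Corpus:
    documents = []
    for gi, group in enumerate(groups):
        doc_id = f"{prefix}{gi:04d}"
        mentions: list[Mention] = []
        offset = 0
        texts = []
        for planned in group:
            if planned.mention is not None:
                s, e, surface, cid, split, pattern = planned.mention
                mentions.append(
                    Mention(
                        surface=surface,
                        start=offset + s,
                        end=offset + e,
                        entity_type=entity_type,
                        concept_ids=(cid,),
                    )
                )
                if split:
                    ledger.mentions.append(
                        LedgerMention(
                            doc_id=doc_id,
                            start=offset + s,
                            end=offset + e,
                            surface=surface,
                            concept_id=cid,
                            split=split,
                            pattern=pattern,
                            is_abbreviation=is_abbreviation(surface),
                        )
                    )
            if planned.unannotated is not None:
                s, e, surface, source = planned.unannotated
                ledger.unannotated.append(
                    {
                        "doc_id": doc_id,
                        "start": offset + s,
                        "end": offset + e,
                        "surface": surface,
                        "source": source,
                    }
                )
            texts.append(planned.text)
            offset += len(planned.text) + 1  # joining space
        title = texts[0]
        abstract = " ".join(texts[1:])
        doc = Document(doc_id=doc_id, title=title, abstract=abstract, mentions=mentions)
        doc.validate()
        documents.append(doc)
    return Corpus(documents=documents, entity_types=(entity_type,), split_role=split_role)


def _group(sentences: list[_Planned], per_doc: int) -> list[list[_Planned]]:
    return [sentences[i : i + per_doc] for i in range(0, len(sentences), per_doc)]


# ---------------------------------------------------------------------------
# main generator
# ---------------------------------------------------------------------------


def generate_corpus(config: GeneratorConfig) -> GeneratedData:
    """Emit (train, test, synonym map, ledger) realizing the configured
    split proportions exactly."""
    config.validate()
    rng = random.Random(config.seed)
    factory = _SurfaceFactory(rng)
    ledger = GeneratorLedger()

    concepts = []
    for i in range(config.n_concepts):
        pattern = _sample_pattern(rng, config)
        surfaces = [
            factory.new_surface(pattern)
            for _ in range(1 + config.synonyms_per_concept)
        ]
        concepts.append(_Concept(cid=f"SYN:{i:06d}", pattern=pattern, surfaces=surfaces))

    # ---- train plan ------------------------------------------------------
    n_train_sent = config.n_train_docs * config.sentences_per_doc
    n_distract = round(config.bias_strength * n_train_sent)
    n_o_usage = round(config.mixed_usage_rate * n_train_sent)
    n_filler = round(config.filler_rate * n_train_sent)
    n_code = round(config.code_filler_rate * n_train_sent)
    n_entity = n_train_sent - n_distract - n_o_usage - n_filler - n_code
    if n_entity < 1:
        raise ValueError("no entity sentences left in the training plan")

    concept_cycle = []
    while len(concept_cycle) < n_entity:
        block = concepts[:]
        rng.shuffle(block)
        concept_cycle.extend(block)
    entity_concepts = concept_cycle[:n_entity]
    used_concepts = {c.cid: c for c in entity_concepts}
    train_pairs = sorted({(c.surfaces[0], c.cid) for c in entity_concepts})

    bias_words = sorted({c.surfaces[0].split()[0] for c in entity_concepts})
    kinds = (
        ["entity"] * n_entity
        + ["distract"] * n_distract
        + ["o_usage"] * n_o_usage
        + ["filler"] * n_filler
        + ["code"] * n_code
    )
    rng.shuffle(kinds)

    train_sentences: list[_Planned] = []
    entity_iter = iter(entity_concepts)
    o_usage_words_used: set[str] = set()
    for kind in kinds:
        if kind == "entity":
            concept = next(entity_iter)
            surface = concept.surfaces[0]
            text, start = _slot_sentence(rng, ENTITY_TEMPLATES, surface)
            train_sentences.append(
                _Planned(
                    text=text,
                    mention=(start, start + len(surface), surface, concept.cid, "", concept.pattern),
                )
            )
        elif kind == "distract":
            word = rng.choice(DISTRACTOR_WORDS)
            text, _ = _slot_sentence(rng, ENTITY_TEMPLATES, word)
            train_sentences.append(_Planned(text=text))
        elif kind == "o_usage":
            concept = rng.choice(entity_concepts)
            word = concept.surfaces[0].split()[0]
            o_usage_words_used.add(word)
            text, _ = _slot_sentence(rng, O_USAGE_TEMPLATES, word)
            train_sentences.append(_Planned(text=text))
        elif kind == "code":
            code = factory.new_surface(PATTERN_ABBREV_NUMBER)
            text, _ = _slot_sentence(rng, CODE_TEMPLATES, code)
            train_sentences.append(_Planned(text=text))
        else:
            train_sentences.append(_Planned(text=rng.choice(FILLER_SENTENCES)))

    # ---- test plan -------------------------------------------------------
    n_test_mentions = config.n_test_docs * config.sentences_per_doc
    mem_n, syn_n, con_n, hom_n = _largest_remainder(
        (config.p_mem, config.p_syn, config.p_con, config.p_homonym), n_test_mentions
    )
    if mem_n and not train_pairs:
        raise ValueError("Mem mentions requested but no training pairs exist")

    synonym_pool = [
        (c, s) for c in used_concepts.values() for s in c.surfaces[1:]
    ]
    rng.shuffle(synonym_pool)
    if syn_n > len(synonym_pool):
        raise ValueError(
            f"Syn split needs {syn_n} unseen synonyms, only {len(synonym_pool)} available"
        )

    specs: list[tuple[str, str, str, str]] = []  # surface, cid, split, pattern
    for _ in range(mem_n):
        surface, cid = rng.choice(train_pairs)
        specs.append((surface, cid, Split.MEM.value, used_concepts[cid].pattern))
    syn_taken = synonym_pool[:syn_n]
    remaining_synonyms = synonym_pool[syn_n:]
    for concept, surface in syn_taken:
        specs.append((surface, concept.cid, Split.SYN.value, concept.pattern))
    next_cid = config.n_concepts
    for _ in range(con_n):
        pattern = config.con_pattern or _sample_pattern(rng, config)
        surface = factory.new_surface(pattern)
        specs.append((surface, f"SYN:{next_cid:06d}", Split.CON.value, pattern))
        next_cid += 1
    for _ in range(hom_n):
        surface, _ = rng.choice(train_pairs)
        cid = used_concepts[[c for s, c in train_pairs if s == surface][0]]
        specs.append((surface, f"SYN:{next_cid:06d}", Split.HOMONYM.value, cid.pattern))
        next_cid += 1
    rng.shuffle(specs)

    test_sentences: list[_Planned] = []
    for surface, cid, split, pattern in specs:
        text, start = _slot_sentence(rng, ENTITY_TEMPLATES, surface)
        test_sentences.append(
            _Planned(
                text=text,
                mention=(start, start + len(surface), surface, cid, split, pattern),
            )
        )

    # ---- label inconsistency: dictionary surfaces left unannotated -------
    n_incons = round(config.inconsistency_rate * n_test_mentions)
    if n_incons:
        n_syn_inj = min(
            round(config.inconsistency_synonym_fraction * n_incons),
            len(remaining_synonyms),
        )
        n_train_inj = n_incons - n_syn_inj
        injections: list[tuple[str, str]] = []
        for _, surface in remaining_synonyms[:n_syn_inj]:
            injections.append((surface, "synonym_surface"))
        for _ in range(n_train_inj):
            surface, _ = rng.choice(train_pairs)
            injections.append((surface, "train_surface"))
        rng.shuffle(injections)
        pre, post = UNANNOTATED_TEMPLATE
        for surface, source in injections:
            text = f"{pre} {surface} {post}"
            start = len(pre) + 1
            test_sentences.append(
                _Planned(
                    text=text,
                    unannotated=(start, start + len(surface), surface, source),
                )
            )

    train = _assemble(
        "T", _group(train_sentences, config.sentences_per_doc), config.entity_type, ledger, "train"
    )
    test_groups = _group(test_sentences, config.sentences_per_doc)
    test = _assemble("D", test_groups, config.entity_type, ledger, "test")

    synonym_map = {c.cid: list(c.surfaces) for c in concepts}
    ledger.split_counts = {
        Split.MEM.value: mem_n,
        Split.SYN.value: syn_n,
        Split.CON.value: con_n,
        Split.HOMONYM.value: hom_n,
    }
    ledger.bias_words = sorted(o_usage_words_used) if n_o_usage else bias_words
    ledger.distractor_words = list(DISTRACTOR_WORDS) if n_distract else []
    ledger.synonym_pool_size = len(synonym_pool)
    return GeneratedData(train=train, test=test, synonym_map=synonym_map, ledger=ledger)


# ---------------------------------------------------------------------------
# perturbations
# ---------------------------------------------------------------------------


def _rebuild_doc(doc: Document, replacements: dict[tuple[int, int], str]) -> Document:
    """Apply surface replacements at the given mention spans, shifting all
    later offsets; every untouched character is preserved."""
    text = doc.text
    title_len = len(doc.title)
    ordered = sorted(doc.mentions, key=lambda m: m.start)
    pieces = []
    new_mentions = []
    cursor = 0
    delta = 0
    new_title_len = title_len
    for m in ordered:
        pieces.append(text[cursor : m.start])
        new_surface = replacements.get((m.start, m.end), m.surface)
        pieces.append(new_surface)
        new_mentions.append(
            Mention(
                surface=new_surface,
                start=m.start + delta,
                end=m.start + delta + len(new_surface),
                entity_type=m.entity_type,
                concept_ids=m.concept_ids,
            )
        )
        if m.end <= title_len:
            new_title_len += len(new_surface) - (m.end - m.start)
        delta += len(new_surface) - (m.end - m.start)
        cursor = m.end
    pieces.append(text[cursor:])
    new_text = "".join(pieces)
    if doc.abstract:
        new_doc = Document(
            doc_id=doc.doc_id,
            title=new_text[:new_title_len],
            abstract=new_text[new_title_len + 1 :],
            mentions=new_mentions,
        )
    else:
        new_doc = Document(doc_id=doc.doc_id, title=new_text, mentions=new_mentions)
    new_doc.validate()
    return new_doc


def replace_all_occurrences(corpus: Corpus, target: str, replacement: str) -> Corpus:
    """Replace the surface of every mention equal to ``target``."""
    documents = []
    for doc in corpus.documents:
        repl = {
            (m.start, m.end): replacement for m in doc.mentions if m.surface == target
        }
        documents.append(_rebuild_doc(doc, repl) if repl else _rebuild_doc(doc, {}))
    return Corpus(
        documents=documents,
        entity_types=corpus.entity_types,
        split_role=corpus.split_role,
    )


def replace_random_abbreviations(
    corpus: Corpus, k: int, seed: int = 0
) -> tuple[Corpus, list[dict]]:
    """Replace k randomly chosen abbreviation mentions with fresh pseudo
    entities (distinct ABBREV-NUMBER strings)."""
    rng = random.Random(seed)
    candidates = [
        (di, mi)
        for di, doc in enumerate(corpus.documents)
        for mi, m in enumerate(doc.mentions)
        if is_abbreviation(m.surface)
    ]
    if len(candidates) < k:
        raise ValueError(
            f"requested {k} abbreviation replacements, only {len(candidates)} available"
        )
    chosen = rng.sample(candidates, k)
    existing = {m.surface for _, m in corpus.all_mentions()}
    fresh: list[str] = []
    while len(fresh) < k:
        s = make_pseudo_entity(rng)
        if s not in existing and s not in fresh:
            fresh.append(s)
    per_doc: dict[int, dict[tuple[int, int], str]] = {}
    records = []
    for (di, mi), new_surface in zip(chosen, fresh):
        m = corpus.documents[di].mentions[mi]
        per_doc.setdefault(di, {})[(m.start, m.end)] = new_surface
        records.append(
            {
                "doc_id": corpus.documents[di].doc_id,
                "old_surface": m.surface,
                "new_surface": new_surface,
            }
        )
    documents = [
        _rebuild_doc(doc, per_doc.get(di, {})) for di, doc in enumerate(corpus.documents)
    ]
    return (
        Corpus(
            documents=documents,
            entity_types=corpus.entity_types,
            split_role=corpus.split_role,
        ),
        records,
    )


def replace_mentions(
    corpus: Corpus,
    policy: str,
    *,
    target: str | None = None,
    replacement: str | None = None,
    k: int | None = None,
    seed: int = 0,
) -> Corpus:
    """Dispatcher over the two replacement policies."""
    if policy == "all-occurrences":
        if target is None or replacement is None:
            raise ValueError("all-occurrences policy needs target and replacement")
        return replace_all_occurrences(corpus, target, replacement)
    if policy == "k-random-abbreviations":
        if k is None:
            raise ValueError("k-random-abbreviations policy needs k")
        return replace_random_abbreviations(corpus, k, seed)[0]
    raise ValueError(f"unknown replacement policy {policy!r}")


def inject_label_bias(
    config: GeneratorConfig, corpus: Corpus, words: Sequence[str] | None = None
) -> tuple[Corpus, list[dict]]:
    """Append sentences using entity words outside any mention (tag O).

    Selected words default to a ``bias_strength`` fraction of the distinct
    first tokens of the corpus's mention surfaces; pass ``words`` to choose
    explicitly. Returns the perturbed corpus and a record per appended
    occurrence (doc, offsets, word, shifted tag).
    """
    rng = random.Random(config.seed)
    if words is None:
        stems = sorted({m.surface.split()[0] for _, m in corpus.all_mentions()})
        n = round(config.bias_strength * len(stems))
        words = rng.sample(stems, n) if n else []
    if not words:
        return corpus, []
    documents = list(corpus.documents)
    records = []
    for i, word in enumerate(words):
        pre, post = O_USAGE_TEMPLATES[i % len(O_USAGE_TEMPLATES)]
        text = f"{pre} {word} {post}"
        start = len(pre) + 1
        doc_id = f"{corpus.split_role[:1].upper()}B{i:04d}"
        documents.append(Document(doc_id=doc_id, title=text))
        records.append(
            {
                "doc_id": doc_id,
                "start": start,
                "end": start + len(word),
                "word": word,
                "tag": "O",
            }
        )
    return (
        Corpus(
            documents=documents,
            entity_types=corpus.entity_types,
            split_role=corpus.split_role,
        ),
        records,
    )


def make_target_corpus(
    target: str,
    n_docs: int,
    seed: int = 0,
    entity_type: str = "Disease",
    concept_id: str = "SYN:999999",
) -> Corpus:
    """Single-mention-per-document corpus for relaxed-recall probes of one
    novel entity (the held-out COVID-19-style set)."""
    rng = random.Random(seed)
    documents = []
    for i in range(n_docs):
        pre, post = rng.choice(ENTITY_TEMPLATES)
        text = f"{pre} {target} {post}"
        start = len(pre) + 1
        documents.append(
            Document(
                doc_id=f"C{i:04d}",
                title=text,
                mentions=[
                    Mention(
                        surface=target,
                        start=start,
                        end=start + len(target),
                        entity_type=entity_type,
                        concept_ids=(concept_id,),
                    )
                ],
            )
        )
    corpus = Corpus(documents=documents, entity_types=(entity_type,), split_role="test")
    corpus.validate()
    return corpus
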