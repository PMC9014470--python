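"""Word-statistics bias product: a fixed per-word class-frequency model
combined with a trainable tagger during training only.

The biased model's row for a word is its empirical tag distribution in the
training set. During training the tagger's per-token distribution p is
replaced by softmax(log p + log b) inside the negative log-likelihood, so
tokens whose tag the statistics already predict contribute little gradient;
at inference only p is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence, TextIO

import numpy as np

from .corpus_io import Corpus, LabelScheme, Mention, Sentence, bio_to_mentions, mentions_to_bio

WordNorm = Callable[[str], str]


def _casefold(word: str) -> str:
    return word.casefold()


# ---------------------------------------------------------------------------
# bias table
# ---------------------------------------------------------------------------


@dataclass
class BiasTable:
    """Per-word probability vectors over the K tag classes.

    ``rows`` are epsilon-floored and renormalized (safe under log);
    ``raw_rows`` keep the exact count ratios. Unseen words get the uniform
    ``default_row`` — a constant shift that carries no signal.
    """

    k: int
    rows: dict[str, np.ndarray] = field(default_factory=dict)
    raw_rows: dict[str, np.ndarray] = field(default_factory=dict)
    epsilon: float = 1e-6
    word_norm: WordNorm = _casefold

    @property
    def default_row(self) -> np.ndarray:
        return np.full(self.k, 1.0 / self.k)

    def row(self, word: str) -> np.ndarray:
        return self.rows.get(self.word_norm(word), self.default_row)

    def raw_row(self, word: str) -> np.ndarray:
        return self.raw_rows.get(self.word_norm(word), self.default_row)

    def to_tsv(self, stream: TextIO) -> None:
        for word in sorted(self.rows):
            probs = "\t".join(f"{p:.10g}" for p in self.rows[word])
            stream.write(f"{word}\t{probs}\n")

    @classmethod
    def from_tsv(cls, stream: TextIO | Iterable[str], k: int, epsilon: float = 1e-6) -> "BiasTable":
        table = cls(k=k, epsilon=epsilon)
        for lineno, line in enumerate(stream, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != k + 1:
                raise ValueError(f"line {lineno}: expected word + {k} probabilities")
            row = np.array([float(x) for x in parts[1:]])
            table.rows[parts[0]] = row
            table.raw_rows[parts[0]] = row
        return table


def _floor_and_normalize(row: np.ndarray, epsilon: float) -> np.ndarray:
    floored = np.maximum(row, epsilon)
    return floored / floored.sum()


def compute_bias_table(
    tagged_sentences: Iterable[Sequence[tuple[str, int]]],
    k: int,
    epsilon: float = 1e-6,
    word_norm: WordNorm = _casefold,
) -> BiasTable:
    """Empirical per-word tag distributions from (word, tag-index) pairs."""
    counts: dict[str, np.ndarray] = {}
    n_tokens = 0
    for sentence in tagged_sentences:
        for word, tag_idx in sentence:
            if not 0 <= tag_idx < k:
                raise ValueError(f"tag index {tag_idx} out of range for K={k}")
            key = word_norm(word)
            if key not in counts:
                counts[key] = np.zeros(k)
            counts[key][tag_idx] += 1
            n_tokens += 1
    if not n_tokens:
        raise ValueError("no tokens: cannot build a bias table from an empty corpus")
    table = BiasTable(k=k, epsilon=epsilon, word_norm=word_norm)
    for word, c in counts.items():
        raw = c / c.sum()
        table.raw_rows[word] = raw
        table.rows[word] = _floor_and_normalize(raw, epsilon)
    return table


def bias_table_from_corpus(
    corpus: Corpus,
    scheme: LabelScheme,
    epsilon: float = 1e-6,
    word_norm: WordNorm = _casefold,
) -> BiasTable:
    def pairs():
        for sentence in corpus.sentences():
            tags = mentions_to_bio(sentence, scheme)
            yield [
                (tok, scheme.index(tag)) for tok, tag in zip(sentence.tokens, tags)
            ]

    return compute_bias_table(pairs(), k=scheme.k, epsilon=epsilon, word_norm=word_norm)


# ---------------------------------------------------------------------------
# bias product
# ---------------------------------------------------------------------------


def combine(p: np.ndarray, b: np.ndarray) -> np.ndarray:
    """softmax(log p + log b) == elementwise product, renormalized."""
    p = np.asarray(p, dtype=float)
    b = np.asarray(b, dtype=float)
    if p.shape != b.shape:
        raise ValueError(f"shape mismatch {p.shape} vs {b.shape}")
    prod = p * b
    z = prod.sum()
    if z <= 0:
        raise ValueError("zero probability mass after combination")
    return prod / z


def debiased_loss(p: np.ndarray, b: np.ndarray, gold_class: int) -> float:
    """Negative log-likelihood of the gold class under the combined
    distribution; gradients (where applicable) flow only through p."""
    return float(-np.log(combine(p, b)[gold_class]))


def nll_loss(p: np.ndarray, gold_class: int) -> float:
    return float(-np.log(np.asarray(p, dtype=float)[gold_class]))


# ---------------------------------------------------------------------------
# reference tagger
# ---------------------------------------------------------------------------


def _shape_features(word: str) -> list[str]:
    feats = []
    if any(c.isdigit() for c in word):
        feats.append("sh:digit")
    if "-" in word:
        feats.append("sh:hyphen")
    if any(c.isalpha() for c in word) and not any(c.islower() for c in word):
        feats.append("sh:nolower")
    if word[:1].isupper():
        feats.append("sh:initcap")
    return feats


class ReferenceTagger:
    """Linear-softmax token classifier: a desk-scale stand-in for large
    pretrained taggers, good enough to exhibit the bias phenomena.

    Features: current/previous/next word identity, shape flags, suffix
    n-grams. Zero-initialized weights and a seeded sentence shuffle make
    training fully deterministic; with ``bias_table`` set, SGD follows the
    gradient of the bias-product NLL (the table itself is never updated).
    """

    def __init__(
        self,
        scheme: LabelScheme,
        seed: int = 0,
        lr: float = 0.5,
        epochs: int = 12,
        suffix_lens: tuple[int, ...] = (2, 3),
    ) -> None:
        self.scheme = scheme
        self.seed = seed
        self.lr = lr
        self.epochs = epochs
        self.suffix_lens = suffix_lens
        self.feature_index: dict[str, int] = {}
        self.weights = np.zeros((scheme.k, 0))
        self.trained = False

    # -- features ----------------------------------------------------------

    def _token_features(self, words: Sequence[str], i: int) -> list[str]:
        w = words[i]
        wcf = w.casefold()
        feats = ["bias", f"w:{wcf}"]
        feats.append(f"p:{words[i - 1].casefold()}" if i > 0 else "p:<s>")
        feats.append(f"n:{words[i + 1].casefold()}" if i < len(words) - 1 else "n:</s>")
        feats.extend(_shape_features(w))
        for n in self.suffix_lens:
            if len(wcf) > n:
                feats.append(f"suf{n}:{wcf[-n:]}")
        return feats

    def _indices(self, words: Sequence[str], i: int, grow: bool) -> list[int]:
        idx = []
        for f in self._token_features(words, i):
            j = self.feature_index.get(f)
            if j is None:
                if not grow:
                    continue
                j = len(self.feature_index)
                self.feature_index[f] = j
            idx.append(j)
        return idx

    # -- training ----------------------------------------------------------

    def fit(
        self,
        tagged_sentences: Sequence[Sequence[tuple[str, int]]],
        bias_table: BiasTable | None = None,
    ) -> "ReferenceTagger":
        """SGD on per-token (possibly bias-combined) softmax NLL."""
        sentences = [list(s) for s in tagged_sentences]
        # first pass: freeze the feature space
        prepared = []
        for sent in sentences:
            words = [w for w, _ in sent]
            feats = [self._indices(words, i, grow=True) for i in range(len(words))]
            golds = [g for _, g in sent]
            if bias_table is not None:
                b_rows = [bias_table.row(w) for w in words]
            else:
                b_rows = None
            prepared.append((feats, golds, b_rows))
        n_feat = len(self.feature_index)
        self.weights = np.zeros((self.scheme.k, n_feat))
        rng = np.random.default_rng(self.seed)
        for _ in range(self.epochs):
            order = rng.permutation(len(prepared))
            for si in order:
                feats, golds, b_rows = prepared[si]
                for ti, idx in enumerate(feats):
                    z = self.weights[:, idx].sum(axis=1)
                    z -= z.max()
                    p = np.exp(z)
                    p /= p.sum()
                    if b_rows is not None:
                        q = combine(p, b_rows[ti])
                    else:
                        q = p
                    grad = q.copy()
                    grad[golds[ti]] -= 1.0
                    self.weights[:, idx] -= self.lr * grad[:, None]
        self.trained = True
        return self

    # -- inference (bias table never consulted) ----------------------------

    def token_probs(self, words: Sequence[str]) -> np.ndarray:
        probs = np.zeros((len(words), self.scheme.k))
        for i in range(len(words)):
            idx = self._indices(words, i, grow=False)
            z = self.weights[:, idx].sum(axis=1) if idx else np.zeros(self.scheme.k)
            z -= z.max()
            p = np.exp(z)
            probs[i] = p / p.sum()
        return probs

    def predict_tags(self, words: Sequence[str]) -> list[str]:
        probs = self.token_probs(words)
        return [self.scheme.classes[int(i)] for i in probs.argmax(axis=1)]

    def predict_sentence(self, sentence: Sentence) -> list[Mention]:
        tags = self.predict_tags(sentence.tokens)
        return bio_to_mentions(sentence, tags, self.scheme)

    def predict_corpus(self, corpus: Corpus) -> list[tuple[str, Mention]]:
        out: list[tuple[str, Mention]] = []
        for sentence in corpus.sentences():
            out.extend((sentence.doc_id, m) for m in self.predict_sentence(sentence))
        return out


def tagged_sentences_from_corpus(
    corpus: Corpus, scheme: LabelScheme
) -> list[list[tuple[str, int]]]:
    out = []
    for sentence in corpus.sentences():
        tags = mentions_to_bio(sentence, scheme)
        out.append([(tok, scheme.index(tag)) for tok, tag in zip(sentence.tokens, tags)])
    return out
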