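import io

import pytest

from splitner.corpus_io import (
    CorpusError,
    Corpus,
    Document,
    LabelScheme,
    Mention,
    bio_to_mentions,
    mentions_to_bio,
    read_conll,
    read_pubtator,
    tokenize,
    write_conll,
    write_conll_sentences,
    write_pubtator,
)
from splitner.synthetic_data import GeneratorConfig, generate_corpus

from util import doc_with


class TestMention:
    def test_empty_span_rejected(self):
        with pytest.raises(CorpusError):
            Mention(surface="", start=5, end=5, entity_type="Disease")

    def test_surface_length_must_match_span(self):
        with pytest.raises(CorpusError):
            Mention(surface="abc", start=0, end=2, entity_type="Disease")

    def test_concept_ids_must_be_nonempty(self):
        with pytest.raises(CorpusError):
            Mention(surface="ab", start=0, end=2, entity_type="Disease", concept_ids=())


class TestTokenize:
    def test_plain_words(self):
        text = "acute encephalopathy after dosing"
        spans = tokenize(text)
        assert [text[s:e] for s, e in spans] == [
            "acute",
            "encephalopathy",
            "after",
            "dosing",
        ]

    def test_internal_hyphen_kept(self):
        text = "treatment of COVID-19 patients"
        spans = tokenize(text)
        assert "COVID-19" in [text[s:e] for s, e in spans]

    def test_edge_punctuation_split_off(self):
        text = "pneumonia (COVID-19) is"
        spans = tokenize(text)
        assert [text[s:e] for s, e in spans] == ["pneumonia", "(", "COVID-19", ")", "is"]

    def test_offset_shift(self):
        spans = tokenize("ab cd", offset=10)
        assert spans == [(10, 12), (13, 15)]

    def test_spans_partition_non_whitespace(self):
        text = "a (b-c) , d10."
        spans = tokenize(text)
        rebuilt = "".join(text[s:e] for s, e in spans)
        assert rebuilt == text.replace(" ", "")
        assert spans == sorted(spans)


class TestLabelScheme:
    def test_single_type_plain_bio(self):
        scheme = LabelScheme()
        assert scheme.classes == ("B", "I", "O")
        assert scheme.k == 3

    def test_multi_type_tags(self):
        scheme = LabelScheme(entity_types=("Disease", "Chemical"))
        assert scheme.classes == ("B-Disease", "I-Disease", "B-Chemical", "I-Chemical", "O")
        assert scheme.parse("I-Chemical") == ("I", "Chemical")

    def test_unknown_tag_rejected(self):
        with pytest.raises(CorpusError):
            LabelScheme().index("B-Disease")


class TestBioConversion:
    def _sentence(self, text, anns=()):
        return doc_with("d1", text, anns=anns).sentences()[0]

    def test_mention_covering_two_tokens(self, scheme):
        sent = self._sentence(
            "acute encephalopathy after dosing .",
            anns=[("acute encephalopathy", "Disease", ["MESH:D1"])],
        )
        assert mentions_to_bio(sent, scheme) == ["B", "I", "O", "O", "O"]

    def test_no_mentions_all_outside(self, scheme):
        sent = self._sentence("no entities here .")
        assert mentions_to_bio(sent, scheme) == ["O"] * 4

    def test_overlapping_mentions_error(self, scheme):
        doc = Document(doc_id="d", title="aa bb cc")
        doc.mentions = [
            Mention(surface="aa bb", start=0, end=5, entity_type="Disease"),
            Mention(surface="bb cc", start=3, end=8, entity_type="Disease"),
        ]
        with pytest.raises(CorpusError):
            mentions_to_bio(doc.sentences()[0], scheme)

    def test_decode_b_i_then_isolated_b(self, scheme):
        sent = self._sentence("alpha beta gamma delta")
        mentions = bio_to_mentions(sent, ["B", "I", "O", "B"], scheme)
        assert [(m.surface, m.start, m.end) for m in mentions] == [
            ("alpha beta", 0, 10),
            ("delta", 17, 22),
        ]

    def test_orphan_i_starts_mention(self, scheme):
        sent = self._sentence("alpha beta gamma")
        mentions = bio_to_mentions(sent, ["O", "I", "I"], scheme)
        assert [(m.surface,) for m in mentions] == [("beta gamma",)]

    def test_all_outside_no_mentions(self, scheme):
        sent = self._sentence("alpha beta gamma")
        assert bio_to_mentions(sent, ["O", "O", "O"], scheme) == []

    def test_round_trip_on_random_synthetic_sentences(self, scheme):
        data = generate_corpus(GeneratorConfig(seed=7, n_train_docs=70))
        count = 0
        for sentence in data.train.sentences():
            tags = mentions_to_bio(sentence, scheme)
            decoded = bio_to_mentions(sentence, tags, scheme)
            assert [(m.start, m.end) for m in decoded] == [
                (m.start, m.end) for m in sentence.mentions
            ]
            count += 1
        assert count >= 200

    def test_tag_round_trip_without_orphans(self, scheme):
        sent = self._sentence("alpha beta gamma delta eps")
        tags = ["B", "I", "O", "B", "O"]
        mentions = bio_to_mentions(sent, tags, scheme)
        rebuilt = sent.__class__(
            doc_id=sent.doc_id,
            text=sent.text,
            start=sent.start,
            end=sent.end,
            token_spans=sent.token_spans,
            mentions=tuple(mentions),
        )
        assert mentions_to_bio(rebuilt, scheme) == tags


class TestPubTator:
    def test_offset_mismatch_rejected(self):
        blob = "10021369|t|Colorectal cancer studies\n10021369|a|More text here\n10021369\t13\t33\tcolorectal cancer\tDisease\tMESH:D015179\n\n"
        with pytest.raises(CorpusError, match="10021369"):
            read_pubtator(io.StringIO(blob))

    def test_composite_concept_split(self):
        title = "colorectal cancer study"
        blob = (
            "1|t|" + title + "\n1|a|\n"
            "1\t0\t17\tcolorectal cancer\tDisease\tD009270|D056486\n\n"
        )
        corpus = read_pubtator(io.StringIO(blob))
        (mention,) = corpus.documents[0].mentions
        assert mention.concept_ids == ("D009270", "D056486")

    def test_unmapped_concept_becomes_unknown(self):
        blob = "1|t|colorectal cancer study\n1|a|\n1\t0\t17\tcolorectal cancer\tDisease\t-1\n\n"
        corpus = read_pubtator(io.StringIO(blob))
        assert corpus.documents[0].mentions[0].concept_ids == ("UNKNOWN",)

    def test_malformed_line_reports_lineno(self):
        blob = "1|t|title text\n1|a|abstract text\n1\t0\t5\n\n"
        with pytest.raises(CorpusError, match="line 3"):
            read_pubtator(io.StringIO(blob))

    def test_round_trip_on_synthetic_fixture(self):
        data = generate_corpus(GeneratorConfig(seed=3, n_train_docs=3, n_test_docs=3))
        buf = io.StringIO()
        write_pubtator(data.train, buf)
        text = buf.getvalue()
        reread = read_pubtator(io.StringIO(text))
        buf2 = io.StringIO()
        write_pubtator(reread, buf2)
        assert buf2.getvalue() == text


class TestConll:
    def test_round_trip(self, small_data, scheme):
        buf = io.StringIO()
        write_conll(small_data.train, scheme, buf)
        text = buf.getvalue()
        sentences = read_conll(io.StringIO(text))
        buf2 = io.StringIO()
        write_conll_sentences(sentences, buf2)
        assert buf2.getvalue() == text

    def test_tags_align_with_mentions(self, scheme):
        doc = doc_with(
            "d1",
            "Patients with acute encephalopathy recovered .",
            anns=[("acute encephalopathy", "Disease", ["MESH:D1"])],
        )
        corpus = Corpus(documents=[doc])
        buf = io.StringIO()
        write_conll(corpus, scheme, buf)
        rows = [line.split("\t") for line in buf.getvalue().splitlines() if line]
        assert rows == [
            ["Patients", "O"],
            ["with", "O"],
            ["acute", "B"],
            ["encephalopathy", "I"],
            ["recovered", "O"],
            [".", "O"],
        ]


class TestSentenceSegmentation:
    def test_period_space_split(self):
        doc = Document(doc_id="d", title="First part here .", abstract="Second part too .")
        sents = doc.sentences()
        assert [s.text for s in sents] == ["First part here .", "Second part too ."]

    def test_mentions_follow_their_sentence(self):
        doc = doc_with(
            "d",
            "Patients with anemia improved .",
            abstract="Screening for anemia was advised .",
            anns=[
                ("anemia", "Disease", ["MESH:D2"]),
                ("anemia", "Disease", ["MESH:D2"]),
            ],
        )
        sents = doc.sentences()
        assert [len(s.mentions) for s in sents] == [1, 1]
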