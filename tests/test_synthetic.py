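import io
import random
import re

import pytest
from scipy import stats

from splitner.corpus_io import write_pubtator
from splitner.debias import bias_table_from_corpus, tagged_sentences_from_corpus
from splitner.partitioner import Split, build_inventory, partition_corpus
from splitner.synthetic_data import (
    GeneratorConfig,
    GeneratorLedger,
    generate_corpus,
    inject_label_bias,
    make_pseudo_entity,
    make_target_corpus,
    replace_all_occurrences,
    replace_mentions,
    replace_random_abbreviations,
)

PSEUDO_RE = re.compile(r"^[A-Z]{3,5}-[0-9]{1,3}$")


class TestConfig:
    def test_proportions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            GeneratorConfig(p_mem=0.5, p_syn=0.5, p_con=0.5).validate()

    def test_rates_bounded(self):
        with pytest.raises(ValueError):
            GeneratorConfig(inconsistency_rate=1.5).validate()

    def test_infeasible_syn_split_errors(self):
        cfg = GeneratorConfig(
            p_mem=0.0, p_syn=1.0, p_con=0.0, n_concepts=2, synonyms_per_concept=1,
            n_test_docs=40,
        )
        with pytest.raises(ValueError, match="Syn"):
            generate_corpus(cfg)


class TestGenerateCorpus:
    def test_all_mem_config(self):
        data = generate_corpus(GeneratorConfig(seed=61, p_mem=1.0, p_syn=0.0, p_con=0.0))
        part = partition_corpus(data.test, build_inventory(data.train))
        assert part.counts[Split.MEM] == len(data.test.all_mentions())

    def test_partition_counts_equal_ledger(self):
        cfg = GeneratorConfig(seed=62, p_mem=0.6, p_syn=0.25, p_con=0.15)
        data = generate_corpus(cfg)
        part = partition_corpus(data.test, build_inventory(data.train))
        assert part.summary() == data.ledger.split_counts

    def test_same_seed_byte_identical(self):
        cfg = GeneratorConfig(seed=63, inconsistency_rate=0.1, bias_strength=0.2)
        a, b = generate_corpus(cfg), generate_corpus(cfg)
        for ca, cb in ((a.train, b.train), (a.test, b.test)):
            fa, fb = io.StringIO(), io.StringIO()
            write_pubtator(ca, fa)
            write_pubtator(cb, fb)
            assert fa.getvalue() == fb.getvalue()
        assert a.ledger.to_json() == b.ledger.to_json()

    def test_slice_invariant_everywhere(self, default_data):
        default_data.train.validate()
        default_data.test.validate()

    def test_ledger_covers_every_test_mention(self, default_data):
        ledger_keys = {
            (m.doc_id, m.start, m.end)
            for m in default_data.ledger.mentions
            if m.doc_id.startswith("D")
        }
        test_keys = {
            (d, m.start, m.end) for d, m in default_data.test.all_mentions()
        }
        assert ledger_keys == test_keys

    def test_unannotated_injections_recorded_and_unannotated(self):
        data = generate_corpus(GeneratorConfig(seed=64, inconsistency_rate=0.2))
        assert data.ledger.unannotated
        mention_keys = {(d, m.start, m.end) for d, m in data.test.all_mentions()}
        for rec in data.ledger.unannotated:
            doc = data.test.doc(rec["doc_id"])
            assert doc.text[rec["start"] : rec["end"]] == rec["surface"]
            assert (rec["doc_id"], rec["start"], rec["end"]) not in mention_keys

    def test_ledger_json_round_trip(self, default_data):
        text = default_data.ledger.to_json()
        assert GeneratorLedger.from_json(text).to_json() == text


class TestPseudoEntity:
    def test_listed_examples_are_producible(self):
        assert PSEUDO_RE.match("IST-5")
        assert PSEUDO_RE.match("CHF-113")

    def test_every_output_matches_regex(self):
        rng = random.Random(0)
        for _ in range(10_000):
            assert PSEUDO_RE.match(make_pseudo_entity(rng))

    def test_letter_length_uniform_chi_square(self):
        rng = random.Random(1)
        counts = {3: 0, 4: 0, 5: 0}
        n = 10_000
        for _ in range(n):
            counts[len(make_pseudo_entity(rng).split("-")[0])] += 1
        result = stats.chisquare(list(counts.values()))
        assert result.pvalue > 1e-3


class TestReplaceMentions:
    def test_replace_all_occurrences_shifts_offsets(self):
        corpus = make_target_corpus("COVID-19", 5, seed=0)
        replaced = replace_all_occurrences(corpus, "COVID-19", "COVID")
        for old_doc, new_doc in zip(corpus.documents, replaced.documents):
            (old_m,), (new_m,) = old_doc.mentions, new_doc.mentions
            assert new_m.surface == "COVID"
            assert new_m.start == old_m.start
            assert new_m.end == old_m.end - 3
            assert len(new_doc.text) == len(old_doc.text) - 3
            # context preserved around the edit
            assert new_doc.text[: new_m.start] == old_doc.text[: old_m.start]
            assert new_doc.text[new_m.end :] == old_doc.text[old_m.end :]
        replaced.validate()

    def test_untouched_mentions_preserved(self, default_data):
        target = default_data.test.all_mentions()[0][1].surface
        replaced = replace_all_occurrences(default_data.test, target, "XYZZY-1")
        old = {
            (d, m.surface) for d, m in default_data.test.all_mentions() if m.surface != target
        }
        new = {(d, m.surface) for d, m in replaced.all_mentions() if m.surface != "XYZZY-1"}
        assert old == new
        replaced.validate()

    def test_k_pseudo_entity_injection(self):
        data = generate_corpus(GeneratorConfig(seed=65, frac_abbrev=0.6, frac_conventional=0.2))
        replaced, records = replace_random_abbreviations(data.train, 10, seed=1)
        assert len(records) == 10
        new_surfaces = {r["new_surface"] for r in records}
        assert len(new_surfaces) == 10
        for s in new_surfaces:
            assert PSEUDO_RE.match(s)
        found = {m.surface for _, m in replaced.all_mentions()}
        assert new_surfaces <= found
        replaced.validate()

    def test_too_few_abbreviations_error(self):
        data = generate_corpus(
            GeneratorConfig(seed=66, frac_abbrev=0.0, frac_conventional=1.0)
        )
        with pytest.raises(ValueError):
            replace_random_abbreviations(data.train, 10)

    def test_dispatcher_policies(self):
        corpus = make_target_corpus("COVID-19", 3, seed=0)
        out = replace_mentions(
            corpus, "all-occurrences", target="COVID-19", replacement="COVID"
        )
        assert all(m.surface == "COVID" for _, m in out.all_mentions())
        with pytest.raises(ValueError):
            replace_mentions(corpus, "no-such-policy")


class TestInjectLabelBias:
    def test_one_hot_in_train_shifted_in_test(self, scheme):
        cfg = GeneratorConfig(seed=67, bias_strength=0.5)
        data = generate_corpus(GeneratorConfig(seed=67))
        table = bias_table_from_corpus(data.train, scheme)
        train_stems = sorted({m.surface.split()[0] for _, m in data.train.all_mentions()})
        test2, records = inject_label_bias(cfg, data.test, words=train_stems[:5])
        assert records
        for rec in records:
            word = rec["word"]
            # the word's training statistics are one-hot on an entity tag
            raw = table.raw_row(word)
            assert raw[scheme.index("O")] == 0.0
            # its injected test occurrence is outside any mention (tag O)
            doc = test2.doc(rec["doc_id"])
            assert doc.text[rec["start"] : rec["end"]] == word
            assert not doc.mentions

    def test_zero_strength_no_op(self, scheme):
        cfg = GeneratorConfig(seed=68, bias_strength=0.0)
        data = generate_corpus(cfg)
        out, records = inject_label_bias(cfg, data.test)
        assert records == [] and out is data.test

    def test_zero_strength_train_test_statistics_agree(self, scheme):
        data = generate_corpus(GeneratorConfig(seed=69, n_train_docs=80, n_test_docs=80))
        t_train = bias_table_from_corpus(data.train, scheme)
        t_test = bias_table_from_corpus(data.test, scheme)
        shared = set(t_train.raw_rows) & set(t_test.raw_rows)
        assert shared
        diffs = [
            abs(t_train.raw_row(w) - t_test.raw_row(w)).max() for w in sorted(shared)
        ]
        assert sum(diffs) / len(diffs) < 0.1
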