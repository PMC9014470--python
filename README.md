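# splitner

Tools for analyzing how named-entity recognition models generalize beyond
their training data, aimed at biomedical corpora where mentions carry
concept identifiers (MeSH/OMIM-style CUIs).

The package partitions every test mention by its overlap with the training
set — **Mem** (surface and concept both seen), **Syn** (new surface of a
seen concept), **Con** (new surface and new concept), plus a **Homonym**
bucket (seen surface, unseen concept) reported separately — and measures
recall within each split, since false positives cannot be attributed to a
split. It ships:

- `corpus_io` — PubTator-style and two-column CoNLL readers/writers,
  offset-verified mentions, tokenization, BIO encoding/decoding.
- `partitioner` — training surface/concept inventory and split assignment.
- `dictionary_tagger` — DICT_train / DICT_syn longest-match baselines
  (longest candidate wins, leftmost on ties, token-aligned matching).
- `evaluation` — entity-level P/R/F1, per-split recall, relaxed
  (containment) recall for a target string, abbreviation-subset recall.
- `debias` — per-word tag-statistics bias table, the bias-product
  combination `softmax(log p + log b)` used during training only, and a
  deterministic linear reference tagger to exercise it at desk scale.
- `synthetic_data` — a seeded corpus generator with a ground-truth ledger:
  controllable split proportions, name-pattern mixes (conventional
  "`<stem> disease`", abbreviations, `ABBREV-NUMBER` pseudo entities),
  label-inconsistency injection, and skewed word-statistics injection.
- `experiments` — drivers for the two directional studies (bias-product
  debiasing improves Con recall without improving Mem; pseudo-entity
  augmentation improves relaxed recall on a novel `ABBREV-NUMBER` entity).

No benchmark data is bundled or downloaded; everything is demonstrated on
generated corpora that emulate the benchmarks' statistical structure. Real
corpora in PubTator format are supported as inputs.

## Command line

```sh
splitner simulate --seed 1 --outdir sim/            # corpora + synonyms + ledger
splitner convert --input sim/train.pubtator --output train.conll
splitner partition --train sim/train.pubtator --test sim/test.pubtator --out splits.tsv
splitner tag --train sim/train.pubtator --input sim/test.pubtator \
    --dict syn --synonyms sim/synonyms.tsv --out pred.pubtator
splitner evaluate --gold sim/test.pubtator --pred pred.pubtator \
    --train sim/train.pubtator
splitner debias-train --train sim/train.pubtator --out bias.tsv
```

## Library sketch

```python
from splitner import (GeneratorConfig, generate_corpus, build_inventory,
                      partition_corpus, build_dict_train, tag_corpus,
                      split_recall)

data = generate_corpus(GeneratorConfig(seed=1))
inventory = build_inventory(data.train)
partition = partition_corpus(data.test, inventory)
preds = tag_corpus(data.test, build_dict_train(data.train))
recalls, totals = split_recall(partition, preds)
```

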