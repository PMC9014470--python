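"""Desk-scale experiment drivers used by the test suite and report script.

Both experiments train the linear reference tagger on generated corpora and
compare a manipulated run against a baseline across seeds: (1) bias-product
training versus plain NLL on a corpus with skewed word statistics, scored by
per-split recall; (2) pseudo-entity augmentation versus none, scored by
relaxed recall on a held-out novel ABBREV-NUMBER entity.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .corpus_io import LabelScheme
from .debias import ReferenceTagger, bias_table_from_corpus, tagged_sentences_from_corpus
from .evaluation import relaxed_recall, split_recall
from .partitioner import Split, build_inventory, partition_corpus
from .synthetic_data import (
    GeneratorConfig,
    PATTERN_ABBREV_NUMBER,
    generate_corpus,
    make_pseudo_entity,
    make_target_corpus,
    replace_random_abbreviations,
)


def bias_experiment_config(seed: int) -> GeneratorConfig:
    """Skewed-statistics corpus: single lowercase-stem entities whose words
    also occur outside mentions, non-entity words in entity contexts, and an
    ABBREV-NUMBER Con split with no training support."""
    return GeneratorConfig(
        seed=seed,
        n_train_docs=90,
        n_test_docs=50,
        sentences_per_doc=3,
        p_mem=0.55,
        p_syn=0.15,
        p_con=0.30,
        n_concepts=25,
        synonyms_per_concept=2,
        frac_conventional=0.0,
        frac_abbrev=0.0,
        frac_abbrev_number=0.0,  # train entities are plain stems
        con_pattern=PATTERN_ABBREV_NUMBER,
        bias_strength=0.30,
        mixed_usage_rate=0.20,
        filler_rate=0.10,
    )


@dataclass
class DebiasRun:
    mem_plain: float
    con_plain: float
    mem_debias: float
    con_debias: float


@dataclass
class DebiasExperiment:
    runs: list[DebiasRun] = field(default_factory=list)

    def mean(self, attr: str) -> float:
        return sum(getattr(r, attr) for r in self.runs) / len(self.runs)

    def summary(self) -> dict[str, float]:
        return {
            a: self.mean(a)
            for a in ("mem_plain", "con_plain", "mem_debias", "con_debias")
        }


def run_debias_experiment(
    n_seeds: int = 10,
    base_seed: int = 0,
    epochs: int = 12,
    lr: float = 0.5,
    epsilon: float = 1e-6,
) -> DebiasExperiment:
    """Train the reference tagger with and without the bias product on the
    skewed corpus, one corpus + two trainings per seed."""
    scheme = LabelScheme()
    experiment = DebiasExperiment()
    for s in range(n_seeds):
        seed = base_seed + s
        data = generate_corpus(bias_experiment_config(seed))
        sentences = tagged_sentences_from_corpus(data.train, scheme)
        inventory = build_inventory(data.train)
        partition = partition_corpus(data.test, inventory)

        plain = ReferenceTagger(scheme, seed=seed, lr=lr, epochs=epochs)
        plain.fit(sentences)
        r_plain, _ = split_recall(partition, plain.predict_corpus(data.test))

        table = bias_table_from_corpus(data.train, scheme, epsilon=epsilon)
        debiased = ReferenceTagger(scheme, seed=seed, lr=lr, epochs=epochs)
        debiased.fit(sentences, bias_table=table)
        r_deb, _ = split_recall(partition, debiased.predict_corpus(data.test))

        experiment.runs.append(
            DebiasRun(
                mem_plain=r_plain[Split.MEM],
                con_plain=r_plain[Split.CON],
                mem_debias=r_deb[Split.MEM],
                con_debias=r_deb[Split.CON],
            )
        )
    return experiment


def augmentation_experiment_config(seed: int) -> GeneratorConfig:
    """Conventional-pattern training data with a minority of plain
    abbreviations available for replacement; numeric filler sentences give
    digit/hyphen shapes an outside-entity prior."""
    return GeneratorConfig(
        seed=seed,
        n_train_docs=90,
        n_test_docs=30,
        sentences_per_doc=3,
        p_mem=0.7,
        p_syn=0.2,
        p_con=0.1,
        n_concepts=25,
        synonyms_per_concept=2,
        frac_conventional=0.5,
        frac_abbrev=0.25,
        frac_abbrev_number=0.0,
        bias_strength=0.20,
        mixed_usage_rate=0.10,
        filler_rate=0.10,
        code_filler_rate=0.12,
    )


@dataclass
class AugmentationRun:
    target: str
    recall_baseline: float
    recall_augmented: float


@dataclass
class AugmentationExperiment:
    runs: list[AugmentationRun] = field(default_factory=list)

    def mean(self, attr: str) -> float:
        return sum(getattr(r, attr) for r in self.runs) / len(self.runs)

    def summary(self) -> dict[str, float]:
        return {
            "recall_baseline": self.mean("recall_baseline"),
            "recall_augmented": self.mean("recall_augmented"),
        }


def run_augmentation_experiment(
    n_seeds: int = 10,
    base_seed: int = 0,
    n_injected: int = 10,
    n_target_docs: int = 40,
    epochs: int = 12,
    lr: float = 0.5,
) -> AugmentationExperiment:
    """Relaxed recall on a held-out novel ABBREV-NUMBER entity, with and
    without replacing ``n_injected`` training abbreviations by pseudo
    entities."""
    scheme = LabelScheme()
    experiment = AugmentationExperiment()
    for s in range(n_seeds):
        seed = base_seed + s
        data = generate_corpus(augmentation_experiment_config(seed))
        train_aug, records = replace_random_abbreviations(
            data.train, n_injected, seed=seed
        )
        injected = {r["new_surface"] for r in records}
        target_rng = random.Random(seed + 10_000)
        target = make_pseudo_entity(target_rng)
        existing = {m.surface for _, m in data.train.all_mentions()}
        while target in injected or target in existing:
            target = make_pseudo_entity(target_rng)
        probe = make_target_corpus(target, n_target_docs, seed=seed)

        baseline = ReferenceTagger(scheme, seed=seed, lr=lr, epochs=epochs)
        baseline.fit(tagged_sentences_from_corpus(data.train, scheme))
        r0 = relaxed_recall(probe, baseline.predict_corpus(probe), target)

        augmented = ReferenceTagger(scheme, seed=seed, lr=lr, epochs=epochs)
        augmented.fit(tagged_sentences_from_corpus(train_aug, scheme))
        r1 = relaxed_recall(probe, augmented.predict_corpus(probe), target)

        experiment.runs.append(
            AugmentationRun(target=target, recall_baseline=r0, recall_augmented=r1)
        )
    return experiment
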