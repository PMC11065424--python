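"""End-to-end desk-scale workflows.

`run_desk_benchmark` runs the full loop — generate a synthetic world,
expand it with downsampled variants, split, train the two-network pair,
and benchmark it against the naive rules on held-out complete genomes —
and returns both the tidy metrics table and a small summary.  It is the
programmatic equivalent of `simulate`+`train`+`evaluate` on the CLI and
the basis of the package's reproducibility checks.

Problem sizes default to a desk-scale study: 600 genomes, 12 modules
spanning both prevalence partitions, a 170-KO universe, and a pair of
2x512 networks trained up to 200 epochs with early stopping.  Labels in
the synthetic world are a deterministic boolean function of the KO set,
so a well-fit model pair should approach perfect per-module F1 on
held-out complete genomes while degrading gracefully under downsampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation_io import FeatureMatrix, LabelMatrix, build_feature_matrix
from .classifier import (
    ClassifierConfig,
    ModelPair,
    partition_modules,
    stratified_multilabel_split,
    train_model_pair,
)
from .evaluation import (
    AGGREGATE_MODULE_NAME,
    ConfusionCounts,
    ModelPairClassifier,
    ProportionalRuleClassifier,
    UniqueGeneRuleClassifier,
    benchmark,
    compute_metrics,
)
from .synthetic_data import (
    DownsampleScheme,
    SyntheticWorldConfig,
    SyntheticWorld,
    expand_with_downsampled,
    generate_world,
)

__all__ = ["DeskBenchmarkResult", "run_desk_benchmark", "desk_classifier_config"]


def desk_classifier_config(seed: int) -> ClassifierConfig:
    """Desk-scale hyperparameters: two 512-unit hidden layers trained up
    to 200 epochs (early stopping, patience 25) — enough capacity and
    optimisation budget to recover the deterministic labelling rule."""
    return ClassifierConfig(
        hidden_layers=2,
        hidden_units=512,
        epochs=200,
        batch_size=128,
        patience=25,
        seed=seed,
    )


@dataclass
class DeskBenchmarkResult:
    world: SyntheticWorld
    models: ModelPair
    table: pd.DataFrame
    per_module_f1_complete: dict
    summary: dict


def _macro(table: pd.DataFrame, model: str, metric: str, percents) -> float:
    sel = table[
        (table["Module name"] == AGGREGATE_MODULE_NAME)
        & (table["Model type"] == model)
        & (table["Metric"] == metric)
        & (table["Percent of protein families retained"].isin(list(percents)))
    ]
    return float(sel["Score"].mean())


def run_desk_benchmark(
    seed: int,
    n_genomes: int = 600,
    n_modules: int = 12,
    n_kos: int = 170,
    retain_fractions: tuple = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9),
    config: ClassifierConfig | None = None,
) -> DeskBenchmarkResult:
    """Simulate, train, and benchmark; deterministic given ``seed``."""
    seed = int(seed) % (2**31)
    world = generate_world(
        SyntheticWorldConfig(
            n_genomes=n_genomes, n_modules=n_modules, n_kos=n_kos, seed=seed
        )
    )
    genomes, labels = expand_with_downsampled(
        world.genomes, world.labels, DownsampleScheme(seed=seed)
    )
    features = build_feature_matrix(genomes, world.ko_universe)
    train_idx, test_idx = stratified_multilabel_split(features, labels, 0.25, seed=seed)
    partition = partition_modules(world.labels)
    if config is None:
        config = desk_classifier_config(seed)
    models = train_model_pair(
        FeatureMatrix(
            [features.genome_ids[i] for i in train_idx],
            features.ko_universe,
            features.bits[train_idx],
        ),
        LabelMatrix(
            [labels.genome_ids[i] for i in train_idx],
            labels.module_ids,
            labels.labels[train_idx],
        ),
        partition,
        config,
    )

    # held-out COMPLETE genomes (downsampled variants carry a __r suffix)
    test_complete = [
        genomes[i] for i in test_idx if "__r" not in genomes[i].genome_id
    ]
    gid_row = {gid: i for i, gid in enumerate(world.labels.genome_ids)}
    clf = ModelPairClassifier(models, world.catalog)
    counts = {m: ConfusionCounts() for m in world.labels.module_ids}
    for g in test_complete:
        calls = clf.predict(g, g, 1.0)
        truth = world.labels.labels[gid_row[g.genome_id]]
        for j, mid in enumerate(world.labels.module_ids):
            counts[mid].add(int(truth[j]), int(calls[mid]))
    per_module_f1 = {m: compute_metrics(c).f1 for m, c in counts.items()}

    lab_sub = LabelMatrix(
        [g.genome_id for g in test_complete],
        world.labels.module_ids,
        world.labels.labels[[gid_row[g.genome_id] for g in test_complete]],
    )
    table = benchmark(
        [
            clf,
            ProportionalRuleClassifier(world.catalog),
            UniqueGeneRuleClassifier(world.catalog),
        ],
        test_complete,
        lab_sub,
        DownsampleScheme(retain_fractions=retain_fractions, seed=seed),
    )

    mid_percents = [int(round(f * 100)) for f in retain_fractions if 0.3 <= f <= 0.7]
    high_percents = [int(round(f * 100)) for f in retain_fractions if f >= 0.3]
    dl = "Deep learning pair"
    summary = {
        "per_module_min_f1_complete": float(
            min(v for v in per_module_f1.values() if v is not None)
        ),
        "mean_f1_retain_30_90": _macro(table, dl, "F1 score", high_percents),
        "mean_precision_retain_30_90": _macro(table, dl, "Precision", high_percents),
        "mean_recall_retain_50": _macro(table, dl, "Recall", [50]),
        "mean_recall_retain_10": _macro(table, dl, "Recall", [10]),
        "model_macro_f1_retain_30_70": _macro(table, dl, "F1 score", mid_percents),
        "proportional_macro_f1_retain_30_70": _macro(
            table, "Proportional rule", "F1 score", mid_percents
        ),
        "unique_gene_macro_f1_retain_30_70": _macro(
            table, "Unique-gene rule", "F1 score", mid_percents
        ),
        "n_test_complete_genomes": len(test_complete),
        "n_balanced_modules": len(partition.balanced_modules),
        "n_imbalanced_modules": len(partition.imbalanced_modules),
    }
    return DeskBenchmarkResult(
        world=world,
        models=models,
        table=table,
        per_module_f1_complete=per_module_f1,
        summary=summary,
    )
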