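import numpy as np
import pytest

from modcast import (
    ClassifierConfig,
    DownsampleScheme,
    FeatureMatrix,
    LabelMatrix,
    SyntheticWorldConfig,
    build_feature_matrix,
    expand_with_downsampled,
    generate_world,
    partition_modules,
    stratified_multilabel_split,
    train_model_pair,
)


@pytest.fixture(scope="session")
def small_world():
    """A small but non-trivial synthetic world used across test modules."""
    return generate_world(
        SyntheticWorldConfig(n_genomes=200, n_modules=8, n_kos=120, seed=1234)
    )


@pytest.fixture(scope="session")
def trained_pair(small_world):
    """A quickly-trained model pair on the small world (downsample-expanded)."""
    world = small_world
    genomes, labels = expand_with_downsampled(
        world.genomes, world.labels, DownsampleScheme(retain_fractions=(0.3, 0.6), seed=5)
    )
    features = build_feature_matrix(genomes, world.ko_universe)
    train_idx, _ = stratified_multilabel_split(features, labels, 0.25, seed=5)
    partition = partition_modules(world.labels)
    config = ClassifierConfig(
        hidden_layers=1, hidden_units=64, epochs=30, batch_size=64, patience=10, seed=5
    )
    pair = train_model_pair(
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
    return pair
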