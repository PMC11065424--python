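"""Two-model multi-label classification of metabolic module presence.

Modules are partitioned by their prevalence among complete training
genomes: one network learns the *balanced* modules (prevalence within
[low, high], default [0.10, 0.90]) and a second learns the *imbalanced*
ones (outside that band).  Modules with fewer positives than an inclusion
floor are excluded entirely.  Both networks see the same KO
presence/absence features; only their label columns differ.

Train/test splitting uses iterative stratification so every module's
positive fraction is preserved across the split, which matters for the
rare, imbalanced modules.
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import dataclass, field, asdict
from io import BytesIO
from typing import Sequence

import numpy as np

from .annotation_io import (
    FeatureMatrix,
    GenomeAnnotation,
    LabelMatrix,
    build_feature_matrix,
)
from .grammar import ModuleAST, evaluate_module
from .nn import MultiLabelMLP

__all__ = [
    "ClassifierConfig",
    "ModulePartition",
    "ModelPair",
    "ModulePrediction",
    "partition_modules",
    "stratified_multilabel_split",
    "train_model_pair",
    "predict_modules",
]

ARCHIVE_FORMAT_VERSION = 1


@dataclass
class ClassifierConfig:
    """Hyperparameters of the two networks.

    Defaults follow the reference architecture: five ReLU hidden layers of
    2048 units, He-uniform initialisation, sigmoid outputs trained with
    binary cross-entropy under Adam (learning rate 0.001), dropout of 10%
    at every layer except the output, and L2 weight decay.  ``threshold``
    is the decision cut on the sigmoid output (inclusive).
    """

    hidden_layers: int = 5
    hidden_units: int = 2048
    dropout_rate: float = 0.10
    l2_strength: float = 1e-4
    learning_rate: float = 0.001
    epochs: int = 50
    batch_size: int = 256
    patience: int = 5
    seed: int = 0
    threshold: float = 0.5
    validation_fraction: float = 0.20


@dataclass
class ModulePartition:
    """Module ids split by training prevalence; exhaustive and disjoint
    over retained modules."""

    balanced_modules: list
    imbalanced_modules: list
    low: float = 0.10
    high: float = 0.90
    min_positive_count: int = 0
    excluded_modules: list = field(default_factory=list)

    @property
    def retained_modules(self) -> list:
        return list(self.balanced_modules) + list(self.imbalanced_modules)


def partition_modules(
    labels: LabelMatrix,
    low: float = 0.10,
    high: float = 0.90,
    min_positive_count: int = 1,
) -> ModulePartition:
    """Partition modules into balanced (low <= prevalence <= high, both
    bounds inclusive) and imbalanced sets; drop modules with fewer than
    ``min_positive_count`` positive genomes.

    Prevalence must be computed on complete training genomes, so pass the
    un-expanded label matrix.
    """
    if labels.labels.shape[0] == 0:
        raise ValueError("empty label matrix")
    prevalence = labels.prevalence()
    positives = labels.labels.sum(axis=0)
    balanced, imbalanced, excluded = [], [], []
    for m, module_id in enumerate(labels.module_ids):
        if positives[m] < min_positive_count:
            excluded.append(module_id)
        elif low <= prevalence[m] <= high:
            balanced.append(module_id)
        else:
            imbalanced.append(module_id)
    if not balanced and not imbalanced:
        raise ValueError(
            f"all {len(labels.module_ids)} modules fall below the inclusion "
            f"floor of {min_positive_count} positives"
        )
    return ModulePartition(
        balanced_modules=balanced,
        imbalanced_modules=imbalanced,
        low=low,
        high=high,
        min_positive_count=min_positive_count,
        excluded_modules=excluded,
    )


# ---------------------------------------------------------------------------
# Iterative stratification (multi-label stratified split)
# ---------------------------------------------------------------------------

def stratified_multilabel_split(
    features: FeatureMatrix | None,
    labels: LabelMatrix,
    test_fraction: float,
    seed: int,
) -> tuple:
    """Greedy iterative stratification of rows into train/test.

    Repeatedly takes the label with the fewest unassigned positive
    examples and deals its remaining rows to whichever split most needs
    them, so that each label's positive fraction is preserved.  Rows that
    carry none of the (remaining) labels are dealt by overall size need.
    All-zero label columns contribute nothing to stratification and fall
    through to the size-based assignment.  Returns ``(train_idx,
    test_idx)`` as sorted integer arrays partitioning the rows.
    """
    if not (0 < test_fraction < 1):
        raise ValueError("test_fraction must lie in (0, 1)")
    Y = labels.labels
    n, n_labels = Y.shape
    if features is not None and features.bits.shape[0] != n:
        raise ValueError("features and labels disagree on row count")
    rng = np.random.default_rng(seed)
    fractions = np.array([1 - test_fraction, test_fraction])
    # hard size budgets (test gets round(n * test_fraction) rows exactly),
    # plus per (split, label) positive-count targets
    budget = np.array([n - round(n * test_fraction), round(n * test_fraction)])
    desired_total = budget.astype(float)
    label_counts = Y.sum(axis=0).astype(float)
    desired_label = np.outer(fractions, label_counts)  # shape (2, n_labels)
    filled = np.zeros(2, dtype=np.int64)

    assigned = np.full(n, -1, dtype=np.int64)
    remaining = np.ones(n, dtype=bool)
    remaining_per_label = label_counts.copy()

    while True:
        active = np.where(remaining_per_label > 0)[0]
        if active.size == 0:
            break
        # label with fewest remaining unassigned positives
        lab = active[np.argmin(remaining_per_label[active])]
        rows = np.where(remaining & (Y[:, lab] > 0))[0]
        rng.shuffle(rows)
        for r in rows:
            want = desired_label[:, lab]
            if want[0] > want[1]:
                split = 0
            elif want[1] > want[0]:
                split = 1
            else:
                # tie on the label: fall back to overall size need, then coin flip
                if desired_total[0] > desired_total[1]:
                    split = 0
                elif desired_total[1] > desired_total[0]:
                    split = 1
                else:
                    split = int(rng.integers(2))
            if filled[split] >= budget[split]:
                split = 1 - split
            assigned[r] = split
            remaining[r] = False
            filled[split] += 1
            desired_total[split] -= 1
            row_labels = np.where(Y[r] > 0)[0]
            desired_label[split, row_labels] -= 1
            remaining_per_label[row_labels] -= 1

    # rows without any positive label: deal by remaining size need
    leftover = np.where(remaining)[0]
    rng.shuffle(leftover)
    for r in leftover:
        split = 0 if desired_total[0] >= desired_total[1] else 1
        if filled[split] >= budget[split]:
            split = 1 - split
        assigned[r] = split
        filled[split] += 1
        desired_total[split] -= 1

    train_idx = np.sort(np.where(assigned == 0)[0])
    test_idx = np.sort(np.where(assigned == 1)[0])
    return train_idx, test_idx


# ---------------------------------------------------------------------------
# Model pair
# ---------------------------------------------------------------------------

@dataclass
class ModelPair:
    """The two trained networks plus everything needed to reuse them."""

    balanced_model: MultiLabelMLP | None
    imbalanced_model: MultiLabelMLP | None
    ko_universe: list
    partition: ModulePartition
    config: ClassifierConfig

    def predict_proba(self, bits: np.ndarray) -> dict:
        """Per-module sigmoid probabilities for feature rows ``bits``."""
        out: dict = {}
        if self.balanced_model is not None and self.partition.balanced_modules:
            P = self.balanced_model.predict_proba(bits)
            for j, mid in enumerate(self.partition.balanced_modules):
                out[mid] = P[:, j]
        if self.imbalanced_model is not None and self.partition.imbalanced_modules:
            P = self.imbalanced_model.predict_proba(bits)
            for j, mid in enumerate(self.partition.imbalanced_modules):
                out[mid] = P[:, j]
        return out

    # -- archive -----------------------------------------------------------

    def save(self, path) -> None:
        """One versioned zip archive: JSON metadata plus npz weights."""
        meta = {
            "format_version": ARCHIVE_FORMAT_VERSION,
            "ko_universe": self.ko_universe,
            "partition": asdict(self.partition),
            "config": asdict(self.config),
            "balanced_meta": (
                self.balanced_model.get_state()["meta"] if self.balanced_model else None
            ),
            "imbalanced_meta": (
                self.imbalanced_model.get_state()["meta"] if self.imbalanced_model else None
            ),
        }
        with zipfile.ZipFile(path, "w") as zf:
            zf.writestr("meta.json", json.dumps(meta))
            for name, model in (
                ("balanced", self.balanced_model),
                ("imbalanced", self.imbalanced_model),
            ):
                if model is None:
                    continue
                buf = BytesIO()
                np.savez(buf, **model.get_state()["arrays"])
                zf.writestr(f"{name}.npz", buf.getvalue())

    @classmethod
    def load(cls, path) -> "ModelPair":
        with zipfile.ZipFile(path) as zf:
            meta = json.loads(zf.read("meta.json"))
            if meta["format_version"] != ARCHIVE_FORMAT_VERSION:
                raise ValueError(
                    f"unsupported model archive version {meta['format_version']}"
                )
            models = {}
            for name in ("balanced", "imbalanced"):
                if meta[f"{name}_meta"] is None:
                    models[name] = None
                    continue
                arrays = dict(np.load(BytesIO(zf.read(f"{name}.npz"))))
                models[name] = MultiLabelMLP.from_state(meta[f"{name}_meta"], arrays)
        return cls(
            balanced_model=models["balanced"],
            imbalanced_model=models["imbalanced"],
            ko_universe=list(meta["ko_universe"]),
            partition=ModulePartition(**meta["partition"]),
            config=ClassifierConfig(**meta["config"]),
        )


def _train_one(
    X: np.ndarray,
    Y: np.ndarray,
    module_ids: Sequence[str],
    config: ClassifierConfig,
    seed_offset: int,
) -> MultiLabelMLP:
    sub_labels = LabelMatrix(
        genome_ids=[str(i) for i in range(X.shape[0])],
        module_ids=list(module_ids),
        labels=Y.astype(np.uint8),
    )
    fit_idx, val_idx = stratified_multilabel_split(
        None, sub_labels, config.validation_fraction, seed=config.seed + seed_offset
    )
    model = MultiLabelMLP(
        n_inputs=X.shape[1],
        n_outputs=Y.shape[1],
        hidden_layers=config.hidden_layers,
        hidden_units=config.hidden_units,
        dropout_rate=config.dropout_rate,
        l2_strength=config.l2_strength,
        learning_rate=config.learning_rate,
        seed=config.seed + seed_offset,
    )
    model.fit(
        X[fit_idx],
        Y[fit_idx],
        X[val_idx],
        Y[val_idx],
        epochs=config.epochs,
        batch_size=config.batch_size,
        patience=config.patience,
    )
    return model


def train_model_pair(
    features: FeatureMatrix,
    labels: LabelMatrix,
    partition: ModulePartition,
    config: ClassifierConfig,
) -> ModelPair:
    """Train the balanced and imbalanced networks on identical features.

    Each network gets an internal stratified 80/20 train/validation split
    (seeded) and early-stops on validation loss.
    """
    if features.bits.shape[0] != labels.labels.shape[0]:
        raise ValueError("feature rows and label rows differ")
    X = features.bits.astype(np.float32)
    col = {mid: j for j, mid in enumerate(labels.module_ids)}
    balanced_model = imbalanced_model = None
    if partition.balanced_modules:
        cols = [col[m] for m in partition.balanced_modules]
        balanced_model = _train_one(
            X, labels.labels[:, cols].astype(np.float32),
            partition.balanced_modules, config, seed_offset=1,
        )
    if partition.imbalanced_modules:
        cols = [col[m] for m in partition.imbalanced_modules]
        imbalanced_model = _train_one(
            X, labels.labels[:, cols].astype(np.float32),
            partition.imbalanced_modules, config, seed_offset=2,
        )
    return ModelPair(
        balanced_model=balanced_model,
        imbalanced_model=imbalanced_model,
        ko_universe=list(features.ko_universe),
        partition=partition,
        config=config,
    )


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------

@dataclass
class ModulePrediction:
    """One module's reconstruction/prediction record for one genome."""

    genome_id: str
    module_id: str
    status: str  # complete | predicted_present | predicted_absent
    probability: float
    completeness: float
    gap_fill_kos: frozenset


def predict_modules(
    models: ModelPair,
    genome: GenomeAnnotation,
    catalog: Sequence[ModuleAST],
    requested: Sequence[str] | None = None,
) -> list:
    """Reconstruct-then-predict for one genome.

    Modules the genome already completes are reported ``complete`` with
    probability 1.0 and never see a network.  Incomplete modules get their
    partition model's sigmoid probability; ``predicted_present`` iff
    probability >= the configured threshold (inclusive), with gap-filling
    KOs attached only in that case.  Incomplete modules that were excluded
    at training time carry probability 0.0 and are ``predicted_absent``.
    """
    by_id = {ast.module_id: ast for ast in catalog}
    if requested is not None:
        unknown = [m for m in requested if m not in by_id]
        if unknown:
            raise KeyError(f"unknown module id(s): {', '.join(sorted(unknown))}")
        wanted = list(requested)
    else:
        wanted = [ast.module_id for ast in catalog]

    feats = build_feature_matrix([genome], models.ko_universe)
    proba = models.predict_proba(feats.bits.astype(np.float32))
    threshold = models.config.threshold

    records = []
    for mid in wanted:
        ast = by_id[mid]
        ev = evaluate_module(ast, genome.kos)
        if ev.status == "complete":
            records.append(
                ModulePrediction(
                    genome_id=genome.genome_id,
                    module_id=mid,
                    status="complete",
                    probability=1.0,
                    completeness=ev.completeness,
                    gap_fill_kos=frozenset(),
                )
            )
            continue
        p = float(proba[mid][0]) if mid in proba else 0.0
        present = p >= threshold
        records.append(
            ModulePrediction(
                genome_id=genome.genome_id,
                module_id=mid,
                status="predicted_present" if present else "predicted_absent",
                probability=p,
                completeness=ev.completeness,
                gap_fill_kos=ev.missing_kos if present else frozenset(),
            )
        )
    return records
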