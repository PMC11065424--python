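"""Performance metrics and the downsampling benchmark harness.

Metrics follow the standard confusion-matrix definitions: precision
tp/(tp+fp), recall tp/(tp+fn), specificity tn/(tn+fp), F1 as the harmonic
mean of precision and recall, prevalence (tp+fn)/n, and the predictive
values in their Bayes form

    PPV = recall * prev / (recall * prev + (1 - spec) * (1 - prev))
    NPV = spec * (1 - prev) / ((1 - recall) * prev + spec * (1 - prev))

which are algebraically identical to tp/(tp+fp) and tn/(tn+fn);
:func:`verify_ppv_identity` checks that identity numerically.  Undefined
metrics (zero denominators) are reported as ``None``/NA, never coerced to
zero, and are excluded from macro-averages with a logged count.

The benchmark harness downsamples each test genome at each retention
fraction, asks every registered classifier for module calls, scores the
calls against the complete genome's labels, and emits a tidy table with
columns ``Module name``, ``Percent of protein families retained``,
``Model type``, ``Metric`` and ``Score``, plus macro-mean aggregate rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Protocol, Sequence

import numpy as np
import pandas as pd

from .annotation_io import GenomeAnnotation, LabelMatrix, build_feature_matrix
from .baselines import proportional_rule, unique_gene_rule
from .grammar import ModuleAST, evaluate_module
from .synthetic_data import DownsampleScheme, _child_seed, downsample_annotation

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "compute_metrics",
    "verify_ppv_identity",
    "ModuleClassifier",
    "ModelPairClassifier",
    "ProportionalRuleClassifier",
    "UniqueGeneRuleClassifier",
    "OracleClassifier",
    "benchmark",
    "AGGREGATE_MODULE_NAME",
]

AGGREGATE_MODULE_NAME = "(macro mean)"
MICRO_MODULE_NAME = "(micro pooled)"
METRIC_NAMES = (
    "Precision",
    "Recall",
    "F1 score",
    "Positive predictive value",
    "Negative predictive value",
)


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def add(self, truth: int, predicted: int) -> None:
        if truth and predicted:
            self.tp += 1
        elif truth and not predicted:
            self.fn += 1
        elif not truth and predicted:
            self.fp += 1
        else:
            self.tn += 1


@dataclass
class MetricsReport:
    """The seven statistics; ``None`` marks an undefined (NA) value."""

    precision: float | None
    recall: float | None
    specificity: float | None
    f1: float | None
    ppv: float | None
    npv: float | None
    prevalence: float | None

    def as_dict(self) -> dict:
        return {
            "Precision": self.precision,
            "Recall": self.recall,
            "F1 score": self.f1,
            "Positive predictive value": self.ppv,
            "Negative predictive value": self.npv,
            "Specificity": self.specificity,
            "Prevalence": self.prevalence,
        }


def _ratio(num: int, den: int) -> float | None:
    return num / den if den else None


def compute_metrics(counts: ConfusionCounts) -> MetricsReport:
    """Confusion counts -> metrics; zero-denominator cases give ``None``."""
    precision = _ratio(counts.tp, counts.tp + counts.fp)
    recall = _ratio(counts.tp, counts.tp + counts.fn)
    specificity = _ratio(counts.tn, counts.tn + counts.fp)
    prevalence = _ratio(counts.tp + counts.fn, counts.total)
    if precision is not None and recall is not None and precision + recall > 0:
        f1 = 2 * precision * recall / (precision + recall)
    elif precision == recall == 0.0:
        f1 = 0.0
    else:
        f1 = None
    ppv = _ratio(counts.tp, counts.tp + counts.fp)
    npv = _ratio(counts.tn, counts.tn + counts.fn)
    return MetricsReport(
        precision=precision,
        recall=recall,
        specificity=specificity,
        f1=f1,
        ppv=ppv,
        npv=npv,
        prevalence=prevalence,
    )


def verify_ppv_identity(counts: ConfusionCounts, tol: float = 1e-12) -> bool:
    """Check that the Bayes-form PPV/NPV equal their count forms.

    PPV via recall/specificity/prevalence must match tp/(tp+fp), and NPV
    likewise must match tn/(tn+fn), within ``tol``.  Requires all
    intermediate denominators non-zero.
    """
    m = compute_metrics(counts)
    if None in (m.recall, m.specificity, m.prevalence):
        raise ValueError("identity undefined: zero denominator in inputs")
    rp = m.recall * m.prevalence
    ppv_den = rp + (1 - m.specificity) * (1 - m.prevalence)
    npv_den = (1 - m.recall) * m.prevalence + m.specificity * (1 - m.prevalence)
    if ppv_den == 0 or npv_den == 0 or counts.tp + counts.fp == 0 or counts.tn + counts.fn == 0:
        raise ValueError("identity undefined: zero denominator in inputs")
    ppv_bayes = rp / ppv_den
    npv_bayes = m.specificity * (1 - m.prevalence) / npv_den
    ppv_counts = counts.tp / (counts.tp + counts.fp)
    npv_counts = counts.tn / (counts.tn + counts.fn)
    return abs(ppv_bayes - ppv_counts) <= tol and abs(npv_bayes - npv_counts) <= tol


# ---------------------------------------------------------------------------
# Pluggable classifiers
# ---------------------------------------------------------------------------

class ModuleClassifier(Protocol):
    """Benchmark plug-in: per-genome module presence calls."""

    name: str

    def predict(
        self,
        downsampled: GenomeAnnotation,
        complete: GenomeAnnotation,
        retain: float,
    ) -> dict: ...


class ModelPairClassifier:
    """Adapter running reconstruct-then-predict through a trained pair."""

    def __init__(self, models, catalog: Sequence[ModuleAST], name: str = "Deep learning pair"):
        self.models = models
        self.catalog = list(catalog)
        self.name = name
        self._by_id = {ast.module_id: ast for ast in self.catalog}

    def predict(self, downsampled, complete, retain) -> dict:
        feats = build_feature_matrix([downsampled], self.models.ko_universe)
        proba = self.models.predict_proba(feats.bits.astype(np.float32))
        threshold = self.models.config.threshold
        out = {}
        for ast in self.catalog:
            if evaluate_module(ast, downsampled.kos).status == "complete":
                out[ast.module_id] = 1
            elif ast.module_id in proba:
                out[ast.module_id] = int(float(proba[ast.module_id][0]) >= threshold)
            else:
                out[ast.module_id] = 0
        return out


class ProportionalRuleClassifier:
    def __init__(self, catalog: Sequence[ModuleAST], name: str = "Proportional rule",
                 denominator: str = "complete"):
        self.catalog = list(catalog)
        self.name = name
        self.denominator = denominator

    def predict(self, downsampled, complete, retain) -> dict:
        return {
            ast.module_id: proportional_rule(
                downsampled, complete, ast, retain, denominator=self.denominator
            )
            for ast in self.catalog
        }


class UniqueGeneRuleClassifier:
    def __init__(self, catalog: Sequence[ModuleAST], name: str = "Unique-gene rule"):
        self.catalog = list(catalog)
        self.name = name

    def predict(self, downsampled, complete, retain) -> dict:
        return unique_gene_rule(downsampled, self.catalog)


class OracleClassifier:
    """Returns the true labels; a harness sanity check, not a competitor."""

    def __init__(self, labels: LabelMatrix, name: str = "Oracle"):
        self.name = name
        self._rows = {
            gid: {mid: int(labels.labels[i, j]) for j, mid in enumerate(labels.module_ids)}
            for i, gid in enumerate(labels.genome_ids)
        }

    def predict(self, downsampled, complete, retain) -> dict:
        return dict(self._rows[complete.genome_id])


# ---------------------------------------------------------------------------
# Benchmark harness
# ---------------------------------------------------------------------------

def benchmark(
    classifiers: Sequence,
    genomes: Sequence[GenomeAnnotation],
    labels: LabelMatrix,
    scheme: DownsampleScheme,
    micro: bool = False,
) -> pd.DataFrame:
    """Downsample, predict, score; one tidy row per (module, fraction,
    classifier, metric), plus macro-mean aggregate rows (and micro-pooled
    rows when ``micro`` is set).

    ``genomes`` are the complete genomes whose labels are the ground
    truth.  A classifier that raises on an input contributes an error row
    and the harness continues.  Output is deterministic for fixed scheme
    seed.
    """
    gid_to_row = {gid: i for i, gid in enumerate(labels.genome_ids)}
    module_ids = list(labels.module_ids)
    rows = []
    na_dropped = 0
    for retain in scheme.retain_fractions:
        downsampled = [
            downsample_annotation(g, retain, _child_seed(scheme.seed, g.genome_id, retain))
            for g in genomes
        ]
        percent = int(round(retain * 100))
        for clf in classifiers:
            counts = {mid: ConfusionCounts() for mid in module_ids}
            pooled = ConfusionCounts()
            failed = False
            for g, d in zip(genomes, downsampled):
                try:
                    calls = clf.predict(d, g, retain)
                except Exception as exc:  # harness must survive plug-in failures
                    logger.warning("%s failed on %s at retain %.2f: %s",
                                   clf.name, g.genome_id, retain, exc)
                    rows.append({
                        "Module name": AGGREGATE_MODULE_NAME,
                        "Percent of protein families retained": percent,
                        "Model type": clf.name,
                        "Metric": "Error",
                        "Score": float("nan"),
                    })
                    failed = True
                    break
                truth_row = labels.labels[gid_to_row[g.genome_id]]
                for j, mid in enumerate(module_ids):
                    pred = int(calls.get(mid, 0))
                    counts[mid].add(int(truth_row[j]), pred)
                    pooled.add(int(truth_row[j]), pred)
            if failed:
                continue
            per_metric_values: dict = {m: [] for m in METRIC_NAMES}
            for mid in module_ids:
                report = compute_metrics(counts[mid]).as_dict()
                for metric in METRIC_NAMES:
                    score = report[metric]
                    rows.append({
                        "Module name": mid,
                        "Percent of protein families retained": percent,
                        "Model type": clf.name,
                        "Metric": metric,
                        "Score": float("nan") if score is None else score,
                    })
                    if score is None:
                        na_dropped += 1
                    else:
                        per_metric_values[metric].append(score)
            for metric in METRIC_NAMES:
                vals = per_metric_values[metric]
                rows.append({
                    "Module name": AGGREGATE_MODULE_NAME,
                    "Percent of protein families retained": percent,
                    "Model type": clf.name,
                    "Metric": metric,
                    "Score": float(np.mean(vals)) if vals else float("nan"),
                })
            if micro:
                pooled_report = compute_metrics(pooled).as_dict()
                for metric in METRIC_NAMES:
                    score = pooled_report[metric]
                    rows.append({
                        "Module name": MICRO_MODULE_NAME,
                        "Percent of protein families retained": percent,
                        "Model type": clf.name,
                        "Metric": metric,
                        "Score": float("nan") if score is None else score,
                    })
    if na_dropped:
        logger.info("%d undefined metric values excluded from macro-means", na_dropped)
    return pd.DataFrame(
        rows,
        columns=[
            "Module name",
            "Percent of protein families retained",
            "Model type",
            "Metric",
            "Score",
        ],
    )
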