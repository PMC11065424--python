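"""Reading KO annotations and building presence/absence matrices.

Supported annotation dialects:

``kofamscan``
    KofamScan *detail* output (columns: significance flag, gene, KO,
    threshold, score, e-value, definition).  Only rows flagged ``*`` —
    hits above the HMM's adaptive scoring threshold — contribute their KO.
    The two-column *mapper* output (gene, KO) is also accepted.
``koala``
    blastKOALA/ghostKOALA two-column gene → KO TSV; rows with an empty KO
    column are unannotated genes and are skipped.
``kolist``
    One KO token per line.

Duplicated KOs collapse to a set: features are presence/absence, not copy
number.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .grammar import ModuleAST, evaluate_module

logger = logging.getLogger(__name__)

__all__ = [
    "GenomeAnnotation",
    "FeatureMatrix",
    "LabelMatrix",
    "AnnotationParseError",
    "read_annotations",
    "build_feature_matrix",
    "label_modules",
    "read_module_catalog",
    "write_module_catalog",
]

_KO_RE = re.compile(r"^[A-Za-z0-9_.]+$")

ANNOTATION_FORMATS = ("kofamscan", "koala", "kolist")


class AnnotationParseError(ValueError):
    """A malformed annotation row; the message names the file and line."""


@dataclass(frozen=True)
class GenomeAnnotation:
    """A genome identifier plus its set of KO identifiers."""

    genome_id: str
    kos: frozenset

    def __post_init__(self):
        object.__setattr__(self, "kos", frozenset(self.kos))


def _check_ko(token: str, path, lineno: int) -> str:
    if not token or not _KO_RE.match(token):
        raise AnnotationParseError(
            f"{path}:{lineno}: non-KO token {token!r} in KO column"
        )
    return token


def read_annotations(path, format: str, genome_id: str | None = None) -> GenomeAnnotation:
    """Read one genome's KO annotations from ``path``.

    ``genome_id`` defaults to the file name without its extension.
    """
    if format not in ANNOTATION_FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {ANNOTATION_FORMATS}")
    path = Path(path)
    gid = genome_id if genome_id is not None else path.stem
    kos: set = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            if format == "kolist":
                token = line.strip()
                kos.add(_check_ko(token, path, lineno))
            elif format == "koala":
                fields = line.split("\t")
                if len(fields) != 2:
                    raise AnnotationParseError(
                        f"{path}:{lineno}: expected 2 tab-separated columns, got {len(fields)}"
                    )
                ko = fields[1].strip()
                if ko:  # unannotated genes have an empty KO column
                    kos.add(_check_ko(ko, path, lineno))
            else:  # kofamscan
                fields = line.split()
                if line.startswith("*"):
                    # detail format, above adaptive threshold
                    if len(fields) < 3:
                        raise AnnotationParseError(
                            f"{path}:{lineno}: truncated kofamscan detail row"
                        )
                    kos.add(_check_ko(fields[2], path, lineno))
                elif raw[:1].isspace():
                    # detail row below threshold: excluded
                    continue
                elif len(fields) == 2:
                    # mapper format: gene<TAB>KO
                    kos.add(_check_ko(fields[1], path, lineno))
                elif len(fields) == 1:
                    continue  # mapper row for an unannotated gene
                else:
                    raise AnnotationParseError(
                        f"{path}:{lineno}: unrecognised kofamscan row"
                    )
    return GenomeAnnotation(genome_id=gid, kos=frozenset(kos))


# ---------------------------------------------------------------------------
# Matrices
# ---------------------------------------------------------------------------

@dataclass
class FeatureMatrix:
    """Genomes x KOs presence/absence bits over a fixed, sorted KO universe."""

    genome_ids: list
    ko_universe: list
    bits: np.ndarray  # shape (n_genomes, n_kos), dtype uint8

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.bits, index=self.genome_ids, columns=self.ko_universe)

    def to_tsv(self, path) -> None:
        df = self.to_frame()
        df.index.name = "genome_id"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=None)
        return cls(
            genome_ids=[str(g) for g in df.index],
            ko_universe=[str(c) for c in df.columns],
            bits=df.to_numpy(dtype=np.uint8),
        )


@dataclass
class LabelMatrix:
    """Genomes x modules presence/absence labels."""

    genome_ids: list
    module_ids: list
    labels: np.ndarray  # shape (n_genomes, n_modules), dtype uint8

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.labels, index=self.genome_ids, columns=self.module_ids)

    def to_tsv(self, path) -> None:
        df = self.to_frame()
        df.index.name = "genome_id"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "LabelMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(
            genome_ids=[str(g) for g in df.index],
            module_ids=[str(c) for c in df.columns],
            labels=df.to_numpy(dtype=np.uint8),
        )

    def prevalence(self) -> np.ndarray:
        return self.labels.mean(axis=0)


def build_feature_matrix(
    annotations: Sequence[GenomeAnnotation], ko_universe: Sequence[str]
) -> FeatureMatrix:
    """Binary genome x KO matrix over a fixed universe.

    KOs outside the universe are dropped (a count is logged); the universe
    must be sorted and duplicate-free so the feature layout is stable
    between training and prediction.
    """
    universe = list(ko_universe)
    if not universe:
        raise ValueError("KO universe is empty")
    if len(set(universe)) != len(universe):
        raise ValueError("KO universe contains duplicates")
    if universe != sorted(universe):
        raise ValueError("KO universe must be sorted lexicographically")
    index = {ko: j for j, ko in enumerate(universe)}
    bits = np.zeros((len(annotations), len(universe)), dtype=np.uint8)
    dropped = 0
    for i, ann in enumerate(annotations):
        for ko in ann.kos:
            j = index.get(ko)
            if j is None:
                dropped += 1
            else:
                bits[i, j] = 1
    if dropped:
        logger.info("dropped %d KO occurrences outside the %d-KO universe", dropped, len(universe))
    return FeatureMatrix(
        genome_ids=[a.genome_id for a in annotations],
        ko_universe=universe,
        bits=bits,
    )


def label_modules(
    annotations: Sequence[GenomeAnnotation], catalog: Sequence[ModuleAST]
) -> LabelMatrix:
    """Label each (genome, module) pair 1 iff the genome's KOs complete the module."""
    labels = np.zeros((len(annotations), len(catalog)), dtype=np.uint8)
    for i, ann in enumerate(annotations):
        for m, ast in enumerate(catalog):
            if evaluate_module(ast, ann.kos).status == "complete":
                labels[i, m] = 1
    return LabelMatrix(
        genome_ids=[a.genome_id for a in annotations],
        module_ids=[ast.module_id for ast in catalog],
        labels=labels,
    )


# ---------------------------------------------------------------------------
# Module catalog TSV
# ---------------------------------------------------------------------------

def read_module_catalog(path) -> list:
    """Read a module catalog TSV (columns ``module_id``, ``definition``,
    optional ``name``; ``#`` comment lines ignored) into parsed ASTs."""
    from .grammar import parse_definition

    asts = []
    with open(path) as fh:
        header = None
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                if "module_id" not in header or "definition" not in header:
                    raise AnnotationParseError(
                        f"{path}:{lineno}: catalog header must contain module_id and definition"
                    )
                id_col = header.index("module_id")
                def_col = header.index("definition")
                continue
            if len(fields) < max(id_col, def_col) + 1:
                raise AnnotationParseError(f"{path}:{lineno}: too few columns")
            asts.append(parse_definition(fields[id_col], fields[def_col]))
    return asts


def write_module_catalog(catalog: Iterable[ModuleAST], path) -> None:
    from .grammar import serialize

    with open(path, "w") as fh:
        fh.write("module_id\tdefinition\n")
        for ast in catalog:
            fh.write(f"{ast.module_id}\t{serialize(ast)}\n")
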