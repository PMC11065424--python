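"""Naive module-presence classification rules used as benchmark competitors.

Two rules:

* **proportional** — a module is called present when the proportion of its
  genes surviving downsampling is at least the overall retention fraction.
  At low retention this rule degenerates toward calling everything with a
  single surviving gene present.
* **unique gene** — a module is called present when the annotation set
  contains at least one KO that occurs in no other catalog module.
  Modules without any unique KO can never be called present.

Both rules ignore optional (``-``-prefixed) components, consistent with
presence labelling.
"""

from __future__ import annotations

from typing import Sequence

from .annotation_io import GenomeAnnotation
from .grammar import ModuleAST, atom_kos

__all__ = ["proportional_rule", "unique_gene_rule", "unique_ko_index"]


def proportional_rule(
    downsampled: GenomeAnnotation,
    complete: GenomeAnnotation,
    ast: ModuleAST,
    retain: float,
    denominator: str = "complete",
) -> int:
    """1 iff the module's retained gene fraction is >= ``retain``.

    With ``denominator="complete"`` (default) the module gene set is
    restricted to the atoms present in the complete genome — the oracle
    knowledge the benchmark grants the rule; ``denominator="all"`` uses
    every atom of the definition instead.  A module with an empty gene set
    is always absent.
    """
    if not (0 < retain <= 1):
        raise ValueError("retain must lie in (0, 1]")
    if denominator not in ("complete", "all"):
        raise ValueError("denominator must be 'complete' or 'all'")
    atoms = atom_kos(ast, include_optional=False)
    if denominator == "complete":
        atoms = atoms & complete.kos
    if not atoms:
        return 0
    kept = len(atoms & downsampled.kos)
    return int(kept / len(atoms) >= retain)


def unique_ko_index(catalog: Sequence[ModuleAST]) -> dict:
    """module_id -> the KOs appearing in that module and no other."""
    counts: dict = {}
    per_module = {}
    for ast in catalog:
        atoms = atom_kos(ast, include_optional=False)
        per_module[ast.module_id] = atoms
        for ko in atoms:
            counts[ko] = counts.get(ko, 0) + 1
    return {
        mid: frozenset(ko for ko in atoms if counts[ko] == 1)
        for mid, atoms in per_module.items()
    }


def unique_gene_rule(genome: GenomeAnnotation, catalog: Sequence[ModuleAST]) -> dict:
    """module_id -> 1 iff the genome carries a KO unique to that module."""
    if not catalog:
        raise ValueError("catalog is empty")
    uniques = unique_ko_index(catalog)
    return {
        mid: int(bool(kos & genome.kos)) for mid, kos in uniques.items()
    }
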