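"""Synthetic module catalogs and genome collections.

The generator builds a closed world in which module presence is, by
construction, a deterministic boolean function of a genome's KO set — the
same property the labelling rule assumes for real genomes.  It emulates:

* a fixed KO feature universe (module atoms plus background KOs that
  belong to no module, standing in for the genome-wide gene content the
  classifiers exploit);
* modules with ordered steps, a configurable fraction of which offer
  alternative KOs, so completion sets are non-trivial;
* a module-prevalence spectrum spanning balanced (10-90%) and imbalanced
  (<10% or >90%) classes, so both classifier partitions are populated;
* genome incompleteness by randomly retaining a fraction of each genome's
  KO annotations while keeping the complete genome's labels as ground
  truth.

Negative genomes carry, half the time, a *partial* subset of a module's
KOs (missing at least one required gene).  Real incomplete genomes look
exactly like this, and it is what makes the naive unique-gene rule
fallible.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .annotation_io import GenomeAnnotation, LabelMatrix, label_modules
from .grammar import (
    AllOf,
    AnyOf,
    Atom,
    Complex,
    ModuleAST,
    Optional,
    Wildcard,
    enumerate_completion_sets,
)

__all__ = [
    "SyntheticWorldConfig",
    "DownsampleScheme",
    "SyntheticWorld",
    "generate_world",
    "downsample_annotation",
    "expand_with_downsampled",
    "random_module_ast",
]

DEFAULT_RETAIN_FRACTIONS = tuple(round(0.1 * k, 1) for k in range(1, 10))


@dataclass
class SyntheticWorldConfig:
    """Parameters of the synthetic world.

    ``prevalence_targets`` are cycled over modules; they must include at
    least one value inside [0.10, 0.90] and one outside it so that both
    the balanced and the imbalanced classifier partitions are non-empty.
    ``background_ko_rate`` is the per-genome inclusion probability of each
    KO that belongs to no module.
    """

    n_kos: int = 160
    n_modules: int = 12
    module_size_range: tuple = (3, 6)
    p_alternative: float = 0.35
    n_genomes: int = 500
    prevalence_targets: tuple = (0.5, 0.3, 0.7, 0.05, 0.95, 0.2, 0.8, 0.15, 0.85, 0.08)
    background_ko_rate: float = 0.3
    partial_negative_rate: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.module_size_range
        if not (1 <= lo <= hi):
            raise ValueError("invalid module_size_range")
        if not self.prevalence_targets:
            raise ValueError("prevalence_targets is empty")
        if not all(0 < p < 1 for p in self.prevalence_targets):
            raise ValueError("prevalence targets must lie in (0, 1)")
        inside = any(0.10 <= p <= 0.90 for p in self.prevalence_targets)
        outside = any(p < 0.10 or p > 0.90 for p in self.prevalence_targets)
        if not (inside and outside):
            raise ValueError(
                "prevalence_targets must span both the balanced [0.10, 0.90] "
                "range and the imbalanced range outside it"
            )


@dataclass
class DownsampleScheme:
    """Retention fractions for simulating genome incompleteness."""

    retain_fractions: tuple = DEFAULT_RETAIN_FRACTIONS
    seed: int = 0

    def __post_init__(self):
        if not all(0 < f <= 1 for f in self.retain_fractions):
            raise ValueError("retain fractions must lie in (0, 1]")


@dataclass
class SyntheticWorld:
    """A generated catalog, genome collection, and their consistent labels."""

    catalog: list
    genomes: list
    labels: LabelMatrix
    config: SyntheticWorldConfig

    @property
    def ko_universe(self) -> list:
        kos: set = set()
        for g in self.genomes:
            kos.update(g.kos)
        from .grammar import atom_kos

        for ast in self.catalog:
            kos.update(atom_kos(ast, include_optional=True))
        return sorted(kos)


def _build_module(module_id: str, n_atoms: int, p_alternative: float,
                  fresh_ko, rng: np.random.Generator) -> ModuleAST:
    """A module of 1+ steps; each step is an Atom or an AnyOf of two atoms."""
    steps = []
    remaining = n_atoms
    while remaining > 0:
        if remaining >= 2 and rng.random() < p_alternative:
            steps.append(AnyOf((Atom(fresh_ko()), Atom(fresh_ko()))))
            remaining -= 2
        else:
            steps.append(Atom(fresh_ko()))
            remaining -= 1
    return ModuleAST(module_id=module_id, steps=tuple(steps))


def generate_world(config: SyntheticWorldConfig) -> SyntheticWorld:
    """Generate a catalog, genomes, and a self-consistent label matrix.

    For each module with prevalence target p, a Bernoulli(p) draw decides
    per genome whether it carries a full completion set (branch chosen at
    random) or not; negatives carry a proper subset of a completion set
    with probability ``partial_negative_rate``, otherwise nothing from the
    module.  A repair pass guarantees at least one positive and one
    negative genome per module.  Background KOs are added independently.
    The returned labels are recomputed from the generated genomes with the
    module-evaluation engine, and generation fails if they disagree with
    the intended assignment.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    lo, hi = config.module_size_range

    counter = [0]

    def fresh_ko() -> str:
        counter[0] += 1
        return f"K{counter[0]:05d}"

    catalog = []
    for m in range(config.n_modules):
        n_atoms = int(rng.integers(lo, hi + 1))
        catalog.append(
            _build_module(f"M{m + 1:05d}", n_atoms, config.p_alternative, fresh_ko, rng)
        )
    atoms_used = counter[0]
    if atoms_used > config.n_kos:
        raise ValueError(
            f"infeasible config: {atoms_used} module atoms needed but n_kos={config.n_kos}"
        )
    background = [fresh_ko() for _ in range(config.n_kos - atoms_used)]

    completion_sets = [enumerate_completion_sets(ast) for ast in catalog]
    targets = [
        config.prevalence_targets[m % len(config.prevalence_targets)]
        for m in range(config.n_modules)
    ]

    # intended presence: Bernoulli(p) per (genome, module), repaired so that
    # each module has >=1 positive and >=1 negative
    intended = np.zeros((config.n_genomes, config.n_modules), dtype=np.uint8)
    for m, p in enumerate(targets):
        col = (rng.random(config.n_genomes) < p).astype(np.uint8)
        if col.sum() == 0:
            col[rng.integers(config.n_genomes)] = 1
        elif col.sum() == config.n_genomes:
            col[rng.integers(config.n_genomes)] = 0
        intended[:, m] = col

    genomes = []
    for g in range(config.n_genomes):
        kos: set = set()
        for m, ast in enumerate(catalog):
            sets = completion_sets[m]
            chosen = sets[rng.integers(len(sets))]
            if intended[g, m]:
                kos.update(chosen)
            elif config.partial_negative_rate and rng.random() < config.partial_negative_rate:
                # proper subset missing >=1 KO of the chosen completion set
                members = sorted(chosen)
                n_keep = int(rng.integers(0, len(members)))
                keep = rng.choice(len(members), size=n_keep, replace=False)
                kos.update(members[i] for i in keep)
        if background and config.background_ko_rate > 0:
            mask = rng.random(len(background)) < config.background_ko_rate
            kos.update(b for b, keep in zip(background, mask) if keep)
        genomes.append(GenomeAnnotation(genome_id=f"G{g + 1:05d}", kos=frozenset(kos)))

    labels = label_modules(genomes, catalog)
    if not np.array_equal(labels.labels, intended):
        raise AssertionError("generated labels disagree with intended assignment")
    return SyntheticWorld(catalog=catalog, genomes=genomes, labels=labels, config=config)


# ---------------------------------------------------------------------------
# Random definition ASTs (for fuzzing the module-evaluation engine)
# ---------------------------------------------------------------------------

def random_module_ast(
    rng: np.random.Generator,
    module_id: str = "Mrand",
    max_atoms: int = 12,
    ko_pool: int | None = None,
    p_optional: float = 0.1,
    p_wildcard: float = 0.05,
) -> ModuleAST:
    """A random definition AST with at most ``max_atoms`` atoms, drawing
    KOs from a pool (with replacement, so branches may share KOs).  Used
    to fuzz-test evaluation against brute-force enumeration."""
    pool = ko_pool if ko_pool is not None else max_atoms
    budget = [int(rng.integers(1, max_atoms + 1))]

    def ko() -> Atom:
        budget[0] -= 1
        return Atom(f"K{int(rng.integers(1, pool + 1)):05d}")

    def expr(depth: int):
        if budget[0] <= 0:
            return None
        if depth > 0 and rng.random() < p_optional:
            return Optional(ko())  # optionals wrap single atoms
        if budget[0] >= 2 and depth < 3:
            kind = rng.random()
            if kind < 0.35:
                n = int(rng.integers(2, min(budget[0], 3) + 1))
                opts = [e for e in (expr(depth + 1) for _ in range(n)) if e is not None]
                if len(opts) >= 2:
                    flat = []
                    for o in opts:
                        flat.extend(o.options) if isinstance(o, AnyOf) else flat.append(o)
                    return AnyOf(tuple(flat))
                return opts[0] if opts else None
            if kind < 0.55:
                n = int(rng.integers(2, min(budget[0], 3) + 1))
                parts = [e for e in (expr(depth + 1) for _ in range(n)) if e is not None]
                if len(parts) >= 2:
                    return Complex(tuple(parts))
                return parts[0] if parts else None
            if kind < 0.70:
                n = int(rng.integers(2, min(budget[0], 3) + 1))
                parts = [e for e in (expr(depth + 1) for _ in range(n)) if e is not None]
                if len(parts) >= 2:
                    return AllOf(tuple(parts))
                return parts[0] if parts else None
        return ko()

    steps: list = []
    while budget[0] > 0:
        if rng.random() < p_wildcard:
            steps.append(Wildcard())
            budget[0] -= 1
            continue
        e = expr(0)
        if e is None:
            break
        # a bare Optional step would make the step trivially satisfied;
        # keep those but ensure at least one non-optional step exists
        steps.append(e)
    if not steps or all(isinstance(s, (Optional, Wildcard)) for s in steps):
        steps.append(Atom(f"K{int(rng.integers(1, pool + 1)):05d}"))
    return ModuleAST(module_id=module_id, steps=tuple(steps))


# ---------------------------------------------------------------------------
# Downsampling
# ---------------------------------------------------------------------------

def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _child_seed(master_seed: int, genome_id: str, retain: float) -> int:
    """Stable per-(genome, fraction) seed, independent of iteration order."""
    key = f"{master_seed}:{genome_id}:{retain:.6f}".encode()
    return int.from_bytes(hashlib.blake2s(key, digest_size=4).digest(), "big") % (2**31)


def downsample_annotation(
    genome: GenomeAnnotation, retain: float, seed: int
) -> GenomeAnnotation:
    """Randomly retain ``round(retain * |kos|)`` KOs (half-up rounding),
    sampled uniformly without replacement.  ``retain=1`` is the identity;
    an empty genome stays empty."""
    if not (0 < retain <= 1):
        raise ValueError("retain must lie in (0, 1]")
    if retain == 1 or not genome.kos:
        return genome
    members = sorted(genome.kos)
    n_keep = _round_half_up(retain * len(members))
    rng = np.random.default_rng(seed)
    keep_idx = rng.choice(len(members), size=n_keep, replace=False)
    return GenomeAnnotation(
        genome_id=genome.genome_id,
        kos=frozenset(members[i] for i in keep_idx),
    )


def expand_with_downsampled(
    genomes: Sequence[GenomeAnnotation],
    labels: LabelMatrix,
    scheme: DownsampleScheme,
) -> tuple:
    """Append downsampled variants of every genome at every retention
    fraction; each variant inherits its complete genome's label row.

    Output size is ``len(genomes) * (1 + len(retain_fractions))``.
    """
    if [g.genome_id for g in genomes] != list(labels.genome_ids):
        raise ValueError("labels must be computed on the complete genomes, in order")
    out_genomes = list(genomes)
    rows = [labels.labels]
    for retain in scheme.retain_fractions:
        retain_rows = np.empty_like(labels.labels)
        for i, g in enumerate(genomes):
            seed = _child_seed(scheme.seed, g.genome_id, retain)
            down = downsample_annotation(g, retain, seed)
            out_genomes.append(
                GenomeAnnotation(
                    genome_id=f"{g.genome_id}__r{int(round(retain * 100))}",
                    kos=down.kos,
                )
            )
            retain_rows[i] = labels.labels[i]
        rows.append(retain_rows)
    expanded = LabelMatrix(
        genome_ids=[g.genome_id for g in out_genomes],
        module_ids=list(labels.module_ids),
        labels=np.concatenate(rows, axis=0),
    )
    return out_genomes, expanded
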