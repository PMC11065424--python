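# Methods

## Problem setting

A bacterial genome is represented by the set of KO (KEGG Ortholog)
identifiers assigned to its genes.  A KEGG module is present in a
genome when the genome's KO set satisfies every ordered step of the
module's boolean definition.  Incomplete genomes (MAGs, SAGs, drafts)
lose annotations roughly at random, so truly present modules appear
incomplete.  The package (1) decides completeness exactly from the
definition, (2) learns to predict presence of incomplete modules from
genome-wide KO presence/absence patterns, and (3) proposes minimal
gap-filling KO sets.

## Module definition grammar and evaluation

Definition strings are parsed by a recursive-descent parser with the
precedence (loosest to tightest): whitespace (step conjunction), `,`
(alternatives), `+`/`-` (complex subunits / optional members), with
parentheses grouping arbitrarily.  `-` before an atom or group marks a
non-essential component; a bare `--` is a wildcard step.  Two
conventions the published module collection leaves implicit are made
explicit here and are deliberate choices: optional components and
wildcard steps never count against completeness (both are treated as
satisfied), and a parenthesised group at the top level is one step even
when it is internally a conjunction.  The serializer is a true inverse
of the parser (parenthesising exactly where a child binds looser than
its context); round-tripping is fuzz-tested over randomly generated
ASTs.

*Completion sets* are enumerated by distributing alternatives through
conjunctions, deduplicating, and pruning strict supersets (a superset
can never be needed for a presence decision or a minimal remainder).
Enumeration is capped (default 10,000 branch choices) because real
definitions can explode combinatorially; past the cap, evaluation uses
AST recursion: satisfiability is exact (monotone boolean formula), and
the missing-KO remainder is computed per branch and unioned, which is
minimal whenever branch KO sets do not overlap and sound (adding it
always completes the module) in general.  Below the cap the remainder
is globally minimal by exhaustive search over completion sets, with
ties broken on the lexicographically smallest sorted KO tuple so
results are deterministic.

*Completeness* is the fraction of top-level steps satisfied; nested
sub-expressions do not contribute fractionally.  Gap-filling returns
exactly the evaluation's missing-KO remainder.

## Feature and label matrices

Features are genome × KO presence/absence bits over a fixed,
lexicographically sorted KO universe chosen at training time; KOs
outside the universe are dropped with a logged count (never appended,
so the input-layer width is stable).  Copy number is deliberately
ignored — features are presence only.  Labels are genome × module bits
computed by the evaluation engine.  Supported annotation dialects:
KofamScan detail output (only rows flagged `*`, i.e. above the HMM's
adaptive score threshold), KofamScan mapper / KOALA two-column TSVs,
and plain KO lists.

## Synthetic worlds

The generator builds a closed world where labels are a deterministic
boolean function of KO sets — the same property the labelling rule
assumes of real genomes.  Defaults (600 genomes, 12 modules of 3–6
atoms, 35% alternative steps, 170-KO universe, background KO rate 0.3,
prevalence targets cycling through
{0.5, 0.3, 0.7, 0.05, 0.95, 0.2, 0.8, 0.15, 0.85, 0.08}) were chosen
once to span balanced and imbalanced module prevalences around a
realistic mean positive-class fraction (~0.35 of targets lie outside
[0.1, 0.9]), with enough background KOs that the classifiers can
exploit genome-wide context.  Positives carry one full completion set
(random branch); half of the negatives carry a *proper subset* of a
completion set, mimicking the partially-annotated absent modules that
make naive rules fail; background KOs are added independently.  A
repair pass guarantees both classes per module, and generation asserts
that recomputed labels equal the intended assignment.

Downsampling retains `round(retain · |KOs|)` KOs (half-up rounding)
uniformly without replacement, at the distinct-KO level (not gene
copies).  Expansion appends one variant per retention fraction
(default 0.1–0.9 in steps of 0.1), each inheriting the complete
genome's label row verbatim.  Per-(genome, fraction) seeds are derived
from the master seed by hashing, so results are independent of
iteration order.

What the world does *not* emulate: taxonomic correlation structure,
gene copy number, annotation false positives, shared KOs between
modules (module atom sets are disjoint by construction), or read-level
incompleteness.  Passing tests therefore demonstrate that the pipeline
recovers a deterministic labelling rule under random annotation loss —
not field performance on real genomes.

## Classifiers

Two multi-label feed-forward networks partition the retained modules by
training prevalence: balanced ([0.10, 0.90], bounds inclusive) and
imbalanced (outside).  Modules with fewer positives than the inclusion
floor (a count parameter, default 1% of complete genomes when used at
scale) are excluded.  The networks are plain numpy: ReLU hidden layers,
sigmoid outputs, mean binary cross-entropy, Adam (lr 0.001), He-uniform
initialisation, inverted dropout (10%) on all layers except the output,
and L2 decay (1e-4) on hidden-side weights.  Training uses a seeded
stratified 80/20 train/validation split and early stopping on
validation loss (restoring the best weights); a non-finite loss aborts
with a diagnostic.  Training is bit-reproducible from the seed.

Reference-scale defaults are five 2048-unit hidden layers; the
desk-scale workflow uses two 512-unit layers trained up to 200 epochs
(batch 128, patience 25), which recovers the synthetic labelling rule
to per-module F1 ≥ 0.95 on held-out complete genomes in well under a
minute.  Epochs, batch size, patience, L2 strength and the decision
threshold (0.5, inclusive ≥) are not dictated by the architecture and
are configurable.

Multi-label train/test splitting uses greedy iterative stratification:
repeatedly take the label with the fewest unassigned positives and deal
its rows to the split whose positive quota for that label is most
unfilled, with hard overall size budgets so the test split has exactly
`round(n · test_fraction)` rows; label-free rows are dealt by size
need.  All-zero label columns simply contribute nothing.

Prediction is reconstruct-then-predict: complete modules bypass the
network with probability 1.0 (so a reconstructed module can never be
called absent); incomplete modules get their partition model's sigmoid
probability, and gap-filling KOs are attached only to
predicted-present modules.  Incomplete modules excluded at training
time are reported absent with probability 0.0.

## Baselines and evaluation

The proportional rule calls a module present iff the fraction of its
genes retained is at least the overall retention fraction; the
denominator defaults to the module atoms present in the complete genome
(oracle knowledge granted to the benchmark), with the all-atoms variant
behind a flag.  The unique-gene rule calls a module present iff the
genome carries a KO found in no other catalog module.  Both exclude
optional atoms.

Metrics follow the standard confusion-matrix definitions; PPV/NPV are
stated in their Bayes forms and verified (fuzz, 1e-12) to equal the
count forms.  Undefined metrics (zero denominators) are NA, never
zero, and are excluded from macro-means with a logged count —
zero-filling would bias means downward.  The benchmark harness
downsamples each test genome per fraction with order-independent
seeds, scores each pluggable classifier per module against the
complete genome's labels, and emits the tidy five-column table
(per-module rows plus unweighted macro-mean aggregates; micro-pooled
rows behind a flag, since the macro/micro choice is a genuine
ambiguity).  Classifier exceptions become error rows; the harness
continues.

## Numerical and degenerate-input choices

- Sigmoid inputs are clipped to ±30 and probabilities to [1e-7, 1-1e-7]
  inside the loss, preventing overflow without affecting decisions.
- Empty genomes are legal everywhere (downsampling returns them
  unchanged; evaluation counts only optional/wildcard steps satisfied).
- Missing-KO tie-breaks, completion-set ordering (size, then
  lexicographic) and split assignment are all deterministic given
  seeds; repeated runs are byte-identical.
- Weights are float32; at desk scale this halves memory with no
  observable effect on decisions.

## Known limitations

- The per-branch remainder fallback above the enumeration cap can
  return a non-minimal (though always sound) gap-fill when alternatives
  share KOs.
- The numpy networks are single-threaded and CPU-bound; the
  reference-scale architecture (5×2048 on an 8,853-KO universe) is
  supported but slow to train here — the package targets desk-scale
  studies and method development, not production retraining at corpus
  scale.
- Prevalence partitioning uses the complete-genome label matrix; if
  given the expanded matrix instead, prevalences are unchanged by
  construction (variants inherit labels), but the inclusion floor then
  counts variants as observations.
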