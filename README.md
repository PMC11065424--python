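# modcast

Reconstruct KEGG metabolic modules from KO gene annotations of
(possibly incomplete) bacterial genomes, predict whether incomplete
modules are nonetheless present using a pair of multi-label neural
classifiers, and suggest the missing KOs that would complete them.

## Who this is for

Environmental microbiologists working with metagenome-assembled genomes
(MAGs), single-amplified genomes (SAGs), or draft isolate genomes.  Such
genomes are routinely incomplete: genes are lost to low coverage,
assembly breaks and annotation misses, so a metabolic module that the
organism truly encodes may be only partially visible in its KO
annotation set.  Presence/absence calls based on module completeness
cutoffs systematically under-call metabolism in these genomes; a
classifier trained on artificially degraded genomes can do much better.

## The model

A **KEGG module** is an ordered series of reaction steps, each a boolean
expression over KO (KEGG Ortholog) identifiers.  In a definition string,
whitespace separates steps (AND), `,` separates alternatives (OR), `+`
joins the subunits of a complex (AND), `-` prefixes a non-essential
component, `--` is a wildcard step, and parentheses group.  A module is
**complete** in a genome iff at least one *completion set* — one choice
of KOs satisfying every step — is contained in the genome's KO set.

For incomplete modules the package trains two feed-forward networks on
genome × KO presence/absence matrices:

- architecture: dense ReLU hidden layers, sigmoid output per module,
  binary cross-entropy loss, Adam (lr 0.001), He-uniform initialisation,
  10% dropout on all layers except the output, L2 weight decay;
- one network for **balanced** modules (prevalence within [0.10, 0.90]
  across training genomes), one for **imbalanced** modules (outside that
  band); together they cover every retained module exactly once;
- training data are complete genomes plus downsampled variants retaining
  10–90% of each genome's KOs, all carrying the complete genome's
  labels; splits use multi-label iterative stratification.

At prediction time, modules the genome already completes bypass the
network (probability 1.0); incomplete modules get a sigmoid probability,
and those at or above the decision threshold (default 0.5) are reported
present together with the minimal gap-filling KO set.

Two naive benchmark rules are included: the *proportional* rule (module
present iff its retained gene fraction ≥ overall retention) and the
*unique-gene* rule (present iff any KO unique to the module is
observed).

## Worked example

The whole loop runs on synthetic data — no downloads:

```bash
modcast simulate --out-dir world --n-genomes 300 --n-modules 12 \
    --n-kos 170 --seed 7 --expand
modcast train --features world/features.tsv --labels world/labels.tsv \
    --out pair.zip --hidden-layers 2 --hidden-units 256 --epochs 60 \
    --batch-size 128 --seed 7
modcast predict world/annotations/G00001__r50.txt --model pair.zip \
    --catalog world/catalog.tsv --format kolist --out predictions.tsv
```

The input here is the 50%-downsampled variant of genome G00001, whose
complete version contains modules M00005, M00006, M00007, M00009 and
M00012.  `predictions.tsv` holds one row per module (excerpt):

```
genome_id    module_id  status             probability  completeness  missing_kos
G00001__r50  M00004     predicted_absent   0.000004     0.000000
G00001__r50  M00005     predicted_present  0.999978     0.500000      K00021;K00023
G00001__r50  M00006     predicted_present  0.766597     0.250000      K00025;K00026;K00027
G00001__r50  M00012     predicted_present  0.887584     0.500000      K00057
```

Read: with half the annotations deleted no module is fully
reconstructable, but the classifier still calls all five truly-present
modules present (and only those), and for each one lists the missing
KOs that would complete it — e.g. adding `K00057` completes M00012.

The same objects are available from Python
(`modcast.generate_world`, `modcast.train_model_pair`,
`modcast.predict_modules`, `modcast.benchmark`), and
`modcast evaluate` writes the tidy benchmark table
(Module name / Percent of protein families retained / Model type /
Metric / Score).

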