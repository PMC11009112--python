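# lepkaryo

Comparative karyotype analysis for Lepidoptera-like clades: infer
ancestral linkage groups ("Merian elements") from per-species orthologue
location tables on a phylogeny, paint extant chromosomes by ancestral
element, detect and phylogenetically place chromosome fusion and fission
events, and test where fusions happen — plus a synthetic
karyotype-evolution simulator that validates every stage against a known
ground truth.

The package is aimed at comparative genomicists working with
chromosome-level assemblies and BUSCO-style single-copy orthologue
tables, in clades where inter-chromosomal rearrangement is rare enough
that linkage groups persist over deep time (Lepidoptera, with its 32
ancestral elements — 31 autosomal plus the Z-linked MZ — is the model
case).

## The core model

A karyotype, ignoring gene order, is a partition of orthologue ids into
chromosomes; a fusion merges two blocks and a fission splits one. The
minimum number of events turning partition *A* into partition *C* on
their shared orthologues is

    d(A, C) = (|A| − c) + (|C| − c),   c = #components of A ∨ C,

where A ∨ C is the partition-lattice join (connected components of the
block-overlap graph): the first term counts fusions, the second fissions.
At each internal node of the species tree the ancestral karyotype is the
median of its two children under this distance, with the sibling clade as
outgroup to break ties (Dollo-leaning). The root partition of the
ingroup, named M1, M2, … by descending orthologue count (MZ for the
sex-linked group), is the ancestral linkage group set. Extant chromosomes
are then painted by these elements; fused and split chromosomes are
called from majority elements in 17-orthologue windows, and calls are
placed on the tree under Dollo parsimony. Branch-length-weighted
permutation tests and rank correlations characterize event placement and
the size bias of fusions.

## Worked example

Simulate a 20-species dataset from a 32-element ancestor with 10 scripted
rearrangements, then recover the elements and the events:

```sh
python analysis/01_simulate_dataset.py
python analysis/02_infer_elements.py
python analysis/03_paint_and_map_events.py
```

which prints:

```
simulated 20 species, 4687 orthologues, 10 true events; outgroup = ['sp18', 'sp19', 'sp20']
root node n1: 32 linkage groups, 4687 orthologues assigned
branch events inferred during the sweep: 10
bootstrap (20 reps, frac 0.5): counts=[32], unanimous=True, assignment consistency=1.000
detected 10 events; true history has 10
kind+branch placements recovered exactly: True
```

Every bootstrap replicate (50% of species, outgroup retained) recovers
the same 32 root linkage groups with no conflicting orthologue
assignments, and the window detector plus Dollo mapping recovers all 10
scripted events with their exact kinds, element sets and branches.
`analysis/04_permutation_tests.py` and `analysis/05_feature_landscapes.py`
continue the narrative: with a planted small-partner bias the per-element
fusion count correlates negatively with element size
(rho(29) = −0.63, P = 1.4e−4), and planted post-fusion homogenization of
repeat density is detected by the paired t-test (p < 1e−10 at 20
fusions).

The same stages are available as a CLI (`lepkaryo simulate`,
`lepkaryo infer-algs`, `lepkaryo find-events`, `lepkaryo run-all`) for
use on real orthologue tables (BUSCO `full_table.tsv` dialect), a rooted
newick tree and a designated outgroup.

See `docs/methods.md` for the model, its assumptions, all tunable
parameters, and what the synthetic validation does and does not
demonstrate.

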