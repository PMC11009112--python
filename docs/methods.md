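# Methods

## Problem setting

Lepidopteran genomes are remarkably conservative at the chromosome level:
most species carry 31 chromosomes descended, via one ancient fusion, from
32 ancestral linkage groups (Merian elements: 31 autosomal elements plus
the Z-linked element MZ). Against this background, occasional end-to-end
fusions, rarer fissions, and a handful of massively reorganized lineages
shape extant karyotypes. `lepkaryo` implements the computational core of
this comparative analysis: inferring the ancestral linkage groups from
orthologue co-occurrence on a phylogeny, painting extant chromosomes by
ancestral element, detecting and placing rearrangement events, and the
statistical tests used to characterize where and how fusions happen.

All inference is order-free: a chromosome is treated as the *set* of
single-copy orthologues it carries. Gene order enters only at the painting
and feature stages (segment structure, breakpoints, synteny score).

## Karyotypes as partitions; the fusion+fission distance

A karyotype is a partition of orthologue ids into chromosomes. A fusion
merges two blocks; a fission splits one block in two. The minimal number
of events transforming partition A into partition C, restricted to their
shared orthologues, has a closed form. An exchange argument shows some
optimal scenario performs all fusions before all fissions, so the
intermediate state is a common coarsening of A and C; the best such
coarsening is the lattice join A ∨ C (connected components of the graph
linking blocks that share an orthologue). Hence

    fusions  = |A| − c(A ∨ C),   fissions = |C| − c(A ∨ C),

with c(·) the number of join components. The closed form is validated in
the test suite against breadth-first search over the explicit move graph.
Orthologues present on only one side are unconstrained by the other, which
is how assembly dropout and duplication are absorbed.

## Ancestral inference (triplet parsimony)

At each internal node the ancestral partition is the median of the two
child partitions under this distance: it minimizes the summed event count
on the two child branches. The median decomposes over connected components
of the children's join (merging across components can never help), and
within a component the search enumerates all set partitions of the
children's meet blocks — exact whenever a component has at most 9 meet
blocks, which covers the sparse-event regime; larger components (only
reachable in heavily reorganized clades) fall back to a small candidate
set (either child's state, the outgroup's, the meet, the join).

Ties between equally parsimonious ancestors are broken in order by
(1) fewer events to the outgroup partition, (2) identity with the
outgroup's restriction (Dollo-leaning), (3) fewer groups, (4) a canonical
sort. The exactness of the component search is validated against
exhaustive search over *all* partitions of the orthologue universe on
random triplet instances.

The tree sweep runs in two stages. Stage 1 moves from tips to root with no
outgroup, producing a preliminary partition at every internal node.
Stage 2 revisits each node in post-order, using the sibling clade's
stage-1 partition as the outgroup; the reported root is the ingroup's most
recent common ancestor, whose outgroup is the reconstruction of the
designated outgroup clade (the caddisfly role in the real analysis). A
literal "sibling's current reconstruction" is circular — each sibling
would need the other first — so the two-stage scheme is this package's
resolution; it reduces to plain parsimony when children agree. Rootward
inference refuses to run without designated outgroup tips. Root groups
smaller than `min_orthologs` (default 5) are reported as unassigned
orthologues rather than elements.

Element naming follows orthologue content: M1, M2, … in strictly
descending count (ties broken by smallest member id), with the group best
overlapping a supplied sex-linked orthologue set labelled MZ and excluded
from numbering.

Stability is assessed by species-subsampling bootstrap: each replicate
keeps a mandatory species set (the outgroup, plus any species needed to
polarize ancient events) and a random half of the rest, then reruns the
sweep. The report gives per-replicate root group counts, the fraction of
orthologues ever assigned to different (maximal-overlap-matched) groups
across replicates, and per-orthologue unassignment frequencies.

## Painting, classification and window-based event calls

Painting labels every Complete orthologue on an extant chromosome by its
root group; unassigned orthologues are retained but invisible to
classification (they cannot create event calls). Chromosome status is:

* **intact** — one element, and that element is nowhere else;
* **fused** — ≥2 elements, each contributing at least the threshold
  (default 17) orthologues, each otherwise whole;
* **fission_fragment** — a single element that majority-paints ≥2
  chromosomes, all fragments unmixed;
* **complex** — anything else (nested histories, sub-threshold fragments).

The window detector scans each chromosome in non-overlapping windows of 17
painted orthologues (a final short remainder merges into the preceding
window so no call rests on fewer than a window of loci) and assigns each
window its majority element; ties take the previous window's label and are
flagged. A chromosome whose windows carry ≥2 elements is a fused call,
with the breakpoint reported as the midpoint of the gap between the last
upstream-element orthologue and the first downstream one (precision is
inherently limited to that orthologue gap). An element that is window
majority on ≥2 chromosomes is a split call. Windows are counted in
orthologues, not bp, so calls are independent of assembly span.

Species-level calls are mapped onto the phylogeny under Dollo parsimony:
for each distinct element combination, every maximal clade whose
(informative) tips all carry the call receives one event on its stem;
independent origins in disjoint clades count separately, and no reversions
are assumed. Species flagged highly rearranged are excluded from mapping
and are the intended input for a rerun of the ancestral sweep at the more
sensitive 5-orthologue threshold.

Karyotype arithmetic is the bookkeeping identity n_child = n_parent −
fusions + fissions, applied per branch and composable along root-to-tip
paths.

## Permutation tests and correlations

*External-branch excess.* Under the null, events land independently on
branches with probability proportional to branch length (substitutions per
site as the time proxy), so the external-branch count is Binomial(n,
p_external); the null is sampled rather than evaluated so the output
carries the same quantiles and percentile machinery as the second test.
Percentile = fraction of null samples strictly below the observed value
plus half the ties, ×100; significance above a configurable cutoff
(default the 99.99th percentile).

*Partition association.* For a focal linkage group, the statistic is the
variance of its orthologue counts across reference groups (e.g. the 24
bilaterian linkage groups); the null draws the same number of orthologues
multinomially with probabilities proportional to reference-group totals
computed from the full shared set. Self-null calibration of both tests at
nominal 0.01 is part of the acceptance suite.

*Correlations.* Spearman's tie-corrected rho with two-sided p (scipy),
cross-checked in tests against the explicit rank-covariance formula. The
feature-vs-length scan applies the filtering rules: autosomes only,
intact-element chromosomes only, species skipped below 10 qualifying
chromosomes. No multiple-testing correction is applied across species,
matching the analysis this reproduces; outputs flag this.

*Repeat amelioration.* For two-segment fused chromosomes, per fusion
Δ_small = (small-segment repeat density) − (mean density of that element
where it is intact across species), likewise Δ_large; a two-sided paired
t-test on Δ_small − Δ_large asks whether the smaller partner has drifted
further from its unfused state. Ancestral densities weight species
equally.

## The synthetic generator

The simulator provides the study conditions all validation runs use:

* **Tree** — pure-birth with unit-rate exponential waiting times, branch
  lengths rescaled to mean 0.05 substitutions/site.
* **Ancestral genome** — 32 elements by default; autosomal orthologue
  counts interpolate the observed extremes (273 down to 19) and the sex
  element carries 161, giving ~4,700 orthologues. Spacing 100 kb per
  orthologue (configurable, with optional jitter).
* **Events** — per-branch Poisson counts (rate × branch length), or an
  explicit script. Fusions join two chromosomes end-to-end in one of the
  four orientations uniformly, preserving internal order; the second
  partner is drawn with weight ∝ length^(−β) (β = 0 uniform; β > 0
  reproduces the small-element bias for power studies). Fissions split at
  a uniform internal orthologue boundary; the sex element can be declared
  fission-protected. The scripted generator used by the validation runs
  draws at most N simple events (each element participates at most once,
  fission fragments keep ≥ 17 orthologues) on branches below the ingroup
  root subtending at most a third of the ingroup tips — mirroring the
  observed predominance of species-specific events and keeping the
  ingroup-root state identifiable under species subsampling.
* **Noise** — per-orthologue dropout and duplication at tips only
  (missingness is an assembly/annotation property, not an ancestral one),
  plus adjacent-transposition shuffling of gene order.
* **Truth log** — every event records its branch and the participating
  orthologue sets, making the log exactly replayable even through nested
  events; replay equality with the simulated tips is asserted in tests.
* **Feature tracks** — per-window repeat fraction and GC of the form
  clip(base + slope/length_Mb + end_enrichment × proximity + noise), with
  proximity 1 at chromosome ends and 0 at the centre; the BED track
  realizes each window's fraction exactly, and optional synthetic
  sequence realizes each window's GC to within one base.

What the generator does **not** emulate: real gene-length and spacing
heterogeneity, inversions and translocations, assembly-specific artefacts
(unlocalized scaffolds, haplotypic duplication), repeat-family structure,
and any sequence-level evolution. Passing validation therefore
demonstrates correctness of the inference machinery under the stated
model, not robustness to every failure mode of real assemblies.

## Problem sizes used in validation

The acceptance suite runs: the bootstrap-stability check at full study
design scale (32 elements, ~4,700 orthologues, 20 tips, 10 events, 20
replicates at 50% sampling); event-recovery over 100 simulations at 20
tips with 12 elements of 40–90 orthologues and ≤6 events each; parsimony
exactness on 200 random triplets over ≤8 orthologues (where exhaustive
search over all partitions is feasible); permutation-test calibration over
10,000 self-null repetitions with 2,000 null draws each; and 50 random
per-base brute-force instances for the coverage and GC3 oracles.

## Known limitations

* The component-enumeration fallback for very large join components is
  heuristic; heavily reorganized clades (the Lysandra/Pierini regime) may
  receive locally suboptimal ancestors there, which is why such species
  are flagged and excluded from simple event mapping.
* Polytomies are resolved by folding children pairwise in input order.
* Fusions of three or more elements are reported as one k-element event;
  no pairwise decomposition is attempted.
* Fragmented orthologues are treated like Duplicated ones: retained in
  tables, excluded from inference and painting.
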