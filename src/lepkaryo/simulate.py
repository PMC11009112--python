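"""Synthetic karyotype-evolution generator.

Emulates the study design the analysis assumes: a set of ~32 ancestral
linkage groups with unequal orthologue counts (273 down to 19 autosomal,
a 161-orthologue sex element), evolving along a rooted tree by end-to-end
fusion and by fission, with optional size-biased fusion partner choice,
a fission-protected sex element, orthologue dropout/duplication noise,
adjacent-transposition gene-order shuffling, and length-dependent
GC/repeat feature tracks.  Every run returns a ground-truth event log
whose replay reproduces the (pre-noise) tip karyotypes exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import dendropy
import numpy as np

from .io_formats import GenomeTable, IntervalTrack, OrthologRecord

# Default orthologue spacing along simulated chromosomes (bp).
DEFAULT_SPACING_BP = 100_000

# Ancestral element orthologue counts bracketing the observed range:
# 31 autosomal elements from 273 down to 19, plus a 161-orthologue
# sex element.
PAPER_AUTOSOME_EXTREMES = (273, 19)
PAPER_SEX_COUNT = 161


def paper_like_counts(n_autosomes: int = 31,
                      extremes: Tuple[int, int] = PAPER_AUTOSOME_EXTREMES,
                      sex_count: int = PAPER_SEX_COUNT) -> List[int]:
    """Autosome counts linearly interpolated between the observed extremes,
    with the sex-element count appended last."""
    hi, lo = extremes
    if n_autosomes == 1:
        counts = [hi]
    else:
        counts = [round(hi + (lo - hi) * i / (n_autosomes - 1))
                  for i in range(n_autosomes)]
    return counts + [sex_count]


@dataclass(frozen=True)
class EvolutionParams:
    """Rates are per unit branch length; probabilities per orthologue."""

    fusion_rate: float = 0.0
    fission_rate: float = 0.0
    fusion_size_bias_beta: float = 0.0  # partner weight ~ length^(-beta)
    z_fission_protected: bool = True
    shuffle_rate: float = 0.0  # expected adjacent transpositions per orthologue
    p_missing: float = 0.0
    p_duplicated: float = 0.0
    spacing_bp: int = DEFAULT_SPACING_BP
    spacing_jitter: float = 0.0  # fractional jitter on spacing
    seed: int = 0

    def __post_init__(self):
        for name in ("fusion_rate", "fission_rate"):
            if getattr(self, name) < 0 or not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite and >= 0")
        for name in ("p_missing", "p_duplicated"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass(frozen=True)
class FeatureModel:
    gc_base: float = 0.35
    gc_length_slope: float = 0.0  # added as slope / length_Mb
    repeat_base: float = 0.25
    repeat_length_slope: float = 0.0
    end_enrichment: float = 0.0  # added * proximity to chromosome end
    noise_sd: float = 0.0


@dataclass(frozen=True)
class TruthEntry:
    branch_id: str  # id of the child node of the branch
    kind: str  # "fusion" | "fission"
    elements: Tuple[str, ...]  # ancestral element labels involved
    breakpoint_index: Optional[int] = None  # orthologue index for fissions
    # participating orthologue sets: the two pre-event chromosomes for a
    # fusion, or the two post-event fragments for a fission.  These make the
    # log exactly replayable even through nested events.
    blocks: Tuple[frozenset, ...] = ()


@dataclass
class TruthLog:
    entries: List[TruthEntry] = field(default_factory=list)

    def events_on(self, branch_id: str) -> List[TruthEntry]:
        return [e for e in self.entries if e.branch_id == branch_id]


@dataclass
class Chromosome:
    """Ordered orthologues plus the ancestral elements they derive from."""

    orthologs: List[str]
    elements: Tuple[str, ...]  # element labels in join order

    def copy(self) -> "Chromosome":
        return Chromosome(list(self.orthologs), tuple(self.elements))


@dataclass
class AncestralGenome:
    """elements: ordered (label, ortholog ids, length_bp)."""

    elements: List[Tuple[str, List[str], int]]
    sex_element: Optional[str] = None

    @property
    def labels(self) -> List[str]:
        return [label for label, _, _ in self.elements]

    def chromosomes(self) -> List[Chromosome]:
        return [Chromosome(list(ids), (label,)) for label, ids, _ in self.elements]

    def partition(self) -> Dict[str, frozenset]:
        return {label: frozenset(ids) for label, ids, _ in self.elements}

    def element_of(self) -> Dict[str, str]:
        out = {}
        for label, ids, _ in self.elements:
            for oid in ids:
                out[oid] = label
        return out


def simulate_tree(n_tips: int, seed: int, mean_branch_length: float = 0.05,
                  prefix: str = "sp") -> dendropy.Tree:
    """Pure-birth (Yule) tree with unit-rate exponential waiting times,
    branch lengths rescaled to the requested mean.  Deterministic in seed."""
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    rng = np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.is_rooted = True
    left = dendropy.Node()
    right = dendropy.Node()
    tree.seed_node.add_child(left)
    tree.seed_node.add_child(right)
    tips = [left, right]
    depth = {left: 0.0, right: 0.0}
    t = 0.0
    while len(tips) < n_tips:
        t += rng.exponential(1.0 / len(tips))
        idx = rng.integers(len(tips))
        node = tips[idx]
        node.edge.length = t - depth[node]
        a, b = dendropy.Node(), dendropy.Node()
        node.add_child(a)
        node.add_child(b)
        depth[a] = depth[b] = t
        tips[idx] = a
        tips.append(b)
    t += rng.exponential(1.0 / len(tips))
    for node in tips:
        node.edge.length = t - depth[node]
    # label tips in a stable order, internal nodes in preorder
    for i, leaf in enumerate(tree.leaf_node_iter(), 1):
        leaf.taxon = taxa.new_taxon(label=f"{prefix}{i}")
    n_internal = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            node.label = node.taxon.label
        else:
            n_internal += 1
            node.label = f"n{n_internal}"
    lengths = [e.length for e in tree.preorder_edge_iter() if e.length is not None]
    scale = mean_branch_length / (sum(lengths) / len(lengths)) if sum(lengths) else 1.0
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= scale
    return tree


def simulate_ancestral_genome(n_elements: int = 32,
                              counts: Optional[Sequence[int]] = None,
                              seed: int = 0,
                              sex_index: Optional[int] = None,
                              bp_per_ortholog: int = DEFAULT_SPACING_BP) -> AncestralGenome:
    """Build the ancestral genome.  ``counts[i]`` orthologues per element;
    ``sex_index`` marks the sex element (default: last entry when using the
    default counts, else None).  Elements are named M1.. in descending
    count order with the sex element labelled MZ."""
    if counts is None:
        if n_elements == 32:
            counts = paper_like_counts()
            if sex_index is None:
                sex_index = len(counts) - 1
        else:
            hi, lo = PAPER_AUTOSOME_EXTREMES
            counts = [round(hi + (lo - hi) * i / max(n_elements - 1, 1))
                      for i in range(n_elements)]
    counts = list(counts)
    if len(counts) != n_elements:
        raise ValueError("counts length must equal n_elements")
    if any(c < 1 for c in counts):
        raise ValueError("all counts must be >= 1")
    order = sorted(range(n_elements),
                   key=lambda i: (-counts[i], i))
    labels = [""] * n_elements
    rank = 1
    for i in order:
        if sex_index is not None and i == sex_index:
            labels[i] = "MZ"
        else:
            labels[i] = f"M{rank}"
            rank += 1
    next_id = 1
    elements = []
    for i in range(n_elements):
        ids = [f"og{next_id + j:05d}" for j in range(counts[i])]
        next_id += counts[i]
        elements.append((labels[i], ids, counts[i] * bp_per_ortholog))
    sex_label = labels[sex_index] if sex_index is not None else None
    return AncestralGenome(elements, sex_element=sex_label)


# ---------------------------------------------------------------------------
# evolution along the tree


def _apply_fusion(chroms: List[Chromosome], i: int, j: int,
                  rng: np.random.Generator) -> Chromosome:
    """End-to-end join of chromosomes i and j, one of the four orientations
    uniformly; internal gene order of each part preserved (up to reversal)."""
    a, b = chroms[i].copy(), chroms[j].copy()
    if rng.random() < 0.5:
        a.orthologs.reverse()
        a = Chromosome(a.orthologs, tuple(reversed(a.elements)))
    if rng.random() < 0.5:
        b.orthologs.reverse()
        b = Chromosome(b.orthologs, tuple(reversed(b.elements)))
    return Chromosome(a.orthologs + b.orthologs, a.elements + b.elements)


def _do_fusion(chroms: List[Chromosome], i: int, j: int,
               rng: np.random.Generator) -> None:
    fused = _apply_fusion(chroms, i, j, rng)
    for idx in sorted((i, j), reverse=True):
        chroms.pop(idx)
    chroms.append(fused)


def _do_fission(chroms: List[Chromosome], idx: int, cut: int,
                left_labels: Tuple[str, ...],
                right_labels: Tuple[str, ...]) -> None:
    chrom = chroms.pop(idx)
    chroms.append(Chromosome(chrom.orthologs[:cut], left_labels))
    chroms.append(Chromosome(chrom.orthologs[cut:], right_labels))


def _fission_partition_labels(chrom: Chromosome, cut: int,
                              element_of: Dict[str, str]) -> Tuple[Tuple[str, ...], Tuple[str, ...]]:
    left = tuple(dict.fromkeys(element_of[o] for o in chrom.orthologs[:cut]))
    right = tuple(dict.fromkeys(element_of[o] for o in chrom.orthologs[cut:]))
    return left, right


def evolve_genomes(tree: dendropy.Tree, ancestor: AncestralGenome,
                   params: EvolutionParams,
                   script: Optional[Dict[str, List[Tuple]]] = None,
                   ) -> Tuple[Dict[str, GenomeTable], TruthLog]:
    """Evolve the ancestral karyotype along ``tree``.

    Without ``script``, per-branch fusion and fission counts are Poisson
    with mean rate x branch length.  With ``script``, the given events are
    applied instead: a mapping branch_id (child-node label) -> list of
    ("fusion", label_a, label_b) or ("fission", label, cut_index) entries,
    where labels are ancestral element labels and cut_index is the
    orthologue offset within that element's current chromosome.

    Returns per-tip GenomeTables (with coordinates, noise applied at tips)
    and the TruthLog.
    """
    if not ancestor.elements:
        raise ValueError("ancestor is empty")
    rng = np.random.default_rng(params.seed)
    element_of = ancestor.element_of()
    truth = TruthLog()
    states: Dict[dendropy.Node, List[Chromosome]] = {
        tree.seed_node: ancestor.chromosomes()}
    tables: Dict[str, GenomeTable] = {}

    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            pass
        else:
            parent_state = states[node.parent_node]
            chroms = [c.copy() for c in parent_state]
            branch_id = node.label or (node.taxon.label if node.taxon else "")
            bl = node.edge.length or 0.0
            if script is not None:
                for entry in script.get(branch_id, []):
                    _apply_scripted(chroms, entry, element_of, rng, truth, branch_id)
            else:
                n_fus = rng.poisson(params.fusion_rate * bl)
                n_fis = rng.poisson(params.fission_rate * bl)
                ops = ["fusion"] * int(n_fus) + ["fission"] * int(n_fis)
                rng.shuffle(ops)
                for op in ops:
                    if op == "fusion":
                        if len(chroms) < 2:
                            continue
                        i = int(rng.integers(len(chroms)))
                        weights = np.array(
                            [len(c.orthologs) ** (-params.fusion_size_bias_beta)
                             if k != i else 0.0
                             for k, c in enumerate(chroms)])
                        j = int(rng.choice(len(chroms), p=weights / weights.sum()))
                        labels = chroms[i].elements + chroms[j].elements
                        blocks = (frozenset(chroms[i].orthologs),
                                  frozenset(chroms[j].orthologs))
                        _do_fusion(chroms, i, j, rng)
                        truth.entries.append(TruthEntry(
                            branch_id, "fusion", labels, blocks=blocks))
                    else:
                        eligible = [k for k, c in enumerate(chroms)
                                    if len(c.orthologs) >= 2 and not (
                                        params.z_fission_protected
                                        and ancestor.sex_element is not None
                                        and ancestor.sex_element in c.elements)]
                        if not eligible:
                            continue
                        idx = int(rng.choice(eligible))
                        cut = int(rng.integers(1, len(chroms[idx].orthologs)))
                        left, right = _fission_partition_labels(
                            chroms[idx], cut, element_of)
                        truth.entries.append(TruthEntry(
                            branch_id, "fission", left + right,
                            breakpoint_index=cut,
                            blocks=(frozenset(chroms[idx].orthologs[:cut]),
                                    frozenset(chroms[idx].orthologs[cut:]))))
                        _do_fission(chroms, idx, cut, left, right)
            states[node] = chroms
        if node.is_leaf():
            species = node.taxon.label
            tables[species] = _to_genome_table(
                species, states[node], params, rng)
    return tables, truth


def _apply_scripted(chroms: List[Chromosome], entry: Tuple,
                    element_of: Dict[str, str], rng: np.random.Generator,
                    truth: TruthLog, branch_id: str) -> None:
    kind = entry[0]
    if kind == "fusion":
        _, la, lb = entry
        i = _chrom_with(chroms, la)
        j = _chrom_with(chroms, lb)
        if i == j:
            raise ValueError(f"{la} and {lb} already share a chromosome")
        labels = chroms[i].elements + chroms[j].elements
        blocks = (frozenset(chroms[i].orthologs), frozenset(chroms[j].orthologs))
        _do_fusion(chroms, i, j, rng)
        truth.entries.append(TruthEntry(branch_id, "fusion", labels, blocks=blocks))
    elif kind == "fission":
        _, label, cut = entry
        idx = _chrom_with(chroms, label)
        chrom = chroms[idx]
        # cut is an offset within the named element's run of orthologues
        positions = [k for k, o in enumerate(chrom.orthologs)
                     if element_of[o] == label]
        cut_abs = positions[0] + cut
        if not 1 <= cut_abs <= len(chrom.orthologs) - 1:
            raise ValueError("fission cut outside chromosome")
        left, right = _fission_partition_labels(chrom, cut_abs, element_of)
        truth.entries.append(TruthEntry(
            branch_id, "fission", left + right, breakpoint_index=cut_abs,
            blocks=(frozenset(chrom.orthologs[:cut_abs]),
                    frozenset(chrom.orthologs[cut_abs:]))))
        _do_fission(chroms, idx, cut_abs, left, right)
    else:
        raise ValueError(f"unknown scripted event kind {kind!r}")


def _chrom_with(chroms: List[Chromosome], label: str) -> int:
    for i, c in enumerate(chroms):
        if label in c.elements:
            return i
    raise ValueError(f"no chromosome carries element {label}")


def _to_genome_table(species: str, chroms: List[Chromosome],
                     params: EvolutionParams, rng: np.random.Generator) -> GenomeTable:
    """Lay orthologues onto bp coordinates and apply tip-level noise."""
    records: List[OrthologRecord] = []
    chrom_lengths: Dict[str, int] = {}
    ordered = sorted(chroms, key=lambda c: -len(c.orthologs))
    for ci, chrom in enumerate(ordered, 1):
        name = f"{species}_chr{ci}"
        order = list(chrom.orthologs)
        if params.shuffle_rate > 0 and len(order) > 1:
            n_swaps = rng.poisson(params.shuffle_rate * len(order))
            for _ in range(int(n_swaps)):
                k = int(rng.integers(len(order) - 1))
                order[k], order[k + 1] = order[k + 1], order[k]
        pos = 0
        gene_len = max(params.spacing_bp // 10, 1)
        for oid in order:
            spacing = params.spacing_bp
            if params.spacing_jitter > 0:
                spacing = max(gene_len + 1, int(spacing * (
                    1 + params.spacing_jitter * rng.standard_normal())))
            start = pos + (spacing - gene_len)
            u = rng.random()
            if u < params.p_missing:
                records.append(OrthologRecord(oid, "Missing"))
            elif u < params.p_missing + params.p_duplicated:
                records.append(OrthologRecord(
                    oid, "Duplicated", name, start, start + gene_len))
            else:
                records.append(OrthologRecord(
                    oid, "Complete", name, start, start + gene_len))
            pos += spacing
        chrom_lengths[name] = pos
    table = GenomeTable(species, records, chrom_lengths)
    table.validate()
    return table


def basal_outgroup(tree: dendropy.Tree, max_tips: int = 3) -> List[str]:
    """Tip labels of a small basal clade: the smaller side of the root
    split, descending into its smaller child while it exceeds ``max_tips``.
    The natural stand-in for a designated outgroup in a simulated tree."""
    node = min(tree.seed_node.child_nodes(),
               key=lambda c: sum(1 for _ in c.leaf_iter()))
    while sum(1 for _ in node.leaf_iter()) > max_tips and not node.is_leaf():
        node = min(node.child_nodes(),
                   key=lambda c: sum(1 for _ in c.leaf_iter()))
    return sorted(l.taxon.label for l in node.leaf_iter())


def random_simple_script(tree: dendropy.Tree, ancestor: AncestralGenome,
                         n_events: int, seed: int,
                         outgroup_tips: Sequence[str] = (),
                         p_fission: float = 0.2,
                         max_clade_frac: float = 1 / 3,
                         min_fragment: int = 17) -> Dict[str, List[Tuple]]:
    """Script at most ``n_events`` simple rearrangements.

    Simple means: each ancestral element participates in at most one event
    across the whole tree, fissions leave at least ``min_fragment``
    orthologues on each side, and events are placed on branches below the
    ingroup root subtending at most ``max_clade_frac`` of the ingroup tips
    (mirroring the observed predominance of shallow, species-specific
    events).  Branch choice is weighted by branch length.
    """
    rng = np.random.default_rng(seed)
    outgroup = set(outgroup_tips)
    ingroup_tips = [l.taxon.label for l in tree.leaf_node_iter()
                    if l.taxon.label not in outgroup]
    max_tips = max(1, int(len(ingroup_tips) * max_clade_frac))
    # place events strictly inside the largest clade disjoint from the
    # outgroup, so the state at the ingroup root stays identifiable
    scope = tree.seed_node
    if outgroup:
        disjoint = [c for c in tree.seed_node.child_nodes()
                    if not ({l.taxon.label for l in c.leaf_iter()} & outgroup)]
        if disjoint:
            scope = max(disjoint, key=lambda c: sum(1 for _ in c.leaf_iter()))
        else:
            scope = tree.mrca(taxon_labels=ingroup_tips)
    candidates, weights = [], []
    for node in scope.preorder_iter():
        if node is scope:
            continue
        n_desc = sum(1 for _ in node.leaf_iter())
        if n_desc <= max_tips and (node.edge.length or 0) > 0:
            candidates.append(node.label or node.taxon.label)
            weights.append(node.edge.length)
    weights = np.asarray(weights) / np.sum(weights)
    free = list(ancestor.labels)
    counts = {label: len(ids) for label, ids, _ in ancestor.elements}
    script: Dict[str, List[Tuple]] = {}
    for _ in range(n_events):
        branch = str(rng.choice(candidates, p=weights))
        fissionable = [l for l in free if counts[l] >= 2 * min_fragment + 2
                       and l != ancestor.sex_element]
        do_fission = rng.random() < p_fission and fissionable
        if do_fission:
            label = str(rng.choice(sorted(fissionable)))
            cut = int(rng.integers(min_fragment, counts[label] - min_fragment))
            script.setdefault(branch, []).append(("fission", label, cut))
            free.remove(label)
        else:
            if len(free) < 2:
                break
            la, lb = rng.choice(sorted(free), size=2, replace=False)
            script.setdefault(branch, []).append(("fusion", str(la), str(lb)))
            free.remove(la)
            free.remove(lb)
    return script


# ---------------------------------------------------------------------------
# feature tracks


def _window_starts(length: int, window_bp: int) -> List[Tuple[int, int]]:
    if window_bp >= length:
        return [(0, length)]
    out = []
    pos = 0
    while pos < length:
        out.append((pos, min(pos + window_bp, length)))
        pos += window_bp
    return out


def planted_fraction(base: float, slope: float, end_enrichment: float,
                     mid: float, length: int, noise: float) -> float:
    """Window feature value: base + slope / length_Mb + end_enrichment *
    proximity + noise, clipped to [0, 1].  Proximity is 1 at chromosome
    ends and 0 at the centre."""
    length_mb = length / 1e6
    proximity = abs(mid - length / 2) / (length / 2)
    return float(np.clip(base + slope / length_mb
                         + end_enrichment * proximity + noise, 0.0, 1.0))


def emit_feature_tracks(tables: Dict[str, GenomeTable], model: FeatureModel,
                        seed: int, window_bp: int = 100_000,
                        with_sequence: bool = False):
    """Per-tip window feature table, repeat BED track and (optionally)
    synthetic sequence realizing the planted per-window GC.

    Returns ``(windows, beds, fastas)`` where ``windows`` maps species to a
    list of dicts (chromosome, start, end, gc, repeat_frac), ``beds`` maps
    species to IntervalTracks whose coverage equals the planted repeat
    fraction per window, and ``fastas`` maps species to {chromosome:
    sequence} (empty unless ``with_sequence``).
    """
    rng = np.random.default_rng(seed)
    windows: Dict[str, List[dict]] = {}
    beds: Dict[str, List[IntervalTrack]] = {}
    fastas: Dict[str, Dict[str, str]] = {}
    for species in sorted(tables):
        table = tables[species]
        rows: List[dict] = []
        tracks: List[IntervalTrack] = []
        seqs: Dict[str, str] = {}
        for chrom in sorted(table.chrom_lengths):
            length = table.chrom_lengths[chrom]
            ivals = []
            chrom_seq: List[str] = []
            for start, end in _window_starts(length, window_bp):
                mid = (start + end) / 2
                rep = planted_fraction(
                    model.repeat_base, model.repeat_length_slope,
                    model.end_enrichment, mid, length,
                    rng.normal(0, model.noise_sd) if model.noise_sd else 0.0)
                gc = planted_fraction(
                    model.gc_base, model.gc_length_slope,
                    model.end_enrichment, mid, length,
                    rng.normal(0, model.noise_sd) if model.noise_sd else 0.0)
                rows.append({"chromosome": chrom, "start": start, "end": end,
                             "gc": gc, "repeat_frac": rep})
                covered = int(round(rep * (end - start)))
                if covered > 0:
                    ivals.append((start, start + covered))
                if with_sequence:
                    n = end - start
                    n_gc = int(round(gc * n))
                    seq = np.empty(n, dtype="<U1")
                    idx = rng.permutation(n)
                    seq[idx[:n_gc]] = np.where(
                        rng.random(n_gc) < 0.5, "G", "C")
                    seq[idx[n_gc:]] = np.where(
                        rng.random(n - n_gc) < 0.5, "A", "T")
                    chrom_seq.append("".join(seq))
            if ivals:
                tracks.append(IntervalTrack(chrom, tuple(ivals), "repeat"))
            if with_sequence:
                seqs[chrom] = "".join(chrom_seq)
        windows[species] = rows
        beds[species] = tracks
        fastas[species] = seqs
    return windows, beds, fastas


class ReplayError(AssertionError):
    pass


def replay(tree: dendropy.Tree, ancestor: AncestralGenome,
           truth: TruthLog) -> Dict[str, List[frozenset]]:
    """Replay the truth log as pure set-partitions (order-free); returns the
    per-tip chromosome partitions.  The recorded orthologue blocks make this
    exact even through nested events; a mismatch between the log and a
    reachable state raises :class:`ReplayError`."""
    states: Dict[dendropy.Node, List[frozenset]] = {
        tree.seed_node: [frozenset(ids) for _, ids, _ in ancestor.elements]}
    by_branch: Dict[str, List[TruthEntry]] = {}
    for e in truth.entries:
        by_branch.setdefault(e.branch_id, []).append(e)
    out: Dict[str, List[frozenset]] = {}
    for node in tree.preorder_node_iter():
        if node is not tree.seed_node:
            branch_id = node.label or (node.taxon.label if node.taxon else "")
            state = list(states[node.parent_node])
            for e in by_branch.get(branch_id, []):
                state = _replay_event(state, e)
            states[node] = state
        if node.is_leaf():
            out[node.taxon.label] = states[node]
    return out


def _replay_event(state: List[frozenset], e: TruthEntry) -> List[frozenset]:
    if e.kind == "fusion":
        a, b = e.blocks
        if a not in state or b not in state:
            raise ReplayError(f"fusion blocks not present on {e.branch_id}")
        return [blk for blk in state if blk not in (a, b)] + [a | b]
    left, right = e.blocks
    whole = left | right
    if whole not in state:
        raise ReplayError(f"fission block not present on {e.branch_id}")
    idx = state.index(whole)
    return state[:idx] + state[idx + 1:] + [left, right]
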