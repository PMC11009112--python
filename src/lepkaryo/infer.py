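"""Ancestral linkage group inference by tips-to-root triplet parsimony.

Each extant genome contributes a partition of orthologue ids into
chromosomes (gene order is deliberately ignored; linkage is co-occurrence).
At every internal node the ancestral partition is the median of its two
children under the fusion+fission distance, with the sibling clade acting
as outgroup to break ties.  The root partition of the ingroup, named by
descending orthologue count, is the set of ancestral linkage groups
("Merian elements" when the ingroup is Lepidoptera).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

import dendropy
import numpy as np

from . import _partition as pt
from .io_formats import GenomeTable

logger = logging.getLogger(__name__)

#: components with more meet-blocks than this fall back to candidate
#: heuristics instead of exhaustive set-partition enumeration
EXACT_COMPONENT_LIMIT = 9


@dataclass(frozen=True)
class InferenceParams:
    min_orthologs: int = 5
    event_threshold: int = 17  # shared with the window-based event finder

    def __post_init__(self):
        if self.min_orthologs < 2:
            raise ValueError("min_orthologs must be >= 2")


@dataclass
class LinkageGroupSet:
    """A partition of orthologue ids into named groups at a tree node."""

    node_id: str
    groups: Dict[str, FrozenSet[str]]
    min_orthologs: int = 5
    below_threshold: Set[str] = field(default_factory=set)

    def partition(self) -> pt.Partition:
        return frozenset(self.groups.values())

    def ortholog_to_group(self) -> Dict[str, str]:
        out = {}
        for label, members in self.groups.items():
            for o in members:
                out[o] = label
        return out

    @property
    def n_groups(self) -> int:
        return len(self.groups)


def cooccurrence_partition(table: GenomeTable,
                           params: InferenceParams = InferenceParams()
                           ) -> LinkageGroupSet:
    """Tip-level partition: one group per chromosome holding its Complete
    orthologues.  Groups below ``min_orthologs`` are flagged, not dropped."""
    by_chrom = table.complete_by_chromosome()
    if not by_chrom:
        warnings.warn(f"{table.species_id}: no Complete records")
    groups = {chrom: frozenset(r.ortholog_id for r in recs)
              for chrom, recs in by_chrom.items()}
    below = {chrom for chrom, members in groups.items()
             if len(members) < params.min_orthologs}
    return LinkageGroupSet(table.species_id, groups,
                           params.min_orthologs, below)


@dataclass(frozen=True)
class BranchEvents:
    """Events inferred on the branch from a node to one child."""

    child_id: str
    fusions: Tuple[FrozenSet[FrozenSet[str]], ...]  # merged ancestor blocks
    fissions: Tuple[FrozenSet[FrozenSet[str]], ...]  # child blocks one split into

    @property
    def n_events(self) -> int:
        nf = sum(len(g) - 1 for g in self.fusions)
        ns = sum(len(g) - 1 for g in self.fissions)
        return nf + ns


def _candidate_scores(candidate: pt.Partition, child: pt.Partition) -> int:
    fu, fi = pt.fusion_fission_distance(candidate, child)
    return fu + fi


def _component_candidates(blocks: List[pt.Block]):
    """All partitions of a component's meet-blocks, each yielding one
    candidate sub-partition of the ancestor."""
    for grouping in pt.set_partitions(blocks):
        yield frozenset(frozenset().union(*cell) for cell in grouping)


def _heuristic_candidates(blocks: List[pt.Block], comp: FrozenSet[str],
                          part_a: pt.Partition, part_b: pt.Partition,
                          outgroup: Optional[pt.Partition]):
    """Fallback for oversized components: restrict to a handful of natural
    candidates (either child's state, the outgroup's, the meet, the join)."""
    cands = [frozenset(blocks),
             frozenset({frozenset().union(*blocks)})]
    for p in (part_a, part_b) + ((outgroup,) if outgroup else ()):
        restricted = pt.restrict(p, comp)
        # coarsen meet-blocks to follow p's grouping
        cells: Dict[int, set] = {}
        index = {}
        for i, blk in enumerate(restricted):
            for x in blk:
                index[x] = i
        for b in blocks:
            key = index.get(next(iter(b)), -1)
            cells.setdefault(key, set()).update(b)
        cands.append(frozenset(frozenset(c) for c in cells.values()))
    seen = set()
    for c in cands:
        if c not in seen:
            seen.add(c)
            yield c


def infer_node(child_a: LinkageGroupSet, child_b: LinkageGroupSet,
               outgroup: Optional[LinkageGroupSet],
               params: InferenceParams = InferenceParams(),
               node_id: str = "node",
               ) -> Tuple[LinkageGroupSet, BranchEvents, BranchEvents]:
    """Median partition of two children under fusion+fission parsimony.

    The ancestral state minimizes the summed event count on the two child
    branches; ties are broken by (1) fewer events to the outgroup, (2)
    identity with the outgroup's restriction, (3) fewer groups, (4) a
    canonical ordering.  The search is exact per connected component of the
    children's join (each component is an independent subproblem: merging
    across components can never reduce the score).
    """
    part_a = child_a.partition()
    part_b = child_b.partition()
    uni_a, uni_b = pt.universe(part_a), pt.universe(part_b)
    shared = uni_a & uni_b
    if len(shared) < params.min_orthologs:
        logger.warning("%s: only %d shared orthologues; unresolved",
                       node_id, len(shared))
        merged = dict(child_a.groups)
        return (LinkageGroupSet(node_id, merged, params.min_orthologs),
                BranchEvents(child_a.node_id, (), ()),
                BranchEvents(child_b.node_id, (), ()))
    universe_all = uni_a | uni_b
    out_part = outgroup.partition() if outgroup is not None else None

    ancestor_blocks: List[pt.Block] = []
    for comp in pt.join_components(part_a, part_b):
        meet = pt.meet_blocks(pt.restrict(part_a, comp),
                              pt.restrict(part_b, comp), frozenset(comp))
        if len(meet) == 1:
            ancestor_blocks.append(meet[0])
            continue
        ra = pt.restrict(part_a, frozenset(comp))
        rb = pt.restrict(part_b, frozenset(comp))
        ro = pt.restrict(out_part, frozenset(comp)) if out_part else None
        if len(meet) <= EXACT_COMPONENT_LIMIT:
            candidates = _component_candidates(meet)
        else:
            candidates = _heuristic_candidates(meet, frozenset(comp),
                                               part_a, part_b, out_part)
        best = None
        for cand in candidates:
            score = _candidate_scores(cand, ra) + _candidate_scores(cand, rb)
            if ro is not None:
                out_score = _candidate_scores(cand, ro)
                identical = 0 if cand == ro else 1
            else:
                out_score, identical = 0, 0
            key = (score, out_score, identical, len(cand),
                   tuple(sorted(tuple(sorted(b)) for b in cand)))
            if best is None or key < best[0]:
                best = (key, cand)
        ancestor_blocks.extend(best[1])

    ancestor_part = frozenset(ancestor_blocks)
    groups = {f"g{i}": blk for i, blk in enumerate(
        sorted(ancestor_part, key=lambda b: (-len(b), sorted(b)[0])))}
    below = {label for label, blk in groups.items()
             if len(blk) < params.min_orthologs}
    anc = LinkageGroupSet(node_id, groups, params.min_orthologs, below)
    ev_a = _branch_events(ancestor_part, part_a, child_a.node_id)
    ev_b = _branch_events(ancestor_part, part_b, child_b.node_id)
    return anc, ev_a, ev_b


def _branch_events(parent: pt.Partition, child: pt.Partition,
                   child_id: str) -> BranchEvents:
    fus, fis = pt.merge_scenario(parent, child)
    return BranchEvents(child_id, tuple(fus), tuple(fis))


# ---------------------------------------------------------------------------
# tree sweep


def _node_children(node) -> List:
    return list(node.child_nodes())


def _node_label(node) -> str:
    if node.is_leaf():
        return node.taxon.label
    return node.label or f"node{id(node)}"


def infer_algs(tables: Dict[str, GenomeTable], tree: dendropy.Tree,
               params: InferenceParams = InferenceParams(),
               outgroup_tips: Sequence[str] = (),
               ) -> Tuple[Dict[str, LinkageGroupSet],
                          Dict[str, BranchEvents], str]:
    """Two-stage tips-to-root sweep.

    Stage 1 computes a preliminary reconstruction at every internal node
    from its children alone.  Stage 2 revisits each node using the
    sibling's preliminary state as outgroup; the ingroup root (the node
    separating the designated outgroup tips from the rest) uses the
    outgroup clade's reconstruction.  Returns (per-node linkage group
    sets, per-branch events keyed by child node id, ingroup root id).

    ``outgroup_tips`` must be non-empty: rootward inference is refused
    without a designated outgroup.
    """
    if not outgroup_tips:
        raise ValueError("rootward inference requires designated outgroup tips")
    tree = _pruned_to(tree, set(tables))
    tips = {l.taxon.label for l in tree.leaf_node_iter()}
    missing_og = set(outgroup_tips) - tips
    if missing_og:
        raise ValueError(f"outgroup tips absent from tree/tables: {missing_og}")
    ingroup_tips = sorted(tips - set(outgroup_tips))
    if len(ingroup_tips) < 2:
        raise ValueError("need >= 2 ingroup tips")

    tip_sets = {sp: cooccurrence_partition(tables[sp], params) for sp in tips}

    prelim: Dict = {}

    def sweep(node, use_outgroup: Dict) -> LinkageGroupSet:
        if node.is_leaf():
            return tip_sets[node.taxon.label]
        states = [sweep(c, use_outgroup) for c in _node_children(node)]
        current = states[0]
        for i, other in enumerate(states[1:], 1):
            og = use_outgroup.get(node)
            current, _, _ = infer_node(current, other, og, params,
                                       node_id=_node_label(node))
        prelim[node] = current
        return current

    # stage 1: no outgroups
    sweep(tree.seed_node, {})
    stage1 = dict(prelim)

    # stage 2: sibling preliminaries as outgroups
    sibling_og: Dict = {}
    for node in tree.preorder_node_iter():
        children = _node_children(node)
        for child in children:
            sibs = [c for c in children if c is not child]
            if sibs:
                sib = sibs[0]
                sibling_og[child] = (stage1.get(sib) or
                                    tip_sets.get(sib.taxon.label if sib.is_leaf()
                                                 else None))

    results: Dict[str, LinkageGroupSet] = {}
    events: Dict[str, BranchEvents] = {}

    def sweep2(node) -> LinkageGroupSet:
        if node.is_leaf():
            lgs = tip_sets[node.taxon.label]
            results[node.taxon.label] = lgs
            return lgs
        states = [sweep2(c) for c in _node_children(node)]
        og = sibling_og.get(node)
        if og is None and node is not tree.seed_node:
            og = stage1.get(node.parent_node)
        current = states[0]
        evs: List[BranchEvents] = []
        for other in states[1:]:
            current, ea, eb = infer_node(current, other, og, params,
                                         node_id=_node_label(node))
            evs = [e for e in evs if e.child_id != ea.child_id] + [ea, eb]
        for e in evs:
            events[e.child_id] = e
        results[_node_label(node)] = current
        return current

    sweep2(tree.seed_node)

    ingroup_mrca = tree.mrca(taxon_labels=ingroup_tips)
    root_id = _node_label(ingroup_mrca)
    root = results[root_id]
    # enforce the minimum group size at the reported root: undersized groups
    # become unassigned orthologues
    kept = {label: blk for label, blk in root.groups.items()
            if len(blk) >= params.min_orthologs}
    results[root_id] = LinkageGroupSet(root_id, kept, params.min_orthologs)
    return results, events, root_id


def _pruned_to(tree: dendropy.Tree, keep: Set[str]) -> dendropy.Tree:
    tree = tree.clone(depth=1)
    present = {l.taxon.label for l in tree.leaf_node_iter()}
    drop = present - keep
    if drop:
        warnings.warn(f"pruning {len(drop)} tips without tables")
        tree.retain_taxa_with_labels(sorted(present & keep))
    # relabel unlabelled internals deterministically
    i = 0
    for node in tree.preorder_node_iter():
        if not node.is_leaf():
            i += 1
            if not node.label:
                node.label = f"n{i}"
    return tree


def name_elements(root: LinkageGroupSet,
                  sex_orthologs: Optional[Set[str]] = None) -> Dict[str, str]:
    """Rename root groups M1, M2, ... by strictly descending orthologue
    count (ties by smallest member id); the group with maximal overlap
    with ``sex_orthologs`` becomes MZ and is excluded from numbering."""
    items = sorted(root.groups.items(),
                   key=lambda kv: (-len(kv[1]), min(kv[1])))
    sex_label = None
    if sex_orthologs:
        overlaps = {label: len(blk & sex_orthologs)
                    for label, blk in root.groups.items()}
        best = max(overlaps.items(), key=lambda kv: (kv[1], kv[0]))
        if best[1] > 0:
            sex_label = best[0]
    mapping = {}
    rank = 1
    for label, _ in items:
        if label == sex_label:
            mapping[label] = "MZ"
        else:
            mapping[label] = f"M{rank}"
            rank += 1
    return mapping


def relabel(root: LinkageGroupSet, mapping: Dict[str, str]) -> LinkageGroupSet:
    return LinkageGroupSet(
        root.node_id,
        {mapping[l]: blk for l, blk in root.groups.items()},
        root.min_orthologs,
        {mapping[l] for l in root.below_threshold if l in mapping})


@dataclass
class BootstrapReport:
    n_reps: int
    group_counts: List[int]
    modal_count: int
    unanimous: bool
    assignment_consistency: float  # 1 - fraction of conflicting assignments
    unassignment_frequency: Dict[str, float]  # ortholog -> fraction of reps


def bootstrap_algs(tables: Dict[str, GenomeTable], tree: dendropy.Tree,
                   params: InferenceParams, n_reps: int, frac: float,
                   mandatory: Set[str], seed: int,
                   outgroup_tips: Sequence[str] = ()) -> BootstrapReport:
    """Species-subsampling bootstrap of root inference.

    Each replicate keeps every ``mandatory`` species plus a random subset
    of the rest so that about ``frac`` of all species are retained, then
    reruns :func:`infer_algs`.  Stability is summarized as the modal (and
    whether unanimous) root group count, the fraction of orthologues ever
    assigned to conflicting groups between replicates, and the per-
    orthologue unassignment frequency.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    all_tips = sorted(tables)
    if not set(mandatory) <= set(all_tips):
        raise ValueError("mandatory species missing from tables")
    optional = [sp for sp in all_tips if sp not in mandatory]
    n_keep_total = max(int(round(frac * len(all_tips))), len(mandatory))
    n_opt = min(len(optional), max(n_keep_total - len(mandatory), 0))
    rng = np.random.default_rng(seed)

    group_counts: List[int] = []
    ref_groups: List[FrozenSet[str]] = []  # from the first replicate
    assignment: Dict[str, int] = {}  # ortholog -> matched reference index
    conflicted: Set[str] = set()
    unassigned_counts: Dict[str, int] = {}
    all_orth: Set[str] = set()
    for t in tables.values():
        all_orth |= {r.ortholog_id for r in t.complete_records()}

    for rep in range(n_reps):
        chosen = set(mandatory)
        if n_opt:
            chosen |= set(rng.choice(optional, size=n_opt, replace=False))
        sub = {sp: tables[sp] for sp in chosen}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)  # expected pruning
            results, _, root_id = infer_algs(sub, tree, params, outgroup_tips)
        root = results[root_id]
        group_counts.append(root.n_groups)
        assigned: Set[str] = set()
        for blk in root.groups.values():
            # match this group to a reference group by maximal overlap
            best, best_ov = None, 0
            for i, ref in enumerate(ref_groups):
                ov = len(blk & ref)
                if ov > best_ov:
                    best, best_ov = i, ov
            if best is None:
                ref_groups.append(blk)
                best = len(ref_groups) - 1
            for o in blk:
                assigned.add(o)
                prev = assignment.get(o)
                if prev is None:
                    assignment[o] = best
                elif prev != best:
                    conflicted.add(o)
        for o in all_orth - assigned:
            unassigned_counts[o] = unassigned_counts.get(o, 0) + 1

    counts = sorted(group_counts)
    modal = max(set(counts), key=lambda c: (counts.count(c), -c))
    consistency = 1.0 - len(conflicted) / max(len(assignment), 1)
    unassign_freq = {o: c / n_reps for o, c in unassigned_counts.items()}
    return BootstrapReport(n_reps, group_counts, modal,
                           len(set(group_counts)) == 1,
                           consistency, unassign_freq)
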