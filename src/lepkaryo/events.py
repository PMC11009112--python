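"""Window-majority fusion/fission detection and phylogenetic event mapping.

The detector scans each painted chromosome in non-overlapping windows of a
fixed number of orthologues (default 17) and assigns each window its
majority ancestral element.  A chromosome whose windows carry two or more
elements is called fused (the switch position is the breakpoint); an
element that is window-majority on two or more chromosomes is called
split.  Species-level calls are then mapped onto the phylogeny under Dollo
parsimony: each distinct element combination is assigned one event on the
stem of every maximal clade whose tips all carry the call.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Set, Tuple

import dendropy

from .paint import Painting

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 17


@dataclass(frozen=True)
class Window:
    start_index: int
    end_index: int  # half-open, orthologue indices among painted loci
    majority: str
    counts: Tuple[Tuple[str, int], ...]
    tied: bool


@dataclass
class WindowAssignment:
    chromosome: str
    windows: List[Window]

    @property
    def labels(self) -> List[str]:
        return [w.majority for w in self.windows]


@dataclass(frozen=True)
class FusedCall:
    chromosome: str
    elements: FrozenSet[str]
    breakpoints_bp: Tuple[int, ...]  # midpoint per element switch


@dataclass(frozen=True)
class SplitCall:
    element: str
    chromosomes: FrozenSet[str]


@dataclass
class SpeciesCalls:
    species_id: str
    fused: List[FusedCall] = field(default_factory=list)
    split: List[SplitCall] = field(default_factory=list)
    highly_rearranged: bool = False


@dataclass(frozen=True)
class RearrangementEvent:
    kind: str  # fusion | fission
    elements: FrozenSet[str]
    placement: str  # branch id = child-node id of the stem branch
    supporting_species: FrozenSet[str]
    chromosome: Optional[str] = None
    breakpoint_bp: Optional[int] = None


def window_assign(painting: Painting, chromosome: str,
                  window_size: int = DEFAULT_WINDOW) -> Optional[WindowAssignment]:
    """Assign majority elements in consecutive windows of ``window_size``
    painted orthologues; a final remainder shorter than the window merges
    into the preceding window.  Majority ties take the previous window's
    label when it is among the leaders, else the lexicographically
    smallest, and are flagged."""
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    painted = [o for o in painting.chromosomes[chromosome].orthologs
               if o.element is not None]
    if not painted:
        logger.info("%s/%s: no painted orthologues, skipped",
                    painting.species_id, chromosome)
        return None
    bounds = list(range(0, len(painted), window_size))
    if len(bounds) > 1 and len(painted) - bounds[-1] < window_size:
        bounds.pop()  # merge remainder into previous window
    windows: List[Window] = []
    prev_label: Optional[str] = None
    for bi, start in enumerate(bounds):
        end = bounds[bi + 1] if bi + 1 < len(bounds) else len(painted)
        counts: Dict[str, int] = {}
        for o in painted[start:end]:
            counts[o.element] = counts.get(o.element, 0) + 1
        top = max(counts.values())
        leaders = sorted(e for e, c in counts.items() if c == top)
        tied = len(leaders) > 1
        if tied and prev_label in leaders:
            label = prev_label
        else:
            label = leaders[0]
        windows.append(Window(start, end, label,
                              tuple(sorted(counts.items())), tied))
        prev_label = label
    return WindowAssignment(chromosome, windows)


def detect_events_species(painting: Painting,
                          window_size: int = DEFAULT_WINDOW) -> SpeciesCalls:
    """Species-level fused/split chromosome calls from window majorities."""
    calls = SpeciesCalls(painting.species_id)
    assignments: Dict[str, WindowAssignment] = {}
    element_locations: Dict[str, Set[str]] = {}  # any painted presence
    for chrom in sorted(painting.chromosomes):
        wa = window_assign(painting, chrom, window_size)
        if wa is None:
            continue
        assignments[chrom] = wa
        for elem in painting.element_counts(chrom):
            element_locations.setdefault(elem, set()).add(chrom)

    majority_on: Dict[str, Set[str]] = {}
    for chrom, wa in assignments.items():
        labels = wa.labels
        distinct = sorted(set(labels))
        for elem in distinct:
            majority_on.setdefault(elem, set()).add(chrom)
        if len(distinct) >= 2:
            breakpoints = _switch_breakpoints(painting, chrom, wa)
            calls.fused.append(FusedCall(chrom, frozenset(distinct),
                                         tuple(breakpoints)))
    for elem, chroms in sorted(majority_on.items()):
        if len(chroms) >= 2:
            calls.split.append(SplitCall(elem, frozenset(chroms)))

    # highly-rearranged flags: an element scattered beyond a clean split,
    # or an element fragment on a chromosome with too few painted loci
    for elem, chroms in element_locations.items():
        major = majority_on.get(elem, set())
        extra = {c for c in chroms - major
                 if painting.element_counts(c).get(elem, 0) >= window_size}
        if extra and major:
            calls.highly_rearranged = True
    for chrom, wa in assignments.items():
        n_painted = sum(1 for o in painting.chromosomes[chrom].orthologs
                        if o.element is not None)
        if n_painted < window_size:
            elems = set(painting.element_counts(chrom))
            for elem in elems:
                if len(element_locations.get(elem, set())) > 1:
                    calls.highly_rearranged = True
    return calls


def _switch_breakpoints(painting: Painting, chrom: str,
                        wa: WindowAssignment) -> List[int]:
    painted = [o for o in painting.chromosomes[chrom].orthologs
               if o.element is not None]
    out = []
    for prev, cur in zip(wa.windows, wa.windows[1:]):
        if cur.majority != prev.majority:
            # midpoint of the gap between the last orthologue of the
            # upstream run and the first of the downstream run
            upstream = painted[cur.start_index - 1]
            downstream = painted[cur.start_index]
            out.append((upstream.position_bp + downstream.position_bp) // 2)
    return out


def map_events_to_tree(calls: Dict[str, SpeciesCalls],
                       tree: dendropy.Tree) -> List[RearrangementEvent]:
    """Dollo mapping: for each distinct call signature, every maximal clade
    in which all tips carry the call receives one event on its stem branch.
    Species flagged highly_rearranged are excluded."""
    tip_labels = {l.taxon.label for l in tree.leaf_node_iter()}
    unknown = set(calls) - tip_labels
    if unknown:
        raise ValueError(f"calls for non-tip species: {sorted(unknown)}")
    simple = {sp: c for sp, c in calls.items() if not c.highly_rearranged}

    fusion_support: Dict[FrozenSet[str], Set[str]] = {}
    fusion_extra: Dict[FrozenSet[str], Dict[str, FusedCall]] = {}
    for sp, c in simple.items():
        for fc in c.fused:
            fusion_support.setdefault(fc.elements, set()).add(sp)
            fusion_extra.setdefault(fc.elements, {})[sp] = fc
    split_support: Dict[str, Set[str]] = {}
    for sp, c in simple.items():
        for sc in c.split:
            split_support.setdefault(sc.element, set()).add(sp)

    considered = set(simple)
    events: List[RearrangementEvent] = []
    for elements, support in sorted(fusion_support.items(),
                                    key=lambda kv: sorted(kv[0])):
        for clade_tips, stem in _maximal_clades(tree, support, considered):
            sp0 = sorted(clade_tips)[0]
            fc = fusion_extra[elements].get(sp0)
            events.append(RearrangementEvent(
                "fusion", elements, stem, frozenset(clade_tips),
                chromosome=fc.chromosome if fc else None,
                breakpoint_bp=(fc.breakpoints_bp[0]
                               if fc and fc.breakpoints_bp else None)))
    for element, support in sorted(split_support.items()):
        for clade_tips, stem in _maximal_clades(tree, support, considered):
            events.append(RearrangementEvent(
                "fission", frozenset([element]), stem, frozenset(clade_tips)))
    return events


def _maximal_clades(tree: dendropy.Tree, support: Set[str],
                    considered: Set[str]) -> List[Tuple[Set[str], str]]:
    """Maximal clades whose (considered) tips all lie in ``support``.
    Tips outside ``considered`` (e.g. highly-rearranged species) are
    uninformative and do not block a clade."""
    out: List[Tuple[Set[str], str]] = []

    def visit(node) -> Tuple[bool, Set[str]]:
        """returns (all informative tips support the call, tip set)"""
        if node.is_leaf():
            label = node.taxon.label
            if label not in considered:
                return True, set()
            return label in support, {label}
        ok_all = True
        tips: Set[str] = set()
        child_states = []
        for child in node.child_nodes():
            ok, t = visit(child)
            child_states.append((child, ok, t))
            ok_all = ok_all and ok
            tips |= t
        if ok_all and tips:
            return True, tips
        # node not uniform: emit maximal supported children
        for child, ok, t in child_states:
            if ok and t & support:
                stem = child.taxon.label if child.is_leaf() else child.label
                out.append((t & support, stem or "?"))
        return False, tips

    ok, tips = visit(tree.seed_node)
    if ok and tips & support:
        root = tree.seed_node
        out.append((tips & support, root.label or "root"))
    return out


@dataclass(frozen=True)
class KaryotypeCount:
    n: int

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("haploid chromosome number must be >= 1")


def karyotype_count(n_parent: int, fusions: int = 0, fissions: int = 0) -> int:
    """Haploid chromosome number after simple events:
    n = n_parent - fusions + fissions."""
    if fusions < 0 or fissions < 0:
        raise ValueError("event counts must be >= 0")
    if fusions >= n_parent:
        raise ValueError("cannot fuse away more chromosomes than exist")
    return KaryotypeCount(n_parent - fusions + fissions).n
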