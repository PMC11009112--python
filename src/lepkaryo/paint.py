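"""Chromosome painting: label each orthologue on an extant chromosome by
the ancestral element it belongs to, classify chromosome status, and
export Oxford-plot pair tables."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Set, Tuple

import pandas as pd

from .infer import LinkageGroupSet
from .io_formats import GenomeTable


@dataclass(frozen=True)
class PaintedOrtholog:
    ortholog_id: str
    position_bp: int
    element: Optional[str]  # None = unassigned


@dataclass(frozen=True)
class Segment:
    element: str
    start_bp: int
    end_bp: int
    n_orthologs: int


@dataclass
class ChromosomePainting:
    orthologs: List[PaintedOrtholog]
    majority_element: Optional[str]
    majority_tied: bool
    segments: List[Segment]


@dataclass
class Painting:
    species_id: str
    chromosomes: Dict[str, ChromosomePainting] = field(default_factory=dict)

    def element_counts(self, chromosome: str) -> Dict[str, int]:
        counts: Dict[str, int] = {}
        for o in self.chromosomes[chromosome].orthologs:
            if o.element is not None:
                counts[o.element] = counts.get(o.element, 0) + 1
        return counts


@dataclass(frozen=True)
class ChromosomeStatus:
    status: str  # intact | fused | fission_fragment | complex
    elements_involved: frozenset


def paint_species(table: GenomeTable, root: LinkageGroupSet) -> Painting:
    """Label every Complete orthologue by its root linkage group; compute
    per-chromosome majority elements and maximal single-element segments
    (unassigned orthologues do not break segments)."""
    element_of = root.ortholog_to_group()
    painting = Painting(table.species_id)
    by_chrom = table.complete_by_chromosome()
    shared = sum(1 for recs in by_chrom.values()
                 for r in recs if r.ortholog_id in element_of)
    if shared == 0:
        warnings.warn(f"{table.species_id}: no orthologues shared with root set")
        return painting
    for chrom, recs in by_chrom.items():
        painted = [PaintedOrtholog(r.ortholog_id, r.start_bp,
                                   element_of.get(r.ortholog_id))
                   for r in recs]
        counts: Dict[str, int] = {}
        for o in painted:
            if o.element is not None:
                counts[o.element] = counts.get(o.element, 0) + 1
        if counts:
            top = max(counts.values())
            leaders = sorted(e for e, c in counts.items() if c == top)
            majority, tied = leaders[0], len(leaders) > 1
        else:
            majority, tied = None, False
        segments = _segments(painted)
        painting.chromosomes[chrom] = ChromosomePainting(
            painted, majority, tied, segments)
    return painting


def _segments(painted: List[PaintedOrtholog]) -> List[Segment]:
    segs: List[Segment] = []
    cur_elem, cur_start, cur_end, cur_n = None, 0, 0, 0
    for o in painted:
        if o.element is None:
            continue
        if o.element == cur_elem:
            cur_end, cur_n = o.position_bp, cur_n + 1
        else:
            if cur_elem is not None:
                segs.append(Segment(cur_elem, cur_start, cur_end, cur_n))
            cur_elem, cur_start, cur_end, cur_n = o.element, o.position_bp, o.position_bp, 1
    if cur_elem is not None:
        segs.append(Segment(cur_elem, cur_start, cur_end, cur_n))
    return segs


def classify_chromosomes(paintings: Dict[str, Painting],
                         threshold: int = 17
                         ) -> Dict[Tuple[str, str], ChromosomeStatus]:
    """Classify every painted chromosome.

    intact: one element, and that element's orthologues map to this
    chromosome only.  fused: >=2 elements each contributing >= threshold
    orthologues, each contributed element otherwise whole (not split
    elsewhere).  fission_fragment: the majority element (>= threshold
    orthologues here) also majority-paints other chromosome(s), every
    fragment unmixed.  complex: anything else.
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    out: Dict[Tuple[str, str], ChromosomeStatus] = {}
    for species, painting in paintings.items():
        # where does each element put its orthologues in this species?
        elem_chroms: Dict[str, Set[str]] = {}
        majority_chroms: Dict[str, Set[str]] = {}
        for chrom in painting.chromosomes:
            for elem, n in painting.element_counts(chrom).items():
                if n >= threshold:
                    elem_chroms.setdefault(elem, set()).add(chrom)
            cp = painting.chromosomes[chrom]
            if cp.majority_element is not None:
                majority_chroms.setdefault(cp.majority_element, set()).add(chrom)
        for chrom, cp in painting.chromosomes.items():
            counts = painting.element_counts(chrom)
            major = {e for e, n in counts.items() if n >= threshold}
            involved = frozenset(counts)
            if not counts:
                out[(species, chrom)] = ChromosomeStatus("complex", involved)
                continue
            if len(counts) == 1:
                elem = next(iter(counts))
                spread = elem_chroms.get(elem, {chrom})
                fragments_unmixed = all(
                    set(painting.element_counts(c)) == {elem} for c in spread)
                if spread == {chrom}:
                    out[(species, chrom)] = ChromosomeStatus("intact", involved)
                elif (len(majority_chroms.get(elem, set())) >= 2
                      and counts[elem] >= threshold and fragments_unmixed):
                    out[(species, chrom)] = ChromosomeStatus(
                        "fission_fragment", involved)
                else:
                    out[(species, chrom)] = ChromosomeStatus("complex", involved)
                continue
            if len(major) >= 2 and all(
                    elem_chroms.get(e, set()) == {chrom} for e in major) \
                    and major == set(counts):
                out[(species, chrom)] = ChromosomeStatus("fused", frozenset(major))
                continue
            out[(species, chrom)] = ChromosomeStatus("complex", involved)
    return out


def oxford_pairs(painting_a: Painting, painting_b: Painting) -> pd.DataFrame:
    """One row per shared painted orthologue with per-chromosome rank
    indices in each species (the data behind an Oxford dot plot)."""
    def index(p: Painting) -> Dict[str, Tuple[str, int]]:
        out = {}
        for chrom, cp in p.chromosomes.items():
            for rank, o in enumerate(cp.orthologs):
                out[o.ortholog_id] = (chrom, rank)
        return out

    ia, ib = index(painting_a), index(painting_b)
    shared = sorted(set(ia) & set(ib))
    if not shared:
        warnings.warn("no shared orthologues between paintings")
    rows = [{"ortholog": o,
             "chrom_a": ia[o][0], "rank_a": ia[o][1],
             "chrom_b": ib[o][0], "rank_b": ib[o][1]} for o in shared]
    return pd.DataFrame(rows, columns=["ortholog", "chrom_a", "rank_a",
                                       "chrom_b", "rank_b"])


def painting_to_frame(painting: Painting) -> pd.DataFrame:
    rows = []
    for chrom, cp in sorted(painting.chromosomes.items()):
        for o in cp.orthologs:
            rows.append({"species": painting.species_id, "chromosome": chrom,
                         "ortholog": o.ortholog_id, "position_bp": o.position_bp,
                         "element": o.element or "unassigned"})
    return pd.DataFrame(rows, columns=["species", "chromosome", "ortholog",
                                       "position_bp", "element"])
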