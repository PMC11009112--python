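"""Windowed and per-chromosome sequence-feature statistics.

Covers GC in fixed bp windows, BED coverage fractions (union semantics),
proportional (k-bin) chromosome profiles, GC3 of coding sequences, the
synteny score (proportion of adjacent shared-orthologue pairs that are
also adjacent in a reference species, orientation-agnostic), single-copy
gene proportions, feature-vs-length correlation scans with the intact-
autosome filtering rules, and the fused-chromosome repeat-amelioration
paired t-test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import stats as sps

from .io_formats import GenomeTable, IntervalTrack
from .stats import CorrelationResult, spearman

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_BP = 100_000


@dataclass(frozen=True)
class FeatureWindow:
    chromosome: str
    start_bp: int
    end_bp: int
    gc: Optional[float] = None
    repeat_frac: Optional[float] = None
    coding_frac: Optional[float] = None


@dataclass
class ChromosomeSummary:
    chromosome: str
    length_bp: int
    prop_length: float
    gc: Optional[float] = None
    gc3: Optional[float] = None
    repeat_frac: Optional[float] = None
    coding_frac: Optional[float] = None
    synteny: Optional[float] = None
    single_copy_prop: Optional[float] = None
    element: Optional[str] = None
    intact: bool = False


def _windows(length: int, window_bp: int) -> List[Tuple[int, int]]:
    out, pos = [], 0
    while pos < length:
        out.append((pos, min(pos + window_bp, length)))
        pos += window_bp
    return out or [(0, length)]


def gc_windows(sequences: Mapping[str, str],
               window_bp: int = DEFAULT_WINDOW_BP) -> List[FeatureWindow]:
    """GC = (G+C)/(A+C+G+T) per window; ambiguous bases leave the
    denominator.  The final short window is retained."""
    if window_bp < 1:
        raise ValueError("window_bp must be >= 1")
    out: List[FeatureWindow] = []
    for chrom in sorted(sequences):
        seq = sequences[chrom].upper()
        if not seq:
            continue
        for start, end in _windows(len(seq), window_bp):
            win = seq[start:end]
            gc = win.count("G") + win.count("C")
            at = win.count("A") + win.count("T")
            denom = gc + at
            out.append(FeatureWindow(chrom, start, end,
                                     gc=gc / denom if denom else None))
    return out


def _flatten(intervals: Iterable[Tuple[int, int]]) -> List[Tuple[int, int]]:
    ivals = sorted(intervals)
    merged: List[List[int]] = []
    for s, e in ivals:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def coverage_windows(tracks: Sequence[IntervalTrack],
                     chrom_lengths: Mapping[str, int],
                     window_bp: int = DEFAULT_WINDOW_BP,
                     feature: str = "repeat_frac") -> List[FeatureWindow]:
    """Covered-base fraction per window with overlapping intervals
    flattened (union semantics) before counting.  Intervals beyond the
    chromosome end are clipped with a warning."""
    by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for track in tracks:
        length = chrom_lengths.get(track.chromosome)
        if length is None:
            continue
        for s, e in track.intervals:
            if e > length:
                logger.warning("%s: interval %d-%d clipped to %d",
                               track.chromosome, s, e, length)
                e = length
            if s < e:
                by_chrom.setdefault(track.chromosome, []).append((s, e))
    out: List[FeatureWindow] = []
    for chrom in sorted(chrom_lengths):
        length = chrom_lengths[chrom]
        flat = _flatten(by_chrom.get(chrom, []))
        starts = np.array([s for s, _ in flat])
        ends = np.array([e for _, e in flat])
        for ws, we in _windows(length, window_bp):
            if starts.size:
                overlap = np.clip(np.minimum(ends, we) - np.maximum(starts, ws),
                                  0, None).sum()
            else:
                overlap = 0
            frac = overlap / (we - ws)
            out.append(FeatureWindow(chrom, ws, we, **{feature: float(frac)}))
    return out


def proportional_windows(windows: Sequence[FeatureWindow],
                         chrom_length: int, k: int = 100,
                         feature: str = "repeat_frac") -> np.ndarray:
    """Re-bin fixed-bp windows of one chromosome into ``k`` equal bp bins;
    the bin value is the coverage-weighted mean of overlapping windows."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if chrom_length < k:
        raise ValueError("chromosome shorter than k bp")
    edges = np.linspace(0, chrom_length, k + 1)
    values = np.zeros(k)
    weights = np.zeros(k)
    for w in windows:
        val = getattr(w, feature)
        if val is None:
            continue
        for b in range(int(w.start_bp * k // chrom_length),
                       min(int((w.end_bp - 1) * k // chrom_length) + 1, k)):
            lo, hi = edges[b], edges[b + 1]
            ov = max(0.0, min(w.end_bp, hi) - max(w.start_bp, lo))
            values[b] += val * ov
            weights[b] += ov
    with np.errstate(invalid="ignore"):
        return np.where(weights > 0, values / np.maximum(weights, 1e-300), np.nan)


def gc3_per_chromosome(cds: Mapping[str, Tuple[str, str]]) -> Dict[str, Optional[float]]:
    """``cds`` maps gene id -> (chromosome, coding sequence).  GC3 is the
    GC fraction at every third base of the frame; sequences whose length is
    not a multiple of three are excluded (counted in the log).  The
    chromosome value is the unweighted mean over retained sequences."""
    per_chrom: Dict[str, List[float]] = {}
    n_excluded = 0
    chroms: Set[str] = set()
    for gene, (chrom, seq) in cds.items():
        chroms.add(chrom)
        seq = seq.upper()
        if len(seq) % 3 != 0 or not seq:
            n_excluded += 1
            continue
        third = seq[2::3]
        counted = sum(third.count(b) for b in "ACGT")
        if counted == 0:
            n_excluded += 1
            continue
        gc3 = (third.count("G") + third.count("C")) / counted
        per_chrom.setdefault(chrom, []).append(gc3)
    if n_excluded:
        logger.info("gc3: excluded %d coding sequences", n_excluded)
    return {chrom: (float(np.mean(per_chrom[chrom])) if chrom in per_chrom
                    else None)
            for chrom in chroms}


def synteny_score(table: GenomeTable, reference: GenomeTable
                  ) -> Dict[str, Optional[float]]:
    """Per focal chromosome: the proportion of consecutive shared-
    orthologue pairs that are on one reference chromosome AND consecutive
    among shared orthologues there, in either orientation."""
    focal_by_chrom = table.complete_by_chromosome()
    ref_by_chrom = reference.complete_by_chromosome()
    shared = ({r.ortholog_id for recs in focal_by_chrom.values() for r in recs}
              & {r.ortholog_id for recs in ref_by_chrom.values() for r in recs})
    # reference: chromosome and rank among shared orthologues
    ref_pos: Dict[str, Tuple[str, int]] = {}
    for chrom, recs in ref_by_chrom.items():
        rank = 0
        for r in recs:
            if r.ortholog_id in shared:
                ref_pos[r.ortholog_id] = (chrom, rank)
                rank += 1
    out: Dict[str, Optional[float]] = {}
    for chrom, recs in focal_by_chrom.items():
        ordered = [r.ortholog_id for r in recs if r.ortholog_id in shared]
        if len(ordered) < 2:
            out[chrom] = None
            continue
        hits = 0
        for a, b in zip(ordered, ordered[1:]):
            (ca, ra), (cb, rb) = ref_pos[a], ref_pos[b]
            if ca == cb and abs(ra - rb) == 1:
                hits += 1
        out[chrom] = hits / (len(ordered) - 1)
    return out


def single_copy_proportion(classes: Mapping[str, str],
                           locations: Mapping[str, str]) -> Dict[str, float]:
    """``classes``: gene -> {single_copy, multicopy, clade_specific};
    ``locations``: gene -> chromosome.  Returns the single-copy fraction
    per chromosome."""
    totals: Dict[str, int] = {}
    single: Dict[str, int] = {}
    for gene, cls in classes.items():
        chrom = locations.get(gene)
        if chrom is None:
            continue
        totals[chrom] = totals.get(chrom, 0) + 1
        if cls == "single_copy":
            single[chrom] = single.get(chrom, 0) + 1
    return {chrom: single.get(chrom, 0) / n for chrom, n in totals.items()}


FEATURES = ("gc", "gc3", "repeat_frac", "coding_frac", "synteny",
            "single_copy_prop")


def correlate_feature_vs_length(summaries: Sequence[ChromosomeSummary],
                                feature: str,
                                sex_element: Optional[str] = None,
                                min_chromosomes: int = 10
                                ) -> Optional[CorrelationResult]:
    """Spearman of a per-chromosome feature against proportional length
    after the filtering rules: autosomes only, intact-element chromosomes
    only, and at least ``min_chromosomes`` left (else the species is
    skipped, returning None)."""
    if feature not in FEATURES:
        raise ValueError(f"unknown feature {feature!r}")
    kept = [s for s in summaries
            if s.intact and s.element != sex_element
            and getattr(s, feature) is not None]
    if len(kept) < min_chromosomes:
        logger.info("species skipped: %d intact autosomes < %d",
                    len(kept), min_chromosomes)
        return None
    return spearman([s.prop_length for s in kept],
                    [getattr(s, feature) for s in kept])


@dataclass(frozen=True)
class PairedTestResult:
    t: float
    p_value: float
    n_pairs: int
    mean_delta_small: float
    mean_delta_large: float


def fusion_amelioration_test(fused_segments: Sequence[Tuple[str, str, float, float]],
                             ancestral_density: Mapping[str, float],
                             small_elements: Set[str],
                             ) -> PairedTestResult:
    """Paired t-test for repeat-density amelioration after fusion.

    ``fused_segments``: one entry per two-segment fused chromosome as
    (element_small, element_large, density_small_segment,
    density_large_segment) where the small element is the one in
    ``small_elements`` (or the shorter of the pair).  Per fusion,
    delta_small = segment density - ancestral mean density of that element
    (over species where it is intact), likewise delta_large; the paired t
    statistic tests delta_small - delta_large = 0 (two-sided).
    """
    deltas_small, deltas_large = [], []
    for e_small, e_large, d_small, d_large in fused_segments:
        if e_small not in ancestral_density or e_large not in ancestral_density:
            continue
        deltas_small.append(d_small - ancestral_density[e_small])
        deltas_large.append(d_large - ancestral_density[e_large])
    if len(deltas_small) < 2:
        raise ValueError("need >= 2 fusion pairs with ancestral densities")
    diffs = np.asarray(deltas_small) - np.asarray(deltas_large)
    if np.all(diffs == 0):
        return PairedTestResult(0.0, 1.0, len(deltas_small),
                                float(np.mean(deltas_small)),
                                float(np.mean(deltas_large)))
    res = sps.ttest_rel(deltas_small, deltas_large)
    return PairedTestResult(float(res.statistic), float(res.pvalue),
                            len(deltas_small),
                            float(np.mean(deltas_small)),
                            float(np.mean(deltas_large)))


def ancestral_element_density(per_species: Mapping[str, Mapping[str, float]]
                              ) -> Dict[str, float]:
    """Mean density of each element across species where it is an intact
    chromosome (equal weight per species).  ``per_species`` maps species ->
    {element: density of the intact chromosome carrying it}."""
    acc: Dict[str, List[float]] = {}
    for densities in per_species.values():
        for elem, d in densities.items():
            acc.setdefault(elem, []).append(d)
    return {elem: float(np.mean(vals)) for elem, vals in acc.items()}
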