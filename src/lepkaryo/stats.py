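"""Branch-length-weighted permutation tests and rank correlations.

Two bespoke permutation tests: (1) are fusion events concentrated on
external (terminal) branches, against a null that events land on branches
with probability proportional to branch length; (2) is the spread of a
focal linkage group's orthologues across a reference partition (e.g.
bilaterian linkage groups) narrower than multinomial assignment predicts,
measured by the variance of per-reference-label counts.

Percentiles are computed as the fraction of null samples strictly below
the observed value, plus half the ties, times 100.  Significance is
declared above a configurable percentile cutoff (default 99.99).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Set

import numpy as np
from scipy import stats as sps

DEFAULT_CUTOFF = 99.99


@dataclass(frozen=True)
class PermutationResult:
    observed: float
    null_samples: int
    null_quantiles: Dict[float, float]
    percentile_of_observed: float
    cutoff: float
    significant: bool


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_value: float
    n: int
    method: str = "spearman"


def _percentile_of(observed: float, null: np.ndarray) -> float:
    below = np.count_nonzero(null < observed)
    ties = np.count_nonzero(null == observed)
    return 100.0 * (below + 0.5 * ties) / null.size


def _result(observed: float, null: np.ndarray, cutoff: float) -> PermutationResult:
    pct = _percentile_of(observed, null)
    quants = {q: float(np.quantile(null, q / 100))
              for q in (1.0, 5.0, 50.0, 95.0, 99.0, 99.99)}
    return PermutationResult(float(observed), int(null.size), quants,
                             pct, cutoff, pct > cutoff)


def branch_length_arrays(tree) -> tuple:
    """(lengths, is_external) over all positive-length branches."""
    lengths, external = [], []
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node or edge.length is None:
            continue
        lengths.append(edge.length)
        external.append(edge.head_node.is_leaf())
    return np.asarray(lengths, dtype=float), np.asarray(external, dtype=bool)


def external_branch_test(tree, n_events: int, observed_external: int,
                         n_sims: int = 100_000, seed: int = 0,
                         cutoff: float = DEFAULT_CUTOFF) -> PermutationResult:
    """Null: ``n_events`` land independently on branches with probability
    proportional to branch length; statistic = number on external
    branches."""
    lengths, external = branch_length_arrays(tree)
    if lengths.size == 0 or lengths.sum() <= 0:
        raise ValueError("tree has no positive-length branches")
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    p_external = lengths[external].sum() / lengths.sum()
    rng = np.random.default_rng(seed)
    null = rng.binomial(n_events, p_external, size=n_sims).astype(float)
    return _result(observed_external, null, cutoff)


def partition_association_test(focal: Dict[str, str], reference: Dict[str, str],
                               n_sims: int = 100_000, seed: int = 0,
                               cutoff: float = DEFAULT_CUTOFF,
                               min_orthologs: int = 2,
                               focal_labels: Optional[Sequence[str]] = None
                               ) -> Dict[str, PermutationResult]:
    """Per focal label: variance of its orthologue counts across reference
    labels, against multinomial assignment weighted by reference label
    totals.  Orthologues present in only one mapping are ignored; the
    reference weights always come from the full shared set, while
    ``focal_labels`` optionally restricts which labels are tested."""
    shared = sorted(set(focal) & set(reference))
    if not shared:
        raise ValueError("no shared orthologues")
    ref_labels = sorted({reference[o] for o in shared})
    ref_index = {l: i for i, l in enumerate(ref_labels)}
    totals = np.zeros(len(ref_labels))
    for o in shared:
        totals[ref_index[reference[o]]] += 1
    probs = totals / totals.sum()
    rng = np.random.default_rng(seed)
    out: Dict[str, PermutationResult] = {}
    if focal_labels is None:
        focal_labels = sorted({focal[o] for o in shared})
    for label in focal_labels:
        members = [o for o in shared if focal[o] == label]
        if len(members) < min_orthologs:
            continue
        counts = np.zeros(len(ref_labels))
        for o in members:
            counts[ref_index[reference[o]]] += 1
        observed = float(np.var(counts))
        null_counts = rng.multinomial(len(members), probs, size=n_sims)
        null = null_counts.var(axis=1)
        out[label] = _result(observed, null, cutoff)
    return out


def spearman(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Tie-corrected Spearman rho with a two-sided t-approximation p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input vector: rho undefined")
    rho, p = sps.spearmanr(x, y)
    return CorrelationResult(float(rho), float(p), int(x.size))


def fusion_size_correlation(fusion_counts: Dict[str, int],
                            mean_prop_length: Dict[str, float],
                            exclude: Set[str] = frozenset()
                            ) -> CorrelationResult:
    """Spearman correlation between per-element fusion involvement and mean
    proportional length, after exclusions (typically the sex element for
    the autosome-only analysis)."""
    elements = sorted((set(fusion_counts) & set(mean_prop_length)) - set(exclude))
    if len(elements) < 3:
        raise ValueError("need >= 3 elements after exclusions")
    counts = [fusion_counts[e] for e in elements]
    lengths = [mean_prop_length[e] for e in elements]
    return spearman(lengths, counts)
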