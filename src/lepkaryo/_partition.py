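"""Set-partition primitives for karyotype parsimony.

A karyotype, viewed without gene order, is a partition of orthologue ids
into chromosomes.  A fusion merges two blocks; a fission splits one block
in two.  The minimum number of fusions + fissions transforming partition A
into partition C (on their shared orthologues) has a closed form: an
exchange argument shows some optimal scenario performs all fusions before
all fissions, so the intermediate state is a common coarsening of A and C,
and the best such coarsening is the lattice join A v C (connected
components of the block-intersection graph).  Hence

    fusions  = |A| - c(A v C)
    fissions = |C| - c(A v C)

where c() counts join components and |.| counts non-empty blocks after
restriction to the shared orthologue universe.
"""

from __future__ import annotations

from typing import Dict, FrozenSet, Hashable, Iterable, List, Sequence, Tuple

Block = FrozenSet[Hashable]
Partition = FrozenSet[Block]


def as_partition(blocks: Iterable[Iterable[Hashable]]) -> Partition:
    """Canonicalize an iterable of iterables into a partition (drops empties)."""
    out = frozenset(frozenset(b) for b in blocks if len(tuple(b)) > 0)
    _check_disjoint(out)
    return out


def _check_disjoint(p: Partition) -> None:
    seen = set()
    for b in p:
        for x in b:
            if x in seen:
                raise ValueError(f"element {x!r} appears in more than one block")
            seen.add(x)


def universe(p: Partition) -> FrozenSet[Hashable]:
    out: set = set()
    for b in p:
        out |= b
    return frozenset(out)


def restrict(p: Partition, elements: FrozenSet[Hashable]) -> Partition:
    """Drop elements outside ``elements``; discard blocks that become empty."""
    return frozenset(b & elements for b in p if b & elements)


class _UnionFind:
    __slots__ = ("parent",)

    def __init__(self) -> None:
        self.parent: Dict[Hashable, Hashable] = {}

    def find(self, x: Hashable) -> Hashable:
        parent = self.parent
        if x not in parent:
            parent[x] = x
            return x
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:
            parent[x], x = root, parent[x]
        return root

    def union(self, a: Hashable, b: Hashable) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


def join_components(*partitions: Partition) -> List[FrozenSet[Hashable]]:
    """Blocks of the lattice join of the given partitions (same universe
    not required; the join lives on the union of universes)."""
    uf = _UnionFind()
    for p in partitions:
        for block in p:
            it = iter(block)
            try:
                first = next(it)
            except StopIteration:
                continue
            uf.find(first)
            for x in it:
                uf.union(first, x)
    comps: Dict[Hashable, set] = {}
    for x in uf.parent:
        comps.setdefault(uf.find(x), set()).add(x)
    return [frozenset(c) for c in comps.values()]


def fusion_fission_distance(parent: Partition, child: Partition) -> Tuple[int, int]:
    """Minimum (fusions, fissions) turning ``parent`` into ``child``,
    counted on their shared orthologue universe only."""
    shared = universe(parent) & universe(child)
    p = restrict(parent, shared)
    c = restrict(child, shared)
    n_comp = len(join_components(p, c))
    return len(p) - n_comp, len(c) - n_comp


def distance(parent: Partition, child: Partition) -> int:
    fu, fi = fusion_fission_distance(parent, child)
    return fu + fi


def meet_blocks(part_a: Partition, part_b: Partition,
                elements: FrozenSet[Hashable]) -> List[Block]:
    """Blocks of the meet of two partitions over ``elements``.

    An element absent from one partition is constrained only by the other:
    its key on the missing side is None-like (grouped with co-members of
    its present-side block that are likewise absent from the other side).
    """
    index_a: Dict[Hashable, int] = {}
    for i, b in enumerate(part_a):
        for x in b:
            index_a[x] = i
    index_b: Dict[Hashable, int] = {}
    for i, b in enumerate(part_b):
        for x in b:
            index_b[x] = i
    cells: Dict[Tuple, set] = {}
    for x in elements:
        key = (index_a.get(x, -1), index_b.get(x, -1))
        cells.setdefault(key, set()).add(x)
    return [frozenset(c) for c in cells.values()]


def set_partitions(items: Sequence) -> Iterable[List[List]]:
    """All set partitions of ``items`` (restricted-growth enumeration)."""
    items = list(items)
    if not items:
        yield []
        return

    def rec(idx: int, parts: List[List]):
        if idx == len(items):
            yield [list(p) for p in parts]
            return
        x = items[idx]
        for p in parts:
            p.append(x)
            yield from rec(idx + 1, parts)
            p.pop()
        parts.append([x])
        yield from rec(idx + 1, parts)
        parts.pop()

    yield from rec(0, [])


def bell_number(n: int) -> int:
    row = [1]
    for _ in range(n):
        new = [row[-1]]
        for v in row:
            new.append(new[-1] + v)
        row = new
    return row[0]


def merge_scenario(parent: Partition, child: Partition) -> Tuple[List[FrozenSet], List[FrozenSet]]:
    """Concrete minimal scenario from parent to child: returns
    (fusion groups, fission groups) where each fusion group is the set of
    parent blocks merged into one intermediate, and each fission group the
    set of child blocks one intermediate splits into."""
    shared = universe(parent) & universe(child)
    p = restrict(parent, shared)
    c = restrict(child, shared)
    fusions: List[FrozenSet] = []
    fissions: List[FrozenSet] = []
    for comp in join_components(p, c):
        p_blocks = frozenset(b for b in p if b & comp)
        c_blocks = frozenset(b for b in c if b & comp)
        if len(p_blocks) > 1:
            fusions.append(p_blocks)
        if len(c_blocks) > 1:
            fissions.append(c_blocks)
    return fusions, fissions
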