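import random

import pytest

from lepkaryo import _partition as pt
from lepkaryo import infer, simulate
from lepkaryo.infer import InferenceParams, LinkageGroupSet
from lepkaryo.simulate import EvolutionParams


def lgs(node_id, *blocks, min_orthologs=2):
    return LinkageGroupSet(
        node_id, {f"c{i}": frozenset(b) for i, b in enumerate(blocks)},
        min_orthologs)


class TestCooccurrencePartition:
    def test_one_group_per_chromosome(self, small_sim):
        table = small_sim["tables"]["sp3"]
        part = infer.cooccurrence_partition(table)
        assert part.n_groups == len(table.complete_by_chromosome())
        total = sum(len(b) for b in part.groups.values())
        assert total == len(table.complete_records())

    def test_small_groups_flagged_not_dropped(self):
        from lepkaryo.io_formats import GenomeTable, OrthologRecord
        recs = [OrthologRecord(f"g{i}", "Complete", "chrA", i * 10, i * 10 + 5)
                for i in range(6)]
        recs.append(OrthologRecord("lone", "Complete", "chrB", 0, 5))
        table = GenomeTable("sp", recs, {"chrA": 100, "chrB": 10})
        part = infer.cooccurrence_partition(table, InferenceParams(5))
        assert part.n_groups == 2
        assert part.below_threshold == {"chrB"}


class TestInferNodeSmall:
    params = InferenceParams(min_orthologs=2)

    def test_identity_triplet(self):
        a = lgs("a", "AB")
        anc, ea, eb = infer.infer_node(a, lgs("b", "AB"), lgs("o", "AB"),
                                       self.params)
        assert anc.partition() == frozenset({frozenset("AB")})
        assert ea.n_events == eb.n_events == 0

    def test_dollo_forced_fusion_on_one_branch(self):
        fused = lgs("a", "ABCDE")
        sep = lgs("b", "AB", "CDE")
        out = lgs("o", "AB", "CDE")
        anc, ea, eb = infer.infer_node(fused, sep, out, self.params)
        assert anc.partition() == frozenset({frozenset("AB"), frozenset("CDE")})
        assert ea.n_events == 1 and eb.n_events == 0

    def test_outgroup_breaks_symmetric_tie(self):
        """Children disagree symmetrically; the ancestor follows the
        outgroup."""
        a = lgs("a", "ABCD")
        b = lgs("b", "AB", "CD")
        anc_sep, *_ = infer.infer_node(a, b, lgs("o", "AB", "CD"), self.params)
        assert anc_sep.partition() == frozenset({frozenset("AB"),
                                                 frozenset("CD")})
        anc_fused, *_ = infer.infer_node(a, b, lgs("o", "ABCD"), self.params)
        assert anc_fused.partition() == frozenset({frozenset("ABCD")})

    def test_insufficient_overlap_passes_children_through(self):
        a = lgs("a", "AB")
        b = lgs("b", "XY")
        anc, ea, eb = infer.infer_node(a, b, None, InferenceParams(3))
        assert anc.partition() == a.partition()
        assert ea.n_events == eb.n_events == 0


def random_partition(rng, elements, max_blocks=4):
    blocks = {}
    n_blocks = rng.randint(1, min(max_blocks, len(elements)))
    for x in elements:
        blocks.setdefault(rng.randrange(n_blocks), set()).add(x)
    return pt.as_partition(blocks.values())


def perturb(rng, part, n_events):
    """Apply up to n_events random fusions/fissions."""
    part = set(part)
    for _ in range(n_events):
        blocks = sorted(part, key=sorted)
        if rng.random() < 0.5 and len(blocks) >= 2:
            a, b = rng.sample(blocks, 2)
            part -= {a, b}
            part.add(a | b)
        else:
            splittable = [b for b in blocks if len(b) >= 2]
            if not splittable:
                continue
            blk = rng.choice(splittable)
            items = sorted(blk)
            k = rng.randint(1, len(items) - 1)
            part.discard(blk)
            part.add(frozenset(items[:k]))
            part.add(frozenset(items[k:]))
    return frozenset(part)


def exhaustive_best_score(universe, part_a, part_b):
    """Minimum summed fusion+fission distance to both children over ALL
    partitions of the universe."""
    best = None
    for grouping in pt.set_partitions(sorted(universe)):
        cand = pt.as_partition(grouping)
        score = (pt.distance(cand, part_a) + pt.distance(cand, part_b))
        if best is None or score < best:
            best = score
    return best


@pytest.mark.parametrize("seed", range(50))
def test_infer_node_matches_exhaustive_parsimony(seed):
    """On random triplets with <= 2 events per child, the inferred ancestor
    achieves the global minimum of summed child events found by exhaustive
    search over every partition of the orthologue universe."""
    rng = random.Random(seed)
    elements = [chr(65 + i) for i in range(rng.randint(4, 8))]
    ancestor_true = random_partition(rng, elements)
    child_a = perturb(rng, ancestor_true, rng.randint(0, 2))
    child_b = perturb(rng, ancestor_true, rng.randint(0, 2))
    outgroup = perturb(rng, ancestor_true, rng.randint(0, 1))
    A = LinkageGroupSet("a", {f"a{i}": b for i, b in enumerate(child_a)}, 2)
    B = LinkageGroupSet("b", {f"b{i}": b for i, b in enumerate(child_b)}, 2)
    O = LinkageGroupSet("o", {f"o{i}": b for i, b in enumerate(outgroup)}, 2)
    anc, ea, eb = infer.infer_node(A, B, O, InferenceParams(2))
    our_score = ea.n_events + eb.n_events
    assert our_score == exhaustive_best_score(elements, child_a, child_b)
    direct = (pt.distance(anc.partition(), child_a)
              + pt.distance(anc.partition(), child_b))
    assert direct == our_score


class TestInferAlgs:
    def test_zero_rate_simulation_recovers_ancestor(self):
        tree = simulate.simulate_tree(8, seed=3)
        anc = simulate.simulate_ancestral_genome(
            5, counts=[30, 25, 20, 15, 10], seed=0)
        tables, _ = simulate.evolve_genomes(tree, anc, EvolutionParams(seed=4))
        og = simulate.basal_outgroup(tree)
        results, events, root_id = infer.infer_algs(
            tables, tree, InferenceParams(), outgroup_tips=og)
        assert set(results[root_id].groups.values()) == set(
            anc.partition().values())
        assert all(e.n_events == 0 for e in events.values())

    def test_requires_outgroup(self, small_sim):
        with pytest.raises(ValueError, match="outgroup"):
            infer.infer_algs(small_sim["tables"], small_sim["tree"],
                             InferenceParams(), outgroup_tips=())

    def test_shared_clade_fusion_stays_off_the_root(self):
        """A fusion shared by one ingroup clade must not merge the two
        elements at the ingroup root (the outgroup separates them), and
        the event lands on that clade's stem branch."""
        tree = simulate.simulate_tree(10, seed=6)
        og = simulate.basal_outgroup(tree)
        anc = simulate.simulate_ancestral_genome(
            5, counts=[40, 35, 30, 25, 20], seed=0)
        # find an internal ingroup branch with 2-4 descendant tips
        ingroup = [l.taxon.label for l in tree.leaf_node_iter()
                   if l.taxon.label not in og]
        mrca = tree.mrca(taxon_labels=ingroup)
        target = None
        for node in mrca.preorder_iter():
            if node is mrca or node.is_leaf():
                continue
            n = sum(1 for _ in node.leaf_iter())
            if 2 <= n <= 4:
                target = node
                break
        assert target is not None
        script = {target.label: [("fusion", "M2", "M4")]}
        tables, _ = simulate.evolve_genomes(tree, anc,
                                            EvolutionParams(seed=1),
                                            script=script)
        results, events, root_id = infer.infer_algs(
            tables, tree, InferenceParams(), outgroup_tips=og)
        assert set(results[root_id].groups.values()) == set(
            anc.partition().values())
        ev = events[target.label]
        assert ev.n_events == 1 and len(ev.fusions) == 1

    def test_scripted_recovery(self, small_sim, small_root):
        assert set(small_root.groups.values()) == set(
            small_sim["ancestor"].partition().values())

    def test_raising_min_orthologs_never_adds_root_groups(self, small_sim):
        counts = []
        for mo in (2, 5, 12):
            results, _, root_id = infer.infer_algs(
                small_sim["tables"], small_sim["tree"],
                InferenceParams(min_orthologs=mo),
                outgroup_tips=small_sim["outgroup"])
            counts.append(results[root_id].n_groups)
        assert counts[0] >= counts[1] >= counts[2]


class TestNameElements:
    def test_descending_count_with_sex_override(self):
        root = lgs("r", "ABCDEFG", "HIJ", "KL")
        mapping = infer.name_elements(root, sex_orthologs={"H", "I"})
        by_size = sorted(root.groups.items(), key=lambda kv: -len(kv[1]))
        assert mapping[by_size[0][0]] == "M1"
        assert mapping[by_size[1][0]] == "MZ"
        assert mapping[by_size[2][0]] == "M2"

    def test_equal_sizes_tie_break_deterministic(self):
        root = lgs("r", "AB", "CD")
        m1 = infer.name_elements(root)
        m2 = infer.name_elements(root)
        assert m1 == m2
        # the group holding the smallest member id wins the lower number
        label_of_ab = next(l for l, b in root.groups.items() if "A" in b)
        assert m1[label_of_ab] == "M1"

    def test_permutation_invariant_membership(self, small_root, small_sim):
        """Same label -> member mapping regardless of input group naming."""
        renamed = LinkageGroupSet(
            small_root.node_id,
            {f"zz{i}": blk for i, blk in
             enumerate(sorted(small_root.groups.values(), key=sorted))},
            small_root.min_orthologs)
        sex = frozenset(o for label, ids, _ in small_sim["ancestor"].elements
                        if label == "MZ" for o in ids)
        m = infer.name_elements(renamed, sex)
        got = {m[l]: blk for l, blk in renamed.groups.items()}
        want = dict(small_root.groups)
        assert got == want


class TestBootstrap:
    def test_single_full_replicate_equals_plain_inference(self, small_sim):
        report = infer.bootstrap_algs(
            small_sim["tables"], small_sim["tree"], InferenceParams(),
            n_reps=1, frac=1.0, mandatory=set(small_sim["outgroup"]),
            seed=0, outgroup_tips=small_sim["outgroup"])
        results, _, root_id = infer.infer_algs(
            small_sim["tables"], small_sim["tree"], InferenceParams(),
            outgroup_tips=small_sim["outgroup"])
        assert report.group_counts == [results[root_id].n_groups]

    def test_zero_rate_bootstrap_fully_stable(self):
        tree = simulate.simulate_tree(10, seed=5)
        anc = simulate.simulate_ancestral_genome(
            4, counts=[30, 25, 20, 15], seed=0)
        tables, _ = simulate.evolve_genomes(tree, anc, EvolutionParams(seed=6))
        og = simulate.basal_outgroup(tree)
        report = infer.bootstrap_algs(tables, tree, InferenceParams(),
                                      n_reps=8, frac=0.5, mandatory=set(og),
                                      seed=7, outgroup_tips=og)
        assert report.unanimous and report.modal_count == 4
        assert report.assignment_consistency == 1.0

    def test_rejects_zero_reps(self, small_sim):
        with pytest.raises(ValueError):
            infer.bootstrap_algs(small_sim["tables"], small_sim["tree"],
                                 InferenceParams(), n_reps=0, frac=0.5,
                                 mandatory=set(), seed=0,
                                 outgroup_tips=small_sim["outgroup"])
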