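import numpy as np
import pytest

from lepkaryo import features as ft
from lepkaryo import simulate
from lepkaryo.features import ChromosomeSummary
from lepkaryo.io_formats import GenomeTable, IntervalTrack, OrthologRecord
from lepkaryo.simulate import EvolutionParams, FeatureModel


class TestGcWindows:
    def test_extremes_and_mixture(self):
        wins = ft.gc_windows({"c": "GGGGCCCC" + "ACGTACGT" + "AATTAATT"},
                             window_bp=8)
        assert [w.gc for w in wins] == [1.0, 0.5, 0.0]

    def test_ambiguous_bases_excluded_from_denominator(self):
        wins = ft.gc_windows({"c": "GCNNNNAT"}, window_bp=8)
        assert wins[0].gc == pytest.approx(0.5)

    def test_short_final_window_retained(self):
        wins = ft.gc_windows({"c": "ACGTACGTAC"}, window_bp=4)
        assert len(wins) == 3 and wins[-1].end_bp == 10


def brute_force_coverage(intervals, length, window_bp):
    covered = np.zeros(length, dtype=bool)
    for s, e in intervals:
        covered[s:min(e, length)] = True
    out = []
    for ws in range(0, length, window_bp):
        we = min(ws + window_bp, length)
        out.append(covered[ws:we].mean())
    return out


class TestCoverageWindows:
    def test_full_and_union_semantics(self):
        tracks = [IntervalTrack("c", ((0, 100),), "r"),
                  IntervalTrack("c", ((0, 100),), "r2")]
        wins = ft.coverage_windows(tracks, {"c": 100}, window_bp=100)
        assert wins[0].repeat_frac == 1.0

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_per_base_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        length = int(rng.integers(500, 10_000))
        n = int(rng.integers(1, 40))
        starts = rng.integers(0, length - 1, size=n)
        ends = starts + rng.integers(1, 500, size=n)
        intervals = tuple((int(s), int(e)) for s, e in zip(starts, ends))
        tracks = [IntervalTrack("c", intervals, "r")]
        window_bp = int(rng.integers(50, 1000))
        wins = ft.coverage_windows(tracks, {"c": length}, window_bp=window_bp)
        expected = brute_force_coverage(intervals, length, window_bp)
        assert [w.repeat_frac for w in wins] == pytest.approx(expected)

    def test_invariant_to_interval_splitting_and_order(self):
        base = [IntervalTrack("c", ((10, 60), (80, 90)), "r")]
        split = [IntervalTrack("c", ((80, 90), (35, 60), (10, 35)), "r")]
        w1 = ft.coverage_windows(base, {"c": 100}, window_bp=25)
        w2 = ft.coverage_windows(split, {"c": 100}, window_bp=25)
        assert [w.repeat_frac for w in w1] == [w.repeat_frac for w in w2]


class TestProportionalWindows:
    def test_constant_feature_constant_bins(self):
        wins = [ft.FeatureWindow("c", s, s + 100, repeat_frac=0.4)
                for s in range(0, 1000, 100)]
        vec = ft.proportional_windows(wins, 1000, k=10)
        assert vec == pytest.approx([0.4] * 10)

    def test_end_enrichment_shows_in_terminal_bins(self):
        tree = simulate.simulate_tree(2, seed=1)
        anc = simulate.simulate_ancestral_genome(
            5, counts=[80, 70, 60, 50, 40], seed=0)
        tables, _ = simulate.evolve_genomes(
            tree, anc, EvolutionParams(seed=1, spacing_bp=1000))
        table = tables["sp1"]
        model = FeatureModel(repeat_base=0.2, end_enrichment=0.3, noise_sd=0.0)
        windows, _, _ = simulate.emit_feature_tracks(
            {"sp1": table}, model, seed=2, window_bp=1000)
        terminal, central = [], []
        for chrom in table.chrom_lengths:
            rows = [r for r in windows["sp1"] if r["chromosome"] == chrom]
            wins = [ft.FeatureWindow(chrom, r["start"], r["end"],
                                     repeat_frac=r["repeat_frac"])
                    for r in rows]
            vec = ft.proportional_windows(wins, table.chrom_lengths[chrom],
                                          k=10)
            terminal += [vec[0], vec[-1]]
            central += list(vec[4:6])
        assert np.mean(terminal) > np.mean(central)

    def test_k_must_be_at_least_two(self):
        with pytest.raises(ValueError):
            ft.proportional_windows([], 1000, k=1)


class TestGc3:
    def test_third_position_only(self):
        assert ft.gc3_per_chromosome({"g": ("c", "ATGGCC")})["c"] == 1.0
        assert ft.gc3_per_chromosome({"g": ("c", "ATAGCT")})["c"] == 0.0

    def test_non_triplet_excluded(self):
        out = ft.gc3_per_chromosome({"g1": ("c", "ATGGCCA"),
                                     "g2": ("c", "ATG")})
        assert out["c"] == pytest.approx(1.0)  # only g2 retained
        out2 = ft.gc3_per_chromosome({"g1": ("c", "ATGGCCA")})
        assert out2["c"] is None

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_per_base_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        cds = {}
        expected = {}
        vals = []
        for i in range(rng.integers(2, 8)):
            n = int(rng.integers(1, 30)) * 3
            seq = "".join(rng.choice(list("ACGT"), size=n))
            cds[f"g{i}"] = ("c", seq)
            third = seq[2::3]
            vals.append(sum(b in "GC" for b in third) / len(third))
        out = ft.gc3_per_chromosome(cds)
        assert out["c"] == pytest.approx(np.mean(vals), abs=1e-12)


def layout_table(species, layout, spacing=100):
    records, lengths = [], {}
    for chrom, ids in layout.items():
        for i, oid in enumerate(ids):
            records.append(OrthologRecord(oid, "Complete", chrom,
                                          i * spacing, i * spacing + 10))
        lengths[chrom] = len(ids) * spacing
    return GenomeTable(species, records, lengths)


class TestSynteny:
    def test_identity_scores_one(self):
        t = layout_table("a", {"c1": [f"g{i}" for i in range(15)],
                               "c2": [f"h{i}" for i in range(10)]})
        scores = ft.synteny_score(t, t)
        assert scores == {"c1": 1.0, "c2": 1.0}

    def test_orientation_agnostic(self):
        ids = [f"g{i}" for i in range(12)]
        focal = layout_table("a", {"c1": ids})
        ref = layout_table("b", {"c1": list(reversed(ids))})
        assert ft.synteny_score(focal, ref)["c1"] == 1.0

    def test_decreases_with_shuffling(self):
        """Average synteny against the unshuffled reference decreases as
        the adjacent-transposition rate grows."""
        tree = simulate.simulate_tree(2, seed=3)
        anc = simulate.simulate_ancestral_genome(
            4, counts=[60, 50, 40, 30], seed=0)
        ref_tables, _ = simulate.evolve_genomes(tree, anc,
                                                EvolutionParams(seed=0))
        ref = ref_tables["sp1"]
        means = []
        for rate in (0.0, 0.3, 1.0):
            vals = []
            for seed in range(10):
                tabs, _ = simulate.evolve_genomes(
                    tree, anc, EvolutionParams(shuffle_rate=rate, seed=seed))
                scores = ft.synteny_score(tabs["sp1"], ref)
                vals += [v for v in scores.values() if v is not None]
            means.append(np.mean(vals))
        assert means[0] == pytest.approx(1.0)
        assert means[0] > means[1] > means[2]

    def test_too_few_shared_is_null(self):
        a = layout_table("a", {"c1": ["g1"]})
        b = layout_table("b", {"c1": ["g1", "g2"]})
        assert ft.synteny_score(a, b)["c1"] is None


class TestSingleCopyProportion:
    def test_fractions(self):
        classes = {f"g{i}": ("single_copy" if i < 5 else "multicopy")
                   for i in range(10)}
        locations = {f"g{i}": "c1" for i in range(10)}
        assert ft.single_copy_proportion(classes, locations) == {"c1": 0.5}
        all_single = {g: "single_copy" for g in classes}
        assert ft.single_copy_proportion(all_single, locations) == {"c1": 1.0}


def make_summaries(n, rho_sign=-1, sex_element=None, intact=True):
    out = []
    for i in range(n):
        length = (i + 1) / sum(range(1, n + 1))
        repeat = 0.5 + rho_sign * 0.4 * (i / n)
        out.append(ChromosomeSummary(
            chromosome=f"c{i}", length_bp=int(length * 1e8),
            prop_length=length, repeat_frac=repeat,
            element=f"M{i}", intact=intact))
    return out


class TestCorrelateFeatureVsLength:
    def test_planted_negative_correlation(self):
        res = ft.correlate_feature_vs_length(make_summaries(15), "repeat_frac")
        assert res.rho < 0 and res.p_value < 0.05

    def test_species_with_too_few_intact_autosomes_skipped(self):
        res = ft.correlate_feature_vs_length(make_summaries(9), "repeat_frac")
        assert res is None

    def test_sex_chromosome_excluded(self):
        summaries = make_summaries(12)
        res_all = ft.correlate_feature_vs_length(summaries, "repeat_frac")
        res_no_sex = ft.correlate_feature_vs_length(summaries, "repeat_frac",
                                                    sex_element="M0")
        assert res_no_sex.n == res_all.n - 1

    def test_unknown_feature_rejected(self):
        with pytest.raises(ValueError):
            ft.correlate_feature_vs_length(make_summaries(12), "banana")


class TestAmelioration:
    def closed_form_t(self, diffs):
        d = np.asarray(diffs, float)
        return d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))

    def test_no_difference_gives_t_zero_p_one(self):
        segs = [("M31", "M1", 0.5, 0.3), ("M30", "M2", 0.45, 0.25)]
        anc = {"M31": 0.5, "M30": 0.45, "M1": 0.3, "M2": 0.25}
        res = ft.fusion_amelioration_test(segs, anc, {"M31", "M30"})
        assert res.t == 0.0 and res.p_value == 1.0

    def test_three_pair_example_matches_closed_form(self):
        segs = [("M31", "M1", 0.40, 0.32), ("M30", "M2", 0.38, 0.30),
                ("M29", "M3", 0.35, 0.33)]
        anc = {"M31": 0.50, "M30": 0.46, "M29": 0.42,
               "M1": 0.30, "M2": 0.29, "M3": 0.31}
        res = ft.fusion_amelioration_test(segs, anc, {"M31", "M30", "M29"})
        diffs = [(0.40 - 0.50) - (0.32 - 0.30),
                 (0.38 - 0.46) - (0.30 - 0.29),
                 (0.35 - 0.42) - (0.33 - 0.31)]
        assert res.t == pytest.approx(self.closed_form_t(diffs), abs=1e-12)
        assert res.n_pairs == 3

    def test_planted_homogenization_detected(self):
        """Small fused segments drifting toward the whole-chromosome repeat
        expectation give a significant negative paired shift."""
        rng = np.random.default_rng(7)
        anc = {}
        segs = []
        for i in range(20):
            e_small, e_large = f"S{i}", f"L{i}"
            anc[e_small] = 0.45 + rng.normal(0, 0.01)
            anc[e_large] = 0.25 + rng.normal(0, 0.01)
            # after fusion the small segment homogenizes toward the large
            # chromosome's expectation; the large one barely moves
            segs.append((e_small, e_large,
                         anc[e_small] - 0.12 + rng.normal(0, 0.02),
                         anc[e_large] - 0.01 + rng.normal(0, 0.02)))
        res = ft.fusion_amelioration_test(segs, anc, set(anc))
        assert res.p_value < 0.01
        assert res.mean_delta_small < res.mean_delta_large

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError):
            ft.fusion_amelioration_test([("a", "b", 0.1, 0.2)],
                                        {"a": 0.1, "b": 0.2}, {"a"})
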