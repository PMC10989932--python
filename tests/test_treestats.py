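"""The tree-based statistics panel, checked against hand-derived values and
independent oracles."""

import itertools

import numpy as np
import pytest

from conftest import patristic_oracle
from phylokit import (
    AlignedMatrix,
    SimulationSpec,
    composition_profile,
    evolution_rate,
    evolve_alignment,
    lb_scores,
    pairwise_sequence_stats,
    parse_newick,
    patristic_matrix,
    rcv,
    root_to_tip_lengths,
    saturation_regression,
    set_outgroup,
    signal_to_noise,
    simulate_yule_tree,
    spurious_species,
    treeness,
    unroot_tree,
)
from phylokit.seqio import AMINO_ACID, NUCLEOTIDE
from phylokit.treeio import TreeError


def nt(rows):
    return AlignedMatrix(rows, NUCLEOTIDE)


class TestPatristic:
    def test_worked_tree_distances(self, worked_tree):
        dm = patristic_matrix(worked_tree)
        expected = {
            ("A", "B"): 3, ("A", "C"): 7, ("A", "D"): 8,
            ("B", "C"): 8, ("B", "D"): 9, ("C", "D"): 7,
        }
        for (a, b), d in expected.items():
            assert dm.get(a, b) == pytest.approx(d)

    def test_two_leaf_tree(self):
        assert patristic_matrix(parse_newick("(A:1,B:2);")).get("A", "B") == pytest.approx(3)

    def test_matches_brute_force_oracle(self):
        for seed in range(30):
            tree = simulate_yule_tree(SimulationSpec(n_taxa=8, seed=seed))
            dm = patristic_matrix(tree)
            oracle = patristic_oracle(tree)
            for key, value in oracle.items():
                a, b = sorted(key)
                assert dm.get(a, b) == pytest.approx(value, abs=1e-12)

    def test_agrees_with_dendropy(self):
        import dendropy

        from phylokit import write_newick

        tree = simulate_yule_tree(SimulationSpec(n_taxa=10, seed=3))
        dm = patristic_matrix(tree)
        dtree = dendropy.Tree.get(data=write_newick(tree), schema="newick")
        pdm = dtree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in dtree.taxon_namespace}
        for a, b in itertools.combinations(dm.taxa, 2):
            assert dm.get(a, b) == pytest.approx(
                pdm.patristic_distance(taxa[a], taxa[b]), rel=1e-9
            )

    def test_four_point_condition(self):
        tree = simulate_yule_tree(SimulationSpec(n_taxa=8, seed=5))
        dm = patristic_matrix(tree)
        for w, x, y, z in itertools.combinations(range(len(dm.taxa)), 4):
            sums = sorted(
                [
                    dm.values[w, x] + dm.values[y, z],
                    dm.values[w, y] + dm.values[x, z],
                    dm.values[w, z] + dm.values[x, y],
                ]
            )
            assert sums[1] == pytest.approx(sums[2], abs=1e-9)

    def test_missing_length_raises(self):
        with pytest.raises(TreeError, match="missing"):
            patristic_matrix(parse_newick("(A:1,B);"))

    def test_invariant_under_rerooting(self, worked_tree):
        dm0 = patristic_matrix(worked_tree)
        for variant in (unroot_tree(worked_tree), set_outgroup(worked_tree, {"C", "D"})):
            dm1 = patristic_matrix(variant)
            for a, b in itertools.combinations(dm0.taxa, 2):
                assert dm1.get(a, b) == pytest.approx(dm0.get(a, b), abs=1e-9)


class TestRootToTip:
    def test_worked_tree(self, worked_tree):
        assert root_to_tip_lengths(worked_tree) == pytest.approx(
            {"A": 2, "B": 3, "C": 5, "D": 6}
        )

    def test_ultrametric_equal(self):
        lengths = root_to_tip_lengths(parse_newick("((A:1,B:1):1,(C:1,D:1):1);"))
        assert all(v == pytest.approx(2) for v in lengths.values())

    def test_unrooted_errors_with_guidance(self):
        with pytest.raises(TreeError, match="outgroup"):
            root_to_tip_lengths(parse_newick("(A:1,B:1,C:1);"))


class TestLBScores:
    def test_worked_tree_scores(self, worked_tree):
        report = lb_scores(worked_tree)
        assert report.lb["A"] == pytest.approx(-14.2857, abs=1e-4)
        assert report.lb["B"] == pytest.approx(-4.7619, abs=1e-4)
        assert report.lb["C"] == pytest.approx(4.7619, abs=1e-4)
        assert report.lb["D"] == pytest.approx(14.2857, abs=1e-4)
        assert report.overall_mean_pd == pytest.approx(7.0)

    def test_star_tree_all_zero(self):
        report = lb_scores(parse_newick("(A:1,B:1,C:1,D:1);"))
        assert all(v == pytest.approx(0, abs=1e-12) for v in report.lb.values())

    def test_scores_sum_to_zero(self):
        for seed in range(50):
            tree = simulate_yule_tree(SimulationSpec(n_taxa=4 + seed % 30, seed=seed))
            report = lb_scores(tree)
            assert np.mean(list(report.lb.values())) == pytest.approx(0, abs=1e-9)

    def test_summary_fields(self, worked_tree):
        s = lb_scores(worked_tree).summary
        assert s["min"] <= s["mean"] <= s["max"]
        assert s["sd"] > 0


class TestSpurious:
    def test_worked_tree_default_threshold(self, worked_tree):
        flagged, median, terminal = spurious_species(worked_tree)
        assert median == pytest.approx(2.0)
        assert flagged == []
        assert terminal == pytest.approx({"A": 1, "B": 2, "C": 3, "D": 4})

    def test_threshold_15_flags_c_and_d(self, worked_tree):
        flagged, _, _ = spurious_species(worked_tree, threshold=1.5)
        assert sorted(flagged) == ["C", "D"]

    def test_boundary_case_is_flagged(self):
        # median of {1,1,1,1,1,6} is 1; terminal 6 == 6 x median
        tree = parse_newick("((A:1,B:1):1,(C:1,D:6):1);")
        flagged, median, _ = spurious_species(tree, threshold=6)
        assert median == pytest.approx(1.0)
        assert flagged == ["D"]

    def test_degenerate_tree_errors(self):
        with pytest.raises(TreeError, match="degenerate"):
            spurious_species(parse_newick("(A:0,B:0,C:0);"))


class TestTreenessAndRate:
    def test_worked_tree_treeness(self, worked_tree):
        assert treeness(worked_tree) == pytest.approx(3 / 13)

    def test_star_tree_zero(self):
        assert treeness(parse_newick("(A:1,B:1,C:1);")) == 0

    def test_longer_internal_edge_increases_treeness(self, worked_tree):
        base = treeness(worked_tree)
        bumped = parse_newick("((A:1,B:2):1.5,(C:3,D:4):2);")
        assert treeness(bumped) > base

    def test_evolution_rate_worked_tree(self, worked_tree):
        assert evolution_rate(worked_tree) == pytest.approx(13 / 4)

    def test_evolution_rate_star_and_scaling(self):
        assert evolution_rate(parse_newick("(A:2,B:2,C:2);")) == pytest.approx(2)
        tree1 = simulate_yule_tree(SimulationSpec(n_taxa=12, seed=2))
        tree2 = simulate_yule_tree(SimulationSpec(n_taxa=12, seed=2, scale=3.0))
        assert evolution_rate(tree2) == pytest.approx(3 * evolution_rate(tree1))

    def test_rooting_invariance_of_tree_statistics(self, worked_tree):
        unrooted = unroot_tree(worked_tree)
        assert treeness(unrooted) == pytest.approx(treeness(worked_tree))
        assert evolution_rate(unrooted) == pytest.approx(evolution_rate(worked_tree))
        lb0 = lb_scores(worked_tree).lb
        lb1 = lb_scores(unrooted).lb
        for taxon in lb0:
            assert lb1[taxon] == pytest.approx(lb0[taxon], abs=1e-9)


class TestComposition:
    def test_degenerate_base_half_weights(self):
        profile = composition_profile(nt([("a", "Y"), ("b", "C")]))
        c = {s: list(profile.counts[i]) for i, s in enumerate(profile.states)}
        assert c["C"] == [0.5, 1.0]
        assert c["T"] == [0.5, 0.0]

    def test_third_weights_for_d(self):
        profile = composition_profile(nt([("a", "D")]))
        by_state = dict(zip(profile.states, profile.counts[:, 0]))
        assert by_state == pytest.approx({"A": 1 / 3, "C": 0, "G": 1 / 3, "T": 1 / 3})

    def test_gaps_contribute_nothing(self):
        profile = composition_profile(nt([("a", "-?"), ("b", "--")]))
        assert profile.counts.sum() == 0
        assert profile.t == 2

    def test_protein_ambiguity(self):
        profile = composition_profile(AlignedMatrix([("a", "B")], AMINO_ACID))
        by_state = dict(zip(profile.states, profile.counts[:, 0]))
        assert by_state["D"] == pytest.approx(0.5)
        assert by_state["N"] == pytest.approx(0.5)


class TestRCV:
    def test_opposite_homopolymers(self):
        assert rcv(nt([("a", "AAAA"), ("b", "TTTT")]))[0] == pytest.approx(1.0)

    def test_identical_rows_zero(self):
        assert rcv(nt([("a", "ACGT"), ("b", "ACGT")]))[0] == pytest.approx(0.0)

    def test_half_weighted_column(self):
        overall, per_taxon = rcv(nt([("a", "Y"), ("b", "C")]))
        assert overall == pytest.approx(0.5)
        assert sum(per_taxon.values()) == pytest.approx(overall)

    def test_per_taxon_sums_to_overall(self):
        spec = SimulationSpec(n_taxa=10, seed=4, length=60)
        aln = evolve_alignment(simulate_yule_tree(spec), spec)
        overall, per_taxon = rcv(aln)
        assert sum(per_taxon.values()) == pytest.approx(overall, abs=1e-12)

    def test_invariance_under_column_permutation_and_duplication(self):
        rng = np.random.default_rng(0)
        spec = SimulationSpec(n_taxa=6, seed=9, length=30)
        aln = evolve_alignment(simulate_yule_tree(spec), spec)
        overall, _ = rcv(aln)
        perm = list(rng.permutation(aln.t))
        assert rcv(aln.columns(perm))[0] == pytest.approx(overall, abs=1e-12)
        doubled = AlignedMatrix([(lab, seq + seq) for lab, seq in aln.rows], NUCLEOTIDE)
        assert rcv(doubled)[0] == pytest.approx(overall, abs=1e-12)


class TestSignalToNoise:
    def test_composition_of_components(self, worked_tree):
        aln = nt([(t, s) for t, s in zip("ABCD", ["AAAA", "TTTT", "AAAA", "TTTT"])])
        result = signal_to_noise(worked_tree, aln)
        assert result["signal_to_noise"] == pytest.approx((3 / 13) / result["rcv"])

    def test_zero_rcv_errors(self, worked_tree):
        aln = nt([(t, "ACGT") for t in "ABCD"])
        with pytest.raises(ZeroDivisionError):
            signal_to_noise(worked_tree, aln)

    def test_branch_scale_invariance(self, worked_tree):
        aln = nt([(t, s) for t, s in zip("ABCD", ["AAAA", "TTTT", "AACC", "TTGG"])])
        doubled = parse_newick("((A:2,B:4):2,(C:6,D:8):4);")
        assert signal_to_noise(doubled, aln)["signal_to_noise"] == pytest.approx(
            signal_to_noise(worked_tree, aln)["signal_to_noise"]
        )

    def test_missing_leaf_errors(self, worked_tree):
        with pytest.raises(ValueError, match="absent"):
            signal_to_noise(worked_tree, nt([("A", "AC"), ("B", "GT")]))


class TestPairwiseStats:
    def test_single_mismatch(self):
        _, records = pairwise_sequence_stats(nt([("a", "ACGT"), ("b", "ACGA")]))
        rec = records[0]
        assert rec["difference"] == pytest.approx(0.25)
        assert rec["identity"] == pytest.approx(0.75)
        assert rec["compared"] == 4

    def test_identical_rows(self):
        _, records = pairwise_sequence_stats(nt([("a", "ACGT"), ("b", "ACGT")]))
        assert records[0]["difference"] == 0 and records[0]["identity"] == 1

    def test_pairwise_deletion_of_gaps_and_ambiguity(self):
        _, records = pairwise_sequence_stats(nt([("a", "AC-TN"), ("b", "ACGTA")]))
        assert records[0]["compared"] == 3
        assert records[0]["difference"] == 0

    def test_difference_plus_identity_is_one(self):
        spec = SimulationSpec(n_taxa=8, seed=6, length=90)
        aln = evolve_alignment(simulate_yule_tree(spec), spec)
        _, records = pairwise_sequence_stats(aln)
        for rec in records:
            assert rec["difference"] + rec["identity"] == pytest.approx(1.0)


class TestSaturation:
    def test_perfectly_linear_points(self):
        tree = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        aln = nt(
            [
                ("A", "AAAAAAAAAA"),
                ("B", "CCAAAAAAAA"),
                ("C", "GGGGAAAAAA"),
                ("D", "GGCCAAAAAA"),
            ]
        )
        result = saturation_regression(tree, aln)
        assert result.slope == pytest.approx(0.1)
        assert result.intercept == pytest.approx(0.0, abs=1e-12)
        assert result.r_squared == pytest.approx(1.0)

    def test_constant_y_gives_zero_slope(self):
        tree = parse_newick("((A:1,B:2):1,(C:3,D:4):2);")
        aln = nt([(t, "ACGT") for t in "ABCD"])
        result = saturation_regression(tree, aln)
        assert result.slope == pytest.approx(0.0)
        assert result.r_squared == pytest.approx(0.0)

    def test_high_divergence_lowers_slope_and_r2(self):
        low = SimulationSpec(n_taxa=12, seed=8, length=2000, scale=0.02)
        high = SimulationSpec(n_taxa=12, seed=8, length=2000, scale=0.5)
        tree_low = simulate_yule_tree(low)
        tree_high = simulate_yule_tree(high)
        res_low = saturation_regression(tree_low, evolve_alignment(tree_low, low))
        res_high = saturation_regression(tree_high, evolve_alignment(tree_high, high))
        assert res_high.slope < res_low.slope
        assert res_high.r_squared < res_low.r_squared

    def test_through_origin_mode(self):
        tree = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        aln = nt(
            [
                ("A", "AAAAAAAAAA"),
                ("B", "CCAAAAAAAA"),
                ("C", "GGGGAAAAAA"),
                ("D", "GGCCAAAAAA"),
            ]
        )
        result = saturation_regression(tree, aln, fit="through_origin")
        assert result.intercept == 0.0
        assert result.slope == pytest.approx(0.1)
        assert 0 <= result.r_squared <= 1

    def test_plot_data_tsv_shape(self, worked_tree):
        aln = nt([(t, s) for t, s in zip("ABCD", ["AAAA", "TTTT", "AACC", "TTGG"])])
        result = saturation_regression(worked_tree, aln)
        lines = result.plot_data_tsv().strip().splitlines()
        assert lines[0].startswith("taxon_1\ttaxon_2")
        assert len(lines) == 1 + 6
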