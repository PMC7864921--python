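import numpy as np
import pandas as pd
import pytest

from crustassembly import (
    OtuTable,
    PhyloTree,
    beta_nti,
    betamntd,
    partition_processes,
    raup_crick_bray,
)
from crustassembly.assembly import (
    BetaNTIMatrix,
    RaupCrickMatrix,
    assembly_by_angle,
    classify_pair,
)
from crustassembly.beta_diversity import DistMatrix
from oracles import exact_rc, naive_beta_nti, naive_betamntd, naive_patristic


def table(rows, samples, taxa):
    return OtuTable(pd.DataFrame(rows, index=samples, columns=taxa, dtype=float))


class TestBetaMntd:
    def test_identical_communities_zero(self, toy_tree):
        t = table([[1, 1, 1], [1, 1, 1]], ["x", "y"], ["A", "B", "C"])
        assert betamntd(t, toy_tree).values[0, 1] == 0

    def test_monodominant_pair_equals_patristic_distance(self, toy_tree):
        t = table([[1, 0, 0], [0, 1, 0]], ["x", "y"], ["A", "B", "C"])
        # d(A, B) = 2 on the toy tree
        assert betamntd(t, toy_tree).values[0, 1] == pytest.approx(2.0)

    def test_three_taxon_worked_example(self, toy_tree):
        """x = {A: 1}, y = {B: 0.5, C: 0.5} on ((A:1,B:1):1,C:2) gives 2.5."""
        t = table([[1.0, 0, 0], [0, 0.5, 0.5]], ["x", "y"], ["A", "B", "C"])
        assert betamntd(t, toy_tree).values[0, 1] == pytest.approx(2.5)

    def test_missing_taxon_error_lists_names(self, toy_tree):
        t = table([[1, 1], [1, 1]], ["x", "y"], ["A", "ZZZ"])
        with pytest.raises(KeyError, match="ZZZ"):
            betamntd(t, toy_tree)

    def test_matches_naive_oracle_on_random_instance(self):
        from crustassembly import simulate_tree
        tree = simulate_tree(12, seed=5)
        rng = np.random.default_rng(6)
        counts = rng.integers(0, 20, size=(5, 12)).astype(float)
        counts[counts.sum(axis=1) == 0, 0] = 1
        D, labels = naive_patristic(tree)
        t = table(counts, [f"s{i}" for i in range(5)], labels)
        ours = betamntd(t, tree).values
        ref = naive_betamntd(counts, D)
        np.testing.assert_allclose(ours, ref, atol=1e-10)

    def test_unweighted_variant_matches_oracle(self):
        from crustassembly import simulate_tree
        tree = simulate_tree(8, seed=9)
        rng = np.random.default_rng(10)
        counts = rng.integers(0, 5, size=(4, 8)).astype(float)
        counts[counts.sum(axis=1) == 0, 0] = 1
        D, labels = naive_patristic(tree)
        t = table(counts, [f"s{i}" for i in range(4)], labels)
        ours = betamntd(t, tree, abundance_weighted=False).values
        ref = naive_betamntd(counts, D, weighted=False)
        np.testing.assert_allclose(ours, ref, atol=1e-10)


class TestBetaNti:
    def test_star_tree_all_pairs_undefined(self):
        star = PhyloTree.from_newick("(A:1,B:1,C:1,D:1);")
        t = table([[1, 2, 0, 0], [0, 0, 2, 1]], ["x", "y"], list("ABCD"))
        res = beta_nti(t, star, n_null=99, seed=0)
        assert np.isnan(res.values[0, 1])
        assert res.undefined_pairs == 1

    def test_same_clade_communities_strongly_negative(self):
        # ten distant clades; x and y occupy disjoint halves of the same
        # clade, so observed nearest-taxon distances are tiny while tip
        # shuffles scatter the two communities across all clades
        taxa = [f"C{c}_{i}" for c in range(10) for i in range(4)]
        clades = ",".join(
            "(" + ",".join(f"C{c}_{i}:0.1" for i in range(4)) + "):5"
            for c in range(10)
        )
        tree = PhyloTree.from_newick(f"({clades});")
        x = np.zeros(40)
        y = np.zeros(40)
        x[:2] = 1.0    # C0_0, C0_1
        y[2:4] = 1.0   # C0_2, C0_3
        t = table([x, y], ["x", "y"], taxa)
        res = beta_nti(t, tree, n_null=199, seed=1)
        assert res.values[0, 1] < -2

    def test_matches_naive_oracle_with_same_shuffle_stream(self):
        from crustassembly import simulate_tree
        tree = simulate_tree(10, seed=2)
        rng = np.random.default_rng(3)
        counts = rng.integers(0, 30, size=(4, 10)).astype(float)
        counts[counts.sum(axis=1) == 0, 0] = 1
        D, labels = naive_patristic(tree)
        # implementation canonicalises taxa to sorted order; feed sorted
        order = np.argsort(labels)
        labels_sorted = [labels[i] for i in order]
        counts_sorted = counts[:, order]
        D_sorted = D[np.ix_(order, order)]
        t = table(counts_sorted, [f"s{i}" for i in range(4)], labels_sorted)
        ours = beta_nti(t, tree, n_null=99, seed=7).values
        ref = naive_beta_nti(counts_sorted, D_sorted, n_null=99, seed=7)
        np.testing.assert_allclose(ours, ref, atol=1e-10)

    def test_invariant_to_column_permutation(self):
        from crustassembly import simulate_tree
        tree = simulate_tree(10, seed=2)
        rng = np.random.default_rng(3)
        counts = rng.integers(0, 30, size=(4, 10)).astype(float)
        counts[counts.sum(axis=1) == 0, 0] = 1
        labels = tree.leaf_labels
        t1 = table(counts, [f"s{i}" for i in range(4)], labels)
        perm = rng.permutation(10)
        t2 = table(counts[:, perm], [f"s{i}" for i in range(4)],
                   [labels[i] for i in perm])
        a = beta_nti(t1, tree, n_null=99, seed=4).values
        b = beta_nti(t2, tree, n_null=99, seed=4).values
        np.testing.assert_allclose(a, b, atol=1e-12)


class TestRaupCrick:
    def test_identical_samples_strongly_negative(self):
        rng = np.random.default_rng(0)
        pool = rng.integers(1, 20, size=30).astype(float)
        t = table([pool, pool], ["x", "y"], [f"t{i}" for i in range(30)])
        res = raup_crick_bray(t, n_null=999, seed=0, null_mode="per_pair")
        assert res.values[0, 1] <= -0.9

    def test_disjoint_samples_strongly_positive(self):
        a = np.zeros(40)
        b = np.zeros(40)
        a[:15] = 5
        b[25:] = 5
        t = table([a, b], ["x", "y"], [f"t{i}" for i in range(40)])
        res = raup_crick_bray(t, n_null=999, seed=0, null_mode="per_pair")
        assert res.values[0, 1] >= 0.9

    def test_non_integer_counts_rejected(self):
        t = OtuTable(pd.DataFrame([[0.5, 0.5], [0.2, 0.8]], index=["x", "y"],
                                  columns=["a", "b"]))
        with pytest.raises(ValueError, match="integer counts"):
            raup_crick_bray(t, n_null=99)

    def test_monte_carlo_matches_enumerated_null(self):
        """5-taxon, 2-sample instance vs the exhaustively enumerated null."""
        a = np.array([2, 1, 0, 0, 0], dtype=float)
        b = np.array([0, 1, 2, 0, 1], dtype=float)
        t = table([a, b], ["x", "y"], list("vwxyz"))
        occupancy = ((np.stack([a, b]) > 0).mean(axis=0))
        regional = (a + b) / (a + b).sum()
        ref = exact_rc(a, b, occupancy, regional)
        res = raup_crick_bray(t, n_null=9999, seed=1, null_mode="per_pair")
        assert res.values[0, 1] == pytest.approx(ref, abs=0.03)

    def test_shared_and_per_pair_modes_agree_in_distribution(self):
        rng = np.random.default_rng(5)
        counts = rng.integers(0, 10, size=(4, 25)).astype(float)
        counts[counts.sum(axis=1) == 0, 0] = 1
        t = table(counts, list("wxyz"), [f"t{i}" for i in range(25)])
        shared = raup_crick_bray(t, n_null=999, seed=2, null_mode="shared")
        per_pair = raup_crick_bray(t, n_null=999, seed=3, null_mode="per_pair")
        iu = np.triu_indices(4, 1)
        np.testing.assert_allclose(shared.values[iu], per_pair.values[iu], atol=0.12)


class TestPartition:
    def test_threshold_rules(self):
        assert classify_pair(3.1, -0.99) == "heterogeneous_selection"
        assert classify_pair(-2.5, 0.99) == "homogeneous_selection"
        assert classify_pair(0.5, 0.99) == "dispersal_limitation"
        assert classify_pair(0.5, -0.99) == "homogenizing_dispersal"
        assert classify_pair(0.5, 0.5) == "drift"
        assert classify_pair(float("nan"), 0.5) is None

    def test_hand_tally_on_ten_pairs(self):
        # 5 samples -> 10 pairs with hand-assigned (bNTI, RC) values
        ids = tuple("abcde")
        bn = np.zeros((5, 5))
        rc = np.zeros((5, 5))
        assignments = {
            (0, 1): (3.0, 0.0),    # het sel
            (0, 2): (-3.0, 0.0),   # hom sel
            (0, 3): (0.0, 0.99),   # displim
            (0, 4): (0.0, -0.99),  # homogenizing
            (1, 2): (1.0, 0.5),    # drift
            (1, 3): (1.9, 0.99),   # displim
            (1, 4): (2.1, -0.99),  # het sel
            (2, 3): (-2.1, 0.99),  # hom sel
            (2, 4): (0.0, 0.0),    # drift
            (3, 4): (0.0, 0.96),   # displim
        }
        for (i, j), (z, r) in assignments.items():
            bn[i, j] = bn[j, i] = z
            rc[i, j] = rc[j, i] = r
        bnm = BetaNTIMatrix(DistMatrix(ids, bn), 999, 0)
        rcm = RaupCrickMatrix(DistMatrix(ids, rc), 999, 0)
        pf = partition_processes(bnm, rcm)
        assert pf.n_pairs == 10
        assert pf.percentages == {
            "homogeneous_selection": 20.0,
            "heterogeneous_selection": 20.0,
            "homogenizing_dispersal": 10.0,
            "dispersal_limitation": 30.0,
            "drift": 20.0,
        }
        assert sum(pf.percentages.values()) == pytest.approx(100.0)
        assert pf.species_sorting == pytest.approx(40.0)

    def test_undefined_pairs_counted_not_dropped_silently(self):
        ids = tuple("abc")
        bn = np.zeros((3, 3))
        bn[0, 1] = bn[1, 0] = np.nan
        bn[0, 2] = bn[2, 0] = 3.0
        rcm = RaupCrickMatrix(DistMatrix(ids, np.zeros((3, 3))), 999, 0)
        pf = partition_processes(BetaNTIMatrix(DistMatrix(ids, bn), 999, 0), rcm)
        assert pf.n_undefined == 1
        assert pf.n_pairs == 2


class TestAssemblyByAngle:
    def test_drift_fixture_selection_below_30pct(self, drift_fixture_dir):
        from crustassembly import read_otu_table, read_metadata, read_tree
        t = read_otu_table(drift_fixture_dir / "otu.tsv")
        tree = read_tree(drift_fixture_dir / "tree.nwk")
        meta = read_metadata(drift_fixture_dir / "metadata.tsv")
        results = assembly_by_angle(t, tree, meta, "longitude",
                                    n_null=99, seed=0)
        assert results  # at least one level
        for pf in results:
            assert pf.species_sorting < 30.0

    def test_small_level_warned_and_skipped(self, toy_tree):
        from conftest import make_metadata
        # one sample in W, three in M: W must be skipped with a warning
        meta = make_metadata(lons=[90.0, 100.0, 101.0, 102.0])
        t = table([[5, 1, 0], [0, 1, 5], [1, 5, 0], [5, 0, 1]],
                  [f"s{i}" for i in range(4)], ["A", "B", "C"])
        with pytest.warns(UserWarning, match="fewer than 2"):
            results = assembly_by_angle(t, toy_tree, meta, "longitude",
                                        n_null=99, seed=0)
        assert [r.group for r in results] == ["M"]

    def test_nnull_doubling_stability(self):
        from crustassembly import simulate_scenario
        otu, meta, env, tax, tree, traits = simulate_scenario(
            "dispersal_limitation", seed=0, n_sites=4, n_taxa=80)
        b1 = beta_nti(otu, tree, n_null=199, seed=5)
        b2 = beta_nti(otu, tree, n_null=398, seed=5)
        iu = np.triu_indices(otu.n_samples, 1)
        assert np.nanmax(np.abs(b1.values[iu] - b2.values[iu])) < 0.2
        r1 = raup_crick_bray(otu, n_null=199, seed=6)
        r2 = raup_crick_bray(otu, n_null=398, seed=6)
        assert np.nanmax(np.abs(r1.values[iu] - r2.values[iu])) < 0.05
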