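import itertools
import shutil
import subprocess
import textwrap

import numpy as np
import pytest

from ecoassembly.assembly import (beta_mntd, beta_mntd_matrix, beta_nti,
                                  cophenetic_distances, pairwise_assembly,
                                  partition_processes, process_fractions,
                                  raup_crick_bray)
from ecoassembly.core import CommunityTable, DataValidationError

from conftest import tree_from_newick


def brute_force_beta_mntd(x, y, d, weighted):
    """Independent reference: explicit loops over nearest taxa."""
    def one_way(a, b):
        pres_a = [i for i, v in enumerate(a) if v > 0]
        pres_b = [j for j, v in enumerate(b) if v > 0]
        total = 0.0
        for i in pres_a:
            nearest = min(d[i][j] for j in pres_b)
            w = a[i] / sum(a) if weighted else 1.0 / len(pres_a)
            total += w * nearest
        return total
    return 0.5 * (one_way(x, y) + one_way(y, x))


class TestCophenetic:
    def test_two_tip(self):
        d, ids = cophenetic_distances(tree_from_newick("(A:1,B:1);"))
        assert d[ids.index("A"), ids.index("B")] == 2.0
        assert np.allclose(np.diag(d), 0)

    def test_hand_computed_path_sums(self):
        d, ids = cophenetic_distances(tree_from_newick("((A:1,B:2):0.5,C:3);"),
                                      taxon_order=["A", "B", "C"])
        assert d[0, 2] == pytest.approx(4.5)
        assert d[1, 2] == pytest.approx(5.5)
        assert d[0, 1] == pytest.approx(3.0)
        assert np.allclose(d, d.T)


class TestBetaMNTD:
    def test_identical_communities_zero(self, four_tip_tree):
        d, ids = cophenetic_distances(four_tip_tree,
                                      taxon_order=["A", "B", "C", "D"])
        x = np.array([3, 1, 0, 2])
        assert beta_mntd(x, x, d) == 0.0

    def test_singletons_reduce_to_pairwise_distance(self):
        d, ids = cophenetic_distances(tree_from_newick("(A:1,B:1);"))
        a = np.zeros(2)
        b = np.zeros(2)
        a[ids.index("A")] = 5
        b[ids.index("B")] = 9
        assert beta_mntd(a, b, d) == pytest.approx(2.0)

    @pytest.mark.parametrize("weighted", [True, False])
    def test_matches_brute_force(self, four_tip_tree, weighted):
        d, _ = cophenetic_distances(four_tip_tree,
                                    taxon_order=["A", "B", "C", "D"])
        cases = [
            (np.array([2, 2, 0, 0]), np.array([0, 0, 1, 3])),
            (np.array([1, 0, 4, 0]), np.array([0, 7, 0, 2])),
            (np.array([1, 1, 1, 1]), np.array([0, 0, 0, 5])),
            (np.array([3, 0, 1, 0]), np.array([3, 0, 1, 0])),
        ]
        for x, y in cases:
            expected = brute_force_beta_mntd(x, y, d, weighted)
            assert beta_mntd(x, y, d, weighted=weighted) == pytest.approx(expected)

    @pytest.mark.parametrize("weighted", [True, False])
    def test_matrix_matches_brute_force_random(self, weighted):
        from ecoassembly.simulate import simulate_tree
        rng = np.random.default_rng(11)
        tree = simulate_tree(12, seed=5)
        table = CommunityTable(
            [f"S{i}" for i in range(5)],
            [t.name for t in tree.tips()],
            rng.integers(0, 8, size=(5, 12)) * rng.integers(0, 2, size=(5, 12)) + 1,
        )
        d, _ = cophenetic_distances(tree, taxon_order=table.taxon_ids)
        mat = beta_mntd_matrix(table, d, weighted=weighted)
        for k in range(5):
            for m in range(k + 1, 5):
                expected = brute_force_beta_mntd(table.counts[k], table.counts[m],
                                                 d, weighted)
                assert mat[k, m] == pytest.approx(expected)

    def test_scale_invariance_weighted(self, four_tip_tree):
        d, _ = cophenetic_distances(four_tip_tree,
                                    taxon_order=["A", "B", "C", "D"])
        x = np.array([2, 1, 0, 0])
        y = np.array([0, 1, 3, 1])
        assert beta_mntd(x * 7, y, d) == pytest.approx(beta_mntd(x, y, d))

    def test_empty_community_error(self, four_tip_tree):
        d, _ = cophenetic_distances(four_tip_tree,
                                    taxon_order=["A", "B", "C", "D"])
        with pytest.raises(DataValidationError):
            beta_mntd(np.zeros(4), np.array([1, 0, 0, 0]), d)


@pytest.mark.skipif(shutil.which("Rscript") is None,
                    reason="Rscript not available")
def test_beta_mntd_matches_picante(tmp_path):
    """Cross-check abundance-weighted betaMNTD against picante::comdistnt."""
    from ecoassembly.simulate import simulate_tree
    rng = np.random.default_rng(3)
    tree = simulate_tree(10, seed=2)
    taxa = [t.name for t in tree.tips()]
    counts = rng.integers(0, 10, size=(4, 10))
    counts[counts.sum(axis=1) == 0, 0] = 1
    table = CommunityTable([f"S{i}" for i in range(4)], taxa, counts)
    tree.write(str(tmp_path / "tree.nwk"))
    np.savetxt(tmp_path / "comm.csv", counts, delimiter=",", fmt="%d")
    script = textwrap.dedent(f"""
        suppressMessages(library(picante))
        tree <- read.tree("{tmp_path}/tree.nwk")
        comm <- as.matrix(read.csv("{tmp_path}/comm.csv", header=FALSE))
        colnames(comm) <- c({', '.join(repr(t) for t in taxa)})
        d <- cophenetic(tree)
        out <- as.matrix(comdistnt(comm, d, abundance.weighted=TRUE))
        write.table(out, "{tmp_path}/out.csv", sep=",", col.names=FALSE,
                    row.names=FALSE)
    """)
    subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
    expected = np.loadtxt(tmp_path / "out.csv", delimiter=",")
    d, _ = cophenetic_distances(tree, taxon_order=taxa)
    ours = beta_mntd_matrix(table, d, weighted=True)
    np.testing.assert_allclose(ours, expected, atol=1e-8)


class TestBetaNTI:
    def test_deterministic_given_seed(self, small_table, four_tip_tree):
        a = beta_nti(small_table, four_tip_tree, n_null=99, seed=4)
        b = beta_nti(small_table, four_tip_tree, n_null=99, seed=4)
        np.testing.assert_array_equal(a.beta_nti, b.beta_nti)

    def test_identical_communities_undefined(self, four_tip_tree):
        table = CommunityTable(["S1", "S2"], ["A", "B", "C", "D"],
                               np.array([[3, 1, 0, 0], [3, 1, 0, 0]]))
        res = beta_nti(table, four_tip_tree, n_null=99, seed=0)
        assert np.isnan(res.beta_nti[0, 1])
        assert res.beta_mntd_obs[0, 1] == 0.0

    def test_invariant_to_consistent_relabeling(self, four_tip_tree):
        # exact for the observed statistic; statistical for the Monte-Carlo
        # null (the null law is permutation-symmetric, the draws are not)
        table = CommunityTable(["S1", "S2"], ["A", "B", "C", "D"],
                               np.array([[3, 1, 2, 0], [0, 1, 0, 5]]))
        shuffled = table.select_taxa(["C", "A", "D", "B"])
        a = beta_nti(table, four_tip_tree, n_null=5000, seed=9)
        b = beta_nti(shuffled, four_tip_tree, n_null=5000, seed=9)
        assert a.beta_mntd_obs[0, 1] == b.beta_mntd_obs[0, 1]
        np.testing.assert_allclose(a.beta_nti[0, 1], b.beta_nti[0, 1], rtol=0.1)

    def test_small_n_null_rejected(self, small_table, four_tip_tree):
        with pytest.raises(ValueError):
            beta_nti(small_table, four_tip_tree, n_null=1)

    def test_null_matches_exhaustive_on_four_tips(self, four_tip_tree):
        """Monte-Carlo null mean/sd converge to the exact tip-permutation
        enumeration (all 4! relabelings) on a 4-tip tree."""
        table = CommunityTable(["S1", "S2"], ["A", "B", "C", "D"],
                               np.array([[4, 2, 0, 0], [0, 0, 3, 5]]))
        d, _ = cophenetic_distances(four_tip_tree,
                                    taxon_order=["A", "B", "C", "D"])
        vals = []
        for perm in itertools.permutations(range(4)):
            p = np.array(perm)
            vals.append(beta_mntd(table.counts[0], table.counts[1],
                                  d[np.ix_(p, p)]))
        exact_mean, exact_sd = np.mean(vals), np.std(vals)
        res = beta_nti(table, four_tip_tree, n_null=20000, seed=12)
        assert res.null_mean[0, 1] == pytest.approx(exact_mean, rel=0.02)
        assert res.null_sd[0, 1] == pytest.approx(exact_sd, rel=0.03)

    def test_per_pair_null_agrees_with_shared(self, four_tip_tree):
        table = CommunityTable(["S1", "S2"], ["A", "B", "C", "D"],
                               np.array([[4, 2, 0, 0], [0, 0, 3, 5]]))
        a = beta_nti(table, four_tip_tree, n_null=5000, seed=1)
        b = beta_nti(table, four_tip_tree, n_null=5000, seed=2,
                     shared_null=False)
        assert a.null_mean[0, 1] == pytest.approx(b.null_mean[0, 1], rel=0.05)


class TestRaupCrick:
    def test_bounded(self):
        rng = np.random.default_rng(5)
        table = CommunityTable([f"S{i}" for i in range(5)],
                               [f"t{j}" for j in range(8)],
                               rng.integers(0, 30, size=(5, 8)) + 1)
        rc = raup_crick_bray(table, n_null=99, seed=0)
        iu = np.triu_indices(5, 1)
        assert (rc[iu] >= -1).all() and (rc[iu] <= 1).all()

    def test_deterministic_given_seed(self, small_table):
        a = raup_crick_bray(small_table, n_null=99, seed=8)
        b = raup_crick_bray(small_table, n_null=99, seed=8)
        np.testing.assert_array_equal(a, b)

    def test_identical_communities_near_minus_one(self):
        # two identical 2-taxon samples inside a broad occurrence pool:
        # virtually every null assembly is more dissimilar than observed
        counts = np.zeros((6, 10), dtype=int)
        counts[0, [0, 1]] = [50, 50]
        counts[1, [0, 1]] = [50, 50]
        for i, s in enumerate(range(2, 6)):
            counts[s, [2 + 2 * i, 3 + 2 * i]] = [40, 60]
        table = CommunityTable([f"S{i}" for i in range(6)],
                               [f"t{j}" for j in range(10)], counts)
        rc = raup_crick_bray(table, n_null=999, seed=3)
        assert rc[0, 1] <= -0.99

    def test_zero_total_rejected(self):
        table = CommunityTable(["S1", "S2"], ["A"], np.array([[1], [0]]))
        with pytest.raises(DataValidationError):
            raup_crick_bray(table, n_null=10)


class TestPartition:
    @pytest.mark.parametrize("nti,rc,expected", [
        (-2.5, None, "homogeneous_selection"),
        (2.5, None, "heterogeneous_selection"),
        (1.0, 0.97, "dispersal_limitation"),
        (1.0, -0.97, "homogenizing_dispersal"),
        (-1.0, 0.30, "undominated"),
    ])
    def test_worked_classifications(self, nti, rc, expected):
        assert partition_processes(nti, rc) == expected

    @pytest.mark.parametrize("nti,rc,expected", [
        (-2.0, 0.0, "undominated"),    # boundary falls to stochastic side
        (2.0, 0.0, "undominated"),
        (0.0, 0.95, "undominated"),
        (0.0, -0.95, "undominated"),
        (np.nan, 0.5, "unassigned"),
        (1.0, np.nan, "unassigned"),
    ])
    def test_boundaries_and_undefined(self, nti, rc, expected):
        assert partition_processes(nti, rc) == expected


class TestProcessFractions:
    def _pairs(self, labels):
        import pandas as pd
        return pd.DataFrame({
            "sample_i": [f"a{i}" for i in range(len(labels))],
            "sample_j": [f"b{i}" for i in range(len(labels))],
            "process": labels,
        })

    def test_all_one_process(self):
        fr = process_fractions(self._pairs(["homogeneous_selection"] * 4))
        assert fr.fractions["homogeneous_selection"] == 1.0
        assert fr.n_pairs == 4

    def test_fractions_sum_to_one(self):
        fr = process_fractions(self._pairs(
            ["undominated", "dispersal_limitation", "undominated",
             "unassigned", "homogenizing_dispersal"]))
        assert sum(fr.fractions.values()) == pytest.approx(1.0, abs=1e-9)
        assert fr.n_unassigned == 1
        assert fr.n_pairs == 4

    def test_no_assigned_pairs_error(self):
        with pytest.raises(DataValidationError):
            process_fractions(self._pairs(["unassigned", "unassigned"]))


def test_pairwise_assembly_tidy_output(four_tip_tree):
    rng = np.random.default_rng(7)
    table = CommunityTable([f"S{i}" for i in range(4)], ["A", "B", "C", "D"],
                           rng.integers(1, 20, size=(4, 4)))
    df = pairwise_assembly(table, four_tip_tree, n_null=99, seed=1)
    assert len(df) == 6
    assert set(df.columns) == {"sample_i", "sample_j", "beta_mntd", "beta_nti",
                               "bray_curtis", "rc_bray", "process"}
    assert df["process"].isin(["homogeneous_selection", "heterogeneous_selection",
                               "dispersal_limitation", "homogenizing_dispersal",
                               "undominated", "unassigned"]).all()
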