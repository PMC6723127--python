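import networkx as nx
import numpy as np
import pandas as pd
import pytest

from radmap import linkage_grouping as lgp


class TestPairwiseRF:
    def test_identical_vectors(self):
        s = np.tile([1.0, 0.0], 45)
        est = lgp.pairwise_rf(s, s)
        assert est.rf == 0.0 and est.phase == "coupling" and est.n_informative == 90
        assert est.reliable

    def test_complementary_vectors_are_zero_repulsion(self):
        s = np.tile([1.0, 0.0], 45)
        est = lgp.pairwise_rf(s, 1.0 - s)
        assert est.rf == 0.0 and est.phase == "repulsion"

    def test_direct_count(self):
        a = np.zeros(90)
        b = np.zeros(90)
        b[:9] = 1.0
        assert lgp.pairwise_rf(a, b).rf == pytest.approx(9 / 90)

    def test_unreliable_below_minimum(self):
        a = np.full(90, np.nan)
        a[:10] = 1.0
        est = lgp.pairwise_rf(a, np.ones(90))
        assert est.n_informative == 10 and not est.reliable

    def test_symmetry_and_matrix_matches_scalar(self, rng):
        states = rng.choice([0.0, 1.0, np.nan], size=(12, 60), p=[0.4, 0.4, 0.2])
        rf, n = lgp.rf_matrix(states, min_informative=5)
        for i in range(12):
            for j in range(12):
                est_ij = lgp.pairwise_rf(states[i], states[j], 5)
                est_ji = lgp.pairwise_rf(states[j], states[i], 5)
                assert est_ij.rf == pytest.approx(est_ji.rf, nan_ok=True)
                if i != j:
                    expected = est_ij.rf if est_ij.reliable else np.nan
                    assert rf[i, j] == pytest.approx(expected, nan_ok=True)
                    assert n[i, j] == est_ij.n_informative


class TestDebias:
    def test_identity_at_zero(self, rng):
        rf = rng.uniform(0, 0.5, (5, 5))
        np.testing.assert_array_equal(lgp.debias_rf(rf, 0.0), rf)

    def test_removes_known_noise_floor(self):
        # true r = 0.1 observed through state error q = 0.025
        q = 0.025
        observed = 0.1 * (1 - 2 * q) ** 2 + 2 * q * (1 - q)
        out = lgp.debias_rf(np.array([[observed]]), 0.05)
        assert out[0, 0] == pytest.approx(0.1, abs=1e-12)


class TestScaffoldRF:
    def test_mean_of_marker_pairs(self):
        rf = np.array(
            [
                [0.0, 0.0, 0.0, 0.1],
                [0.0, 0.0, 0.1, 0.0],
                [0.0, 0.1, 0.0, 0.05],
                [0.1, 0.0, 0.05, 0.0],
            ]
        )
        scafs = ["A", "A", "B", "B"]
        table = lgp.scaffold_rf_matrix([(rf, scafs)])
        # cross pairs: (0,2)=0, (0,3)=0.1, (1,2)=0.1, (1,3)=0 -> mean 0.05
        assert table.loc["A", "B"] == pytest.approx(0.05)

    def test_matches_brute_force(self, rng):
        states = rng.choice([0.0, 1.0, np.nan], size=(25, 80), p=[0.42, 0.42, 0.16])
        scafs = [f"s{i % 5}" for i in range(25)]
        rf, _ = lgp.rf_matrix(states, 10)
        table = lgp.scaffold_rf_matrix([(rf, scafs)])
        for a in table.index:
            for b in table.columns:
                if a >= b:
                    continue
                vals = [
                    rf[i, j]
                    for i in range(25)
                    for j in range(25)
                    if i < j
                    and {scafs[i], scafs[j]} == {a, b}
                    and not np.isnan(rf[i, j])
                ]
                expected = np.mean(vals) if vals else np.nan
                assert table.loc[a, b] == pytest.approx(expected, nan_ok=True)


class TestClustering:
    def _frame(self, names, entries):
        names = list(names)
        m = pd.DataFrame(np.nan, index=names, columns=names)
        np.fill_diagonal(m.values, 0.0)
        for a, b, v in entries:
            m.loc[a, b] = m.loc[b, a] = v
        return m

    def test_chain_linkage(self):
        m = self._frame("ABC", [("A", "B", 0.05), ("B", "C", 0.05), ("A", "C", 0.4)])
        groups = lgp.cluster_scaffolds(m, {"A": 10, "B": 10, "C": 10})
        assert len(groups) == 1 and groups[0].scaffolds == ["A", "B", "C"]

    def test_unlinked_singletons(self):
        m = self._frame("AB", [("A", "B", 0.3)])
        groups = lgp.cluster_scaffolds(m, {"A": 10, "B": 5})
        assert [g.scaffolds for g in groups] == [["A"], ["B"]]

    def test_group_numbering_by_length(self):
        m = self._frame("ABCD", [("A", "B", 0.01), ("C", "D", 0.01)])
        groups = lgp.cluster_scaffolds(m, {"A": 10, "B": 10, "C": 100, "D": 100})
        assert groups[0].scaffolds == ["C", "D"]
        assert groups[0].group_id == "LG01"

    def test_matches_graph_components_oracle(self, rng):
        n = 30
        m = rng.uniform(0, 0.5, (n, n))
        m = (m + m.T) / 2
        m[rng.random((n, n)) < 0.2] = np.nan
        m = np.triu(m, 1) + np.triu(m, 1).T
        names = [f"s{i:02d}" for i in range(n)]
        frame = pd.DataFrame(m, index=names, columns=names)
        groups = lgp.cluster_scaffolds(frame, {s: 1 for s in names}, 0.07)
        g = nx.Graph()
        g.add_nodes_from(names)
        for i in range(n):
            for j in range(i + 1, n):
                if not np.isnan(m[i, j]) and m[i, j] < 0.07:
                    g.add_edge(names[i], names[j])
        expected = {frozenset(c) for c in nx.connected_components(g)}
        assert {frozenset(gr.scaffolds) for gr in groups} == expected

    def test_threshold_validation(self):
        m = self._frame("AB", [("A", "B", 0.3)])
        with pytest.raises(ValueError):
            lgp.cluster_scaffolds(m, {"A": 1, "B": 1}, threshold=0.6)


class TestChimeraFlags:
    def _states(self, rng, pattern, n_off=80):
        """pattern: list of base vectors, one per marker."""
        return np.array(pattern, dtype=float)

    def test_two_chromosome_scaffold_flagged(self, rng):
        x = rng.choice([0.0, 1.0], 80)
        y = rng.choice([0.0, 1.0], 80)  # independent block
        states = np.array([x, x, y, y])
        rf, _ = lgp.rf_matrix(states, 10)
        flags = lgp.flag_chimeric_scaffolds(
            rf, np.array(["S"] * 4), np.array([10, 20, 30, 40])
        )
        assert flags["S"] == "chimeric"

    def test_colinear_scaffold_ok(self, rng):
        x = rng.choice([0.0, 1.0], 80)
        states = np.array([x, x, x, x])
        rf, _ = lgp.rf_matrix(states, 10)
        flags = lgp.flag_chimeric_scaffolds(
            rf, np.array(["S"] * 4), np.array([10, 20, 30, 40])
        )
        assert flags["S"] == "ok"

    def test_too_few_markers_untestable(self, rng):
        states = rng.choice([0.0, 1.0], (3, 80))
        rf, _ = lgp.rf_matrix(states, 10)
        flags = lgp.flag_chimeric_scaffolds(
            rf, np.array(["S"] * 3), np.array([10, 20, 30])
        )
        assert flags["S"] == "untestable"


class TestMultiGroupExclusion:
    def test_cross_linked_locus_excluded(self):
        # marker 0 linked tightly to both groups
        rf = np.array(
            [
                [0.0, 0.03, 0.03],
                [0.03, 0.0, 0.45],
                [0.03, 0.45, 0.0],
            ]
        )
        scafs = np.array(["x", "a", "b"])
        keep = lgp.exclude_multigroup_loci(
            rf, scafs, {"x": "LG1", "a": "LG1", "b": "LG2"}
        )
        assert not keep[0]
        assert keep[1] and keep[2]

    def test_within_group_locus_retained(self):
        rf = np.array(
            [
                [0.0, 0.02, 0.45],
                [0.02, 0.0, 0.45],
                [0.45, 0.45, 0.0],
            ]
        )
        scafs = np.array(["a", "a", "b"])
        keep = lgp.exclude_multigroup_loci(
            rf, scafs, {"a": "LG1", "b": "LG2"}
        )
        assert keep.all()


class TestThinning:
    def _table(self, n, cls="AAxAB"):
        return pd.DataFrame(
            {
                "locus_id": [f"l{i:02d}" for i in range(n)],
                "scaffold": "S",
                "informative_class": cls,
                "n_called": np.arange(n),
                "position": np.arange(n) * 10 + 1,
            }
        )

    def test_keeps_five_most_complete(self):
        out = lgp.thin_markers(self._table(12), 5)
        assert len(out) == 5
        assert sorted(out["n_called"]) == [7, 8, 9, 10, 11]

    def test_small_class_kept_whole(self):
        assert len(lgp.thin_markers(self._table(3), 5)) == 3

    def test_invariant_to_input_order(self, rng):
        t = pd.concat([self._table(12), self._table(8, "ABxBB")])
        shuffled = t.sample(frac=1.0, random_state=3)
        a = lgp.thin_markers(t, 5).sort_values("locus_id")
        b = lgp.thin_markers(shuffled, 5).sort_values("locus_id")
        pd.testing.assert_frame_equal(a.reset_index(drop=True), b.reset_index(drop=True))

    def test_classes_thinned_separately(self):
        t = pd.concat([self._table(12), self._table(12, "ABxBB")])
        out = lgp.thin_markers(t, 5)
        assert len(out) == 10


class TestDoubleCrossoverRemoval:
    def test_singleton_flip_removes_locus(self):
        base = np.zeros((5, 30))
        base[2, 0] = 1.0  # one individual flips only at the middle locus
        keep = lgp.remove_double_crossover_loci(
            base, np.array(["S"] * 5), np.arange(5) * 10
        )
        assert not keep[2]
        assert keep[[0, 1, 3, 4]].all()

    def test_concordant_scaffold_untouched(self, rng):
        x = rng.choice([0.0, 1.0], 30)
        states = np.tile(x, (5, 1))
        keep = lgp.remove_double_crossover_loci(
            states, np.array(["S"] * 5), np.arange(5) * 10
        )
        assert keep.all()

    def test_real_crossover_not_removed(self):
        """A state change that persists downstream is a real crossover,
        not a double-crossover artifact."""
        states = np.zeros((5, 30))
        states[2:, 0] = 1.0  # individual 0 recombines between loci 1 and 2
        keep = lgp.remove_double_crossover_loci(
            states, np.array(["S"] * 5), np.arange(5) * 10
        )
        assert keep.all()

    def test_injected_error_count(self, rng):
        x = rng.choice([0.0, 1.0], 40)
        states = np.tile(x, (6, 1))
        states[3, 7] = 1.0 - states[3, 7]  # single injected error
        keep = lgp.remove_double_crossover_loci(
            states, np.array(["S"] * 6), np.arange(6) * 10
        )
        assert (~keep).sum() == 1 and not keep[3]

    def test_phase_difference_not_a_crossover(self, rng):
        x = rng.choice([0.0, 1.0], 40)
        states = np.array([x, 1.0 - x, x])  # middle marker in repulsion phase
        keep = lgp.remove_double_crossover_loci(
            states, np.array(["S"] * 3), np.arange(3) * 10
        )
        assert keep.all()
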