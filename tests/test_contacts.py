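"""Contact graphs, mixing/assortativity, and permutation enrichment."""

import numpy as np
import pandas as pd
import pytest

from tme_evolve.contacts import (
    ContactGraph,
    build_contact_graph,
    compare_enrichment_groups,
    mixing_and_assortativity,
    permutation_enrichment,
)


def cells_at(points, labels=None, roi_id="r0"):
    pts = np.asarray(points, dtype=float)
    df = pd.DataFrame({"cell_id": np.arange(len(pts)), "roi_id": roi_id,
                       "x_um": pts[:, 0], "y_um": pts[:, 1]})
    if labels is not None:
        df["cell_type"] = list(labels)
    return df


def path_graph(labels):
    """Vertices on a line with unit spacing, edges between neighbors only."""
    n = len(labels)
    return ContactGraph(
        cell_ids=np.arange(n),
        positions=np.column_stack([np.arange(n, dtype=float), np.zeros(n)]),
        edges=np.array([[i, i + 1] for i in range(n - 1)]),
        roi_id="path",
    ), np.array(labels, dtype=object)


class TestBuildContactGraph:
    def test_triangle_has_three_edges(self):
        g = build_contact_graph(cells_at([(0, 0), (10, 0), (5, 8)]), max_edge_um=50)
        assert g.n_edges == 3

    def test_unit_square_pruning_drops_diagonal(self):
        # threshold between side (10) and diagonal (14.14): perimeter only
        g = build_contact_graph(
            cells_at([(0, 0), (10, 0), (10, 10), (0, 10)]), max_edge_um=12
        )
        assert g.n_edges == 4
        lengths = np.linalg.norm(
            g.positions[g.edges[:, 0]] - g.positions[g.edges[:, 1]], axis=1
        )
        np.testing.assert_allclose(lengths, 10.0)

    def test_distant_clusters_are_disconnected(self):
        near = [(0, 0), (10, 0), (5, 8)]
        far = [(500, 500), (510, 500), (505, 508)]
        g = build_contact_graph(cells_at(near + far), max_edge_um=50)
        crosses = [(a, b) for a, b in g.edges if (a < 3) != (b < 3)]
        assert crosses == [] and g.n_edges == 6

    def test_too_few_or_collinear_named_error(self):
        with pytest.raises(ValueError, match="roiX"):
            build_contact_graph(cells_at([(0, 0), (1, 1)], roi_id="roiX"))
        with pytest.raises(ValueError, match="degenerate"):
            build_contact_graph(cells_at([(0, 0), (1, 0), (2, 0), (3, 0)]))


class TestMixingAndAssortativity:
    def test_same_type_only_edges_give_r_of_one(self):
        g, labels = path_graph(["A", "A", "A", "B", "B", "B"])
        g.edges = np.array([[0, 1], [1, 2], [3, 4], [4, 5]])  # no cross edge
        mm = mixing_and_assortativity(g, labels)
        assert mm.r == pytest.approx(1.0)
        assert not mm.degenerate

    def test_balanced_cross_type_edges_give_r_of_minus_one(self):
        # e = [[0, .5], [.5, 0]] -> r = (0 - 0.5) / (1 - 0.5) = -1
        g, labels = path_graph(["A", "B", "A", "B"])
        g.edges = np.array([[0, 1], [2, 3]])
        mm = mixing_and_assortativity(g, labels)
        np.testing.assert_allclose(mm.e.to_numpy(), [[0, 0.5], [0.5, 0]])
        assert mm.r == pytest.approx(-1.0)

    def test_random_relabeling_averages_to_zero(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 300, (300, 2))
        cells = cells_at(pts)
        g = build_contact_graph(cells, max_edge_um=50)
        base = np.array(["A"] * 150 + ["B"] * 150, dtype=object)
        rs = [mixing_and_assortativity(g, rng.permutation(base)).r for _ in range(300)]
        se = np.std(rs) / np.sqrt(len(rs))
        assert abs(np.mean(rs)) <= 3 * se + 1e-3

    def test_single_type_degenerate_flag(self):
        g, labels = path_graph(["A", "A", "A"])
        mm = mixing_and_assortativity(g, labels)
        assert mm.r == 1.0 and mm.degenerate

    def test_mixing_matrix_is_normalized_and_symmetric(self, small_dataset):
        roi = small_dataset.rois["roi_id"].iloc[0]
        sub = small_dataset.cells_for_roi(roi)
        g = build_contact_graph(sub)
        mm = mixing_and_assortativity(g, sub["cell_type"].to_numpy())
        e = mm.e.to_numpy()
        assert e.sum() == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(e, e.T)
        assert -1.0 <= mm.r <= 1.0


class TestPermutationEnrichment:
    def test_exhaustive_path_graph_worked_example(self):
        """A-A-B-B path: observed cross contacts 1; exact permutation mean 2.0
        over the 6 distinct labelings; add-one avoidance p = 3/7."""
        g, labels = path_graph(["A", "A", "B", "B"])
        enr = permutation_enrichment(g, labels, exhaustive=True)
        ab = enr[(enr.type_a == "A") & (enr.type_b == "B")].iloc[0]
        assert ab.observed == 1.0
        assert ab.perm_mean == pytest.approx(2.0)
        assert ab.direction == "avoidance"
        assert ab.p == pytest.approx(3 / 7)

    def test_single_type_cross_pairs_trivial(self):
        g, labels = path_graph(["A", "A", "A", "A"])
        enr = permutation_enrichment(g, labels, n_perm=100, types=("A", "B"))
        cross = enr[(enr.type_a == "A") & (enr.type_b == "B")].iloc[0]
        assert cross.observed == 0.0 and cross.p == 1.0 and not cross.significant

    def test_observed_counts_sum_to_edge_count(self, small_dataset):
        roi = small_dataset.rois["roi_id"].iloc[0]
        sub = small_dataset.cells_for_roi(roi)
        g = build_contact_graph(sub)
        enr = permutation_enrichment(g, sub["cell_type"].to_numpy(), n_perm=100, seed=0)
        unordered = enr[enr.type_a <= enr.type_b]
        assert unordered.observed.sum() == g.n_edges

    def test_deterministic_given_seed(self):
        g, labels = path_graph(["A", "B"] * 10)
        a = permutation_enrichment(g, labels, n_perm=150, seed=5)
        b = permutation_enrichment(g, labels, n_perm=150, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_table_is_symmetric_in_the_pair(self):
        g, labels = path_graph(["A", "B", "A", "B", "B", "A"])
        enr = permutation_enrichment(g, labels, n_perm=120, seed=2)
        ab = enr[(enr.type_a == "A") & (enr.type_b == "B")].iloc[0]
        ba = enr[(enr.type_a == "B") & (enr.type_b == "A")].iloc[0]
        assert ab.observed == ba.observed and ab.p == ba.p

    def test_min_permutations_enforced(self):
        g, labels = path_graph(["A", "B", "A", "B"])
        with pytest.raises(ValueError, match="n_perm"):
            permutation_enrichment(g, labels, n_perm=10)


class TestCompareEnrichmentGroups:
    def _tables(self, delta, n=10, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for grp, shift in (("K", 0.0), ("U", delta)):
            for i in range(n):
                rows.append({"roi_id": f"{grp}{i}", "type_a": "t1", "type_b": "t2",
                             "z": rng.normal(shift, 1.0)})
        df = pd.DataFrame(rows)
        groups = pd.Series({r: r[0] for r in df.roi_id.unique()})
        return df, groups

    def test_identical_groups_not_significant(self):
        df, groups = self._tables(delta=0.0, seed=1)
        # make the two groups literally identical
        df.loc[df.roi_id.str.startswith("U"), "z"] = \
            df.loc[df.roi_id.str.startswith("K"), "z"].to_numpy()
        out = compare_enrichment_groups(df, groups)
        assert out.iloc[0].p == pytest.approx(1.0)

    def test_planted_difference_detected(self):
        df, groups = self._tables(delta=2.0, n=20, seed=2)
        out = compare_enrichment_groups(df, groups)
        assert out.iloc[0].testable and out.iloc[0].p < 0.05

    def test_single_roi_group_flagged_not_testable(self):
        df, groups = self._tables(delta=1.0, n=1)
        out = compare_enrichment_groups(df, groups)
        assert not out.iloc[0].testable
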