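"""Community-landscape decomposition: influence, centers, memberships."""

import numpy as np
import pytest

from oracles import solve_influence
from conftest import build_graph
from stagenet.module_decomposition import (community_landscape, decompose,
                                           effective_size, find_centers,
                                           influence_matrix, memberships)


def two_triangles_with_bridge():
    return build_graph([("A", "B"), ("B", "C"), ("A", "C"),
                        ("D", "E"), ("E", "F"), ("D", "F"),
                        ("C", "D")])


class TestInfluence:
    def test_single_edge_symmetric_rows_sum_to_one(self):
        g = build_graph([("A", "B")])
        X, order = influence_matrix(g)
        assert order == ["A", "B"]
        assert np.allclose(X.sum(axis=1), 1.0)
        assert X[0, 0] == pytest.approx(X[1, 1])
        assert X[0, 1] == pytest.approx(X[1, 0])

    def test_k3_off_diagonals_equal_by_symmetry(self):
        g = build_graph([("A", "B"), ("B", "C"), ("A", "C")])
        X, _ = influence_matrix(g)
        off = X[~np.eye(3, dtype=bool)]
        assert np.allclose(off, off[0])

    def test_path_of_five_matches_dense_solve(self):
        g = build_graph([("A", "B"), ("B", "C"), ("C", "D"), ("D", "E")])
        X, _ = influence_matrix(g, tol=1e-12)
        assert np.allclose(X, solve_influence(g), atol=1e-8)

    def test_isolated_node_keeps_own_influence(self):
        g = build_graph([("A", "B")], isolated=["Z"])
        X, order = influence_matrix(g)
        z = order.index("Z")
        assert X[z, z] == pytest.approx(1.0)

    def test_invalid_restart_rejected(self):
        with pytest.raises(ValueError):
            influence_matrix(build_graph([("A", "B")]), restart=0.0)


class TestLandscape:
    def test_heights_sum_to_node_count(self):
        g = two_triangles_with_bridge()
        X, _ = influence_matrix(g)
        assert community_landscape(X).sum() == pytest.approx(
            g.number_of_nodes())

    def test_star_center_has_strictly_maximal_height(self):
        g = build_graph([("C", f"L{i}") for i in range(4)])
        X, order = influence_matrix(g)
        h = dict(zip(order, community_landscape(X)))
        assert h["C"] > max(h[f"L{i}"] for i in range(4))

    def test_relabeling_permutes_heights(self):
        g = build_graph([("A", "B"), ("B", "C"), ("C", "D")])
        relabel = {"A": "P", "B": "Q", "C": "R", "D": "S"}
        h = build_graph([(relabel[u], relabel[v])
                         for u, v, _w, _t in g.edges()])
        Xg, og = influence_matrix(g)
        Xh, oh = influence_matrix(h)
        hg = dict(zip(og, community_landscape(Xg)))
        hh = dict(zip(oh, community_landscape(Xh)))
        assert all(hg[k] == pytest.approx(hh[relabel[k]]) for k in hg)


class TestCenters:
    def _centers(self, g):
        X, order = influence_matrix(g)
        return find_centers(g, community_landscape(X), order)

    def test_two_triangles_one_center_each(self):
        centers = self._centers(two_triangles_with_bridge())
        assert len(centers) == 2
        assert any(c in {"A", "B", "C"} for c in centers)
        assert any(c in {"D", "E", "F"} for c in centers)

    def test_star_single_center_at_hub(self):
        g = build_graph([("C", f"L{i}") for i in range(4)])
        assert self._centers(g) == ["C"]

    def test_complete_graph_lexicographic_tie_rule(self):
        g = build_graph([("A", "B"), ("B", "C"), ("A", "C"), ("A", "D"),
                         ("B", "D"), ("C", "D")])
        assert self._centers(g) == ["A"]

    def test_flat_plateau_next_to_peak_is_not_a_center(self):
        # P-Q plateau attached under a strictly taller hub is not a maximum
        g = build_graph([("H", f"L{i}") for i in range(5)] +
                        [("H", "P"), ("H", "Q"), ("P", "Q")])
        centers = self._centers(g)
        assert centers == ["H"]


class TestMemberships:
    def test_single_center_everything_belongs(self):
        g = build_graph([("A", "B"), ("B", "C")])
        X, order = influence_matrix(g)
        M = memberships(X, order, ["B"])
        assert np.allclose(M, 1.0)

    def test_rows_sum_to_one(self):
        g = two_triangles_with_bridge()
        X, order = influence_matrix(g)
        M = memberships(X, order, ["A", "E"])
        assert np.allclose(M.sum(axis=1), 1.0)

    def test_bridge_split_is_symmetric_and_matches_dense_solve(self):
        # centers are the bridge endpoints C and D; the triangle-swapping
        # automorphism forces mirrored memberships, and the dense linear
        # solve provides the exact values
        g = two_triangles_with_bridge()
        X, order = influence_matrix(g, tol=1e-12)
        M = memberships(X, order, ["C", "D"])
        exact = solve_influence(g)
        idx = {v: i for i, v in enumerate(order)}
        for v in ("C", "D"):
            i = idx[v]
            expected = exact[idx["C"], i] / (exact[idx["C"], i]
                                             + exact[idx["D"], i])
            assert M[i, 0] == pytest.approx(expected, abs=1e-7)
        assert M[idx["C"], 0] == pytest.approx(M[idx["D"], 1], abs=1e-9)
        # the two modules split every node the same mirrored way
        assert M[idx["A"], 0] == pytest.approx(M[idx["F"], 1], abs=1e-9)

    def test_no_centers_rejected(self):
        g = build_graph([("A", "B")])
        X, order = influence_matrix(g)
        with pytest.raises(ValueError):
            memberships(X, order, [])


class TestEffectiveSize:
    def test_uniform_membership(self):
        assert effective_size(np.full(4, 0.25)) == pytest.approx(4.0)

    def test_single_node(self):
        assert effective_size(np.array([1.0])) == pytest.approx(1.0)

    def test_mixed_weights(self):
        assert effective_size(np.array([1.0, 0.5])) == pytest.approx(1.8)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            effective_size(np.zeros(3))


class TestDecompose:
    def test_single_edge_one_module_effective_size_two(self):
        g = build_graph([("A", "B")])
        dec = decompose(g)
        assert len(dec.modules) == 1
        assert dec.modules[0].effective_size == pytest.approx(2.0)

    def test_two_planted_cliques_recovered(self):
        edges = []
        cliq1, cliq2 = ["A", "B", "C", "D"], ["W", "X", "Y", "Z"]
        for grp in (cliq1, cliq2):
            edges += [(u, v) for i, u in enumerate(grp) for v in grp[i + 1:]]
        edges.append(("D", "W"))
        dec = decompose(build_graph(edges), threshold=0.3)
        assert len(dec.modules) == 2
        members = {m.center: set(m.members) for m in dec.modules}
        assert any(set(cliq1) <= s for s in members.values())
        assert any(set(cliq2) <= s for s in members.values())

    def test_planted_cliques_k_centers_and_own_module_maximal(self):
        """k sparsely bridged cliques give exactly k centers; each clique's
        nodes put their maximal membership in their own module."""
        for k in (2, 3, 5):
            edges, cliques = [], []
            for c in range(k):
                grp = [f"C{c}N{i}" for i in range(5)]
                cliques.append(grp)
                edges += [(u, v) for i, u in enumerate(grp)
                          for v in grp[i + 1:]]
            for c in range(k - 1):  # sparse bridges via connector nodes
                edges.append((cliques[c][0], f"X{c}"))
                edges.append((f"X{c}", cliques[c + 1][0]))
            dec = decompose(build_graph(edges))
            assert len(dec.centers) == k
            idx = {v: i for i, v in enumerate(dec.node_order)}
            center_of = {c: j for j, c in enumerate(dec.centers)}
            for grp in cliques:
                own = [j for c, j in center_of.items()
                       if c in grp]
                assert len(own) == 1
                for v in grp:
                    assert int(np.argmax(dec.membership[idx[v]])) == own[0]

    def test_deterministic_and_relabel_equivariant(self):
        g = two_triangles_with_bridge()
        d1, d2 = decompose(g), decompose(g)
        assert d1.centers == d2.centers
        assert np.array_equal(d1.membership, d2.membership)
        relabel = {n: f"Z{n}" for n in g.nodes}
        h = build_graph([(relabel[u], relabel[v])
                         for u, v, _w, _t in g.edges()])
        dh = decompose(h)
        assert sorted(relabel[c] for c in d1.centers) == dh.centers

    def test_driver_and_hub_cross_references(self):
        g = two_triangles_with_bridge()
        dec = decompose(g, driver_seeds={"A", "E"}, hubs={"B"})
        for m in dec.modules:
            assert set(m.driver_members) <= {"A", "E"}
            assert set(m.hub_members) <= {"B"}

    def test_center_graph_links_overlapping_modules(self):
        g = two_triangles_with_bridge()
        dec = decompose(g, threshold=0.2)
        assert len(dec.center_graph_edges) in (0, 1)
        if dec.center_graph_edges:
            a, b = dec.center_graph_edges[0]
            assert a in dec.centers and b in dec.centers

    def test_membership_bounds_on_random_graphs(self):
        from oracles import random_graph
        rng = np.random.default_rng(8)
        for _ in range(10):
            g = random_graph(rng, n_max=10)
            try:
                dec = decompose(g)
            except ValueError:
                continue
            n = g.number_of_nodes()
            covered = dec.membership.sum(axis=1) > 0
            assert np.allclose(dec.membership[covered].sum(axis=1), 1.0,
                               atol=1e-9)
            for m in dec.modules:
                assert 1.0 - 1e-9 <= m.effective_size <= n + 1e-9
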