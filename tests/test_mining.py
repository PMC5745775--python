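import itertools

import networkx as nx
import numpy as np
import pytest

from conftest import connected_edge_subsets, make_labeled_graph, random_labeled_graph
from homst.mining import (
    LabeledGraph,
    SubgraphPattern,
    contains,
    discriminative_scores,
    frequency,
    gspan_mine,
    min_dfs_code,
    select_top_k,
    subject_pattern_graph,
    tree_to_labeled_graph,
)


def brute_force_frequent(graphs, min_fq):
    """Oracle: enumerate every connected edge-subset subgraph of every
    database graph, canonicalize by minimum DFS code, filter by frequency."""
    seen = {}
    for g in graphs:
        for sub in connected_edge_subsets(g):
            seen.setdefault(min_dfs_code(sub), sub)
    return {
        code: frequency(sub, graphs)
        for code, sub in seen.items()
        if frequency(sub, graphs) >= min_fq - 1e-9
    }


class TestContainsAndFrequency:
    def test_direct_count(self):
        pattern = make_labeled_graph([(0, 1)])
        graphs = [make_labeled_graph(e) for e in
                  ([(0, 1)], [(0, 1), (1, 2)], [(0, 2)], [(1, 0)])]
        assert frequency(pattern, graphs) == 0.75

    def test_graph_contains_itself(self):
        g = make_labeled_graph([(0, 1), (1, 2)])
        assert frequency(g, [g]) == 1.0

    def test_matches_brute_force_containment(self, rng):
        for _ in range(25):
            g = random_labeled_graph(rng, 6, int(rng.integers(2, 8)), n_labels=3)
            sub_pool = connected_edge_subsets(g) or [make_labeled_graph([(0, 1)])]
            pattern = sub_pool[int(rng.integers(len(sub_pool)))]
            probe = random_labeled_graph(rng, 5, int(rng.integers(1, 7)), n_labels=3)
            oracle = nx.algorithms.isomorphism.GraphMatcher(
                probe.to_networkx(), pattern.to_networkx(),
                node_match=lambda a, b: a["label"] == b["label"],
                edge_match=lambda a, b: a["elabel"] == b["elabel"],
            ).subgraph_is_monomorphic()
            assert contains(probe, pattern) == oracle

    def test_identity_fast_path_agrees_with_vf2(self, rng):
        for _ in range(20):
            g = random_labeled_graph(rng, 7, int(rng.integers(3, 10)))
            subs = connected_edge_subsets(g)
            pattern = subs[int(rng.integers(len(subs)))]
            probe = random_labeled_graph(rng, 7, int(rng.integers(1, 10)))
            slow = nx.algorithms.isomorphism.GraphMatcher(
                probe.to_networkx(), pattern.to_networkx(),
                node_match=lambda a, b: a["label"] == b["label"],
                edge_match=lambda a, b: a["elabel"] == b["elabel"],
            ).subgraph_is_monomorphic()
            assert contains(probe, pattern) == slow

    def test_disconnected_pattern_rejected(self):
        g = LabeledGraph()
        for v in range(4):
            g.add_node(v, v)
        g.add_edge(0, 1)
        g.add_edge(2, 3)
        with pytest.raises(ValueError, match="connected"):
            frequency(g, [g])

    def test_empty_database_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            frequency(make_labeled_graph([(0, 1)]), [])


class TestMinDFSCode:
    def test_isomorphic_graphs_share_code(self, rng):
        for _ in range(20):
            g = random_labeled_graph(rng, 6, int(rng.integers(2, 9)), n_labels=2)
            if not g.is_connected():
                continue
            perm = rng.permutation(6)
            h = LabeledGraph()
            for v in range(6):
                h.add_node(int(perm[v]), g.node_labels[v])
            for u, v, el in g.edges():
                h.add_edge(int(perm[u]), int(perm[v]), el)
            assert min_dfs_code(g) == min_dfs_code(h)

    def test_distinct_graphs_get_distinct_codes(self):
        path = make_labeled_graph([(0, 1), (1, 2)], node_labels={0: 0, 1: 0, 2: 0})
        star = make_labeled_graph([(0, 1), (0, 2)], node_labels={0: 0, 1: 0, 2: 0})
        # same label multiset and size, different topology is still resolved
        # on labeled variants
        tri = make_labeled_graph([(0, 1), (1, 2), (0, 2)], node_labels={0: 0, 1: 0, 2: 0})
        assert min_dfs_code(path) == min_dfs_code(star)  # unlabeled P3 == S2
        assert min_dfs_code(tri) != min_dfs_code(path)


class TestGspanMine:
    def test_identical_trees_yield_all_connected_subgraphs(self):
        tree = make_labeled_graph([(0, 1), (1, 2), (1, 3)])
        db = [tree, tree, tree]
        mined = gspan_mine(db, min_fq=1.0)
        expected = {min_dfs_code(s) for s in connected_edge_subsets(tree)}
        assert {p.code for p in mined} == expected
        assert all(p.fq == 1.0 for p in mined)
        # star on 3 edges: 3 singles + 3 pairs + 1 triple = 7 patterns
        assert len(mined) == 7

    def test_disjoint_label_alphabets_mine_nothing(self):
        g1 = make_labeled_graph([(0, 1)], node_labels={0: "a", 1: "b"})
        g2 = make_labeled_graph([(0, 1)], node_labels={0: "c", 1: "d"})
        assert gspan_mine([g1, g2], min_fq=1.0) == []

    def test_matches_enumeration_oracle_on_random_dbs(self, rng):
        for _ in range(20):
            db = [
                random_labeled_graph(
                    rng, int(rng.integers(2, 6)), int(rng.integers(1, 8)),
                    n_labels=int(rng.integers(1, 4)),
                )
                for _ in range(int(rng.integers(1, 6)))
            ]
            db = [g for g in db if g.n_edges]
            if not db:
                continue
            min_fq = float(rng.choice([0.34, 0.5, 0.75, 1.0]))
            mined = {p.code: p.fq for p in gspan_mine(db, min_fq)}
            assert mined == brute_force_frequent(db, min_fq)

    def test_anti_monotonicity(self, rng):
        db = [random_labeled_graph(rng, 5, 6, n_labels=2) for _ in range(4)]
        mined = gspan_mine(db, min_fq=0.5)
        codes = {p.code for p in mined}
        for p in mined:
            for sub in connected_edge_subsets(p.graph):
                if sub.n_edges < p.n_edges:
                    assert min_dfs_code(sub) in codes

    def test_database_order_invariance(self, rng):
        db = [random_labeled_graph(rng, 5, 5, n_labels=2) for _ in range(5)]
        a = {(p.code, p.fq) for p in gspan_mine(db, 0.4)}
        b = {(p.code, p.fq) for p in gspan_mine(db[::-1], 0.4)}
        assert a == b

    def test_max_edges_cap(self):
        chain = make_labeled_graph([(i, i + 1) for i in range(6)])
        mined = gspan_mine([chain], 1.0, max_edges=2)
        assert max(p.n_edges for p in mined) == 2

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            gspan_mine([make_labeled_graph([(0, 1)])], 0.0)


class TestDiscriminativeScores:
    def _db(self, edges_list):
        return [make_labeled_graph(e) for e in edges_list]

    def test_score_bounds_plus_one(self):
        pos = self._db([[(0, 1), (1, 2)]] * 4)
        neg = self._db([[(3, 4)]] * 4)
        pats = gspan_mine(pos, 1.0)
        scored = discriminative_scores(pats, [], pos, neg)
        assert all(p.score == 1.0 for p in scored)

    def test_score_bounds_minus_one(self):
        pos = self._db([[(3, 4)]] * 4)
        neg = self._db([[(0, 1), (1, 2)]] * 4)
        pats = gspan_mine(neg, 1.0)
        scored = discriminative_scores([], pats, pos, neg)
        assert all(p.score == -1.0 for p in scored)

    def test_equal_frequencies_score_zero(self):
        db = self._db([[(0, 1)]] * 3)
        pats = gspan_mine(db, 1.0)
        scored = discriminative_scores(pats, pats, db, db)
        assert all(p.score == 0.0 for p in scored)

    def test_group_swap_negates_scores(self, rng):
        pos = [random_labeled_graph(rng, 5, 5) for _ in range(4)]
        neg = [random_labeled_graph(rng, 5, 5) for _ in range(4)]
        p_pos = gspan_mine(pos, 0.5)
        p_neg = gspan_mine(neg, 0.5)
        fwd = {p.code: p.score for p in discriminative_scores(p_pos, p_neg, pos, neg)}
        rev = {p.code: p.score for p in discriminative_scores(p_neg, p_pos, neg, pos)}
        assert set(fwd) == set(rev)
        for code in fwd:
            assert fwd[code] == pytest.approx(-rev[code])


class TestSelectTopK:
    def _scored(self, scores):
        out = []
        for i, s in enumerate(scores):
            p = SubgraphPattern(
                code=min_dfs_code(make_labeled_graph([(i, 100 + i)])),
                graph=make_labeled_graph([(i, 100 + i)]),
            )
            p.fq_pos = max(s, 0.0)
            p.fq_neg = max(-s, 0.0)
            out.append(p)
        return out

    def test_extremes_selected(self):
        scored = self._scored([0.9, 0.5, -0.4, -0.8])
        picked = select_top_k(scored, 1)
        assert [p.score for p in picked] == [0.9, -0.8]

    def test_shortfall_warns_and_returns_available(self):
        scored = self._scored([0.9, -0.1])
        with pytest.warns(UserWarning, match="positive"):
            picked = select_top_k(scored, 3)
        assert len(picked) == 2

    def test_balanced_counts(self):
        scored = self._scored([0.5, 0.4, 0.3, -0.2, -0.3, -0.6])
        assert len(select_top_k(scored, 2)) == 4

    def test_deterministic_on_ties(self):
        scored = self._scored([0.5, 0.5, -0.5, -0.5])
        a = [p.code for p in select_top_k(scored, 1)]
        b = [p.code for p in select_top_k(list(reversed(scored)), 1)]
        assert a == b


class TestSubjectPatternGraph:
    def test_subject_without_patterns_gets_empty_graph(self):
        tree = nx.path_graph(4)
        tg = tree_to_labeled_graph(tree)
        pat = SubgraphPattern(
            code=min_dfs_code(make_labeled_graph([(7, 8)])),
            graph=make_labeled_graph([(7, 8)]),
        )
        out = subject_pattern_graph(tg, [pat])
        assert out.n_nodes == 0 and out.n_edges == 0

    def test_tree_identical_to_pattern_returned_whole(self):
        tree = nx.path_graph(4)
        tg = tree_to_labeled_graph(tree)
        pat = SubgraphPattern(code=min_dfs_code(tg), graph=tg)
        out = subject_pattern_graph(tg, [pat])
        assert {frozenset((u, v)) for u, v, _ in out.edges()} == {
            frozenset(e) for e in tree.edges
        }

    def test_union_of_contained_patterns(self, rng):
        for _ in range(10):
            tree = tree_to_labeled_graph(nx.random_labeled_tree(8, seed=int(rng.integers(100))))
            subs = connected_edge_subsets(tree)
            pats = []
            for _ in range(3):
                g = subs[int(rng.integers(len(subs)))]
                pats.append(SubgraphPattern(code=min_dfs_code(g), graph=g))
            # one pattern the tree cannot contain
            alien = make_labeled_graph([(50, 51)])
            pats.append(SubgraphPattern(code=min_dfs_code(alien), graph=alien))
            out = subject_pattern_graph(tree, pats)
            expected = set()
            for p in pats:
                if contains(tree, p.graph):
                    for u, v, _ in p.graph.edges():
                        lu, lv = p.graph.node_labels[u], p.graph.node_labels[v]
                        expected.add(frozenset((lu, lv)))
            got = {
                frozenset((out.node_labels[u], out.node_labels[v]))
                for u, v, _ in out.edges()
            }
            assert got == expected

    def test_degree_label_mode_roundtrip(self):
        tree = nx.star_graph(3)
        tg = tree_to_labeled_graph(tree, labels="degree")
        assert sorted(tg.node_labels.values()) == [1, 1, 1, 3]
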