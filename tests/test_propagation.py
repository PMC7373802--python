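import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

import splicewalk as sw
from splicewalk.propagation import ConvergenceWarning


def random_multigraph(rng, n_lnc=10, m_gene=15, p=0.2, n_layers=3):
    names = ["coexpression", "epigenetic", "ppi"]
    lnc = [f"L{i:02d}" for i in range(n_lnc)]
    gene = [f"G{i:02d}" for i in range(m_gene)]
    layers = []
    for k in range(n_layers):
        edges = {}
        if names[k] == "ppi":
            for i in range(m_gene):
                for j in range(i + 1, m_gene):
                    if rng.random() < p:
                        edges[(gene[i], gene[j])] = float(rng.uniform(0.1, 1.0))
        else:
            for u in lnc:
                for v in gene:
                    if rng.random() < p:
                        key = (u, v) if u < v else (v, u)
                        edges[key] = float(rng.uniform(0.1, 1.0))
        layers.append(sw.Layer(names[k], edges))
    nodes = [sw.NodeMeta(i, "lncRNA") for i in lnc] + [
        sw.NodeMeta(g, "AS_gene") for g in gene
    ]
    return sw.build_multigraph(layers, nodes)


class TestMergeLayers:
    def test_edge_in_all_three_layers_averages_to_one(self):
        nodes = [sw.NodeMeta("L1", "lncRNA"), sw.NodeMeta("G1", "AS_gene"),
                 sw.NodeMeta("G2", "AS_gene")]
        layers = [
            sw.Layer("coexpression", {("G1", "L1"): 1.0}),
            sw.Layer("epigenetic", {("G1", "L1"): 1.0}),
            sw.Layer("ppi", {("G1", "G2"): 1.0}),
        ]
        # (G1,L1) appears in 2 of 3; a pair in all 3 layers needs same-side
        # endpoints, so check the formula directly on weights instead
        mg = sw.build_multigraph(layers, nodes)
        adj = sw.merge_layers(mg, node_order=["L1", "G1", "G2"])
        A = adj.A.toarray()
        assert A[0, 1] == pytest.approx(2 / 3)
        assert A[1, 2] == pytest.approx(1 / 3)

    def test_denominator_is_total_layer_count(self):
        nodes = [sw.NodeMeta("L1", "lncRNA"), sw.NodeMeta("G1", "AS_gene")]
        layers = [
            sw.Layer("coexpression", {("G1", "L1"): 1.0}),
            sw.Layer("epigenetic", {}),
            sw.Layer("ppi", {}),
        ]
        adj = sw.merge_layers(sw.build_multigraph(layers, nodes),
                              node_order=["L1", "G1"])
        assert adj.A.toarray()[0, 1] == pytest.approx(1 / 3)

    def test_fractional_weights_average(self):
        nodes = [sw.NodeMeta("L1", "lncRNA"), sw.NodeMeta("G1", "AS_gene")]
        layers = [
            sw.Layer("coexpression", {("G1", "L1"): 0.6}),
            sw.Layer("epigenetic", {("G1", "L1"): 0.9}),
            sw.Layer("ppi", {}),
        ]
        adj = sw.merge_layers(sw.build_multigraph(layers, nodes),
                              node_order=["L1", "G1"])
        assert adj.A.toarray()[0, 1] == pytest.approx(0.5)

    def test_symmetric_zero_diagonal_on_random_layers(self, rng):
        mg = random_multigraph(rng)
        A = sw.merge_layers(mg).A.toarray()
        assert np.allclose(A, A.T)
        assert np.all(np.diag(A) == 0)
        assert A.min() >= 0 and A.max() <= 1


class TestTransitionMatrix:
    def test_column_normalization(self):
        nodes = [sw.NodeMeta(f"G{i}", "AS_gene") for i in range(4)]
        layer = sw.Layer("ppi", {("G0", "G1"): 1.0, ("G0", "G2"): 0.5,
                                 ("G0", "G3"): 0.5})
        adj = sw.merge_layers(sw.build_multigraph([layer], nodes),
                              node_order=["G0", "G1", "G2", "G3"])
        B = sw.transition_matrix(adj).B.toarray()
        assert np.allclose(B[:, 0], [0, 0.5, 0.25, 0.25])

    def test_single_edge_two_nodes(self):
        nodes = [sw.NodeMeta("G0", "AS_gene"), sw.NodeMeta("G1", "AS_gene")]
        layer = sw.Layer("ppi", {("G0", "G1"): 1.0})
        adj = sw.merge_layers(sw.build_multigraph([layer], nodes),
                              node_order=["G0", "G1"])
        assert np.allclose(sw.transition_matrix(adj).B.toarray(), [[0, 1], [1, 0]])

    def test_isolated_node_self_absorbing(self):
        nodes = [sw.NodeMeta("G0", "AS_gene"), sw.NodeMeta("G1", "AS_gene"),
                 sw.NodeMeta("G2", "AS_gene")]
        layer = sw.Layer("ppi", {("G0", "G1"): 1.0})
        adj = sw.merge_layers(sw.build_multigraph([layer], nodes),
                              node_order=["G0", "G1", "G2"])
        B = sw.transition_matrix(adj).B.toarray()
        assert B[2, 2] == 1.0
        assert np.allclose(B.sum(axis=0), 1.0)

    def test_columns_stochastic_on_random_graphs(self, rng):
        for _ in range(5):
            mg = random_multigraph(rng, p=0.1)
            B = sw.transition_matrix(sw.merge_layers(mg)).B
            assert np.allclose(np.asarray(B.sum(axis=0)).ravel(), 1.0)


class TestSeedVector:
    def test_single_seed(self):
        v = sw.make_seed_vector(["a"], ["a", "b", "c"])
        assert np.allclose(v.p_s, [1, 0, 0])

    def test_two_seeds_uniform(self):
        v = sw.make_seed_vector(["a", "b"], ["a", "b", "c"])
        assert np.allclose(v.p_s, [0.5, 0.5, 0])

    def test_unnormalized_literal_entries(self):
        v = sw.make_seed_vector(["a", "b"], ["a", "b", "c"], normalize=False)
        assert np.allclose(v.p_s, [1, 1, 0])

    def test_unknown_seed_listed_in_error(self):
        with pytest.raises(ValueError, match="z"):
            sw.make_seed_vector(["z"], ["a", "b"])

    def test_empty_seed_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            sw.make_seed_vector([], ["a"])


def two_node_setup():
    nodes = [sw.NodeMeta("a", "AS_gene"), sw.NodeMeta("b", "AS_gene")]
    layer = sw.Layer("ppi", {("a", "b"): 1.0})
    adj = sw.merge_layers(sw.build_multigraph([layer], nodes), node_order=["a", "b"])
    B = sw.transition_matrix(adj)
    return B, sw.make_seed_vector(["a"], adj.node_order)


class TestRWR:
    def test_two_node_fixed_point(self):
        B, ps = two_node_setup()
        p = sw.rwr(B, ps, alpha=0.5)
        assert np.allclose(p.p, [2 / 3, 1 / 3], atol=1e-9)
        assert p.converged

    def test_three_node_path_fixed_point(self):
        nodes = [sw.NodeMeta(x, "AS_gene") for x in "abc"]
        layer = sw.Layer("ppi", {("a", "b"): 1.0, ("b", "c"): 1.0})
        adj = sw.merge_layers(sw.build_multigraph([layer], nodes),
                              node_order=["a", "b", "c"])
        B = sw.transition_matrix(adj)
        p = sw.rwr(B, sw.make_seed_vector(["a"], adj.node_order), alpha=0.5)
        assert np.allclose(p.p, [7 / 12, 1 / 3, 1 / 12], atol=1e-9)

    def test_alpha_one_returns_seed_vector(self):
        B, ps = two_node_setup()
        p = sw.rwr(B, ps, alpha=1.0)
        assert np.array_equal(p.p, ps.p_s)

    def test_probability_conserved_every_iteration(self):
        B, ps = two_node_setup()
        sums = []
        sw.rwr(B, ps, alpha=0.5, callback=lambda t, p: sums.append(p.sum()))
        assert np.allclose(sums, 1.0, atol=1e-12)

    def test_geometric_contraction(self):
        B, ps = two_node_setup()
        deltas = []
        last = [None]

        def cb(t, p):
            if last[0] is not None:
                deltas.append(np.abs(p - last[0]).sum())
            last[0] = p.copy()

        sw.rwr(B, ps, alpha=0.5, callback=cb, tol=1e-12)
        ratios = [d2 / d1 for d1, d2 in zip(deltas, deltas[1:]) if d1 > 1e-13]
        assert all(r <= 0.5 + 1e-9 for r in ratios)

    def test_agrees_with_closed_form_on_random_graphs(self, rng):
        for _ in range(5):
            mg = random_multigraph(rng, n_lnc=15, m_gene=20, p=0.15)
            adj = sw.merge_layers(mg)
            B = sw.transition_matrix(adj)
            seeds = list(rng.choice([n.id for n in mg.nodes], 3, replace=False))
            ps = sw.make_seed_vector(seeds, adj.node_order)
            p_iter = sw.rwr(B, ps, alpha=0.5)
            p_exact = sw.closed_form_rwr(B, ps, alpha=0.5)
            assert np.abs(p_iter.p - p_exact.p).sum() < 1e-8

    def test_closed_form_identity_transition_returns_seed(self):
        nodes = [sw.NodeMeta(x, "AS_gene") for x in "ab"]
        layer = sw.Layer("ppi", {})
        adj = sw.merge_layers(sw.build_multigraph([layer], nodes), node_order=["a", "b"])
        B = sw.transition_matrix(adj)  # both isolated -> identity
        ps = sw.make_seed_vector(["a"], adj.node_order)
        assert np.allclose(sw.closed_form_rwr(B, ps, 0.5).p, ps.p_s)

    def test_uniform_seed_on_vertex_transitive_cycle_is_uniform(self):
        n = 6
        ids = [f"G{i}" for i in range(n)]
        edges = {tuple(sorted((ids[i], ids[(i + 1) % n]))): 1.0 for i in range(n)}
        nodes = [sw.NodeMeta(i, "AS_gene") for i in ids]
        adj = sw.merge_layers(sw.build_multigraph([sw.Layer("ppi", edges)], nodes))
        B = sw.transition_matrix(adj)
        p = sw.rwr(B, sw.make_seed_vector(ids, adj.node_order), alpha=0.5)
        assert np.allclose(p.p, 1 / n, atol=1e-9)

    def test_permutation_equivariance(self, rng):
        mg = random_multigraph(rng, n_lnc=8, m_gene=10, p=0.2)
        order1 = [n.id for n in mg.nodes]
        order2 = list(rng.permutation(order1))
        seeds = order1[:2]
        out = {}
        for order in (order1, order2):
            adj = sw.merge_layers(mg, node_order=order)
            p = sw.rwr(sw.transition_matrix(adj), sw.make_seed_vector(seeds, order))
            out[tuple(order)] = pd.Series(p.p, index=order)
        s1, s2 = out[tuple(order1)], out[tuple(order2)]
        assert np.allclose(s1.sort_index().to_numpy(), s2.sort_index().to_numpy(), atol=1e-9)

    def test_nonconvergence_warns_and_flags(self):
        B, ps = two_node_setup()
        with pytest.warns(ConvergenceWarning):
            p = sw.rwr(B, ps, alpha=0.5, tol=1e-15, max_iter=3)
        assert not p.converged

    def test_invalid_alpha_rejected(self):
        B, ps = two_node_setup()
        with pytest.raises(ValueError):
            sw.rwr(B, ps, alpha=0.0)


class TestRankCandidates:
    def scores(self):
        return sw.ScoreVector(
            p=np.array([0.5, 0.3, 0.2]), node_order=["a", "L1", "L2"],
            iterations_used=1, converged=True
        )

    def test_filters_to_candidate_classes(self):
        classes = {"a": "AS_gene", "L1": "lncRNA", "L2": "lncRNA"}
        ranked = sw.rank_candidates(self.scores(), classes)
        assert list(ranked["id"]) == ["L1", "L2"]
        assert list(ranked["rank"]) == [1, 2]

    def test_ties_break_by_id_with_distinct_ranks(self):
        s = sw.ScoreVector(np.array([0.2, 0.2]), ["Lb", "La"], 1, True)
        ranked = sw.rank_candidates(s, {"La": "lncRNA", "Lb": "lncRNA"})
        assert list(ranked["id"]) == ["La", "Lb"]
        assert list(ranked["rank"]) == [1, 2]

    def test_all_candidates_seeds_excluded_is_error(self):
        classes = {"a": "AS_gene", "L1": "lncRNA", "L2": "lncRNA"}
        with pytest.raises(ValueError):
            sw.rank_candidates(self.scores(), classes, exclude_seeds=True,
                               seed_ids=["L1", "L2"])


class TestRandomWalkRanker:
    def test_fit_sets_attributes(self, toy_multigraph):
        r = sw.RandomWalkRanker().fit(toy_multigraph, ["G1"])
        assert r.converged_
        assert np.isclose(r.scores_.p.sum(), 1.0)
        ranking = r.rank()
        assert set(ranking["node_class"]) <= {"lncRNA", "pseudogene"}

    def test_sklearn_clone_compatible(self):
        r = sw.RandomWalkRanker(alpha=0.3, tol=1e-8)
        r2 = clone(r)
        assert r2.get_params() == r.get_params()

    def test_unnormalized_seeds_scale_scores_not_ranking(self, toy_multigraph):
        seeds = ["G1", "G2"]
        a = sw.RandomWalkRanker(normalize_seeds=True).fit(toy_multigraph, seeds)
        b = sw.RandomWalkRanker(normalize_seeds=False).fit(toy_multigraph, seeds)
        assert list(a.rank()["id"]) == list(b.rank()["id"])
        assert np.allclose(b.scores_.p, 2 * a.scores_.p, atol=1e-8)

    def test_unfitted_rank_raises(self):
        with pytest.raises(RuntimeError):
            sw.RandomWalkRanker().rank()
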