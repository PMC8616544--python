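import itertools

import numpy as np
import pandas as pd
import pytest

from perturbnem.io_and_design import COMBOS, NODES, parse_combo
from perturbnem.nem import (
    ATTACHMENTS,
    assign_regulators,
    bootstrap_edges,
    enumerate_sgraphs,
    infer_best,
    perturbation_map,
    predicted_effects,
    score_graph,
    transitive_closure,
    transitive_reduction,
)
from perturbnem.synthetic import CHAIN


def _chain_closed():
    return CHAIN.copy()


class TestEnumeration:
    @pytest.mark.parametrize("k,expected", [(1, 1), (2, 4), (3, 29)])
    def test_quasi_order_counts(self, k, expected):
        assert len(enumerate_sgraphs(k)) == expected

    def test_matches_bruteforce_transitivity_scan(self):
        # all 64 off-diagonal patterns, kept iff closed under composition
        count = 0
        for bits in itertools.product([0, 1], repeat=6):
            adj = np.eye(3, dtype=bool)
            adj[0, 1], adj[0, 2], adj[1, 0], adj[1, 2], adj[2, 0], adj[2, 1] = map(bool, bits)
            transitive = all(
                not (adj[i, m] and adj[m, j]) or adj[i, j]
                for i in range(3) for m in range(3) for j in range(3)
            )
            count += transitive
        assert count == len(enumerate_sgraphs(3)) == 29

    def test_chain_with_closure_edge_is_member(self):
        graphs = enumerate_sgraphs(3)
        assert any(np.array_equal(g, _chain_closed()) for g in graphs)

    def test_every_graph_is_its_own_closure(self):
        for g in enumerate_sgraphs(3):
            np.testing.assert_array_equal(g, transitive_closure(g))

    def test_large_k_rejected(self):
        with pytest.raises(ValueError):
            enumerate_sgraphs(6)


class TestReduction:
    def test_chain_drops_closure_edge(self):
        red = transitive_reduction(_chain_closed())
        expected = np.zeros((3, 3), dtype=bool)
        expected[0, 1] = expected[1, 2] = True
        np.testing.assert_array_equal(red, expected)

    def test_two_cycle_keeps_both_edges(self):
        adj = np.eye(3, dtype=bool)
        adj[0, 1] = adj[1, 0] = True
        red = transitive_reduction(adj)
        assert red[0, 1] and red[1, 0]


class TestPredictedEffects:
    def test_chain_wnt_row_all_true(self):
        effects = predicted_effects(_chain_closed())
        assert effects[NODES.index("WNT")].all()

    def test_empty_graph_no_propagation(self):
        effects = predicted_effects(np.eye(3, dtype=bool))
        for s, node in enumerate(NODES):
            expected = [node in parse_combo(c) for c in COMBOS]
            np.testing.assert_array_equal(effects[s], expected)

    def test_complete_graph_all_attached_rows_true(self):
        effects = predicted_effects(np.ones((3, 3), dtype=bool))
        assert effects[: len(NODES)].all()

    def test_none_row_all_false(self):
        for g in enumerate_sgraphs(3):
            assert not predicted_effects(g)[-1].any()

    def test_perturbation_map_rows_are_the_seven_subsets(self):
        pm = perturbation_map()
        rows = {tuple(r) for r in pm}
        assert len(rows) == 7 and (0, 0, 0) not in rows


class TestScoreGraph:
    def test_zero_R_uninformative(self):
        R = pd.DataFrame(np.zeros((5, 7)), columns=list(COMBOS))
        for g in enumerate_sgraphs(3):
            score, post = score_graph(R, g)
            assert score == 0.0
            np.testing.assert_allclose(post, 0.25)

    def test_matches_per_gene_attachment_enumeration(self):
        # literal oracle: loop genes, loop the 4 attachments, exp/sum
        rng = np.random.default_rng(7)
        for _ in range(10):
            R = rng.normal(0, 3, size=(6, 7))
            graph = enumerate_sgraphs(3)[rng.integers(0, 29)]
            score, post = score_graph(pd.DataFrame(R, columns=list(COMBOS)), graph)
            F = predicted_effects(graph)
            total = 0.0
            for e in range(6):
                weights = [
                    0.25 * np.exp(sum(R[e, j] for j in range(7) if F[s, j]))
                    for s in range(4)
                ]
                total += np.log(sum(weights))
                np.testing.assert_allclose(post[e], np.array(weights) / sum(weights),
                                           atol=1e-9)
            assert abs(score - total) < 1e-9

    def test_relabeling_symmetry(self):
        rng = np.random.default_rng(8)
        R = pd.DataFrame(rng.normal(size=(10, 7)), columns=list(COMBOS))
        graph = _chain_closed()
        perm = [2, 0, 1]  # relabel S-genes
        graph_p = graph[np.ix_(perm, perm)]
        # permute R columns consistently: combo of relabeled nodes
        relabel = {NODES[i]: NODES[perm.index(i)] for i in range(3)}
        new_cols = {}
        for c in COMBOS:
            mapped = frozenset(relabel[t] for t in parse_combo(c))
            target = "+".join(n for n in NODES if n in mapped)
            new_cols[target] = R[c]
        R_p = pd.DataFrame(new_cols)[list(COMBOS)]
        s1, _ = score_graph(R, graph)
        s2, _ = score_graph(R_p, graph_p)
        assert abs(s1 - s2) < 1e-9

    def test_posteriors_normalized(self, screen):
        _, post = score_graph(screen["R"], _chain_closed())
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-9)

    def test_monotone_in_discriminating_experiment(self):
        # raising R in the one experiment only WNT-attachment predicts
        # (WNT single under the chain) raises the WNT posterior
        R = np.zeros((1, 7))
        graph = _chain_closed()
        wnt_col = list(COMBOS).index("WNT")
        _, post_lo = score_graph(pd.DataFrame(R, columns=list(COMBOS)), graph)
        R[0, wnt_col] = 2.0
        _, post_hi = score_graph(pd.DataFrame(R, columns=list(COMBOS)), graph)
        assert post_hi[0, NODES.index("WNT")] > post_lo[0, NODES.index("WNT")]

    def test_chain_beats_all_alternatives_on_synthetic_R(self, screen):
        fit = infer_best(screen["R"])
        np.testing.assert_array_equal(fit.graph, _chain_closed())
        scores = sorted((s for _, s in fit.score_table), reverse=True)
        assert fit.log_score == scores[0] > scores[1]


class TestInferBest:
    def test_tie_broken_to_empty_graph(self):
        R = pd.DataFrame(np.zeros((4, 7)), columns=list(COMBOS))
        fit = infer_best(R)
        np.testing.assert_array_equal(fit.graph, np.eye(3, dtype=bool))

    def test_best_equals_max_of_score_table(self, screen):
        fit = infer_best(screen["R"])
        assert fit.log_score == max(s for _, s in fit.score_table)

    def test_score_table_covers_all_29_graphs(self, screen):
        assert len(infer_best(screen["R"]).score_table) == 29


class TestAssignRegulators:
    def test_uniform_posterior_unassigned(self):
        R = pd.DataFrame(np.zeros((3, 7)), columns=list(COMBOS))
        fit = infer_best(R)
        assert (assign_regulators(fit) == "unassigned").all()

    def test_softmax_arithmetic(self):
        # a gene whose WNT attachment accumulates +5 while others stay <= 0
        R = np.full((1, 7), 5.0 / 7.0)
        fit_graph = _chain_closed()
        _, post = score_graph(pd.DataFrame(R, columns=list(COMBOS)), fit_graph)
        # direct softmax: chain predicts 4, 6, 7 and 0 of the 7 experiments
        A = np.array([5 * 4 / 7, 5 * 6 / 7, 5.0, 0.0])
        expected = np.exp(A) / np.exp(A).sum()
        np.testing.assert_allclose(post[0], expected, atol=1e-12)

    def test_recovery_of_attached_genes(self, screen):
        truth, fit = screen["truth"], infer_best(screen["R"])
        ids = pd.Index(truth.gene_ids)
        attached = ids[truth.attachment != "none"].intersection(fit.regulator.index)
        truth_map = pd.Series(truth.attachment, index=ids)
        # the NEM regulator (argmax attachment) matches truth for >= 95%
        agree = (fit.regulator.loc[attached] == truth_map.loc[attached]).mean()
        assert agree >= 0.95
        # and the confident (posterior > 0.9) calls are nearly always right
        calls = assign_regulators(fit, threshold=0.9)
        confident = calls.loc[attached][calls.loc[attached] != "unassigned"]
        assert len(confident) > 100
        assert (confident == truth_map.loc[confident.index]).mean() >= 0.97


class TestBootstrap:
    def test_identity_resample_reproduces_full_fit(self, screen):
        fit = infer_best(screen["R"])
        support = bootstrap_edges(
            screen["R"], B=1, seed=0, resampler=lambda rng, n: np.arange(n)
        )
        expected = set(fit.edges(reduced=True))
        for (a, b), count in support.reduction_counts.items():
            assert count == (1 if (a, b) in expected else 0)

    def test_reported_out_of_B(self, screen):
        support = bootstrap_edges(screen["R"], B=5, seed=1)
        assert support.B == 5
        assert all(0 <= c <= 5 for c in support.reduction_counts.values())

    def test_seeded_reproducibility(self, screen):
        a = bootstrap_edges(screen["R"], B=10, seed=3)
        b = bootstrap_edges(screen["R"], B=10, seed=3)
        assert a.reduction_counts == b.reduction_counts

    def test_chain_edges_strongly_supported(self, screen):
        support = bootstrap_edges(screen["R"], B=50, seed=2)
        assert support.support("TGFB", "LATS") >= 49
        assert support.support("LATS", "WNT") >= 49
        others = [
            (a, b) for (a, b) in support.reduction_counts
            if (a, b) not in [("TGFB", "LATS"), ("LATS", "WNT")]
        ]
        assert all(support.support(a, b) <= 2 for a, b in others)
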