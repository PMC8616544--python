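"""Exhaustive nested-effects-model (NEM) inference over three S-genes.

A candidate hierarchy is a reflexive, transitively closed boolean relation
(a quasi-order) over the S-genes {TGFB, LATS, WNT}.  An edge s -> t means
perturbing s also affects everything attached to t.  Each experiment
perturbs the subset of S-genes in its treatment combination, so the
predicted effect of experiment j on a gene attached to node s is 1 iff s
is reachable from at least one perturbed S-gene.

Given the log-density matrix R (genes x 7 experiments; R > 0 evidence of
an effect, R < 0 evidence of none), the attachment likelihood of gene e at
node s is exp(sum_j R[e, j] * effect(s, j)); genes are marginalized over
the four attachments {TGFB, LATS, WNT, none} with a uniform prior, and the
network score is the sum of gene-wise log marginals.  At three S-genes the
29 candidate quasi-orders are scored exhaustively; edge stability is
assessed by bootstrapping genes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .io_and_design import NODES, COMBOS, parse_combo

ATTACHMENTS: tuple[str, ...] = NODES + ("none",)


# ---------------------------------------------------------------------------
# Quasi-order enumeration
# ---------------------------------------------------------------------------

def transitive_closure(adj: np.ndarray) -> np.ndarray:
    """Reflexive-transitive closure of a boolean adjacency (Warshall)."""
    closed = adj.astype(bool).copy()
    k = closed.shape[0]
    np.fill_diagonal(closed, True)
    for m in range(k):
        closed |= np.outer(closed[:, m], closed[m, :])
    return closed


def transitive_reduction(adj: np.ndarray) -> np.ndarray:
    """A minimal edge set with the same reachability (greedy removal in
    fixed row-major order; unique for acyclic relations, deterministic for
    cyclic ones)."""
    closed = transitive_closure(adj)
    reduced = closed.copy()
    np.fill_diagonal(reduced, False)
    k = closed.shape[0]
    changed = True
    while changed:
        changed = False
        for i, j in itertools.product(range(k), repeat=2):
            if i != j and reduced[i, j]:
                reduced[i, j] = False
                trial = transitive_closure(reduced)
                if not np.array_equal(trial, closed):
                    reduced[i, j] = True
                else:
                    changed = True
    return reduced


def enumerate_sgraphs(k: int = 3) -> list[np.ndarray]:
    """All distinct reflexive, transitively closed digraphs on k labeled
    nodes, by brute-force scan of the 2**(k*(k-1)) off-diagonal patterns.

    k=1 gives 1 graph, k=2 gives 4, k=3 gives 29.  Refuses k > 5.
    """
    if k > 5:
        raise ValueError("exhaustive enumeration is limited to k <= 5")
    off_diag = [(i, j) for i in range(k) for j in range(k) if i != j]
    graphs = []
    for bits in itertools.product([False, True], repeat=len(off_diag)):
        adj = np.eye(k, dtype=bool)
        for (i, j), b in zip(off_diag, bits):
            adj[i, j] = b
        if np.array_equal(adj, transitive_closure(adj)):
            graphs.append(adj)
    return graphs


# ---------------------------------------------------------------------------
# Predicted effects and scoring
# ---------------------------------------------------------------------------

def perturbation_map() -> np.ndarray:
    """7 experiments x 3 S-genes boolean matrix: experiment j perturbs
    S-gene s iff s is in the j-th treatment combination (COMBOS order)."""
    pm = np.zeros((len(COMBOS), len(NODES)), dtype=bool)
    for j, combo in enumerate(COMBOS):
        for s in parse_combo(combo):
            pm[j, NODES.index(s)] = True
    return pm


def predicted_effects(
    graph: np.ndarray, perturbations: np.ndarray | None = None
) -> np.ndarray:
    """4 x 7 boolean effect predictions (rows: TGFB, LATS, WNT, none).

    Entry (s, j) is True iff attachment node s is reachable in `graph`
    from at least one S-gene perturbed in experiment j; the "none" row is
    all False.
    """
    pm = perturbation_map() if perturbations is None else perturbations
    closed = transitive_closure(graph)
    effects = np.zeros((len(ATTACHMENTS), pm.shape[0]), dtype=bool)
    # pm[j, p] and closed[p, s]  ->  effect on attachment s in experiment j
    effects[: len(NODES), :] = (pm @ closed).T > 0
    return effects


def score_graph(
    R: pd.DataFrame | np.ndarray,
    graph: np.ndarray,
    prior: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Marginal log score of one candidate hierarchy and the per-gene
    attachment posteriors.

    For gene e and attachment s, A(e, s) = sum_j R[e, j] * effect(s, j);
    the gene's marginal is logsumexp_s(log prior(s) + A(e, s)) and the
    network score is the sum over genes.  Posteriors are the normalized
    exponentials, computed stably.
    """
    Rm = R.to_numpy(dtype=float) if hasattr(R, "to_numpy") else np.asarray(R, float)
    if prior is None:
        prior = np.full(len(ATTACHMENTS), 1.0 / len(ATTACHMENTS))
    F = predicted_effects(graph).astype(float)  # 4 x 7
    A = Rm @ F.T  # genes x 4
    logw = A + np.log(prior)
    gene_marginals = logsumexp(logw, axis=1)
    posterior = np.exp(logw - gene_marginals[:, None])
    return float(gene_marginals.sum()), posterior


@dataclass
class NemFit:
    """Result of exhaustive NEM inference."""

    graph: np.ndarray
    log_score: float
    attachment_posterior: pd.DataFrame  # genes x ATTACHMENTS
    regulator: pd.Series  # argmax attachment label per gene
    score_table: list = field(repr=False, default_factory=list)

    def edges(self, reduced: bool = True) -> list[tuple[str, str]]:
        adj = transitive_reduction(self.graph) if reduced else self.graph
        return [
            (NODES[i], NODES[j])
            for i in range(len(NODES))
            for j in range(len(NODES))
            if i != j and adj[i, j]
        ]


def _graph_sort_key(adj: np.ndarray, score: float):
    off = tuple(int(v) for v in adj[~np.eye(adj.shape[0], dtype=bool)])
    return (-score, int(sum(off)), off)


def infer_best(
    R: pd.DataFrame, prior: np.ndarray | None = None
) -> NemFit:
    """Score all 29 candidate hierarchies and return the best.

    Ties are broken toward fewer edges, then lexicographically smaller
    off-diagonal adjacency, so inference is deterministic.
    """
    if len(R) < 1:
        raise ValueError("need at least one gene")
    graphs = enumerate_sgraphs(len(NODES))
    scored = []
    best = None
    for adj in graphs:
        s, post = score_graph(R, adj, prior)
        scored.append((adj, s))
        key = _graph_sort_key(adj, s)
        if best is None or key < best[0]:
            best = (key, adj, s, post)
    _, adj, s, post = best
    index = R.index if hasattr(R, "index") else pd.RangeIndex(len(post))
    post_df = pd.DataFrame(post, index=index, columns=list(ATTACHMENTS))
    regulator = post_df.idxmax(axis=1).rename("regulator")
    return NemFit(
        graph=adj,
        log_score=s,
        attachment_posterior=post_df,
        regulator=regulator,
        score_table=scored,
    )


def assign_regulators(fit: NemFit, threshold: float = 0.9) -> pd.Series:
    """Per-gene regulator call: the argmax attachment when its posterior
    exceeds `threshold`, else "unassigned".  Genes whose winning attachment
    is "none" are non-responders."""
    top = fit.attachment_posterior.max(axis=1)
    calls = fit.regulator.where(top > threshold, "unassigned")
    return calls.rename("regulator")


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

@dataclass
class BootstrapSupport:
    """Per-edge bootstrap counts out of B gene-resampling runs.

    ``reduction_counts`` counts edges of the transitive reduction of each
    run's best graph (the display convention); ``closure_counts`` counts
    edges of the closure, so support for implied edges is also reported.
    """

    reduction_counts: dict
    closure_counts: dict
    B: int
    seed: int

    def support(self, src: str, tgt: str, reduced: bool = True) -> int:
        counts = self.reduction_counts if reduced else self.closure_counts
        return counts.get((src, tgt), 0)


def bootstrap_edges(
    R: pd.DataFrame,
    B: int = 10000,
    seed: int = 0,
    resampler=None,
) -> BootstrapSupport:
    """Bootstrap edge support: each run resamples genes (rows of R) with
    replacement to the original size, reruns :func:`infer_best`, and
    records the winning graph's edges.

    `resampler(rng, n) -> indices` can replace the default with-replacement
    draw (e.g. the identity, for degenerate checks)."""
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    Rm = R.to_numpy(dtype=float) if hasattr(R, "to_numpy") else np.asarray(R, float)
    n = Rm.shape[0]
    if resampler is None:
        resampler = lambda rng, n: rng.integers(0, n, size=n)
    pairs = [(a, b) for a in NODES for b in NODES if a != b]
    red_counts = {p: 0 for p in pairs}
    clo_counts = {p: 0 for p in pairs}
    graphs = enumerate_sgraphs(len(NODES))
    F_all = np.stack([predicted_effects(g).astype(float) for g in graphs])  # 29x4x7
    log_prior = np.log(1.0 / len(ATTACHMENTS))
    keys = [_graph_sort_key(g, 0.0)[1:] for g in graphs]
    for _ in range(B):
        idx = resampler(rng, n)
        A = np.einsum("gj,kaj->kga", Rm[idx], F_all, optimize=True)
        scores = logsumexp(A + log_prior, axis=2).sum(axis=1)  # per graph
        order = sorted(
            range(len(graphs)), key=lambda k: (-scores[k],) + keys[k]
        )
        winner = graphs[order[0]]
        red = transitive_reduction(winner)
        clo = winner.copy()
        for (a, b) in pairs:
            i, j = NODES.index(a), NODES.index(b)
            if red[i, j]:
                red_counts[(a, b)] += 1
            if clo[i, j]:
                clo_counts[(a, b)] += 1
    return BootstrapSupport(
        reduction_counts=red_counts, closure_counts=clo_counts, B=B, seed=seed
    )
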