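"""Sign-pattern census, overlap/concordance statistics and dominance calls.

Across the seven treatment contrasts each gene shows one of 2**7 = 128
up/down patterns (sign of the log2 fold change per contrast, in the fixed
COMBOS order).  This module counts those patterns, quantifies how often
pairs and the triple of single treatments regulate shared significant
genes in the same direction, classifies which single treatment dominates
the combined treatment when two singles disagree in direction, and builds
the top-N gene tables for the two flagship patterns (all-same-direction,
and WNT-single opposite to the other six).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_and_design import NODES, COMBOS, combo_name

SINGLES = NODES  # the three single-treatment contrasts


def all_patterns() -> list[str]:
    """The 128 sign patterns as '+'/'-' strings in COMBOS order."""
    return [
        "".join(p) for p in itertools.product("+-", repeat=len(COMBOS))
    ]


@dataclass
class PatternCounts:
    """Census over the 128 sign patterns.

    ``counts`` has exactly the 128 pattern keys (zeros included) and sums
    to ``total``; genes with a zero fold change in any contrast have no
    defined sign and are excluded (``n_excluded``)."""

    counts: pd.Series
    total: int
    n_excluded: int

    def ranked(self) -> pd.DataFrame:
        out = self.counts.sort_values(ascending=False).rename("count").to_frame()
        out.index.name = "pattern"
        out["rank"] = np.arange(1, len(out) + 1)
        return out


def count_patterns(
    results, significance_filter: float | None = 0.10
) -> PatternCounts:
    """Count genes per sign pattern over the seven contrasts.

    With `significance_filter` set (default 10% FDR), only genes
    significant in at least one contrast enter the census; pass None to
    census every gene.  Zero fold changes leave the sign undefined, so
    those genes are excluded and tallied separately.
    """
    lfc = results.log2fc
    keep = pd.Series(True, index=lfc.index)
    if significance_filter is not None:
        keep &= (results.fdr <= significance_filter).any(axis=1)
    nonzero = (lfc != 0).all(axis=1)
    excluded = int((keep & ~nonzero).sum())
    use = lfc.loc[keep & nonzero]
    signs = np.where(use.to_numpy() > 0, "+", "-")
    patterns = ["".join(row) for row in signs]
    counts = pd.Series(0, index=pd.Index(all_patterns(), name="pattern"))
    observed = pd.Series(patterns).value_counts()
    counts.loc[observed.index] = observed
    return PatternCounts(counts=counts, total=int(counts.sum()), n_excluded=excluded)


# ---------------------------------------------------------------------------
# Overlap & concordance
# ---------------------------------------------------------------------------

def overlap_and_concordance(effects) -> dict:
    """Overlap and same-direction concordance of the three single treatments.

    Returns a dict with:
      - ``exact``: genes significant in exactly each subset of the singles
        (the 7 Venn regions, keyed by '+'-joined subset names)
      - ``at_least``: genes significant in at least each subset
      - ``pairs``: per single-treatment pair, shared gene count,
        same-direction count, and same-direction fraction (None when the
        intersection is empty)
      - ``triple``: analogous summary for all three singles (same direction
        = identical fold-change sign in all three)
    """
    sig = effects.significant[list(SINGLES)]
    sign = effects.sign[list(SINGLES)]
    union = sig.any(axis=1)

    exact = {}
    at_least = {}
    for r in range(1, 4):
        for subset in itertools.combinations(SINGLES, r):
            inside = sig[list(subset)].all(axis=1)
            outside = sig[[s for s in SINGLES if s not in subset]].any(axis=1) \
                if len(subset) < 3 else pd.Series(False, index=sig.index)
            key = "+".join(subset)
            exact[key] = int((inside & ~outside).sum())
            at_least[key] = int(inside.sum())
    assert sum(exact.values()) == int(union.sum())

    pairs = {}
    for a, b in itertools.combinations(SINGLES, 2):
        shared = sig[a] & sig[b]
        n_shared = int(shared.sum())
        if n_shared == 0:
            pairs[f"{a}+{b}"] = dict(shared=0, same_direction=None, fraction=None)
            continue
        same = int((shared & (sign[a] == sign[b])).sum())
        pairs[f"{a}+{b}"] = dict(
            shared=n_shared, same_direction=same, fraction=same / n_shared
        )

    shared3 = sig.all(axis=1)
    n3 = int(shared3.sum())
    if n3 == 0:
        triple = dict(shared=0, same_direction=None, fraction=None)
    else:
        same3 = int((shared3 & (sign.nunique(axis=1) == 1)).sum())
        triple = dict(shared=n3, same_direction=same3, fraction=same3 / n3)
    return dict(exact=exact, at_least=at_least, pairs=pairs, triple=triple)


def dominance(
    results,
    effects,
    a: str,
    b: str,
    require_significant_combined: bool = False,
) -> dict:
    """Which single treatment the combined treatment follows.

    Over genes significant in both singles `a` and `b` (at the effects'
    FDR cutoff) with *opposite* fold-change signs: the gene is a-dominant
    if the combined contrast a+b has a's sign, b-dominant if b's sign, and
    unresolved on a zero combined fold change.  With
    `require_significant_combined`, the combined contrast must itself be
    significant for a call (otherwise unresolved).
    """
    if a == b:
        raise ValueError("treatments must differ")
    combined = combo_name(frozenset((a, b)))
    if combined not in results.log2fc.columns:
        raise ValueError(f"no combined contrast for {a}+{b}")
    sig = effects.significant
    sign = effects.sign
    shared = sig[a] & sig[b]
    product = sign[a] * sign[b]
    eligible = shared & (product == -1)
    degenerate = shared & (product == 0)  # zero fold change in a single
    comb_sign = np.sign(results.log2fc[combined]).astype(int)
    if require_significant_combined:
        comb_sign = comb_sign.where(sig[combined], 0)
    a_dom = int((eligible & (comb_sign == sign[a])).sum())
    b_dom = int((eligible & (comb_sign == sign[b])).sum())
    unresolved = int((eligible & (comb_sign == 0)).sum()) + int(degenerate.sum())
    same_direction = int((shared & (product == 1)).sum())
    return dict(
        a=a, b=b, combined=combined,
        n_eligible=int(eligible.sum()),
        a_dominant=a_dom, b_dominant=b_dom, unresolved=unresolved,
        shared=int(shared.sum()), same_direction=same_direction,
    )


# ---------------------------------------------------------------------------
# Top pattern tables
# ---------------------------------------------------------------------------

def top_pattern_genes(
    results, pattern_class: int, top_n: int = 30, fdr_cutoff: float = 0.10
) -> pd.DataFrame:
    """Top genes of the two flagship expression patterns.

    Eligible genes have FDR < `fdr_cutoff` in all three single treatments
    and no zero fold change.  Pattern 1: all seven contrasts share one
    sign.  Pattern 2: the WNT single contrast is opposite in sign to the
    other six (which share one sign).  Genes are ranked by the absolute
    log2 fold change of the WNT single treatment, descending, ties broken
    by gene id; at most `top_n` rows of the genes x 7 log2fc table are
    returned.
    """
    if pattern_class not in (1, 2):
        raise ValueError("pattern_class must be 1 or 2")
    lfc = results.log2fc
    eligible = (results.fdr[list(SINGLES)] < fdr_cutoff).all(axis=1)
    eligible &= (lfc != 0).all(axis=1)
    signs = np.sign(lfc.to_numpy())
    others = [c for c in COMBOS if c != "WNT"]
    other_idx = [list(COMBOS).index(c) for c in others]
    wnt_idx = list(COMBOS).index("WNT")
    others_same = np.abs(signs[:, other_idx].sum(axis=1)) == len(other_idx)
    if pattern_class == 1:
        match = others_same & (signs[:, wnt_idx] == signs[:, other_idx[0]])
    else:
        match = others_same & (signs[:, wnt_idx] == -signs[:, other_idx[0]])
    pool = lfc.loc[eligible & pd.Series(match, index=lfc.index)]
    # rank by |WNT single log2fc| descending, exact ties broken by gene id
    order = pool.loc[
        sorted(pool.index, key=lambda g: (-abs(pool.at[g, "WNT"]), g))
    ]
    return order.head(top_n)
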