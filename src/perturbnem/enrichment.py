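"""Rank-based gene-set enrichment of contrast fold changes.

Genes are ranked by their log2 fold change in one contrast; enrichment of
a gene set (e.g. a proliferative or invasive melanoma state signature) is
tested with the Wilcoxon rank-sum test of member versus non-member ranks.
The enrichment curve visualizes where the m set members sit in the global
ranking of n genes:

    f(i) = | rank(i)/n - i/m |,   i = 1..m,

with rank(i) the global rank of the i-th member (in rank order).  f stays
near 0 when members are spread uniformly and rises toward 1 for extreme
concentrations at one end.

Identifier matching is exact string matching on the caller's namespace;
any cross-namespace mapping happens upstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: tuple[str, ...]
    description: str = ""

    def __post_init__(self):
        if len(set(self.genes)) != len(self.genes):
            object.__setattr__(self, "genes", tuple(dict.fromkeys(self.genes)))


@dataclass
class EnrichmentResult:
    """Curve points (i, rank(i), f(i)) with the test p-value and sizes."""

    set_name: str
    p_value: float
    curve: pd.DataFrame  # columns: i, rank, f
    n: int
    m: int


def read_gmt(path) -> list[GeneSet]:
    """Parse a GMT gene-set file (name <tab> description <tab> members...)."""
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}, line {lineno}: expected at least 3 tab-separated "
                    "fields (name, description, members)"
                )
            members = tuple(g for g in fields[2:] if g)
            sets.append(GeneSet(name=fields[0], description=fields[1], genes=members))
    return sets


def _split_members(log2fc: pd.Series, gene_set: GeneSet):
    member_mask = log2fc.index.isin(gene_set.genes)
    if not member_mask.any():
        missing = sorted(set(gene_set.genes))
        raise ValueError(
            f"no members of {gene_set.name!r} found among ranked genes; "
            f"missing ids: {missing[:10]}{'...' if len(missing) > 10 else ''}"
        )
    return member_mask


def wilcoxon_enrichment(
    log2fc: pd.Series,
    gene_set: GeneSet,
    side: str = "two-sided",
    descending: bool = True,
) -> float:
    """Wilcoxon rank-sum p-value for set members vs non-members.

    Genes are ranked by log2 fold change (`descending` puts up-regulated
    genes at the top; the two-sided p-value is direction-invariant).  With
    ``side='greater'`` the alternative is that members sit at the top of
    the ranking.  Ties receive mid-ranks; the exact distribution is used
    when there are no ties and sizes permit.
    """
    member_mask = _split_members(log2fc, gene_set)
    if member_mask.all():
        return float("nan")  # no non-members to compare against
    values = log2fc.to_numpy(dtype=float)
    scores = values if descending else -values
    res = mannwhitneyu(
        scores[member_mask], scores[~member_mask], alternative=side
    )
    return float(res.pvalue)


def enrichment_curve(
    log2fc: pd.Series,
    gene_set: GeneSet,
    side: str = "two-sided",
    descending: bool = True,
) -> EnrichmentResult:
    """Enrichment curve f(i) = |rank(i)/n - i/m| plus the rank-sum p-value.

    Global ranks are positions in the fold-change-sorted gene list
    (1-based; ties keep the input order within the stable sort).
    """
    member_mask = _split_members(log2fc, gene_set)
    n = len(log2fc)
    order = np.argsort(
        -log2fc.to_numpy(float) if descending else log2fc.to_numpy(float),
        kind="stable",
    )
    member_sorted = member_mask[order]
    ranks = np.nonzero(member_sorted)[0] + 1  # global rank of each member
    m = len(ranks)
    i = np.arange(1, m + 1)
    f = np.abs(ranks / n - i / m)
    curve = pd.DataFrame({"i": i, "rank": ranks, "f": f})
    p = wilcoxon_enrichment(log2fc, gene_set, side=side, descending=descending)
    return EnrichmentResult(
        set_name=gene_set.name, p_value=p, curve=curve, n=n, m=m
    )
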