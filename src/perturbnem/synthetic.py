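"""Synthetic combinatorial perturbation screens with a known hierarchy.

Generates negative-binomial count matrices in which each responsive gene
(E-gene) is attached to one node of a known three-node hierarchy over the
treatments TGFB, LATS (siLATS1/2) and WNT (Wnt-3a).  A gene responds to a
treatment combination iff its attachment node is reachable from at least
one perturbed node, mirroring the nested-effects reading of the screen:
with the default chain TGFB -> LATS -> WNT, TGFB-attached genes react to
TGFB only, LATS-attached genes to TGFB and LATS, and WNT-attached genes to
all three single treatments.

A configurable fraction of WNT-attached genes responds to the WNT single
treatment in the *opposite* direction, and upstream perturbations dominate
(override the flip) in combined treatments — emulating the two dominant
response patterns seen in such screens and making dominance classification
testable against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io_and_design import NODES, COMBOS, combo_name, parse_combo, all_conditions

CHAIN = np.array(
    [[True, True, True],
     [False, True, True],
     [False, False, True]]
)  # TGFB -> LATS -> WNT, transitively closed, reflexive


@dataclass
class SyntheticTruth:
    """Ground truth for one simulated screen.

    hierarchy      : 3x3 boolean reachability over NODES (row upstream of col)
    attachment     : per gene, one of {"TGFB", "LATS", "WNT", "none"}
    effect_log2fc  : per gene signed effect size, log2 units (0 if unattached)
    wnt_opposite   : per gene, True if the WNT-single response is flipped
    dispersion     : per gene NB dispersion (var = mu + disp * mu^2)
    baseline_mean  : per gene control-condition mean count
    batch_log2fc   : per gene multiplicative cell-line effect, log2 units
    seed           : generator seed
    """

    hierarchy: np.ndarray
    attachment: np.ndarray
    effect_log2fc: np.ndarray
    wnt_opposite: np.ndarray
    dispersion: np.ndarray
    baseline_mean: np.ndarray
    batch_log2fc: np.ndarray
    seed: int
    gene_ids: np.ndarray = field(default=None)

    def __post_init__(self):
        n = len(self.attachment)
        if self.gene_ids is None:
            self.gene_ids = np.array([f"gene{i:05d}" for i in range(n)])
        unattached = self.attachment == "none"
        if self.effect_log2fc[unattached].any():
            raise ValueError("unattached genes must have zero effect")
        if (self.dispersion <= 0).any() or (self.baseline_mean <= 0).any():
            raise ValueError("dispersion and baseline_mean must be positive")

    @property
    def n_genes(self) -> int:
        return len(self.attachment)

    def to_json_dict(self) -> dict:
        d = asdict(self)
        return {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in d.items()
        }


def generate_truth(
    n_genes: int = 1000,
    fractions: tuple[float, float, float] = (0.1, 0.1, 0.1),
    effect_magnitude: float = 2.0,
    opposite_fraction: float = 0.5,
    dispersion: float = 0.1,
    batch_sd: float = 0.5,
    hierarchy: np.ndarray | None = None,
    seed: int = 0,
) -> SyntheticTruth:
    """Draw a reproducible ground truth.

    `fractions` are the per-node attachment probabilities in NODES order
    (remainder unattached); effects are +/- `effect_magnitude` with equal
    probability; `opposite_fraction` of WNT-attached genes get the flipped
    WNT-single direction; per-gene baseline means are log-normal and
    cell-line effects are Normal(0, `batch_sd`) in log2 units.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    fractions = np.asarray(fractions, dtype=float)
    if len(fractions) != 3 or (fractions < 0).any() or fractions.sum() > 1:
        raise ValueError("fractions must be 3 nonnegative values summing to <= 1")
    rng = np.random.default_rng(seed)
    probs = np.append(fractions, 1.0 - fractions.sum())
    labels = np.array(list(NODES) + ["none"])
    attachment = labels[rng.choice(4, size=n_genes, p=probs)]
    attached = attachment != "none"
    signs = rng.choice([-1.0, 1.0], size=n_genes)
    effect = np.where(attached, signs * effect_magnitude, 0.0)
    wnt_opposite = (attachment == "WNT") & (rng.random(n_genes) < opposite_fraction)
    baseline = rng.lognormal(mean=np.log(500.0), sigma=1.0, size=n_genes)
    batch = rng.normal(0.0, batch_sd, size=n_genes)
    return SyntheticTruth(
        hierarchy=(CHAIN.copy() if hierarchy is None else np.asarray(hierarchy, bool)),
        attachment=attachment,
        effect_log2fc=effect,
        wnt_opposite=wnt_opposite,
        dispersion=np.full(n_genes, float(dispersion)),
        baseline_mean=baseline,
        batch_log2fc=batch,
        seed=int(seed),
    )


def expected_log2fc(truth: SyntheticTruth, combo) -> np.ndarray:
    """Per-gene expected log2 fold change (vs control) under `combo`.

    A gene is affected iff its attachment node is reachable in the
    hierarchy from at least one perturbed node.  For affected genes the
    effect equals `effect_log2fc`, with the sign flipped in WNT-containing
    combos only when the gene carries the WNT-opposite flag *and* no node
    upstream of its attachment is perturbed (upstream dominance).
    """
    if isinstance(combo, str):
        combo = parse_combo(combo)
    if not combo:
        raise ValueError("combo must be nonempty (control has no fold change)")
    node_idx = {n: i for i, n in enumerate(NODES)}
    perturbed = [node_idx[n] for n in combo]
    reach = truth.hierarchy
    out = np.zeros(truth.n_genes)
    for g in range(truth.n_genes):
        a = truth.attachment[g]
        if a == "none":
            continue
        ai = node_idx[a]
        if not any(reach[p, ai] for p in perturbed):
            continue
        value = truth.effect_log2fc[g]
        if truth.wnt_opposite[g] and "WNT" in combo:
            # strict upstream of the attachment node that is perturbed
            upstream_hit = any(
                reach[p, ai] and p != ai for p in perturbed
            )
            if not upstream_hit:
                value = -value
        out[g] = value
    return out


def simulate_counts(
    truth: SyntheticTruth,
    n_replicates: int = 2,
    library_size: float = 1e6,
    cell_lines: tuple[str, str] = ("CL1", "CL2"),
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a (CountMatrix, SampleTable) pair.

    Counts are negative binomial with mean
    ``baseline_mean * 2**(batch_log2fc * L) * 2**expected_log2fc * s``
    where ``s`` scales expected control totals to `library_size`, and
    variance ``mu + dispersion * mu**2``.  The sample table enumerates
    2 cell lines x 8 conditions x `n_replicates` technical replicates.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(truth.seed + 1 if seed is None else seed)
    size_factor = library_size / truth.baseline_mean.sum()
    elfc = {
        combo_name(c): (expected_log2fc(truth, c) if c else np.zeros(truth.n_genes))
        for c in all_conditions()
    }
    records = []
    columns = {}
    n_over_disp = 1.0 / truth.dispersion
    for line_i, line in enumerate(cell_lines):
        batch_mult = 2.0 ** (truth.batch_log2fc * line_i)
        for combo in all_conditions():
            cname = combo_name(combo)
            mu = truth.baseline_mean * batch_mult * 2.0 ** elfc[cname] * size_factor
            p = n_over_disp / (n_over_disp + mu)
            for rep in range(1, n_replicates + 1):
                sid = f"{line}_{cname or 'ctrl'}_r{rep}"
                columns[sid] = rng.negative_binomial(n_over_disp, p)
                records.append(
                    dict(sample_id=sid, cell_line=line, combo=cname, replicate=rep)
                )
    counts = pd.DataFrame(columns, index=pd.Index(truth.gene_ids, name="gene_id"))
    samples = pd.DataFrame.from_records(records)
    return counts, samples
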