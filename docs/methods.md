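# Methods

## Experimental design and model

The screen crosses two cell lines with eight conditions: untreated control
and all seven nonempty combinations of three perturbations — TGFβ ligand
(`TGFB`), siRNA knockdown of LATS1/2 (`LATS`), and Wnt-3a ligand (`WNT`) —
with technical duplicates, i.e. 2 × 8 × 2 = 32 samples by default.
Expression of gene *g* in sample *i* is modeled as negative binomial with

    log mu_gi = beta_0 + beta_1 L_i + sum_c beta_c x_ic + log(N_i f_i)

where `L` indicates the second cell line (reference level: the
lexicographically first label; the treatment contrasts are invariant to
this choice), `x_ic` indicates the sample's treatment combination (one
indicator per nonempty combination, fixed column order TGFB, LATS, WNT,
TGFB+LATS, TGFB+WNT, LATS+WNT, TGFB+LATS+WNT), `N_i` is the library size
and `f_i` the TMM scaling factor.  Each treatment coefficient is therefore
a contrast of that condition against control, adjusted for the cell line.
Technical duplicates are treated as independent observations; the model is
fit to all 32 samples.

### Negative-binomial fitting

The NB parameterization is var = μ + φμ².  Coefficients are estimated by
iteratively reweighted least squares at fixed per-gene dispersion,
vectorized across genes (batched 9×9 normal-equation solves); unit tests
verify agreement with `statsmodels` GLM fits to ~10⁻⁴ log2 units.
Dispersion is estimated per gene by profiling the **Cox–Reid adjusted**
likelihood (ll − ½ log det X'WX) on a 61-point log-spaced grid over
[10⁻⁴, 10] with quadratic refinement, then shrunk toward the pooled
estimate on the log scale with 20 prior degrees of freedom against the
residual degrees of freedom.  The Cox–Reid adjustment matters: plain ML
dispersion is biased low with 9 mean parameters and 32 samples, which
makes the likelihood-ratio test anti-conservative (empirically ~10% of
null p-values below 0.05 instead of ~5.5% with the adjustment).

Each of the seven contrasts is tested by a likelihood-ratio test (full
model vs the model with that coefficient removed, χ²₁).  P-values are
BH-corrected **per contrast** and binarized at FDR ≤ 10%.  Genes first
pass an expression filter (≥ 1 count-per-million in ≥ 2 samples); genes
whose fit does not converge are dropped and counted.  Exact numeric
agreement with any specific moderated-dispersion DE package is a
non-goal; on real data the FDR lists may differ slightly at the margin.

### Normalization

TMM scaling factors: the reference sample is the one whose 75th
count-per-million percentile is closest to the mean; per sample, log2
ratios against the reference are doubly trimmed (30% on M, 5% on A) and
averaged with inverse asymptotic-variance weights; factors are rescaled
to geometric mean 1.  The GLM offset is log(library size × factor).

### PCA input

For visualization, log(x+1) of raw counts, optionally with the per-gene
cell-line effect removed by least squares on the line indicator.  Raw
counts (not normalized counts) are transformed.

## β-uniform mixture

Raw p-values pooled over all genes × 7 contrasts are fit by maximum
likelihood to f(p) = λ + (1−λ)·a·p^(a−1), 0 < a ≤ 1, with L-BFGS-B from
four fixed starting points (the likelihood is flat near a = 1, so a
single start can stall).  A per-contrast fit is available behind a flag.
The NEM evidence is R = log a + (a−1) log p, the log density of the beta
component, which equals the log likelihood-ratio of signal against the
unit-uniform null; an option uses the full mixture density instead.
P-values are clamped to [10⁻¹⁰, 1] before evaluating R because p^(a−1)
diverges at 0; the density itself is left unclamped so it integrates
to 1.

## Nested effects model

Candidate hierarchies are the 29 reflexive, transitively closed relations
(quasi-orders) on the three perturbations, enumerated by brute force.
Experiment j perturbs the S-genes in its treatment combination; a gene
attached to node s is predicted affected in experiment j iff s is
reachable from a perturbed node.  With attachment prior uniform over
{TGFB, LATS, WNT, none} (the "none" attachment, predicting no effects
anywhere, absorbs non-responders so they do not distort the score), the
gene marginal is logsumexp over attachments of the prior plus
Σⱼ R(e,j)·effect(s,j), and the network score sums gene marginals.  Ties
are broken toward fewer edges, then lexicographic adjacency, making
inference deterministic (an all-zero R yields the empty graph).

The regulator of a gene is its maximum-posterior attachment; a
*confident* call additionally requires posterior > 0.9.  Under the
default synthetic conditions about a third of truly attached genes stay
below that threshold: nested attachments (e.g. TGFB vs LATS under the
chain) differ only in experiments where the gene is predicted
unaffected, so their separation rests on a couple of null-density terms.
The argmax regulator still matches truth for ≥ 95% of attached genes.

Bootstrap support resamples genes (rows of R) with replacement to the
original size and reruns the exhaustive search; edges are counted on the
transitive *reduction* of each winner (the display convention), with
closure-edge counts reported in a secondary table.  Gene resampling is
the established NEM bootstrap; experiment resampling is not meaningful
with only seven informative experiments.  The transitive reduction of a
cyclic relation is not unique; a greedy fixed-order removal is used,
which is deterministic and exact for acyclic winners.

## Patterns, concordance, dominance

The sign census maps each gene to the 7-vector of fold-change signs
(2⁷ = 128 patterns, fixed contrast order); genes with an exactly zero
fold change are excluded from the census (their sign is undefined) and
tallied separately.  By default only genes significant in ≥ 1 contrast
at 10% FDR enter; an unfiltered census is available.

For each pair of single treatments, *shared* genes are significant in
both; the same-direction fraction is the share with equal sign.  Among
shared genes with opposite signs, the gene is A-dominant if the combined
contrast's sign equals A's, B-dominant if B's, unresolved if zero.  Genes
with a zero single-treatment fold change among the shared set are counted
as unresolved so that same-direction + A-dominant + B-dominant +
unresolved always partitions the shared count.  Dominance uses the
combined contrast's sign only; an optional gate additionally requires the
combined contrast to be significant.

Top-pattern tables: genes with FDR < 10% in all three single treatments,
matching pattern 1 (all seven contrasts one sign) or pattern 2 (WNT
single opposite to the other six, which share one sign), ranked by the
absolute WNT-single log2 fold change, ties broken by gene id, top 30.

## Enrichment

Genes are ranked by log2 fold change (descending for positive enrichment
of up-regulated signatures; both directions exposed).  The p-value is the
Wilcoxon rank-sum test of member vs non-member ranks (two-sided default,
one-sided options; exact distribution when tie-free and sizes permit).
The curve is f(i) = |rank(i)/n − i/m| for the i-th set member in rank
order — the printed form of this formula in the source material is
typographically garbled, and this is the only reading consistent with its
symbol glossary.  Fold changes are never clipped in statistics (a ±1 clip
is a plot-only convention).  Identifier matching is exact string match.

## Synthetic data generator

The generator emulates the screen's structure: 2 cell lines × 8
conditions × technical duplicates, NB counts (var = μ + φμ²), a per-gene
multiplicative cell-line effect, and a known hierarchy with per-gene
attachments.  Defaults, chosen once as a strong-but-realistic regime:

| parameter           | default | meaning                                     |
|---------------------|---------|---------------------------------------------|
| n_genes             | 1000    | genes                                       |
| fractions           | .1/.1/.1| genes attached to TGFB / LATS / WNT         |
| effect_magnitude    | 2.0     | attached-gene \|log2FC\|, sign ± equiprobable |
| opposite_fraction   | 0.5     | WNT-attached genes with flipped WNT-single  |
| dispersion          | 0.1     | NB dispersion φ (typical bulk RNA-seq)      |
| library_size        | 10⁶     | expected control-sample total counts        |
| batch_log2fc        | N(0,0.5)| per-gene cell-line effect, log2 units       |
| baseline_mean       | logN(log 500, 1) | per-gene control mean (relative)   |
| n_replicates        | 2       | technical duplicates per condition per line |

A gene responds to a combination iff its attachment is reachable from a
perturbed node.  The `opposite_fraction` flag flips the WNT-single
direction of flagged WNT-attached genes; in combined treatments that also
perturb a node *upstream* of the attachment the unflipped sign wins
(upstream dominance), which makes the dominance classifier testable
against ground truth.  What the generator does **not** emulate:
biological replicates, gene–gene correlation, GC/length bias, outlier
dispersions, unbalanced designs and count-level batch interactions —
passing recovery tests therefore demonstrates correctness of the
inference machinery under the stated generative model, not performance
guarantees on arbitrary real data.

## Pipeline determinism and problem sizes

A single seed is expanded into per-stage child seeds via
`numpy.random.SeedSequence(seed).generate_state` (synthetic stage first,
bootstrap second, reduced mod 2³¹), so identical config + seed give
byte-identical outputs and stages can be rerun in isolation.  The test
suite and `scripts/acceptance.py` use 1,000-gene screens, 20 seeds for
hierarchy recovery and B = 100 bootstrap runs — sizes at which the full
chain completes in seconds per screen while keeping Monte-Carlo error
well inside the asserted bounds; production runs would typically use
B = 10,000 (the CLI default).

## Known limitations

- Exhaustive enumeration is limited to ≤ 5 S-genes (quasi-order counts
  explode combinatorially); larger screens need greedy or MCMC search,
  which is out of scope.
- The BUM fit pools all contrasts; strongly heterogeneous signal fractions
  across contrasts would argue for the per-contrast option.
- The LRT is asymptotic; at very low counts or few replicates its
  calibration degrades (the acceptance check covers the default design).
- Real-data FDR lists will not numerically match moderated-dispersion DE
  tools gene for gene, although calls agree for clear effects.
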