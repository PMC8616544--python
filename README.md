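# perturbnem

Inference of signaling hierarchies from combinatorial perturbation RNA-seq
screens with nested effects models (NEMs).

## The problem

Melanoma cells switch between a proliferative and an invasive state under
the control of several signaling pathways — TGFβ/SMAD, Hippo/YAP/TAZ
(probed by LATS1/2 knockdown) and Wnt/β-catenin (probed by Wnt-3a).  A
screen that applies these three perturbations alone and in every
combination (control + 7 combinations, two cell lines, technical
duplicates) produces genome-wide expression readouts from which the
*epistatic hierarchy* of the three pathways can be inferred: if
perturbation A affects a superset of the genes affected by B, A acts
upstream of B.  `perturbnem` implements that full analysis chain for
researchers working with such factorial perturbation screens:

1. **Differential expression** — per gene, a negative-binomial GLM
   `log μ = β₀ + β₁L + β₂·TGFB + … + β₈·(TGFB+LATS+WNT) + offset` with a
   cell-line covariate `L` and TMM library-size offsets; each of the seven
   treatment coefficients β₂…β₈ is a contrast against control, tested by
   likelihood ratio, BH-corrected and binarized at 10% FDR.
2. **β-uniform mixture (BUM)** — raw p-values are modeled as
   `f(p) = λ + (1−λ)·a·p^(a−1)`; the log density of the beta component
   `R = log a + (a−1)·log p` is the evidence score fed to the NEM
   (`R > 0`: affected, `R < 0`: unaffected).
3. **NEM inference** — all 29 transitively closed hierarchies over the
   three perturbations are scored exhaustively by marginalizing each
   gene's attachment over {TGFB, LATS, WNT, none}; edge stability is
   quantified by bootstrapping genes.
4. **Pattern analysis** — census of the 2⁷ = 128 up/down sign patterns
   across the seven contrasts, overlap/concordance of the single
   treatments, and dominance calls (which single treatment the combined
   treatment follows when two singles disagree in direction).
5. **Enrichment** — Wilcoxon rank-sum enrichment of fold-change rankings
   against gene sets (e.g. proliferative/invasive melanoma signatures),
   with the positional curve `f(i) = |rank(i)/n − i/m|`.

A synthetic-data generator produces count matrices from a known
ground-truth hierarchy (default: the chain TGFB → LATS → WNT), so the
whole pipeline is testable end to end without any external data.

## Worked example

```python
from perturbnem import infer_best, bootstrap_edges, assign_regulators
from perturbnem.pipeline import run_synthetic_screen

# simulate a 1,000-gene screen (chain truth), run DE + BUM
truth, results, bum_fit, R = run_synthetic_screen(seed=7)
print(f"BUM fit: lambda={bum_fit.lam:.3f}, a={bum_fit.a:.3f}")

fit = infer_best(R)
print(f"best hierarchy: {fit.edges(reduced=True)}  (log score {fit.log_score:.1f})")

support = bootstrap_edges(R, B=100, seed=8)
for edge, count in support.reduction_counts.items():
    if count:
        print(f"edge {edge[0]}->{edge[1]}: {count}/100 bootstrap runs")

print(assign_regulators(fit, threshold=0.9).value_counts().to_string())
```

prints

```
BUM fit: lambda=0.669, a=0.068
best hierarchy: [('TGFB', 'LATS'), ('LATS', 'WNT')]  (log score 24397.7)
edge TGFB->LATS: 100/100 bootstrap runs
edge LATS->WNT: 100/100 bootstrap runs
regulator
none          655
unassigned    132
WNT            97
TGFB           70
LATS           46
```

The fitted mixture says ~67% of p-values are null (λ) with a strongly
decreasing signal component (a ≪ 1).  The inferred hierarchy is exactly
the generating chain, with both edges supported in every bootstrap run.
Of the 1,000 genes, 655 are confidently non-responders, 213 are assigned
to a regulator with posterior > 0.9 (genes attached to WNT respond to all
three single treatments, LATS genes to TGFB and LATS, TGFB genes to TGFB
only), and 132 respond but cannot be placed confidently.

The same analysis runs from the shell:

```bash
perturbnem simulate --config config.yaml      # synthetic benchmark
perturbnem run --config config.yaml           # counts + sample sheet TSVs
perturbnem nem --logdensities R.tsv -B 1000   # NEM on a precomputed R
perturbnem enrich --gmt sets.gmt --results contrasts.tsv
```

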