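"""End-to-end pipeline: I/O -> differential expression -> BUM -> NEM
(+bootstrap) -> patterns -> enrichment, driven by a YAML config.

A single global seed is expanded into per-stage child seeds through
``numpy.random.SeedSequence(seed).generate_state`` (synthetic data first,
bootstrap second), so stages can be re-run in isolation and identical
config + seed gives byte-identical numeric outputs.
"""

from __future__ import annotations

import itertools
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (
    io_and_design as iod,
    synthetic,
    diffexp,
    bum,
    nem,
    patterns,
    enrichment as enr,
)
from .io_and_design import NODES, COMBOS

logger = logging.getLogger("perturbnem")


@dataclass
class PipelineConfig:
    output_dir: str = "perturbnem_out"
    counts_path: str | None = None
    samples_path: str | None = None
    gene_sets_path: str | None = None
    fdr_cutoff: float = 0.10
    posterior_threshold: float = 0.9
    bootstrap_B: int = 10000
    seed: int = 0
    synthetic: dict | None = None  # synthetic-mode parameters, None = real data

    def __post_init__(self):
        if not (0 < self.fdr_cutoff < 1) or not (0 < self.posterior_threshold < 1):
            raise ValueError("cutoffs must lie in (0, 1)")
        if self.bootstrap_B < 1:
            raise ValueError("bootstrap_B must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def stage_seeds(self) -> dict:
        state = np.random.SeedSequence(self.seed).generate_state(2)
        return {
            "synthetic": int(state[0] % 2**31),
            "bootstrap": int(state[1] % 2**31),
        }


def run_synthetic_screen(
    seed: int,
    n_genes: int = 1000,
    n_replicates: int = 2,
    library_size: float = 1e6,
    **truth_kwargs,
):
    """Simulate a screen and run it through differential expression and the
    BUM stage, in memory.

    Returns (truth, contrast results, BUM fit, log-density matrix R) —
    the inputs every downstream stage consumes.
    """
    truth = synthetic.generate_truth(n_genes=n_genes, seed=seed, **truth_kwargs)
    counts, samples = synthetic.simulate_counts(
        truth, n_replicates=n_replicates, library_size=library_size
    )
    design = iod.build_design(samples)
    keep = diffexp.expression_filter(counts)
    filtered = counts.loc[keep]
    norm = diffexp.normalization_factors(filtered)
    results = diffexp.fit_contrasts(filtered, design, norm)
    fit = bum.fit_bum(results.p_raw.to_numpy().ravel())
    R = bum.log_density(results, fit)
    return truth, results, fit, R


def _stage(manifest: dict, name: str, **info) -> None:
    manifest["stages"].append({"stage": name, **info})
    logger.info("stage=%s %s", name, " ".join(f"{k}={v}" for k, v in info.items()))


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the manifest (also written as JSON)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = config.stage_seeds()
    manifest = {
        "package": "perturbnem",
        "parameters": asdict(config),
        "stage_seeds": seeds,
        "stages": [],
    }
    try:
        _run_stages(config, out, seeds, manifest)
    except Exception as exc:
        manifest["error"] = {
            "stage": manifest["stages"][-1]["stage"] if manifest["stages"] else "io",
            "message": str(exc),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _run_stages(config, out, seeds, manifest):
    t0 = time.perf_counter()
    truth = None
    if config.synthetic is not None:
        params = dict(config.synthetic)
        sim = {
            k: params.pop(k)
            for k in ("n_replicates", "library_size")
            if k in params
        }
        truth = synthetic.generate_truth(seed=seeds["synthetic"], **params)
        counts, samples = synthetic.simulate_counts(truth, **sim)
        iod.write_counts(counts, out / "counts.tsv")
        iod.write_samples(samples, out / "samples.tsv")
        (out / "truth.json").write_text(json.dumps(truth.to_json_dict(), indent=2))
    else:
        counts = iod.read_counts(config.counts_path)
        samples = iod.read_samples(config.samples_path, counts)
    design = iod.build_design(samples)
    _stage(manifest, "io", n_genes=counts.shape[0], n_samples=counts.shape[1],
           elapsed=round(time.perf_counter() - t0, 3))

    t0 = time.perf_counter()
    keep = diffexp.expression_filter(counts)
    filtered = counts.loc[keep]
    norm = diffexp.normalization_factors(filtered)
    results = diffexp.fit_contrasts(filtered, design, norm)
    effects = diffexp.binarize_effects(results, cutoff=config.fdr_cutoff)
    results.to_long().to_csv(out / "contrasts.tsv", sep="\t", index=False)
    _stage(manifest, "diffexp", n_filtered=int(keep.sum()),
           n_tested=len(results.genes), n_nonconverged=results.n_nonconverged,
           n_significant=int(effects.significant.to_numpy().sum()),
           elapsed=round(time.perf_counter() - t0, 3))

    t0 = time.perf_counter()
    fit = bum.fit_bum(results.p_raw.to_numpy().ravel())
    R = bum.log_density(results, fit)
    R.to_csv(out / "log_densities.tsv", sep="\t")
    (out / "bum_fit.json").write_text(json.dumps(asdict(fit), indent=2))
    _stage(manifest, "bum", lam=round(fit.lam, 4), a=round(fit.a, 4),
           elapsed=round(time.perf_counter() - t0, 3))

    t0 = time.perf_counter()
    nem_fit = nem.infer_best(R)
    regulators = nem.assign_regulators(nem_fit, threshold=config.posterior_threshold)
    support = nem.bootstrap_edges(R, B=config.bootstrap_B, seed=seeds["bootstrap"])
    reg_table = pd.DataFrame({
        "gene": regulators.index,
        "regulator": regulators.to_numpy(),
        "posterior": nem_fit.attachment_posterior.max(axis=1).to_numpy(),
    })
    reg_table.to_csv(out / "regulators.tsv", sep="\t", index=False)
    nem_json = {
        "adjacency": nem_fit.graph.astype(int).tolist(),
        "nodes": list(NODES),
        "log_score": nem_fit.log_score,
        "edges_reduced": nem_fit.edges(reduced=True),
        "edges_closure": nem_fit.edges(reduced=False),
        "score_table": [
            {"adjacency": g.astype(int).tolist(), "log_score": s}
            for g, s in nem_fit.score_table
        ],
    }
    (out / "nem_fit.json").write_text(json.dumps(nem_json, indent=2))
    (out / "bootstrap_support.json").write_text(json.dumps({
        "B": support.B,
        "seed": support.seed,
        "reduction": {f"{a}->{b}": c for (a, b), c in support.reduction_counts.items()},
        "closure": {f"{a}->{b}": c for (a, b), c in support.closure_counts.items()},
    }, indent=2))
    _stage(manifest, "nem", edges=nem_fit.edges(reduced=True),
           log_score=round(nem_fit.log_score, 2), B=support.B,
           elapsed=round(time.perf_counter() - t0, 3))
    manifest["recovered_edges"] = nem_fit.edges(reduced=True)
    if truth is not None:
        manifest["truth_edges"] = [
            (NODES[i], NODES[j])
            for i, j in zip(*np.nonzero(nem.transitive_reduction(truth.hierarchy)))
        ]
        manifest["hierarchy_recovered"] = bool(
            np.array_equal(nem_fit.graph, nem.transitive_closure(truth.hierarchy))
        )

    t0 = time.perf_counter()
    census = patterns.count_patterns(results, significance_filter=config.fdr_cutoff)
    census.ranked().to_csv(out / "pattern_counts.tsv", sep="\t")
    overlaps = patterns.overlap_and_concordance(effects)
    dominance_calls = {
        f"{a}_vs_{b}": patterns.dominance(results, effects, a, b)
        for a, b in itertools.combinations(NODES, 2)
    }
    (out / "overlap_summary.json").write_text(
        json.dumps({"overlaps": overlaps, "dominance": dominance_calls}, indent=2)
    )
    for cls in (1, 2):
        patterns.top_pattern_genes(
            results, cls, fdr_cutoff=config.fdr_cutoff
        ).to_csv(out / f"top_pattern{cls}.tsv", sep="\t")
    _stage(manifest, "patterns", census_total=census.total,
           elapsed=round(time.perf_counter() - t0, 3))

    if config.gene_sets_path:
        t0 = time.perf_counter()
        gene_sets = enr.read_gmt(config.gene_sets_path)
        rows = []
        curves = []
        for gs in gene_sets:
            for contrast in COMBOS:
                res = enr.enrichment_curve(results.log2fc[contrast], gs)
                rows.append(dict(set=gs.name, contrast=contrast,
                                 p=res.p_value, m=res.m, n=res.n))
                curves.append(res.curve.assign(set=gs.name, contrast=contrast))
        pd.DataFrame(rows).to_csv(out / "enrichment.tsv", sep="\t", index=False)
        pd.concat(curves, ignore_index=True).to_csv(
            out / "enrichment_curves.tsv", sep="\t", index=False
        )
        _stage(manifest, "enrichment", n_sets=len(gene_sets),
               elapsed=round(time.perf_counter() - t0, 3))
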