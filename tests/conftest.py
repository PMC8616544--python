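import numpy as np
import pandas as pd
import pytest

import perturbnem as pn
from perturbnem.diffexp import ContrastResults
from perturbnem.io_and_design import COMBOS


@pytest.fixture(scope="session")
def truth_default():
    return pn.generate_truth(n_genes=1000, seed=42)


@pytest.fixture(scope="session")
def sim_data(truth_default):
    return pn.simulate_counts(truth_default)


@pytest.fixture(scope="session")
def screen(truth_default, sim_data):
    """Full diffexp + BUM run on the default synthetic screen."""
    counts, samples = sim_data
    design = pn.build_design(samples)
    keep = pn.expression_filter(counts)
    filtered = counts.loc[keep]
    norm = pn.normalization_factors(filtered)
    results = pn.fit_contrasts(filtered, design, norm)
    fit = pn.fit_bum(results.p_raw.to_numpy().ravel())
    R = pn.log_density(results, fit)
    return dict(truth=truth_default, counts=counts, samples=samples,
                design=design, norm=norm, results=results, bum=fit, R=R)


def make_results(log2fc: np.ndarray, fdr: np.ndarray | None = None,
                 p_raw: np.ndarray | None = None) -> ContrastResults:
    """Hand-build a ContrastResults from gene x 7 arrays."""
    log2fc = np.asarray(log2fc, dtype=float)
    genes = pd.Index([f"g{i}" for i in range(log2fc.shape[0])], name="gene_id")
    cols = list(COMBOS)
    if p_raw is None:
        p_raw = np.full_like(log2fc, 0.5)
    if fdr is None:
        fdr = p_raw.copy()
    return ContrastResults(
        log2fc=pd.DataFrame(log2fc, index=genes, columns=cols),
        p_raw=pd.DataFrame(p_raw, index=genes, columns=cols),
        fdr=pd.DataFrame(fdr, index=genes, columns=cols),
        dispersion=pd.Series(0.1, index=genes),
    )
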