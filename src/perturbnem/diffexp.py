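"""Negative-binomial differential expression over the seven treatment contrasts.

Each gene is modeled with a log-linear negative-binomial GLM over the nine
design coefficients (intercept, cell line, seven treatment-combination
indicators) with TMM library-size offsets.  Each of the seven contrasts is
tested with a likelihood-ratio test of the corresponding coefficient being
zero; p-values are Benjamini-Hochberg corrected per contrast and binarized
at 10% FDR.

The NB parameterization throughout is var = mu + dispersion * mu**2.
Dispersion is estimated per gene by profile maximum likelihood and shrunk
toward the common (pooled) dispersion with 20 prior degrees of freedom.
The IRLS solver is vectorized across genes (batched 9x9 normal-equation
solves), which keeps a 1,000-gene screen under a second per model fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .io_and_design import COMBOS

_ETA_CLIP = 30.0  # bound on the linear predictor minus offset, log scale


# ---------------------------------------------------------------------------
# Normalization (TMM)
# ---------------------------------------------------------------------------

@dataclass
class NormFactors:
    """Per-sample library sizes and TMM scaling factors.

    Factors have geometric mean 1; the GLM offset for a sample is
    ``log(lib_size * factor)``.
    """

    lib_size: pd.Series
    factors: pd.Series

    def __post_init__(self):
        if (self.factors <= 0).any():
            raise ValueError("scaling factors must be positive")

    @property
    def offset(self) -> pd.Series:
        return np.log(self.lib_size * self.factors)


def normalization_factors(
    counts: pd.DataFrame,
    logratio_trim: float = 0.3,
    abs_trim: float = 0.05,
) -> NormFactors:
    """Trimmed-mean-of-M-values scaling factors.

    The reference sample is the one whose 75th count-per-million percentile
    is closest to the mean over samples.  For each sample, log2 ratios (M)
    against the reference are doubly trimmed — `logratio_trim` on M and
    `abs_trim` on average log intensity (A) — and averaged with inverse
    asymptotic-variance weights.  Factors are rescaled to geometric mean 1.
    """
    if counts.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    y = counts.to_numpy(dtype=float)
    lib = y.sum(axis=0)
    if (lib == 0).any():
        bad = counts.columns[np.nonzero(lib == 0)[0][0]]
        raise ValueError(f"sample {bad!r} has zero total counts")
    cpm = y / lib * 1e6
    q75 = np.quantile(cpm, 0.75, axis=0)
    ref = int(np.argmin(np.abs(q75 - q75.mean())))
    yr, libr = y[:, ref], lib[ref]
    log_factors = np.zeros(counts.shape[1])
    for j in range(counts.shape[1]):
        if j == ref:
            continue
        yj, libj = y[:, j], lib[j]
        keep = (yj > 0) & (yr > 0)
        pj, pr = yj[keep] / libj, yr[keep] / libr
        m = np.log2(pj / pr)
        a = 0.5 * np.log2(pj * pr)
        w = (libj - yj[keep]) / (libj * yj[keep]) + (libr - yr[keep]) / (libr * yr[keep])
        # double trim: keep the central mass in both M and A ranks
        n = len(m)
        if n == 0:
            continue
        m_rank = m.argsort().argsort()
        a_rank = a.argsort().argsort()
        lo_m, hi_m = np.floor(n * logratio_trim) + 1, n - np.floor(n * logratio_trim)
        lo_a, hi_a = np.floor(n * abs_trim) + 1, n - np.floor(n * abs_trim)
        sel = (
            (m_rank + 1 >= lo_m) & (m_rank + 1 <= hi_m)
            & (a_rank + 1 >= lo_a) & (a_rank + 1 <= hi_a)
        )
        if sel.any():
            log_factors[j] = np.sum(m[sel] / w[sel]) / np.sum(1.0 / w[sel])
    factors = 2.0 ** log_factors
    factors /= np.exp(np.mean(np.log(factors)))
    cols = counts.columns
    return NormFactors(
        lib_size=pd.Series(lib, index=cols, name="lib_size"),
        factors=pd.Series(factors, index=cols, name="tmm_factor"),
    )


def expression_filter(
    counts: pd.DataFrame, min_cpm: float = 1.0, min_samples: int = 2
) -> pd.Series:
    """Keep genes with at least `min_cpm` counts-per-million in at least
    `min_samples` samples (guards against degenerate all-zero fits)."""
    cpm = counts.to_numpy(float) / counts.sum(axis=0).to_numpy() * 1e6
    keep = (cpm >= min_cpm).sum(axis=1) >= min_samples
    return pd.Series(keep, index=counts.index, name="keep")


# ---------------------------------------------------------------------------
# Batched NB GLM
# ---------------------------------------------------------------------------

def _nb_loglik(y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Row sums of the NB log likelihood; y, mu are (G, n), phi is (G,) or scalar."""
    r = 1.0 / np.atleast_1d(phi)[:, None]
    return (
        gammaln(y + r) - gammaln(r) - gammaln(y + 1.0)
        + r * np.log(r / (r + mu)) + y * np.log(mu / (r + mu) + 1e-300)
    ).sum(axis=1)


def _irls_nb(
    y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    phi: np.ndarray,
    max_iter: int = 60,
    tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Batched IRLS for NB log-linear models at fixed per-gene dispersion.

    y: (G, n) counts; X: (n, p) design; offset: (n,); phi: (G,) dispersions.
    Returns (beta (G, p), loglik (G,), converged (G,) bool).
    """
    G, n = y.shape
    p = X.shape[1]
    eta0 = np.log(y + 0.5) - offset
    beta = eta0 @ np.linalg.pinv(X).T
    ll = np.full(G, -np.inf)
    converged = np.zeros(G, dtype=bool)
    phi_col = np.atleast_1d(phi)[:, None]
    for _ in range(max_iter):
        eta = np.clip(beta @ X.T, -_ETA_CLIP, _ETA_CLIP)
        mu = np.exp(eta + offset)
        w = mu / (1.0 + phi_col * mu)
        z = eta + (y - mu) / mu
        xtwx = np.einsum("ni,gn,nj->gij", X, w, X, optimize=True)
        xtwz = np.einsum("ni,gn,gn->gi", X, w, z, optimize=True)
        xtwx += 1e-10 * np.eye(p)  # ridge jitter for unidentified corners
        beta = np.linalg.solve(xtwx, xtwz[..., None])[..., 0]
        eta = np.clip(beta @ X.T, -_ETA_CLIP, _ETA_CLIP)
        mu = np.exp(eta + offset)
        ll_new = _nb_loglik(y, mu, phi)
        delta = np.abs(ll_new - ll) / (np.abs(ll_new) + 1.0)
        converged = delta < tol
        ll = ll_new
        if converged.all():
            break
    return beta, ll, converged


def _profile_dispersion(
    y: np.ndarray,
    mu: np.ndarray,
    X: np.ndarray | None = None,
    grid: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Per-gene and pooled dispersion given fitted means, by grid profile
    with quadratic refinement on the log scale.

    When the design `X` is supplied, the Cox-Reid adjusted profile
    likelihood (ll - 0.5 * logdet(X'WX)) is used, which removes the
    downward bias of plain ML when the mean model has many coefficients.
    """
    if grid is None:
        grid = np.exp(np.linspace(np.log(1e-4), np.log(10.0), 61))
    curves = []
    for g in grid:
        ll = _nb_loglik(y, mu, np.full(y.shape[0], g))
        if X is not None:
            w = mu / (1.0 + g * mu)
            xtwx = np.einsum("ni,gn,nj->gij", X, w, X, optimize=True)
            ll = ll - 0.5 * np.linalg.slogdet(xtwx)[1]
        curves.append(ll)
    lls = np.stack(curves)  # (K, G)

    def refine(ll_curve: np.ndarray) -> float:
        k = int(np.argmax(ll_curve))
        if k == 0 or k == len(grid) - 1:
            return float(grid[k])
        x = np.log(grid[k - 1: k + 2])
        f = ll_curve[k - 1: k + 2]
        denom = (f[0] - 2 * f[1] + f[2])
        if denom >= 0:
            return float(grid[k])
        shift = 0.5 * (f[0] - f[2]) / denom
        return float(np.exp(x[1] + shift * (x[1] - x[0])))

    genewise = np.array([refine(lls[:, g]) for g in range(y.shape[0])])
    common = refine(lls.sum(axis=1))
    return genewise, common


# ---------------------------------------------------------------------------
# Contrast fitting
# ---------------------------------------------------------------------------

@dataclass
class ContrastResults:
    """Per gene x contrast estimates: log2 fold change, raw likelihood-ratio
    p-value, BH-adjusted FDR; per gene the shrunk dispersion estimate."""

    log2fc: pd.DataFrame
    p_raw: pd.DataFrame
    fdr: pd.DataFrame
    dispersion: pd.Series
    n_nonconverged: int = 0

    @property
    def genes(self) -> pd.Index:
        return self.log2fc.index

    def to_long(self) -> pd.DataFrame:
        """One row per gene x contrast (TSV-friendly)."""
        rows = []
        for c in self.log2fc.columns:
            rows.append(pd.DataFrame({
                "gene": self.log2fc.index,
                "contrast": c,
                "log2fc": self.log2fc[c].to_numpy(),
                "p_raw": self.p_raw[c].to_numpy(),
                "fdr": self.fdr[c].to_numpy(),
            }))
        return pd.concat(rows, ignore_index=True)


def bh_adjust(p_raw: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR values (monotone, in [0, 1])."""
    p = np.asarray(p_raw, dtype=float)
    if np.isnan(p).any():
        raise ValueError("NaN p-values are not allowed")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fit_contrasts(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    norm: NormFactors,
    prior_df: float = 20.0,
) -> ContrastResults:
    """Fit the 9-coefficient NB model per gene and LR-test the 7 contrasts.

    Genes should be pre-filtered with :func:`expression_filter`.  Dispersion
    is profiled per gene at the full-model fit and shrunk toward the pooled
    estimate on the log scale with `prior_df` prior degrees of freedom
    against the residual degrees of freedom.  Genes whose full-model fit
    fails to converge are dropped and counted in ``n_nonconverged``.
    """
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise ValueError("design matrix is rank deficient")
    X = design.to_numpy(dtype=float)
    y = counts.loc[:, design.index].to_numpy(dtype=float)
    offset = norm.offset.loc[design.index].to_numpy()
    G, n = y.shape

    # Pass 1: moderate-dispersion fit to get means for dispersion profiling.
    beta0, _, _ = _irls_nb(y, X, offset, np.full(G, 0.1))
    mu0 = np.exp(np.clip(beta0 @ X.T, -_ETA_CLIP, _ETA_CLIP) + offset)
    genewise, common = _profile_dispersion(y, mu0, X=X)
    df_resid = max(n - X.shape[1], 1)
    phi = np.exp(
        (prior_df * np.log(common) + df_resid * np.log(genewise))
        / (prior_df + df_resid)
    )

    # Pass 2: full model and the 7 single-coefficient-dropped models.
    beta, ll_full, ok = _irls_nb(y, X, offset, phi)
    contrast_cols = [design.columns.get_loc(c) for c in COMBOS]
    log2fc = np.empty((G, len(COMBOS)))
    p_raw = np.empty((G, len(COMBOS)))
    for k, j in enumerate(contrast_cols):
        keep_cols = [c for c in range(X.shape[1]) if c != j]
        _, ll_red, ok_red = _irls_nb(y, X[:, keep_cols], offset, phi)
        ok &= ok_red
        stat = np.maximum(2.0 * (ll_full - ll_red), 0.0)
        p_raw[:, k] = chi2.sf(stat, df=1)
        log2fc[:, k] = beta[:, j] / np.log(2.0)

    finite = np.isfinite(log2fc).all(axis=1) & np.isfinite(p_raw).all(axis=1)
    keep = ok & finite
    n_dropped = int((~keep).sum())
    idx = counts.index[keep]
    fdr = np.column_stack([bh_adjust(p_raw[keep, k]) for k in range(len(COMBOS))])
    return ContrastResults(
        log2fc=pd.DataFrame(log2fc[keep], index=idx, columns=list(COMBOS)),
        p_raw=pd.DataFrame(p_raw[keep], index=idx, columns=list(COMBOS)),
        fdr=pd.DataFrame(fdr, index=idx, columns=list(COMBOS)),
        dispersion=pd.Series(phi[keep], index=idx, name="dispersion"),
        n_nonconverged=n_dropped,
    )


# ---------------------------------------------------------------------------
# Binarization and PCA input
# ---------------------------------------------------------------------------

@dataclass
class BinaryEffects:
    """Gene x contrast significance calls at an FDR cutoff, with the sign
    of the fold change recorded for significant entries (0 otherwise)."""

    significant: pd.DataFrame
    sign: pd.DataFrame
    cutoff: float


def binarize_effects(results: ContrastResults, cutoff: float = 0.10) -> BinaryEffects:
    """Binarize BH-corrected p-values: significant iff fdr <= cutoff."""
    sig = results.fdr <= cutoff
    sign = np.sign(results.log2fc).astype(int).where(sig, 0)
    return BinaryEffects(significant=sig, sign=sign, cutoff=cutoff)


def pca_input(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    remove_cell_line: bool = False,
) -> pd.DataFrame:
    """Samples x genes log(x+1) matrix for PCA, optionally with the
    cell-line effect regressed out per gene (least squares on the line
    indicator, fitted line effect subtracted)."""
    logx = np.log(counts.to_numpy(dtype=float) + 1.0).T  # samples x genes
    order = counts.columns
    if remove_cell_line:
        meta = samples.set_index("sample_id").loc[order]
        lines = sorted(meta["cell_line"].unique())
        if len(lines) == 2:
            L = (meta["cell_line"] == lines[1]).to_numpy(dtype=float)
            Z = np.column_stack([np.ones_like(L), L])
            coef, *_ = np.linalg.lstsq(Z, logx, rcond=None)
            logx = logx - np.outer(L, coef[1])
    return pd.DataFrame(logx, index=order, columns=counts.index)
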