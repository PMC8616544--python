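"""Beta-uniform mixture (BUM) model for p-value distributions.

A screen's raw p-values are modeled as a two-component mixture

    f(p) = lambda + (1 - lambda) * a * p**(a - 1),      0 < p <= 1,

with the uniform component (weight lambda) absorbing true nulls and a
decreasing Beta(a, 1) component (0 < a <= 1) absorbing signals.  The log
density of the beta component,

    R(p) = log(a) + (a - 1) * log(p),

is the log likelihood-ratio of "effect" against the unit-uniform null and
is the per-gene, per-contrast data input of the nested-effects model:
R > 0 flags an affected gene (small p), R < 0 an unaffected one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

P_EPS = 1e-10  # clamp floor: p**(a-1) diverges at 0


@dataclass
class BumFit:
    """Fitted mixture: uniform weight `lam`, beta shape `a`, log-likelihood."""

    lam: float
    a: float
    loglik: float

    def density(self, p: np.ndarray) -> np.ndarray:
        """Mixture density f(p) (integrates to 1 on (0, 1]; the pole at 0
        is integrable and left unclamped)."""
        p = np.clip(np.asarray(p, dtype=float), np.finfo(float).tiny, 1.0)
        return self.lam + (1.0 - self.lam) * self.a * p ** (self.a - 1.0)

    def beta_log_density(self, p: np.ndarray) -> np.ndarray:
        p = np.clip(np.asarray(p, dtype=float), P_EPS, 1.0)
        return np.log(self.a) + (self.a - 1.0) * np.log(p)


def simulate_bum(
    n: int, lam: float = 0.6, a: float = 0.3, seed: int = 0
) -> np.ndarray:
    """Draw p-values from the mixture (uniform w.p. lam, Beta(a,1) otherwise)."""
    rng = np.random.default_rng(seed)
    from_null = rng.random(n) < lam
    p = np.where(from_null, rng.random(n), rng.random(n) ** (1.0 / a))
    return p


def fit_bum(p_raw: np.ndarray) -> BumFit:
    """Maximum-likelihood fit of (lambda, a) by bounded optimization.

    P-values are clamped to [1e-10, 1].  Multiple deterministic starting
    points guard against the flat-likelihood corner at a -> 1; the best
    iterate is kept.  Raises if no start converges.
    """
    p = np.clip(np.asarray(p_raw, dtype=float), P_EPS, 1.0)
    if p.ndim != 1:
        p = p.ravel()
    logp = np.log(p)

    def nll(theta):
        lam, a = theta
        dens = lam + (1.0 - lam) * a * np.exp((a - 1.0) * logp)
        return -np.sum(np.log(np.maximum(dens, 1e-300)))

    bounds = [(1e-6, 1.0 - 1e-9), (1e-6, 1.0)]
    best = None
    errors = []
    for start in [(0.5, 0.5), (0.8, 0.2), (0.2, 0.8), (0.95, 0.5)]:
        res = minimize(nll, start, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
        if not res.success:
            errors.append(res.message)
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError(f"BUM optimization failed: {errors}; best={best}")
    lam, a = best.x
    return BumFit(lam=float(lam), a=float(a), loglik=float(-best.fun))


def log_density(results, fit: BumFit, use_mixture: bool = False) -> pd.DataFrame:
    """Genes x 7 contrasts log-density matrix R feeding the NEM.

    By default R is the log density of the beta component evaluated at the
    clamped raw p-value; with ``use_mixture=True`` the full mixture density
    is used instead.  R is finite everywhere and strictly decreasing in p
    for a < 1.
    """
    p = results.p_raw if hasattr(results, "p_raw") else results
    values = np.clip(p.to_numpy(dtype=float), P_EPS, 1.0)
    if use_mixture:
        r = np.log(fit.density(values))
    else:
        r = fit.beta_log_density(values)
    return pd.DataFrame(r, index=p.index, columns=p.columns)
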