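"""Monte Carlo simulation of the noisy encoding circuit.

Draw order is fixed and documented for bit-reproducibility: stimulus, then
upstream noise (jointly across pathways), then the stochastic response
stage per pathway, then downstream noise (jointly across pathways). A
single ``numpy.random.Generator`` seeded from ``seed`` produces all draws.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .model import CircuitParams, Nonlinearity, PoissonVariant

__all__ = ["DrawSet", "simulate", "conditional_moments"]


@dataclass
class DrawSet:
    """One batch of Monte Carlo draws through the circuit.

    Arrays have shape (n,) for the stimulus and (n_pathways, n) for the
    per-pathway quantities; ``r = stage + zeta`` elementwise.
    """

    s: np.ndarray
    eta: np.ndarray
    stage: np.ndarray  # stochastic response-stage output (kappa*m etc.)
    zeta: np.ndarray
    r: np.ndarray
    seed: int
    n: int
    params: CircuitParams

    def to_csv(self, path: str | Path) -> None:
        cols = {"s": self.s}
        for i in range(self.params.n_pathways):
            cols[f"eta_{i + 1}"] = self.eta[i]
            cols[f"stage_{i + 1}"] = self.stage[i]
            cols[f"zeta_{i + 1}"] = self.zeta[i]
            cols[f"r_{i + 1}"] = self.r[i]
        pd.DataFrame(cols).to_csv(path, index=False)
        sidecar = Path(path).with_suffix(".json")
        sidecar.write_text(
            json.dumps({"params": self.params.to_dict(), "seed": self.seed, "n": self.n}, indent=2)
        )


def _correlated_pair(rng: np.random.Generator, sigma: float, rho: float, n: int) -> np.ndarray:
    """Two zero-mean Gaussian rows with common s.d. and correlation rho."""
    if sigma == 0.0:
        return np.zeros((2, n))
    cov = sigma**2 * np.array([[1.0, rho], [rho, 1.0]])
    # Cholesky with a tiny jitter-free fallback at |rho| = 1
    if abs(rho) == 1.0:
        a = rng.standard_normal(n)
        return sigma * np.vstack([a, np.sign(rho) * a])
    L = np.linalg.cholesky(cov)
    return L @ rng.standard_normal((2, n))


def _stage_draw(
    rng: np.random.Generator, p: CircuitParams, fvals: np.ndarray
) -> np.ndarray:
    """Stochastic response stage: conditional mean f, variant-specific variance."""
    if p.poisson_variant is PoissonVariant.scaled_poisson:
        if p.kappa == 0.0:
            return fvals.copy()
        return p.kappa * rng.poisson(fvals / p.kappa)
    if p.poisson_variant is PoissonVariant.multiplicative_gaussian:
        # additive Gaussian output noise with variance kappa * f; not clipped
        return fvals + np.sqrt(p.kappa * fvals) * rng.standard_normal(fvals.shape)
    # binomial: count / N, mean f, variance f (1 - f) / N
    return rng.binomial(p.binomial_n, fvals) / p.binomial_n


def simulate(
    p: CircuitParams,
    f: Nonlinearity | tuple[Nonlinearity, Nonlinearity],
    n: int,
    seed: int,
) -> DrawSet:
    """Draw ``n`` samples of (s, eta, stage output, zeta, r).

    For two pathways ``f`` is a pair; upstream and downstream noises are
    bivariate Gaussian with correlations rho_up, rho_down, and the stage
    draws are conditionally independent across pathways given the inputs.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    fs = (f,) if isinstance(f, Nonlinearity) else tuple(f)
    if len(fs) != p.n_pathways:
        raise ValueError(f"expected {p.n_pathways} nonlinearities, got {len(fs)}")
    rng = np.random.default_rng(seed)
    s = p.sigma_s * rng.standard_normal(n)
    if p.n_pathways == 1:
        eta = p.sigma_up * rng.standard_normal((1, n))
    else:
        eta = _correlated_pair(rng, p.sigma_up, p.rho_up, n)
    stage = np.vstack([_stage_draw(rng, p, np.asarray(fi(s + eta[i]))) for i, fi in enumerate(fs)])
    if p.n_pathways == 1:
        zeta = p.sigma_down * rng.standard_normal((1, n))
    else:
        zeta = _correlated_pair(rng, p.sigma_down, p.rho_down, n)
    return DrawSet(s=s, eta=eta, stage=stage, zeta=zeta, r=stage + zeta, seed=seed, n=n, params=p)


def conditional_moments(
    p: CircuitParams, f: Nonlinearity, z: float | np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Mean and variance of the response r given total input s + eta = z.

    Conditional mean is f(z) for every variant; the conditional variance is
    kappa*f(z) (scaled Poisson and multiplicative Gaussian) or
    f(z)(1-f(z))/N (binomial), plus the downstream variance.
    """
    fz = np.asarray(f(z), dtype=float)
    if p.poisson_variant is PoissonVariant.binomial:
        stage_var = fz * (1.0 - fz) / p.binomial_n
    else:
        stage_var = p.kappa * fz
    return fz, stage_var + p.sigma_down**2
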