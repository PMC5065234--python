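"""Parametric optimisation of logistic nonlinearities by exhaustive sweep.

Mirrors the simulation route to the optimum: parametrise the nonlinearity
as a two-parameter logistic f(z) = 1 / (1 + exp(-nu (z - phi))), simulate
the circuit over a (nu, phi) grid, fit the optimal linear readout per grid
point, and keep the arg-optimum under either the MSE or the MI criterion.
Common random numbers (one shared seed across grid points) sharpen the
comparison between neighbouring grid points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .info import mutual_information
from .metrics import mse, mse_monte_carlo
from .model import CircuitParams, Nonlinearity

__all__ = ["SweepResult", "sweep", "suboptimality_gap", "default_nu_grid", "default_phi_grid"]


def default_nu_grid(p: CircuitParams, n: int = 25) -> np.ndarray:
    """Log-spaced slopes bracketing the rescaled-unit range, in raw units."""
    return np.geomspace(0.2, 50.0, n) / p.input_scale


def default_phi_grid(p: CircuitParams, n: int = 25) -> np.ndarray:
    """Linear offsets over +-3 rescaled units, in raw units."""
    return np.linspace(-3.0, 3.0, n) * p.input_scale


@dataclass
class SweepResult:
    """Scores over the (nu, phi) grid and the identified optimum."""

    table: pd.DataFrame  # columns nu, phi, score, score_sem
    objective: str
    best: Nonlinearity
    best_score: float
    near_optimal: pd.DataFrame  # grid points within 1% of the optimum

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def sweep(
    p: CircuitParams,
    objective: str = "mse",
    nu_grid: np.ndarray | None = None,
    phi_grid: np.ndarray | None = None,
    n_draws: int = 200_000,
    n_reps: int = 3,
    seed: int = 0,
    mi_settings: dict | None = None,
) -> SweepResult:
    """Score every (nu, phi) combination and return the arg-optimum.

    MSE scores use Monte Carlo simulation with least-squares-fitted
    decoding weights; MI scores use the entropy-difference estimator with
    automatic binless/binned selection. The near-optimal set collects grid
    points scoring within 1% of the optimum — with substantial upstream
    noise this set is typically broad (many shapes perform almost equally).
    """
    if p.n_pathways != 1:
        raise ValueError("the sweep optimises one pathway; pair sweeps go through phase tools")
    if objective not in ("mse", "mi"):
        raise ValueError("objective must be 'mse' or 'mi'")
    nu_grid = default_nu_grid(p) if nu_grid is None else np.asarray(nu_grid, dtype=float)
    phi_grid = default_phi_grid(p) if phi_grid is None else np.asarray(phi_grid, dtype=float)
    if nu_grid.size == 0 or phi_grid.size == 0:
        raise ValueError("grids must be non-empty")
    rows = []
    for nu in nu_grid:
        for phi in phi_grid:
            f = Nonlinearity.logistic(nu=nu, phi=phi)
            if objective == "mse":
                score, sem = mse_monte_carlo(p, f, D=None, n=n_draws, n_reps=n_reps, seed=seed)
            else:
                score, sem = mutual_information(
                    p, f, seed=seed, **(mi_settings or {"n_stimuli": 5000, "n_repeats": 2000, "n_reps": 3})
                )
            rows.append({"nu": nu, "phi": phi, "score": score, "score_sem": sem})
    table = pd.DataFrame(rows)
    idx = table.score.idxmin() if objective == "mse" else table.score.idxmax()
    best_row = table.loc[idx]
    if objective == "mse":
        near = table[table.score <= best_row.score * 1.01]
    else:
        near = table[table.score >= best_row.score * 0.99]
    return SweepResult(
        table=table,
        objective=objective,
        best=Nonlinearity.logistic(nu=float(best_row.nu), phi=float(best_row.phi)),
        best_score=float(best_row.score),
        near_optimal=near.reset_index(drop=True),
    )


def suboptimality_gap(
    p: CircuitParams,
    f_candidate: Nonlinearity,
    f_reference: Nonlinearity,
) -> float:
    """Percent excess closed-form MSE of a candidate over a reference:
    100 (chi2_cand - chi2_ref) / chi2_ref, each at its own optimal weights."""
    return 100.0 * (mse(p, f_candidate) - mse(p, f_reference)) / mse(p, f_reference)
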