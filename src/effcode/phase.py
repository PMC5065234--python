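"""Strategy maps over noise-parameter space.

For two pathways the rescaled optimum depends only on (rho_eff, kappa,
sigma_down, rho_down). This module grids that space, solves both polarity
classes per cell (ON-OFF vs ON-ON), and records which wins and by how much
— the phase-map picture in which positively correlated downstream noise
favours ON-OFF pairs and negatively correlated downstream noise favours
ON-ON pairs. It also locates the equal-MSE polarity boundary in rho_down
by bisection and the threshold-splitting onset of non-identical ON-ON
pairs as rho_eff approaches 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dual import DualSolution, multi_seed_solve, picard_solve
from .model import CircuitParams, Nonlinearity, rho_up_for_effective

__all__ = [
    "PhaseMapCell",
    "phase_map",
    "phase_map_table",
    "polarity_boundary",
    "splitting_threshold",
    "sweep_trends",
    "shape_summary",
]


def _params(
    rho_eff: float,
    kappa: float,
    sigma_down: float,
    rho_down: float,
    sigma_s: float = 1.0,
    sigma_up: float = 2.0,
) -> CircuitParams:
    return CircuitParams(
        sigma_s=sigma_s,
        sigma_up=sigma_up,
        kappa=kappa,
        sigma_down=sigma_down,
        rho_up=rho_up_for_effective(rho_eff, sigma_s, sigma_up),
        rho_down=rho_down,
        n_pathways=2,
    )


@dataclass
class PhaseMapCell:
    """One grid point of the strategy map."""

    rho_eff: float
    kappa: float
    sigma_down: float
    rho_down: float
    sigma_s: float
    sigma_up: float
    best_mixed: DualSolution | None  # best ON-OFF / OFF-ON
    best_same: DualSolution | None  # best ON-ON (identical or split)
    winner: str
    pct_diff: float  # 100 (MSE_other - MSE_winner) / MSE_other
    converged: bool

    def pct_diff_at(self, sigma_s: float, sigma_up: float) -> float:
        """Percent MSE difference when the same rho_eff is realised with a
        different (sigma_s, sigma_up); the winner never changes, only the
        margin does."""
        if not self.converged:
            return float("nan")
        ms = [s.mse_at(sigma_s, sigma_up) for s in (self.best_mixed, self.best_same)]
        lo, hi = min(ms), max(ms)
        return 100.0 * (hi - lo) / hi


def _solve_cell(
    p: CircuitParams, n_seeds: int, seed: int, max_iter: int
) -> tuple[DualSolution | None, DualSolution | None]:
    res = multi_seed_solve(p, n_seeds=n_seeds, seed=seed, max_iter=max_iter)
    return res.best_of_polarity("mixed"), res.best_of_polarity("same")


def phase_map(
    rho_eff_grid=(0.0, 0.25, 0.5, 0.75, 1.0),
    kappa_grid=(0.0, 0.25, 0.5, 0.75, 1.0),
    sigma_down_grid=(0.1, 0.25, 0.5, 0.75, 1.0),
    rho_down_grid=(-1.0, -0.75, -0.5, -0.25, 0.0, 0.25, 0.5, 0.75, 1.0),
    sigma_s: float = 1.0,
    sigma_up: float = 2.0,
    n_seeds: int = 3,
    seed: int = 0,
    max_iter: int = 2000,
) -> list[PhaseMapCell]:
    """Solve both polarity classes on a parameter grid.

    Defaults reproduce the full sweep grids; pass shorter grids for a
    reduced preset. Cells where either class fails to converge are flagged
    and carry NaN percent differences.
    """
    cells: list[PhaseMapCell] = []
    for re in rho_eff_grid:
        for k in kappa_grid:
            for sd in sigma_down_grid:
                for rd in rho_down_grid:
                    p = _params(re, k, sd, rd, sigma_s, sigma_up)
                    mixed, same = _solve_cell(p, n_seeds, seed, max_iter)
                    ok = mixed is not None and same is not None
                    if ok:
                        if mixed.mse <= same.mse:
                            winner, pct = mixed.strategy, 100.0 * (same.mse - mixed.mse) / same.mse
                        else:
                            winner, pct = same.strategy, 100.0 * (mixed.mse - same.mse) / mixed.mse
                    else:
                        winner, pct = "unconverged", float("nan")
                    cells.append(
                        PhaseMapCell(
                            rho_eff=re,
                            kappa=k,
                            sigma_down=sd,
                            rho_down=rd,
                            sigma_s=sigma_s,
                            sigma_up=sigma_up,
                            best_mixed=mixed,
                            best_same=same,
                            winner=winner,
                            pct_diff=pct,
                            converged=ok,
                        )
                    )
    return cells


def phase_map_table(cells: list[PhaseMapCell]) -> pd.DataFrame:
    """Long-format table of a phase map (one row per cell)."""
    rows = []
    for c in cells:
        rows.append(
            {
                "rho_eff": c.rho_eff,
                "kappa": c.kappa,
                "sigma_down": c.sigma_down,
                "rho_down": c.rho_down,
                "sigma_s": c.sigma_s,
                "sigma_up": c.sigma_up,
                "winner": c.winner,
                "pct_diff": c.pct_diff,
                "mse_mixed": c.best_mixed.mse if c.best_mixed else np.nan,
                "mse_same": c.best_same.mse if c.best_same else np.nan,
                "converged": c.converged,
            }
        )
    return pd.DataFrame(rows)


def polarity_boundary(
    kappa: float,
    sigma_down: float,
    rho_eff: float = 0.5,
    sigma_s: float = 1.0,
    sigma_up: float = 2.0,
    n_seeds: int = 2,
    seed: int = 0,
    lo: float = -0.6,
    hi: float = 0.6,
    resolution: float = 0.01,
    max_iter: int = 2000,
) -> float:
    """rho_down at which best ON-OFF and best ON-ON MSE cross, by bisection.

    The bracketing interval must straddle the sign change of
    MSE(ON-OFF) - MSE(ON-ON); positive rho_down favours ON-OFF.
    """

    def gap(rd: float) -> float:
        p = _params(rho_eff, kappa, sigma_down, rd, sigma_s, sigma_up)
        mixed, same = _solve_cell(p, n_seeds, seed, max_iter)
        if mixed is None or same is None:
            raise RuntimeError(f"solver failed at rho_down={rd}")
        return mixed.mse - same.mse

    g_lo, g_hi = gap(lo), gap(hi)
    if g_lo * g_hi > 0:
        raise ValueError("bracket does not straddle the polarity boundary")
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        g_mid = gap(mid)
        if g_mid == 0.0:
            return mid
        if g_lo * g_mid < 0:
            hi, g_hi = mid, g_mid
        else:
            lo, g_lo = mid, g_mid
    return 0.5 * (lo + hi)


def _onon_solution(
    p: CircuitParams, seed: int, max_iter: int, n_retries: int = 5
) -> DualSolution | None:
    """A converged same-polarity solution, retrying seeds on basin swaps."""
    for k in range(n_retries):
        s = picard_solve(p, init_class="on_on", seed=seed + 101 * k, max_iter=max_iter)
        if s.converged and s.strategy in ("ON_ON_identical", "ON_ON_split", "OFF_OFF"):
            return s
    return None


def splitting_threshold(
    kappa: float,
    sigma_down: float,
    rho_down: float = 0.0,
    resolution: float = 0.01,
    lo: float = 0.8,
    hi: float = 1.0,
    sigma_s: float = 1.0,
    sigma_up: float = 2.0,
    seed: int = 0,
    max_iter: int = 2000,
) -> tuple[float, bool]:
    """Smallest rho_eff with a non-identical (split) ON-ON optimum.

    Bisects on the identical/split classification over [lo, hi] (the onset
    is a sharp transition in rho_eff). Returns (threshold, found); if no
    split exists below rho_eff = 1 the threshold is 1.0 with found=False.
    A single seed per point follows the fine-scan practice; basin swaps to
    ON-OFF are retried with fresh seeds.
    """

    def is_split(re: float) -> bool:
        s = _onon_solution(_params(re, kappa, sigma_down, rho_down, sigma_s, sigma_up), seed, max_iter)
        if s is None:
            raise RuntimeError(f"no ON-ON solution at rho_eff={re}")
        return s.strategy == "ON_ON_split"

    if not is_split(hi):
        return 1.0, False
    if is_split(lo):
        return lo, True
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        if is_split(mid):
            hi = mid
        else:
            lo = mid
    return hi, True


def shape_summary(f: Nonlinearity, grid: np.ndarray | None = None) -> dict:
    """Slope, offset and base (threshold) of a monotone nonlinearity.

    Measured from quantile crossings of the tabulated curve: slope =
    0.5 / (x_{0.75} - x_{0.25}), offset = x at f = 0.5, base = x at
    f = 0.05 (ON) or 0.95 (OFF, measured on the mirrored curve).
    """
    if grid is None:
        from .model import X_GRID

        grid = X_GRID
    vals = np.asarray(f(grid), dtype=float)
    increasing = vals[-1] >= vals[0]
    v = vals if increasing else vals[::-1]
    x = grid if increasing else -grid[::-1]

    def crossing(q: float) -> float:
        idx = np.searchsorted(v, q)
        if idx == 0 or idx >= v.size:
            return float("nan")
        x0, x1_, v0, v1_ = x[idx - 1], x[idx], v[idx - 1], v[idx]
        return float(x0 + (q - v0) / (v1_ - v0) * (x1_ - x0)) if v1_ > v0 else float(x0)

    q25, q50, q75, q05 = (crossing(q) for q in (0.25, 0.5, 0.75, 0.05))
    slope = 0.5 / (q75 - q25) if q75 > q25 else float("inf")
    return {
        "slope": slope if increasing else -slope,
        "offset": q50 if increasing else -q50,
        "base": q05 if increasing else -q05,
        "polarity": "ON" if increasing else "OFF",
    }


def sweep_trends(
    axis: str,
    values,
    fixed: dict,
    sigma_s: float = 1.0,
    sigma_up: float = 2.0,
    n_seeds: int = 2,
    seed: int = 0,
    max_iter: int = 2000,
) -> pd.DataFrame:
    """Rescaled slope/offset traces of both polarity classes along one axis.

    ``axis`` is one of 'rho_eff', 'kappa', 'sigma_down' (with the other
    two plus 'rho_down' supplied in ``fixed``). One row per (grid value,
    class, pathway).
    """
    if axis not in ("rho_eff", "kappa", "sigma_down"):
        raise ValueError("axis must be rho_eff, kappa or sigma_down")
    rows = []
    for v in values:
        kw = dict(fixed)
        kw[axis] = v
        p = _params(kw["rho_eff"], kw["kappa"], kw["sigma_down"], kw["rho_down"], sigma_s, sigma_up)
        mixed, same = _solve_cell(p, n_seeds, seed, max_iter)
        for label, sol in (("mixed", mixed), ("same", same)):
            if sol is None:
                continue
            for i, fi in enumerate((sol.f1, sol.f2), start=1):
                sh = shape_summary(fi)
                rows.append(
                    {
                        axis: v,
                        "class": label,
                        "strategy": sol.strategy,
                        "pathway": i,
                        "slope": sh["slope"],
                        "offset": sh["offset"],
                        "base": sh["base"],
                        "mse": sol.mse,
                    }
                )
    return pd.DataFrame(rows)
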