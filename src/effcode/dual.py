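"""Coupled two-pathway optimal nonlinearities by Picard fixed-point iteration.

In rescaled coordinates the optimal pair (f~1, f~2) and rescaled weights
(D~1, D~2) satisfy

    [A1 C; C A2] [D~1; D~2] = [<y f~1>; <y f~2>],
        A_i = kappa <f~i> + var f~i + sigma_down^2,
        C   = cov[f~1, f~2] + sigma_down^2 rho_down,
    f~1(x) = clip( x/D~1 - kappa/2 + <f~1>
                   + (D~2/D~1) (<f~2> - K2(x)) , 0, 1),   (and 1 <-> 2)
    K2(x) = Int dy N(y; 0,1) f~2(sqrt(1-rho_eff^2) y + rho_eff x),

which depend on the circuit only through (rho_eff, kappa, sigma_down,
rho_down). The solver iterates these maps from randomised initial guesses
until every weight and every grid value changes by less than an absolute
tolerance (default 1e-4). ON-OFF solutions are reached from opposite-sign
weight guesses, ON-ON from same-sign guesses; multiple seeds guard against
the rare basin swap.

The kernel's change of variables keeps the iteration stable as
rho_eff -> 1, where K2 collapses to f~2(x) itself and the fixed points
become piecewise linear.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.interpolate import CubicSpline

from .metrics import QUAD_NODES, QUAD_WEIGHTS
from .model import CircuitParams, Nonlinearity, X_GRID, effective_correlation

__all__ = [
    "DualSolution",
    "picard_solve",
    "multi_seed_solve",
    "classify_solution",
    "fixed_point_residual",
]

STRATEGIES = ("ON_OFF", "ON_ON_identical", "ON_ON_split", "OFF_OFF", "OFF_ON")


@dataclass
class DualSolution:
    """A converged (or flagged) fixed point of the coupled equations.

    Nonlinearities are tabulated on the rescaled grid; ``score`` is the
    sigma-independent quantity T = D~1 <y f~1> + D~2 <y f~2> from which the
    MSE at any (sigma_s, sigma_up) realisation of rho_eff follows as
    chi^2 = sigma_s^2 (1 - T sigma_s^2 / (sigma_s^2 + sigma_up^2)).
    """

    f1: Nonlinearity
    f2: Nonlinearity
    Dt1: float
    Dt2: float
    score: float
    mse: float
    strategy: str
    n_iterations: int
    converged: bool
    seed: int
    rho_eff: float
    params: CircuitParams
    change_trace: np.ndarray = field(repr=False, default=None)

    @property
    def D(self) -> tuple[float, float]:
        """Raw-coordinate decoding weights."""
        s = self.params.sigma_s**2 / self.params.input_scale
        return (s * self.Dt1, s * self.Dt2)

    def mse_at(self, sigma_s: float, sigma_up: float) -> float:
        """MSE of this rescaled solution under another (sigma_s, sigma_up)
        realisation of the same rho_eff."""
        frac = sigma_s**2 / (sigma_s**2 + sigma_up**2)
        return sigma_s**2 * (1.0 - frac * self.score)

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "rho_eff": self.rho_eff,
            "Dt1": self.Dt1,
            "Dt2": self.Dt2,
            "score": self.score,
            "mse": self.mse,
            "strategy": self.strategy,
            "n_iterations": self.n_iterations,
            "converged": self.converged,
            "seed": self.seed,
            "f1": self.f1.to_dict(),
            "f2": self.f2.to_dict(),
        }


def _eval_clipped(grid_f: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Cubic-spline evaluation of a tabulated nonlinearity with boundary
    hold outside the grid and output clipped to [0, 1]."""
    sp = CubicSpline(X_GRID, grid_f, extrapolate=False)
    out = sp(pts)
    out = np.where(pts < X_GRID[0], grid_f[0], out)
    out = np.where(pts > X_GRID[-1], grid_f[-1], out)
    return np.clip(out, 0.0, 1.0)


def _signed_gaussian(rng: np.random.Generator, centre: float) -> float:
    """N(centre, 0.5^2) draw, resampled until it shares centre's sign."""
    for _ in range(100):
        d = rng.normal(centre, 0.5)
        if d * centre > 0:
            return d
    return centre


def picard_solve(
    p: CircuitParams,
    init_class: str = "on_off",
    seed: int = 0,
    tol: float = 1e-4,
    max_iter: int = 2000,
    relax: float = 1.0,
    init: tuple[np.ndarray, np.ndarray, float, float] | None = None,
) -> DualSolution:
    """Iterate the coupled fixed-point maps from one randomised start.

    Parameters
    ----------
    init_class : {"on_off", "on_on"}
        Sign pattern of the initial weight guess (D1 > 0 > D2, or both > 0).
    seed : int
        Seed for the initial guess (weights ~ N(+-1, 0.5^2) with the class
        sign enforced; nonlinearity guesses clip(x/D - kappa/2 + U[0,1])
        per grid point).
    tol : float
        Absolute convergence tolerance on every weight and grid value.
    relax : float
        Under-relaxation factor in (0, 1] for stiff corners (rho_eff -> 1
        with little noise); 1.0 is plain Picard iteration. When plain
        iteration stalls in a cycle (change norm not shrinking over 50
        iterations) the solver drops to 0.5 automatically.
    init : optional warm start (f1 grid, f2 grid, Dt1, Dt2) overriding the
        randomised guess.
    """
    if p.n_pathways != 2:
        raise ValueError("picard_solve requires a two-pathway circuit")
    rho = effective_correlation(p)
    kappa, vdown, rdown = p.kappa, p.sigma_down**2, p.rho_down
    y, wq = QUAD_NODES, QUAD_WEIGHTS
    root1m = np.sqrt(max(0.0, 1.0 - rho * rho))
    # kernel evaluation points are fixed across iterations
    pts_grid = root1m * y[None, :] + rho * X_GRID[:, None]  # (241, 200)
    pts_quad = root1m * y[None, :] + rho * y[:, None]  # (200, 200)

    rng = np.random.default_rng(seed)
    if init is not None:
        f1g, f2g, Dt1, Dt2 = np.array(init[0]), np.array(init[1]), init[2], init[3]
    else:
        Dt1 = _signed_gaussian(rng, 1.0)
        Dt2 = _signed_gaussian(rng, -1.0 if init_class == "on_off" else 1.0)
        u1 = rng.uniform(size=X_GRID.size)
        u2 = rng.uniform(size=X_GRID.size)
        f1g = np.clip(X_GRID / Dt1 - kappa / 2.0 + u1, 0.0, 1.0)
        f2g = np.clip(X_GRID / Dt2 - kappa / 2.0 + u2, 0.0, 1.0)

    trace = np.empty(max_iter)
    converged = False
    n_it = 0
    for n_it in range(1, max_iter + 1):
        f1q = _eval_clipped(f1g, y)
        f2q = _eval_clipped(f2g, y)
        m1, m2 = float(wq @ f1q), float(wq @ f2q)
        yf1, yf2 = float(wq @ (y * f1q)), float(wq @ (y * f2q))
        v1 = float(wq @ f1q**2) - m1 * m1
        v2 = float(wq @ f2q**2) - m2 * m2
        k2_quad = _eval_clipped(f2g, pts_quad) @ wq
        cross = float(wq @ (f1q * k2_quad))
        a1 = kappa * m1 + v1 + vdown
        a2 = kappa * m2 + v2 + vdown
        c = (cross - m1 * m2) + vdown * rdown
        det = a1 * a2 - c * c
        if not np.isfinite(det) or abs(det) < 1e-300:
            break
        Dt1_new = (a2 * yf1 - c * yf2) / det
        Dt2_new = (a1 * yf2 - c * yf1) / det
        if Dt1_new == 0.0 or Dt2_new == 0.0:
            break
        k2_grid = _eval_clipped(f2g, pts_grid) @ wq
        k1_grid = _eval_clipped(f1g, pts_grid) @ wq
        f1_upd = np.clip(
            X_GRID / Dt1_new - kappa / 2.0 + m1 + (Dt2_new / Dt1_new) * (m2 - k2_grid), 0.0, 1.0
        )
        f2_upd = np.clip(
            X_GRID / Dt2_new - kappa / 2.0 + m2 + (Dt1_new / Dt2_new) * (m1 - k1_grid), 0.0, 1.0
        )
        if relax < 1.0:
            f1_upd = (1.0 - relax) * f1g + relax * f1_upd
            f2_upd = (1.0 - relax) * f2g + relax * f2_upd
        change = max(
            abs(Dt1_new - Dt1),
            abs(Dt2_new - Dt2),
            float(np.abs(f1_upd - f1g).max()),
            float(np.abs(f2_upd - f2g).max()),
        )
        trace[n_it - 1] = change
        f1g, f2g, Dt1, Dt2 = f1_upd, f2_upd, Dt1_new, Dt2_new
        if change < tol:
            converged = True
            break
        if relax == 1.0 and n_it >= 60 and change >= 0.99 * trace[n_it - 51]:
            relax = 0.5  # plain iteration is cycling; damp it

    # final expectations for the score
    f1q = _eval_clipped(f1g, y)
    f2q = _eval_clipped(f2g, y)
    yf1, yf2 = float(wq @ (y * f1q)), float(wq @ (y * f2q))
    score = Dt1 * yf1 + Dt2 * yf2
    sol = DualSolution(
        f1=Nonlinearity.tabulated(X_GRID, f1g),
        f2=Nonlinearity.tabulated(X_GRID, f2g),
        Dt1=Dt1,
        Dt2=Dt2,
        score=score,
        mse=p.sigma_s**2 * (1.0 - p.signal_fraction * score),
        strategy="",
        n_iterations=n_it,
        converged=converged,
        seed=seed,
        rho_eff=rho,
        params=p,
        change_trace=trace[:n_it].copy(),
    )
    sol.strategy = classify_solution(sol)
    return sol


def classify_solution(sol: DualSolution, tol: float = 1e-2) -> str:
    """Strategy label from weight signs and the pair-identity test.

    Opposite weight signs mean opposite polarity (ON-OFF / OFF-ON); same
    signs are ON-ON (or OFF-OFF), subdivided into identical vs split pairs
    by the sup-norm distance of the tabulated nonlinearities.
    """
    s1, s2 = np.sign(sol.Dt1), np.sign(sol.Dt2)
    if s1 > 0 and s2 < 0:
        return "ON_OFF"
    if s1 < 0 and s2 > 0:
        return "OFF_ON"
    if s1 < 0 and s2 < 0:
        return "OFF_OFF"
    dist = float(np.abs(sol.f1.grid_f - sol.f2.grid_f).max())
    return "ON_ON_identical" if dist < tol else "ON_ON_split"


def polarity_class(strategy: str) -> str:
    """Coarse polarity class: 'mixed' (ON-OFF / OFF-ON) or 'same' (ON-ON)."""
    return "mixed" if strategy in ("ON_OFF", "OFF_ON") else "same"


@dataclass
class MultiSeedResult:
    """Best converged solution per strategy label plus replication stats."""

    best: dict[str, DualSolution]
    dispersion: dict[str, float]
    n_converged: int
    n_total: int

    def best_of_polarity(self, which: str) -> DualSolution | None:
        """Lowest-MSE solution of coarse polarity 'mixed' or 'same'."""
        cands = [s for k, s in self.best.items() if polarity_class(k) == which]
        return min(cands, key=lambda s: s.mse) if cands else None


def multi_seed_solve(
    p: CircuitParams,
    n_seeds: int = 20,
    classes: tuple[str, ...] = ("on_off", "on_on"),
    seed: int = 0,
    tol: float = 1e-4,
    max_iter: int = 2000,
    relax: float = 1.0,
) -> MultiSeedResult:
    """Run picard_solve over seeds and init classes; keep per-class winners.

    Solutions are grouped by their *classified* strategy (a seed may cross
    to the opposite class; it is then counted where it lands). Dispersion
    is the max pairwise sup-norm distance among co-converged solutions of
    the same label, a replication-consistency diagnostic.
    """
    by_label: dict[str, list[DualSolution]] = {}
    n_conv = n_total = 0
    for cls in classes:
        for k in range(n_seeds):
            s = picard_solve(
                p, init_class=cls, seed=seed + 1000 * k, tol=tol, max_iter=max_iter, relax=relax
            )
            n_total += 1
            if s.converged:
                n_conv += 1
                by_label.setdefault(s.strategy, []).append(s)
    best: dict[str, DualSolution] = {}
    disp: dict[str, float] = {}
    for label, sols in by_label.items():
        best[label] = min(sols, key=lambda s: s.mse)
        d = 0.0
        for i in range(len(sols)):
            for j in range(i + 1, len(sols)):
                d = max(
                    d,
                    float(np.abs(sols[i].f1.grid_f - sols[j].f1.grid_f).max()),
                    float(np.abs(sols[i].f2.grid_f - sols[j].f2.grid_f).max()),
                )
        disp[label] = d
    return MultiSeedResult(best=best, dispersion=disp, n_converged=n_conv, n_total=n_total)


# independent quadrature (different order and span) for residual checks
_rnodes, _rw = leggauss(400)
_RES_NODES = 6.5 * _rnodes
_RES_W = 6.5 * _rw * np.exp(-0.5 * _RES_NODES**2) / np.sqrt(2.0 * np.pi)


def fixed_point_residual(sol: DualSolution) -> float:
    """Max violation of the stationarity equations by independent quadrature.

    Re-evaluates all expectations with a 400-node rule on [-6.5, 6.5] and
    returns the largest absolute residual over the two weight equations and
    the two nonlinearity equations (on the grid, inside the clip region the
    update must reproduce f; outside it must saturate consistently).
    """
    p = sol.params
    rho, kappa, vdown, rdown = sol.rho_eff, p.kappa, p.sigma_down**2, p.rho_down
    y, wq = _RES_NODES, _RES_W
    norm = float(wq.sum())  # renormalise truncated weight
    wq = wq / norm
    f1g, f2g = sol.f1.grid_f, sol.f2.grid_f
    f1q, f2q = _eval_clipped(f1g, y), _eval_clipped(f2g, y)
    m1, m2 = float(wq @ f1q), float(wq @ f2q)
    yf1, yf2 = float(wq @ (y * f1q)), float(wq @ (y * f2q))
    v1 = float(wq @ f1q**2) - m1 * m1
    v2 = float(wq @ f2q**2) - m2 * m2
    root1m = np.sqrt(max(0.0, 1.0 - rho * rho))
    pts_q = root1m * y[None, :] + rho * y[:, None]
    cross = float(wq @ (f1q * (_eval_clipped(f2g, pts_q) @ wq)))
    a1 = kappa * m1 + v1 + vdown
    a2 = kappa * m2 + v2 + vdown
    c = (cross - m1 * m2) + vdown * rdown
    r_w1 = sol.Dt1 * a1 + sol.Dt2 * c - yf1
    r_w2 = sol.Dt2 * a2 + sol.Dt1 * c - yf2
    pts_g = root1m * y[None, :] + rho * X_GRID[:, None]
    k2 = _eval_clipped(f2g, pts_g) @ wq
    k1 = _eval_clipped(f1g, pts_g) @ wq
    upd1 = np.clip(X_GRID / sol.Dt1 - kappa / 2.0 + m1 + sol.Dt2 / sol.Dt1 * (m2 - k2), 0, 1)
    upd2 = np.clip(X_GRID / sol.Dt2 - kappa / 2.0 + m2 + sol.Dt1 / sol.Dt2 * (m1 - k1), 0, 1)
    r_f = max(float(np.abs(upd1 - f1g).max()), float(np.abs(upd2 - f2g).max()))
    return max(abs(r_w1), abs(r_w2), r_f)
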