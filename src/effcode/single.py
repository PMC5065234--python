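"""Exact single-pathway optimal nonlinearity.

Variational minimisation of the linear-readout MSE under the bound
0 <= f <= 1 yields a piecewise-linear optimum: f(z) = 0 below z0, 1 above
z1, linear between. In rescaled coordinates x = z / sqrt(sigma_s^2 +
sigma_up^2) the kinks (x0, x1) depend only on kappa and sigma_down and
satisfy two self-consistency relations (with w = x1 - x0 equal to the
rescaled decoding weight):

    w * (kappa <f~> + var f~ + sigma_down^2) = <y f~>
    x0 = w * (kappa / 2 - <f~>)

The expectations are closed-form normal integrals of the ramp, so the
system is solved by a grid-seeded quasi-Newton root find to residual 1e-8.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import root

from .metrics import ramp_expectations
from .metrics import snr as _snr
from .model import CircuitParams, DecodingWeights, Nonlinearity

__all__ = ["SingleSolution", "solve_single", "slope_offset", "ramp_expectations"]


def _residuals(x: np.ndarray, kappa: float, var_down: float) -> np.ndarray:
    x0, x1 = x
    if not x1 > x0:
        return np.array([1e6, 1e6])
    mean, y_f, f_sq = ramp_expectations(x0, x1)
    w = x1 - x0
    g1 = w * (kappa * mean + (f_sq - mean**2) + var_down) - y_f
    g2 = x0 - w * (kappa / 2.0 - mean)
    return np.array([g1, g2])


@dataclass(frozen=True)
class SingleSolution:
    """Converged single-pathway optimum (raw and rescaled forms)."""

    f: Nonlinearity  # piecewise linear, raw input coordinates
    f_rescaled: Nonlinearity
    D: DecodingWeights
    mse: float
    snr: float
    x0: float
    x1: float
    residual: float
    converged: bool
    params: CircuitParams

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "x0": self.x0,
            "x1": self.x1,
            "z0": self.f.z0,
            "z1": self.f.z1,
            "D": self.D.to_dict(),
            "mse": self.mse,
            "snr": self.snr,
            "residual": self.residual,
            "converged": self.converged,
        }


def solve_single(p: CircuitParams, residual_tol: float = 1e-8) -> SingleSolution:
    """Solve the single-pathway self-consistency system for any noise mix.

    A coarse scan over ramp centre and (log) width seeds a quasi-Newton
    root find; the scan avoids the spurious basin of nearly flat ramps. The
    all-noise-zero corner (kappa = sigma_down = 0 with sigma_up = 0) has a
    diverging optimal width and is reported as non-converged.
    """
    kappa, var_down = p.kappa, p.sigma_down**2
    if kappa == 0.0 and var_down == 0.0:
        # without response-stage or downstream noise the optimal width
        # diverges (an ever-shallower ramp linearises the readout); the
        # infimum chi^2 = sigma_s^2 sigma_up^2/(sigma_s^2+sigma_up^2) is
        # approached but never attained, so report non-convergence
        f = Nonlinearity.ramp(-25.0, 25.0)
        return SingleSolution(
            f=f,
            f_rescaled=f,
            D=DecodingWeights(D=(0.0,), degenerate=True),
            mse=float("nan"),
            snr=float("inf"),
            x0=-25.0,
            x1=25.0,
            residual=float("nan"),
            converged=False,
            params=p,
        )
    # coarse seed scan over centre c and width w
    centres = np.linspace(-3.0, 3.0, 25)
    widths = np.geomspace(1e-2, 50.0, 41)
    best = []
    for c in centres:
        for w in widths:
            r = _residuals(np.array([c - w / 2, c + w / 2]), kappa, var_down)
            best.append((float(np.abs(r).max()), c, w))
    best.sort(key=lambda t: t[0])

    sol = None
    for _, c, w in best[:8]:
        res = root(
            _residuals, np.array([c - w / 2, c + w / 2]), args=(kappa, var_down), method="hybr"
        )
        if res.success and res.x[1] > res.x[0]:
            resid = float(np.abs(_residuals(res.x, kappa, var_down)).max())
            if resid < residual_tol:
                sol = res.x
                break
    if sol is None:
        # report the best found, flagged unconverged
        _, c, w = best[0]
        sol = np.array([c - w / 2, c + w / 2])
        resid = float(np.abs(_residuals(sol, kappa, var_down)).max())
        converged = False
    else:
        converged = True

    x0, x1 = float(sol[0]), float(sol[1])
    scale, frac = p.input_scale, p.signal_fraction
    mean, y_f, _ = ramp_expectations(x0, x1)
    w = x1 - x0  # rescaled decoding weight D~
    D_raw = p.sigma_s**2 * w / scale
    f_raw = Nonlinearity.ramp(scale * x0, scale * x1)
    f_res = Nonlinearity.ramp(x0, x1)
    chi2 = p.sigma_s**2 * (1.0 - frac * w * y_f)
    return SingleSolution(
        f=f_raw,
        f_rescaled=f_res,
        D=DecodingWeights(D=(D_raw,), D0=-D_raw * mean),
        mse=chi2,
        snr=_snr(p, f_raw),
        x0=x0,
        x1=x1,
        residual=resid,
        converged=converged,
        params=p,
    )


def slope_offset(sol: SingleSolution, rescaled: bool = True) -> tuple[float, float]:
    """Slope 1/(z1 - z0) and midpoint offset (z0 + z1)/2 of the optimum."""
    if rescaled:
        return 1.0 / (sol.x1 - sol.x0), (sol.x0 + sol.x1) / 2.0
    z0, z1 = sol.f.z0, sol.f.z1
    return 1.0 / (z1 - z0), (z0 + z1) / 2.0
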