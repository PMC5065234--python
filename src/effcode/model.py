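"""Parameter and nonlinearity data model shared by all solvers.

The encoding circuit is: a zero-mean Gaussian stimulus ``s`` (variance
``sigma_s**2``) is corrupted by additive Gaussian upstream noise ``eta``
(variance ``sigma_up**2``), passed through a bounded nonlinearity
``f: R -> [0, 1]``, emitted through a stochastic response stage (scaled
Poisson with quantal size ``kappa`` by default), and finally corrupted by
additive Gaussian downstream noise ``zeta`` (variance ``sigma_down**2``).
For two parallel pathways the upstream and downstream noises may be
correlated across pathways (``rho_up``, ``rho_down``) while the stimulus is
shared.

Because the total input ``s + eta`` is Gaussian, every optimal nonlinearity
depends on ``sigma_s`` and ``sigma_up`` only through the normalisation
``z = sqrt(sigma_s**2 + sigma_up**2) * x``; this module provides that
rescaling as an exact bijection, plus the effective input correlation
``rho_eff`` that summarises how upstream noise decorrelates the two
pathways' inputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.special import expit

__all__ = [
    "X_GRID",
    "CircuitParams",
    "Nonlinearity",
    "DecodingWeights",
    "PoissonVariant",
    "Polarity",
    "effective_correlation",
    "rescale_nonlinearity",
]

# Rescaled input grid for tabulated nonlinearities: +-6 standard deviations
# of the (standard-normal) rescaled total input, 241 points (spacing 0.05).
X_GRID = np.linspace(-6.0, 6.0, 241)


class PoissonVariant(str, Enum):
    """Noise model of the stochastic response stage."""

    scaled_poisson = "scaled_poisson"
    multiplicative_gaussian = "multiplicative_gaussian"
    binomial = "binomial"


class Polarity(str, Enum):
    ON = "ON"
    OFF = "OFF"


@dataclass(frozen=True)
class CircuitParams:
    """Full parameterisation of the noise model for one or two pathways.

    Parameters
    ----------
    sigma_s : float
        Stimulus standard deviation (> 0). All results are reported in
        stimulus units; the default of 1 makes the stimulus standard normal.
    sigma_up : float
        Upstream (pre-nonlinearity) additive Gaussian noise s.d. (>= 0).
    kappa : float
        Quantal size of the scaled-Poisson response stage (>= 0). The stage
        output is ``kappa * Poisson(f / kappa)``: mean ``f``, variance
        ``kappa * f``. ``kappa = 0`` means a deterministic stage.
    sigma_down : float
        Downstream (post-nonlinearity) additive Gaussian noise s.d. (>= 0).
    rho_up, rho_down : float
        Correlation of the upstream / downstream noise across the two
        pathways, in [-1, 1]. Ignored for a single pathway.
    n_pathways : int
        1 or 2.
    poisson_variant : PoissonVariant
        Response-stage noise model; the alternatives keep the conditional
        mean equal to ``f`` but change the conditional variance law.
    binomial_n : int
        Event count for the binomial variant (stage output is
        ``Binomial(N, f) / N``).
    """

    sigma_s: float = 1.0
    sigma_up: float = 0.0
    kappa: float = 0.0
    sigma_down: float = 0.0
    rho_up: float = 0.0
    rho_down: float = 0.0
    n_pathways: int = 1
    poisson_variant: PoissonVariant = PoissonVariant.scaled_poisson
    binomial_n: int = 10

    def __post_init__(self) -> None:
        if not self.sigma_s > 0:
            raise ValueError(f"sigma_s must be > 0, got {self.sigma_s}")
        for name in ("sigma_up", "kappa", "sigma_down"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        for name in ("rho_up", "rho_down"):
            if not -1.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [-1, 1], got {getattr(self, name)}")
        if self.n_pathways not in (1, 2):
            raise ValueError(f"n_pathways must be 1 or 2, got {self.n_pathways}")
        if self.poisson_variant is PoissonVariant.binomial and self.binomial_n < 1:
            raise ValueError("binomial_n must be a positive integer")

    @property
    def input_scale(self) -> float:
        """sqrt(sigma_s**2 + sigma_up**2), the total-input s.d."""
        return float(np.hypot(self.sigma_s, self.sigma_up))

    @property
    def signal_fraction(self) -> float:
        """sigma_s**2 / (sigma_s**2 + sigma_up**2)."""
        return self.sigma_s**2 / (self.sigma_s**2 + self.sigma_up**2)

    def to_dict(self) -> dict:
        return {
            "sigma_s": self.sigma_s,
            "sigma_up": self.sigma_up,
            "kappa": self.kappa,
            "sigma_down": self.sigma_down,
            "rho_up": self.rho_up,
            "rho_down": self.rho_down,
            "n_pathways": self.n_pathways,
            "poisson_variant": self.poisson_variant.value,
            "binomial_n": self.binomial_n,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CircuitParams":
        d = dict(d)
        if "poisson_variant" in d:
            d["poisson_variant"] = PoissonVariant(d["poisson_variant"])
        return cls(**d)


def effective_correlation(p: CircuitParams) -> float:
    """Effective correlation of the two pathways' total inputs s + eta.

    rho_eff = (sigma_s**2 + sigma_up**2 * rho_up) / (sigma_s**2 + sigma_up**2).

    The shared stimulus contributes perfectly correlated input; upstream
    noise dilutes that correlation unless it is itself fully correlated.
    """
    if p.n_pathways != 2:
        raise ValueError("effective_correlation requires a two-pathway circuit")
    vs, vu = p.sigma_s**2, p.sigma_up**2
    return (vs + vu * p.rho_up) / (vs + vu)


def rho_up_for_effective(rho_eff: float, sigma_s: float, sigma_up: float) -> float:
    """Invert rho_eff -> rho_up at fixed sigma_s, sigma_up.

    Raises if the requested rho_eff is not realizable with |rho_up| <= 1.
    """
    vs, vu = sigma_s**2, sigma_up**2
    if vu == 0:
        if abs(rho_eff - 1.0) > 1e-12:
            raise ValueError("with sigma_up = 0 only rho_eff = 1 is realizable")
        return 0.0
    rho_up = (rho_eff * (vs + vu) - vs) / vu
    if not -1.0 - 1e-12 <= rho_up <= 1.0 + 1e-12:
        raise ValueError(
            f"rho_eff={rho_eff} not realizable at sigma_s={sigma_s}, sigma_up={sigma_up}"
            f" (needs rho_up={rho_up:.4f})"
        )
    return float(np.clip(rho_up, -1.0, 1.0))


@dataclass(frozen=True)
class Nonlinearity:
    """A bounded transfer function f: R -> [0, 1].

    Three representations:

    - ``piecewise_linear``: 0 below ``z0``, 1 above ``z1``, linear between
      (the exact form of the variationally optimal single-pathway solution).
    - ``logistic``: 1 / (1 + exp(-nu (z - phi))).
    - ``tabulated``: values on a strictly increasing grid, interpolated by a
      clipped cubic spline and held at the boundary values outside the grid.

    OFF polarity is stored as a flag: an OFF cell is the mirror image of its
    ON form, evaluated as f_ON(-z). ON and OFF encoders are mathematically
    equivalent (identical MSE and MI), so no math is duplicated.
    """

    representation: str = "piecewise_linear"
    z0: float = 0.0
    z1: float = 1.0
    nu: float = 1.0
    phi: float = 0.0
    grid_x: np.ndarray | None = None
    grid_f: np.ndarray | None = None
    polarity: Polarity = Polarity.ON
    _spline: CubicSpline | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.representation not in ("piecewise_linear", "logistic", "tabulated"):
            raise ValueError(f"unknown representation {self.representation!r}")
        if self.representation == "piecewise_linear" and not self.z1 > self.z0:
            raise ValueError("piecewise_linear requires z1 > z0 (use polarity=OFF to mirror)")
        if self.representation == "tabulated":
            x = np.asarray(self.grid_x, dtype=float)
            f = np.asarray(self.grid_f, dtype=float)
            if x.ndim != 1 or x.shape != f.shape or x.size < 4:
                raise ValueError("tabulated form needs matching 1-D grids of >= 4 points")
            if not np.all(np.diff(x) > 0):
                raise ValueError("grid_x must be strictly increasing")
            f = np.clip(f, 0.0, 1.0)
            object.__setattr__(self, "grid_x", x)
            object.__setattr__(self, "grid_f", f)
            object.__setattr__(self, "_spline", CubicSpline(x, f, extrapolate=False))

    # -- constructors ----------------------------------------------------
    @classmethod
    def ramp(cls, z0: float, z1: float, polarity: Polarity = Polarity.ON) -> "Nonlinearity":
        return cls(representation="piecewise_linear", z0=z0, z1=z1, polarity=polarity)

    @classmethod
    def logistic(cls, nu: float, phi: float, polarity: Polarity = Polarity.ON) -> "Nonlinearity":
        return cls(representation="logistic", nu=nu, phi=phi, polarity=polarity)

    @classmethod
    def tabulated(
        cls,
        grid_x: Sequence[float],
        grid_f: Sequence[float],
        polarity: Polarity = Polarity.ON,
    ) -> "Nonlinearity":
        return cls(
            representation="tabulated",
            grid_x=np.asarray(grid_x, dtype=float),
            grid_f=np.asarray(grid_f, dtype=float),
            polarity=polarity,
        )

    # -- evaluation ------------------------------------------------------
    def __call__(self, z):
        z = np.asarray(z, dtype=float)
        if self.polarity is Polarity.OFF:
            z = -z
        if self.representation == "piecewise_linear":
            out = np.clip((z - self.z0) / (self.z1 - self.z0), 0.0, 1.0)
        elif self.representation == "logistic":
            out = expit(self.nu * (z - self.phi))
        else:
            out = self._spline(z)
            # hold boundary values outside the grid, clip spline overshoot
            out = np.where(z < self.grid_x[0], self.grid_f[0], out)
            out = np.where(z > self.grid_x[-1], self.grid_f[-1], out)
            out = np.clip(out, 0.0, 1.0)
        return out if out.ndim else float(out)

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        d: dict = {"representation": self.representation, "polarity": self.polarity.value}
        if self.representation == "piecewise_linear":
            d.update(z0=self.z0, z1=self.z1)
        elif self.representation == "logistic":
            d.update(nu=self.nu, phi=self.phi)
        else:
            d.update(grid_x=self.grid_x.tolist(), grid_f=self.grid_f.tolist())
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Nonlinearity":
        d = dict(d)
        rep = d["representation"]
        pol = Polarity(d.get("polarity", "ON"))
        if rep == "piecewise_linear":
            return cls.ramp(d["z0"], d["z1"], pol)
        if rep == "logistic":
            return cls.logistic(d["nu"], d["phi"], pol)
        return cls.tabulated(d["grid_x"], d["grid_f"], pol)

    def to_table(self, path: str | Path, n: int = 241, span: float = 6.0) -> None:
        """Write a two-column plain-text table (x, f(x))."""
        if self.representation == "tabulated":
            x = self.grid_x
        else:
            x = np.linspace(-span, span, n)
        np.savetxt(path, np.column_stack([x, self(x)]), header="x f", comments="# ")

    @classmethod
    def from_table(cls, path: str | Path) -> "Nonlinearity":
        arr = np.loadtxt(path)
        return cls.tabulated(arr[:, 0], arr[:, 1])

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "Nonlinearity":
        return cls.from_dict(json.loads(Path(path).read_text()))


def rescale_nonlinearity(
    f: Nonlinearity, p: CircuitParams, direction: str = "to_rescaled"
) -> Nonlinearity:
    """Map between raw input coordinates z and rescaled x = z / sqrt(ss^2+su^2).

    The optimal rescaled nonlinearity f~(x) = f(sqrt(sigma_s^2+sigma_up^2) x)
    is independent of sigma_s and sigma_up, so solvers work in x and results
    are reported in either coordinate via this exact bijection.
    """
    scale = p.input_scale
    if direction == "to_rescaled":
        a = 1.0 / scale
    elif direction == "to_raw":
        a = scale
    else:
        raise ValueError("direction must be 'to_rescaled' or 'to_raw'")
    # abscissa transform x = a * z: kinks/offsets scale by a, slopes by 1/a
    if f.representation == "piecewise_linear":
        return replace(f, z0=f.z0 * a, z1=f.z1 * a)
    if f.representation == "logistic":
        return replace(f, nu=f.nu / a, phi=f.phi * a)
    return Nonlinearity.tabulated(f.grid_x * a, f.grid_f, f.polarity)


@dataclass(frozen=True)
class DecodingWeights:
    """Optimal-linear-readout weights: s_est = D0 + sum_i D_i r_i.

    At the optimum D0 = -sum_i D_i <r_i>, so the readout is a weighted sum
    of mean-subtracted responses.
    """

    D: tuple[float, ...]
    D0: float = 0.0
    degenerate: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "D", tuple(float(d) for d in self.D))

    def to_dict(self) -> dict:
        return {"D": list(self.D), "D0": self.D0, "degenerate": self.degenerate}
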