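"""Frozen-seed fixture sets for the printed parameter tables.

The named parameter sets are the figure-generating conditions: nine
single-pathway noise mixes spanning a low/medium/high-noise column for
each dominant noise source, three optimal-vs-suboptimal comparison sets,
and six two-pathway sets. ``generate_fixtures`` solves each set and draws
a reduced-size Monte Carlo batch, all reproducible bit-for-bit from the
recorded seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

from .dual import DualSolution, picard_solve
from .model import CircuitParams
from .simulate import DrawSet, simulate
from .single import SingleSolution, solve_single

__all__ = ["SINGLE_PATHWAY_SETS", "COMPARISON_SETS", "DUAL_PATHWAY_SETS", "FixtureSet", "generate_fixtures"]

# single-pathway noise mixes (sigma_s = 1 throughout); columns are
# low / medium / high total noise (SNR ~ 5 / 1 / 0.1)
SINGLE_PATHWAY_SETS: dict[str, CircuitParams] = {
    "upstream_low": CircuitParams(sigma_up=0.375, kappa=1e-3, sigma_down=0.05),
    "upstream_medium": CircuitParams(sigma_up=0.92, kappa=1e-3, sigma_down=0.05),
    "upstream_high": CircuitParams(sigma_up=3.1, kappa=1e-3, sigma_down=0.05),
    "poisson_low": CircuitParams(sigma_up=0.05, kappa=0.0395, sigma_down=0.05),
    "poisson_medium": CircuitParams(sigma_up=0.05, kappa=0.5, sigma_down=0.05),
    "poisson_high": CircuitParams(sigma_up=0.05, kappa=6.6, sigma_down=0.05),
    "downstream_low": CircuitParams(sigma_up=0.05, kappa=1e-3, sigma_down=0.135),
    "downstream_medium": CircuitParams(sigma_up=0.05, kappa=1e-3, sigma_down=0.4175),
    "downstream_high": CircuitParams(sigma_up=0.05, kappa=1e-3, sigma_down=1.54),
}

# optimal-vs-suboptimal comparison conditions
COMPARISON_SETS: dict[str, CircuitParams] = {
    "upstream_dominant": CircuitParams(sigma_up=0.8, kappa=0.0, sigma_down=0.005),
    "poisson_dominant": CircuitParams(sigma_up=0.0, kappa=0.2, sigma_down=0.005),
    "downstream_dominant": CircuitParams(sigma_up=0.05, kappa=0.0, sigma_down=0.3),
}

# two-pathway conditions (sigma_s = 1)
DUAL_PATHWAY_SETS: dict[str, CircuitParams] = {
    "upstream_low": CircuitParams(
        sigma_up=0.85, rho_up=0.9762, kappa=0.1, sigma_down=0.1, rho_down=0.0, n_pathways=2
    ),
    "upstream_high": CircuitParams(
        sigma_up=0.85, rho_up=-0.9073, kappa=0.1, sigma_down=0.1, rho_down=0.0, n_pathways=2
    ),
    "poisson_low": CircuitParams(
        sigma_up=0.25, rho_up=-0.7, kappa=0.25, sigma_down=0.1, rho_down=0.0, n_pathways=2
    ),
    "poisson_high": CircuitParams(
        sigma_up=0.25, rho_up=-0.7, kappa=0.9, sigma_down=0.1, rho_down=0.0, n_pathways=2
    ),
    "downstream_low": CircuitParams(
        sigma_up=0.25, rho_up=-0.7, kappa=0.1, sigma_down=0.25, rho_down=0.0, n_pathways=2
    ),
    "downstream_high": CircuitParams(
        sigma_up=0.25, rho_up=-0.7, kappa=0.1, sigma_down=0.9, rho_down=0.0, n_pathways=2
    ),
}


@dataclass
class FixtureSet:
    """Solved references and frozen-seed draw sets for the named conditions."""

    seed: int
    single_solutions: dict[str, SingleSolution]
    dual_solutions: dict[str, DualSolution]
    draws: dict[str, DrawSet]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        refs = {
            "seed": self.seed,
            "single": {k: s.to_dict() for k, s in self.single_solutions.items()},
            "dual": {k: s.to_dict() for k, s in self.dual_solutions.items()},
        }
        (outdir / "references.json").write_text(json.dumps(refs, indent=2))
        for name, ds in self.draws.items():
            ds.to_csv(outdir / f"draws_{name}.csv")


def generate_fixtures(seed: int = 0, n_draws: int = 2000) -> FixtureSet:
    """Solve every named parameter set and draw a reduced-n batch for each.

    Regeneration with the same seed is bit-identical; n_draws defaults to
    a desk-scale size suitable for regression tests.
    """
    single = {name: solve_single(p) for name, p in {**SINGLE_PATHWAY_SETS, **COMPARISON_SETS}.items()}
    dual = {
        name: picard_solve(p, init_class="on_off", seed=seed)
        for name, p in DUAL_PATHWAY_SETS.items()
    }
    draws: dict[str, DrawSet] = {}
    for i, (name, p) in enumerate(SINGLE_PATHWAY_SETS.items()):
        draws[f"single_{name}"] = simulate(p, single[name].f, n_draws, seed + i)
    for i, (name, p) in enumerate(DUAL_PATHWAY_SETS.items()):
        sol = dual[name]
        from .model import rescale_nonlinearity

        f1 = rescale_nonlinearity(sol.f1, p, "to_raw")
        f2 = rescale_nonlinearity(sol.f2, p, "to_raw")
        draws[f"dual_{name}"] = simulate(p, (f1, f2), n_draws, seed + 100 + i)
    return FixtureSet(seed=seed, single_solutions=single, dual_solutions=dual, draws=draws)
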