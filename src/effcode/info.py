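"""Differential-entropy estimation and stimulus-response mutual information.

Entropy is estimated either binlessly, from nearest-neighbour distances
(Kozachenko-Leonenko form: shorter distances mean locally higher density),
or by a histogram with the bin-width correction for differential entropy.
The binless estimator requires strictly distinct samples; with a scaled-
Poisson response stage and tiny downstream noise many responses coincide
to numerical precision, so the binned estimator is auto-selected there.

Mutual information between stimulus and response is MI = H(R) - <H(R|S)>:
the response entropy across stimulus draws minus the average entropy of
repeated responses to a fixed stimulus. Everything is in bits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .model import CircuitParams, Nonlinearity
from .simulate import _correlated_pair, _stage_draw, simulate

__all__ = [
    "EntropyEstimate",
    "DuplicateSamplesError",
    "entropy_binless",
    "entropy_binned",
    "mutual_information",
]

_EULER_GAMMA = 0.5772156649015329
# surface area of the unit d-sphere, d = 1, 2
_SPHERE_SURFACE = {1: 2.0, 2: 2.0 * np.pi}


class DuplicateSamplesError(ValueError):
    """Raised when identical samples break the nearest-neighbour estimator;
    use the binned estimator instead."""


@dataclass(frozen=True)
class EntropyEstimate:
    value: float  # bits
    estimator: str
    d: int
    n_samples: int
    settings: dict


def entropy_binless(samples: np.ndarray) -> EntropyEstimate:
    """Nearest-neighbour differential entropy in bits.

    H ~= log2(S_d (M-1) / d) + gamma/ln 2 + (d/M) sum_j log2 lambda_j,
    with lambda_j the Euclidean distance from sample j to its nearest
    neighbour, S_d the unit-sphere surface area and gamma the
    Euler-Mascheroni constant. Exact (brute/kd-tree) neighbour search.
    """
    x = np.asarray(samples, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    m, d = x.shape
    if m < 2:
        raise ValueError("need at least two samples")
    if d not in _SPHERE_SURFACE:
        raise ValueError("dimensions supported: 1 (one pathway) or 2 (two pathways)")
    nn = NearestNeighbors(n_neighbors=2, algorithm="auto").fit(x)
    dist, _ = nn.kneighbors(x)
    lam = dist[:, 1]
    if np.any(lam == 0.0):
        raise DuplicateSamplesError(
            "identical samples present; the binless estimator is undefined "
            "(use entropy_binned)"
        )
    h = (
        np.log2(_SPHERE_SURFACE[d] * (m - 1) / d)
        + _EULER_GAMMA / np.log(2.0)
        + d / m * float(np.sum(np.log2(lam)))
    )
    return EntropyEstimate(value=float(h), estimator="binless", d=d, n_samples=m, settings={})


def entropy_binned(
    samples: np.ndarray,
    n_bins: int = 50,
    span: tuple[float, float] | None = None,
) -> EntropyEstimate:
    """Histogram differential entropy in bits: -sum p_j log2(p_j / w).

    Empty bins contribute zero. The default span is data-driven (min to
    max); a fixed span can be passed and is recorded in the settings.
    """
    x = np.asarray(samples, dtype=float).ravel()
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    lo, hi = span if span is not None else (float(x.min()), float(x.max()))
    if hi <= lo:
        raise ValueError("degenerate sample range; differential entropy undefined")
    counts, edges = np.histogram(x, bins=n_bins, range=(lo, hi))
    w = edges[1] - edges[0]
    pj = counts / counts.sum()
    nz = pj > 0
    h = -float(np.sum(pj[nz] * np.log2(pj[nz] / w)))
    return EntropyEstimate(
        value=h,
        estimator="binned",
        d=1,
        n_samples=x.size,
        settings={"n_bins": n_bins, "span": (lo, hi), "bin_width": float(w)},
    )


def _response_entropy(
    r: np.ndarray, estimator: str, n_bins: int, span: tuple[float, float] | None = None
) -> float:
    """Entropy of a (n_pathways, n) response block, in bits.

    For the binned route a shared ``span`` (from the marginal response
    range) keeps the bin width identical between the marginal and the
    conditional entropies, so it cancels in the MI difference even when a
    conditional block is concentrated in a single bin.
    """
    if estimator == "binless":
        return entropy_binless(r.T if r.ndim == 2 else r).value
    if r.ndim == 2 and r.shape[0] == 2:
        raise ValueError("binned estimator is one-dimensional")
    return entropy_binned(np.ravel(r), n_bins=n_bins, span=span).value


def mutual_information(
    p: CircuitParams,
    f: Nonlinearity | tuple[Nonlinearity, Nonlinearity],
    n_stimuli: int = 10_000,
    n_repeats: int = 10_000,
    n_reps: int = 10,
    seed: int = 0,
    estimator: str = "auto",
    n_bins: int = 50,
) -> tuple[float, float]:
    """Monte Carlo MI(S; R) in bits: H(R) - <H(R|S)>_S.

    H(R) is estimated from one response per stimulus draw; H(R|S) by
    averaging the entropy of ``n_repeats`` responses to each of a subset of
    stimulus draws (the conditional entropy varies slowly with s, so a
    subsample suffices). The whole procedure is repeated ``n_reps`` times
    and averaged; the spread across repetitions is returned as a standard
    error. ``estimator='auto'`` picks the binned estimator whenever the
    scaled-Poisson stage discretises responses (kappa > 0) with small
    downstream noise, where duplicate responses break the binless method.
    """
    if estimator == "auto":
        discrete = p.kappa > 0 and p.sigma_down < 1e-3 * max(p.kappa, 1.0)
        # 2-D responses need the NN estimator; 1-D discretised ones the histogram
        estimator = "binned" if (discrete and p.n_pathways == 1) else "binless"
    n_cond = min(n_stimuli, 50)  # stimuli at which H(R|S) is evaluated
    vals = []
    for rep in range(n_reps):
        rng_seed = seed + 7919 * rep
        ds = simulate(p, f, n_stimuli, rng_seed)
        span = None
        if estimator == "binned":
            pad = 3.0 * p.sigma_down
            span = (float(ds.r.min()) - pad - 1e-9, float(ds.r.max()) + pad + 1e-9)
        h_r = _response_entropy(ds.r if p.n_pathways == 2 else ds.r[0], estimator, n_bins, span)
        # conditional entropies at fixed stimuli
        rng = np.random.default_rng(rng_seed + 1)
        h_cond = []
        fs = (f,) if isinstance(f, Nonlinearity) else tuple(f)
        for s_fixed in ds.s[:n_cond]:
            # condition on the stimulus: freeze s, redraw all noise
            if p.n_pathways == 1:
                eta = p.sigma_up * rng.standard_normal((1, n_repeats))
                zeta = p.sigma_down * rng.standard_normal((1, n_repeats))
            else:
                eta = _correlated_pair(rng, p.sigma_up, p.rho_up, n_repeats)
                zeta = _correlated_pair(rng, p.sigma_down, p.rho_down, n_repeats)
            stage = np.vstack(
                [_stage_draw(rng, p, np.asarray(fi(s_fixed + eta[i]))) for i, fi in enumerate(fs)]
            )
            r = stage + zeta
            h_cond.append(
                _response_entropy(r if p.n_pathways == 2 else r[0], estimator, n_bins, span)
            )
        vals.append(h_r - float(np.mean(h_cond)))
    vals = np.asarray(vals)
    sem = vals.std(ddof=1) / np.sqrt(n_reps) if n_reps > 1 else float("nan")
    return float(vals.mean()), float(sem)


def gaussian_entropy_bits(sigma: float) -> float:
    """Closed-form differential entropy of N(0, sigma^2) in bits."""
    return 0.5 * np.log2(2.0 * np.pi * np.e * sigma**2)
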