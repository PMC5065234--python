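# Methods

This note records the model, the numerical scheme, and the design choices
behind `effcode`, at the level of detail a maintainer or a careful user
needs to judge what the package computes and what its tests do and do not
establish.

## Model and assumptions

The encoder is static: one trial is one draw of (stimulus, noises,
response); there are no dynamics and no adaptation process — the
nonlinearity is assumed already adapted to the stationary stimulus and
noise statistics. The stimulus and both additive noise sources are
zero-mean Gaussians; the stochastic response stage has conditional mean
`f(s+η)` and a variant-specific conditional variance:

| variant | stage output | conditional variance |
|---|---|---|
| `scaled_poisson` (default) | `κ·Poisson(f/κ)` | `κ·f` |
| `multiplicative_gaussian` | `f + N(0, κ·f)` | `κ·f` |
| `binomial` | `Binomial(N, f)/N` | `f(1−f)/N` |

`κ = 0` (or `N → ∞`) makes the stage deterministic. The scaled-Poisson and
multiplicative-Gaussian variants share first and second conditional
moments by construction, which is why they produce the same optimal
nonlinearities under the MSE criterion; the binomial variant's variance
vanishes at both saturation levels. The multiplicative-Gaussian output is
deliberately not clipped to [0, 1]: it models additive output noise, and
clipping would silently change its moments. The binomial variant returns
counts divided by `N` so that all three variants have conditional mean
`f`.

The decoder is strictly linear; nonlinear decoding is out of scope. The
saturation level of every nonlinearity is hard-coded to 1: only the ratio
of noise scales to the dynamic range matters, so a different ceiling is
equivalent to rescaling `κ`, `σ_down`, and the decoding weights.

## Rescaling

Because `s + η` is Gaussian, every expectation reduces to an integral of
the rescaled shape `f~(x) = f(√(σ_s²+σ_up²)·x)` against a standard normal.
The package exploits this throughout:

- `solve_single` finds the rescaled kinks `(x₀, x₁)`, which depend only on
  `(κ, σ_down)`; raw-coordinate results follow from the exact bijection in
  `rescale_nonlinearity`.
- `picard_solve` iterates the coupled fixed-point maps directly in
  rescaled variables, parameterised by `(ρ_eff, κ, σ_down, ρ_down)`. The
  printed-form fixed-point equations are already rescaled, and carrying
  `σ_s, σ_up` through the iteration would add bookkeeping without changing
  a single iterate. Each `DualSolution` stores the scale-free score
  `T = D̃₁⟨y f̃₁⟩ + D̃₂⟨y f̃₂⟩`, from which the MSE at any realisation is
  `χ² = σ_s²(1 − T·σ_s²/(σ_s²+σ_up²))`. This identity is also why the
  winning polarity class cannot depend on `(σ_s, σ_up)` except through
  `ρ_eff` — only the margin changes.

## Quadrature

Single-variable Gaussian expectations use a 200-node Gauss–Legendre rule
on [−6, 6] with the explicit normal density (truncated mass ≈ 2·10⁻⁹);
cross-expectations `⟨f̃₁(y₁) f̃₂(y₂)⟩` at correlation ρ substitute
`y₂ = √(1−ρ²)·t + ρ·y₁` and use the tensor-product rule, which remains
stable at ρ → 1 where the kernel becomes a delta. Double integrals are
thus deterministic rather than Monte Carlo; an MC cross-check lives in the
test suite (closed-form vs simulated MSE).

Piecewise-linear nonlinearities bypass quadrature entirely: their
expectations have closed forms in the normal pdf/cdf (`ramp_expectations`;
`⟨y f̃⟩ = (Φ(x₁)−Φ(x₀))/(x₁−x₀)` by Stein's lemma). This matters because a
fixed-order rule resolves a kinked integrand only to ~10⁻³ when the ramp
is steep; tabulated (spline) shapes keep the quadrature route and inherit
that accuracy class, which is consistent with the 10⁻⁴ solver tolerance
and the ≥10⁻² decision tolerances built on top.

Tabulated nonlinearities live on a fixed grid x ∈ [−6, 6] with 241 points
(spacing 0.05), interpolated by a cubic spline, clipped to [0, 1], and
held at their boundary values outside the grid.

## Single-pathway solver

Unknowns `(x₀, x₁)`; residual system

    (x₁−x₀)·(κ⟨f̃⟩ + var f̃ + σ_down²) − ⟨y f̃⟩ = 0
    x₀ − (x₁−x₀)·(κ/2 − ⟨f̃⟩) = 0

with ramp expectations in closed form. A coarse scan over ramp centre
(25 points in [−3, 3]) and log-width (41 points in [10⁻², 50]) seeds a
quasi-Newton (`hybr`) root find; the scan avoids the spurious basin of
nearly flat ramps, where the residuals decay asymptotically. Residual
tolerance 10⁻⁸ (the system is 2-D and cheap, so a strict tolerance costs
nothing). The corner `κ = σ_down = 0` is degenerate — the optimal width
diverges, the infimum `χ² = σ_s²σ_up²/(σ_s²+σ_up²)` is approached but not
attained — and is reported as non-converged rather than solved.

## Dual-pathway Picard solver

Fixed-point maps: the 2×2 linear solve for the rescaled weights
(diagonal `κ⟨f̃ᵢ⟩ + var f̃ᵢ + σ_down²`, off-diagonal
`cov[f̃₁,f̃₂] + σ_down²ρ_down`), then the clipped update

    f̃₁(x) ← clip( x/D̃₁ − κ/2 + ⟨f̃₁⟩ + (D̃₂/D̃₁)(⟨f̃₂⟩ − K₂(x)), 0, 1 )

where `K₂(x) = ∫ φ(y) f̃₂(√(1−ρ_eff²)·y + ρ_eff·x) dy` (and symmetrically
for `f̃₂`). The weights feed the same-iteration nonlinearity update
(Gauss–Seidel ordering), which has the same fixed points as the fully
simultaneous form and converges at least as fast. Convergence requires
every weight and every grid value to change by less than the absolute
tolerance ε = 10⁻⁴; the iteration cap is 2000.

Initial guesses: weights drawn from N(±1, 0.5²) with the sign pattern of
the requested class (ON-OFF: `D̃₁ > 0 > D̃₂`; ON-ON: both positive;
redrawn on the rare sign crossing), and per-grid-point nonlinearity
guesses `clip(x/D̃⁰ − κ/2 + u(x))` with `u(x)` i.i.d. uniform on [0, 1] —
the uniform draw stands in for the bounded kernel-integral term, and
independence across grid points is the natural default. A converged run
is classified by its weight signs (ON-OFF / OFF-ON / OFF-OFF) and, for
same-polarity pairs, by a sup-norm identity test at tolerance 10⁻² —an
order of magnitude above ε and well below any observed threshold split.

Plain Picard iteration suffices almost everywhere, but at stiff corners
(ρ_eff → 1 with weak Poisson and downstream noise) it can enter a
period-2 cycle. The solver detects a stalled change norm (no decrease
over 50 iterations) and drops to under-relaxation ω = 0.5, which breaks
the cycle; a fixed relaxation factor is also exposed. `multi_seed_solve`
runs 20 seeds per class by default (reduced in CI presets), groups
solutions by their classified strategy — a seed occasionally lands in the
opposite basin and is counted where it lands — and reports the best MSE
per class plus a max-pairwise-sup-norm dispersion diagnostic.

Residual verification re-evaluates the stationarity equations with an
independent 400-node rule on [−6.5, 6.5]; converged solutions satisfy
them to better than 10× ε.

## Entropy and mutual information

Differential entropies are in bits. The binless estimator is the
nearest-neighbour (Kozachenko–Leonenko) form with exact neighbour search
(deterministic at the ≤10⁵ sample sizes used); it refuses duplicate
samples — exact floating-point ties — and recommends the histogram
estimator, which applies the bin-width correction `−Σ p_j log₂(p_j/w)`
with empty bins contributing zero. MI is estimated as
`H(R) − ⟨H(R|S)⟩_S`, with the conditional term averaged over 50 stimulus
draws (the conditional entropy varies slowly in `s`) and the whole
procedure repeated and averaged. When the scaled-Poisson stage
discretises responses and downstream noise is negligible, the binned
estimator is auto-selected with a bin span fixed from the marginal
response range — using one bin width for both entropy terms makes the
width cancel in the MI difference even for degenerate conditional blocks.
Defaults (10⁴ stimuli, 10⁴ repeats, 10 repetitions) match full-scale use;
tests and the `ci` preset shrink them.

## Parametric sweep

The simulation route scores logistic nonlinearities
`1/(1+exp(−ν(z−φ)))` on a (ν, φ) grid — default 25 log-spaced slopes ×
25 linear offsets over ±3 rescaled units — by simulating draws, fitting
the decoding weights by least squares, and averaging repetitions; common
random numbers across grid points sharpen the arg-optimum. The
`near_optimal` set (within 1% of the best score) is reported because with
strong upstream noise it is typically broad: many shapes perform almost
identically. Full-scale defaults are 10⁷ draws × 5 repetitions; tests use
10⁴–10⁵.

The unconstrained (piecewise-linear) optimum always weakly dominates the
best logistic. At the method-comparison condition (σ_up = 0.2, κ = 10⁻³,
σ_down = 0.2) the gap is real but small: best logistic χ² = 0.350 vs
analytic 0.339, i.e. 0.011·σ_s² (about 3% relative). Tests assert the
dominance ordering and agreement within 0.02·σ_s².

## Strategy maps and boundaries

`phase_map` solves both polarity classes per grid cell and records the
winner and the percent MSE decrease `100·(χ²_other − χ²_win)/χ²_other`.
Default grids are ρ_eff ∈ {0, 0.25, 0.5, 0.75, 1}, κ ∈ {0, …, 1},
σ_down ∈ {0.1, …, 1}, ρ_down ∈ {−1, …, 1} (σ_down starts at 0.1 because
the all-noise-weak corner converges very slowly); the CI preset
subsamples to 3×1×3×5 cells with 2 seeds per class. κ = 0 boundary claims
are probed at κ = 10⁻⁶ to stay clear of the degenerate corner. The
polarity boundary is located by bisection in ρ_down on the sign of
`χ²(ON-OFF) − χ²(ON-ON)`; the ON-ON splitting onset by bisection in
ρ_eff on the identical/split classification (a sharp transition), with a
single seed per point and automatic retry on basin swaps. Analytic
boundary formulas are out of scope.

Observed behaviour at the reduced grids: the splitting onset at κ = 1,
σ_down = 0.1, ρ_down = 0 sits near ρ_eff ≈ 0.95; the κ→0 polarity
crossover sits at ρ_down = 0 to within the bisection resolution for all
σ_down probed; the maximum percent MSE difference at κ = 1 is ≈ 20% when
the grid is realised at σ_s = σ_up = 1 and ≈ 7.7% at σ_up = 2 — both
extremes at the (ρ_eff = 0, σ_down = 1, ρ_down = ±1) corner, where
perfectly anticorrelated downstream noise is fully cancelled by an ON-ON
sum but amplified by an ON-OFF difference (verified against Monte Carlo
decoding). These two numbers are linked algebraically through the shared
rescaled score `T`, so their ratio is fixed near 2.6 at that corner.

## What the synthetic data does and does not show

All inputs are generated from the stated Gaussian/Poisson model with a
single seeded generator and a documented draw order (stimulus, upstream
noise, stage, downstream noise), so every simulation is bit-reproducible.
The generator emulates exactly the distributional assumptions of the
theory — it contains no temporal correlations, no non-Gaussian stimulus
statistics, no unequal noise variances across pathways, and no spiking.
Passing tests therefore establish internal correctness of the solvers and
estimators under the model's assumptions, not robustness of the
conclusions to real sensory statistics; heavy-tailed inputs, adaptation
dynamics, and asymmetric pathways are explicitly out of scope.

## Known limitations

- Only monotone (single-threshold) nonlinearities emerge from the
  variational form implemented; non-monotonic shapes are not searched.
- The quadrature accuracy class (~10⁻³ on steep kinked tabulated shapes)
  bounds how finely MSE differences below ~10⁻⁴·σ_s² can be resolved;
  boundary locations are quoted no finer than the bisection resolution.
- Entropy estimation is limited to one and two dimensions (the pathway
  counts supported); the binless estimator's small positive bias at 10⁵
  samples (~0.01 bit) is inside all stated tolerances.
- `n_pathways > 2` and unequal per-pathway noise variances are not
  supported.
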