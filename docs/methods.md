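# Methods

## Model

`fragdisp` integrates `n` coupled population density fields
`Ψ_k(x, y, t)`, one per dispersal-ability genotype, on a rectangular
periodic tile. The general dynamics combine three processes:

* **Dispersal.** Genotype `k` performs a random walk with step-size
  parameter `a_k = a0·k`, giving Fickian diffusion with coefficient
  `a_k²/4`.
* **Births by mate-finding.** Matings arise from random pairwise encounters,
  so the rate of (i, j) matings is proportional to `Ψ_i Ψ_j` (the
  bimolecular-collision form of a mate-finding Allee effect), attenuated by
  the logistic crowding factor `(1 − Ψ)`. An inheritance kernel
  `χ[k, i, j]` (probabilities summing to 1 over k) distributes offspring
  over genotypes; the package implements the general kernel
  (`model.birth_term_general`) and the 50/50 Mendelian kernel, under which
  the birth term collapses to `β Ψ (1 − Ψ) Ψ_k` — the form actually
  integrated. The equivalence of the two paths is asserted in the tests.
* **Deaths** at rate `δ`, optionally spatially varying `δ(x, y)` (habitat
  islands).

All simulations use the nondimensional form: densities as fractions of the
carrying capacity K, `a0 = 1`, leaving the birth parameter `β = K(r0/a0)²b`
and death rate `δ = (r0/a0)²d` (`model.nondimensionalize`; the printed
scaling is typographically ambiguous in the source material, and this
reading is the unique dimensionally consistent one given the time rescaling
`t = (a0/r0)²τ`). The shared per-capita rate `c(Ψ) = βΨ(1 − Ψ) − δ` is
negative at low density (strong Allee effect) and bistable: uniform states
decay to 0 below the threshold `Ψ₋` and saturate at `Ψ₊`, with
`Ψ∓ = (1 ∓ √(1 − 4δ/β))/2`. `4δ > β` is reported as a no-persistence
regime flag, not an error — extinction is a legitimate model outcome.
Because `c` is genotype-independent, genotype frequencies are exactly
conserved in spatially uniform states; every change in mean dispersal
ability is attributable to spatial structure.

## Geometry

Single-scale layouts tile an equilateral triangular lattice of circular
fragments with nearest-neighbour spacing `s`: the tile is `s × √3·s`
(`Nx = ⌈s/Δx⌉`, `Ny = ⌈√3 s/Δx⌉`, `x_i = −s/2 + Δx(i−1)`,
`y_j = −⌈(√3/2)s/Δx⌉Δx + Δx(j−1)`, the unique rectangle that tiles an
equilateral lattice of spacing s), with one
whole disc at the centre and quarter-discs in the corners. Node membership
is boundary-inclusive (`x² + y² ≤ r²`) at node centres; mask areas converge
to the analytic `2πr²` per tile at rate O(Δx). Fragments carry density
`ρ_int` split equally over genotypes (so `ā(0) = (1+n)/2` exactly), the
exterior `ρ_ext`. Patch overlap (2r > s) is allowed with a warning;
overlapping regions take `ρ_int` once.

The two-scale layout places regular flat-topped hexagonal macro-fragments
(circumradius R) on a triangular macro-lattice of spacing S, each filled
with the micro-lattice of discs. **Whole discs whose centres fall inside the
hexagon are used, not discs clipped by the hexagon edge**: with S = 13.2,
R = 5 this gives exactly 19 coarse (s = 2.2, r = 1.0) and 61 fine (s = 1.1,
r = 0.5) discs per hexagon — the pair of integers that appears, garbled,
in the published fine-variant density entry. The fine variant's interior
density is fixed by requiring the same total initial population as the
coarse variant, giving `ρ_fine = ρ_coarse·(19·4)/61 ≈ 0.1586`. The
published "≈ 0.0397" equals `ρ_coarse·19/61`, which omits the 4× disc-area
ratio; a density that low lies below the Allee threshold everywhere and
cannot reproduce the published fine-variant survival, so the
equal-population value is used.

## Numerics

* **Spatial discretization**: compact 9-point Laplacian
  `(4·(N+S+E+W) + (NE+NW+SE+SW) − 20·C)/(6Δx²)` with periodic wrap-around.
  The stencil is symmetric with zero row sum, so pure diffusion conserves
  the discrete total population to rounding (asserted at 10⁻¹⁰ relative).
* **Time integration**: adaptive embedded Dormand–Prince 5(4) pair
  (`scipy.integrate.RK45`), error-controlled on the stacked field vector,
  default tolerances rtol 10⁻⁶ / atol 10⁻⁹ (configurable). The hot
  right-hand side is a numba-compiled fused stencil+reaction kernel; a
  readable numpy reference implementation is kept alongside and asserted
  equal to 10⁻¹².
* **Non-negativity**: `Ψ_k = 0` is invariant in the continuum (the reaction
  term is proportional to `Ψ_k`); floating-point excursions below zero are
  clipped to 0 after each accepted step and counted.
* **Termination monitors**, evaluated at accepted steps only (stop times
  are accurate to one step; no dense-output root finding):
  * *uniformity* — std/mean of the genotype-1 field < 10⁻³ (the slowest
    dispersers have become spatially uniform; the run is over);
  * *extinction* — total population P < 10⁻⁴;
  * *stagnation* — the signed node sum `Σ ∂Ψ_k/∂t Δx² = dP_k/dt < 0.1` for
    every genotype. The signed, one-sided form follows the published
    formula literally; it fires as net growth levels off immediately after
    the habitat saturates (t ≈ 0.1 in the habitat-islands drain run),
    while a two-sided form with the magnitude would not fire until slow
    redistributive drifts die out (t ≈ 18 in the same run), contradicting
    the published account of when the rule fires. The one-sided form is
    only meaningful for runs whose genotype totals are growing during the
    transient (true for the habitat-islands experiment it is defined for);
  * *quiescence* — the two-sided variant, `|dP_k/dt| < 0.1` for all k,
    provided for layouts (Experiment E) whose genotype totals transiently
    shrink and whose tiles are too large for the uniformity criterion to be
    reached in reasonable time.

## Experiments

Presets A–E carry the published parameterizations (lattice spacings,
radii, densities, β, δ and sweep ranges). Noteworthy choices:

* **A (habitat islands)**: death field `δ_int` on the fragment discs,
  `δ_ext` outside; the reported ā is the value at the stagnation event —
  deliberately *not* a steady state. `experimentA_drain` then continues to
  t = 6 to expose the slow heterogeneity-driven loss of fast dispersers.
  The drain configuration assigns δ = 10 inside the discs / 35 outside
  (the published description of this run is internally contradictory about
  which region carries which rate; this orientation is the one whose
  dynamics — hospitable islands draining fast dispersers into a harsher
  matrix — match the published account); at Δx = 0.04 the retained
  fraction is ≈ 89.4%. The
  quantity is resolution-sensitive at the percent level: the published
  90% figure is stated at Δx = 0.02, and the acceptance run reports the
  Δx = 0.04 value.
* **C (size–density trade-off)**: `ρ_int(r) = 0.1273/r²` with s fixed at
  2.0, so every disc carries the same population (0.1273·π ≈ 0.4) and the
  initial overall density is independent of r. Densities above 1
  (supersaturated fragments at small r) are intentional and permitted.
* **E (two-scale)**: stops on the quiescence monitor; genotype abundances
  are effectively frozen well before (drift < 0.01 per unit time after
  t ≈ 1 at Δx = 0.08).
* Sweep step sizes within the published ranges are configuration choices
  (defaults: s step 0.05, r step 0.1, β step 5, δ step 1). Extinct runs
  carry a missing final ā and are omitted from plots.
* There is no randomness anywhere: identical configurations are
  bit-reproducible.

Test-suite and acceptance runs use reduced resolutions (Δx = 0.04 for the
single-scale layouts, 0.08 for the two-scale layout, half the published
values) — the package's standard "reduced" tier; full resolution is a
configuration flag away (`--dx` / `ExperimentConfig.dx`).

## Validation oracles

* **Well-mixed ODE** (`validation.wellmixed_oracle`): high-accuracy DOP853
  integration of `dΨ_k/dt = c(Ψ)Ψ_k`. Spatially uniform PDE runs reproduce
  it to < 10⁻⁶ max density error over t ∈ [0, 1]; uniform-state genotype
  frequencies are conserved to 10⁻¹⁰.
* **Absorbing-disk eigenvalue** (`validation.disk_dirichlet_eigen`): the
  smallest Dirichlet eigenvalue of the Laplacian on the unit disk satisfies
  `√λ₁ = j0,1 ≈ 2.405` (the first zero of the Bessel function J0, written
  j1 in some sources), the constant in the classical critical-patch-size
  growth rate. The finite-difference assembly embeds the disk in a grid
  with zero exterior values, so the dominant eigenvalue error is first
  order in Δx (measured order ≈ 0.75–1); Richardson extrapolation across
  two levels assumes order 1, and with three or more levels the order is
  estimated from the data. At Δx = {0.02, 0.01} the extrapolated value is
  2.4021 (0.11% error). This validates the diffusion discretization
  against a closed form without simulating the classical model itself.
* **Bistability classifier** (`validation.classify_bistable`): uniform
  initial conditions are classified extinct/saturating by the ODE oracle;
  outcomes flip across `Ψ₋` within a bracket of 10⁻⁶.

## What the layouts do and do not emulate

The periodic tile makes the simulated fragment lattice effectively
infinite and perfectly regular: it cannot capture larger-scale spatial
phenomena, irregular or random fragment placement, true bounded domains
with absorbing edges, fluctuating sex ratios, mutation between genotypes,
or continuous dispersal-trait spaces. Passing tests demonstrate the
mechanism under these idealized geometries, not quantitative predictions
for real landscapes. Exact published figure-panel times and pixel-level
sweep curves are not reproduction targets; qualitative directions and the
quantities listed in `scripts/acceptance.py` are.
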