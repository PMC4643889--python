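# Methods

## Model and coordinate systems

The dynamics couple two single-patch evolutionary games through
phenotype-independent migration. Two equivalent coordinate systems are
implemented and their equivalence is enforced by a property test (the
pushforward of the abundance field through the Jacobian of the coordinate
map must equal the frequency field to 1e-9, and trajectories integrated in
either system must agree after conversion):

* **Abundance form** (x₁, x₂, y₁, y₂): polynomial, smooth on the closed
  positive orthant, forward-invariant. All numerical integration happens
  here, so trajectories can approach extinction or boundary frequencies
  without coordinate singularities.
* **Frequency form** (p, q, n₁, n₂): the replicator-like form used for all
  equilibrium algebra; it divides by patch densities and is therefore only
  used where n₁, n₂ > 0.

Payoff matrices are required non-negative (`allow_negative=True` relaxes
this with a warning — the flow is still well defined, but the admissibility
argument α_i − c_i + mean payoff > 0 below uses non-negativity). The
migration rate of each patch must stay strictly below its intrinsic growth
rate; this makes the empty state (both patches extinct) a repeller, which
is why the censuses cover only *positive* equilibria.

## Density subsystem

At fixed frequencies the two density balances form parabolas in the
(n₁, n₂) plane. On the positive quadrant one balance defines a convex
increasing branch, the other a concave increasing branch, and the
difference of two such functions that starts negative and ends positive is
convex, so it has exactly one zero: **the positive density solution is
unique for every admissible parameter set**. `solve_density` exploits this:
a bracketed 1-D root (bisection/Brent on the reduction obtained by
substituting one balance into the other) followed by a 2-D Newton polish to
residuals near machine precision. The unit tests cross-check it on a 21×21
frequency grid against an independent oracle that reads all roots of the
quartic reduction off a companion matrix, asserting uniqueness as well as
agreement.

## Equilibrium enumeration

Three routes, chosen by the migration pattern:

* **c₁ = c₂ = 0.** Patches decouple; the census is the Cartesian product of
  the per-patch replicator rest points {0, 1, p*} × {0, 1, q*} with logistic
  densities — up to nine states in closed form.
* **One-way migration (c₁ > 0, c₂ = 0).** Patch 1 is autonomous; for each
  of its rest frequencies p̂ the patch-2 frequency must zero an explicit
  scalar function on [0, 1] (the replicator term plus the immigration
  correction written through the positive root of the patch-2 density
  quadratic). Roots are located by a 4001-point scan with sign-change
  bracketing and Brent refinement. By default only branches with p̂ stable
  in patch 1 are enumerated — the convention under which the published
  census counts (e.g. "six equilibria, four stable") are stated —
  with `branches="all"` enumerating the full stationary set including the
  equilibria that ride an unstable mixed branch (for the bistable-bistable
  example at c₁ = 0.5 this grows the set from 4 to 7; the extra states are
  all unstable, so attractor censuses are unaffected).
* **Two-way migration (c₁, c₂ > 0).** The only boundary equilibria are the
  two symmetric monomorphic states (an asymmetric boundary state is
  impossible: immigration pushes a vanishing phenotype back in). Interior
  equilibria are zeros of the two frequency-stationarity residuals on the
  open unit square after substituting the unique density solution; a
  201×201 grid (vectorized bisection for the densities) flags cells where
  both residuals change sign, each cell seeds a damped Newton iteration on
  the full 4-D system with the closed-form Jacobian, and converged roots
  are deduplicated with a scaled max-norm radius of 1e-6 (densities
  non-dimensionalized by (α + max payoff)/β). Every reported equilibrium
  carries a residual certificate below 1e-9.

When both games have interior rest points, interior equilibria must satisfy
the sign identity Δ₁Δ₂ p(1−p)q(1−q)(p−p*)(q−q*) = −c₁c₂(p−q)² (multiply the
two frequency balances); the grid search uses it as a cell pre-filter and
the tests assert it at every returned interior equilibrium.

## Candidate curves versus positive equilibria

Eliminating n₁ through the patch-1 equations and n₂ through the patch-2
equations collapses stationarity to two polynomial curves on the (p, q)
plane (poles at p = q cleared by (p−q)²). This is the planar picture in
which multistable censuses are usually drawn and counted.
`curve_intersections` reproduces it exactly — and makes a point the planar
picture hides: **an intersection of the reduced curves need not be an
equilibrium**, because the implied density of a patch can come out negative
(or zero — the extinct state appears as one such intersection). On the
bifurcation template at c = 0.014 the curves intersect 10 times in the open
square (12 counting the boundary states), but only 7 intersections carry
positive densities; the genuine census is 9 equilibria, 4 stable. Both
counts are exposed, flagged, and reported by the acceptance script; the
attractor set was confirmed independently by multistart root finding
(8000 random Newton starts) and by basin simulation.

## Stability

Each equilibrium is classified by the eigenvalues of the closed-form 4×4
Jacobian of the frequency dynamics, valid wherever densities are positive
(boundary frequencies included). A finite-difference Jacobian — central in
the interior, second-order one-sided stencils toward the interior at
boundary frequencies — must agree entrywise to 1e-6 (scaled) and serves as
a standing cross-check. Labels: stable / unstable when the spectral
abscissa is beyond ±1e-8, otherwise **marginal** — reported as such rather
than forced, since marginal spectra are exactly the bifurcation points a
scan steps over. For the one-way case the 2×2 Jacobian of the autonomous
patch-2 subsystem, with its trace/determinant stability conditions, is
implemented separately and tested to agree with the 4×4 labels. The empty
state is handled in its own chart (the density growth block, whose trace is
positive by α_i > c_i).

Two theorem-level properties are exercised over randomized regime fixtures:
a phenotype that is a pure ESS in both games makes the corresponding
symmetric boundary state stable; a shared interior ESS (p* = q*) makes the
symmetric interior state stable. A third, subtler effect is tested as an
existence search: migration can stabilize a monomorphic state that is *not*
an ESS in one patch, provided its payoff deficit there is small.

## Bifurcation scan

The scan applies c₁ = c₂ = c to a template system and re-enumerates at each
grid value (no continuation; c = 0 uses the exact product route). Intervals
where any census count changes are densified (step 5e-4 by default) and
thresholds are reported as brackets, which refinement can only narrow. On
the bistable-bistable template the census runs: 9 equilibria with 4
attractors at c = 0; the planar candidate count jumps to 12 for any
positive rate; an attractor pair annihilates near c ≈ 0.0155; the last
asymmetric attractor — a near-edge state around (p, q) ≈ (0.82, 0.003) —
survives until c ≈ 0.0209 (bisection to 2e-4), after which only the two
monomorphic symmetric states attract. That near-edge attractor is easy to
miss in a plotted phase square (its q-coordinate is ~0.003); its stability
here is certified both spectrally and by perturbation/basin simulation, so
the collapse threshold is reported as ~0.021 rather than the nominal 0.019
one reads off the planar picture.

## Simulation oracle

`integrate` runs LSODA on the abundance form (defaults rtol 1e-9,
atol 1e-12, horizon 2000) in chunks of 50 time units, declaring convergence
only when the vector-field max-norm is below 1e-8 at two consecutive chunk
boundaries — a guard against premature exits during slow saddle passages.
`basin_census` samples initial frequencies uniformly on the open unit
square (boundaries are invariant manifolds and would bias a census of
interior basins) and densities log-uniformly over two decades below each
patch's carrying-capacity scale, deterministic under the seed. Converged
end states are matched to enumerated equilibria within a scaled distance of
1e-4; a converged state that matches nothing is surfaced as an
"unexplained attractor" — the census is thus a completeness check on the
enumeration, and on every built-in scenario the 500-start census finds
exactly the spectrally stable set. The census can flag, but not rule out,
non-equilibrium attractors; none arise in the built-in scenarios.

## Scenarios and the generator

The registry ships the printed parameter sets: sixteen one-way examples
(one per generic regime of a game pair), eight two-way examples, the
bifurcation template, two constant-payoff density illustrations (encoded as
games whose entries all equal the stated mean payoff, hence degenerate for
ESS classification and excluded from regime suites), and `case1-sixeq` —
the bistable-bistable pair at the weaker one-way rate c₁ = 0.1, the
package's own choice of a parameter set at which the one-way census attains
its maximum of six equilibria with four attractors (at c₁ = 0.5 the same
games have only two interior roots). `generate_regime_scenarios(seed)`
rejection-samples payoff entries from [0, 5] until each game pair hits each
of the 16 regimes, deterministically under the seed; these fixtures drive
the theorem checks, so passing them supports the claims across the generic
parameter space, not just at the printed examples.

## Numerical choices and limitations

* Boundary frequencies are snapped to exactly 0/1 within 1e-9 so kind
  labels stay discrete; ties in payoff comparisons return "degenerate"
  instead of a guessed classification.
* The interior grid search is complete only up to its resolution; roots
  closer than one cell to each other or to the boundary rely on the Newton
  polish pulling them in (the built-in scenarios' near-edge roots at
  q ≈ 0.001–0.003 are found at the default 201×201 grid, and censuses are
  cross-validated by the basin oracle). No completeness proof is attempted
  for the two-way case.
* Global-stability statements are supported only by finite basin censuses
  (500 seeded starts), never proved.
* Degenerate (tied) games are rejected by the classifier rather than
  resolved; the dynamics themselves still run and report marginal spectra
  where eigenvalues sit on the axis.
* Time units are abstract; all rates are per unit time and only ratios
  matter.
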