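# Methods

## Model structure

`landshift` simulates land-use/land-cover change on a regular lattice of
square cells. Each cell carries a compositional state: the percent of cell
area under each of six dynamic classes plus a static "others" class
(artificial surfaces, water, bare land) that never changes. For every valid
cell the fractions sum to 100; this invariant is enforced at I/O boundaries
and preserved exactly by the allocator.

A scenario couples three components per simulated year:

1. **Demand** — exogenous national targets. Each class's demand is linear
   between an initial and final endpoint: the annual change is the endpoint
   difference divided by the number of years, and the yearly series is the
   cumulative recursion. The recursion and the closed form
   `D(t) = L(t_i) + (t − t_i)·C` agree to machine precision, and the final
   iterate reproduces the printed endpoint to < 1e-6 km². Per-year
   overrides are possible through the config for non-linear trajectories;
   the default is linear.
2. **Potential** — a per-cell, per-class score in [−1, 1] expressing how
   much a cell's class fraction "wants" to change, computed as the spatial
   lag regression prediction minus current use and clamped. Prediction is
   conditional on the previous year's map (`ρ·W·y_{t−1} + Xβ`), not the
   reduced form `(I−ρW)⁻¹Xβ`: the potential is defined against the current
   landscape and yearly updates stay local. The surface is recomputed each
   year (dynamic potential), then damped by active restriction schedules.
3. **Allocation** — iterative, competition-mediated distribution of the
   demanded change (details below), converging when every class's national
   total is within `max_error` × study area of its demand.

## Spatial weights and the lag estimator

Queen contiguity, row-standardized, is the default neighborhood (rook is
available); invalid (outside-region) cells are excluded from the adjacency
and from all sums. Cell indexing is row-major with the origin at the
north-west corner; distances are centroid-to-centroid Euclidean in
projected km.

The spatial lag model `y = ρWy + Xβ + ε, ε ~ N(0, σ²I)` is estimated by
maximum likelihood with the likelihood concentrated in ρ: β and σ² have
closed forms given ρ, and the 1-D concentrated likelihood is maximised by
bounded search (tolerance 1e-8) over the admissible interval
`(1/λ_min, 1/λ_max)` given by the extreme eigenvalues of W. The
log-determinant `ln|I − ρW|` is evaluated exactly from the eigenvalue
spectrum: the row-standardized W = D⁻¹A is similar to the symmetric
D^{-1/2}AD^{-1/2}, so one symmetric eigendecomposition (cached on the
weights object) serves every likelihood evaluation and every refit on the
same lattice. Tests verify the result against a dense `slogdet`
implementation to 1e-6 and against OLS in the ρ = 0 limit.

Inference: the covariance of (β, ρ) is the inverse numerical Hessian
(central differences) of the full log-likelihood in (β, ρ, ln σ²);
p-values are two-sided normal. Pseudo-R² is the squared correlation
between observed and (conditionally) predicted response — the conventional
determination coefficient is not defined for this estimator, so the choice
is documented rather than canonical. AIC = 2k − 2ℓ with k counting the
intercept, driver coefficients, ρ and σ².

Driver screening is greedy Spearman pruning: pairs with |rho| above the
threshold (default 0.60) are visited in descending |rho| and the member
with the larger mean absolute correlation to all other candidates is
dropped (ties: the later candidate). Constant fields correlate with
nothing and are kept with a warning. Model selection fits every candidate
specification, keeps those whose driver coefficients all have p < 0.05,
and returns the minimum-AIC survivor; if none survives, the minimum-AIC
model is returned flagged non-compliant. The pseudo-R² ≥ 0.75 target is
recorded as a flag, not enforced per class — it is an average-across-uses
criterion. The p filter applies to driver coefficients only, not the
intercept or ρ: the filter exists to discard uninformative drivers.

Calibration in the engine is on levels of the class fraction at the
calibration year. One model per class per region is supported (synthetic
tests use a single region).

## Allocation algorithm

Demand in km² is converted to percent-sum units via the cell area so the
whole iteration runs in fraction space. Each year:

* the demand direction per class is the sign of (demand − current area);
  classes with exactly zero gap sit out. Classes with any nonzero gap stay
  in play even when already inside the convergence band — a class can only
  change against a counterparty in the same cell, so freezing near-target
  classes would strand the out-of-tolerance ones;
* candidate deltas are `potential × ITF_c`, kept only where the potential
  sign matches the class's demand direction;
* per-cell competition clips losses at the available fraction and gains at
  the cell's dynamic share, then scales down whichever side (gain or loss)
  requests more, proportionally to requested magnitudes, so deltas sum to
  zero within each cell; an optional per-cell cap on the summed anthropic
  fraction (a reduced stand-in for legal-reserve rules) additionally scales
  anthropic gains;
* ITF_c is updated multiplicatively,
  `ITF_c ← ITF_c · (1 + λ·d_c·(D_c − A_c)/max(|D_c|, floor))` with gain
  λ = 0.5 and the factor clipped to [0.1, 10] for numerical safety, and the
  candidate year is recomputed from the year-start map (non-compounding);
* convergence requires every class gap ≤ `max_error` × study area
  (default 0.5%); non-convergence raises an error carrying the report, or
  warns if the configuration accepts it.

The update rule is a reconstruction in the CLUE tradition — the reference
description of the iteration factor is verbal — and is validated by its
convergence behavior: equilibrium demand converges in one iteration,
symmetric inputs allocate uniformly, infeasible demand (a growing class
with no positive potential anywhere) errors out, and 50-year runs keep
every cell sum at 100 ± 1e-6 while meeting every year's demands. Because
iteration stops on entering the band, per-year totals track demand with a
lag bounded by `max_error`; for classes whose demanded change is smaller
than the band (forestry, at 0.67% of the dynamic area), the direction of
allocated change is not identifiable from a single run — only demands
distinguish it.

## Validation metrics

All metrics operate per class on fractional (percent) fields, not hardened
single-class maps, because the data model is compositional. For window
size w the grid is partitioned into w×w blocks (edge blocks partial — no
cell is discarded); observed change `Δreal = Σ(real_tf − real_t0)` and
simulated change `Δsim = Σ(sim_tf − real_t0)` are aggregated per block and

    NS_w = (1 − Σ_j |Δsim_j − Δreal_j| / (2 Σ_j |Δreal_j|)) · 100.

When no block shows observed change, NS is 100 if the simulation also shows
none, else 0 (the limiting behavior; avoids 0/0). Raw NS can be negative
when simulated change overshoots by more than twice the observed total;
both the raw and the [0, 100]-clamped value are reported. Window 1 scores
per-cell agreement; a simulation predicting no change at all scores exactly
50 there. The pattern fit is the same agreement statistic on the final
maps over all valid cells; the modified-areas fit restricts it to cells
whose observed change exceeds a threshold (default 0); with no such cell it
is reported as missing. Omission is the per-cell positive part of
(|Δreal| − |Δsim|) summed as percent of study area — observed change the
simulation failed to produce — and commission the converse.

## Synthetic study systems

The generator produces complete inputs with known ground truth: per-class
latent suitabilities follow the exact spatial-lag process
`z = (I − ρW)⁻¹(Xβ + ε)` (default ρ = 0.4, σ = 0.1) over driver fields in
the four categories of the reference database — a smoothed Gaussian random
field for water deficit, a noisy gradient for agricultural suitability, a
random field for large-farm share, and distance-to-random-features fields
for roads and urban centres — plus a random-blob protected-area mask. A
temperature-controlled softmax maps latents to fractions summing to the
dynamic share (100 minus a fixed "others" percent, default 7), which
guarantees the compositional invariants while preserving driver
monotonicity. Per-class log-share offsets anchor the mean composition at
the national 2000 shares (forest-dominated, forestry marginal); without
that anchoring, applying national relative change rates to an equal-share
landscape flips the direction of the weakly changing classes.

Scenario configurations for synthetic runs scale the landscape's own
initial areas by the national 2050/2000 change ratios and renormalize so
total dynamic area is conserved exactly. The true models handed to the
engine are the generator's lag parameters with intercepts anchored so each
class's spatial equilibrium lies one demanded-change beyond its endpoint
(the transition is half-complete at the end year). This keeps demand and
potential mutually consistent — in the reference application the
calibrated potential and the externally computed demand are consistent by
construction — and per-driver loadings that sum to zero across classes
keep per-cell equilibrium totals compatible with the dynamic share.
Without these properties long runs strand surplus area in cells where
every class is simultaneously above equilibrium, and allocation becomes
structurally infeasible; that failure mode is real (the engine reports it
as non-convergence) and remains reachable, e.g. by fully protecting the
cells that hold all remaining convertible land, or under the
afforestation-plus-contraction endpoint pattern on small grids.

What the generator does **not** emulate: Brazil's geography and biome
shapes, the real drivers' marginal distributions and cross-correlations,
observation error in the underlying maps, and any demand–allocation
feedback. Passing tests therefore demonstrate that the machinery is
correct and self-consistent — estimator recovery, conservation, metric
identities — not that the national maps would be reproduced; the published
national agreement figures require the real observed maps and driver
database and are out of scope here.

## Numerical choices and defaults

| parameter | default | meaning |
|---|---|---|
| `cell_side_km` | 10 | cell side, projected km |
| weights scheme | queen | row-standardized contiguity |
| Spearman threshold | 0.60 | max |rho| between retained drivers |
| p filter | 0.05 | driver-coefficient significance |
| pseudo-R² target | 0.75 | recorded as a flag (average-across-uses) |
| ρ search tolerance | 1e-8 | bounded 1-D concentrated ML |
| `max_error` | 0.005 | convergence band, fraction of study area |
| `max_iterations` | 1000 | per-year allocation iterations |
| `itf_gain` λ | 0.5 | multiplicative ITF update gain |
| others share | 7% | static class, synthetic default |
| softmax temperature | 1.0 | latent-to-fraction sharpness |
| synthetic scale | 50×50 | large enough for stable lag estimation, seconds-scale tests |
| protection level | 0.5 | default synthetic scenario (partial protection) |

Deterministic tie-breaks: class order (as listed in the class table) for
exact ties in competition; input order for Spearman-pruning ties. Degenerate
inputs: empty feature masks yield a sentinel distance field with a warning;
constant drivers survive screening with a warning; zero observed change
short-circuits NS as above. Ties, clamps and floors are all exercised in
the test suite.

Test and example problem sizes (16×16 to 50×50 lattices, 10–50 year runs,
20 recovery replicates) were chosen so the full suite runs in well under a
minute of numerical work per module while keeping the lag estimator's
sampling error far inside the asserted recovery bands.

## Known limitations

* The ITF update rule is a documented reconstruction; other rules
  (additive iteration variables, elasticity terms) would satisfy the same
  verbal description.
* Only lag models are fitted — no spatial-error or SARAR alternatives, no
  heteroscedasticity-robust inference.
* Allocation has no explicit transition matrix; any dynamic class may
  exchange with any other, subject to sign gating and the optional
  anthropic cap.
* Demand is strictly exogenous; allocation shortfalls do not feed back.
* Projection handling is metadata-only; grids are abstract lattices.
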