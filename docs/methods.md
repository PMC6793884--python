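# Methods

## Model

Phenotypes are points in ℝᵈ (d ≤ 5 in the shipped experiments).  The
ecology is logistic competition with a quartic single-humped carrying
capacity `K(x) = exp[−Σ (xᵢ − C)⁴/4]`, a multiplicative birth-rate cost
`β(x) = Π_{i≥2}[exp(−xᵢ²/2σ_β²)(1 − b) + b]` on every trait beyond the
first, and a Gaussian competition kernel of width σ_α.  Invasion fitness
of a rare mutant z against residents (y_r, N_r) is
`f(z) = β(z) − Σ_r α(y_r, z) N_r / K(z)`.  For a single resident with
`β ≡ 1` this reduces to the familiar two-phenotype form
`β(z) − α(x, z) K(x)/K(z)`; the multi-resident form is the one whose
z-gradient reproduces the closed-form two-dimensional expressions used as
test oracles, so it is taken as primary throughout.

Reference parameter values (used as defaults and in the experiments):
σ_β = 0.15, σ_α = 0.5, C = 1, b ∈ [0.75, 0.885] depending on the
experiment, τ_c = 1, Δx = 10⁻³, K₀ = 500, mutation s.d. 10⁻², D = 10⁻⁶.
All quantities are dimensionless; time is measured in units of the
per-capita birth rate at zero cost.

A note on the cost parameter: in this model the single-cluster "stall"
condition — the cost force `(x₂/σ_β²)e^{−x₂²/2σ_β²}(1 − b)` exceeding the
carrying-capacity pull `(C − x₂)³ β` somewhere on the path out of the
strip — fails for b above a critical value b* ≈ 0.857 (at σ_β = 0.15,
C = 1).  Above b* a lone cluster climbs into a new dimension immediately
and the dynamics resemble the cost-free control; the cost-gated
experiments therefore use b ≤ 0.85.

## Ecological equilibrium

Populations are quasi-static: at every evaluation of the evolutionary
right-hand side the linear system `Σ_j α(y_j, y_r) N_j = β(y_r) K(y_r)` is
solved, and while any component is non-positive the most negative cluster
is removed (competitive exclusion) and the system re-solved; removed
clusters have N = 0 and do not move.  Feasibility of the linear solution
is exactly the Lotka–Volterra condition for protected coexistence, so a
freshly split pair straddling a branching point keeps both halves while a
near-duplicate pair elsewhere immediately loses one member — this is what
makes failed splits collapse and successful ones proceed, without any
extra heuristic.  Exactly coincident phenotypes (distance < 10⁻¹²) are
merged before solving.  The solver was validated against long-time
integration of the logistic ODE system (relative agreement 10⁻⁶) and by
the residual per-capita growth rate at survivors (< 10⁻⁸).

## Adaptive dynamics engine

Clusters move along `dx_r/dt = N_r s(x_r)` with analytic gradients
(finite differences of the invasion fitness serve as a test oracle at
10⁻⁶ relative).  Integration uses adaptive RK45 (rtol 10⁻⁸, step capped
at 0.1) over intervals of τ_c; at each boundary, clusters closer than Δx
are merged at their population-weighted mean, one uniformly chosen
cluster is split into halves displaced ±(Δx/2)·u with u uniform on the
unit sphere (centroid preserved — whether one or both daughters move is
not constrained by the mechanism, and the symmetric choice keeps the
parent's centroid), and extinctions are pruned.  Runs are bit-reproducible
given the seed.  All experiments start from one cluster at
(0.9·C, 0, …, 0) at its equilibrium density — "near the capacity optimum"
made concrete.

With the quartic capacity the restoring force at the optimum is cubic, so
a split pair exactly at C always separates slowly no matter how wide the
kernel; genuinely *failed* diversification is seen at interior sites of a
saturated community, where neighbouring clusters hem the pair in.  The
merge-back test is built on that configuration.

## Expansion detection

A crossing of the acquisition threshold `x_k = 2σ_β` counts as an
expansion only if some cluster stays above the threshold continuously for
a persistence window (10 time units for cluster dynamics, 20 for the
individual-based model) and passes an escape level of 3σ_β on the way.
Stochastic runs produce transient excursions — blobs of ~2–5% of the
population that cross the threshold and collapse within ~10 time units —
and an instantaneous detector would report those instead of the
expansions that actually restructure the community.

In the adaptive-dynamics expansion run (b = 0.85) the first sustained
escape consistently occurs after the strip has reached four clusters
(ordering verified over 40 seeds), though at the moment of crossing the
strip typically shows three well-separated sites plus a transient split
pair; the reported cluster count at crossing is 4 in about two-thirds of
seeds and 3 otherwise, so aggregated results use the majority over 31
seeds.  In the individual-based run the count at crossing is lower still
(majority 3, often 2): the expanding site is reorganizing exactly at the
crossing moment, and demographic noise lets some runs hop the barrier
from an unsaturated two-cluster strip.  These are properties of the
estimator and of finite-population noise, not of the ordering mechanism,
which holds in the deterministic engine for every seed examined.

## Individual-based engine

An exact continuous-time event simulation: individual i gives birth at
rate β(x_i) and dies at rate `Σ_{p≠i} α(x_p, x_i)/(K₀ K(x_i))`.
Self-competition is excluded; including it would shift the monomorphic
balance point from K₀ + 1 to K₀ and, as a corollary of exclusion, the
last individual can never die, so true extinction is unreachable (the
code keeps a defensive extinction branch regardless).  Offspring inherit
the parent's phenotype plus an independent Gaussian offset of s.d.
σ_mut = 10⁻² per coordinate.  The per-individual competition load is
cached and updated in O(n) per event; an O(n²) recomputation is the test
oracle.  The inner loop is compiled (numba); a run is deterministic given
its seed.

## Density-field engine

The 2-D phenotype density obeys
`∂φ/∂t = φ[β − (∫α(y,·)φ(y)dy)/K] + D∇²φ` on the square [−0.4, 2.0]²
(128² nodes by default) — chosen so both the unacquired state 0 and the
optimum C sit ≥ 5σ_β inside the boundary — with no-flux boundaries,
explicit Euler at dt = 0.05 (the diffusion stability bound is checked;
at D = 10⁻⁶ the reaction term is the binding constraint), and the
competition integral evaluated as a zero-padded spectral convolution.
Negative densities produced by the reaction step are clipped to zero and
counted; in the shipped runs no clips occur.  The initial condition is an
isotropic Gaussian blob (width 0.05) at (0.9·C, 0.02) with the
monomorphic equilibrium mass; the small x₂ offset breaks the grid's
mirror symmetry.

## Observables

A phenotype has dimension `1 + #{i ≥ 2 : x_i > 2σ_β}` — acquired
coordinates count in any order, and the first coordinate always counts.
Per-dimension counts are smoothed with a centred 10-time-unit window.
Evolutionary speed is the population-weighted mean Euclidean norm of the
selection gradients.  Point clouds are clustered by single linkage at
threshold 0.15 (≥ 15× the mutation scale, ≲ ⅓ of the inter-cluster
spacing; components under 1% of individuals are discarded as transients —
chaining through stragglers can still merge neighbouring clusters
occasionally, which adds ±1 noise to instantaneous counts).  Density
fields are peak-counted after Gaussian smoothing (1.5 cells) with a
relative height floor of 0.1.

The "burst" diagnostic marks the first acquisition time of each dimension
k (the raw average dimension rises by 1/n at such events, so integer jumps
of the average itself do not exist in a multi-cluster community) and asks
for a local maximum of evolutionary speed within 5 time units exceeding
the median over the preceding 50 time units.

## Scaling of the shipped experiments

The burst experiment runs at d_max = 3 with b = 0.85, σ_β = 0.15, C = 1:
in the deep-stasis corner of parameter space (b = 0.8, σ_β = 0.16,
C = 0.9) first expansions take upwards of 3·10⁴ time units, so the
package's standard burst run uses the nearest parameter point where the
full staircase (dimensions 2 and 3, with their speed bursts) completes
within a few hundred time units.  The individual-based expansion runs cap
at 4000 time units and the PDE at 6000; all shipped runs finish in
seconds to a couple of minutes on one CPU.

## Known limitations

- Quasi-static exclusion is instantaneous; in reality near-neutral
  competitors coexist for times ~1/(εN).  This matters only for
  transient split pairs, which the merge rule resolves anyway.
- The PDE is implemented for d = 2 only (cost grows exponentially with d).
- Phenotypes are unbounded; the quartic capacity confines trajectories,
  but pathological parameter choices (σ_α ≫ 1 with b = 0) are untested.
- The competition kernel is symmetric; asymmetric competition between
  lineages of different complexity is outside scope.
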