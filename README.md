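# dimburst

Simulators of competition-driven increases in organismal complexity:
adaptive dynamics, individual-based, and density-field (PDE) realizations
of a logistic competition model in *d*-dimensional phenotype space.

## The scientific problem

Evolutionary increases in complexity — new metabolic capabilities, organs,
behaviours — tend to come in bursts separated by long stasis rather than by
gradual accumulation.  `dimburst` implements a minimal eco-evolutionary
model in which this pattern emerges from frequency-dependent competition:
acquiring a new phenotypic dimension carries a physiological cost (a lower
birth rate), so an isolated lineage is trapped at the base of that
dimension; but as diversification fills the already-occupied dimensions,
competitive pressure grows until it pushes a lineage over the cost barrier
into the empty dimension, where a fresh round of diversification begins.

The package is aimed at researchers in adaptive dynamics and
eco-evolutionary modelling who want a reproducible, tested implementation
of this mechanism in three complementary realizations.

## The model

A phenotype is a point **x** ∈ ℝᵈ.  Ecology is logistic competition set by

- carrying capacity `K(x) = exp[−Σᵢ (xᵢ − C)⁴ / 4]`, single-humped with
  its maximum at `x = (C, …, C)`, `C ~ 1`;
- birth rate `β(x) = Π_{i≥2} [exp(−xᵢ²/(2σ_β²))(1 − b) + b]` — the first
  trait is free, every further trait multiplies the birth rate by a factor
  that falls from 1 (trait at 0) to `b ≤ 1` (trait acquired), so `1 − b`
  is the acquisition cost;
- Gaussian competition kernel `α(y, x) = exp[−Σᵢ (xᵢ − yᵢ)²/(2σ_α²)]`,
  with `α(x, x) = 1`.

A rare mutant `z` in a community of resident clusters `y_r` with
equilibrium populations `N_r` (the stationary solution of
`dN_r/dt = N_r [β(y_r) − Σ_j α(y_j, y_r) N_j / K(y_r)]`) has invasion
fitness

```
f(z) = β(z) − Σ_r α(y_r, z) N_r / K(z),
```

and each cluster evolves along its selection gradient,
`dx_r/dt = N_r ∇_z f |_{z=x_r}`, with all derivatives coded analytically.
Diversification is a split/merge procedure: every `τ_c ≈ 1` time units a
random cluster is split into halves separated by `Δx ≈ 10⁻³`; pairs closer
than `Δx` at the next check are merged back, so splits only "take" under
disruptive selection.  A cluster counts as having acquired dimension *k*
when `x_k > 2σ_β`.

The same ecology drives an exact event-driven birth–death simulation
(individuals, mutation at birth) and a nonlocal reaction–diffusion
equation for the phenotype density (diffusion `D` standing in for
mutation).

## Worked example

`python examples/expansion_2d.py` runs the two-dimensional adaptive
dynamics from a single one-dimensional cluster and prints:

```
with acquisition cost (b = 0.85):
  four 1-D clusters reached at t = 12
  first sustained expansion at  t = 44
  clusters still in dimension 1 at that moment: 4

without cost (b = 1):
  first expansion at t = 1 (before any saturation)
```

With a finite cost the escape into the second trait dimension happens only
after the first dimension has filled with four clusters; removing the cost
makes the escape immediate.  The other examples show the same mechanism in
the other realizations, each printing what it computes:

- `examples/saturation_1d.py` — one-dimensional diversification saturating
  at exactly 4 clusters (positions `0.107, 0.768, 1.232, 1.893`);
- `examples/individual_based.py` — the stochastic simulator with
  `K0 = 500` individuals per unit carrying capacity;
- `examples/density_field.py` — the PDE developing 3 density peaks before
  1% of its mass escapes the strip;
- `examples/speed_bursts.py` — bursts of population-weighted evolutionary
  speed at each acquisition of a new dimension.

A thin CLI wraps the engines for shell use:

```
dimburst ad  --config run.yaml --seed 1 --out out/   # also: ibs, pde
dimburst analyze --in out/ad_trajectory.jsonl --out observables.csv
```

Config files are YAML mirroring the `ModelParams`/`ADConfig`/`IBSConfig`/
`PDEConfig` fields; every output file embeds its full configuration and
seed.

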