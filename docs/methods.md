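# Methods

## Model

A slice is a pair `(X, S)`: an `n × p` spot-by-feature expression matrix
and an `n × 2` coordinate matrix. Given slices at timepoints `t1` and `t2`,
the aligner seeks a non-negative coupling `Π ∈ R^{n1×n2}` minimizing

```
E(Π) = (1−α) Σ_{ij'} C_{ij'} Π_{ij'}                                (doublet)
     + α [ ½( Σ_{ij'k'} Π_{ij'}Π_{ik'} (M2_{j'k'})²
            + Σ_{ijk'} Π_{ik'}Π_{jk'} (M1_{ij})² )                  (triplet)
          + Σ_{ij'kl'} (M1_{ik} − M2_{j'l'})² Π_{ij'}Π_{kl'} ]      (quartet)
```

subject to the semi-relaxed constraint set: `Πᵀ1 = g2` exactly, and
`γ·KL(Π1 ‖ g1)` added to the objective with an entropy regularizer
`−ε·H(Π)`. Here `C` is the inter-slice expression distance matrix and
`M_i = normalize(C_i) ∘ normalize(D_i)` the merged feature-spatial matrix of
slice `i` (entrywise product of intra-slice expression and spatial
distances). Both marginals assign weight `1/n1` per spot, so `g2` is a
positive measure of total mass `n2/n1` and the growth vector
`ξ = Π1 − g1` sums to `(n2−n1)/n1` whenever the column constraint holds.

The three cost orders are complementary. The doublet matches expression
across slices. The quartet is a Gromov–Wasserstein term on the merged
geometry: because `M` scales feature distance by spatial distance, a region
whose cells keep their relative expression gradient may expand spatially at
much lower cost than under a purely spatial geometry. The triplet
penalizes predicting distant descendants for one ancestor (and vice
versa), regularizing the extra freedom the relaxed row marginal creates.
All quadratic terms are evaluated with `O(n²·n)`-matrix identities
(`⟨Π, Π(M2∘M2)⟩`-style contractions and the square-expansion of the
quartet); the `O(n⁴)` tensor sums exist only as test oracles. Because the
row marginal `r = Π1` is free, the `r`-dependent quartet pieces
`2(M1∘M1)r·1ᵀ` are retained in the gradient.

## Optimization

The outer loop is the standard fused-GW linearization: at iterate `Π_t`,
form `G_t = (1−α)C + α·∇E_M(Π_t)` and solve the linear semi-relaxed
entropic problem in `G_t`, repeating until the relative objective change
falls below `outer_tol` (default 1e-7, cap 200 iterations). Dual
potentials are warm-started across outer iterations.

The inner problem

```
min_{Π≥0, Πᵀ1=g2}  ⟨G, Π⟩ + γ·KL(Π1 ‖ g1) − ε·H(Π)
```

has the Gibbs solution `Π_ij = exp((f_i + h_j − G_ij)/ε)`. The column
potential update is exact (`h ← h + ε(log g2 − log colsum)`), the row
update is the KL-prox `f ← (γ/(γ+ε))·ε·(log g1 − logsumexp((h−G)/ε))`, all
in the log domain with stabilized log-sum-exp. The plain alternation
contracts at rate `γ/(γ+ε)` — arbitrarily slow when `γ ≫ ε` — so the fixed
point is accelerated with safeguarded Anderson extrapolation (memory 5) on
`f`: an extrapolated iterate is accepted only if it reduces the
fixed-point residual, otherwise the memory is restarted and the plain step
is taken. The accelerator changes only the path, never the fixed point.
Termination: column-marginal violation below `inner_tol` (default 1e-8,
cap 2000 iterations); a final exact column update makes the returned
coupling column-feasible to machine precision, which is what guarantees
the `Σξ` mass rule.

**Initialization.** The outer loop starts from the solution of the
doublet-only problem rather than the product coupling. The quadratic
merged term has spurious geometry-matching optima — on a 1D tissue whose
two cell-type blocks swap relative sizes, the mirror alignment is a strong
local optimum at large α because it avoids the spatial expansion — and the
product-coupling start falls into them, while the expression-driven start
(equally deterministic) does not. On designs where both starts converge to
the same basin the results are identical.

**Self-diagnostics.** The aligner records the objective trace; it is
non-increasing up to small fixed-point fluctuation near convergence, and
runs that show sustained increases or inner non-convergence carry warning
flags on the result rather than raising.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `alpha` | 0.5 | doublet vs merged-term balance, in [0,1] |
| `gamma` | 0.1 | KL strength tying the row marginal to `g1` |
| `epsilon` | 0.01 | entropic regularization (unit-mean-normalized costs) |
| `inner_tol` | 1e-8 | column-marginal violation at termination |
| `outer_tol` | 1e-7 | relative objective change at termination |
| `metric` | euclidean | expression distance (`euclidean`, `cosine`, `kl`) |
| `normalization` | unit_mean | distance rescaling before products |

All distance matrices are rescaled to unit (off-diagonal) mean before use,
so `α`, `γ` and `ε` are unit-free and defaults transfer across coordinate
and expression scales. `γ` is the knob that matters most: the KL cost of
the *true* growth pattern grows with how drastically type proportions
change, and `γ` must leave that cost well below the expression-matching
savings. At `γ = 0.1` the KL cost of the packaged designs' true growth is
~0.02–0.05 against expression savings of ~0.4; at `γ = 50` the penalty
(~9) would dominate and force near-uniform rows, suppressing all growth
inference. Larger `γ` (0.2+) visibly smooths `ξ` toward uniformity —
useful for noisy real data, at some cost in sharpness of the inferred
growth boundaries. `ε = 0.01` keeps couplings sharp enough for near-binary
type assignment while converging in tens to a few hundred inner
iterations; `α = 0.5` weights expression and geometry equally and is the
midpoint of the range over which behavior was verified (0.1–0.9).

## Growth and evaluation metrics

`ξ = Π1 − g1` (mass units; multiply by `n1` for cell units) and
`J = log(1 + n1·ξ)/Δt`, defined when no spot is fully extinct
(`1 + n1·ξ > 0`); `Δt` defaults to 1 when timepoints are untagged.

**Growth distortion.** Given cell-type partitions with per-type counts
`m1p, m2p`, the equal-share true growth is `γ_p = (m2p − m1p)/(m1p·n1)` and
the metric is `Σ_p Σ_{i∈type p} (ξ_i − γ_p)²`. When cell types transition
(or new types appear at `t2`), the target is redistributed by the
reverse-time, column-stochastic transition matrix induced by the coupling,
`T_pq = (n1/m2q)·Σ_{i∈p,j'∈q} Π_{ij'}`; algebraically the redistributed
target equals the within-type mean of `ξ`, so the metric becomes the
within-type sum of squared deviations — the minimum achievable under *any*
column-stochastic transition, which the test suite verifies against random
alternatives. A transition graph keeps off-diagonal entries above a
threshold (default 0.20), self-loops omitted.

**Migration.** `(1/n2) Σ_j' Σ_i (Π_{ij'}/c_{j'}) ‖s_i − φ(s'_{j'})‖²` with
columns normalized to conditional ancestor distributions and `φ(z) = Qz − h`
the coupling-weighted Procrustes rigid map (SVD of the weighted
cross-covariance; reflections allowed by default since only orthogonality
is assumed, `allow_reflection=False` restricts to rotations). Column
normalization makes the metric a proper expectation under "sample a
descendant uniformly, then an ancestor from its conditional", and re-fitting
`φ` makes it invariant to rigid motions of either slice.

## Synthetic designs

The generators emit the study conditions used throughout the tests, with
ground truth. Both have two cell types, A and B, whose proportions change
sharply between timepoints while total counts stay equal — so any method
that matches shapes or conserves per-spot mass must fail, and correct
alignment requires discovering growth.

**1D.** 101 spots at integer positions; A occupies the left block (30
spots at `t1`, 60 at `t2`), B the rest (71 → 41). Features are
8-dimensional, four coordinates per type (disjoint support): two trace
`(cos θ, sin θ)` with `θ = λ·π/2` linear in the spot's fractional position
`λ` within its type block, two are constant 1. Equal fractional position
⇒ identical features across timepoints; the design is noiseless.

**2D.** 988 spots on a triangular lattice (spacing 0.95) trimmed to an
axis-aligned ellipse (semi-axes 19 and 13) by ranking points by elliptical
radius with a deterministic tie-break — the count is exact by
construction. A vertical boundary splits A (right; 240 → 726) from B
(left; 748 → 262), moved between timepoints so the per-type counts are
exact. Each spot's noiseless feature is the bilinear blend
`λx·f_x,right + (1−λx)·f_x,left + λy·f_y,top + (1−λy)·f_y,bottom` of four
per-type corner vectors, with `(λx, λy)` the min-max-normalized position
inside the spot's own type region at its own timepoint — the invariant
ancestor coordinate. The corner vectors are scaled unit basis vectors
(scale 3, disjoint support per type, pairwise distance `3√2`). The scale
fixes what the noise grid σ = 0.1…0.8 *means*: i.i.d. per-dimension
Gaussian noise at σ = 0.8 produces pairwise noise distances (~3.2)
comparable to the inter-type contrast (~4.2), so alignment quality
degrades toward the end of the grid and not before — the regime the
method is meant to be exercised in. Truth objects record per-spot `(λ)`
coordinates, per-type true growth, and two reference couplings: the
within-type-uniform coupling (exactly the equal-share growth; zero
distortion by construction) and the nearest-`λ` hard assignment (the
discretization floor a spot-to-spot matching can achieve).

**What the simulations do not model:** count noise (features are
continuous with Gaussian perturbations, not sequencing counts), batch
effects between timepoints, spatial deformation of the coordinate frame
(both slices share one lattice), partial overlap, and more than two cell
types. Passing on these designs shows the solver discovers growth from
geometry and expression alone; it does not certify performance under real
Stereo-seq noise or complex type hierarchies.

## Numerical notes and edge cases

- Ties in the lattice trim and type-boundary placement are broken
  lexicographically (elliptical radius, then x, then y; boundary by largest
  x, then y), making the generators bit-reproducible across runs.
- `merged_matrix` rejects all-zero factors (normalization undefined);
  slices with constant expression therefore need `normalization="none"`.
- Zero columns in a coupling are skipped (with a warning) by the migration
  metric; empty types at `t2` are dropped from transition matrices.
- Collinear coordinates make the Procrustes cross-covariance rank-deficient;
  a warning is emitted and one completing rotation returned.
- The balanced large-`γ` limit is only meaningful when `n1 = n2` (the hard
  column mass `n2/n1` must match the row target mass 1).
- Extinct spots (`ξ = −1/n1`) have no defined growth rate; `growth_rate`
  raises and names the spot.

## Problem sizes

The packaged verification runs use the full designed sizes: 101-spot 1D
pairs across nine α values (seconds) and 988-spot 2D pairs at σ ∈
{0.1, 0.4} (tens of seconds each on one CPU). Dense `O(n²)` memory is used
throughout; slices up to a few thousand spots are comfortable, beyond
which the `n1·n2` log-domain kernels dominate.

## Known limitations

- The fused-GW outer loop solves a non-convex problem; only local
  convergence is guaranteed. The expression-first start removes the known
  mirror-flip trap, but adversarial geometries may hold others.
- No ε or γ annealing is performed.
- Two slices only; multi-timepoint trajectories must be stitched pairwise.
- Growth inference attributes all row-mass deviation to growth/death;
  segmentation artifacts or capture-efficiency gradients in real data would
  be absorbed into `ξ`.
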