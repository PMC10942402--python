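# stoat

**S**patio**T**emporal **O**ptimal-transport **A**lignment **T**ool: aligns
spatially resolved transcriptomics (SRT) slices taken at two developmental
timepoints, and infers per-spot growth, death and cell-type transitions from
the alignment.

## The problem

SRT assays measure gene expression at thousands of spatially indexed spots
in a tissue section. When sections are taken at successive developmental
timepoints, a correspondence between the two spot sets describes which
early spots are the ancestors of which later spots. Developing tissue
grows, shrinks and differentiates, so the correspondence is many-to-one and
mass is *not* conserved per spot — assumptions that break classical
balanced optimal-transport alignment, which forces every spot to keep
exactly its share of mass and prefers matching identical shapes.

`stoat` solves a **semi-relaxed entropic optimal transport** problem: with
uniform weights `g1 = 1/n1` over the `n1` early spots and weight `1/n1` on
each of the `n2` late spots,

```
min_Π  E(Π) + γ·KL(Π1 ‖ g1) − ε·H(Π)    s.t.  Πᵀ1 = g2,  Π ≥ 0
```

Every later spot must be fully explained (hard column constraint), but an
earlier spot may send more or less than its share of mass (KL-penalized row
marginal). The **growth vector** `ξ = Π1 − g1` is then a per-spot mass
flux: `ξᵢ > 0` means spot *i*'s lineage expanded, `ξᵢ < 0` that it
contracted, and `Σξ = (n2−n1)/n1` always. A per-spot growth *rate* is
`J = log(1 + n1·ξ)/(t2−t1)`.

The transported cost `E(Π)` combines three orders of interaction:

- **doublet** `(1−α)·Σ C_ij Π_ij` — expression distance between one spot
  from each slice;
- **triplet** — two descendants of one ancestor (or two ancestors of one
  descendant) should be close in the merged feature-spatial geometry;
- **quartet** — a Gromov–Wasserstein comparison of spot pairs under the
  merged geometry `M = C_intra ∘ D_intra` (entrywise product of intra-slice
  expression and spatial distances), which tolerates tissue expansion that
  a purely spatial geometry would penalize.

Alignment quality is measured by two metrics: **growth distortion** (sum of
squared differences between `ξ` and the per-type growth implied by
cell-type counts, minimized in closed form over reverse-time cell-type
transition matrices) and **migration** (coupling-weighted mean squared
displacement after weighted-Procrustes rigid registration).

## Worked example

The package ships the two synthetic designs used to validate the method: a
1D pair of 101-spot slices where cell type A doubles (30→60 spots) while B
shrinks (71→41), and a 2D pair of 988-spot elliptical slices (A 240→726,
B 748→262) with Gaussian feature noise.

```python
from stoat import (simulate_1d, align, SolverConfig, growth_vector,
                   CellTypePartition, growth_distortion_with_transitions,
                   migration_metric, type_concordance)

s1, s2, truth = simulate_1d(seed=0)
result = align(s1, s2, SolverConfig(alpha=0.5))
gv = growth_vector(result.pi)
p1 = CellTypePartition.from_labels(s1.labels)
p2 = CellTypePartition.from_labels(s2.labels)
dist, tm = growth_distortion_with_transitions(gv, result.pi, p1, p2)

print(f"type concordance: {type_concordance(result.pi, s1.labels, s2.labels):.4f}")
print(f"growth distortion: {dist:.3e}")
print(f"sum(xi) = {gv.xi.sum():.4f}")
```

prints

```
type concordance: 1.0000
growth distortion: 1.305e-03
sum(xi) = -0.0000
```

All coupling mass links spots of the same cell type; the inferred per-spot
growth is close to the true equal-share growth (a uniform, growth-blind
coupling scores 4.2e-3 on the same design); and the flux sums to zero
because the two slices have equally many spots even though type proportions
changed drastically. The induced transition matrix is the 2×2 identity: no
spurious cell-type transitions are inferred.

The same pipeline is available from the shell:

```
stoat simulate --design 1d --seed 1 --out sim/
stoat align --slice1 sim/slice1_expression.csv --coords1 sim/slice1_coords.csv \
            --slice2 sim/slice2_expression.csv --coords2 sim/slice2_coords.csv \
            --out aln/
stoat eval --pi aln/pi.csv --labels1 sim/slice1_labels.csv \
           --labels2 sim/slice2_labels.csv --coords1 sim/slice1_coords.csv \
           --coords2 sim/slice2_coords.csv --out eval/
```

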