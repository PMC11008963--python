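# Methods

## Mechanical model

The mandible is modeled as a small-displacement, linear-elastic solid meshed
with ten-node quadratic tetrahedra (TET10; 4 corner nodes plus one node per
edge, ordered 0-1, 1-2, 2-0, 0-3, 1-3, 2-3). Each element belongs to exactly
one of four anatomical regions — masticatory margin (MM), blade (BLADE),
dorsal and ventral articulation (DMA, VMA) — and each region carries one
isotropic material (Young's modulus E, Poisson's ratio ν). ν = 0.3 in every
default material, a common choice for insect-cuticle FE work. Biting is
static: the "strike" is represented, like the impact it stands for, as a
static nodal load, and no contact, damping or material nonlinearity is
modeled.

Units are chosen so that matrix entries stay well scaled at specimen scale:
lengths in µm, forces in µN, E supplied in GPa and converted to 10³ MPa
internally; stresses then come out in MPa (µN/µm² = MPa). The standard total
bite load of 100 000 nN enters as 100 µN.

### Discretization and solution

- Element stiffness uses the 4-point degree-2 Gauss rule, exact for
  straight-edged quadratic tetrahedra; tests compare against an independent
  dense assembly at the 5-point degree-3 rule.
- Element stress is the tensor at the centroid (single evaluation point),
  giving one effective von Mises value per element,
  σ_vM = √(½[(σxx−σyy)² + (σyy−σzz)² + (σzz−σxx)²] + 3(τxy²+τyz²+τzx²)).
  Centroid versus Gauss-point averaging differs far below the granularity of
  the volume-weighted statistics downstream.
- Dirichlet constraints are enforced by system reduction (row/column
  elimination), so fixed nodes are at exactly zero displacement; prescribed
  non-zero displacements are supported for verification patch tests.
- Solver: sparse LU (SuperLU with minimum-degree ordering on KᵀK's pattern)
  up to 200 000 degrees of freedom, Jacobi-preconditioned conjugate
  gradients (rtol 1e-10) above. Within one E treatment all four scenarios
  share one factorization: pressure bites, which additionally pin the
  engaged tooth tips, are solved from the strike factorization by block
  elimination (a Woodbury-style constraint update with batched triangular
  solves), which is exact and verified against the direct solve.
- A node appearing in both a fixed set and a force set is an error, not a
  silent precedence.

### Biting scenarios

Strike: the total load, split equally across the contact tip node set
(apical tooth tip, or the tips of the remaining teeth for a margin bite),
with DMA ∪ VMA fixed. Pressure: the load split equally across the apodeme
patch, with DMA ∪ VMA and the contact tip set fixed. Equal per-node splitting
is the least-informative reading of "a nodal force on the tips"; the
verification problems instead use work-equivalent (consistent) face
tractions, because equal splitting is an inconsistent load for quadratic
faces and pollutes closed-form comparisons.

Load directions are not derivable from the mesh alone and are explicit
configuration: strike forces default to (0, 0, −1), the bite-closing axis
normal to the synthetic blade plane (the articulation axis lies in-plane, so
closing motion at the teeth is out-of-plane); the pressure (muscle) pull
defaults to (−1, 0, 0), from the apodeme insertion toward the head.

The homogeneous treatment assigns the blade's (E, ν) to all four regions;
the heterogeneous treatment leaves the per-region map untouched. With force
loading and zero-displacement constraints the homogeneous stress field is
independent of the E value (verified to 1e-10), so treatment contrasts
measure redistribution only.

## The intervals statistic

1. Per simulation, the ⌈0.02 n⌉ highest-σ_vM elements are removed (stable
   sort, ties broken by element order), suppressing the artificially high
   values at point loads and constraints.
2. Stresses are log-transformed (natural log; the base only shifts the axis
   affinely and cannot affect min/quantile-anchored intervals). Exact zeros,
   possible in synthetic fields, are floored to 1e-3 × the smallest positive
   value and this is the only data edit.
3. Thresholds are pooled across all simulations: the lower threshold is the
   pooled minimum and the upper threshold the pooled element-count-weighted
   75th percentile, so the open-ended top interval holds the 25 % highest
   *values* (not volume). Pooling makes interval j mean the same stress range
   in every row, which the PCA comparison requires; a per-simulation variant
   is available for sensitivity checks.
4. N−1 equal-width intervals partition the thresholds (left-closed,
   right-open; a value exactly at the upper threshold closes the last body
   interval), plus the top interval. Row entries are volume fractions of the
   retained elements, so every row sums to 1 to machine precision.
5. PCA standardizes columns (zero-variance columns are dropped and
   recorded) and uses an SVD; scores are tested against a dense
   eigendecomposition of the correlation matrix. Scaled PCA is the default
   (matching the common default of PCA software); unscaled is available.
6. The interval count is selected over the ladder (5, 10, 15, 25, 50, 75):
   for each consecutive pair, PC1 and PC2 scores are regressed against the
   next count's scores (R² is invariant to PCA sign flips); the chosen N is
   the left member of the first pair whose mean R² fails to exceed the
   previous pair's by more than ε = 0.01 — the point where R² stops
   increasing — or the last candidate if it keeps rising. The ε tie-break
   operationalizes a qualitative stopping idea and is configurable.

## Statistics conventions

- Mann–Whitney W is the first-sample U (pooled rank sum of x minus
  n₁(n₁+1)/2), equal to #(xᵢ > yⱼ) + ½#(xᵢ = yⱼ); on element-scale samples
  this is the only convention whose magnitude (~n₁·n₂) matches W values of
  order 10¹⁰ reported for full-size meshes. Exact enumeration below
  n₁·n₂ = 10⁴ without ties, tie- and continuity-corrected normal
  approximation otherwise. All tests are two-sided.
- Kruskal–Wallis uses the tie-corrected H with a χ² approximation
  (df = k−1); all-identical data are reported as degenerate, not H = 0.
- Dunn's post-hoc z uses pooled mean ranks with the tie term Σ(t³−t), and
  Bonferroni adjustment m·p with m = k(k−1)/2; the two-group case satisfies
  z² = H, which the tests check.
- Spearman matrices are pairwise-complete with average ranks; constant
  columns or pairs with fewer than 3 complete observations are reported as
  missing (NaN), never as 0. Below-noise EDS readings load as missing.

## Synthetic specimen

The generator defines the study conditions for all tests; it is not meant to
be anatomically accurate.

**Mesh.** A linearly tapered, extruded blade (default 600 × 420 × 60 µm,
taper 0.45) built on a structured grid, each cell split into six tetrahedra,
then promoted to TET10 (node sets gain the mid-edge nodes of member edges).
The masticatory margin is the +y lateral free edge: over the distal 60 % of
the blade it carries n_teeth = 7 triangular teeth (the most distal is the
apical tooth) and a 70 µm band of elements re-labeled MM. DMA and VMA are
patch neighbourhoods of two basal points at ±0.4 × base width, the apodeme
patch sits between them on the basal edge. Margin-bite tip sets contain the
teeth *except* the apical tooth, which degenerates to the apical set when
n_teeth = 1. Placing the margin along the side edge — rather than as a
distal strip — matters mechanically: a distal strip sits in series with the
blade, making the load path nearly statically determinate and the stress
field nearly E-insensitive; the real margin runs alongside the blade, in
parallel over the load path from the teeth to the articulations, which is
exactly what lets a stiff margin take over load from the soft blade. Mesh
generation is a pure function of its parameters; the seed is provenance
only.

**Materials.** Default E of 6.0 / 3.0 / 4.0 / 4.5 GPa for MM / BLADE / DMA /
VMA with ν = 0.3. These preserve the measured ordering (margin stiffest,
blade softest) but are illustrative placeholders, not measured values —
absolute stress magnitudes require a measured material table (normalized and
rank-based outputs do not).

**Site tables.** 395 sites by default (99/99/99/98 across the four regions),
each with hardness H, modulus E and 13 atomic-% columns (P and Pt share a
column because their spectral peaks overlap). Columns are drawn from a
Gaussian copula (Spearman targets converted by r = 2 sin(πρ/6); the target
matrix must be positive semidefinite or generation fails naming the columns
involved) with per-region log-normal marginals — positive, right-skewed, a
reasonable family for such measurements. Default medians encode the regional
orderings (E, H: MM > VMA > DMA > BLADE; Zn, Cu, P+Pt enriched in the
margin, then DMA/VMA, lowest in the blade; Ca, Mg, Na, S flat). Default
correlation targets are the reported study coefficients (E–H 0.92, Zn–H
0.70, Zn–E 0.77, P+Pt–E 0.54, Cu–E 0.50, Zn–P+Pt 0.69, Zn–Cu 0.64, F–K
−0.51, F–Mn −0.54, F–Mg 0.62, K–Cl 0.50, S–Ca 0.67) plus seven explicitly
documented consistency fills (e.g. Cu–H 0.45) required for positive
definiteness. Because the copula correlation applies within regions, pooled
sample correlations exceed the targets for columns with regional gradients
(region separation adds concordance) — parameter-recovery tests therefore
use homogeneous marginals, under which pooled Spearman estimates the copula
parameter directly (±0.03 at n = 4000).

**Indent averaging** keeps readings at 600–1000 nm penetration depth (the
configured window) and averages them to one H and one E per site.

## What the synthetic data do and do not show

Passing tests demonstrate that the pipeline recovers the structure the
generator puts in: regional orderings, copula correlations, and the
parallel-load-path heterogeneity effect (margin median stress up, blade
down, under the heterogeneous treatment, p < 0.001 on ~14 000-element strike
simulations). They do not certify anatomical stress magnitudes: the real
mandible's curvature, thickness gradients, measured E values and mesh
refinement near E transitions are all absent. Real per-site tables, interval
profiles and element tables can be loaded through
`read_supplementary_table` for analysis with the same machinery.

## Problem sizes and numerical tolerances

The test suite and the acceptance script use a ~3 800-element mandible for
end-to-end checks and a ~13 700-element (≈66 000 dof) mandible for the
study-scale heterogeneity contrast and pipeline quantities; solver
verification uses bars and slender beams of a few hundred to a few thousand
elements. Tolerances: patch test 1e-10 absolute on displacement; axial bar
2 % and cantilever 5 % of the Euler–Bernoulli closed forms (consistent end
tractions; the beam tolerance absorbs shear and 3-D effects); force balance
1e-8 relative; E-scaling invariance 1e-10 relative; profile row sums 1e-12;
copula recovery ±0.03 at n = 4000; Kruskal–Wallis type-I rate in
[0.03, 0.07] at α = 0.05 over 2000 seeded replicates.

## Known limitations

- Linear elasticity only: no contact, impact transients, viscoelasticity or
  damage; "strike" is a static surrogate.
- Point-load singularities at tip nodes are handled statistically (the 2 %
  trim), not by load smoothing.
- The structured-grid geometry cannot represent curved articulation condyles
  or tooth cusps; patches are node neighbourhoods.
- Mesh I/O covers the legacy ASCII VTK unstructured-grid dialect and a
  subset of Abaqus INP (*NODE, *ELEMENT C3D4/C3D10, *ELSET, *NSET); meshes
  are assumed to be in µm (file metadata cannot always declare units, so
  absolute stresses require knowing the mesh unit).
- Dunn's test uses the normal approximation; very small groups should be
  interpreted accordingly.
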