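# Methods

## Model

Head capsules are idealized as 2D plane-stress continua of unit thickness:
the full-face outline bounds a homogeneous, isotropic, linear-elastic domain
(insect cuticle, E = 2.75 GPa = 2750 MPa, ν = 0.3). Working units are mm, N
and MPa (N/mm²), which are self-consistent at unit thickness.

The head frame is fixed by convention: midline along the vertical axis,
mandibular (base) margin at the bottom. Loads emulating the mandible-closing
muscle are concentrated nodal forces on two lateral-margin arcs, inclined
45° from the vertical midline, pointing medially and toward the base; the
total per side is the side load, divided equally over that side's loaded
nodes (no traction profile is imposed). Displacements are fixed to zero in
both directions on two base-corner arcs, approximating mandible reaction
forces during a bite. Left/right arcs are mirror-symmetric in arc-length
extent and carry the same number of nodes (the larger set is trimmed from
its arc-interior end when a mesh is asymmetric).

The arc extents are not physical constants; they are exposed as a
`RegionSpec` with defaults of 20 % of the perimeter per lateral load arc and
5 % per corner constraint arc. Arc centres are found from scale-free vertex
extremes: lateral arcs centre on each side's widest point within the
mid-height band (30–80 % of head height), corner arcs on the bottom-left /
bottom-right extremes with the vertical coordinate double-weighted so
rounded (minor-like) heads keep the corner arcs clear of the load arcs. An
orientation guard flags outlines whose bottom quarter-band is > 1.10× wider
than the top band as upside down; a featureless rounded outline is accepted
in either orientation because the two are geometrically indistinguishable.

### Load normalization

The largest-area model is the reference and carries 1 N per side; every
other model receives `F = F_ref * sqrt(A_model / A_ref)`. For plane models
of unit thickness, scaling the geometry by k and the load by k leaves the
stress field pointwise unchanged (verified as a solver property test at
1e-6 relative), which is exactly the invariance that makes stress
distributions comparable across head sizes. This square-root rule also
reproduces all nine published non-reference side loads to the printed two
decimals from the published areas alone.

## Discretisation

Elements are 6-node straight-sided quadratic triangles (CPS6-style: corner
nodes plus midside nodes at edge midpoints). Straight sides keep the
Jacobian affine and the element exact for the 3-point interior Gauss rule;
boundary fidelity is obtained by refinement, not curved edges. Stiffness is
assembled sparse (COO→CSR); constraints are applied by row/column
elimination so fixed displacements are exactly zero; the sparse direct solve
must meet a 1e-8 relative residual. Stresses are sampled at element
centroids (the per-element table values); principal stresses come from the
Mohr-circle closed form and the plane-stress Tresca equivalent is
max(|σ₁|, |σ₂|, |σ₁−σ₂|) with σ₃ = 0. Nodal (probe) values are arithmetic
averages over adjacent elements.

### Mesher

No constrained-triangulation library is assumed: the mesher resamples the
boundary polygon at the target edge length (true corners, turn angle > 25°,
are always kept; chords whose sagitta against the underlying polygon
exceeds 0.3 % of area/perimeter are split further, keeping the meshed area
within 0.5 % of the outline area at any density), seeds the interior with a
hexagonal lattice kept 0.7 edge lengths clear of the boundary, applies four
Laplacian smoothing passes, takes the Delaunay triangulation, removes
triangles whose centroid lies outside the polygon, and upgrades to
quadratic with globally deduplicated midside nodes. The lattice is centred
on the bounding-box midline so mirror-symmetric outlines get
mirror-symmetric seeds. There is no randomness anywhere: the same outline
and density always produce the same mesh. Typical minimum corner angles on
head outlines are 27–31° (a 20° quality gate is available).

### Mesh density and convergence

Mesh density is parameterized by target edge length. The published study
reports only final element counts (~80–85k per head); matching those counts
is explicitly not attempted — tests run at roughly 0.5–5k elements. The
convergence protocol walks a coarse-to-fine ladder of densities and, for
each consecutive pair, compares nodal Tresca stress at three fixed material
points; the first pair with all three relative changes below 2 % (taken
against the finer member) selects its coarser member. Default probes sit at
the area centroid and 60 % of the way from the centroid toward the widest
lateral point and toward the vertex: interior points, because stress at the
loaded boundary nodes themselves is dominated by the concentrated nodal
forces and sharpens indefinitely under refinement. Probe values are
linearly interpolated at the exact material point rather than mapped to the
nearest node — at desk-scale densities, nearest-node sampling adds position
jitter of order the edge length, which masks genuine field convergence.

## The intervals method

1. Per model, remove the ceil(2 % · n) highest-stress elements (ties broken
   by element id, so filtering is deterministic). The filter counts
   elements, not area.
2. Transform stresses to natural logarithm.
3. Upper threshold T = the 98th linear-interpolation percentile of the
   pooled transformed stresses, so the last interval holds only the top 2 %
   of all simulations' values. The lower bound is the pooled post-filter
   minimum; values below it (possible when a scheme is reused on new data)
   are clamped into the first interval and logged.
4. With N intervals, the first N−1 are equal-width on [lower, T) and the
   last is [T, ∞). Element areas are summed per interval and normalized per
   model (rows sum to 1).
5. PCA on the models × intervals matrix, variables centred and standardized
   to unit variance (zero-variance intervals are dropped with a warning; a
   covariance-based PCA is available behind a flag).
6. Interval-count selection over candidates {5, 15, 25, 50, 75}: for each
   consecutive pair, PC1 (and PC2) scores of the smaller count are
   regressed on the larger; the pair score is min(R²_PC1, R²_PC2). The
   selected count is the smaller member of the first pair at which the
   score stops increasing, or the first candidate when the first pair is
   already at R² = 1; if the score rises through the last pair, the largest
   candidate is returned with a warning.

## Statistics

Kruskal–Wallis uses midranks with the standard tie-correction in H, df =
k−1, chi-square p. Dunn post hoc z-tests use pooled midranks with the tie
term subtracted from the null rank variance; two-sided p-values are
multiplied by the number of pairs and capped at 1. Sculpture categories
(ordinal 0–3, one row per species × subcaste) are tested with a Pearson χ²
(no continuity correction) on the 2 × 4 subcaste-by-category table
(df = 3), with per-cell standardized-residual post hoc tests
Bonferroni-corrected over the 8 cells — the exact cell test of the original
tooling is not documented, so standardized residuals are used and flagged.

## Synthetic data

The outline generator draws a radius-modulated closed curve r(θ) with
Gaussian angular bumps for posterolateral lobes ("heart-shapedness"), a
vertex notch, and a fixed mild base flattening, plus optional low-order
Fourier noise; the curve is scaled anisotropically to the requested
width/height ratio (exact) and uniformly to the requested area (exact), so
generated outlines always pass geometry validation. With zero noise the
outline is midline-symmetric to machine precision. Cohorts draw majors from
width/height 1.15–1.35 with lobes 0.15–0.30, minors from 0.80–0.95 with
lobes ≤ 0.05, and areas spanning the 0.14–3.5 mm² magnitudes of real worker
heads. What this generator does *not* emulate: real digitized outline
noise, inter-species allometry, or any statistical match to measured
*Pheidole* shape variation — green tests establish that the pipeline
machinery is correct on head-*like* geometry, not that it reproduces any
particular species.

Element-stress tables are drawn log-normal per model (default log-scale
σ = 0.8, locations near ln 0.45 MPa, 5000 elements), giving the heavy right
tail that motivates the top-2 % filter; areas are log-normal with mild
spread. Both generators are pure functions of (params, seed).

## Numerical choices

- 3-point Gauss integration (degree-2 exact): exact stiffness for
  straight-sided quadratic triangles with constant material.
- Sparse direct solve (SuperLU); singular reduced systems (missing
  constraints) are reported as free rigid-body modes.
- Percentiles use linear interpolation between order statistics.
- The 2 % filter's tie-break (element id) and the stable sort make the
  whole chain bit-reproducible; reruns of a pipeline config are identical
  down to the CSV outputs.
- The cantilever benchmark converges to the plane-stress continuum
  solution, which sits ~0.6 % above Euler–Bernoulli for a 10:1 strip (shear
  deflection and clamped-edge effects), so its error plateaus there rather
  than at zero; the 5 % acceptance bound is met at every tested density.

## Qualitative shape contrast at desk scale

The wide/heart-shaped vs narrow/rounded comparison is asserted on computed
area fractions: within a lateral-margin band (|x| > 60 % of half-width,
25–85 % of head height), the wide shape keeps a larger fraction of its
element area in the top fifth of the interval range; and of the area in
those top intervals, the narrow shape concentrates a larger fraction within
0.15 head heights of the base-corner constraint nodes. The top-fifth slice
is used rather than the upper half because at desk-scale densities with
concentrated nodal loads the entire loaded margin sits above mid-range for
both shapes; the ordering is stable for any top-slice between 3 and 7 of 15
intervals.

## Known limitations

- No geometric or material nonlinearity, no contact, no dynamics, no 3D,
  no cuticle-thickness or material heterogeneity.
- Concentrated nodal loads make stresses *at the loaded nodes*
  mesh-dependent (hence interior convergence probes and the top-2 % filter).
- The published per-species stress fields are not reproducible from
  scratch: the original vectorized outlines are not archived, so solver
  acceptance is property-based (patch test, equilibrium, beam benchmark,
  symmetry, scale invariance) rather than value-based.
- The supplementary per-element tables are needed to reproduce the
  published PCA percentages, H statistic and sculpture χ²; the dedicated
  acceptance test runs only when CSV exports are provided under
  `data/supplementary/` (`element_stress.csv`, `element_area.csv`,
  `sculpture.csv`).
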