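# Methods

This note documents the models, conventions and numerical choices behind
`graymorph`, and what its validation on synthetic cells does and does not
establish about real reconstructions.

## Input model and preprocessing

A reconstruction is a rooted tree of SWC nodes (position in µm, radius in
µm, integer type code). Exactly one root (parent −1) is required; ids may
be arbitrary but unique, and parent-before-child ordering is not assumed.
Both spaces and tabs separate columns; `#` and blank lines are ignored;
columns beyond the seventh are ignored with a warning. Structural defects
raise distinct exceptions (duplicate id, dangling parent, cycle, malformed
line, not-exactly-one root). Writing renumbers nodes 1..N preorder and
prints 17 significant digits so read∘write is the identity.

Axons (type 2) are removed with their whole subtrees: axonal
reconstructions are typically absent or truncated, so all projection
statistics refer to dendritic (or glial) processes.

Spine removal has no standard criterion, so the package declares one: a
terminal side branch is a spine when its path length is ≤ 3 µm **and** its
mean radius is ≤ 0.3 µm **and** it attaches to a node where the dendrite
continues. The joint predicate keeps genuine short terminal tips; both
thresholds are parameters. Nodes type-coded as spines (via
`metadata['spine_type_codes']`) are always removed.

Quality control mirrors the inclusion rules used for public
reconstructions: connectivity, positive radii, non-zero variance on all
three axes (a flat trace is 2D), and a constant-dendritic-radius flag —
identical radii signal a nominal diameter rather than a measured one,
which invalidates all radius-dependent descriptors.

## Structural descriptors

The soma is the node set within the root node's nominal radius of the
root; edges crossing that sphere are split at the crossing point (radius
linearly interpolated) and each crossing starts a primary projection, so
N_proj is the number of threshold crossings. Branches run between
bifurcation/termination nodes and consist of cylindrical sub-segments at
the mean of the endpoint radii (a conical-frustum mode is available behind
a flag; for the node spacings of typical reconstructions the two differ at
the sub-percent level). Branch surfaces are lateral only — branch ends
merge into the soma or into sibling branches.

Per-branch descriptors follow directly: path length (sum of sub-segment
lengths); straightness τ = chord/path (the conventional tortuosity is
1/τ); beading CV (population std over mean of sub-segment radii);
S/V = Σ lateral surface / Σ volume; undulation µOD (mean angle between
sub-segment directions and the branch chord, rad); curvature radius (mean
circumradius over consecutive node triplets, with collinear triplets —
circumradius above 10⁴ µm — excluded so near-straight runs do not drive
the mean to infinity; branches with fewer than 3 nodes report NaN);
bifurcation angle θ between daughter initial directions, each estimated
as the chord over the first min(5 µm, length) of the daughter path, which
is robust to node jitter. Branch order starts at 1 for primary branches
and increments at each bifurcation; trifurcations are handled as stacked
virtual bifurcations with a warning.

Effective MR radii use the moment ratios (⟨R⁷⟩/⟨R³⟩)^¼ for soma
populations and (⟨R⁶⟩/⟨R²⟩)^¼ for branch (cylinder) populations — the
high moments express the volume-weighted sensitivity of the dMRI signal
to a size distribution. The exponent pairs are parameters. For a single
cell, whose soma contributes one radius, R_MRsoma equals R_soma; the
population-level quantity comes from the reporting layer.

Soma surface and volume are measured on an explicit surface: by default
the convex hull of 512 near-uniform points per soma-node sphere (fast,
adequate for compact somas), or a marching-cubes mesh of the
union-of-spheres implicit surface (`method='mesh'`, voxel = r/20 by
default). Both are approximations of an ill-defined boundary; expected
bias is below ~2% for a spherical soma and can reach tens of percent for
somas reconstructed as a single node with multi-node contours, which is a
known limitation of skeleton-based soma definitions in general. η_soma
(Σ π r² of primary projections over soma surface, clipped to [0,1]) uses
the entry radii at the threshold sphere.

## Shape descriptors

Branch paths are cut into consecutive chunks of ≤ 10 µm path length
(chunks under 2 µm merge into their neighbour). Chunk orientation is the
principal axis of its nodes (chord for 2-node chunks), sign-aligned with
travel; the weight is the chunk's cylinder volume. Orientations are axes:
every fit identifies ±u. Segmenting along branch paths rather than along
persistence components is a deliberate simplification; for every property
tested the two decompositions give the same segment multiset, because
both partition the same set of sub-segments by path length.

The scatter matrix Σ wᵢuᵢuᵢᵀ/Σwᵢ gives eigenvalues τ₁ ≤ τ₂ ≤ τ₃,
normalised to unit trace (FA is invariant to the normalisation; reporting
needs the convention). FA uses the standard deviation-over-norm form and
is scale-free; adjusted FA replaces τ₁ by τ₂ without renormalising
(immaterial for a scale-free statistic) to discount the depth-of-field
artifact that deflates the out-of-plane eigenvalue.

Watson concentration κ is fitted by maximum likelihood: the MLE condition
matches E[(u·n)²] = M'(½,3/2,κ)/(3M(½,3/2,κ)) (Kummer functions; the
concentrated regime κ > 600 uses the 1 − 1/κ asymptote) to the weighted
sample mean about the principal scatter axis, solved by bisection to
10⁻⁶. Only the bipolar branch κ ≥ 0 is considered; fully aligned samples
return the cap 10⁴. The Bingham fit maximises the likelihood of
f(u) ∝ exp(−κ₁(u·e₁)² − κ₂(u·e₂)²) over κ₁, κ₂ ≥ 0 (e₁, e₂ the minor and
intermediate scatter axes), with the normalising constant evaluated by
48×48 Gauss–Legendre quadrature (absolute accuracy ~10⁻¹⁰ for κ up to a
few hundred) and Nelder–Mead in log-concentration space. With κ₁ = κ₂ the
model reduces exactly to Watson, which the tests exploit as a
cross-check. The planarity rule: κ₁/κ₂ ≥ 10 (configurable) marks a girdle
sample, for which κ₂ alone is the honest Watson proxy; otherwise the two
are averaged. OD = (2/π)arctan(1/κ).

## Topological descriptors

The persistence barcode of a projection uses the path-length filtration
from the projection's soma attachment point (radial distance is available
behind a flag). Processing terminals bottom-up, at each bifurcation the
sibling subtree with the smaller maximal path dies, recording the bar
(bifurcation path length, terminal path length); ties break toward the
smaller node id for reproducibility; the global survivor contributes
(0, max path). Bar count therefore equals terminal count exactly.

Persistence images place an isotropic Gaussian at each bar in the
(birth, death) plane, evaluated on a [0, extent]² grid (default 100×100,
extent = max death over the compared set) and normalised to unit sum;
bandwidth defaults to Scott's rule on the pooled bars. The distance
D = Σ|p₁ᵢ − p₂ᵢ| ∈ [0,2]. Group comparisons average per-cell normalised
images (renormalised) rather than pooling bars — both are defensible; the
per-cell route weights cells equally regardless of terminal count and is
the package default, with pooled-bar imaging available by passing a bar
list. Significance uses a resampling null: cells drawn with replacement
from the pooled set into pseudo-groups of the original sizes, n_boot
times (default 1000), p = (#{D_null ≥ D_obs} + 1)/(n_boot + 1).

## Exchange and relevance calculators

Units are strict: S/V in µm⁻¹, permeability κ in µm/s, diffusivity in
µm²/ms, all times in ms (1/( µm⁻¹ · µm/s ) = s → ×1000). τᵢ = 1/((S/V)κ),
τ_ex = τᵢ·f_ec with f_ec default 0.30. Thresholds: restriction R²/(5D);
curvedness R_c²/(2D) applied to both δ and Δ; branching L²/(2D); soma
exchange τ_soma = πR³/(3R_b√N D) with the combined soma–projection
threshold (1/τ_soma + ⅓/τ_soma)⁻¹ = 0.75·τ_soma under the ~1:3
soma-to-projection volume split (of a total of 4). All thresholds scale
as 1/D, so metabolite values (D = 0.4) are 5× the water values (D = 2).
Verdicts count the boundary as measurable.

The spine adjustment adds, per µm of branch, a density of mushroom-like
spines (head sphere + neck cylinder) to the cylinder's surface and
volume. The default geometry — head radius 0.25 µm, neck radius 0.06 µm,
neck length 1.0 µm — is a declared calibration chosen inside the range of
measured spine dimensions so that 1 spine/µm on a 0.6 µm branch raises
S/V by ~22% (reference band 20–30%) with the corresponding ~18% residence
-time reduction, and 2 spines/µm raises it by ~42%, close to linear in
density. Active transport and water channels are not modelled.

## Synthetic cells

The generator is the validation oracle. Defaults describe a realistic
cortical-neuron-like cell: soma radius 5 µm; 7 primary projections with
orientations Watson-distributed (κ = 2) about +z; 2 bifurcations per
projection (branch order 3, keeping default cells near 1.5k nodes);
branch lengths lognormal (median 54 µm, σ = 0.35, right-skewed as
observed); base radius 0.6 µm tapering 45% per branch (the taper is what
places branch S/V in the observed 4–19 µm⁻¹ band); sinusoidal beading
(amplitude 0.12 µm, wavelength 10 µm → CV contribution a/(r√2) ≈ 0.14);
planar sinusoidal undulation (amplitude 3 µm, wavelength 30 µm, random
azimuth per branch) giving τ ≈ 0.92 and µOD ≈ 0.37 rad, inside the
observed 0.43–0.95 and 0.05–0.60 bands; bifurcation angle 60°; node
spacing 2 µm. Optional features: Z-compression factor, explicit spines
(neck + head side branches at a set linear density, attached only where
the dendrite continues for ≥3 further edges so the remaining tail can
never itself look spine-like), and a straight axonal subtree.

Branch curves are sampled at equal arc length, with the sinusoid's
parameter solved numerically so the realized path length equals the drawn
length; per-branch truths (length, τ, µOD) are evaluated on the
continuous curve, not the sampled polyline. Ground truth therefore
reflects the construction, and recovery tests measure genuine pipeline
error: lengths recover within 1%, radii within 2%, τ within 0.01, θ
within 0.05 rad, Watson κ within 20% at ≥500 segments.

One RNG stream per cell is consumed in a fixed order (projection
directions; per branch depth-first: length, undulation azimuth, beading
phase, bifurcation plane; then spines; then axon), so enabling a later
feature does not perturb earlier draws; populations derive per-cell seeds
by seed-sequence spawning. Output is byte-identical for identical
(spec, seed).

What the generator does **not** emulate: multi-node soma contours,
reconstruction noise and breakages, diameter quantisation, spatially
correlated branching statistics, cell-type-specific arborisation (apical
trunks, basket nests), or tissue context. Passing recovery tests shows the
estimators are correct on clean geometry at realistic parameter values;
it does not certify accuracy on degraded real reconstructions, where the
QC layer is the first defence.

## Meshing

The cell surface is the zero level set of the signed distance to the
union of node spheres and edge capsules (radius linearly interpolated
along each edge), sampled on a voxel grid (default voxel min(r)/4;
coarser than min(r) is refused) and triangulated by marching cubes. Each
primitive only updates voxels in its padded bounding box, so cost scales
with skeleton length rather than domain volume; memory still scales with
the bounding-box voxel count, so whole-cell meshes of large cells should
use a coarser voxel than soma-only meshes. The implicit-union route is
robust at branch junctions where boolean CSG fails. Meshes are watertight
and outward-oriented with positive signed volume; sphere volume converges
with voxel size at first order or better (≈0.2% at r/20). Exports: PLY
(binary/ASCII), OBJ (1-based indices), STL; coordinates stay in the
cell's native µm frame.

## Reporting

Quartiles use linear-interpolation quantiles (the convention must be
stated, none being standard). Spearman correlations use average ranks for
ties; the Bonferroni family is all off-diagonal feature pairs within the
analysed set, adjusted p = min(1, p·m). The CLI writes UTF-8 comma CSVs
with '.' decimals; µm units are implicit throughout.

## Problem sizes in validation

The validation suite runs on deliberately modest problems: default
generator populations of 3–30 cells (~0.6–1.5k nodes each), 100 small
trees for the barcode-count property, bootstrap calibration with 20
seeded repetitions of 8-cell groups at n_boot = 1000 on 50×50 images, and
meshes of a 5 µm sphere at 0.25 µm voxels, a 50 µm cylinder at 0.15 µm
and three small cells at 0.3 µm. These sizes were chosen as the smallest
at which each statistical claim is stable across seeds.

## Known limitations

- The soma boundary is intrinsically ill-defined in skeleton data; both
  measurement modes carry bias for non-spherical or multi-node somas.
- Whether branch S/V should include end caps is a convention; the
  package excludes them (ends merge into neighbouring structures).
- R_domain is measured from the root node, not the soma surface.
- The spine heuristic is a declared stand-in; reconstructions with
  unusual short-tip morphology should be stripped with explicit type
  codes instead.
- The full matrix-Bingham normalisation (hypergeometric of matrix
  argument) is replaced by direct quadrature; accuracy degrades above
  κ ≈ several hundred, far beyond biologically observed dispersion.
- Population values reported for real datasets depend on those datasets;
  the package reproduces the calculators and the methodology, not the
  population tables.
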