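# Methods

## Tubular model

The lateral surface of a tube is developed into a flat raster whose
abscissa (`x`, columns) is the transverse, periodic axis and whose
ordinate (`y`, rows) is the longitudinal axis. The default apical domain
is 512 × 4096 px with 40–800 seeds (200 by default). A Voronoi diagram is
computed raster-wise: every pixel (centres at integer + 0.5) is assigned
to the seed minimising the periodic Euclidean distance, equidistant
pixels to the lowest seed id. The implementation replicates the seed set
one period to each side and queries a k-d tree — the classical
"triple-and-crop" construction, provably identical to the periodic
metric because every replica is exactly one period away.

Lloyd relaxation replaces each seed by the centroid of its region on the
tripled raster; the centroid retained for a cell is whichever of its
three replica centroids falls inside the central one-period band
(generically exactly one; if none does, the seed is kept and a warning
logged). Four iterations produce the fifth diagram, which is the one
analysed: by then the tessellation is close to centroidal and the CVT
quantisation energy has stopped changing appreciably. The energy is
non-increasing across iterations (tested).

The basal surface at surface ratio r = R_b/R_a multiplies seed abscissas
and the raster width by r, leaving the longitudinal axis unchanged; the
nine-step study series is r = 1/(1 − x/10), x = 1..9, ending at r = 10.
Intermediate depths use the factor 1 + λ(r − 1), λ ∈ [0, 1].

**Scutoid census (tubes).** Cells touching the first or last row on
either surface (tube tips) are excluded. A valid cell is a scutoid when
it shares a 4-connected raster contact with another valid cell on
exactly one of the two surfaces. Four-cell `TransitionEvent`s — the pair
(A, B) adjacent on one surface only, a flank pair (C, D) adjacent on the
other only, all four mutually in contact otherwise — are enumerated
separately and drive the motif machinery; the headline percentage is the
edge-based census, which also counts exchanges whose surrounding motif is
degenerate (e.g. passes through a fourfold vertex).

## Spheroidal model

The epithelium is the shell between an apical ellipsoid with radii
(a, b, c), b = c, and a basal ellipsoid offset by the cell height t on
every radius. Presets map to egg-chamber stages: stage 4 = (1.26, 1, 1),
t = 0.22, up to 200 seeds; stage 8 = (2.16, 1, 1), t = 0.15, up to 450;
plus sphere/balloon/zeppelin shapes (a = 1, 1.5, 2) with t ∈ {0.5, 1, 2}.

Seeds are drawn area-uniformly on the apical surface (sphere-map
rejection sampling) and accepted only when at least d_min from every
earlier seed, with d_min = 0.7·√(area/n_max); sampling stops at n_max
seeds or after 200·n_max candidates, so the realised count can fall
short on crowded surfaces. The 0.7 prefactor keeps the target count
reachable (disc packing at that spacing covers ~40 % of the surface)
while suppressing near-coincident seeds. Surface area is computed by
numeric quadrature of the parametric area element.

Each seed is extrapolated to the basal ellipsoid along the outward
apical surface normal (a radial-ray variant is available behind a flag);
the intersection solves a quadratic, so basal points satisfy the basal
ellipsoid equation to machine precision. Every voxel of the shell whose
centre lies between the ellipsoids is assigned to the apical–basal
segment of minimum point-to-segment distance (exact, chunked; for large
problems a k-d tree over points sampled along the segments proposes
candidates and the exact distance decides — verified against brute force
on small grids).

**Grid resolution.** The census grid is chosen by voxel pitch, not by a
fixed voxel count: every shape is discretised with cubic voxels at the
reference pitch 2·(1.26 + 0.22)/256 ≈ 0.0116 length units (the stage-4
shell then spans 256 voxels along x; larger shapes span proportionally
more), so cells of comparable physical size are always resolved
comparably and noise is commensurate across axes — anisotropic voxels
would break the sphere calibration below for prolate shells. Coarser
pitches are unusable here: at half this resolution the discretisation
noise and the short-edge transitions that dominate the signal overlap,
and percentages collapse. Only the two
one-voxel surface layers are labelled by default — the assignment is
pointwise, so this is exactly equivalent to labelling the whole shell
for everything the census needs; `surfaces_only=False` labels the full
shell.

**Scutoid census (spheroids).** Adjacency is read off the one-voxel
layers hugging each ellipsoid (26-connectivity). A cell inside the
region of interest (apical seed |X| ≤ (2/3)a, mimicking the imaging
window of egg-chamber measurements) is a scutoid when it gains or loses
a neighbour between the layers, where a gained/lost contact counts only
if it is entirely absent on one surface and longer than that surface's
noise threshold on the other. The threshold is the three-dimensional
analogue of the minimum edge-length rule and is calibrated the same
way — on spheres, where the apico-basal expansion is isotropic and no
true neighbour exchange can occur, every detected one is a
discretisation artefact. Those artefacts come from near-tangent cell
pairs, and their raster contact extent grows with the square root of
the cell size in voxels; the per-surface threshold is therefore
k_s = √(d_s/pitch), with d_s the mean cell diameter (√ of area per
cell) on that surface. The coefficient 1.0 is the smallest round value
clearing every spurious contact over 10 sphere realizations at each
height t ∈ {0.5, 1, 2} on reference-pitch grids, with margin (observed
spurious contacts reach ~85 % of the threshold at the thickest shell).
Unfiltered set comparison leaves a few percent of false positives on
spheres; a fixed count cannot work across shapes because basal cells of
thick shells are several times larger than apical ones; and requiring a
complementary motif flip instead of a length threshold does not help,
because near-fourfold contacts flicker between layers in both
directions.

With these definitions spheres give exactly 0 % scutoids for all tested
cell heights, and elongation raises the fraction monotonically
(sphere < balloon < zeppelin).

## Four-cell motif morphometry

Junctions are detected as 2 × 2 pixel windows where ≥ 3 labels meet; the
shared pixel corner is the junction estimate and coincident windows are
averaged. The central edge of a motif is the straight segment between
its two tri-junctions ({A,B,C} and {A,B,D}); its angle θ to the
transverse axis is folded into [0°, 90°]. The motif quadrilateral is
spanned by the four outer junctions where two motif cells meet a
non-motif cell; corners are ordered around the centroid (periodic
coordinates unwrapped about the central-edge midpoint), the opposite
side pair more aligned with the longitudinal axis gives w₁, w₂ and the
other h₁, h₂, so ε = ⟨h⟩/⟨w⟩ grows under transverse expansion. L_T sums
the five internal edges (central + four radiating), each as a straight
junction-to-junction segment.

Motifs are discarded when a cell is non-valid on either surface, the
four cells do not stay together on both surfaces, a fourfold vertex
involves the four cells, the outer corners are ambiguous (e.g. two cells
sharing two disjoint boundaries on a very small circumference), or the
central edge is ≤ 4 px — the same minimum-length rule as the spheroid
census.

## Line-tension energy model

A four-cell motif of width w (longitudinal) and height h (transverse)
with constant line tension σ can open a central edge l_w or l_h; the
energy is the total edge length times σ (see README for the
functional). Normalising lengths by w and energy by the fourfold value
E₀ = 2σ√(h² + w²) leaves one landscape Ê(l; ε) on l ∈ (−1, ε) with
ε = h/w; negative l encodes the l_w branch. The model ignores pressure,
surface stress and cortical contractility, and treats the motif in
isolation from its neighbours.

Closed forms: the l_h minimum l* = ε − 1/√3 with
Ê* = (ε + √3)/(2√(ε² + 1)) exists iff ε > 1/√3; the l_w minimum
l* = −(1 − ε/√3) with Ê* = (1 + √3·ε)/(2√(ε² + 1)) exists iff ε < √3.
Below 1/√3 only l_w is stable, above √3 only l_h, in between the system
is bistable with the fourfold vertex (Ê = 1) as the barrier; the exact
boundary values are classified bistable with a degeneracy flag
(measure-zero case). A cell whose ε crosses the window between its
apical and basal surfaces can settle into different attractors at each
end — the energetic reading of the scutoid.

Numerics: `relax` is fixed-step explicit gradient descent (step 10⁻³ in
l, stop when |ΔÊ| < 10⁻¹⁰, cap 10⁶ steps; the flow equation fixes no
timescale, so the step is a pure solver choice). Exactly l = 0 is left
unmoved (unstable stationary point); descent may cross the kink at 0
when the starting branch has no interior minimum. One printed form of
the dimensionless energy reads "h" where dimensional consistency
requires ε inside the second branch; the implementation uses ε, and the
dimensional and dimensionless forms agree to 10⁻¹² (tested).

Measured motifs get Ê_exp = L̂_T/(2√(1 + ⟨ε⟩²)) with L̂_T = L_T/⟨w⟩, split
into Ê_w = Ê_exp·sin θ and Ê_h = Ê_exp·cos θ; each surface uses its own
⟨w⟩, ⟨ε⟩ and θ, and basal→apical trajectories are vectors in (Ê_h, Ê_w)
space. Edge configurations classify as l_w above 50°, l_h below 40°,
discarded between.

## Statistics and reproducibility

Distribution comparisons (edge angle and length, transition vs
no-transition) use the two-sample Kolmogorov–Smirnov test
(`scipy.stats.ks_2samp`). Replicate summaries report mean ± population
SD. A single run seed fans out to per-stage child seeds via numpy
`SeedSequence`, and every CLI run writes a JSON manifest of parameters
and seeds.

## What the generator does and does not emulate

The synthetic tessellations reproduce the geometric mechanism — apical
and basal diagrams coupled through seed scaling or segment seeding on
curved surfaces — under the study conditions (domain sizes, seed counts,
expansion series, egg-chamber-proportioned shapes). They contain no cell
mechanics, no rearrangement in time, no proliferation, and no active
migration; the seeding is statistically homogeneous, unlike real
follicular epithelia, which are dynamic and can exceed the geometric
scutoid fraction. Passing tests therefore validate the geometric model
and its measurement pipeline, not a mechanical account of any real
tissue, and percentages measured on real stacks are out of scope.

## Known limitations

* All geometry is raster/voxel based, as in the original pipelines; no
  exact polygonal Voronoi diagrams are constructed, and small contacts
  near the discretisation scale are explicitly filtered rather than
  resolved.
* Tubes with very few cells around the circumference (cell diameter
  approaching half the period) produce motifs whose cells touch twice
  around the wrap; such motifs are invalidated rather than measured.
* The spheroid census depends on the sphere-calibrated contact filter;
  at pitches much coarser than the reference the filter and the signal
  overlap and percentages are not meaningful. The reported percentages
  inherit the filter scale, as any minimum-edge-length rule's do.
* Maximum-intensity projections can juxtapose cells across the
  silhouette rim, so projected adjacency is validated only as an
  approximate subset of true surface adjacency within the ROI.
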