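# Methods

This note records the models implemented in `capsidkit`, the numerical and
design choices made where the construction was genuinely open, what the
synthetic-data generators do and do not emulate, and the known limitations.

## Generalized T-number algebra (`capsidkit.lattice`)

The classic triangulation number is T₀(h, k) = h² + hk + k² for integer
steps h, k ≥ 0, (h, k) ≠ (0, 0); a shell carries 60·T₀ major capsid
proteins (MCPs), five of which are replaced by the portal in a virion.
Four Archimedean tilings can carry the icosahedral layout; at conserved MCP
footprint each inflates the surface by the exact area ratio of its unit
cell (one hexagon plus secondary polygons, unit edge) to the plain hexagon:

| lattice            | unit cell                     | α (exact)      | α (num.) |
|--------------------|-------------------------------|----------------|----------|
| hexagonal          | 1 hexagon                     | 1              | 1.0000   |
| trihexagonal       | 1 hexagon + 2 triangles       | 4/3            | 1.3333   |
| snub hexagonal     | 1 hexagon + 8 triangles       | 7/3            | 2.3333   |
| rhombitrihexagonal | 1 hexagon + 2 tri. + 3 sq.   | 4/3 + 2√3/3    | 2.4880   |

The generalized T-number is T = α·T₀. Note that α for the
rhombitrihexagonal lattice is 4/3 + 2·√3/3, the exact area ratio
(3 + 2√3)/(3√3/2 · 2) of the 3.4.6.4 cell; a commonly seen shorthand
"4/3 + 2/3" is a typographical corruption (it equals 2, not ≈ 2.49) and is
not used anywhere in the package. The value 2.4880 is what reproduces the
series element ≈ 2.49, the T ≈ 7.46 grid point, and the 8.94 kbp model mean.

(h, k) is canonicalised to h ≥ k on input: genome-length classification can
never distinguish the two mirror orientations of the step vector, so both
are accepted and one is reported. Enumeration keeps numerically equal T
values from different (h, k, lattice) realisations as distinct entries
(e.g. T = 4 from hexagonal (2,0) and trihexagonal (1,1)); the classifier
operates on the deduplicated numeric grid (tolerance 10⁻⁹) because genome
length alone cannot separate degenerate realisations.

## Cage meshes (`capsidkit.cage`)

The builder follows the canonical Caspar–Klug construction. Each planar
tiling is generated with unit edge; the hexagonal, trihexagonal and snub
hexagonal tilings are realised as decorations of the unit triangular
lattice, with hexagons centred on the sublattice generated by the step
(1,1), (2,0) or (2,1) respectively (the snub lattice is chiral: (1,2)
yields the dextro form; laevo is the default, a flag flips it), and every
unit triangle not incident to a sublattice point kept as a minor-protein
triangle. The rhombitrihexagonal tiling (hexagon-centre lattice constant
1 + √3) is decorated directly with hexagons, one unit square per lattice
edge and corner-sharing triangles at the triangle centroids.

The facet triangle has corners at hexagon centres 0, h·c₁ + k·c₂ and that
vector rotated +60° (c₂ = rot₆₀ c₁). Tiling polygons are clipped to it with
exact polygon intersection (shapely), the clipped set is mapped affinely
onto all 20 faces of a regular icosahedron (standard orientation, two
opposite vertices on the z axis; faces ordered counter-clockwise from
outside, deterministically), coincident vertices are welded (k-d tree,
tolerance 10⁻⁶ of a tiling edge), and fragments of one polygon split across
facet boundaries are re-assembled by pairing their clipping-cut edges and
cancelling matched directed edges. A cut edge is an edge lying on the facet
boundary that is *not* part of the source polygon's own boundary — the
distinction matters for h = k architectures, where genuine tiling edges run
along the facet triangle's sides. Hexagons centred on the 12 five-fold
vertices lose one 60° wedge per construction and close into pentagons;
their apex point and all degree-2 "bend" vertices (crossings of tiling
edges with facet edges) are suppressed from the face loops.

Geometry: at sphericity 0 every vertex lies on the flat icosahedron
surface; sphericity f ∈ [0, 1] moves each vertex radius linearly,
r(v) = (1−f)·|v| + f·R, reaching the circumscribing sphere at f = 1. The
linear radial interpolation is this package's definition of the
"sphericity"/"sphere factor" slider used when measuring capsid
reconstructions in molecular viewers; the exact interpolation those viewers
use is not documented, so agreement is by construction at the endpoints
only. Faces that wrap an icosahedron edge are intrinsically bent at
sphericity 0 (a property of any Caspar–Klug folding, not an artefact);
faces contained in one facet are exactly planar. Each primal mesh carries
`face_flat_areas`, the exact developable (intrinsic) area of every face:
pentagons carry exactly 5/6 of a hexagon-equivalent, and per-lattice totals
normalised to unit tiling edge reproduce the area factors α to floating
precision — the invariant the surface bookkeeping is tested against.

The dual (Laves-lattice) cage places one vertex at each face centroid
(radially positioned by the same sphericity rule) and one face per primal
vertex, ordered by walking the faces around the vertex; orientation is
fixed by Newell normals. Writers emit Wavefront OBJ, OFF and Chimera BILD
(one `.polygon` per face) with stable vertex order; meshes are verified
closed (every edge shared by exactly two faces), with Euler characteristic
2, 12 pentagons, icosahedral symmetry of the vertex set at sphericity 1,
and the four (1,0) cages reproduce the pentagonal dodecahedron,
icosidodecahedron, snub dodecahedron and rhombicosidodecahedron censuses.

## Structural metrics (`capsidkit.metrics`)

From a per-capsid measurement record (interior/exterior vertex-to-vertex
diameters in nm, sphericities, surfaces in nm², volumes in nm³, genome in
kbp): shell thickness = (d_ext − d_int)/2 (radii subtraction; diameters are
halved first), genome packing density = genome·1000 / v_int in bp/nm³
(kbp→bp is exactly 1000), per-MCP interior/exterior area = surface /
(60·T₀), and exterior surface excess = s_ext/s_int − 1. The MCP surface
fraction defaults to 1 (all shell surface attributed to MCPs) and can be
lowered when a decoration-protein fraction is known; no published
apportioning rule exists. Correlations against capsid diameter use the
non-parametric Spearman coefficient with the two-tailed p-value;
normality uses Shapiro–Wilk. Both reject degenerate inputs (constant
samples, n below the statistic's minimum).

## Allometric models (`capsidkit.allometry`)

G(T) = a_G·T^{b_G} (kbp) and D(T) = a_D·T^{b_D} (nm) are fitted by ordinary
least squares on base-10 logs. Observations sharing a T value are averaged
**arithmetically in linear space first** (this de-biases over-sampled
architectures such as T = 7 and reads most naturally from fitting "average"
values; a geometric mean would shift the intercept), then both axes are
logged. A fresh fit stores the parameter standard errors, R², residual SD
(log₁₀ units), the predictor mean and sum of squares, and degrees of
freedom n − 2, which support the standard linear-regression interval at
x₀ = log₁₀ T:

half-width = t₁₋(1−level)/2,df · s · sqrt([1 if new-observation] + 1/n + (x₀ − x̄)²/Sxx)

back-transformed by 10^(·), hence asymmetric on the linear scale. Intervals
default to the mean-response kind; new-observation intervals are available.
Published-parameter fits (shipped in `capsidkit/data/printed_params.json`:
log₁₀ a_G = 0.37 ± 0.10, b_G = 1.47 ± 0.09; log₁₀ a_D = 1.38 ± 0.34,
b_D = 0.52 ± 0.03, each with R² ≈ 0.985/0.986 at n = 7) carry no residual
statistics and raise a capability error if asked for intervals or
diagnostics. Because those parameters are printed rounded to two decimals,
model means evaluated from them can differ from published means by up to
about 1% (e.g. D(3) evaluates to 42.47 nm against a published 42.76 nm);
the package reports what it computes.

Residual diagnostics return internally studentised residuals
(r_i / (s·√(1−h_i))), leverages h_i = 1/n + (x_i − x̄)²/Sxx, a Shapiro–Wilk
p-value on the residuals, and a heteroscedasticity flag raised when
|residual| is significantly (p < 0.05) and substantially (|ρ| > 0.5)
rank-correlated with the fitted value.

The theoretical exponents follow from two conserved structural facts:
constant packing density makes G proportional to shell volume ∝ D³, and
constant exposed per-MCP surface makes T proportional to shell surface
∝ D², hence b_G = 3/2 and b_D = 1/2 exactly. These constants are exposed as
`THEORETICAL_EXPONENTS` and anchor the generator-recovery tests.

## Classification (`capsidkit.predictor`)

A genome of L kbp is assigned argmin over the grid of |L − G(t)|, distance
in **linear kbp** ("nearest average genome length" read literally);
log-space matching is available behind a flag for sensitivity analysis.
Exact ties break to the smaller T (parsimony; implemented with a relative
tolerance of 10⁻¹² so floating rounding at an exact midpoint cannot flip
the choice). The default grid is all four lattices, deduplicated, capped at
T < 40. Because G is strictly increasing, the decision regions are exactly
the arithmetic-midpoint intervals of consecutive model means; the test
suite checks the argmin implementation against that closed-form oracle over
a 1 bp – 600 kbp sweep, along with monotonicity. Genomes with assigned
T ≤ 4 are flagged small-capsid candidates; `candidate_report` filters,
sorts by (T, length) and counts per architecture.

Genome-length densities use Gaussian kernels with the classic rule-of-thumb
bandwidth 0.9·min(sd, IQR/1.34)·n^(−1/5) — the default of the reference
statistics environment, verified to match its `density()` output — on a
512-point grid spanning [min − 3·bw, max + 3·bw]. Peaks are strict
grid-local maxima sorted by density. Genome length from FASTA is the
residue count (ambiguity codes included); dsDNA is assumed so one residue
is one bp.

## Synthetic data (`capsidkit.simulate`)

**Structure tables.** For each architecture in the default training set
{4, 7, 9, 12, 13, 16, 27} (the seven distinct T values with published
high-resolution structures; configurable): exterior per-MCP area →
exterior surface = area·60·T₀ → exterior diameter of the quasi-spherical
shell (D = √(S/π)); shell thickness increases linearly with diameter
within 3–8 nm (anchored to the published 49–143 nm diameter range);
interior diameter, surface and volume follow; genome = packing density ×
interior volume. Synthetic sphericities decrease linearly with diameter
inside the published 0.25–0.75 (interior) and 0.14–0.55 (exterior) ranges,
reproducing the reported negative sphericity–diameter correlation sign.
With `noise_sd_log10 = 0` the per-MCP area (24–35 nm²) and density
(0.34–0.62 bp/nm³) sit at their range midpoints, so the table is a pure
realisation of the scaling laws and refitting recovers b_D = 1/2 exactly
and b_G within 0.05 of 3/2 (the small excess is real: the 3–8 nm thickness
growth makes interior volume rise slightly faster than D³ₑₓₜ). With noise,
area and density are drawn uniformly per capsid and lognormal noise of the
given log₁₀ width multiplies the diameter (surfaces/volumes recomputed
consistently) and the genome; 95% parameter CIs from such tables cover the
generating exponent at close to nominal rate. Identical specs (including
seed) produce identical tables. Record ids are labelled `SYN-*`.

**Genome mixtures.** Lengths are drawn from a lognormal mixture (genome
lengths are positive and right-skewed) and rounded to integer bp; an
optional FASTA writer emits random A/C/G/T sequence of each length. Two
presets emulate the published collections. Component means are anchored at
the published KDE peak locations; the weights and log-sds are this
package's free choices, set once so that (a) the default-bandwidth KDE
resolves every anchored peak — as the real data does — and (b) the mixture
median and mean sit near the published 50.3/72.7 kbp (isolates) and
44.8/55.8 kbp (gut) values:

* `isolates` (n = 3000): (18.3 kbp, w 0.13, sd 0.04), (42.0, 0.65, 0.09),
  (158.9, 0.22, 0.025) — realised median ≈ 43, mean ≈ 65 kbp.
* `gut` (n = 1500): (12.6, 0.09, 0.035), (42.9, 0.69, 0.10),
  (98.2, 0.11, 0.02), (160.8, 0.11, 0.02) — realised median ≈ 45,
  mean ≈ 59 kbp.

The flanking components are kept narrow (a few phage groups dominate the
small- and large-genome ends; crAss-like genomes cluster tightly) and the
~42 kbp component broad. A broad large-genome component is incompatible
with rule-of-thumb-bandwidth peak recovery at these sample sizes: it
inflates the IQR (oversmoothing swallows the minor peak) or, at small
bandwidths, fragments into sampling wiggles.

**What the generators do not emulate.** Real measurement error structure
(manual icosahedron fitting at discrete radius/sphericity steps),
correlated errors between interior and exterior measurements, the actual
long right tail and fine substructure of genome-length databases, sequence
content, and assembly artefacts. Passing tests therefore demonstrate
correctness of the algebra, the fitting machinery and the classifier's
decision geometry under the stated generative assumptions — not that the
published parameter values are recoverable from any particular real
dataset, which requires the original measurement table.

## Problem sizes and numerical choices

Tests run the cage builder up to T₀ = 7 across all four lattices (the
small-capsid model set plus a T = 7 control), coverage simulations at 500
replicates of seven-point fits, classifier sweeps at ~400–600 grid points
over 1 bp – 600 kbp, and mixture KDEs at the preset sizes n = 3000/1500 —
the whole suite completes in a few seconds. Welding tolerance is 10⁻⁶ of a
tiling edge (vertex spacings are O(1) tiling edges, so this is
unambiguous); clip/boundary tolerances are 10⁻⁷ in tiling units; T-grid
deduplication 10⁻⁹; classification tie tolerance 10⁻¹² relative. The
icosahedron is built from the golden-ratio coordinates, hull faces oriented
outward and sorted, so all meshes and CLI outputs are byte-identical across
runs.

## Known limitations

* Elongated (prolate) capsids and Q-numbers are out of scope; the models
  treat all shells as icosahedral.
* Printed-parameter fits cannot produce confidence intervals (no residual
  statistics are published), so published CI bounds such as 8.1–17.1 kbp at
  T = 3 are not reproduced; interval machinery is validated by its
  closed-form properties on fresh fits instead.
* The classifier's accuracy inherits the allometric model's large intercept
  CV (~27%): neighbouring small-T architectures have heavily overlapping
  plausible genome ranges, so assignments near boundaries are hypotheses to
  rank candidates, not structure determinations.
* The sphericity parameter is an endpoint-exact but otherwise assumed
  linear interpolation (see above).
* `CapsidStructureRecord.mcp_count` resolves a generalized T to its
  smallest-area-factor realisation when several lattices share the value.
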