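# Methods

## Problem setting

`ventromech` quantifies mechanical loading of the lateral ventricular wall
from longitudinal deformation. The input is a closed, consistently oriented
triangle mesh of the ventricular surface at baseline together with either a
topology-identical follow-up mesh or a dense displacement volume produced by
nonlinear registration of baseline to follow-up MRI. All coordinates are
world millimetres in the RAS convention. Because the mesh topology is shared
across configurations, every quantity can be compared node-by-node between
time points and across subjects.

## Mechanomarkers

Four node-wise markers plus two scalars are computed per subject:

**Displacement magnitude** ‖x_fu − x_bl‖ per vertex (mm).

**Volume and surface area.** Surface area is the sum of triangle areas
A = ½‖(p₂−p₁)×(p₃−p₁)‖. The enclosed volume sums *signed* tetrahedra formed
by each triangle with the vertex centroid and takes the absolute value — a
divergence-theorem decomposition that is exact for any closed oriented
surface, convex or not, and needs no tetrahedral mesher. The standalone
tetrahedron primitive uses the unsigned scalar-triple-product form
V = |(d−a)·((b−a)×(c−a))|/6.

**Mean curvature and curvature change.** At each vertex a quadratic height
patch S(u,v) = a u² + 2 b u v + c v² is fitted by least squares to the
k-ring neighbourhood, where (u, v) are coordinates in the tangent plane of
the area-weighted vertex normal and the height w is measured along the
*inward* normal, so a convex outward-bulging surface has positive curvature.
The principal curvatures follow from the fitted coefficients,
k₁,₂ = a + c ± √((a−c)² + 4b²) (the eigenvalues of the patch Hessian),
and the mean curvature is M = ½(k₁+k₂) = a + c. The curvature-change marker
is ΔM = M_followup − M_baseline, so inflation of a convex region gives
negative ΔM ("flattening", a growing local radius). The patch has no linear
terms; residual normal error is reported as the fit RMS rather than fitted.
The fit starts from the 1-ring and expands to the 2- and 3-ring whenever
fewer than 5 usable neighbours are available or the normal-equation system
is rank-deficient; the fit is unweighted. On an icosphere at subdivision 4
the median M is within 0.02 % of 1/R; the error decreases monotonically
with refinement.

**Membrane strain and area stretch.** Per triangle, the edge matrices
X = [X₂−X₁, X₃−X₁] and x = [x₂−x₁, x₃−x₁] are expressed in per-triangle
2-D orthonormal frames (first axis along the first edge, second axis
completing a right-handed in-plane basis), which makes them square 2×2 and
maps every rigid motion to F = I exactly. The deformation gradient is
F = x·X⁻¹, the Green–Lagrange strain E = ½(FᵀF − I), and the maximum
principal wall strain is the larger eigenvalue of E (closed-form 2×2
eigenvalues, ordered λ₁ ≥ λ₂). The area stretch is λ_A = |det F|, equal to
the deformed/reference triangle area ratio. The eigenvalues of E are
invariant to the frame anchor; this is tested by cyclic vertex permutation
and against an independent oracle that derives the principal strains purely
from squared edge lengths (Gram matrices, first fundamental form).

**Element-to-vertex smoothing.** Per-element strain and stretch are averaged
onto vertices with weights equal to the *undeformed* incident-triangle areas,
consistent with strain measures referred to the reference configuration.

## Warp-field sampling and registration metrics

Displacement volumes are 4-D NIfTI grids of world-frame 3-vectors (mm).
Meshes are deformed by trilinear interpolation of the field at vertex
positions after mapping through the inverse voxel-to-world affine; trilinear
sampling reproduces affine displacement fields to machine precision, which
is the basis of the warp-exactness oracle. Out-of-bounds sampling raises by
default; nearest-edge clamping must be requested explicitly because silent
clamping biases boundary strain.

Dice overlap, Hausdorff distance (HD) and average symmetric surface distance
(ASSD) compare binary masks on a shared grid. HD and ASSD operate on the
world-mm centres of boundary voxels (mask voxels with at least one
six-connected background neighbour); six-connectivity is chosen for
determinism. ASSD pools nearest-neighbour distances from both directions,
weighted by boundary point counts. Cross-resolution marker comparison maps
one mesh's vertex field onto another by scattered linear (Delaunay)
interpolation with nearest-neighbour fallback outside the source hull, and
reports NRMSE normalised by the reference field's range (the normalisation
is recorded in output metadata so alternatives can be compared).

## WMH probability mapping

Vertex intensities are trilinearly sampled from co-registered FLAIR-like
volumes. A vertex is a white-matter-hyperintensity (WMH) location when its
baseline intensity exceeds the subject's 90th-percentile baseline intensity
over the surface-sampled values (linear-interpolation percentile); the same
baseline-derived threshold is applied to follow-up intensities to detect
newly emerged lesions. The exceedance is strict, with a 1e-9 relative tie
tolerance so round-off from interpolating near-constant image regions never
flags vertices. Per-vertex occurrence probability is P_i = (1/N) Σ_s W_i^(s)
and longitudinal change ΔP_i = P_i^fu − P_i^bl. Burden bins are
noWMH (P = 0), low (0 < P < 1/3), intermediate (1/3 ≤ P ≤ 2/3) and
high (P > 2/3); boundary values go to the intermediate bin because inward
assignment is deterministic and attainable probabilities rarely hit the
boundaries at realistic cohort sizes. Vertices adjacent to deep grey matter
are excluded via a user-supplied vertex set — the anatomical criterion is
not algorithmically specified, so it is an input, not a heuristic.

Peak-load likelihood maps count, per vertex, the fraction of subjects for
which (i) area stretch > 1 and strain above that subject's 90th strain
percentile (expansion) or (ii) area stretch < 1 and strain below the 10th
percentile (shrinking). The strict stretch inequalities carry a 1e-12
tolerance so exactly strain-free deformations satisfy neither. Wall
fractions are area-weighted: each vertex carries one third of its incident
triangle areas.

## Cohort statistics

Node-wise two-group comparisons use Welch's unequal-variance t-test with
Benjamini–Hochberg FDR correction across vertices at α = 0.05. Vertices
where both groups are constant report t = 0, p = 1 (no evidence) to keep
maps total. Hemispheric pairing reflects vertices across a midsagittal plane
(default: sagittal plane through the mesh centroid, overridable) and pairs
each vertex with its nearest mirror partner; pairing distances localise
asymmetries, and left–right differences are Welch-tested per paired vertex.
Marker homogeneity across the cohort is the per-vertex sample variance after
per-subject min–max normalisation to [0, 1]; variance fields of two markers
are compared by a Kullback–Leibler divergence estimated on shared
equal-width histograms spanning the pooled range (default 50 bins, additive
ε = 1e-10 smoothing; estimator settings are emitted in metadata since the
histogram estimator is one of several defensible choices). Burden-bin
effects use one-way ANOVA with η² = SS_between/SS_total and BH-corrected
post-hoc pairwise Welch tests when the omnibus F is significant.

## Synthetic data

The generators define the study conditions under which the toolkit is
validated. Analytic deformations (uniform inflation, affine, rigid, local
radial bump) come with closed-form expected markers: inflation by λ gives
area stretch λ², maximum principal strain (λ²−1)/2 and volume ratio λ³ on
any shape, plus displacement (λ−1)R and curvature change (1/λ−1)/R on a
sphere of radius R; rigid motions null every marker; affine maps have
per-triangle strain equal to the restriction of ½(AᵀA − I) to the triangle
plane, computed here through the metric so the oracle is independent of the
deformation-gradient pathway. Deformations are rasterised onto voxel grids
to emulate registration warp fields.

Synthetic FLAIR volumes stamp a bright one-voxel shell
(intensity 100·(1+contrast) over a background of 100) in the 3×3×3 voxel
neighbourhood of each labelled vertex on a 0.5 mm grid, so that with zero
noise and vertex spacing above ~2 mm, labelled vertices sample exactly the
bright value and all others exactly the background — WMH recovery is then an
exact, enumerable property. Seeded Gaussian noise can be added.

Synthetic cohorts draw per-subject expansion factors
λ ~ exp(N(ln 1.066, 0.03)) applied to a shared icosphere of radius 14 mm
(≈11.5 cm³), with i.i.d. Gaussian vertex noise of SD 0.05 mm and balanced
female/male labels; an optional additive sex effect on λ plants detectable
group differences. These defaults produce ≈ +21 % volume change and
≈0.9 ± 0.45 mm wall displacement — the magnitudes this class of longitudinal
ventricular analysis operates at. Subjects derive independent RNG streams
from the master seed via spawn keys, so cohorts are bit-reproducible and
order-insensitive. The generators emulate expansion magnitude, noise and
cohort structure; they do not emulate real ventricular geometry's
topology-preserving registration errors, scanner intensity non-uniformity,
or anatomically realistic lesion shapes — passing tests demonstrate
correctness of the computational pipeline, not clinical validity on MRI.

## Numerical choices and limitations

- Degenerate triangles (area ≤ 1e-12 mm²) fail mesh validation rather than
  being skipped silently; STL vertex merging uses exact coordinate equality
  after rounding to 1e-6 mm.
- Meshes are 0-based internally; writers emit each format's native
  convention. Supported formats: PLY, OFF, STL, legacy ASCII VTK polydata;
  fields travel as indexed CSV with a units-bearing header.
- Curvature at mesh boundaries (open patches) uses whatever neighbours
  exist; values at boundary vertices of open meshes are less reliable than
  interior ones, which the flat-patch tests account for by checking interior
  vertices.
- The percentile for WMH thresholding is computed over surface-sampled
  intensities, not the whole volume.
- Problem sizes in the validation suite (icospheres at subdivisions 2–4,
  cohorts of 6–50 subjects, 500-vertex statistical fields) were chosen to
  exercise every tolerance at realistic signal-to-grid ratios while keeping
  the full suite fast to run.
- No constitutive model is used anywhere: the toolkit measures kinematics
  (strain, stretch, curvature), not stress, and performs no volumetric
  (parenchymal) strain estimation and no registration itself.
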