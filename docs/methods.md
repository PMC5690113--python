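# Methods

`beamfab` implements the design-to-print pipeline for patient-specific
radiotherapy beam modifiers — electron bolus and double-scattering
proton range compensators — together with the quality-assurance
computations used to qualify the printed objects. This note documents
the models, the numerical choices, and what the synthetic fixtures do
and do not show about real prints.

## Coordinate conventions

All geometry is in millimetres in the DICOM LPS patient frame. Contours
are closed planar polygons on axial slices, stored without a duplicated
closing vertex. CT volumes are indexed `[z, y, x]` with the origin at
the centre of voxel `[0, 0, 0]`. Depth-dose curves use centimetres of
water (the clinical convention for proton ranges).

## Surface reconstruction

A bolus design arrives as per-slice contours in an RT Structure Set; a
compensator arrives as a row x column thickness matrix in an RT Ion
Plan. Both are converted to closed triangle surfaces:

1. **Resampling.** Each contour is subdivided (never decimated) until no
   edge exceeds the target spacing (default 1 mm); an edge of length L
   is split into ceil(L / target) equal parts, so original vertices are
   preserved and the perimeter is exact. Slices are then densified in z
   the same way, with intermediate contours formed as vertex-wise linear
   blends.
2. **Correspondence.** Slice-to-slice vertex correspondence is needed
   before blending and strip construction: all contours are resampled by
   arc length to a common point count, oriented counter-clockwise, and
   each ring is cyclically aligned to its predecessor by minimising the
   summed squared inter-vertex distance over cyclic shifts. This is the
   standard shape-blending choice; the alignment is chained down the
   stack so one global indexing covers every ring.
3. **Walls and caps.** Adjacent rings are joined by triangle strips; the
   two end contours are capped with a constrained Delaunay
   triangulation (CDT). A Delaunay tetrahedralisation of the full point
   cloud would return the convex hull rather than the object surface,
   so the Delaunay criterion is applied where it is well-posed: the
   planar caps and the compensator top surface. The CDT is built by ear
   clipping (strictly convex ears only, vectorised containment tests)
   followed by Lawson edge flips on non-boundary edges until every
   interior edge satisfies the empty-circumcircle criterion. Cocircular
   configurations are tie-broken by a tolerance guard
   (1e-9 x extent^4 on the incircle determinant) that leaves exact ties
   unflipped — deterministic and terminating.
4. **Compensator extrusion.** The height field is split cell-by-cell
   along a fixed diagonal (a valid Delaunay triangulation of a
   rectangular grid; the cocircular cell corners make any diagonal
   admissible, and the fixed choice is the deterministic tie-break).
   Vertical perimeter walls drop to a flat base, so the enclosed volume
   equals the prismatoid integral of the triangulated thickness field
   exactly — this identity is used as a test oracle. Thickness is
   extruded along +z by default; `beam_axis="-z"` mirrors the solid for
   tray-mounted orientation.

Every produced mesh must pass validation: each undirected edge shared
by exactly two facets, consistent winding (each edge traversed once per
direction), Euler characteristic 2 per component, no degenerate facets,
positive signed volume (outward normals). Non-watertight meshes are
refused at STL export unless explicitly overridden.

STL output is binary by default (80-byte header carrying a `units=mm`
comment, little-endian facet count, 50 bytes per facet, zero attribute
bytes). Vertices are rounded to single precision before writing, so
binary and ASCII exports re-read float32-identical.

## Geometric conformity

The conformity index between a design and a CT-extracted profile stack
is the per-slice largest Euclidean distance, averaged over slices. Per
slice, both contours are resampled to <= 0.5 mm spacing and the
symmetric Hausdorff distance on the sampled points is taken: the
maximum over either contour's points of the distance to the nearest
point of the other. Choices the source material leaves open, decided
here:

- **Symmetric, not directed** — conservative (never smaller than either
  directed distance).
- **Point-to-point, not point-to-segment** — matches the point-cloud
  character of the extracted profiles; the <= 0.5 mm resampling bounds
  the discretisation error at 0.25 mm.
- **Registration off by default** — a phantom scanned in the design
  frame needs none; `register=True` applies centroid translation plus
  rigid 2-D ICP, pooled over slices, and records the transform.
- Summary spread is the population (N) standard deviation, stated in
  the report metadata.

Profiles are extracted by marching squares with linear interpolation at
a threshold defaulting to the midpoint between the background and
material mean HU (one two-means split of the slice histogram). The
midpoint threshold places the iso-contour at the half-rise of the
interface ramp, which is where the physical surface sits under a
symmetric point-spread function.

## HU uniformity, density, height checks

Interior HU statistics are computed after eroding the object mask by a
1.25 mm Euclidean ball (distance transform with physical voxel
sampling, so anisotropic 0.5 x 0.5 x 0.625 mm voxels are handled
exactly). The margin removes partial-volume and PSF-ramp voxels at the
air interface that otherwise bias the mean toward air — the no-erosion
bias is demonstrated in the tests. Mass density is measured weight
divided by design-mesh volume (divergence-theorem sum over facets). The
height-gauge check bilinearly interpolates the design height field at
probe positions (exact for locally linear fields) and flags deviations
at a 1.0 mm default tolerance. The HU to relative-electron-density
mapping is scanner-specific, so it takes a user-supplied
piecewise-linear calibration table and clamps (with a warning) outside
its range; no default table is shipped.

## Proton model and RSP estimation

The pristine Bragg curve is modelled as the power-law stopping curve
D0(z) ∝ (R0 − z)^(1/p − 1), p = 1.77, convolved with a Gaussian
range-straggling kernel of width sigma = 0.012 R^0.935 cm (an empirical
Bortfeld-style scaling — a modelling choice of this package). The cell
integral of the integrable singularity at R0 is computed analytically,
so the discrete curve is insensitive to grid phase; the default grid
spacing is 0.1 mm and spacings above sigma/2 are refused. R0 is
calibrated by a 1-D root find so the distal 80% crossing (d80, linear
interpolation between samples) of the generated curve equals the
nominal beam range — 15.0 cm for the characterization beam.

A slab of thickness t and relative stopping power rsp translates the
curve upstream by its water-equivalent thickness WET = t * rsp
(first-order model; straggling growth inside the slab is neglected,
which is immaterial because the estimator uses only the shift). The
estimator inverts this: rsp = (d80_ref − d80_sample) / t. d80 is the
standard clinical range surrogate; the level is configurable (0.8/0.9).
A 1-D slab has no orientation, so print-direction effects are outside
this model by construction. Measured chamber noise is emulated as
multiplicative i.i.d. Gaussian noise; 100-replicate recovery at 1%
noise holds the mean absolute error under 1%.

## Synthetic fixtures

The generators produce every input the pipeline consumes, so all tests
run without patient data or physical prints:

- **Scalp bolus**: crescent-shaped shell contours (outer ellipse arc
  minus a 12 mm inward offset), ~140 x 110 mm laterally over a 40 mm z
  extent with 2.5 mm design slices, tapered along z and perturbed by
  seeded low-order harmonics (<= 2 mm) to emulate an anatomy-fitted
  design. All contours are verified simple.
- **Compensator**: 81 x 81 cells at 1 mm (matching clinical export
  resolution), 20 mm base plus a 15 mm radial bowl (centre thinner than
  edge — the concave shape that conforms dose to a convex distal target
  surface) plus <= 1 mm band-limited noise.
- **Simulated CT**: voxel centres are classified inside/outside the
  mesh by vertical-ray parity (sub-micron per-axis ray offsets avoid
  degenerate edge hits on grid-aligned fixtures); defaults are
  0.5 x 0.5 x 0.625 mm voxels, −1000 HU background, material HU of
  130.1 ± 10.1 (PLA-like) or −72.1 ± 5.3 (polyamide-like), optional 3^3
  partial-volume supersampling, 0.4 mm PSF blur, and noise added after
  the blur so interior statistics keep the nominal sd. HU are rounded
  to integers as a scanner reports them.
- **DICOM fixtures**: minimal but standard-conformant RTSTRUCT, RT Ion
  Plan and CT series files with deterministic UIDs and fixed dates.
  Generator coordinates are quantised to 1e-6 mm so the 16-character
  DICOM decimal strings round-trip bit-exactly.

What passing these tests shows: the conversion and QA chain is
self-consistent at voxel scale — a design pushed through meshing,
simulated scanning and re-extraction comes back within the voxel
diagonal (~0.95 mm at the default spacing), the same scale as published
print-conformity results. What it does not show: fidelity of any
physical printer or material. Printed-object HU, density and RSP values
appear here only as generator parameters and constructed truths for
recovery tests, never as outputs of a physics computation.

## Known limitations

- Single closed contour per slice: branching topology, holes and
  multi-component designs are out of scope.
- The compensator reader assumes the standard ion range-compensator
  attributes; vendor-specific tray/milling extensions are ignored.
- The slab model omits straggling growth and lateral scattering in the
  sample; fine for shift-based RSP estimation, not for full curve
  prediction.
- The CT simulator models partial volume, PSF blur and white noise, but
  not beam hardening, rings, or printing artifacts (layer lines,
  underfill).
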