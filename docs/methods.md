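# Methods

## The measurement

The bone-to-implant contact ratio (BIC) of a screw-type implant is the
percentage of the implant thread profile length that is in direct contact
with bone tissue.  Histomorphometry measures it on a stained section through
the implant's long axis; `microbic` measures it on 2D longitudinal reslices
of a reconstructed micro-CT volume, which can be taken at any rotation angle
θ about the implant axis.  The protocol implemented here:

1. **Axis estimation.**  Metal voxels (intensity ≥ `implant_min`, default
   200 on the 8-bit scale) are collected; the axis point is their centroid
   and the axis direction the principal eigenvector of their coordinate
   covariance, sign-normalised so the scanner-z component is positive.  This
   replaces the manual, marker-based alignment an operator performs in
   scanner software; it is *not* an emulation of that manual step.

2. **Reslicing.**  For each angle θ ∈ {0°, 45°, 90°, 135°} (configurable;
   each plane also shows the opposite side of the implant at θ + 180°), a
   plane containing the axis is sampled at voxel-size spacing by trilinear
   interpolation of the *grayscale* volume.  Thresholding happens after
   interpolation: interpolating label images would create stair-step contact
   artifacts.  The sample grid is anchored on the volume's integer
   coordinates along the axial and radial directions, so axis-aligned
   extraction is lossless.  θ = 0° is the +x radial direction of the volume;
   a user-supplied `angle_offset` maps it onto a physically meaningful
   reference plane (e.g. a histology section) when one exists.

3. **Segmentation.**  Pixels are classified IMPLANT (≥ `implant_min`), BONE
   (inside the inclusive window [`bone_min`, `bone_max`] = [60, 90] by
   default), else BACKGROUND.  The window is inclusive at both ends — a
   convention choice; the window itself is the histology-calibrated window
   for newly formed bone on 8-bit reconstructions.  Air, soft tissue and the
   intensity gap between bone and metal all map to one background class.
   An optional minimum-component speckle filter and an optional 3×3 median
   prefilter exist but are off by default.

4. **Profile tracing and groove selection.**  The implant's lateral
   boundary is traced per side as a staircase of unit pixel-edge elements
   (4-neighbour implant/non-implant crossings), top to bottom, end faces
   excluded.  Thread crests are plateaus where the profile's distance from
   the implant midline exceeds the midpoint between its minimum and maximum;
   a groove is the boundary between two consecutive crest centres.  The
   upper four grooves per side (configurable) are measured, indexed from the
   implant top — the end with the smaller axial coordinate; `invert_top`
   covers the opposite mounting.

5. **Contact probing with interface exclusion.**  Metal-induced intensity
   artifacts corrupt the voxels at the bone-metal junction, so an exclusion
   band — the non-implant pixels within `exclusion_layers` (default 1)
   chessboard distance of the implant — is skipped.  Each boundary element
   steps outward along its quantized perpendicular (axis-parallel for
   lateral faces, diagonal at staircase corners, the tie broken toward the
   radial direction) until it leaves the band; the element is in contact iff
   the first pixel beyond the band is BONE.  Probes leaving the image read
   background.

6. **Pooling.**  Per-slice BIC = 100 · Σcontact / Σtotal over the selected
   grooves (pooled lengths, the default: grooves are weighted by their
   actual profile length).  `pooling="groove-mean"` averages per-groove
   ratios instead; with the identical groove geometry of the phantoms below
   the two coincide, but on real implants they differ slightly.  Per-implant
   BIC is the unweighted arithmetic mean of per-slice BIC over the
   extraction angles.

Boundary length is counted in pixel-edge units (1 px per element); sub-pixel
contour smoothing is deliberately out of scope.  Whether the interface
exclusion is applied in-slice (2D) or on the volume (3D) is a genuine
protocol ambiguity; it is applied in-slice here because the measurement
itself is per-slice.

## The phantom generator

No real scan comes with per-groove contact truth, so validation uses
synthetic implant-in-bone volumes with *prescribed* osseointegration.

**Geometry.**  The implant is an axis-aligned cylinder (default Ø 4 mm ×
8.5 mm, the modelled implant) with its thread modelled as annular rings at
pitch spacing rather than a true helix.  In any longitudinal plane the two
are visually equivalent, but rings make every plane's groove geometry
identical, so the per-plane BIC implied by the contact pattern is *exact*,
not approximate.  Thread pitch (1.2 mm), depth (0.6 mm) and crest axial
fraction (0.4) are free parameters — no measured values exist for them —
chosen to give six complete grooves per side, comfortably above the four
that are measured.  Voxels are 20 µm isotropic, the modelled scan
resolution.

**Contact pattern.**  A contact map is piecewise constant over groove rings
× angular sectors (default granularity 8; sector k is centred on k·45°, so
the default measurement angles fall at sector centres rather than on
knife-edge sector boundaries).  `sample_contact_map` gives each groove
exactly `round(target · granularity)` contacting sectors via nested seeded
permutations, making ground-truth BIC monotone in the target fraction.
Where the map says contact, bone (intensity 75, the centre of the default
bone window) fills the annulus right up to the metal; where it says no
contact, bone within 3 voxels (chessboard) of the implant is carved back to
background (20), emulating an unmineralised interface.  The carve boundaries
sit exactly on crest centres, the same planes that delimit grooves in the
measurement, so the analytic truth and an ideal measurement coincide.

**Artifacts** (`add_artifacts`, all off by default):

* *Interface halo* — residual beam hardening: voxels within
  `halo_width_voxels` Euclidean distance of the metal are raised to at least
  `halo_intensity` (default 75, i.e. bone-like).  A saturating floor rather
  than an additive offset: brightening dark interface voxels to the artifact
  level while leaving already-bright bone in its window is what makes the
  artifact read as spurious bone, the failure mode the exclusion layer
  exists to suppress.  The band is Euclidean, not chessboard, so its stated
  thickness holds in every direction — a chessboard band would be √2×
  thicker along diagonals and would genuinely extend past an equally wide
  exclusion band in oblique slices.
* *Ceramic granules* — residual β-TCP: spheres (default radius 40 µm, the
  granule scale of the modelled ceramic) at bone intensity, uniformly seeded
  over the peri-implant region.  Deliberately indistinguishable from bone by
  thresholding: histology can exclude them, CT cannot.
* *Gaussian noise*, clipped to [0, 255].

**What the phantom does not emulate:** trabecular microarchitecture,
implant surface roughness, partial-volume gradients of real reconstructions,
helical thread geometry, projection physics (ring artifacts, cupping,
photon starvation).  Scanner-side corrections (filtered scanning,
beam-hardening and ring-artifact correction) are treated as upstream: the
phantom models only the *residual* post-reconstruction artifacts.  Passing
the validation sweeps therefore shows the measurement machinery is correct
and the exclusion logic does what it claims on clean geometry plus modelled
residual artifacts — not that the thresholds would be well calibrated on any
particular scanner's output.

## Problem sizes

Tests and the acceptance script run a geometrically similar phantom at
validation scale (`PhantomConfig.validation_scale()`): Ø 0.8 mm × 2.4 mm on
a 144 × 128 × 128 grid at the native 20 µm voxel size, preserving every
ratio that matters (thread depth/pitch vs diameter, five grooves per side vs
four measured, bone annulus width in voxels).  The full-scale default
(464 × 320 × 320) runs the identical code path and reproduces the same
exact agreement; it is simply ~20× more voxels for no additional coverage.

## Agreement statistics

Paired two-sided t-tests and Pearson correlation, computable from raw pairs
or from printed summary statistics.  Correlation significance uses the exact
transform t = r√(n−2)/√(1−r²) with n−2 degrees of freedom.  Conventions,
each chosen to be consistent with every published value they reproduce:
two-sided tests throughout; n−1 sample standard deviations; P-values
reported at full precision and rounded half-away-from-zero to two decimals
for table reproduction; strength labels by |r| with cut-offs 0.40 and 0.70
(the published narrative labels 0.30 weak, 0.41 and 0.46 moderate, 0.71,
0.74, 0.81, 0.84 strong — any cut-off pair in (0.30, 0.41] × (0.46, 0.71]
is consistent; 0.40/0.70 are the conventional round values in that region).
One published inconsistency exists: the TCP-group correlation P is printed
as 0.35 in the text but 0.46 (P = 0.36) in the table; the closed-form
recomputation from r = 0.46, n = 6 gives 0.359, which rounds to the table's
0.36.  Both are reported here as computed; the text value appears to carry
an intermediate-rounding artifact.

Identical pairs (zero difference variance) are reported as t = 0, P = 1 —
no evidence of a difference — rather than an error, since the undefined
0/0 statistic has an unambiguous interpretation there.

## Design choices that were genuinely open

* **Exclusion metric:** chessboard (8-neighbourhood), so "one layer" means
  one full voxel shell including diagonals — the visual meaning of a
  one-voxel band on a label image.
* **Inclusive bone window** at both ends; "min/max" wording does not fix
  openness, and inclusivity makes the boundary cases testable.
* **Implant threshold 200:** only the bone window is prescribed by the
  protocol being modelled; titanium sits far above the window ceiling, so
  any value in (90, 230) separates the phantom classes.  200 leaves margin
  for partial-volume blending in oblique slices.
* **Granules count as contact** when they touch the interface — they
  classify as bone, reproducing the ceramic confound rather than correcting
  it.  The paired-batch experiment (`paired_modality_experiment`) uses a
  gamma-distributed per-implant granule load (CV 0.8) because residual
  ceramic burden varies strongly between defects; the granule-free and
  granule-laden batches share all other randomness, giving a paired
  comparison of truth–CT correlation.

## Known limitations

* The groove detector assumes an approximately axis-aligned implant in the
  slice (per-row convex cross-sections); severe tilt must be corrected by
  the axis estimate first (it is, to < 0.1° at 5° tilt on phantoms).
* BIC is measured on 2D planes only; 3D contact over the full helical
  surface is out of scope.
* With `exclusion_layers = 0` the measurement is sensitive to partial-volume
  blending at oblique angles even on artifact-free volumes — a faithful
  property of interface-adjacent voxels, and the reason the exclusion layer
  is the default.
* The phantom's analytic truth is exact only because thread rings make
  grooves angle-invariant; a helical phantom would need a numerical truth.
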