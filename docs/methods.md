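# Methods

## The measurement model

The package treats burden quantification as a three-stage measurement
on a reconstructed micro-CT volume of an I2E-stained, ethanol-immersed
*ex vivo* mouse lung:

1. **Organ extraction.** Stained tissue is brighter than the ethanol
   bath. The organ mask is the largest connected component of voxels
   above a background threshold, after morphological closing (ball
   radius, default 3 voxels) and hole filling. Hole filling pulls the
   air-filled airway lumina into the mask: the burden denominator is
   the *entire specimen*, lumina included. An `include_lumen=False`
   flag exposes the alternative denominator for label-based truth.

2. **Seeded region growing.** A growth from seed $s$ with tolerance
   $t$ accepts voxel $v$ iff $|I(v)-I(s)| \le t/2$, $v$ lies in the
   domain, and (if set) $v$'s center is within `radius_um` of $s$'s
   center; the result is the connected component of the acceptance set
   containing the seed. Two conventions are deliberately fixed:
   - the *reference* gray value is the seed voxel's value, held
     constant for the entire growth. This matches a "static"
     acceptance rule, makes multi-seed unions order-independent, and
     guarantees tolerance monotonicity (a running-mean reference would
     do neither);
   - default connectivity is 26, exposed in every config. Interactive
     tools do not document their connectivity; ours is a declared
     convention, not a claim about any particular software.
   Airways are grown from a trachea seed over the organ mask; tumors
   are grown per lesion with the airway mask removed from the domain
   *before* growth, so a flood cannot tunnel through excluded voxels.

3. **Burden arithmetic.** 3D burden is the tumor/organ voxel ratio ×
   100. 2D burden is the same ratio on one virtual slice (axis 0 by
   default). The histogram split reports whole-organ and
   segmented-part gray histograms over shared bin edges; its
   segmented fraction equals the volume fraction by construction.
   The per-sample report carries three columns — histology-surrogate
   2D, micro-CT virtual-slice 2D, micro-CT volumetric 3D — plus truth
   and signed errors when ground-truth labels exist. CSV output is
   rounded to one decimal; full precision is kept in memory.

## The phantom generator

The generator emulates the contrast structure of stained lungs, not
their anatomy. It emits a gray volume and an exact label partition
(background, parenchyma, tumor, airway lumen, halo, vessel/airway
wall; tumor precedence highest).

- **Organ**: an ellipsoid (default semi-axes 40 % of the grid). Real
  murine lobe anatomy is out of scope.
- **Airway tree**: a deterministic recursive bifurcation — fixed
  branch angle (40°), per-level length and radius decay (0.7), depth 3
  — chosen for bit-reproducibility over realism. The trachea lumen is
  capped 2 voxels below the organ surface, mirroring the surgical
  suture that closes the trachea after inflation in the actual sample
  preparation; this also makes every lumen voxel an enclosed hole of
  the organ mask. Lumen walls carry the bright stained-wall class,
  1 voxel thick.
- **Tumors**: spheres with an optional smooth angular perturbation of
  the radial surface (amplitude = `shape_irregularity`, built from six
  deterministic quadratic modes per lesion). `boundary_sharpness`
  selects a hard step or a linear intensity ramp of `ramp_width`
  voxels; for diffuse lesions the ground-truth label boundary sits at
  the 50 % intensity point (the nominal radius), which gives an
  unambiguous truth for bias studies. Overlapping lesions are allowed
  (merged multifocal tumors); a lesion centered outside the organ is
  rejected.
- **Halo**: a morphological shell (26-connected dilation by the stated
  thickness, clipped to the organ) around a tumor, representing
  inflamed/dead/stressed tissue. Its default gray value *equals* the
  tumor mean — the non-specific stain makes them indistinguishable,
  which is the overestimation mechanism the bias study measures.
- **Noise**: additive zero-mean Gaussian, clipped to [0, 65535].
  Poisson statistics and reconstruction streaks are out of scope.

Absolute gray values are free parameters (micro-CT gray scales depend
on instrument, exposure and reconstruction): defaults are air 2000,
ethanol background 8000, parenchyma 22000, vessel/airway wall 30000,
tumor = halo 40000, on the 16-bit scale, fixing only the ordering the
stain produces. They are documented model choices, not measurements.
`require_well_separated=True` validates that distinct class means are
at least 4σ apart for the configured noise.

What the phantoms do *not* emulate: lobar anatomy, vascular contrast
kinetics, beam hardening, histological shrinkage/deformation, and
pathologist judgment (the "histology surrogate" is simply the true
tumor label on one slice, excluding halo). Passing tests therefore
demonstrate correctness of the segmentation and burden arithmetic and
the *direction* of the stain-driven bias, not performance on real
tissue with ambiguous boundaries.

## Estimator settings and the operator model

Default settings are matched to the default intensity model: organ
threshold 15000 (between bath and parenchyma), airway and tumor
tolerance 16000 (acceptance half-width 8000, well inside the 18000
tumor–parenchyma gap). For phantom-driven runs, each per-lesion growth
is confined to a sphere just covering that lesion (maximal radial
extent + halo + half ramp + 2 voxel margin) via the tool's radius
restriction — emulating the operator who sets the radius around the
lesion at hand to keep the flood from leaking into nearby bright
structures (vessels, trachea). Per-seed tolerance/radius overrides are
part of the config surface, as different lesions genuinely need
different settings. When seeds are supplied explicitly for real data,
no automatic radius is applied.

## Bias study design

`bias_study` replicates generate→segment→report over a phantom family
with per-replicate seeds drawn from one top-level seed, and summarizes
the signed error of (a) the 3D estimate vs truth and (b) a single-slice
2D estimate vs the true 3D burden, under a stated slice rule (central
slice, or a random lung-containing slice). Two canonical families:

- *sharp-contrast, no-halo* (64³ grids, 1–10 tumors, radii 3–15
  voxels, noise σ uniform in [0, gap/8] = [0, 2250]): recovery —
  |3D error| < 1 percentage point in ≥ 95 % of replicates.
- *multifocal halo* (3–8 tumors, radii 3–7, halo 2 voxels at tumor
  gray, σ = 1000): the 3D estimate strictly exceeds truth (halo
  swallowed), while the histology surrogate excludes halo, so the
  report shows 3D ≥ surrogate — the qualitative bias structure the
  three-method comparison is designed to expose. A single-slice
  estimate can sit on either side of the 3D value depending on what
  the slice cuts, and the tables report both directions.

Problem sizes (64³ grids, 20–21 recovery replicates, 12 halo
replicates) are the package's chosen study scale; they keep the full
suite under ten seconds while leaving every estimate comfortably
determined.

## Numerical choices and degenerate inputs

- Gray comparisons use exact integer arithmetic promoted to float only
  at the ≤ t/2 test; ties (|ΔI| = t/2) are accepted.
- Sphere restriction compares center-to-center Euclidean distance in
  μm; isotropic voxels are assumed throughout.
- Connected components via `scipy.ndimage.label` with the 6/18/26
  structuring element; this is exactly the set a breadth-first flood
  visits, which the test suite verifies against a naive BFS oracle and
  against SimpleITK's ConnectedThreshold (6-connectivity).
- Empty cases are errors where silence would corrupt a denominator
  (empty organ mask, empty slice) and empty results where a union over
  zero seeds is well defined (no seeds → empty tumor mask).
- Determinism: every stochastic component consumes a
  `numpy.random.default_rng` stream derived from one configured seed;
  identical configs give bit-identical volumes, masks and CSVs.

## Known limitations

- The flooding rule operates on raw gray values; no denoising or
  intensity normalization is applied, so very low-contrast data needs
  tighter operator control (smaller radii, per-lesion tolerances).
- Diffuse-boundary lesions are segmented at whatever iso-level the
  seed value and tolerance imply, not at the 50 % truth point; the
  resulting bias is measurable with the diffuse family but no
  correction is attempted (manual contour editing, the practical fix,
  is out of scope).
- Anisotropic voxels, DICOM and vendor-native formats are not
  supported.
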