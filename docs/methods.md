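# Methods

This note documents the models, conventions and design choices behind
`rob4d`, in the spirit of the methods documentation of simulation packages:
what is computed, under which assumptions, and what the synthetic test bed
does and does not show.

## Coordinate and unit conventions

All geometry is in patient LPS millimetres: array axis 0 points to the
patient's left, axis 1 posterior, axis 2 superior (SI).  Images are regular
axis-aligned lattices (`Grid`); NIfTI I/O uses a diagonal voxel-to-world
affine.  Image values are *relative proton stopping powers* (water = 1),
not Hounsfield units: the analytic engine consumes stopping power directly,
which avoids committing to a HU calibration curve that is scanner-specific
anyway.  All doses are in Gy (RBE) with the constant RBE factor 1.1 folded
into the prescription; physical dose is never serialized.

## The synthetic 4D phantom

`phantom4d.build_phantom` renders an 8-phase amplitude-binned 4DCT
surrogate: a water-equivalent body cylinder (radius 80 mm), two lung
compartments of relative stopping power 0.26 separated by a unit-density
mediastinal column (half-width 18 mm), and a spherical tumor (default
radius 12 mm, density 1.0) that translates rigidly along one anatomical
axis.  Densities are assigned binarily — no partial-volume blending, no
noise, no CT artifacts.

**Phases and displacements.**  The eight phases CT0in … CT100in … CT25ex
correspond to five amplitude levels (0/25/50/75/100 % of the peak-to-peak
amplitude) with the intermediate levels split into inhale and exhale
branches.  Because the binning is by amplitude, a phase's displacement is
fixed by its level alone — CT0in at full exhale (0), CT100in at full inhale
— regardless of the breathing waveform; the waveform only redistributes
*time* among the phases.  CT50ex is the reference phase, and
`tumor_center_mm` is the tumor position in that phase.

**Displacement fields.**  Each phase carries an analytic DVF on the
reference grid in the pull-back convention: reference point x corresponds
to x + u(x) in the phase.  u(x) = d<sub>p</sub> · g(x) with g = 1 inside a
rigid core (tumor radius + 8 mm, so the CTV moves rigidly with the tumor)
and decaying linearly to zero across the transition shell.  A linear decay
keeps the displacement gradient below Δ/shell, so requiring
`transition_shell_mm` > amplitude/2 guarantees an invertible deformation;
the test suite verifies this with a fixed-point inversion oracle.  The body
outline, mediastinum and OARs are static — the phantom emulates a tumor
moving through low-density lung, not diaphragm or chest-wall motion.

**Breathing weights.**  `breathing_weights` returns the time fraction per
amplitude bin for three assumptions: equal (w = 1/8), a cosine signal
x(t) = A·(1 − cos 2πt/T)/2, and the same expression raised to the fourth
power, which dwells near exhale as real breathing does.  Bin edges sit at
the midpoints between amplitude levels (12.5/37.5/62.5/87.5 %); the
extremes own one bin each and intermediate bins are split by branch.
Sampled weights (4·10⁵ midpoint samples per period) are cross-checked in
the tests against the closed-form arc-cosine bin times.  The exact bin
edges used by scanner reconstructions are vendor-specific; midpoint edges
are this package's convention.

**What the phantom does not emulate:** deformable anatomy (everything
outside the transition shell is static), hysteresis (inhale and exhale
pass through identical geometry), irregular breathing and baseline drift,
CT noise, and density heterogeneity inside organs.  Passing tests
demonstrate the correctness of the evaluation *machinery* under controlled
motion, not the clinical magnitude of motion effects in patients.

## Target construction

CTV = GTV + 5 mm isotropic; ITV = voxel-wise union of the per-phase CTVs;
ITVp_02 = ITV + 2 mm as the robust-optimization target; planning CT =
voxel-wise mean of the eight phases (avgCT).  Margin expansion is exact
Euclidean (distance transform with anisotropic spacing).  The tumor
amplitude is the largest per-axis distance between bounding-box midpoints
of the GTV over any two phases; the bounding-box center (rather than the
centroid) is used because it captures extreme surface excursions — the
common clinical reading of "midpoint".  Phantom GTV/CTV masks are analytic
spheres, which keeps the ground truth free of double discretization.

## The analytic dose engine

The engine is a broad-beam SOBP model, intentionally simple: the package's
subject is the *evaluation strategy*, which is engine-agnostic, and the
engine hides behind one `compute_dose` call so a clinical dose engine could
be substituted.

Per beam (axis-aligned directions only):

* **Depth dose**: cumulative water-equivalent depth (WEPL) along the
  propagation axis (midpoint rule), mapped through an SOBP profile — unity
  plateau between the proximal and distal bounds, a reduced proximal
  plateau ramping from 0.85 at the surface, and a Gaussian distal shoulder
  with an 80–20 % falloff width of 5 mm.
* **Lateral profile**: the target silhouette in the beam's eye view,
  expanded by the aperture margin and blurred with a Gaussian penumbra
  (σ = 4 mm).

The plan is fitted once on the planning CT: SOBP bounds from the target
WEPL span ± 12 mm, apertures from the ITVp_02 silhouette, and a single
normalization constant mapping the median nominal target dose to the
prescription (60 Gy RBE in 30 fractions).  Nothing is ever re-fitted per
scenario or phase — setup and range errors are systematic, so every
scenario perturbs the delivery of the same fixed plan.

**Aperture margins** default to 12 mm in the axial plane and 10 mm along
SI.  The SI margin can be tighter because the ITV-based target already
encloses the full breathing excursion along the motion axis; the default
values were chosen, as in clinical practice, by iterating plan creation
and 3D robust evaluation until the plan met the acceptability constraints
on the planning CT while the penumbra remained realistically narrow.  With
these defaults the extreme breathing phases graze the aperture penumbra
under 5 mm setup shifts — which is precisely the regime in which the three
4D evaluation strategies disagree and the phase-averaged strategy shows
its value.

**Scenario application.**  A scenario is a rigid setup shift (applied to
the whole patient, common to all beams) plus a global multiplicative
density scale (range error).  The patient grid is translated by −shift,
densities are scaled, dose is cast, and the result is translated back onto
the patient grid so it can be evaluated against unshifted contours.
Voxel-multiple translations use exact integer rolling; others trilinear
resampling.

## Scenario sets

* Evaluation: 28 scenarios = 14 shift directions (6 cube faces + 8 cube
  corners renormalized to the 5 mm setup magnitude) × 2 density scales
  (±3 %), nominal not included.  The direction set follows the face+corner
  convention common in robust-evaluation protocols; the count and closure
  under negation are what the envelope semantics requires.
* Optimization: 21 scenarios = 1 nominal + 6 axis shifts + 2 pure density
  scales + 12 axis-shift×density combinations.  Extending every scenario
  to all 8 phases gives 168 4D optimization scenarios — the package counts
  them (`count_4d_scenarios`) but deliberately performs no 4D robust
  optimization.

## Evaluation strategies

All four strategies evaluate the same fixed, once-normalized plan.

* **3D robust** (planning CT): nominal dose plus VWmin/VWmax over the 28
  scenarios.  Target goals are read from VWmin, OAR near-maximum goals
  (D0.03cc) from VWmax, mean-dose goals from the nominal — the standard
  distribution-selection rule.
* **4DNom**: nominal dose recomputed on each phase with that phase's
  contours; each DVH parameter is reported as the worst over phases
  (lowest target dose, highest OAR dose).
* **4DRobInd**: an independent 3D robust evaluation per phase (8 VWmin +
  8 VWmax grids); parameters reported as the phase mean.
* **4DRobAvg**: per scenario, compute on every phase, warp to the
  reference, form the breathing-weighted sum; then VWmin/VWmax over the 28
  weighted sums plus the weighted nominal — exactly three output dose
  distributions.  DVH parameters use the reference-phase contours, and the
  accumulated (tissue-following) dose is judged against the reference CTV,
  not against the ITV (a geometric envelope, not tissue).

Voxel-wise, min over scenarios of the weighted phase sum dominates the
weighted sum of per-phase minima — the elementary inequality behind the
observation that the per-phase envelope strategy is over-conservative.  In
the static limit (zero amplitude, identity DVFs) the phase-averaged
evaluation reproduces the 3D robust evaluation exactly; the test suite
asserts agreement to 10⁻⁹ Gy.

The `RobustDose` envelope is clamped to include the nominal member, so
vwmin ≤ nominal ≤ vwmax holds voxel-wise by construction while the
scenario count still refers to the 28 error scenarios.

## Dose warping

Pure trilinear pull-back interpolation of dose, with out-of-grid samples
set to zero and counted; masks are warped as scalar fields and
re-thresholded at 0.5.  No energy/mass-conserving correction is applied:
instead of correcting the mapping, the QA module quantifies its DVH impact
(below).  Identity DVFs short-circuit to an exact copy, so the static
limit is bitwise clean.  Dose (not energy) is interpolated.

## DVH metrics and clinical goals

Voxel-rank conventions without sub-voxel interpolation: Dx% is the dose at
rank ⌈x/100·N⌉ of the descending-sorted structure doses; VxGy counts
voxels at or above the threshold; D0.03cc walks the sorted voxels until
the cumulative volume reaches 0.03 cm³ (structures smaller than the probe
volume return their minimum with a warning).  These choices are
deterministic and oracle-checkable; comparisons with a commercial TPS
should expect small differences from interpolated-DVH conventions.

Default goal set: targets D95% > 95 %·D_pres and V95% > 95 % on VWmin;
D0.03cc < 76 Gy for heart, esophagus and the 5 mm-expanded mediastinal
envelope and < 54 Gy for spinal cord on VWmax; contralateral-lung
V5Gy < 60 % and mean lung-minus-GTV dose < 20 Gy on the nominal dose; and
soft (preferred) mean-dose goals of 10 Gy for heart and 26 Gy for
esophagus.  A goal whose structure is missing is reported as
not-evaluable, never as a pass; a hard-goal failure sets a non-zero
process exit code in the CLI.

## QA checks

* **Dose-deformation DVH consistency**: for all 29 cases (28 scenarios +
  nominal) and each of the 7 non-reference phases, DVH parameters are
  extracted before warping (phase dose, phase contours) and after warping
  (warped dose, reference contours); absolute differences above 1 Gy are
  flagged as clinically relevant, and differences above 2 % of the
  prescription on any CTV structure raise a user notification.  Both
  thresholds are configuration defaults, not constants.
* **Containment**: the per-phase (unadjusted) CTV contours must lie inside
  ITVp_02; violations are reported with voxel counts and locations.

## Numerical choices and degenerate inputs

Equality-critical paths avoid interpolation: zero shifts skip the
translation entirely, identity DVFs skip resampling, voxel-aligned
translations use integer rolling.  Weighted sums use exact 1/8 weights in
the equal scheme, so eight identical phases reproduce the single-phase
dose to double-precision rounding.  Empty masks warn and propagate
(expansion, containment) or raise (DVH metrics, amplitude), matching
whether an empty input is meaningful or an error.  Dice of two empty masks
is defined as 1.0.

Default problem sizes — a 64³ grid at 3 mm spacing and a 20 mm default
amplitude — resolve the 4 mm penumbra with about one voxel per sigma;
coarser grids (tested at 4 and 8 mm) under-resolve the penumbra and their
plans legitimately fail the target constraints, which the test suite uses
as a negative control rather than hiding.

## Known limitations

* The engine has no spot-level delivery, no MLC/aperture trimming, no
  interplay simulation, and no robust optimization — plans are
  constructed, not optimized, and only axis-aligned beams are supported.
* The phantom's motion is locally rigid; registration error is emulated
  only through deliberate fault injection (biased DVFs), not through a
  deformable registration algorithm.
* Evaluations cover the planning 4DCT only: no repeat-CT anatomy changes,
  no fraction-by-fraction accumulation, no breathing-pattern variability.
* DICOM-RT I/O is out of scope for this version; images, masks, DVFs and
  doses round-trip through NIfTI + JSON.
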