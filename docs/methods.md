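# Methods

`rodentmri` implements the computational core of a small-animal brain MRI
preprocessing workflow: intensity bias correction, histogram-based brain
extraction with a quantitative mask-quality report, intensity-driven
rigid/affine/nonlinear registration, iterative group-template
construction, per-slice EPI distortion correction, BOLD realignment, and
FAIR arterial-spin-labeling CBF quantification. Everything is exercised
end to end on synthetic head phantoms with ground truth known by
construction; no external data or binaries are required.

## Geometry and data model

Voxel indices are 0-based; the 4×4 affine maps homogeneous index
`(i, j, k, 1)` to world millimetres; the world frame is RAS+ (+x right,
+y anterior, +z superior) after reorientation. Reorientation applies only
the nearest axis permutation/flips — never a resampling — so world
coordinates are preserved exactly; oblique affines stay oblique with a
warning. Intensities are processed as float64 regardless of on-disk
dtype; masks and label maps are integers and are only ever resampled with
nearest-neighbour interpolation.

All spatial transforms use the *pull* convention: a transform maps
reference (fixed) world coordinates into moving (source) world
coordinates, which is what a resampler consumes directly. A
`TransformChain` applies its elements in order and merges adjacent
affines analytically, so applying a chain is bit-identical to applying
its composed "one big step" form; images crossing several spaces are
interpolated exactly once.

## Synthetic head phantom

The default phantom is a 64×64×32 grid at 0.2×0.2×0.5 mm — the strongly
anisotropic multislice geometry typical of rodent acquisitions. It
consists of concentric ellipsoids: a brain (semiaxes 4.0×4.4×5.0 mm) with
a bright cortex-like rim (intensity 1.0), a mid-intensity interior
(0.75), and two dark mirrored ventricle-like inclusions (0.25); a
near-zero CSF gap of 1.0 mm; and a skull/scalp shell (1.3, brighter than
cortex so histogram methods see two tissue modes above background). The
gap is deliberately wider than the largest voxel so the shell stays
topologically separate from the brain after discretization.

The brain interior additionally carries deterministic piecewise-constant
"pseudo-structure": a smooth harmonic field quantized to four intensity
levels (amplitude 0.15). This serves two purposes at once. Nonlinear
warps are only identifiable where the image has contrast — on a
textureless interior *no* method can recover the true displacement — and
the quantization keeps the intensity histogram discrete, which is what
real near-piecewise-constant brain compartments look like and what the
bias model below exploits. The texture is even in (x − centre), so the
noise-free symmetric phantom is exactly mirror-symmetric, a property
several tests rely on.

Corruptions with known ground truth: smooth multiplicative bias fields
(seeded low-order polynomial, exact mean 1, range within
[1−a, 1+a]); rigid/affine/nonlinear warps applied consistently to image
and masks; frame-wise rigid motion for BOLD; per-slice quadratic
in-plane EPI-like distortion; and FAIR signal series (below). Every
generator is a pure function of its spec and seed. Noise is Gaussian
(not Rician) — a documented simplification; magnitude signal positivity
is respected by the FAIR model itself.

What passing these tests does *not* show: performance under Rician noise,
partial-volume boundaries, susceptibility dropout, real coil-profile
bias, or inter-subject anatomical variability. The phantoms validate the
numerics and the contracts, not in-vivo robustness.

## Bias correction

The observed log-intensity inside the head is modelled as

    log I(x) = P(x) + c_{k(x)}

with `P` a low-order 3D spatial polynomial (default order 3, the log of
the multiplicative bias field) and `c_k` an offset for the intensity
class `k(x)` of the voxel. Classes come from a deterministic 1D k-means
(quantile initialisation, 12 classes) over bias-corrected
log-intensities and are re-estimated alternately with the least-squares
fit (8 alternations). The decomposition matters: fitting the polynomial
alone would absorb the brain's own radial contrast (bright rim, darker
interior) into the "bias"; giving each tissue class its own offset makes
the smooth field identifiable. The returned field has geometric mean 1
over the head mask (a multiplicative field is only defined up to scale)
and `corrected × field` reconstructs the input to machine precision.
Degenerate inputs (constant image, empty head mask) raise.

## Brain extraction and mask QC

Extraction thresholds at the deepest valley between the two most
prominent peaks of the 64-bin, σ=2-bin-smoothed intensity histogram
(ties toward the lower threshold), or at a user fraction of the robust
maximum (99th percentile); then a one-voxel morphological opening and
closing, retention of the largest 6-connected component, and hole
filling. The mask report computes, per threshold: volume (voxel count ×
voxel volume), world-axis bounding-box extents (right–left,
antero-posterior, inferior–superior, counting whole voxels), and the
mid-sagittal symmetry correlation. Failed thresholds produce NaN rows,
not exceptions.

The mid-sagittal plane is restricted to near-x-normal planes (offset
plus two tilts ≤ ~10°): brains are imaged roughly axis-aligned and the
restriction keeps the search cheap and well-posed. Search is a coarse
grid (half-voxel offsets over the central third, 2° tilt steps, at half
resolution) followed by Nelder-Mead refinement at full resolution. The
symmetry score is the Pearson correlation between the mask and its
reflection, computed over the one-voxel neighbourhood of the union of
both supports — the neighbourhood keeps the correlation defined (nonzero
variance) when mask and reflection coincide exactly, and still penalises
asymmetry because disagreeing voxels enter the union.

## Registration

**Metric.** Normalised mutual information, NMI = (H(A)+H(B))/H(A,B),
from a 32-bin joint histogram over the overlap of nonzero supports with
1st–99th-percentile intensity limits; NMI(X,X)=2 and the implementation
is exactly symmetric (entropy terms are summed in sorted order). An SSD
option exists for same-contrast problems (realignment, FFD).

**Linear.** Rigid (6-dof) and affine (12-dof, parameterised as rotation
· shear · log-scales about the target centre) registration maximise the
metric with a derivative-free Powell search over a multiresolution
pyramid (×4, ×2, ×1; levels that would leave fewer than ~8 voxels per
axis are skipped; the finest level only polishes). Initialisation is
centroid pre-alignment (mask centroid when available, intensity centroid
otherwise); the affine starts from the rigid solution and gets a larger
line-search budget (the rotation/shear trade-off needs it). Two
safeguards keep the search honest: the result is never worse (in metric)
than its initialisation, and a warning is raised if it fails to improve
on the centroid-aligned start. Masks, when given, gate the metric only —
the returned transform always maps whole-head geometry. There is no
stochastic restart anywhere; identical inputs give identical transforms.

**Nonlinear.** A coarse-to-fine cubic B-spline free-form deformation:
control-grid spacing starts at a quarter of the field of view and halves
per level. Each level minimises SSD (after robust intensity matching)
with L-BFGS-B using the analytic gradient, under a box constraint of
0.4 × spacing per control-point component — the classical sufficient
condition for a cubic FFD to remain diffeomorphic. Level fields are
*composed*, not added, so the total stays a diffeomorphism; the emitted
dense field must have strictly positive discrete Jacobian at every
interior voxel or the registration aborts. A small L2 penalty on the
displacement (1e-3 × the target's mean squared intensity) anchors the
metric's null space: in flat regions image similarity cannot determine
the warp and the field would otherwise drift.

**Per-slice EPI correction.** The 2D analogue of the FFD, run
independently per z-slice between the EPI and the anatomical image
resampled into EPI space — deliberately more conservative than a global
3D warp, matching how EPI distortion behaves (in-plane, slice-wise).
Slices with ≤1 % tissue keep identity warps; out-of-plane displacement
is identically zero and is looked up nearest-in-z so slices stay
independent.

**Inversion.** Affines invert exactly; displacement fields and slice
warps invert by a damped fixed-point iteration (the undamped iteration
can oscillate near the support edge), with a verified mean round-trip
residual ≤ 0.1 voxel.

## Group template

The template pipeline follows the classic multi-level iterative scheme:
median-normalised, bias-corrected heads are first averaged after
translating each brain-mask centroid to the grid centre; then, per
schedule stage (rigid → affine → nonlinear, degrees of freedom never
decreasing), every subject is registered to the current template, its
transform chain extended, the subject resampled from its *original*
image in one step, and the average recomputed. Stage updates are guarded
— a subject keeps its previous chain if the new registration lowers its
NMI to the template — and the linear-stage metric is gated by an
auto-extracted template mask. The log records per-iteration mean
relative template change and mean pairwise NMI of the aligned subjects.
The default schedule is centroid → rigid×2 → affine×2 → nonlinear
(levels 1, 2); iteration counts are configurable and the defaults are
sized for single-CPU desk-scale runs. The template grid defaults to the
first subject's grid.

## BOLD and coregistration

Slice-timing correction linearly interpolates each voxel series to the
middle-of-acquisition reference time (first/last frames clamped) —
linear, not sinc, a documented simplification. Realignment registers
every frame rigidly to frame 0 (SSD metric by default — frames share
contrast); the motion table holds rotations (deg) and translations (mm)
about the grid centre, frame 0 exactly zero. Translational motion is
recovered to a fraction of a voxel; rotational motion is recovered more
coarsely (~1°) and is reported without a hard guarantee. The
representative BOLD volume is the post-realignment temporal mean
(median available).

`coregister` aligns an anatomical image with a modality: the
representative volume is the BOLD temporal mean or, for FAIR perfusion,
the fitted equilibrium-magnetization (M0) map; the anatomical is
reoriented (losslessly) to the modality axes; optionally a
modality-to-anatomical rigid transform is estimated and its inverse
applied to the anatomical (or inter-scan motion is assumed negligible);
finally the per-slice warps absorb EPI distortion.
`register_to_template` chains rigid → affine (brain-masked metric) →
nonlinear (whole head); an affine indistinguishable from identity is
snapped to identity so the nonlinear stage never sees a needlessly
resampled image. Modality images reach template space through the full
chain (slice warps → rigid → anatomical warp) in a single interpolation;
the inverse chain carries template-space images (atlases) back to the
individual's modality space.

Pipeline steps accept a work directory for content-hash memoization
(SHA-256 over array bytes and parameters); a cache hit returns exactly
what a fresh run computes, and reruns on identical inputs are
bit-identical.

## FAIR perfusion quantification

Per voxel, both series are fitted with the magnitude inversion-recovery
model `S(TI) = |M0 (1 − 2α e^{−TI/T1})|` — M0 equilibrium magnetization,
T1 apparent relaxation time (s), α ∈ [0.5, 1] inversion efficiency.
Fitting the magnitude directly is robust to the polarity flip at the
null point. Initialisation is a grid search (13 T1 values in 0.2–3.0 s ×
3 α values, closed-form M0 per candidate); refinement is a bounded
Levenberg–Marquardt vectorised over all voxels simultaneously. Voxels
with relative residual above 20 % (config-exposed), or without signal,
are excluded from the fit mask; all output maps carry 0 outside it, with
the mask as the authority on validity.

For CBF the selective/nonselective pair is fitted with a *shared*
inversion efficiency (`fit_fair_pair`): α is a property of the sequence
and coil, not of the voxel, and letting it float independently in both
series inflates the variance of the small rate difference CBF is built
from. The nonselective series is fitted with free α, the median fitted α
over its mask becomes the global efficiency, and both series are then
refitted with α pinned — this roughly halves the worst-case region-median
CBF error at realistic SNR compared with fully independent fits.

CBF follows the standard FAIR difference of apparent relaxation rates,

    CBF = 6000 · λ · (1/T1_sel − 1/T1_ns)   [ml/100 g/min]

with λ the blood–brain partition coefficient, default 0.9 ml/g
(literature standard); both λ and the constant are exposed. Negative
values are retained but counted. The simulated protocol uses 16 linear
inversion times from 0.05 to 6.0 s: a dense ladder keeps the low-flow
rate difference identifiable at realistic SNR, where sparse 8-point
ladders showed several-percent median bias. Regional summaries report
count, median, quartiles, Tukey adjacent values, mean and SD per atlas
label. Transit-time and multi-compartment effects are out of scope.

## Evaluation

Dice = 2|A∩B|/(|A|+|B|), computed by exact set counting; both masks
empty is defined as 1.0 (the formula is 0/0 there) and exactly one empty
as 0.0. `regional_dice` applies the same per label, background excluded,
labels matched by integer id only.

## Problem sizes and numerical defaults

Validation runs use the 64×64×32 phantom for registration, extraction,
bias, template (6 subjects) and realignment, and an EPI-resolution
32×32×16 grid for the ASL phantom — sizes chosen as representative
single-CPU desk-scale problems. Key defaults: 32 histogram bins;
pyramid ×4/×2/×1; Powell xtol 1e-3 (in degrees/voxel-scaled units);
FFD cap 0.4 × spacing, L-BFGS-B ≤80 iterations per level; k-means 12
classes; fit-mask residual threshold 20 %; λ = 0.9 ml/g. Ties in the
histogram-valley search break toward the lower threshold; empty-overlap
metric evaluations score −∞ inside the optimizer rather than raising.

## Known limitations

Reorientation across genuinely oblique acquisitions leaves obliquity in
place; the rotational component of motion is estimated more coarsely
than translation; NMI is not available for the nonlinear stage (SSD with
intensity matching stands in); the FFD can develop small spurious
displacements (fractions of a voxel) in completely flat regions when the
inputs differ only by interpolation blur, bounded by the displacement
penalty; Rician noise, partial volume and susceptibility artefacts are
not simulated.
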