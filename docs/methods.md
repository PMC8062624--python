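# Methods

This note documents the models and procedures `octsclera` implements, the
parameters that matter, the synthetic data the package validates itself
on, and the design decisions taken where the underlying method description
leaves room.

## Boundary segmentation

The segmentation runs in four steps: (i) an initial choroid inner boundary
(CIB) per B-scan, (ii) a final CIB from smoothing across B-scans, (iii) an
initial choroid outer boundary (COB) per B-scan conditioned on the final
CIB, and (iv) the same smoothing for the COB.

### The two-step enhancement

Both detectors share one enhancement chain on preprocessed B-scans
(two passes of a 6 × 6 median filter, then contrast-limited adaptive
histogram equalization with 6 × 6 tiles, clip limit 0.01):

* raw scale: `I_raw = (I/255)^4`. The fourth power makes bright reflectors
  (RPE complex, choroidal stroma) dominate every sum that follows.
* exponentiation: `I_expenh = (I_raw / (2·S))^n` with `n = 10`.
  The default denominator `S` is the **full column sum** of `I_raw`, i.e. a
  per-A-scan normalization. Under it the ratio never exceeds 1/2 (the sum
  contains the pixel), so the output is bounded by `0.5^n`, and every
  dominant reflector of a column responds together — which is what lets
  thresholding produce large connected components of the retinal layers.
  A `denominator="tail"` option sums from the pixel's own row to the image
  bottom instead; with `n = 10` that variant responds essentially only at
  the last signal row of each column and is kept for completeness, not
  used by the detectors.
* depth weighting: `I_nonlin = x²·I_expenh`, `x` the 0-based axial row.
  Row 0 is thereby forced to zero; boundaries never sit on the first row.
  For the CIB the chain runs on the vertically flipped B-scan (retina at
  the bottom, highest row indices, so the retinal layers saturate); for
  the COB, in the original orientation.

### Binarization

The enhanced response spans many decades (a ratio to the 10th power), so
"threshold at mid-gray 128" is defined on a compressed 8-bit rendering of
the response, not on its raw values:

* CIB: the rendering is the `1/n`-th root of the response, max-normalized —
  a pixel passes when its response is within `(128/255)^n` of the peak.
  On this scale the bright retinal band passes as a whole while choroid
  and sclera, an intensity factor below it, fall out (the factor enters to
  the 4·n-th power).
* COB: binarization happens inside the sub-retinal region only (rows more
  than `cib_margin_px` = 8 below the final CIB, a margin larger than the
  smoothing half-window so retinal brightness cannot leak into the
  normalization), and the rendering uses the full `1/(4n)`-th root — the
  equivalent-intensity scale — because choroid-vs-sclera contrast is an
  intensity ratio (~2.5×), much smaller than the RPE-vs-stroma contrast
  the CIB step exploits.

Both renderings are median-filtered (window = the preprocessing median
window) before thresholding, which regularizes the speckle-driven response
into contiguous regions.

### From masks to traces

* CIB: the binarized (un-flipped) mask is first filtered for depth
  consistency — connected components whose mean row lies further than 10 %
  of the axial extent from the largest component's mean row are spurious
  structure, not retina — then morphologically closed (disk radius 3),
  opened with a small element (radius 1, so the thin RPE band survives),
  and cleaned of components below 0.5 % of the B-scan area. Each column's
  estimate is the deepest (choroid-facing) retained pixel. Columns whose
  estimate jumps more than 8 px from a 31-column running median become
  gaps; columns with no component are gaps as well. An all-NaN trace flags
  the B-scan as empty.
* COB: the sub-retinal bright mask is closed, hole-filled (vessel lumina
  belong to the vascular mass) and size-filtered; the per-column deepest
  pixel of the retained mass is the extreme point towards the sclera.
  The extreme-point envelope is despiked with a 9-column median (speckle
  spikes and the dips over unfilled lumen openings are both narrower than
  half a large vessel) and interpolated/smoothed by tensor voting into a
  continuous initial trace.

### Tensor voting

Sparse (column, depth) anchors are completed by a stick-vote scheme: each
anchor's orientation is a Gaussian-weighted local line fit over its
neighbours (scale `tv_scale` = 15 px); the anchor votes the linear
prediction `d_i + s_i (c − c_i)` onto every column with strength
`exp(−(c−c_i)²/2σ²)`, and each column takes the strength-weighted mean of
its votes. Collinear anchors are completed exactly by their line; one
anchor gives a constant trace. This is a deliberately compact formulation
of the classical stick-voting saliency framework — votes are cast along
estimated tangents with Gaussian decay, but no curvature penalty or full
tensor accumulation is kept, since the traces being completed are nearly
horizontal single-valued curves.

### Orthogonal smoothing (RLOESS)

For each lateral column, the depth series across B-scan index is smoothed
by robust LOESS: local quadratic fits with tricube distance weights,
bisquare robustness reweighting (5 iterations, scale = 6 × median absolute
residual, floored at 10⁻⁶ of the data scale so an already-exact fit is not
reweighted on numerical noise), window span 0.1 of the series but at least
9 points — a robust quadratic needs roughly three points per parameter,
and smaller windows would chase the very outliers the step must reject.
Local windows with fewer valid points than parameters yield no estimate
and are filled from neighbouring estimates; lateral columns with too few
valid B-scans are interpolated from neighbouring columns (logged).
A tensor-voting pass along each B-scan then smooths residual deformations.
Finally the COB is clamped to at least CIB + 1 (positive choroidal
thickness, logged when it triggers).

Degenerate inputs: a volume where more than half the B-scans are empty, or
where fewer than 25 % of A-scans produce a retinal estimate, raises
`SegmentationError` — pure-noise input fails loudly instead of returning a
surface.

## Flattening and en-face extraction

Each A-scan is shifted axially by `plane − COB(y, x)` so the interface
lands on a common plane (default: the deepest COB, so no scleral content
is cropped). Integer shifting is the default — bit-exact and invertible
over non-vacated voxels; vacated voxels fill with 0 (dark, like signal-free
regions). A sub-pixel mode interpolates linearly along each A-scan for
smoother slices. En-face slices are the constant-depth planes at and below
the interface; substack projections (mean or minimum intensity over 5–30
slices) follow the practice of scrolling a short stack to confirm a vessel
across depths. Substack choice remains the user's; `suggest_substack` only
ranks windows by dark-spot contrast.

## Topography

The 12 mm field divides into nine 4 × 4 mm sectors; cells are half-open
with the far edge belonging to the last cell, so the field is exactly
partitioned. Anatomical labels need the eye's laterality: in a
fundus-orientation image the temporal retina is on the image left for OD
and on the right for OS (configurable if a source uses another display
convention); smaller y is superior. Eyes with fewer than 10 identified
arteries are excluded — the histological minimum number of SPCAs per eye.
Cohort summaries use the sample (n−1) standard deviation; a single eye
reports SD 0 with a flag. Report tables round percentages half away from
zero to whole percent; full precision is kept internally.

## Validation statistics

* Dice: per A-scan, the compared segmentations span pixel-index sets
  (choroid band between CIB and COB, or anterior-to-boundary bands for
  single-boundary comparisons, after rounding to integer pixels);
  `DC = 2|A∩B|/(|A|+|B|)`. Two empty sets score 1 — both raters agree
  there is no choroid at that A-scan. The production path computes DC by
  interval arithmetic and is tested against a literal set-based oracle.
  An "average of two manual readings" reference is the per-A-scan mean
  boundary depth rounded half-up.
* Observer agreement: each mark reduces to its radial pixel position
  `Z = √(X²+Y²)` with the bottom-left corner as origin; paired trials are
  matched by greedy nearest-neighbour within 1 mm, correlated with
  Pearson's r per eye, and summarized by the median over eyes, computed as
  the mean of the two middle order statistics for even counts. The radial
  reduction discards angular information by construction; two marks at the
  same eccentricity are indistinguishable to it, which this package
  documents rather than repairs. The consistency tolerance ε (default
  1.5 px) flags marks whose expert position departs from the radial value.
* Qualification bins: below 0.20 very weak, 0.20–0.40 weak, 0.40–0.60
  moderate, 0.60–0.80 strong, above 0.80 very strong; a value exactly on
  an edge belongs to the higher bin (the ranges overlap at their
  endpoints, so a convention is required), and the label applies to |r|
  with the sign reported separately.

## The synthetic phantom

The generator emulates what an exported 8-bit wide-field volume of a
healthy posterior pole looks like:

* layers top-down: a detector noise floor (~25 gray), retina (150) with a
  bright RPE–Bruch's complex (240, 8 px) at its bottom, vascular choroid
  stroma (170) holding dark lumina (45) — small Sattler-type tubes in the
  inner choroid and large Haller-type tubes whose lower walls ride on the
  interface — sclera (90) crossed by dark oblique SPCA cylinders entering
  the choroid at known en-face positions;
* geometry: a bowl-shaped warp (12 px amplitude) for the curvature of the
  eye and a gentle sinusoidal choroidal-thickness variation (±4 px);
* signal model: exported OCT scans are log-compressed, so attenuation
  appears as a linear gray ramp with depth (0.08 gray/px default) rather
  than a multiplicative exponential; speckle is multiplicative unit-mean
  Gamma noise (variance 0.15 default);
* a fixed seed reproduces the volume bit-exactly; the ground truth is
  returned in the same `BoundarySurface`/`VesselMarkSet` containers the
  detectors emit.

Default scale is 256 × 256 × 64 (axial × lateral × B-scans) over a 12 mm
field — large enough for the 6 × 6 filter windows and the across-B-scan
smoothing spans, small enough that a full segmentation takes seconds; the
test suite uses a 128 × 96 × 24 variant for unit-level checks, and
full-scale 1024 × 1536 × 1024 generation is supported but not default.
What the phantom does **not** model: a point-spread function, polarization
effects, retinal sublayer anatomy beyond the RPE complex, the optic nerve
head, motion artefacts, vessel shadowing, and pathology. Passing the
phantom tests therefore shows the pipeline recovers layered anatomy of the
assumed contrast ordering (RPE brightest, stroma above sclera, lumina
dark) under speckle and curvature — not that it handles every clinical
acquisition.

Observer simulation drops each true mark with probability 0.05 and jitters
survivors by isotropic 0.2 mm Gaussian noise (defaults). Per-eye
randomness derives deterministically from the seed and eye index, so runs
at different jitter levels perturb identical truths with identically drawn
displacements — jitter comparisons are paired.

## Known limitations

* The COB estimate rides the deepest detected extent of the vascular
  choroid and carries a small systematic shallow bias (≈1–3 px at default
  scale) where large lumina open through the binarized mass.
* Sector labels assume fundus display orientation; mis-set laterality
  mirrors nasal/temporal labels (the OD/OS symmetry test guards the
  convention, not the metadata).
* The radial agreement statistic is scale-free but blind to angular
  displacement, as noted above.
* Boundary detection assumes one retina per A-scan; detached or duplicated
  retinal layers violate the depth-consistency filter's single-mass
  assumption.
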