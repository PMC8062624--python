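# octsclera

Choroid segmentation, choroid–sclera interface flattening and scleral
en-face topography of short posterior ciliary artery (SPCA) entry sites in
wide-field swept-source OCT volumes.

## The problem

The choroid is perfused by posterior ciliary arteries whose short branches
(SPCAs) cross the sclera obliquely before entering the choroid. Wide-field
swept-source OCT (12 × 12 mm volumes of ~1024 B-scans) reaches deep enough
to show these vessels as hyporeflective tracks in the sclera — but only in
en-face view, and only after the curved choroid–sclera interface (CSI/COB)
has been flattened. `octsclera` implements the full chain a reading-centre
workflow needs:

1. **Boundary segmentation.** Per B-scan, the choroid inner boundary (CIB,
   the retina/choroid interface at the RPE–Bruch's complex) and choroid
   outer boundary (COB, the choroid–sclera interface) are detected from a
   two-step exponentiation enhancement: raw intensities `I_raw = (I/255)^4`
   are normalized per A-scan, raised to a power *n* = 10
   (`I_expenh = (I_raw / 2Σ I_raw)^n`), and depth-weighted
   (`I_nonlin = x² · I_expenh`, *x* the axial row). For the CIB the chain
   runs on a vertically flipped B-scan so the retinal layers saturate; for
   the COB it runs in the original orientation so deep choroidal structure
   wins. Binarization at the mid-gray threshold 128, morphological
   cleaning, per-column extreme points and tensor-voting interpolation give
   initial traces; robust LOESS across B-scans plus a tensor-voting pass
   within B-scans gives the final, gap-free surfaces.
2. **Flattening and en-face extraction.** Every A-scan is shifted so its
   COB lands on one plane; constant-depth slices below that plane are
   scleral en-face images, and 5–30-slice substack projections make the
   dark SPCA entry sites easy to follow.
3. **Topography.** Entry-site marks (per eye, observer and trial) are
   assigned to a 3 × 3 grid of 4 × 4 mm sectors with anatomical
   (superior/inferior × nasal/temporal) labels; eyes with fewer than 10
   identified arteries are excluded (the histological minimum per eye).
4. **Validation statistics.** Per-A-scan Dice coefficients
   `DC = 2|C_x ∩ C_y| / (|C_x| + |C_y|)` between segmentations, and
   observer agreement via Pearson correlation of radial mark positions
   `Z = √(X² + Y²)` (bottom-left image origin), with the median over eyes
   taken as the mean of the two middle order statistics and qualified on
   the five-bin scale (very weak < 0.20 … very strong > 0.80).

No clinical volumes ship with the package. A synthetic-phantom module
generates layered OCT volumes (retina with a bright RPE complex, vascular
choroid, sclera with oblique SPCA tracks, bowl-shaped curvature, speckle)
with exact ground-truth surfaces and marks, so every stage is testable end
to end.

## Worked example

```sh
octsclera simulate --seed 7 --out phantom.tif --truth-prefix truth
octsclera segment  --input phantom.tif --out-prefix auto
octsclera validate --seg1 auto --seg2 truth --boundary band
octsclera enface   --input phantom.tif --cob auto_cob --first 2 --count 8 --mode min --out sclera.png
octsclera sectors  --marks truth_marks.csv --laterality OD
```

prints (abridged):

```
wrote phantom.tif shape=(256, 256, 64)
segmented phantom.tif: CIB depth 92.7 px, COB depth 142.1 px (means); surfaces under auto_*
{"boundary": "band", "mean_dice": 0.9553, "sd_dice": 0.0335}
wrote sclera.png (slices 2..9 below the interface, min)
{"mean_count": 14.0, ..., "pooled_percent": [[0, 14, 0], [21, 21, 7], [14, 14, 7]]}
```

The phantom's true mean CIB/COB depths here are 92.0 and 142.0 px, so the
detected surfaces are within a pixel on average; the choroid band between
the detected and true surfaces overlaps with a Dice coefficient of 0.955.
The sector table counts the 14 planted SPCA entry sites per 4 × 4 mm cell
(rows superior→inferior, columns left→right of the image) and the
percentages sum to ~100 after rounding.

Observer repeatability on simulated paired trials (18 eyes, 0.2 mm mark
jitter, 5 % missed marks):

```sh
octsclera agree --marks observer_marks.csv --mode auto
# -> median_r 0.9954, "very strong correlation", n_pairs 18
```

The same operations are available as a library (`octsclera.segment_volume`,
`flatten_volume`, `compute_distribution`, `dice_report`,
`agreement_analysis`, `generate_phantom`, …); see `docs/methods.md` for the
model, parameters and design choices.

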