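"""Choroid inner/outer boundary detection for OCT volumes.

The pipeline follows the four-step scheme: (i) an initial choroid inner
boundary (CIB) estimate per B-scan, (ii) a final CIB from robust smoothing
across B-scans, (iii) an initial choroid outer boundary (COB) estimate per
B-scan conditioned on the final CIB, and (iv) a final COB from the same
orthogonal smoothing.

Initial estimates are intensity-driven: the shared exponentiation /
nonlinear enhancement chain saturates the target structures (retinal layers
for the CIB on a flipped B-scan, deep choroidal structures for the COB),
a mid-grayscale threshold binarizes the enhanced image, and morphological
cleaning isolates the relevant components.  The CIB is the choroid-facing
edge of the retained retinal mass; the COB is interpolated by tensor voting
through the scleral-most points of the choroidal vessel sections.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import morphology

from .enhance import EnhancementParams, enhance_for_cib, enhance_for_cob, preprocess_bscan
from .io import OCTVolume
from .smoothing import rloess_batch, tensor_vote_interpolate

__all__ = [
    "BoundarySurface",
    "SegmentationParams",
    "SegmentationError",
    "detect_cib_initial",
    "detect_cob_initial",
    "smooth_orthogonal",
    "segment_volume",
]

log = logging.getLogger(__name__)


class SegmentationError(RuntimeError):
    """Raised when a volume cannot be segmented (e.g. no layered structure)."""


@dataclass
class BoundarySurface:
    """Per-(lateral column, B-scan) axial depth of a layer boundary.

    ``depth`` has shape ``(n_lateral, n_bscans)`` and may hold NaN gaps at
    the ``initial`` stage; a ``final`` surface is gap-free.
    """

    depth: np.ndarray
    kind: str  # "CIB" | "COB"
    stage: str  # "initial" | "final"
    n_axial: int

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        if self.depth.ndim != 2:
            raise ValueError("surface depth must be 2D (lateral, B-scan)")
        if self.kind not in ("CIB", "COB"):
            raise ValueError("kind must be 'CIB' or 'COB'")
        if self.stage not in ("initial", "final"):
            raise ValueError("stage must be 'initial' or 'final'")
        finite = self.depth[np.isfinite(self.depth)]
        if finite.size and (finite.min() < 0 or finite.max() >= self.n_axial):
            raise ValueError("surface depths must lie in [0, n_axial)")
        if self.stage == "final" and not np.isfinite(self.depth).all():
            raise ValueError("a final-stage surface must be gap-free")

    @property
    def shape(self) -> tuple[int, int]:
        return self.depth.shape


@dataclass(frozen=True)
class SegmentationParams:
    """Knobs of the boundary detectors.

    binarize_threshold
        Mid-grayscale cut applied to the max-normalized enhanced image
        (8-bit scale), default 128.
    min_component_frac
        Minimum connected-component area kept by the retinal-mass cleaning,
        as a fraction of the B-scan area (default 0.5%).
    morph_radius
        Disk radius of the close/open structuring element.
    rloess_span
        Fraction of B-scans in each local robust-LOESS fit.
    tv_scale
        Tensor-voting influence scale, pixels.
    min_lumen_px
        Minimum area of a dark region accepted as a choroidal vessel
        section during COB detection.
    min_extreme_points
        Minimum number of vessel extreme points for a B-scan's initial COB;
        below it the scan is flagged low-evidence and its trace is left to
        the orthogonal smoothing.
    empty_fail_frac
        Volume-level failure threshold: fraction of B-scans allowed to
        yield no initial trace before segmentation aborts.
    cib_margin_px
        Search for choroidal structure starts this many pixels below the
        final CIB.
    """

    binarize_threshold: int = 128
    min_component_frac: float = 0.005
    morph_radius: int = 3
    open_radius: int = 1
    rloess_span: float = 0.1
    tv_scale: float = 15.0
    min_lumen_px: int = 30
    envelope_median_px: int = 9
    trace_median_px: int = 31
    trace_outlier_px: float = 8.0
    min_extreme_points: int = 3
    empty_fail_frac: float = 0.5
    min_valid_frac: float = 0.25
    cib_margin_px: int = 8

    def __post_init__(self) -> None:
        if not 0 < self.binarize_threshold < 255:
            raise ValueError("binarize_threshold must be in (0, 255)")
        if not 0 < self.rloess_span <= 1:
            raise ValueError("rloess_span must be in (0, 1]")
        if self.morph_radius < 1 or self.min_lumen_px < 1:
            raise ValueError("morphological sizes must be positive")
        if not 0 < self.min_component_frac < 1:
            raise ValueError("min_component_frac must be a fraction of the B-scan area")


def _binarize_enhanced(
    enhanced: np.ndarray, threshold: int, n: float, smooth_px: int = 6
) -> np.ndarray:
    """Mid-grayscale thresholding of an enhanced image.

    The exponentiation enhancement spreads its response over many decades
    (it is a ratio raised to the ``n``-th power), so the 8-bit rendering the
    threshold applies to is the compressed ``n``-th root of the response: a
    pixel passes when its compressed value reaches ``threshold``/255 of the
    rendering's full scale, i.e. when its response is within
    ``(threshold/255)**n`` of the peak.  A median filter on the compressed
    rendering regularizes the speckle-driven response before thresholding.
    An all-zero image yields an empty mask.
    """
    peak = enhanced.max()
    if peak <= 0:
        return np.zeros(enhanced.shape, dtype=bool)
    compressed = (enhanced / peak) ** (1.0 / n)
    if smooth_px > 1:
        compressed = ndimage.median_filter(compressed, size=smooth_px, mode="nearest")
    cpeak = compressed.max()
    if cpeak <= 0:
        return np.zeros(enhanced.shape, dtype=bool)
    return compressed >= (threshold / 255.0) * cpeak


def _remove_small(mask: np.ndarray, min_px: int) -> np.ndarray:
    labels, n_lab = ndimage.label(mask)
    if n_lab == 0:
        return mask
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n_lab + 1))
    keep = np.concatenate(([False], sizes >= min_px))
    return keep[labels]


def _clean_mask(mask: np.ndarray, close_radius: int, open_radius: int, min_px: int) -> np.ndarray:
    """Close (bridge speckle gaps), open (shave isolated specks), then drop
    small components.  The opening element is kept small so thin but genuine
    bands (e.g. the RPE complex) survive."""
    out = ndimage.binary_closing(mask, structure=morphology.disk(close_radius))
    if open_radius >= 1:
        out = ndimage.binary_opening(out, structure=morphology.disk(open_radius))
    return _remove_small(out, min_px)


def detect_cib_initial(
    scan: np.ndarray,
    params: SegmentationParams | None = None,
    enh: EnhancementParams | None = None,
) -> np.ndarray:
    """Initial CIB trace (one depth per lateral column) for one
    preprocessed B-scan.

    The enhancement runs on the flipped B-scan so the retinal layers
    saturate; after thresholding, morphological close/open and small-object
    removal isolate the retinal mass, and each column's CIB estimate is the
    deepest (choroid-facing) retained pixel in the original orientation.
    Columns with no retained component are NaN; an all-NaN trace marks an
    empty B-scan for the caller.
    """
    params = params or SegmentationParams()
    enh = enh or EnhancementParams()
    scan = np.asarray(scan)
    enhanced = enhance_for_cib(scan, enh)  # flipped frame
    mask = _binarize_enhanced(
        enhanced, params.binarize_threshold, enh.enh_exponent, enh.median_window
    )
    mask = np.flipud(mask)  # back to original orientation

    trace = np.full(scan.shape[1], np.nan)
    if not mask.any():
        return trace
    # before any closing can bridge structures, keep only raw components at
    # a depth consistent with the main retinal mass (the largest component);
    # spurious deep or shallow structure is dropped
    labels, n_lab = ndimage.label(mask)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n_lab + 1))
    rows = np.arange(scan.shape[0])[:, None]
    row_grid = np.broadcast_to(rows, mask.shape)
    row_means = ndimage.mean(row_grid, labels, index=np.arange(1, n_lab + 1))
    ref = row_means[int(np.argmax(sizes))]
    tol = 0.1 * scan.shape[0]
    keep = np.concatenate(([False], np.abs(row_means - ref) <= tol))
    mask = keep[labels]

    min_px = max(int(params.min_component_frac * scan.size), 1)
    mask = _clean_mask(mask, params.morph_radius, params.open_radius, min_px)
    if not mask.any():
        return trace

    deepest = np.where(mask, rows, -1).max(axis=0)
    has = deepest >= 0
    trace[has] = deepest[has]

    # columns whose estimate jumps away from the local consensus (e.g. onto
    # deeper structure seen through a hole in the retinal mass) become gaps
    if has.any():
        consensus = ndimage.median_filter(
            np.where(has, trace, np.nanmedian(trace)), size=params.trace_median_px,
            mode="nearest",
        )
        jump = np.abs(trace - consensus) > params.trace_outlier_px
        trace[jump & has] = np.nan
    return trace


def detect_cob_initial(
    scan: np.ndarray,
    cib_trace: np.ndarray,
    params: SegmentationParams | None = None,
    enh: EnhancementParams | None = None,
) -> np.ndarray:
    """Initial COB trace for one preprocessed B-scan, given its final CIB.

    The enhancement runs in the original orientation so deep choroidal
    structure saturates.  Binarizing the sub-retinal region (threshold
    relative to the brightest choroidal, not retinal, response) gives the
    vascular choroid as a bright mass; closing and hole-filling absorb the
    vessel lumina into it, producing the vessel-section image.  Per column,
    the deepest (most scleral) pixel of the retained mass is an extreme
    point, and 2D tensor voting interpolates the extreme points into a
    continuous trace.  Returns an all-NaN trace when fewer than
    ``min_extreme_points`` extreme points are found.
    """
    params = params or SegmentationParams()
    enh = enh or EnhancementParams()
    scan = np.asarray(scan)
    n_axial, n_cols = scan.shape

    enhanced = enhance_for_cob(scan, enh)

    rows = np.arange(n_axial)[:, None]
    cib = np.asarray(cib_trace, dtype=float)
    cib_filled = np.where(np.isfinite(cib), cib, np.nanmedian(cib) if np.isfinite(cib).any() else 0)
    below = rows > (cib_filled[None, :] + params.cib_margin_px)

    # choroidal contrast (stroma vs sclera) lives on the intensity scale, so
    # the sub-retinal rendering is compressed by the full exponent chain
    enhanced_below = np.where(below, enhanced, 0.0)
    bright_below = (
        _binarize_enhanced(
            enhanced_below,
            params.binarize_threshold,
            enh.enh_exponent * enh.raw_exponent,
            enh.median_window,
        )
        & below
    )
    selem = morphology.disk(params.morph_radius)
    mass = ndimage.binary_closing(bright_below, structure=selem)
    mass = ndimage.binary_fill_holes(mass)  # lumina belong to the vascular mass
    min_px = max(int(params.min_component_frac * scan.size), 1)
    mass = _remove_small(mass, min_px)

    anchors_depth = np.where(mass, rows, -1).max(axis=0)
    cols = np.nonzero(anchors_depth >= 0)[0]
    if cols.size < params.min_extreme_points:
        return np.full(n_cols, np.nan)
    # despike the extreme-point envelope (speckle spikes and narrow lumen
    # dips are both narrower than half a large vessel) before interpolation
    env = np.interp(np.arange(n_cols), cols, anchors_depth[cols].astype(float))
    if params.envelope_median_px > 1:
        env = ndimage.median_filter(env, size=params.envelope_median_px, mode="nearest")
    trace = tensor_vote_interpolate(
        np.arange(n_cols), env, scale=params.tv_scale, width=n_cols
    )
    return np.clip(trace, 0, n_axial - 1)


def smooth_orthogonal(
    surface: BoundarySurface, params: SegmentationParams | None = None
) -> BoundarySurface:
    """Final boundary surface from an initial one.

    For each lateral column, the depth series across B-scans is smoothed by
    robust LOESS (local quadratic fit, bisquare reweighting), which fills
    gaps and suppresses outlier B-scans; each B-scan's trace is then
    regularized by a tensor-voting pass along its columns.  The output is
    gap-free.
    """
    params = params or SegmentationParams()
    depth = surface.depth  # (n_lateral, n_bscans)
    n_lat, n_b = depth.shape

    smoothed = rloess_batch(depth, span=params.rloess_span)
    # lateral columns with too few valid B-scans: fill from neighbouring columns
    bad = ~np.isfinite(smoothed).all(axis=1)
    if bad.any():
        if bad.all():
            raise SegmentationError("no lateral column has enough valid boundary estimates")
        log.warning("filling %d lateral columns from neighbours", int(bad.sum()))
        good_idx = np.nonzero(~bad)[0]
        for j in range(n_b):
            col = smoothed[:, j]
            valid = np.isfinite(col)
            if not valid.all():
                col[~valid] = np.interp(np.nonzero(~valid)[0], good_idx, col[good_idx])

    # tensor-voting regularization within each B-scan
    cols = np.arange(n_lat)
    final = np.empty_like(smoothed)
    for j in range(n_b):
        final[:, j] = tensor_vote_interpolate(
            cols, smoothed[:, j], scale=params.tv_scale, width=n_lat
        )
    final = np.clip(final, 0, surface.n_axial - 1)
    return BoundarySurface(depth=final, kind=surface.kind, stage="final", n_axial=surface.n_axial)


def segment_volume(
    volume: OCTVolume,
    params: SegmentationParams | None = None,
    enh: EnhancementParams | None = None,
    preprocessed: np.ndarray | None = None,
) -> tuple[BoundarySurface, BoundarySurface]:
    """Detect the final CIB and COB surfaces of a volume.

    Runs the four-step scheme (initial CIB per B-scan, orthogonal smoothing,
    initial COB per B-scan conditioned on the final CIB, orthogonal
    smoothing) and enforces positive choroidal thickness by clamping the COB
    to ``CIB + 1`` wherever the estimates would cross.

    ``preprocessed`` may carry an already median-filtered/equalized copy of
    the volume (same shape) to avoid repeating the preprocessing.
    """
    params = params or SegmentationParams()
    enh = enh or EnhancementParams()
    n_axial, n_lat, n_b = volume.shape

    if preprocessed is None:
        preprocessed = np.empty(volume.shape, dtype=np.uint8)
        for j in range(n_b):
            preprocessed[:, :, j] = preprocess_bscan(volume.bscan(j), enh)

    cib_init = np.empty((n_lat, n_b))
    n_empty = 0
    for j in range(n_b):
        trace = detect_cib_initial(preprocessed[:, :, j], params, enh)
        if not np.isfinite(trace).any():
            n_empty += 1
        cib_init[:, j] = trace
    if n_empty > params.empty_fail_frac * n_b:
        raise SegmentationError(
            f"{n_empty}/{n_b} B-scans yielded no retinal structure; "
            "volume does not look like layered OCT data"
        )
    valid_frac = float(np.isfinite(cib_init).mean())
    if valid_frac < params.min_valid_frac:
        raise SegmentationError(
            f"only {valid_frac:.0%} of A-scans produced a retinal boundary "
            "estimate; volume does not look like layered OCT data"
        )
    cib = smooth_orthogonal(
        BoundarySurface(cib_init, kind="CIB", stage="initial", n_axial=n_axial), params
    )

    cob_init = np.empty((n_lat, n_b))
    n_low = 0
    for j in range(n_b):
        trace = detect_cob_initial(preprocessed[:, :, j], cib.depth[:, j], params, enh)
        if not np.isfinite(trace).any():
            n_low += 1
        cob_init[:, j] = trace
    if n_low > params.empty_fail_frac * n_b:
        raise SegmentationError(
            f"{n_low}/{n_b} B-scans yielded no choroidal vessel evidence"
        )
    cob = smooth_orthogonal(
        BoundarySurface(cob_init, kind="COB", stage="initial", n_axial=n_axial), params
    )

    crossing = cob.depth <= cib.depth
    if crossing.any():
        log.warning("clamping COB below CIB at %d A-scans", int(crossing.sum()))
        cob.depth[crossing] = np.minimum(cib.depth[crossing] + 1, n_axial - 1)
    return cib, cob
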