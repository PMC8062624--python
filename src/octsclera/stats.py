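"""Validation statistics: Dice-coefficient segmentation agreement and
observer-agreement correlation analysis.

Segmentation accuracy is scored per A-scan with the Dice coefficient of the
two pixel-index sets spanned by the compared boundaries; observer agreement
reduces each mark to its radial position from the bottom-left image corner
and correlates paired trials (Pearson), with the median over eyes taken as
the mean of the two middle order statistics and qualified on the standard
five-bin scale (very weak < 0.20 ... very strong > 0.80).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .boundaries import BoundarySurface
from .io import VesselMarkSet

__all__ = [
    "DiceReport",
    "AgreementReport",
    "UndefinedCorrelationError",
    "dice_coefficient",
    "average_segmentation",
    "dice_report",
    "radial_positions",
    "position_consistency",
    "pearson",
    "qualify_correlation",
    "even_median",
    "pair_trials",
    "agreement_analysis",
]


class UndefinedCorrelationError(ValueError):
    """Raised when a correlation is requested for a zero-variance series."""


def dice_coefficient(a, b) -> float:
    """Dice coefficient ``2|a n b| / (|a| + |b|)`` of two pixel-index sets.

    1 means the two measurements are identical, 0 that they are disjoint.
    Two empty sets score 1 by convention (the raters agree there is no
    choroid at that A-scan).
    """
    sa, sb = set(np.asarray(list(a)).ravel().tolist()), set(np.asarray(list(b)).ravel().tolist())
    if not sa and not sb:
        return 1.0
    return 2.0 * len(sa & sb) / (len(sa) + len(sb))


def _band_sets(cib: np.ndarray, cob: np.ndarray, mode: str, top: int = 0):
    """Integer (lo, hi] bounds per A-scan for the requested band mode."""
    cib_i = np.rint(cib).astype(int)
    cob_i = np.rint(cob).astype(int)
    if mode == "CIB":
        return np.full_like(cib_i, top), cib_i
    if mode == "COB":
        return np.full_like(cob_i, top), cob_i
    if mode == "band":
        return cib_i, cob_i
    raise ValueError("boundary mode must be 'CIB', 'COB' or 'band'")


def _interval_dice(lo1, hi1, lo2, hi2) -> np.ndarray:
    """Vectorized Dice of the pixel-index intervals (lo, hi] per A-scan."""
    n1 = np.maximum(hi1 - lo1, 0)
    n2 = np.maximum(hi2 - lo2, 0)
    inter = np.maximum(np.minimum(hi1, hi2) - np.maximum(lo1, lo2), 0)
    dc = np.where(n1 + n2 > 0, 2.0 * inter / np.maximum(n1 + n2, 1), 1.0)
    return dc


def average_segmentation(s1: BoundarySurface, s2: BoundarySurface) -> BoundarySurface:
    """Per-A-scan average of two boundary surfaces, rounded half-up to an
    integer pixel index (the "M" reference built from two manual readings)."""
    if s1.shape != s2.shape or s1.kind != s2.kind:
        raise ValueError("can only average surfaces of one kind on one grid")
    mean = np.floor((s1.depth + s2.depth) / 2.0 + 0.5)
    return BoundarySurface(depth=mean, kind=s1.kind, stage="final", n_axial=s1.n_axial)


@dataclass
class DiceReport:
    """Per-A-scan, per-B-scan and dataset-level Dice agreement."""

    per_ascan: np.ndarray  # (n_lateral, n_bscans)
    per_bscan_mean: np.ndarray
    mean: float
    sd: float
    boundary: str
    comparison: str = ""


def dice_report(
    seg1: tuple[BoundarySurface, BoundarySurface],
    seg2: tuple[BoundarySurface, BoundarySurface],
    boundary: str = "band",
    reference_top: int = 0,
    comparison: str = "",
) -> DiceReport:
    """Dice agreement between two (CIB, COB) segmentations of one volume.

    ``boundary`` picks the pixel set per A-scan: ``"CIB"`` spans the
    reference top to the CIB, ``"COB"`` the reference top to the COB, and
    ``"band"`` the CIB-to-COB choroidal band.  The report aggregates the
    per-A-scan coefficients into per-B-scan means and a dataset mean (SD).
    """
    cib1, cob1 = seg1
    cib2, cob2 = seg2
    if cib1.shape != cib2.shape:
        raise ValueError("segmentations live on different grids")
    lo1, hi1 = _band_sets(cib1.depth, cob1.depth, boundary, reference_top)
    lo2, hi2 = _band_sets(cib2.depth, cob2.depth, boundary, reference_top)
    dc = _interval_dice(lo1, hi1, lo2, hi2)
    return DiceReport(
        per_ascan=dc,
        per_bscan_mean=dc.mean(axis=0),
        mean=float(dc.mean()),
        sd=float(dc.std(ddof=1)) if dc.size > 1 else 0.0,
        boundary=boundary,
        comparison=comparison,
    )


def radial_positions(marks: VesselMarkSet, n_px: int = 1024) -> np.ndarray:
    """Radial pixel position ``sqrt(X^2 + Y^2)`` of each mark, with the
    bottom-left image corner as the origin."""
    px_per_mm = n_px / marks.extent_mm
    x_px = marks.positions_mm[:, 0] * px_per_mm
    y_px = (marks.extent_mm - marks.positions_mm[:, 1]) * px_per_mm  # re-base to bottom-left
    return np.sqrt(x_px**2 + y_px**2)


def position_consistency(
    marks: VesselMarkSet, expert_z: np.ndarray, epsilon: float = 1.5, n_px: int = 1024
) -> dict:
    """Check each mark's expert position ``Z`` against its radial position.

    A mark is valid when ``|Z - sqrt(X^2 + Y^2)| < epsilon`` (pixels,
    bottom-left origin); ``epsilon`` sets the robustness of the artery
    detection.  Returns the radial series, the validity flags and the ``Z``
    series used downstream for correlation.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    z = np.asarray(expert_z, dtype=float)
    radial = radial_positions(marks, n_px)
    if z.shape != radial.shape:
        raise ValueError("expert Z series must pair one value per mark")
    return {"radial": radial, "z": z, "valid": np.abs(z - radial) < epsilon}


def pearson(u: np.ndarray, v: np.ndarray) -> float:
    """Pearson product-moment correlation of two equal-length series."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.ndim != 1 or len(u) < 2:
        raise ValueError("pearson needs two equal-length 1D series of length >= 2")
    if np.ptp(u) == 0 or np.ptp(v) == 0:
        raise UndefinedCorrelationError("correlation undefined for a constant series")
    return float(sps.pearsonr(u, v).statistic)


_BINS = (
    (0.20, "very weak correlation"),
    (0.40, "weak correlation"),
    (0.60, "moderate correlation"),
    (0.80, "strong correlation"),
    (np.inf, "very strong correlation"),
)


def qualify_correlation(r: float) -> str:
    """Five-bin qualification of a correlation coefficient.

    Applied to ``|r|``; a value exactly on a bin edge belongs to the higher
    bin (0.40 is already 'moderate', 0.80 already 'very strong').
    """
    if not -1 <= r <= 1:
        raise ValueError("correlation coefficient must lie in [-1, 1]")
    mag = abs(r)
    for upper, label in _BINS:
        if mag < upper:
            return label
    return _BINS[-1][1]


def even_median(values: np.ndarray) -> float:
    """Median as the mean of the two middle order statistics for an even
    count (for 18 eyes: the average of the sorted 9th and 10th values)."""
    v = np.sort(np.asarray(values, dtype=float))
    n = len(v)
    if n == 0:
        raise ValueError("median of an empty set")
    if n % 2:
        return float(v[n // 2])
    return float((v[n // 2 - 1] + v[n // 2]) / 2.0)


def pair_trials(
    a: VesselMarkSet, b: VesselMarkSet, max_dist_mm: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Greedy nearest-neighbour matching of two trials' marks.

    Returns index arrays ``(ia, ib)`` of the matched pairs (each mark used
    at most once, pairs farther than ``max_dist_mm`` discarded).
    """
    pa, pb = a.positions_mm, b.positions_mm
    if len(pa) == 0 or len(pb) == 0:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=2)
    ia, ib = [], []
    used_a, used_b = set(), set()
    for flat in np.argsort(d, axis=None):
        i, j = np.unravel_index(flat, d.shape)
        if d[i, j] > max_dist_mm:
            break
        if i in used_a or j in used_b:
            continue
        ia.append(i)
        ib.append(j)
        used_a.add(i)
        used_b.add(j)
    return np.asarray(ia, dtype=int), np.asarray(ib, dtype=int)


@dataclass
class AgreementReport:
    """Observer-agreement summary over eyes."""

    per_eye_r: np.ndarray
    median_r: float
    label: str
    mode: str
    n_dropped: int = 0


def agreement_analysis(
    trial_pairs: list[tuple[VesselMarkSet, VesselMarkSet]],
    mode: str = "auto",
    n_px: int = 1024,
    max_dist_mm: float = 1.0,
) -> AgreementReport:
    """Correlation analysis of paired mark trials, one pair per eye.

    ``auto`` pairs consecutive trials of one observer (repeatability),
    ``cross`` pairs the two observers (reproducibility); the pairing only
    names the comparison, the computation is identical.  Each eye's marks
    are matched between trials, reduced to radial positions ``Z`` from the
    bottom-left corner, and correlated (Pearson); eyes with an undefined
    correlation are dropped with a warning.  The median over eyes uses the
    even-count two-middle-values rule and is qualified on the five-bin
    scale.
    """
    if mode not in ("auto", "cross"):
        raise ValueError("mode must be 'auto' or 'cross'")
    rs = []
    dropped = 0
    for t1, t2 in trial_pairs:
        ia, ib = pair_trials(t1, t2, max_dist_mm=max_dist_mm)
        if len(ia) < 2:
            dropped += 1
            warnings.warn("eye dropped: fewer than 2 matched marks", stacklevel=2)
            continue
        z1 = radial_positions(t1, n_px)[ia]
        z2 = radial_positions(t2, n_px)[ib]
        try:
            rs.append(pearson(z1, z2))
        except UndefinedCorrelationError:
            dropped += 1
            warnings.warn("eye dropped: undefined correlation", stacklevel=2)
    if not rs:
        raise ValueError("no eye yielded a defined correlation")
    med = even_median(np.asarray(rs))
    return AgreementReport(
        per_eye_r=np.asarray(rs),
        median_r=med,
        label=qualify_correlation(med),
        mode=mode,
        n_dropped=dropped,
    )
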