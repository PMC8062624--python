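"""SPCA entry-site topography over the 3 x 3 posterior-pole sector grid.

The 12 x 12 mm en-face field is divided into nine 4 x 4 mm sectors.  Marks
are assigned to sectors by position, counted, and summarized; eyes in which
fewer than 10 arteries could be identified are excluded (histology puts the
per-eye minimum at 10 short posterior ciliary arteries).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io import VesselMarkSet

__all__ = [
    "SectorGrid",
    "SectorDistribution",
    "assign_sector",
    "compute_distribution",
    "apply_exclusion",
    "summarize_eyes",
]

_ROW_NAMES = ("superior", "central", "inferior")  # smaller y = superior


@dataclass(frozen=True)
class SectorGrid:
    """The 3 x 3 grid of square sectors covering the en-face field."""

    extent_mm: float = 12.0
    sector_mm: float = 4.0

    def __post_init__(self) -> None:
        if abs(self.extent_mm - 3 * self.sector_mm) > 1e-9:
            raise ValueError("grid extent must equal 3 sector edges")

    def cell_of(self, x_mm: float, y_mm: float) -> tuple[int, int]:
        """(row, col) of a position; cells are half-open except the far edge,
        which belongs to the last cell."""
        if not (0 <= x_mm <= self.extent_mm and 0 <= y_mm <= self.extent_mm):
            raise ValueError(f"mark ({x_mm}, {y_mm}) lies outside the {self.extent_mm} mm field")
        col = min(int(x_mm // self.sector_mm), 2)
        row = min(int(y_mm // self.sector_mm), 2)
        return row, col


def _horizontal_name(col: int, laterality: str) -> str:
    # fundus orientation: temporal retina on the left of the image for OD,
    # on the right for OS
    if laterality == "OD":
        names = ("temporal", "central", "nasal")
    elif laterality == "OS":
        names = ("nasal", "central", "temporal")
    else:
        raise ValueError("laterality must be 'OD' or 'OS' for anatomical labels")
    return names[col]


def sector_label(row: int, col: int, laterality: str | None) -> str:
    """Anatomical name of a grid cell ('central' for the middle cell)."""
    vert = _ROW_NAMES[row]
    if laterality is None:
        return f"r{row}c{col}"
    horiz = _horizontal_name(col, laterality)
    if vert == "central" and horiz == "central":
        return "central"
    return f"{vert}-{horiz}"


def assign_sector(
    mark_mm: tuple[float, float],
    grid: SectorGrid | None = None,
    laterality: str | None = None,
) -> dict:
    """Assign one en-face mark to its sector.

    Returns a dict with the 0-based ``(row, col)`` cell index and, when a
    laterality is given, the anatomical ``label`` (superior/central/inferior
    x nasal/central/temporal).
    """
    grid = grid or SectorGrid()
    row, col = grid.cell_of(*mark_mm)
    return {"row": row, "col": col, "label": sector_label(row, col, laterality)}


@dataclass
class SectorDistribution:
    """Counts and percentages of marks over the nine sectors."""

    counts: np.ndarray  # (3, 3) rows = superior..inferior, cols = image left..right
    total: int
    laterality: str | None = None

    @property
    def percentages(self) -> np.ndarray:
        return 100.0 * self.counts / self.total

    def rounded_percentages(self) -> np.ndarray:
        """Whole-percent table (round half away from zero, as in reports)."""
        return np.vectorize(lambda p: math.floor(p + 0.5))(self.percentages).astype(int)

    def label_table(self) -> dict[str, float]:
        out = {}
        for r in range(3):
            for c in range(3):
                out[sector_label(r, c, self.laterality)] = float(self.percentages[r, c])
        return out


def compute_distribution(
    marks: VesselMarkSet, grid: SectorGrid | None = None
) -> SectorDistribution:
    """Sector counts and percentages for one mark set (>= 1 mark required)."""
    grid = grid or SectorGrid()
    if len(marks) == 0:
        raise ValueError("sector distribution is undefined for an empty mark set")
    counts = np.zeros((3, 3), dtype=int)
    for x_mm, y_mm in marks.positions_mm:
        row, col = grid.cell_of(x_mm, y_mm)
        counts[row, col] += 1
    return SectorDistribution(counts=counts, total=len(marks), laterality=marks.laterality)


def apply_exclusion(markset: VesselMarkSet, min_count: int = 10) -> bool:
    """True when the eye stays in the analysis (>= ``min_count`` marks).

    Eyes with fewer identified arteries than the histological minimum of 10
    SPCAs per eye are excluded as low-contrast acquisitions.
    """
    return len(markset) >= min_count


def summarize_eyes(
    marksets: list[VesselMarkSet],
    grid: SectorGrid | None = None,
    min_count: int = 10,
) -> dict:
    """Cohort summary over the included eyes.

    Returns the per-eye counts, their mean and sample (n-1) standard
    deviation (0 with a flag for a single eye), and the pooled sector
    distribution of all included marks.
    """
    grid = grid or SectorGrid()
    included = [ms for ms in marksets if apply_exclusion(ms, min_count)]
    if not included:
        raise ValueError("all eyes excluded; cohort summary undefined")
    counts = np.array([len(ms) for ms in included], dtype=float)
    pooled = np.zeros((3, 3), dtype=int)
    for ms in included:
        pooled += compute_distribution(ms, grid).counts
    sd = float(counts.std(ddof=1)) if len(counts) > 1 else 0.0
    return {
        "n_eyes": len(included),
        "n_excluded": len(marksets) - len(included),
        "per_eye_counts": counts.astype(int).tolist(),
        "mean_count": float(counts.mean()),
        "sd_count": sd,
        "sd_defined": len(counts) > 1,
        "pooled": SectorDistribution(counts=pooled, total=int(pooled.sum())),
    }
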