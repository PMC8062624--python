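"""Reading and writing OCT volumes, boundary surfaces, en-face images and vessel marks.

A volume is stored in memory as an 8-bit array with axes ``(z, y, x)``:
axial depth first, then lateral column within a B-scan, then B-scan index.
On disk a volume is a multi-page grayscale TIFF where page ``i`` is B-scan
``i`` and, within a page, the image row is axial depth.  Vessel-mark tables
travel as plain CSV with a mandatory header.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "OCTVolume",
    "VesselMarkSet",
    "load_volume",
    "save_volume",
    "load_marks",
    "save_marks",
    "load_surface",
    "save_surface",
]


class FormatError(ValueError):
    """Raised when an on-disk file violates the expected layout."""


@dataclass
class OCTVolume:
    """An 8-bit OCT volume with axes (axial z, lateral y, B-scan x).

    Parameters
    ----------
    intensities
        3D ``uint8`` array, shape ``(n_axial, n_lateral, n_bscans)``.
    lateral_extent_mm
        Physical width/height of the scanned field (the en-face square);
        the wide-field protocol this package targets uses 12 mm.
    source
        Optional provenance metadata (path, original dtype, ...).
    """

    intensities: np.ndarray
    lateral_extent_mm: float = 12.0
    source: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities)
        if arr.ndim != 3:
            raise ValueError(f"volume must be 3D (z, y, x), got shape {arr.shape}")
        if any(s < 2 for s in arr.shape):
            raise ValueError(f"all volume dimensions must be >= 2, got {arr.shape}")
        if arr.dtype != np.uint8:
            if np.issubdtype(arr.dtype, np.integer) and arr.min() >= 0 and arr.max() <= 255:
                arr = arr.astype(np.uint8)
            else:
                raise ValueError("volume intensities must be 8-bit (uint8 in [0, 255])")
        if self.lateral_extent_mm <= 0:
            raise ValueError("lateral_extent_mm must be positive")
        self.intensities = arr

    @property
    def n_axial(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_lateral(self) -> int:
        return self.intensities.shape[1]

    @property
    def n_bscans(self) -> int:
        return self.intensities.shape[2]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    def bscan(self, index: int) -> np.ndarray:
        """The 2D B-scan (axial depth x lateral column) at B-scan index ``index``."""
        return self.intensities[:, :, index]

    def mm_per_px(self, n_px: int | None = None) -> float:
        """Lateral millimetres per pixel (defaults to the lateral axis)."""
        n = self.n_lateral if n_px is None else n_px
        return self.lateral_extent_mm / n


@dataclass
class VesselMarkSet:
    """En-face SPCA entry-site marks for one eye / observer / trial.

    Positions are millimetres from the image corner (0-based, origin top-left
    in display orientation; statistical routines re-base to bottom-left where
    the radial-position convention requires it).
    """

    positions_mm: np.ndarray  # (n, 2) columns (x_mm, y_mm)
    eye_id: str = ""
    laterality: str | None = None  # "OD" | "OS"
    observer_id: str = ""
    trial_id: str = ""
    extent_mm: float = 12.0

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions_mm, dtype=float).reshape(-1, 2)
        if pos.size and (pos.min() < 0 or pos.max() > self.extent_mm):
            raise ValueError("mark positions must lie within [0, extent_mm] on both axes")
        if self.laterality is not None and self.laterality not in ("OD", "OS"):
            raise ValueError("laterality must be 'OD', 'OS' or None")
        self.positions_mm = pos

    def __len__(self) -> int:
        return len(self.positions_mm)

    def with_positions(self, positions_mm: np.ndarray) -> "VesselMarkSet":
        return replace(self, positions_mm=np.asarray(positions_mm, dtype=float).reshape(-1, 2))


_IMAGE_SUFFIXES = (".tif", ".tiff", ".png")


def load_volume(path: str | Path, layout: str = "auto") -> OCTVolume:
    """Load an OCT volume from a multi-page TIFF or a directory of B-scan images.

    ``layout`` is ``"tiff"``, ``"directory"`` or ``"auto"`` (decide from the
    path).  Pages/files are taken in order as the B-scan (x) axis; within an
    image, row = axial depth (z) and column = lateral position (y).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    if layout == "auto":
        layout = "directory" if path.is_dir() else "tiff"

    if layout == "tiff":
        pages = tifffile.imread(path)
        if pages.ndim == 2:
            raise FormatError(f"{path} holds a single page; a volume needs >= 2 B-scans")
        if pages.ndim != 3:
            raise FormatError(f"{path}: expected grayscale pages, got shape {pages.shape}")
    elif layout == "directory":
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES)
        if len(files) < 2:
            raise FormatError(f"{path} holds {len(files)} B-scan images; need >= 2")
        import imageio.v3 as iio

        frames = [np.asarray(iio.imread(f)) for f in files]
        shapes = {f.shape for f in frames}
        if len(shapes) != 1:
            raise FormatError(f"inconsistent B-scan dimensions across files in {path}: {shapes}")
        if frames[0].ndim != 2:
            raise FormatError(f"B-scan images in {path} must be single-channel grayscale")
        pages = np.stack(frames, axis=0)
    else:
        raise ValueError(f"unknown layout {layout!r}")

    if pages.dtype != np.uint8:
        if np.issubdtype(pages.dtype, np.integer) and pages.min() >= 0 and pages.max() <= 255:
            pages = pages.astype(np.uint8)
        else:
            raise FormatError(f"{path}: volume is not 8-bit (dtype {pages.dtype})")

    # (x, z, y) page stack -> (z, y, x)
    intensities = np.moveaxis(pages, 0, 2)
    return OCTVolume(
        intensities=intensities,
        source={"path": str(path), "layout": layout, "shape": tuple(intensities.shape)},
    )


def save_volume(volume: OCTVolume, path: str | Path) -> None:
    """Write ``volume`` as a multi-page 8-bit grayscale TIFF (page = B-scan)."""
    path = Path(path)
    pages = np.moveaxis(volume.intensities, 2, 0)
    tifffile.imwrite(path, pages, photometric="minisblack")


_REQUIRED_MARK_COLUMNS = ("eye_id", "observer_id", "trial_id")


def load_marks(path: str | Path, extent_mm: float = 12.0) -> list[VesselMarkSet]:
    """Load vessel-mark tables from CSV, one :class:`VesselMarkSet` per
    (eye, observer, trial) group.

    The CSV must carry either millimetre columns ``x_mm, y_mm`` or pixel
    columns ``x_px, y_px`` plus ``n_px`` (lateral pixel count) so positions
    can be converted as ``mm = px * extent_mm / n_px``.  An optional
    ``laterality`` column ("OD"/"OS") is honoured.
    """
    path = Path(path)
    df = pd.read_csv(path)
    for col in _REQUIRED_MARK_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    if {"x_mm", "y_mm"} <= set(df.columns):
        xcol, ycol = "x_mm", "y_mm"
    elif {"x_px", "y_px", "n_px"} <= set(df.columns):
        for axis in ("x_px", "y_px"):
            bad = df.index[~np.isfinite(pd.to_numeric(df[axis], errors="coerce"))]
            if len(bad):
                raise FormatError(f"{path}: non-numeric {axis} at line {bad[0] + 2}")
        df = df.assign(
            x_mm=df["x_px"].astype(float) * extent_mm / df["n_px"].astype(float),
            y_mm=df["y_px"].astype(float) * extent_mm / df["n_px"].astype(float),
        )
        xcol, ycol = "x_mm", "y_mm"
    else:
        raise FormatError(f"{path}: need columns (x_mm, y_mm) or (x_px, y_px, n_px)")

    for axis in (xcol, ycol):
        coerced = pd.to_numeric(df[axis], errors="coerce")
        bad = df.index[~np.isfinite(coerced)]
        if len(bad):
            raise FormatError(f"{path}: non-numeric {axis} at line {bad[0] + 2}")
        df[axis] = coerced

    sets = []
    for (eye, obs, trial), grp in df.groupby(list(_REQUIRED_MARK_COLUMNS), sort=True):
        laterality = None
        if "laterality" in grp.columns and len(grp["laterality"].dropna()):
            laterality = str(grp["laterality"].dropna().iloc[0])
        sets.append(
            VesselMarkSet(
                positions_mm=grp[[xcol, ycol]].to_numpy(dtype=float),
                eye_id=str(eye),
                observer_id=str(obs),
                trial_id=str(trial),
                laterality=laterality,
                extent_mm=extent_mm,
            )
        )
    return sets


def save_marks(marksets: list[VesselMarkSet], path: str | Path) -> None:
    """Write mark sets to one CSV (columns eye_id, observer_id, trial_id, x_mm, y_mm, laterality)."""
    rows = []
    for ms in marksets:
        for x_mm, y_mm in ms.positions_mm:
            rows.append(
                {
                    "eye_id": ms.eye_id,
                    "observer_id": ms.observer_id,
                    "trial_id": ms.trial_id,
                    "x_mm": x_mm,
                    "y_mm": y_mm,
                    "laterality": ms.laterality if ms.laterality is not None else "",
                }
            )
    pd.DataFrame(
        rows, columns=["eye_id", "observer_id", "trial_id", "x_mm", "y_mm", "laterality"]
    ).to_csv(path, index=False)


def save_surface(surface, path_prefix: str | Path) -> None:
    """Serialize a boundary surface as 32-bit TIFF plus a JSON sidecar."""
    prefix = Path(path_prefix)
    tifffile.imwrite(prefix.with_suffix(".tif"), surface.depth.astype(np.float32))
    meta = {"kind": surface.kind, "stage": surface.stage, "n_axial": int(surface.n_axial)}
    prefix.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_surface(path_prefix: str | Path):
    from .boundaries import BoundarySurface

    prefix = Path(path_prefix)
    depth = tifffile.imread(prefix.with_suffix(".tif")).astype(float)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    return BoundarySurface(
        depth=depth, kind=meta["kind"], stage=meta["stage"], n_axial=meta["n_axial"]
    )
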