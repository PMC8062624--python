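"""Choroid-sclera interface flattening and scleral en-face extraction.

Once the choroid outer boundary (COB) of a volume is known, every A-scan is
shifted axially so that its COB lands on one common plane; constant-depth
slices of the flattened volume are then genuine en-face views of the sclera
at successive depths below the interface, and short substack projections
make the dark SPCA entry sites easy to follow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .boundaries import BoundarySurface
from .io import OCTVolume

__all__ = [
    "FlattenedVolume",
    "EnFaceStack",
    "flatten_volume",
    "unflatten_volume",
    "extract_enface_stack",
    "project_substack",
    "suggest_substack",
]


@dataclass
class FlattenedVolume:
    """A volume after per-A-scan axial shifting.

    ``shift_map[y, x]`` pixels were added to the depth of A-scan ``(y, x)``
    so that its COB lies at ``flatten_plane_depth``; vacated voxels hold 0.
    """

    intensities: np.ndarray
    flatten_plane_depth: int
    shift_map: np.ndarray
    lateral_extent_mm: float = 12.0
    subpixel: bool = False

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape


@dataclass
class EnFaceStack:
    """Constant-depth en-face slices at and below the flattened interface."""

    slices: np.ndarray  # (n_slices, n_lateral, n_bscans)
    depth_offsets: np.ndarray  # pixels below the choroid-sclera interface
    lateral_extent_mm: float = 12.0

    def __post_init__(self) -> None:
        off = np.asarray(self.depth_offsets)
        if off.size and (np.any(np.diff(off) <= 0) or off.min() < 0):
            raise ValueError("depth_offsets must be strictly increasing and >= 0")
        self.depth_offsets = off

    def __len__(self) -> int:
        return len(self.slices)


def flatten_volume(
    volume: OCTVolume,
    cob: BoundarySurface,
    plane_depth: int | None = None,
    subpixel: bool = False,
) -> FlattenedVolume:
    """Shift every A-scan so its COB lands on a common axial plane.

    By default the plane is the deepest COB of the volume (rounded), so no
    scleral content is pushed off the bottom.  Integer shifting (the
    default) is bit-exact and invertible over non-vacated voxels; the
    sub-pixel mode interpolates linearly along each A-scan for smoother
    en-face slices.
    """
    if cob.stage != "final":
        raise ValueError("flattening requires a final-stage COB surface")
    if cob.shape != volume.shape[1:]:
        raise ValueError("COB surface does not match the volume's lateral grid")
    nz, ny, nx = volume.shape
    depth = cob.depth
    if plane_depth is None:
        plane_depth = int(np.rint(depth.max()))
    plane_depth = min(plane_depth, nz - 1)

    if not subpixel:
        shift = plane_depth - np.rint(depth).astype(int)  # (ny, nx), may be negative
        z = np.arange(nz)[:, None, None]
        src = z - shift[None, :, :]
        valid = (src >= 0) & (src < nz)
        src = np.clip(src, 0, nz - 1)
        flat = np.where(
            valid,
            np.take_along_axis(volume.intensities, src, axis=0),
            0,
        ).astype(np.uint8)
        shift_map = shift.astype(float)
    else:
        shift_map = plane_depth - depth
        z = np.arange(nz, dtype=float)[:, None, None]
        src = z - shift_map[None, :, :]
        lo = np.floor(src).astype(int)
        frac = src - lo
        valid = (src >= 0) & (src <= nz - 1)
        lo_c = np.clip(lo, 0, nz - 1)
        hi_c = np.clip(lo + 1, 0, nz - 1)
        vol = volume.intensities.astype(float)
        interp = (1 - frac) * np.take_along_axis(vol, lo_c, axis=0) + frac * np.take_along_axis(
            vol, hi_c, axis=0
        )
        flat = np.where(valid, np.clip(np.rint(interp), 0, 255), 0).astype(np.uint8)

    return FlattenedVolume(
        intensities=flat,
        flatten_plane_depth=plane_depth,
        shift_map=shift_map,
        lateral_extent_mm=volume.lateral_extent_mm,
        subpixel=subpixel,
    )


def unflatten_volume(flat: FlattenedVolume) -> np.ndarray:
    """Undo integer-mode flattening; voxels vacated by the forward shift
    come back as 0."""
    nz = flat.intensities.shape[0]
    shift = np.rint(flat.shift_map).astype(int)
    z = np.arange(nz)[:, None, None]
    src = z + shift[None, :, :]
    valid = (src >= 0) & (src < nz)
    src = np.clip(src, 0, nz - 1)
    return np.where(valid, np.take_along_axis(flat.intensities, src, axis=0), 0).astype(np.uint8)


def extract_enface_stack(flat: FlattenedVolume, max_depth_px: int) -> EnFaceStack:
    """Constant-depth en-face slices from the flattened interface downward.

    Returns up to ``max_depth_px`` slices; the stack is truncated at the
    image bottom if fewer remain below the flatten plane.
    """
    if max_depth_px <= 0:
        raise ValueError("max_depth_px must be positive")
    nz = flat.intensities.shape[0]
    n = min(max_depth_px, nz - flat.flatten_plane_depth)
    depths = flat.flatten_plane_depth + np.arange(n)
    return EnFaceStack(
        slices=flat.intensities[depths, :, :],
        depth_offsets=np.arange(n),
        lateral_extent_mm=flat.lateral_extent_mm,
    )


def project_substack(
    stack: EnFaceStack,
    first: int = 0,
    count: int = 5,
    mode: str = "mean",
    bounds: tuple[int, int] = (5, 30),
    enforce_bounds: bool = True,
) -> np.ndarray:
    """Pixel-wise projection over ``count`` consecutive en-face slices.

    ``mode`` is ``"mean"`` or ``"min"`` (minimum intensity keeps the dark
    SPCA dots dark).  ``count`` is held to ``bounds`` (default 5..30 slices)
    unless ``enforce_bounds`` is False.
    """
    lo, hi = bounds
    if enforce_bounds and not lo <= count <= hi:
        raise ValueError(f"substack count {count} outside bounds {bounds}")
    if count < 1 or first < 0 or first + count > len(stack):
        raise ValueError("substack window falls outside the en-face stack")
    window = stack.slices[first : first + count].astype(float)
    if mode == "mean":
        return window.mean(axis=0)
    if mode == "min":
        return window.min(axis=0)
    raise ValueError("mode must be 'mean' or 'min'")


def suggest_substack(stack: EnFaceStack, count: int = 10) -> list[tuple[int, float]]:
    """Rank candidate substack windows by dark-spot contrast.

    Scores each start index by the gap between the median and the 1st
    percentile of its mean projection (dark vessel dots against the scleral
    background).  Purely advisory: substack choice remains the user's.
    """
    scores = []
    for first in range(0, max(len(stack) - count + 1, 1)):
        proj = project_substack(stack, first, min(count, len(stack)), enforce_bounds=False)
        scores.append((first, float(np.percentile(proj, 50) - np.percentile(proj, 1))))
    return sorted(scores, key=lambda t: -t[1])
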