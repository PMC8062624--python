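"""Synthetic layered OCT phantoms with known ground truth.

A phantom emulates the posterior segment as seen by wide-field swept-source
OCT: a bright retinal band, a choroidal band holding dark vessel lumina
(small inner Sattler-type vessels and large outer Haller-type vessels whose
lower walls ride on the choroid-sclera interface), a dimmer scleral bed
crossed obliquely by dark short-posterior-ciliary-artery (SPCA) tracks, a
global bowl-shaped warp for the curvature of the eye, exponential depth
attenuation, a detector noise floor, and multiplicative speckle.  The
generator returns the exact boundary surfaces and SPCA entry marks it used,
in the same containers the detectors emit, so segmentation and topography
can be validated without clinical data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .boundaries import BoundarySurface
from .io import OCTVolume, VesselMarkSet

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "generate_phantom",
    "perturb_marks",
    "simulate_observer_trials",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a synthetic OCT phantom.

    Geometry is in pixels on the (axial, lateral, B-scan) grid; reflectivity
    on the 8-bit scale before attenuation and speckle.  The defaults draw a
    256 x 256 x 64 volume over a 12 mm square field: large enough for the
    6 x 6 filtering windows and the across-B-scan smoothing spans, small
    enough that a segmentation runs in seconds.
    """

    shape: tuple[int, int, int] = (256, 256, 64)  # (axial, lateral, n_bscans)
    lateral_extent_mm: float = 12.0
    retina_top_px: float = 40.0
    cib_depth_px: float = 90.0
    choroid_thickness_px: float = 50.0
    thickness_wave_px: float = 4.0  # smooth lateral variation of choroidal thickness
    retina_reflect: float = 150.0  # inner/outer retina above the RPE complex
    rpe_reflect: float = 240.0  # RPE-Bruch's complex, the brightest band
    rpe_thickness_px: float = 8.0
    choroid_reflect: float = 170.0
    sclera_reflect: float = 90.0
    lumen_reflect: float = 45.0
    background_reflect: float = 25.0  # detector noise floor (vitreous / deep signal)
    n_haller: int = 9
    haller_radius_px: tuple[float, float] = (6.0, 10.0)
    n_sattler: int = 8
    sattler_radius_px: tuple[float, float] = (3.0, 5.0)
    attenuation_coeff: float = 0.08  # gray levels lost per axial pixel (log-domain export)
    speckle_level: float = 0.15  # variance of the multiplicative speckle
    n_spca: int = 14
    spca_positions_mm: tuple[tuple[float, float], ...] | None = None
    spca_radius_px: float = 3.0
    spca_incline: float = 0.6  # lateral pixels walked per axial pixel of descent
    curvature_px: float = 12.0  # bowl-warp amplitude
    seed: int = 0

    def __post_init__(self) -> None:
        nz, ny, nx = self.shape
        if min(self.shape) < 8:
            raise ValueError("phantom dimensions must each be >= 8")
        if not 0 < self.retina_top_px < self.cib_depth_px:
            raise ValueError("retina band must have positive thickness")
        if not 0 < self.rpe_thickness_px <= self.cib_depth_px - self.retina_top_px:
            raise ValueError("RPE band must fit inside the retina")
        max_cob = (
            self.cib_depth_px
            + self.choroid_thickness_px
            + self.thickness_wave_px
            + self.curvature_px
        )
        if max_cob >= nz - 4:
            raise ValueError("choroid-sclera interface leaves the axial extent after warp")
        for r in (self.retina_reflect, self.choroid_reflect, self.sclera_reflect):
            if not 0 < r <= 255:
                raise ValueError("reflectivities must lie in (0, 255]")
        if self.speckle_level < 0 or self.attenuation_coeff < 0 or self.curvature_px < 0:
            raise ValueError("noise, attenuation and curvature must be >= 0")

    @classmethod
    def for_shape(cls, shape: tuple[int, int, int], **overrides) -> "PhantomSpec":
        """A spec whose depth geometry is scaled from the default 256-px
        axial layout to fit ``shape``; keyword overrides win."""
        f = shape[0] / 256.0
        scaled = dict(
            shape=tuple(shape),
            retina_top_px=40.0 * f,
            cib_depth_px=90.0 * f,
            choroid_thickness_px=50.0 * f,
            thickness_wave_px=4.0 * f,
            rpe_thickness_px=max(8.0 * f, 3.0),
            curvature_px=12.0 * f,
            haller_radius_px=(max(6.0 * f, 2.0), max(10.0 * f, 3.0)),
            sattler_radius_px=(max(3.0 * f, 1.5), max(5.0 * f, 2.0)),
        )
        scaled.update(overrides)
        return cls(**scaled)


@dataclass
class PhantomTruth:
    """Exact ground truth of a generated phantom."""

    cib: BoundarySurface
    cob: BoundarySurface
    spca_marks: VesselMarkSet
    layer_masks: dict = field(default_factory=dict)


def _carve_tube(
    reflect: np.ndarray,
    centers_zy: np.ndarray,  # (n_bscans, 2) per-B-scan (z, y) centre
    radius: float,
    value: float,
    zz: np.ndarray,
    yy: np.ndarray,
) -> None:
    """Carve a tube running along the B-scan axis as a dark disk per B-scan."""
    for j in range(reflect.shape[2]):
        cz, cy = centers_zy[j]
        sel = (zz - cz) ** 2 + (yy - cy) ** 2 <= radius**2
        reflect[:, :, j][sel] = value


def generate_phantom(spec: PhantomSpec) -> tuple[OCTVolume, PhantomTruth]:
    """Build a phantom volume and its exact ground truth.

    The layered reflectivity map is assembled first (retina over choroid
    over sclera, bowl-warped, with vessel lumina and SPCA tracks carved
    out), then attenuated as ``exp(-attenuation_coeff * z)``, multiplied by
    unit-mean Gamma speckle of variance ``speckle_level``, and quantized to
    8 bits.  The same seed always yields a bit-identical volume.
    """
    rng = np.random.default_rng(spec.seed)
    nz, ny, nx = spec.shape

    yn = (np.arange(ny) - (ny - 1) / 2) / ((ny - 1) / 2)
    xn = (np.arange(nx) - (nx - 1) / 2) / ((nx - 1) / 2)
    bowl = spec.curvature_px * (yn[:, None] ** 2 + xn[None, :] ** 2) / 2.0  # (ny, nx)

    retina_top = spec.retina_top_px + bowl
    cib = spec.cib_depth_px + bowl
    thickness = spec.choroid_thickness_px + spec.thickness_wave_px * np.sin(
        2 * np.pi * np.arange(ny)[:, None] / ny
    ) * np.cos(2 * np.pi * np.arange(nx)[None, :] / nx)
    cob = cib + thickness

    z = np.arange(nz, dtype=float)[:, None, None]
    reflect = np.full(spec.shape, spec.background_reflect, dtype=float)
    retina_mask = (z >= retina_top[None]) & (z < cib[None])
    rpe_mask = (z >= (cib - spec.rpe_thickness_px)[None]) & (z < cib[None])
    choroid_mask = (z >= cib[None]) & (z < cob[None])
    sclera_mask = z >= cob[None]
    reflect[retina_mask] = spec.retina_reflect
    reflect[rpe_mask] = spec.rpe_reflect
    reflect[choroid_mask] = spec.choroid_reflect
    reflect[sclera_mask] = spec.sclera_reflect

    zz, yy = np.meshgrid(np.arange(nz), np.arange(ny), indexing="ij")

    # Haller-type vessels: large lumina hugging the choroid-sclera interface
    margin = max(spec.haller_radius_px[1] + 2, 8)
    y_haller = np.linspace(margin, ny - margin, spec.n_haller) + rng.uniform(
        -4, 4, spec.n_haller
    )
    for y0 in y_haller:
        r = rng.uniform(*spec.haller_radius_px)
        wob = rng.uniform(0, 2 * np.pi)
        centers = np.empty((nx, 2))
        for j in range(nx):
            yj = np.clip(y0 + 3 * np.sin(2 * np.pi * j / nx + wob), 0, ny - 1)
            centers[j] = (cob[int(round(yj)), j] - r - 1.5, yj)
        _carve_tube(reflect, centers, r, spec.lumen_reflect, zz, yy)

    # Sattler-type vessels: smaller lumina in the inner choroid
    y_sattler = rng.uniform(margin, ny - margin, spec.n_sattler)
    for y0 in y_sattler:
        r = rng.uniform(*spec.sattler_radius_px)
        frac = rng.uniform(0.25, 0.5)
        centers = np.empty((nx, 2))
        for j in range(nx):
            yj = np.clip(y0 + 2 * np.sin(2 * np.pi * j / nx), 0, ny - 1)
            iy = int(round(yj))
            centers[j] = (cib[iy, j] + frac * thickness[iy, j], yj)
        _carve_tube(reflect, centers, r, spec.lumen_reflect, zz, yy)

    # re-impose the layer boundaries so lumina never pierce retina or sclera
    reflect[retina_mask] = spec.retina_reflect
    reflect[rpe_mask] = spec.rpe_reflect
    reflect[sclera_mask & (reflect[:, :, :] == spec.lumen_reflect)] = spec.sclera_reflect

    # SPCA tracks: dark oblique cylinders crossing the sclera into the choroid
    px_per_mm_y = ny / spec.lateral_extent_mm
    px_per_mm_x = nx / spec.lateral_extent_mm
    if spec.spca_positions_mm is None:
        lo, hi = 1.5, spec.lateral_extent_mm - 1.5
        positions = rng.uniform(lo, hi, size=(spec.n_spca, 2))
    else:
        positions = np.asarray(spec.spca_positions_mm, dtype=float)
    angles = rng.uniform(0, 2 * np.pi, len(positions))
    for (x_mm, y_mm), ang in zip(positions, angles):
        y0 = y_mm * px_per_mm_y
        x0 = x_mm * px_per_mm_x
        iy0, ix0 = int(np.clip(round(y0), 0, ny - 1)), int(np.clip(round(x0), 0, nx - 1))
        z_entry = cob[iy0, ix0]
        # walk down from the entry point at the stated inclination
        for t in np.arange(0.0, nz - z_entry - 2, 0.5):
            zc = z_entry + t
            yc = y0 + spec.spca_incline * t * np.cos(ang)
            xj = int(np.clip(round(x0 + spec.spca_incline * t * np.sin(ang) * nx / ny), 0, nx - 1))
            if not 0 <= yc < ny:
                break
            sel = (zz - zc) ** 2 + (yy - yc) ** 2 <= spec.spca_radius_px**2
            # only darken scleral/choroidal voxels, never the retina
            dark = sel & (zz >= cib[iy0, xj] + 1)
            reflect[:, :, xj][dark] = spec.lumen_reflect

    # exported 8-bit OCT scans are log-compressed, so exponential signal
    # decay appears as a linear gray ramp with depth
    volume = np.maximum(reflect - spec.attenuation_coeff * z, 2.0)
    if spec.speckle_level > 0:
        shape_k = 1.0 / spec.speckle_level
        volume = volume * rng.gamma(shape_k, 1.0 / shape_k, size=spec.shape)
    volume = np.clip(np.rint(volume), 0, 255).astype(np.uint8)

    truth = PhantomTruth(
        cib=BoundarySurface(depth=cib, kind="CIB", stage="final", n_axial=nz),
        cob=BoundarySurface(depth=cob, kind="COB", stage="final", n_axial=nz),
        spca_marks=VesselMarkSet(
            positions_mm=positions,
            eye_id="phantom",
            observer_id="truth",
            trial_id="0",
            extent_mm=spec.lateral_extent_mm,
        ),
        layer_masks={
            "retina": retina_mask,
            "choroid": choroid_mask,
            "sclera": sclera_mask,
        },
    )
    return OCTVolume(volume, lateral_extent_mm=spec.lateral_extent_mm), truth


def perturb_marks(
    truth: VesselMarkSet,
    jitter_sd_mm: float = 0.2,
    drop_prob: float = 0.0,
    seed: int = 0,
) -> VesselMarkSet:
    """Simulate one observer trial: drop each mark with ``drop_prob``, then
    displace the survivors by isotropic Gaussian jitter of scale
    ``jitter_sd_mm`` (clipped to the field)."""
    if not 0 <= drop_prob <= 1:
        raise ValueError("drop_prob must be a probability")
    if jitter_sd_mm < 0:
        raise ValueError("jitter_sd_mm must be >= 0")
    rng = np.random.default_rng(seed)
    pos = np.asarray(truth.positions_mm, dtype=float)
    kept = rng.random(len(pos)) >= drop_prob
    out = pos[kept] + rng.normal(0.0, jitter_sd_mm, size=(int(kept.sum()), 2))
    out = np.clip(out, 0.0, truth.extent_mm)
    return truth.with_positions(out)


def simulate_observer_trials(
    n_eyes: int = 18,
    jitter_sd_mm: float = 0.2,
    drop_prob: float = 0.05,
    seed: int = 0,
    n_marks_range: tuple[int, int] = (10, 21),
    extent_mm: float = 12.0,
    margin_mm: float = 1.5,
) -> list[tuple[VesselMarkSet, VesselMarkSet, VesselMarkSet]]:
    """Simulate a cohort of eyes, each marked twice by a masked observer.

    Per eye, a ground-truth mark set is drawn (count uniform in
    ``n_marks_range``, positions uniform inside the field with a margin) and
    two independent trials are produced by :func:`perturb_marks`.  The
    per-eye randomness is derived deterministically from ``seed`` and the
    eye index, so two calls with the same seed but different jitter perturb
    identical truths with identically drawn (rescaled) displacements —
    comparisons across jitter levels are therefore paired.

    Returns a list of ``(truth, trial_1, trial_2)`` triples.
    """
    triples = []
    for e in range(n_eyes):
        g = np.random.default_rng((seed * 100003 + e * 7919) % 2**31)
        n = int(g.integers(*n_marks_range))
        pos = g.uniform(margin_mm, extent_mm - margin_mm, size=(n, 2))
        truth = VesselMarkSet(
            pos, eye_id=f"eye{e:02d}", observer_id="truth", trial_id="0", extent_mm=extent_mm
        )
        s1 = (seed * 100003 + e * 7919 + 1) % 2**31
        s2 = (seed * 100003 + e * 7919 + 2) % 2**31
        t1 = perturb_marks(truth, jitter_sd_mm, drop_prob, seed=s1)
        t2 = perturb_marks(truth, jitter_sd_mm, drop_prob, seed=s2)
        triples.append((truth, t1, t2))
    return triples
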