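import numpy as np
import pytest

from octsclera import (
    BoundarySurface,
    OCTVolume,
    PhantomSpec,
    SegmentationError,
    SegmentationParams,
    detect_cib_initial,
    detect_cob_initial,
    dice_report,
    generate_phantom,
    segment_volume,
    smooth_orthogonal,
)


def _band_scan(h=160, w=96, band=(40, 80), band_val=210, choroid_val=120):
    scan = np.zeros((h, w), dtype=np.uint8)
    scan[band[0] : band[1]] = band_val
    scan[band[1] : band[1] + 40] = choroid_val
    return scan


class TestCibInitial:
    def test_bright_band_lower_edge(self):
        """A bright retinal band over a dimmer choroid: the trace follows
        the band's choroid-facing (lower) edge."""
        trace = detect_cib_initial(_band_scan())
        params = SegmentationParams()
        valid = np.isfinite(trace)
        assert valid.mean() > 0.9
        assert np.abs(trace[valid] - 79).max() <= params.morph_radius + 1

    def test_gap_in_band_yields_gaps_only_there(self):
        scan = _band_scan()
        scan[40:80, 40:50] = 0  # punch a 10-column hole through the band
        trace = detect_cib_initial(scan)
        params = SegmentationParams()
        pad = params.morph_radius + params.open_radius
        inside = np.arange(40 + pad, 50 - pad)
        outside = np.concatenate([np.arange(5, 40 - pad), np.arange(50 + pad, 91)])
        assert np.isnan(trace[inside]).all()
        assert np.isfinite(trace[outside]).all()

    def test_all_zero_scan_flags_empty(self):
        trace = detect_cib_initial(np.zeros((64, 48), dtype=np.uint8))
        assert np.isnan(trace).all()


class TestCobInitial:
    def test_flat_bottom_choroidal_mass(self):
        """The trace follows the deepest (scleral-most) extent of the
        choroidal vascular mass."""
        scan = np.zeros((160, 96), dtype=np.uint8)
        scan[20:40] = 220  # retina
        scan[60:100] = 180  # vascular choroid with a flat bottom at 99
        scan[100:150] = 60  # sclera
        cib = np.full(96, 39.0)
        trace = detect_cob_initial(scan, cib)
        assert np.isfinite(trace).all()
        assert np.abs(trace - 99).max() <= 3

    def test_lumen_lower_envelope(self):
        """Dark vessel lumina riding on the interface do not drag the trace
        above their lower envelope."""
        scan = np.zeros((160, 96), dtype=np.uint8)
        scan[20:40] = 220
        scan[60:100] = 180
        zz, yy = np.meshgrid(np.arange(160), np.arange(96), indexing="ij")
        for yc in (20, 50, 80):
            scan[((zz - 92) ** 2 + (yy - yc) ** 2) <= 36] = 45  # lumina at the bottom
        cib = np.full(96, 39.0)
        trace = detect_cob_initial(scan, cib)
        assert np.abs(trace - 99).max() <= 4

    def test_no_evidence_flags_empty(self):
        scan = np.zeros((64, 48), dtype=np.uint8)
        scan[10:20] = 200  # retina only, nothing below
        trace = detect_cob_initial(scan, np.full(48, 19.0))
        assert np.isnan(trace).all()


class TestSmoothOrthogonal:
    def test_plane_with_gross_outliers_recovered(self, rng):
        ny, nx = 96, 48
        Y, X = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
        plane = 0.15 * X + 0.08 * Y + 50.0
        noisy = plane.copy()
        idx = rng.choice(plane.size, int(0.05 * plane.size), replace=False)
        noisy.flat[idx] += 50.0
        fin = smooth_orthogonal(BoundarySurface(noisy, "CIB", "initial", 256))
        assert np.sqrt(((fin.depth - plane) ** 2).mean()) <= 1.0

    def test_constant_surface_near_identity(self):
        const = np.full((48, 24), 33.0)
        fin = smooth_orthogonal(BoundarySurface(const, "CIB", "initial", 128))
        assert np.abs(fin.depth - 33.0).max() <= 0.5

    def test_missing_bscan_filled_between_neighbours(self):
        ny, nx = 48, 24
        surf = np.tile(np.linspace(20, 40, nx), (ny, 1))
        surf[:, 10] = np.nan
        fin = smooth_orthogonal(BoundarySurface(surf, "COB", "initial", 128))
        assert np.isfinite(fin.depth).all()
        lo = np.tile(np.linspace(20, 40, nx), (ny, 1))[:, 9] - 0.5
        hi = np.tile(np.linspace(20, 40, nx), (ny, 1))[:, 11] + 0.5
        assert ((fin.depth[:, 10] >= lo) & (fin.depth[:, 10] <= hi)).all()

    def test_inliers_barely_moved_when_mostly_clean(self, rng):
        ny, nx = 64, 32
        plane = np.fromfunction(lambda y, x: 0.1 * x + 30, (ny, nx))
        noisy = plane.copy()
        idx = rng.choice(plane.size, int(0.05 * plane.size), replace=False)
        noisy.flat[idx] += 40
        fin = smooth_orthogonal(BoundarySurface(noisy, "CIB", "initial", 128))
        inlier = np.ones(plane.size, dtype=bool)
        inlier[idx] = False
        moved = np.abs(fin.depth.ravel() - plane.ravel())[inlier]
        assert np.percentile(moved, 99) < 2.0


class TestSegmentVolume:
    def test_phantom_recovery(self, small_phantom, small_segmentation):
        vol, truth = small_phantom
        cib, cob = small_segmentation
        assert cib.stage == "final" and cob.stage == "final"
        assert (cob.depth > cib.depth).all()
        assert np.isfinite(cib.depth).all() and np.isfinite(cob.depth).all()
        assert np.abs(cib.depth - truth.cib.depth).mean() <= 2.0
        band = dice_report((cib, cob), (truth.cib, truth.cob), boundary="band")
        # the fixture's choroid is only ~30 px thick, so the same absolute
        # boundary accuracy costs proportionally more Dice than at full scale
        assert band.mean >= 0.93

    def test_deterministic(self, small_phantom, small_segmentation):
        vol, _ = small_phantom
        cib1, cob1 = small_segmentation
        cib2, cob2 = segment_volume(vol)
        assert np.array_equal(cib1.depth, cib2.depth)
        assert np.array_equal(cob1.depth, cob2.depth)

    def test_round_trip_through_disk_preserves_result(self, small_phantom, tmp_path):
        from octsclera import load_volume, save_volume

        vol, _ = small_phantom
        save_volume(vol, tmp_path / "v.tif")
        back = load_volume(tmp_path / "v.tif")
        cib1, _ = segment_volume(vol)
        cib2, _ = segment_volume(back)
        assert np.array_equal(cib1.depth, cib2.depth)

    def test_pure_noise_volume_fails(self, rng):
        noise = rng.integers(0, 256, (96, 96, 12)).astype(np.uint8)
        with pytest.raises(SegmentationError):
            segment_volume(OCTVolume(noise))

    def test_dice_degrades_monotonically_with_speckle(self):
        from tests.conftest import SMALL_SPEC
        from dataclasses import replace

        dices = []
        for level in (0.05, 0.3, 0.8):
            vol, truth = generate_phantom(replace(SMALL_SPEC, speckle_level=level))
            cib, cob = segment_volume(vol)
            dices.append(dice_report((cib, cob), (truth.cib, truth.cob), "band").mean)
        assert dices[0] >= dices[1] >= dices[2]


def test_surface_invariants():
    with pytest.raises(ValueError, match="gap-free"):
        BoundarySurface(np.array([[1.0, np.nan]]), "CIB", "final", 64)
    with pytest.raises(ValueError, match="lie in"):
        BoundarySurface(np.array([[70.0]]), "CIB", "final", 64)
    with pytest.raises(ValueError, match="kind"):
        BoundarySurface(np.array([[1.0]]), "RPE", "final", 64)
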