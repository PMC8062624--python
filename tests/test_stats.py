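import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from octsclera import (
    BoundarySurface,
    VesselMarkSet,
    agreement_analysis,
    dice_coefficient,
    dice_report,
    pair_trials,
    pearson,
    position_consistency,
    qualify_correlation,
    radial_positions,
    simulate_observer_trials,
)
from octsclera.stats import UndefinedCorrelationError, average_segmentation, even_median


class TestDiceCoefficient:
    def test_identical_sets(self):
        assert dice_coefficient(range(10), range(10)) == 1.0

    def test_disjoint_sets(self):
        assert dice_coefficient({1, 2, 3}, {4, 5}) == 0.0

    def test_half_overlap(self):
        assert dice_coefficient(range(10), range(5, 15)) == 0.5

    def test_both_empty_agree(self):
        assert dice_coefficient([], []) == 1.0

    @given(st.sets(st.integers(0, 30)), st.sets(st.integers(0, 30)))
    @settings(max_examples=100, deadline=None)
    def test_symmetric_and_bounded(self, a, b):
        d1, d2 = dice_coefficient(a, b), dice_coefficient(b, a)
        assert d1 == d2
        assert 0.0 <= d1 <= 1.0
        if a and a == b:
            assert d1 == 1.0

    def test_shrinking_overlap_decreases(self):
        prev = 1.0
        for shift in range(0, 11, 2):
            d = dice_coefficient(range(10), range(shift, shift + 10))
            assert d <= prev
            prev = d


def _surfaces(cib, cob, n_axial=128):
    return (
        BoundarySurface(np.asarray(cib, dtype=float), "CIB", "final", n_axial),
        BoundarySurface(np.asarray(cob, dtype=float), "COB", "final", n_axial),
    )


class TestDiceReport:
    def test_identical_segmentations(self):
        seg = _surfaces(np.full((8, 4), 30.0), np.full((8, 4), 70.0))
        rep = dice_report(seg, seg, boundary="band")
        assert rep.mean == 1.0 and rep.sd == 0.0

    def test_uniform_cob_shift_matches_set_oracle(self):
        cib = np.full((6, 3), 30.0)
        seg1 = _surfaces(cib, np.full((6, 3), 70.0))
        seg2 = _surfaces(cib, np.full((6, 3), 75.0))
        rep = dice_report(seg1, seg2, boundary="band")
        # brute-force pixel-index sets at one A-scan
        a = set(range(31, 71))
        b = set(range(31, 76))
        expect = 2 * len(a & b) / (len(a) + len(b))
        assert rep.mean == pytest.approx(expect)

    def test_random_surfaces_match_per_ascan_oracle(self, rng):
        cib1 = rng.uniform(20, 40, (5, 4))
        cob1 = cib1 + rng.uniform(10, 30, (5, 4))
        cib2 = cib1 + rng.normal(0, 2, (5, 4))
        cob2 = cob1 + rng.normal(0, 2, (5, 4))
        rep = dice_report(_surfaces(cib1, cob1), _surfaces(cib2, cob2), boundary="band")
        for i in range(5):
            for j in range(4):
                a = set(range(int(round(cib1[i, j])) + 1, int(round(cob1[i, j])) + 1))
                b = set(range(int(round(cib2[i, j])) + 1, int(round(cob2[i, j])) + 1))
                expect = dice_coefficient(a, b)
                assert rep.per_ascan[i, j] == pytest.approx(expect, abs=1e-12)

    def test_boundary_modes(self):
        seg1 = _surfaces(np.full((4, 2), 30.0), np.full((4, 2), 70.0))
        seg2 = _surfaces(np.full((4, 2), 33.0), np.full((4, 2), 70.0))
        # COB mode ignores the differing CIB
        assert dice_report(seg1, seg2, boundary="COB").mean == 1.0
        assert dice_report(seg1, seg2, boundary="CIB").mean < 1.0

    def test_average_segmentation_rounds_half_up(self):
        s1 = BoundarySurface(np.array([[30.0]]), "CIB", "final", 64)
        s2 = BoundarySurface(np.array([[31.0]]), "CIB", "final", 64)
        assert average_segmentation(s1, s2).depth[0, 0] == 31.0


class TestPositionConsistency:
    def test_radial_rebased_to_bottom_left(self):
        # a mark at the bottom-left corner has radial position 0
        ms = VesselMarkSet([[0.0, 12.0]], extent_mm=12.0)
        assert radial_positions(ms, n_px=1024)[0] == 0.0

    def test_three_four_five(self):
        ms = VesselMarkSet([[3.0, 12.0 - 4.0]], extent_mm=12.0)
        r = radial_positions(ms, n_px=12)  # 1 px per mm
        assert r[0] == pytest.approx(5.0)
        res = position_consistency(ms, [5.0], epsilon=0.5, n_px=12)
        assert res["valid"][0]

    def test_outside_tolerance(self):
        ms = VesselMarkSet([[3.0, 8.0]], extent_mm=12.0)
        res = position_consistency(ms, [6.0], epsilon=0.5, n_px=12)
        assert not res["valid"][0]

    def test_negative_epsilon_rejected(self):
        ms = VesselMarkSet([[3.0, 8.0]])
        with pytest.raises(ValueError, match="epsilon"):
            position_consistency(ms, [5.0], epsilon=-1)


class TestPearson:
    def test_perfect_and_inverse(self):
        u = np.array([1.0, 2.0, 5.0])
        assert pearson(u, u) == pytest.approx(1.0)
        assert pearson(u, -u) == pytest.approx(-1.0)

    def test_reference_value(self):
        assert pearson([1, 2, 3], [1, 2, 4]) == pytest.approx(0.98198, abs=1e-4)

    def test_zero_variance_flagged(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson([1, 1, 1], [1, 2, 3])

    @given(
        st.lists(st.floats(-100, 100), min_size=3, max_size=10, unique=True),
        st.floats(0.1, 5),
        st.floats(-10, 10),
    )
    @settings(max_examples=50, deadline=None)
    def test_positive_affine_invariance(self, u, a, b):
        from hypothesis import assume

        u = np.asarray(u)
        assume(np.ptp(u) > 1e-3 and np.ptp(a * u + b) > 1e-6)
        v = np.arange(len(u), dtype=float)
        assert pearson(a * u + b, v) == pytest.approx(pearson(u, v), abs=1e-6)


class TestQualifyCorrelation:
    @pytest.mark.parametrize(
        "r,label",
        [
            (0.9406, "very strong correlation"),
            (0.10, "very weak correlation"),
            (0.54, "moderate correlation"),
            (0.20, "weak correlation"),  # lower bin edge belongs to the higher bin
            (0.40, "moderate correlation"),
            (0.60, "strong correlation"),
            (0.80, "very strong correlation"),
            (-0.54, "moderate correlation"),  # magnitude-based
        ],
    )
    def test_bins(self, r, label):
        assert qualify_correlation(r) == label

    def test_total_on_unit_interval(self):
        for r in np.linspace(-1, 1, 201):
            assert qualify_correlation(float(r)) in {
                "very weak correlation",
                "weak correlation",
                "moderate correlation",
                "strong correlation",
                "very strong correlation",
            }


class TestMedianConvention:
    def test_even_count_averages_two_middle(self, rng):
        for _ in range(200):
            v = rng.normal(size=rng.integers(2, 40))
            s = np.sort(v)
            n = len(s)
            expect = s[n // 2] if n % 2 else (s[n // 2 - 1] + s[n // 2]) / 2
            assert even_median(v) == pytest.approx(expect)

    def test_eighteen_eyes_uses_ninth_and_tenth(self, rng):
        v = rng.normal(size=18)
        s = np.sort(v)
        assert even_median(v) == pytest.approx((s[8] + s[9]) / 2)


class TestAgreement:
    def test_pair_trials_matches_nearest(self):
        a = VesselMarkSet([[1.0, 1.0], [5.0, 5.0], [9.0, 9.0]])
        b = VesselMarkSet([[5.1, 5.0], [1.0, 1.1]])
        ia, ib = pair_trials(a, b, max_dist_mm=0.5)
        assert set(zip(ia.tolist(), ib.tolist())) == {(0, 1), (1, 0)}

    def test_small_jitter_gives_strong_agreement(self):
        triples = simulate_observer_trials(n_eyes=18, jitter_sd_mm=0.2, drop_prob=0.05, seed=7)
        rep = agreement_analysis([(t1, t2) for _, t1, t2 in triples], mode="auto")
        assert rep.median_r > 0.8
        assert rep.label in ("strong correlation", "very strong correlation")

    def test_more_jitter_less_agreement(self):
        meds = []
        for jitter in (0.1, 0.25, 0.5):
            triples = simulate_observer_trials(18, jitter, 0.05, seed=7)
            rep = agreement_analysis(
                [(t1, t2) for _, t1, t2 in triples], mode="auto", max_dist_mm=1.5
            )
            meds.append(rep.median_r)
        assert meds[0] > meds[1] > meds[2]

    def test_no_pairs_rejected(self):
        empty = VesselMarkSet(np.empty((0, 2)))
        with pytest.raises(ValueError, match="no eye"), pytest.warns(UserWarning):
            agreement_analysis([(empty, empty)])
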