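"""Contour length, position fraction, bend angle, MW calibration, filters."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import afmscan as a


def _two_arm_polyline(kink_deg, arm_len=80.0, n=81):
    """Two straight arms meeting at the origin end with a direction change."""
    t = np.linspace(0, arm_len, n)
    left = np.column_stack([t, np.zeros_like(t)])[:-1]
    ang = np.deg2rad(kink_deg)
    right = np.column_stack([arm_len + t * np.cos(ang), t * np.sin(ang)])
    return a.PolylineTrace(0, np.vstack([left, right]))


class TestContourLength:
    def test_three_four_five(self):
        assert a.contour_length(a.PolylineTrace(0, [[0, 0], [3, 4]])) == 5.0

    def test_open_square(self):
        sq = a.PolylineTrace(0, [[0, 0], [10, 0], [10, 10], [0, 10]])
        assert a.contour_length(sq) == 30.0

    def test_single_point_rejected(self):
        with pytest.raises(a.InvalidTraceError):
            a.contour_length(a.PolylineTrace(0, [[1.0, 1.0]]))

    def test_simulated_chain_lengths_center_at_contour(self):
        rng = np.random.default_rng(0)
        lengths = [a.contour_length(a.PolylineTrace(0, a.generate_wlc_chain(
            165.0, 50.0, 2.5, rng))) for _ in range(50)]
        center, _ = a.fit_length_distribution(lengths)
        assert center == pytest.approx(165.0, abs=2.5)


class TestPositionFraction:
    @pytest.mark.parametrize("s_frac,expect", [(0.5, 50.0), (0.0, 0.0),
                                               (0.46, 46.0), (0.7, 30.0)])
    def test_folds_to_closer_end(self, straight_chain, s_frac, expect):
        L = a.contour_length(straight_chain)
        assert a.position_fraction(straight_chain, s_frac * L) == \
            pytest.approx(expect)

    def test_out_of_range_rejected(self, straight_chain):
        with pytest.raises(a.InvalidParameterError):
            a.position_fraction(straight_chain, 200.0)

    def test_invariant_under_reversal(self, straight_chain):
        rev = a.PolylineTrace(0, straight_chain.points[::-1])
        L = a.contour_length(straight_chain)
        assert a.position_fraction(straight_chain, 40.0) == \
            pytest.approx(a.position_fraction(rev, L - 40.0))


class TestBendAngle:
    @pytest.mark.parametrize("kink", [0.0, 70.0, 90.0, 135.0])
    def test_constructed_kinks_recovered_exactly(self, kink):
        tr = _two_arm_polyline(kink)
        assert a.bend_angle(tr, 80.0) == pytest.approx(kink, abs=1e-9)

    def test_direction_change_of_70_gives_beta_70(self):
        # arms (1,0) and (cos 110, sin 110) measured at the vertex enclose
        # alpha = 110 deg, so beta = 180 - 110 = 70
        tr = _two_arm_polyline(70.0)
        beta = a.bend_angle(tr, 80.0)
        assert beta == pytest.approx(70.0, abs=1e-9)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(angle=st.floats(0, 2 * np.pi), dx=st.floats(-500, 500),
           dy=st.floats(-500, 500))
    def test_invariant_under_rigid_motion_and_reversal(self, angle, dx, dy):
        tr = _two_arm_polyline(70.0)
        c, s = np.cos(angle), np.sin(angle)
        moved = tr.points @ np.array([[c, -s], [s, c]]).T + [dx, dy]
        beta_m = a.bend_angle(a.PolylineTrace(0, moved), 80.0)
        beta_r = a.bend_angle(a.PolylineTrace(0, moved[::-1]), 80.0)
        assert beta_m == pytest.approx(70.0, abs=1e-6)
        assert beta_r == pytest.approx(70.0, abs=1e-6)

    def test_insufficient_arm_flags_unmeasurable(self, straight_chain):
        with pytest.raises(a.UnmeasurableComplexError):
            a.bend_angle(straight_chain, 2.0)

    def test_imposed_kink_on_wlc_recovered_at_short_window(self):
        # short tangent windows keep thermal curvature out of the estimate
        rng = np.random.default_rng(3)
        errs = []
        for _ in range(30):
            pts = a.generate_wlc_chain(165.0, 50.0, 1.0, rng)
            pts = a.impose_kink(pts, 80.0, 70.0, rng)
            errs.append(a.bend_angle(a.PolylineTrace(0, pts), 80.0,
                                     exclusion_radius=1.0, arm_window=8.0) - 70.0)
        assert abs(np.mean(errs)) < 5.0


class TestVolumeToMW:
    def test_calibration_constants(self):
        assert a.volume_to_mw(0.0) == pytest.approx(4.9167, abs=1e-4)
        assert a.volume_to_mw(49.3) == pytest.approx(46.0, abs=1e-9)

    def test_monotone(self):
        v = np.linspace(0, 200, 50)
        mw = a.volume_to_mw(v)
        assert np.all(np.diff(mw) > 0)

    def test_nonfinite_rejected(self):
        with pytest.raises(a.InvalidParameterError):
            a.volume_to_mw(np.nan)


class TestFlagFilters:
    def _traces(self, lengths):
        return [a.PolylineTrace(i, [[0, 0], [L, 0]])
                for i, L in enumerate(lengths)]

    def test_length_window_and_end_zone(self):
        traces = self._traces([165.0, 250.0])
        recs = [a.ComplexRecord(0, 5.0, position_fraction=3.0),
                a.ComplexRecord(1, 100.0, position_fraction=40.0)]
        kept = a.flag_filters(recs, traces, length_fit=(165.0, 24.0))
        assert [r.fragment_id for r in kept] == [0]  # 250 nm outside 2 SD
        assert kept[0].end_bound  # 3% < 5%

    def test_close_neighbors_both_flagged(self):
        traces = self._traces([165.0])
        recs = [a.ComplexRecord(0, 50.0, position_fraction=30.0),
                a.ComplexRecord(0, 80.0, position_fraction=48.0)]
        kept = a.flag_filters(recs, traces, length_fit=(165.0, 24.0))
        assert all(r.neighbor_excluded for r in kept)  # 30 nm < 50 nm

    def test_distant_neighbors_not_flagged(self):
        traces = self._traces([165.0])
        recs = [a.ComplexRecord(0, 30.0, position_fraction=18.0),
                a.ComplexRecord(0, 120.0, position_fraction=27.0)]
        kept = a.flag_filters(recs, traces, length_fit=(165.0, 24.0))
        assert not any(r.neighbor_excluded for r in kept)


class TestIntrinsicBendScan:
    def test_straight_chain_all_near_zero(self, straight_chain):
        scan = a.intrinsic_bend_scan(straight_chain)
        assert scan and all(abs(b) < 1e-6 for _, b in scan)

    def test_scan_interval_margins(self, straight_chain):
        # 165 nm at 50 nm intervals: only 50 and 100 nm leave full arms
        positions = [s for s, _ in a.intrinsic_bend_scan(straight_chain)]
        assert positions == [50.0, 100.0]

    def test_site_mode_recovers_imposed_lesion_bend(self, straight_chain, rng):
        pts = a.impose_kink(straight_chain.points, 0.46 * 165.0, 30.0, rng)
        scan = a.intrinsic_bend_scan(a.PolylineTrace(0, pts),
                                     site_fraction=0.46)
        assert len(scan) == 1
        assert scan[0][1] == pytest.approx(30.0, abs=1.0)
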