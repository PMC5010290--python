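"""Track metrics: speeds, turns, meandering, filtering, MSD, autocorrelation."""

import numpy as np
import pytest

from leukowalk.tracks import (
    EmptyProfileError,
    Track,
    TrackDataset,
    apply_displacement_filter,
    build_motility_profile,
    displacement_autocorrelation,
    meandering_index,
    msd_curve,
    net_displacement,
    step_speeds,
    turn_speeds,
)
from tests.conftest import make_track


class TestTrackValidation:
    def test_too_short(self):
        with pytest.raises(ValueError):
            make_track([[0, 0, 0]])

    def test_nonuniform_times_rejected(self):
        with pytest.raises(ValueError):
            Track("x", np.zeros((3, 3)) + np.arange(3)[:, None], dt=30.0,
                  times=np.array([0.0, 30.0, 70.0]))

    def test_nonfinite_rejected(self):
        pts = np.zeros((3, 3))
        pts[1, 2] = np.nan
        with pytest.raises(ValueError):
            make_track(pts)


class TestStepSpeeds:
    @pytest.mark.parametrize(
        "points,dt,expected",
        [
            ([[0, 0, 0], [5, 0, 0]], 30.0, [10.0]),       # 5 µm per half-minute
            ([[1, 2, 3], [1, 2, 3]], 30.0, [0.0]),         # stationary
            ([[0, 0, 0], [3, 0, 0], [9, 0, 0]], 60.0, [3.0, 6.0]),
        ],
    )
    def test_examples(self, points, dt, expected):
        np.testing.assert_allclose(step_speeds(make_track(points, dt)), expected)


class TestTurnSpeeds:
    def test_straight_is_zero(self, straight_track):
        np.testing.assert_allclose(turn_speeds(straight_track), 0.0, atol=1e-9)

    @pytest.mark.parametrize("dt,ceiling", [(30.0, 360.0), (45.0, 240.0)])
    def test_reversal_hits_sampling_ceiling(self, dt, ceiling):
        """An exact reversal is the largest measurable turn: 180° per
        interval, i.e. 360 °/min at 30 s and 240 °/min at 45 s sampling."""
        tr = make_track([[0, 0, 0], [1, 0, 0], [0, 0, 0]], dt)
        np.testing.assert_allclose(turn_speeds(tr), [ceiling])

    def test_right_angle_turn(self):
        tr = make_track([[0, 0, 0], [1, 0, 0], [1, 1, 0]], 60.0)
        np.testing.assert_allclose(turn_speeds(tr), [90.0])

    def test_zero_displacement_skipped(self):
        tr = make_track([[0, 0, 0], [1, 0, 0], [1, 0, 0], [2, 0, 0]], 30.0)
        vals, skipped = turn_speeds(tr, return_skipped=True)
        assert skipped == 2  # both turns touch the zero-length middle step
        assert vals.size == 0

    def test_ceiling_never_exceeded(self):
        rng = np.random.default_rng(0)
        for dt in (30.0, 45.0):
            tr = make_track(rng.normal(size=(30, 3)) * 10, dt)
            assert turn_speeds(tr).max() <= 180.0 / (dt / 60.0) + 1e-9

    def test_needs_three_points(self):
        with pytest.raises(ValueError):
            turn_speeds(make_track([[0, 0, 0], [1, 0, 0]]))


class TestMeanderingIndex:
    def test_straight(self, straight_track):
        assert meandering_index(straight_track) == pytest.approx(1.0)

    def test_closed_loop(self):
        tr = make_track([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 0, 0]])
        assert meandering_index(tr) == pytest.approx(0.0)

    def test_perpendicular_steps(self):
        tr = make_track([[0, 0, 0], [10, 0, 0], [10, 10, 0]])
        assert meandering_index(tr) == pytest.approx(np.sqrt(200) / 20)

    def test_zero_path_undefined(self):
        with pytest.raises(ValueError):
            meandering_index(make_track([[0, 0, 0], [0, 0, 0]]))

    def test_rigid_motion_invariance(self):
        """Meandering index is invariant under global rotation+translation."""
        rng = np.random.default_rng(5)
        pts = np.cumsum(rng.normal(size=(12, 3)), axis=0)
        mi = meandering_index(make_track(pts))
        from scipy.spatial.transform import Rotation

        for seed in range(5):
            r = Rotation.random(rng=np.random.default_rng(seed)).as_matrix()
            moved = pts @ r.T + np.array([50.0, -20.0, 7.0])
            assert meandering_index(make_track(moved)) == pytest.approx(mi, abs=1e-9)


class TestDisplacementFilter:
    def _track_with_net(self, d, tid):
        return make_track([[0, 0, 0], [d, 0, 0]], track_id=tid)

    def test_boundary_semantics(self):
        """Strictly-below-threshold tracks are removed; the boundary is
        retained (net first-to-last displacement reading)."""
        ds = TrackDataset(
            [self._track_with_net(26.9, "a"), self._track_with_net(27.0, "b")]
        )
        kept = apply_displacement_filter(ds, 27.0)
        assert [t.track_id for t in kept] == ["b"]

    def test_counts(self):
        ds = TrackDataset(
            [self._track_with_net(d, f"t{d}") for d in (10, 27, 40)]
        )
        assert len(apply_displacement_filter(ds, 27.0)) == 2

    def test_zero_threshold_identity(self, brownian_dataset):
        assert len(apply_displacement_filter(brownian_dataset, 0.0)) == len(
            brownian_dataset
        )


class TestMotilityProfile:
    def test_multiset_sizes_counting_oracle(self, brownian_dataset):
        """Pooled sizes: Σ(n−1) translations, ≤ Σ(n−2) turns, one meandering
        index and one median pair per surviving track."""
        prof = build_motility_profile(brownian_dataset, filter_um=0.0)
        n = [len(t) for t in brownian_dataset]
        assert prof.pooled_translational_speeds.size == sum(x - 1 for x in n)
        assert prof.pooled_turn_speeds.size <= sum(x - 2 for x in n)
        assert prof.meandering_indices.size == len(brownian_dataset)
        assert prof.median_track_translational_speeds.size == len(brownian_dataset)

    def test_pooling_is_concatenation(self, straight_track):
        twin = Track("twin", straight_track.positions, straight_track.dt)
        one = build_motility_profile(TrackDataset([straight_track]), 0.0)
        two = build_motility_profile(TrackDataset([straight_track, twin]), 0.0)
        assert two.pooled_translational_speeds.size == 2 * one.pooled_translational_speeds.size
        assert two.meandering_indices.size == 2

    def test_empty_after_filter_raises(self):
        ds = TrackDataset([make_track([[0, 0, 0], [1, 0, 0], [2, 0, 0]])])
        with pytest.raises(EmptyProfileError):
            build_motility_profile(ds, filter_um=27.0)


def long_straight_track():
    pts = np.zeros((21, 3))
    pts[:, 0] = np.arange(21) * 6.0
    return make_track(pts)


class TestMsd:
    def test_ballistic_slope_exact(self):
        _, _, slope = msd_curve(TrackDataset([long_straight_track()]))
        assert slope == pytest.approx(2.0, abs=1e-6)

    def test_brownian_ensemble_diffusive(self, brownian_dataset):
        _, _, slope = msd_curve(brownian_dataset)
        assert slope == pytest.approx(1.0, abs=0.1)

    def test_stationary_undefined(self):
        ds = TrackDataset([make_track(np.zeros((10, 3)))])
        with pytest.raises(ValueError):
            msd_curve(ds)

    def test_lag_window(self):
        tr = long_straight_track()
        lags, _, _ = msd_curve(TrackDataset([tr]), max_fraction=0.25)
        assert lags.max() <= 0.25 * tr.duration + 1e-9


class TestAutocorrelation:
    def test_straight_fully_correlated(self, straight_track):
        _, med, _, _ = displacement_autocorrelation(TrackDataset([straight_track]))
        np.testing.assert_allclose(med, 1.0)

    def test_zigzag_anticorrelated_at_lag_one(self, zigzag_track):
        lags, med, _, _ = displacement_autocorrelation(TrackDataset([zigzag_track]))
        assert med[0] == pytest.approx(-1.0)

    def test_brownian_uncorrelated(self, brownian_dataset):
        _, med, _, _ = displacement_autocorrelation(brownian_dataset)
        assert np.abs(med[:5]).max() < 0.05

    def test_values_bounded(self, brownian_dataset):
        _, med, lo, hi = displacement_autocorrelation(brownian_dataset)
        assert (med >= -1).all() and (med <= 1).all()
        assert (lo <= med).all() and (med <= hi).all()


def test_net_displacement_geometry():
    tr = make_track([[0, 0, 0], [3, 0, 0], [3, 4, 0]])
    assert net_displacement(tr) == pytest.approx(5.0)
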