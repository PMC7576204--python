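"""Primitive-feature math, alignment, standardization and padding."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from deephl.errors import ValidationError
from deephl.features import (ALL_CHANNELS, SENTINEL, angle_from_origin,
                             build_feature_tensor, moving_stats,
                             relative_angular_speed, speed,
                             straight_line_distance_from_origin, travel_distance)
from deephl.trajectory_io import Trajectory


def traj_from_xy(x, y, t=None, tid="t", label="A"):
    x = np.asarray(x, dtype=float)
    t = np.arange(len(x), dtype=float) if t is None else np.asarray(t, dtype=float)
    return Trajectory(id=tid, t=t, x=x, y=np.asarray(y, dtype=float), label=label)


class TestSpeed:
    def test_constant_velocity(self):
        tr = traj_from_xy([0, 0, 0], [0, 1, 2])
        np.testing.assert_allclose(speed(tr), [1, 1])

    def test_stationary(self):
        np.testing.assert_allclose(speed(traj_from_xy([1, 1, 1], [2, 2, 2])), [0, 0])

    def test_345_triangle(self):
        tr = traj_from_xy([0, 3], [0, 4], t=[0, 2])
        np.testing.assert_allclose(speed(tr), [2.5])


class TestAngularSpeed:
    def test_collinear_is_zero(self):
        tr = traj_from_xy([0, 1, 2, 3, 4], [0, 1, 2, 3, 4])
        np.testing.assert_allclose(relative_angular_speed(tr), 0, atol=1e-12)

    def test_ccw_square_corners(self):
        """Counter-clockwise unit square at 1 Hz turns +pi/2 at each corner."""
        tr = traj_from_xy([0, 1, 1, 0, 0], [0, 0, 1, 1, 0])
        np.testing.assert_allclose(relative_angular_speed(tr), np.pi / 2, atol=1e-12)

    def test_wrap_through_pi(self):
        """Heading 170 deg then -170 deg is a +20 deg step, not -340."""
        h1, h2 = np.deg2rad(170), np.deg2rad(-170)
        pts = np.array([[0, 0], [np.cos(h1), np.sin(h1)],
                        [np.cos(h1) + np.cos(h2), np.sin(h1) + np.sin(h2)]])
        tr = traj_from_xy(pts[:, 0], pts[:, 1])
        np.testing.assert_allclose(relative_angular_speed(tr), np.deg2rad(20), atol=1e-9)

    def test_zero_length_steps_carry_heading(self):
        tr = traj_from_xy([0, 1, 1, 2], [0, 0, 0, 0])
        np.testing.assert_allclose(relative_angular_speed(tr), 0, atol=1e-12)


class TestOriginFeatures:
    def test_straight_path_along_y(self):
        tr = traj_from_xy([0, 0, 0, 0], [0, 1, 2, 3])
        np.testing.assert_allclose(angle_from_origin(tr), 0, atol=1e-12)
        np.testing.assert_allclose(travel_distance(tr),
                                   straight_line_distance_from_origin(tr), atol=1e-12)

    def test_point_east_is_right_angle(self):
        tr = traj_from_xy([0, 1], [0, 0])
        assert angle_from_origin(tr)[1] == pytest.approx(np.pi / 2)

    def test_travel_ge_straight_line(self, rng):
        xy = rng.standard_normal((100, 2)).cumsum(axis=0)
        tr = traj_from_xy(xy[:, 0], xy[:, 1])
        assert (travel_distance(tr) - straight_line_distance_from_origin(tr)
                >= -1e-12).all()


class TestInvariance:
    @given(st.integers(0, 2 ** 31 - 1), st.floats(-np.pi, np.pi),
           st.floats(-50, 50), st.floats(-50, 50))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_speed_and_turning_invariant_to_rigid_motion(self, seed, phi, dx, dy):
        rng = np.random.default_rng(seed)
        xy = rng.standard_normal((30, 2)).cumsum(axis=0)
        R = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
        xy2 = xy @ R.T + [dx, dy]
        tr1 = traj_from_xy(xy[:, 0], xy[:, 1])
        tr2 = traj_from_xy(xy2[:, 0], xy2[:, 1])
        np.testing.assert_allclose(speed(tr1), speed(tr2), atol=1e-9)
        np.testing.assert_allclose(relative_angular_speed(tr1),
                                   relative_angular_speed(tr2), atol=1e-9)


class TestMovingStats:
    def test_constant_series(self):
        mavg, mvar, deriv = moving_stats(np.full(30, 2.5), window=5)
        np.testing.assert_allclose(mavg, 2.5)
        np.testing.assert_allclose(mvar, 0, atol=1e-15)
        np.testing.assert_allclose(deriv, 0, atol=1e-15)

    def test_linear_ramp(self):
        x = np.arange(20.0)
        mavg, _, deriv = moving_stats(x, window=5, dt=1.0)
        np.testing.assert_allclose(mavg[2:-2], x[2:-2], atol=1e-12)
        np.testing.assert_allclose(deriv[1:], 1.0)

    def test_matches_direct_window_oracle(self, rng):
        x = rng.standard_normal(40)
        w = 5
        mavg, mvar, _ = moving_stats(x, window=w)
        for i in range(len(x)):
            lo, hi = max(0, i - w // 2), min(len(x), i + w // 2 + 1)
            win = x[lo:hi]
            assert mavg[i] == pytest.approx(win.mean(), abs=1e-12)
            assert mvar[i] == pytest.approx(win.var(), abs=1e-12)

    def test_window_validation(self):
        with pytest.raises(ValidationError):
            moving_stats(np.arange(10.0), window=4)
        with pytest.raises(ValidationError):
            moving_stats(np.arange(5.0), window=7)


class TestFeatureTensor:
    def make_dataset(self, lengths, seed=0):
        rng = np.random.default_rng(seed)
        trajs = []
        for i, n in enumerate(lengths):
            xy = rng.standard_normal((n, 2)).cumsum(axis=0)
            trajs.append(traj_from_xy(xy[:, 0], xy[:, 1], tid=f"t{i}",
                                      label="A" if i % 2 == 0 else "B"))
        return trajs

    def test_pooled_standardization(self):
        bundle = build_feature_tensor(self.make_dataset([50, 50, 60, 60]))
        pooled = np.concatenate([ft.values[ft.mask] for ft in bundle.tensors])
        np.testing.assert_allclose(pooled.mean(axis=0), 0, atol=1e-9)
        np.testing.assert_allclose(pooled.std(axis=0), 1, atol=1e-9)

    def test_padding_counts_mixed_lengths(self):
        bundle = build_feature_tensor(self.make_dataset([50, 80]))
        assert bundle.l_max == 78  # 80 raw points -> 78 aligned steps
        short = bundle.tensors[0]
        assert short.valid_length == 48
        assert (short.values[48:] == SENTINEL).all()
        assert (~short.mask[48:]).all() and short.mask[:48].all()

    def test_equal_lengths_full_masks(self):
        bundle = build_feature_tensor(self.make_dataset([40, 40]))
        assert all(ft.mask.all() for ft in bundle.tensors)

    def test_zero_sd_channel_rejected(self):
        trajs = self.make_dataset([30, 30])
        for tr in trajs:
            tr.extras["flat"] = np.ones(len(tr))
        with pytest.raises(ValidationError, match="flat"):
            build_feature_tensor(trajs, channels=("speed", "angular_speed", "flat"))

    def test_sentinels_do_not_leak_into_statistics(self):
        """Channel stats recomputed from unpadded series match the frozen ones."""
        trajs = self.make_dataset([30, 45, 60])
        bundle = build_feature_tensor(trajs)
        from deephl.features import raw_channel
        for j, ch in enumerate(bundle.channel_names):
            pooled = np.concatenate([raw_channel(tr, ch) for tr in trajs])
            assert bundle.channel_means[j] == pytest.approx(pooled.mean(), abs=1e-12)
            assert bundle.channel_sds[j] == pytest.approx(pooled.std(), abs=1e-12)

    def test_hdf5_cache_round_trip(self, tmp_path):
        from deephl.features import load_tensors, save_tensors
        bundle = build_feature_tensor(self.make_dataset([30, 45]))
        save_tensors(bundle, tmp_path / "cache.h5")
        tensors, means, sds = load_tensors(tmp_path / "cache.h5")
        np.testing.assert_allclose(means, bundle.channel_means)
        np.testing.assert_allclose(sds, bundle.channel_sds)
        by_id = {ft.trajectory_id: ft for ft in tensors}
        for ft in bundle.tensors:
            got = by_id[ft.trajectory_id]
            assert got.label == ft.label
            np.testing.assert_array_equal(got.values, ft.values)
            np.testing.assert_array_equal(got.mask, ft.mask)

    def test_series_set_keeps_selected_channels_and_common_extras(self):
        trajs = self.make_dataset([30, 30])
        for tr in trajs:
            tr.extras["temp"] = np.linspace(0, 1, len(tr)) + 0.1 * float(tr.label == "B")
        bundle = build_feature_tensor(trajs, channels=ALL_CHANNELS[:3])
        assert set(bundle.series_set.channel_names) == set(ALL_CHANNELS[:3]) | {"temp"}
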