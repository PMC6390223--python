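"""Object-frame transforms, grasp summaries, surface contacts, reach distances."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from graspbias import (
    GraspRecord,
    ObjectPose,
    grasp_summary,
    is_long_axis_grasp,
    reach_distance,
    surface_contacts,
    to_object_frame,
)
from graspbias.geometry import (
    DegenerateGraspError,
    OffObjectError,
    from_object_frame,
    grasp_axis_angle,
)

from conftest import START


def record(thumb, index, theta=150.0, **kw):
    defaults = dict(participant="P01", material="wood", repetition=1)
    defaults.update(kw)
    return GraspRecord(
        theta_condition=theta, thumb=np.asarray(thumb, float),
        index=np.asarray(index, float), **defaults
    )


class TestObjectPose:
    def test_theta_normalised_to_half_turn(self):
        assert ObjectPose(theta=240.0).theta == 60.0
        assert ObjectPose(theta=-30.0).theta == 150.0

    @pytest.mark.parametrize(
        "kw", [dict(length=-1), dict(radius=0), dict(length=2.0, radius=1.25)]
    )
    def test_invalid_dimensions_rejected(self, kw):
        with pytest.raises(ValueError):
            ObjectPose(**{"length": 10.0, "radius": 1.25, **kw})


class TestObjectFrame:
    @pytest.mark.parametrize(
        "theta, p, expected_u",
        [
            (0.0, (2.0, 0.0, 0.0), 2.0),
            (60.0, (1.0, 1.7320508, 0.0), 2.0),
            (90.0, (0.0, 3.0, 0.0), 3.0),
        ],
    )
    def test_long_axis_coordinate(self, theta, p, expected_u):
        u, v, w = to_object_frame(p, ObjectPose(theta=theta))
        assert u == pytest.approx(expected_u, abs=1e-6)
        assert v == pytest.approx(0.0, abs=1e-6)
        assert w == 0.0

    def test_center_maps_to_origin(self):
        pose = ObjectPose(center=(3.0, -2.0, 1.0), theta=37.0)
        assert to_object_frame(pose.center, pose) == pytest.approx((0, 0, 0))

    @settings(max_examples=200, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_round_trip_and_periodicity(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(-50, 50, 3)
        center = rng.uniform(-20, 20, 3)
        theta = rng.uniform(0, 360)
        pose = ObjectPose(center=center, theta=theta)
        uvw = to_object_frame(p, pose)
        np.testing.assert_allclose(from_object_frame(uvw, pose), p, atol=1e-9)
        # the axis is undirected: theta + 180 describes the same pose
        pose_flip = ObjectPose(center=center, theta=theta + 180.0)
        assert to_object_frame(p, pose_flip) == pytest.approx(uvw, abs=1e-9)


class TestGraspSummary:
    def test_symmetric_perpendicular_grasp_sits_on_midline(self, pose_150):
        n = pose_150.normal
        g = record(thumb=-1.25 * n, index=1.25 * n)
        s = grasp_summary(g, pose_150)
        assert s.u == pytest.approx(0.0, abs=1e-12)
        assert s.grasp_axis_angle == pytest.approx(90.0)

    def test_collinear_grasp_along_axis(self, pose_150):
        a = pose_150.axis
        s = grasp_summary(record(thumb=1.0 * a, index=3.0 * a), pose_150)
        assert s.u == pytest.approx(2.0)
        assert s.grasp_axis_angle == pytest.approx(0.0)

    def test_constructed_offset_round_trips(self, pose_150):
        # contacts straddling the axis at u = -1.5 recover that deviation
        on_axis = np.array([1.299038, -0.75, 0.0])  # -1.5 * axis(150 deg)
        n = pose_150.normal
        g = record(thumb=on_axis + 1.25 * n, index=on_axis - 1.25 * n)
        s = grasp_summary(g, pose_150)
        assert s.u == pytest.approx(-1.5, abs=1e-5)
        np.testing.assert_allclose(s.center, on_axis, atol=1e-9)

    def test_coincident_digits_rejected(self):
        with pytest.raises(DegenerateGraspError):
            record(thumb=(1, 1, 0), index=(1, 1, 0))


class TestLongAxisFilter:
    @pytest.mark.parametrize(
        "angle_from_axis, expected",
        [(90.0, False), (0.0, True), (30.0, True), (60.0, False)],
    )
    def test_default_threshold_partitions_at_45(
        self, pose_60, angle_from_axis, expected
    ):
        t = np.deg2rad(angle_from_axis)
        d = np.cos(t) * pose_60.axis + np.sin(t) * pose_60.normal
        g = record(thumb=-d, index=d, theta=60.0)
        assert grasp_axis_angle(g, pose_60) == pytest.approx(angle_from_axis)
        assert is_long_axis_grasp(g, pose_60) is expected

    def test_threshold_is_configurable(self, pose_60):
        d = np.cos(np.deg2rad(30)) * pose_60.axis + np.sin(np.deg2rad(30)) * pose_60.normal
        g = record(thumb=-d, index=d, theta=60.0)
        assert not is_long_axis_grasp(g, pose_60, angle_threshold=20.0)


class TestSurfaceContacts:
    def test_axis_on_x_contacts_on_y(self):
        thumb, index = surface_contacts(ObjectPose(theta=0.0), 0.0)
        np.testing.assert_allclose(thumb, [0, -1.25, 0], atol=1e-12)
        np.testing.assert_allclose(index, [0, 1.25, 0], atol=1e-12)

    def test_rotated_pose_ties_broken_by_x(self):
        # at theta=90 both contacts share y; thumb takes the smaller x
        thumb, index = surface_contacts(ObjectPose(theta=90.0), 0.0)
        np.testing.assert_allclose(thumb, [-1.25, 0, 0], atol=1e-12)
        np.testing.assert_allclose(index, [1.25, 0, 0], atol=1e-12)

    def test_thumb_side_far_swaps_digits(self, pose_60):
        near = surface_contacts(pose_60, 1.0, "near")
        far = surface_contacts(pose_60, 1.0, "far")
        np.testing.assert_allclose(near[0], far[1])
        np.testing.assert_allclose(near[1], far[0])

    @settings(max_examples=200, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_contact_pair_invariants(self, seed):
        rng = np.random.default_rng(seed)
        pose = ObjectPose(
            center=rng.uniform(-10, 10, 3),
            theta=rng.uniform(0, 180),
            length=rng.uniform(5, 20),
            radius=rng.uniform(0.5, 2.0),
        )
        u_off = rng.uniform(-pose.length / 2, pose.length / 2)
        thumb, index = surface_contacts(pose, u_off)
        assert np.linalg.norm(thumb - index) == pytest.approx(2 * pose.radius)
        mid_u, _, _ = to_object_frame(0.5 * (thumb + index), pose)
        assert mid_u == pytest.approx(u_off, abs=1e-9)
        assert thumb[1] <= index[1]

    def test_off_object_offset_rejected(self, pose_60):
        with pytest.raises(OffObjectError):
            surface_contacts(pose_60, 5.01)


class TestReachDistance:
    def test_study_layout_start_is_36cm_from_object(self):
        assert reach_distance(START, (0.0, 0.0, 0.0)) == pytest.approx(36.07, abs=0.005)

    @pytest.mark.parametrize(
        "start, p, d", [((3, 4, 0), (0, 0, 0), 5.0), ((1, 2, 3), (1, 2, 3), 0.0)]
    )
    def test_known_distances(self, start, p, d):
        assert reach_distance(start, p) == pytest.approx(d)

    def test_metric_axioms_on_random_triples(self, rng):
        for _ in range(200):
            a, b, c = rng.uniform(-30, 30, (3, 3))
            assert reach_distance(a, b) == pytest.approx(reach_distance(b, a))
            assert (
                reach_distance(a, c)
                <= reach_distance(a, b) + reach_distance(b, c) + 1e-12
            )


def test_theta_convention_matches_described_layout():
    """At 150° the rightward axis end is also the start-near end; at 60°
    the rightward (hand-side) end is *farther* from the start — the
    decoupling that makes the two-orientation design informative."""
    for theta, same_side in ((150.0, True), (60.0, False)):
        pose = ObjectPose(theta=theta)
        ends = [s * (pose.length / 2) * pose.axis for s in (+1, -1)]
        right_end = max(ends, key=lambda e: e[0])
        near_end = min(ends, key=lambda e: reach_distance(START, e))
        assert np.allclose(right_end, near_end) is same_side
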