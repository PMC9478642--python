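"""Superposition, rotation measurements and filament-axis fitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from filbundle.errors import DegenerateGeometryError, SelectionError
from filbundle.structmath import (
    HelicalParams,
    PlastinAnnotation,
    RigidTransform,
    atom_displacement,
    domain_swing,
    fit_filament_axis,
    linker_gap,
    orientation_vector_angle,
    rotation_about_axis,
    rotation_angle,
    superpose,
)

from conftest import toy_model


def random_points(seed, n=20, scale=10.0):
    return np.random.default_rng(seed).normal(scale=scale, size=(n, 3))


class TestSuperpose:
    def test_identity(self):
        pts = random_points(0)
        t, rmsd = superpose(pts, pts)
        np.testing.assert_allclose(t.rotation, np.eye(3), atol=1e-9)
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_pure_translation(self):
        pts = random_points(1)
        t, rmsd = superpose(pts, pts + [5.0, 0.0, 0.0])
        np.testing.assert_allclose(t.translation, [5.0, 0.0, 0.0], atol=1e-9)
        assert rotation_angle(t) == pytest.approx(0.0, abs=1e-9)
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_recovers_known_rotation(self):
        pts = random_points(3)
        R = rotation_about_axis([0, 0, 1], 37.0)
        t, rmsd = superpose(pts, pts @ R.T + [1.0, 2.0, 3.0])
        assert rotation_angle(t) == pytest.approx(37.0, abs=1e-6)
        assert rmsd == pytest.approx(0.0, abs=1e-8)

    def test_reflection_disallowed(self):
        # mirrored target: best proper rotation leaves residual, det stays +1
        pts = random_points(4)
        mirrored = pts * [-1.0, 1.0, 1.0]
        t, rmsd = superpose(pts, mirrored)
        assert np.linalg.det(t.rotation) == pytest.approx(1.0, abs=1e-9)
        assert rmsd > 0.1

    def test_degenerate_inputs(self):
        with pytest.raises(DegenerateGeometryError):
            superpose(random_points(0, n=2), random_points(1, n=2))
        line = np.outer(np.arange(5.0), [1.0, 0.0, 0.0])
        with pytest.raises(DegenerateGeometryError, match="collinear"):
            superpose(line, line)

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_rmsd_symmetric_and_rigid_invariant(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(scale=8, size=(12, 3))
        b = a + rng.normal(scale=1.0, size=a.shape)
        _, r_ab = superpose(a, b)
        _, r_ba = superpose(b, a)
        assert r_ab == pytest.approx(r_ba, abs=1e-9)
        # applying one global rigid motion to both sets changes nothing
        R = rotation_about_axis(rng.normal(size=3), rng.uniform(0, 180))
        shift = rng.normal(scale=50, size=3)
        _, r_moved = superpose(a @ R.T + shift, b @ R.T + shift)
        assert r_moved == pytest.approx(r_ab, abs=1e-9)

    def test_matches_independent_oracle(self):
        # oracle: quaternion-based alignment from scipy, an independent path
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(11)
        a = rng.normal(scale=10, size=(25, 3))
        b = a @ rotation_about_axis([1, 2, 3], 25.0).T + [4.0, -1.0, 2.0]
        b += rng.normal(scale=0.3, size=a.shape)
        t, rmsd = superpose(a, b)
        rot, rssd = Rotation.align_vectors(b - b.mean(0), a - a.mean(0))
        np.testing.assert_allclose(t.rotation, rot.as_matrix(), atol=1e-9)
        assert rmsd == pytest.approx(rssd / np.sqrt(len(a)), abs=1e-9)


class TestRotationAngle:
    @pytest.mark.parametrize("deg", [0.0, 45.0, 180.0])
    def test_known_angles(self, deg):
        t = RigidTransform(rotation_about_axis([1, 1, 0], deg), np.zeros(3))
        assert rotation_angle(t) == pytest.approx(deg, abs=1e-9)

    def test_composition_about_common_axis(self):
        r1 = rotation_about_axis([0, 1, 0], 20.0)
        r2 = rotation_about_axis([0, 1, 0], 25.0)
        assert rotation_angle(r2 @ r1) == pytest.approx(45.0, abs=1e-9)

    def test_conjugation_invariance(self):
        rng = np.random.default_rng(2)
        R = rotation_about_axis([3, 1, 2], 73.0)
        Q = rotation_about_axis(rng.normal(size=3), 111.0)
        assert rotation_angle(Q @ R @ Q.T) == pytest.approx(73.0, abs=1e-9)
        assert rotation_angle(R @ R.T) == pytest.approx(0.0, abs=1e-9)


class TestDomainMeasurements:
    def _two_domain_model(self, seed=0):
        rng = np.random.default_rng(seed)
        dom1 = rng.normal(scale=6, size=(30, 3))
        dom2 = rng.normal(scale=6, size=(30, 3)) + [40.0, 0.0, 0.0]
        return np.vstack([dom1, dom2])

    def test_swing_self_is_zero(self):
        m = toy_model(self._two_domain_model())
        assert domain_swing(m, m, ("A", (1, 30)), ("A", (31, 60))) == pytest.approx(0.0, abs=1e-7)

    def test_constructed_hinge_motion(self):
        coords = self._two_domain_model()
        m1 = toy_model(coords)
        hinge = np.array([20.0, 0.0, 0.0])
        R = rotation_about_axis([0, 0, 1], 120.0)
        moved = coords.copy()
        moved[30:] = (coords[30:] - hinge) @ R.T + hinge
        m2 = toy_model(moved)
        swing = domain_swing(m1, m2, ("A", (1, 30)), ("A", (31, 60)))
        assert swing == pytest.approx(120.0, abs=1e-6)

    def test_atom_displacement_constructed(self):
        coords = self._two_domain_model(1)
        m1 = toy_model(coords)
        moved = coords.copy()
        moved[45] += [0.0, 10.0, 0.0]
        m2 = toy_model(moved)
        d = atom_displacement(m1, m2, ("A", (1, 30)), ("A", 46, "CA"))
        assert d == pytest.approx(10.0, abs=1e-6)
        # co-moving the alignment region rigidly cancels out
        R = rotation_about_axis([1, 0, 0], 30.0)
        m3 = toy_model(coords @ R.T + [3.0, 4.0, 5.0])
        assert atom_displacement(m1, m3, ("A", (1, 30)), ("A", 46, "CA")) == pytest.approx(0.0, abs=1e-6)
        with pytest.raises(SelectionError):
            atom_displacement(m1, m2, ("A", (1, 30)), ("A", 999, "CA"))

    def test_orientation_vector_angle_constructed(self):
        coords = self._two_domain_model(2)
        m1 = toy_model(coords)
        pivot = coords[40]
        R = rotation_about_axis([0, 1, 0], 50.0)
        moved = coords.copy()
        moved[40:50] = (coords[40:50] - pivot) @ R.T + pivot
        m2 = toy_model(moved)
        ang = orientation_vector_angle(m1, m2, ("A", (1, 30)),
                                       ("A", 41), ("A", 50))
        assert ang == pytest.approx(50.0, abs=1.0)
        assert orientation_vector_angle(m1, m1, ("A", (1, 30)),
                                        ("A", 41), ("A", 50)) == pytest.approx(0.0, abs=1e-4)


class TestLinkerGap:
    def test_constructed_gap_distance(self):
        coords = np.array([[0.0, 0.0, 0.0], [13.5, 0.0, 0.0], [20.0, 0.0, 0.0]])
        m = toy_model(coords, resnums=[369, 394, 395])
        assert linker_gap(m, "A") == pytest.approx(13.5, abs=1e-9)
        assert linker_gap(m, "A", gap=(369, 394)) == pytest.approx(13.5, abs=1e-9)

    def test_no_gap_is_error_listing_available(self):
        m = toy_model(np.zeros((3, 3)), resnums=[1, 2, 3])
        with pytest.raises(SelectionError, match=r"\[\]"):
            linker_gap(m, "A")

    def test_orientation_invariance(self):
        rng = np.random.default_rng(9)
        coords = rng.normal(scale=15, size=(10, 3))
        m = toy_model(coords, resnums=[1, 2, 3, 4, 5, 30, 31, 32, 33, 34])
        d0 = linker_gap(m, "A")
        R = rotation_about_axis(rng.normal(size=3), 77.0)
        m2 = toy_model(coords @ R.T + [10.0, -4.0, 2.0],
                       resnums=[1, 2, 3, 4, 5, 30, 31, 32, 33, 34])
        assert linker_gap(m2, "A") == pytest.approx(d0, abs=1e-9)


def helix_points(n=13, rise=27.5, twist=-166.7, radius=25.0):
    k = np.arange(n)
    az = np.deg2rad(k * twist)
    return np.c_[radius * np.cos(az), radius * np.sin(az), k * rise]


class TestFilamentAxis:
    def test_exact_helix(self):
        pose, info = fit_filament_axis(helix_points(), HelicalParams())
        np.testing.assert_allclose(pose.direction, [0, 0, 1], atol=1e-8)
        np.testing.assert_allclose(pose.origin[:2], [0, 0], atol=1e-6)
        assert info["residual"] < 1e-6
        assert info["rise"] == pytest.approx(27.5, abs=1e-6)
        assert info["twist"] == pytest.approx(-166.7, abs=1e-6)
        assert not info["degenerate"]

    def test_reversed_order_flips_direction(self):
        pose, _ = fit_filament_axis(helix_points()[::-1], HelicalParams())
        np.testing.assert_allclose(pose.direction, [0, 0, -1], atol=1e-8)

    def test_noisy_centroids_recover_direction(self):
        rng = np.random.default_rng(0)
        pts = helix_points() + rng.normal(scale=1.0, size=(13, 3))
        pose, _ = fit_filament_axis(pts, HelicalParams())
        angle = np.degrees(np.arccos(np.clip(pose.direction @ [0, 0, 1], -1, 1)))
        assert angle < 1.0

    def test_rise_twist_estimator_consistency(self):
        # across many noise realisations the estimates stay centered on truth
        rises, twists = [], []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            pts = helix_points() + rng.normal(scale=0.5, size=(13, 3))
            _, info = fit_filament_axis(pts, HelicalParams())
            rises.append(info["rise"])
            twists.append(info["twist"])
        assert abs(np.mean(rises) - 27.5) < 3 * np.std(rises) / 10 + 0.05
        assert abs(np.mean(twists) - (-166.7)) < 3 * np.std(twists) / 10 + 0.2

    def test_too_few_points(self):
        with pytest.raises(DegenerateGeometryError):
            fit_filament_axis(helix_points()[:2], HelicalParams())


class TestAnnotation:
    def test_default_annotation_consistent(self):
        ann = PlastinAnnotation()
        assert ann.linker_length("linker12") == 30  # stated range 240-269
        assert ann.linker_length("linker23") == 20
        assert ann.linker_length("linker34") == 7
        assert ann.domains["CH1"][0] <= ann.landmarks["F191"] <= ann.domains["CH1"][1]
        assert ann.domains["CH2"][0] <= ann.landmarks["I309"] <= ann.domains["CH2"][1]
        assert ann.domains["linker23"][0] <= ann.landmarks["W390"] <= ann.domains["linker23"][1]
        assert ann.domains["CH4"][0] <= ann.landmarks["R594"] <= ann.domains["CH4"][1]

    def test_overlapping_domains_rejected(self):
        bad = dict(PlastinAnnotation().domains)
        bad["CH2"] = (250, 380)  # overlaps linker12
        with pytest.raises(DegenerateGeometryError):
            PlastinAnnotation(domains=bad)

    def test_helical_params_validation(self):
        with pytest.raises(DegenerateGeometryError):
            HelicalParams(rise=-1.0)
        with pytest.raises(DegenerateGeometryError):
            HelicalParams(twist=200.0)
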