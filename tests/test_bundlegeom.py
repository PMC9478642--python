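"""Bundle geometry: frame definition, pose ingestion, bridge span, docking,
summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from filbundle.bundlegeom import (
    BodyReference,
    bridge_span,
    dock_model_into_map,
    pair_geometry,
    per_particle_geometry,
    poses_from_bodies,
    summarize,
)
from filbundle.errors import DegenerateGeometryError, SelectionError
from filbundle.formats import PoseTable, VolumeMap
from filbundle.structmath import FilamentPose, RigidTransform, rotation_about_axis
from filbundle.synthgen import place_pair, sample_bundle_config

from conftest import toy_model


def pose(origin, direction, spin=0.0):
    return FilamentPose(np.asarray(origin, float), np.asarray(direction, float), spin)


class TestPairGeometry:
    def test_parallel_ideal(self):
        g = pair_geometry(pose([0, 0, 0], [0, 0, 1]), pose([150, 0, 0], [0, 0, 1]))
        assert g.polarity == "parallel"
        assert g.skew == pytest.approx(0.0, abs=1e-12)
        assert g.splay == pytest.approx(0.0, abs=1e-12)
        assert g.interfilament_distance == pytest.approx(150.0, abs=1e-12)

    def test_antiparallel_ideal(self):
        g = pair_geometry(pose([0, 0, 0], [0, 0, 1]), pose([150, 0, 0], [0, 0, -1]))
        assert g.polarity == "antiparallel"
        assert g.skew == pytest.approx(0.0, abs=1e-12)
        assert g.splay == pytest.approx(0.0, abs=1e-12)

    def test_constructed_splay(self):
        d = rotation_about_axis([0, 1, 0], 10.0) @ np.array([0, 0, 1.0])
        g = pair_geometry(pose([0, 0, 0], [0, 0, 1]), pose([150, 0, 0], d))
        # rotation about +y within the x-z plane tips the axis toward +x
        assert g.splay == pytest.approx(10.0, abs=1e-9)
        assert g.skew == pytest.approx(0.0, abs=1e-9)

    def test_constructed_skew(self):
        d = np.array([0.0, np.sin(np.deg2rad(9.0)), np.cos(np.deg2rad(9.0))])
        g = pair_geometry(pose([0, 0, 0], [0, 0, 1]), pose([150, 0, 0], d))
        assert g.skew == pytest.approx(9.0, abs=1e-9)
        assert g.splay == pytest.approx(0.0, abs=1e-9)

    def test_round_trip_with_place_pair(self):
        rng = np.random.default_rng(1)
        for _ in range(1000):
            c = sample_bundle_config(rng)
            g = pair_geometry(*place_pair(c))
            assert g.polarity == c.polarity
            assert g.skew == pytest.approx(c.skew, abs=1e-9)
            assert g.splay == pytest.approx(c.splay, abs=1e-9)
            assert g.interfilament_distance == pytest.approx(
                c.interfilament_distance, abs=1e-9)
            assert g.axial_offset == pytest.approx(c.axial_offset, abs=1e-9)

    @given(st.integers(0, 100_000))
    @settings(max_examples=30, deadline=None)
    def test_invariance_to_global_rigid_motion(self, seed):
        rng = np.random.default_rng(seed)
        c = sample_bundle_config(rng)
        pa, pb = place_pair(c)
        g0 = pair_geometry(pa, pb)
        R = rotation_about_axis(rng.normal(size=3), rng.uniform(0, 180))
        t = RigidTransform(R, rng.normal(scale=100, size=3))
        g1 = pair_geometry(pa.transformed(t), pb.transformed(t))
        assert g1.polarity == g0.polarity
        assert g1.skew == pytest.approx(g0.skew, abs=1e-9)
        assert g1.splay == pytest.approx(g0.splay, abs=1e-9)
        assert g1.interfilament_distance == pytest.approx(
            g0.interfilament_distance, abs=1e-9)

    @given(st.integers(0, 100_000))
    @settings(max_examples=30, deadline=None)
    def test_swap_preserves_polarity_and_angle_magnitudes(self, seed):
        # Swapping A and B keeps the polarity call and the total inter-axis
        # angle; the skew/splay decomposition is re-expressed in B's frame and
        # the origin-referenced distance changes only by the projection factor.
        rng = np.random.default_rng(seed)
        c = sample_bundle_config(rng)
        pa, pb = place_pair(c)
        g, gs = pair_geometry(pa, pb), pair_geometry(pb, pa)
        assert gs.polarity == g.polarity

        def total_angle(x):
            sk, sp = np.deg2rad([x.skew, x.splay])
            return np.degrees(np.arccos(np.clip(np.cos(sk) * np.cos(sp), -1, 1)))

        assert total_angle(gs) == pytest.approx(total_angle(g), abs=1e-9)
        # origin-referenced distance changes only by the frame projection
        # factor: |Delta| and the inter-axis angle bound the difference
        sinang = np.sin(np.deg2rad(total_angle(g)))
        bound = (abs(g.axial_offset) + g.interfilament_distance) * sinang + 1e-9
        assert abs(gs.interfilament_distance - g.interfilament_distance) <= bound
        # the line-line minimum distance is exactly symmetric
        assert gs.axis_min_distance == pytest.approx(g.axis_min_distance, abs=1e-9)

    def test_coincident_axes_flagged_degenerate(self):
        g = pair_geometry(pose([0, 0, 0], [0, 0, 1]), pose([0, 0, 30], [0, 0, 1]))
        assert g.degenerate
        assert g.interfilament_distance == pytest.approx(0.0, abs=1e-9)
        assert g.skew == 0.0 and g.splay == 0.0


class TestBridgeSpan:
    def _bridge_model(self, span=98.2):
        # two actin protomer chains (centroids `span` apart) plus a plastin
        # chain whose CH1 range touches protomer 1 and CH3 range protomer 2
        rng = np.random.default_rng(0)
        prot1 = rng.normal(scale=5, size=(20, 3))
        prot2 = rng.normal(scale=5, size=(20, 3))
        prot1 -= prot1.mean(axis=0)
        prot2 = prot2 - prot2.mean(axis=0) + [span, 0.0, 0.0]
        ch1 = prot1[:3] + [0.0, 2.0, 0.0]          # contacts protomer 1
        ch3 = prot2[:3] + [0.0, -2.0, 0.0]         # contacts protomer 2
        coords = np.vstack([prot1, prot2, ch1, ch3])
        chains = ["A"] * 20 + ["B"] * 20 + ["P"] * 6
        resnums = (list(range(1, 21)) + list(range(1, 21))
                   + [190, 191, 192] + [400, 401, 402])
        return toy_model(coords, chain=chains, resnums=resnums)

    def test_constructed_span(self):
        model = self._bridge_model(98.2)
        assert bridge_span(model, plastin_chain="P") == pytest.approx(98.2, abs=1e-6)

    def test_rigid_invariance(self):
        model = self._bridge_model(93.1)
        d0 = bridge_span(model, plastin_chain="P")
        R = rotation_about_axis([1, 2, 3], 60.0)
        moved = model.transformed(R, np.array([10.0, -30.0, 5.0]))
        assert bridge_span(moved, plastin_chain="P") == pytest.approx(d0, abs=1e-9)

    def test_single_filament_contact_is_error(self):
        rng = np.random.default_rng(1)
        prot = rng.normal(scale=5, size=(20, 3))
        ch = np.vstack([prot[:3] + [0, 2, 0], prot[3:6] - [0, 2, 0]])
        coords = np.vstack([prot, ch])
        model = toy_model(coords, chain=["A"] * 20 + ["P"] * 6,
                          resnums=list(range(1, 21)) + [190, 191, 192, 400, 401, 402])
        with pytest.raises(SelectionError):
            bridge_span(model, plastin_chain="P")


class TestPosesFromBodies:
    def _refs(self):
        ref_a = FilamentPose([0, 0, 0], [0, 0, 1], 0.0)
        ref_b = FilamentPose([150, 0, 0], [0, 0, 1], 0.0)
        return {1: BodyReference(ref_a, [0, 0, 0]),
                2: BodyReference(ref_b, [150, 0, 0])}

    def _rows(self, rot=0.0, tilt=0.0, psi=0.0, ox=0.0, oy=0.0, oz=0.0):
        return pd.DataFrame([
            {"particle": "p", "body": 1, "rot": 0.0, "tilt": 0.0, "psi": 0.0,
             "ox": 0.0, "oy": 0.0, "oz": 0.0},
            {"particle": "p", "body": 2, "rot": rot, "tilt": tilt, "psi": psi,
             "ox": ox, "oy": oy, "oz": oz},
        ])

    def test_identity_returns_references(self):
        pa, pb = poses_from_bodies(self._rows(), self._refs())
        np.testing.assert_allclose(pa.origin, [0, 0, 0], atol=1e-12)
        np.testing.assert_allclose(pb.origin, [150, 0, 0], atol=1e-12)
        np.testing.assert_allclose(pb.direction, [0, 0, 1], atol=1e-12)

    def test_tilt_about_body_center_gives_skew_or_splay(self):
        # ZYZ with rot=psi=0: tilt rotates about the lab y axis through the
        # body center; for the frame here that tips B within x-z -> splay
        pa, pb = poses_from_bodies(self._rows(tilt=9.0), self._refs())
        g = pair_geometry(pa, pb)
        assert abs(g.splay) == pytest.approx(9.0, abs=1e-9)
        assert g.skew == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(pb.origin, [150, 0, 0], atol=1e-9)

    def test_translation_only_changes_distance(self):
        pa, pb = poses_from_bodies(self._rows(ox=12.0), self._refs())
        g = pair_geometry(pa, pb)
        assert g.interfilament_distance == pytest.approx(162.0, abs=1e-9)
        assert g.skew == 0.0 and g.splay == 0.0

    def test_per_particle_table(self):
        refs = self._refs()
        rows = pd.concat([self._rows().assign(particle=f"p{i}") for i in range(100)])
        table = PoseTable(rows.reset_index(drop=True))
        out = per_particle_geometry(table, refs)
        assert len(out) == 100
        assert (out["error"] == "").all()
        assert out["interfilament_distance"].nunique() == 1

    def test_injected_skew_recovered_exactly(self):
        rng = np.random.default_rng(0)
        skews = rng.normal(2.4, 9.7, size=500)
        rows = []
        for i, sk in enumerate(skews):
            rows.append({"particle": i, "body": 1, "rot": 0.0, "tilt": 0.0,
                         "psi": 0.0, "ox": 0.0, "oy": 0.0, "oz": 0.0})
            # rotation about the lab x axis through the body center:
            # Rx(-sk) = ZYZ(-90, -sk, 90); it tips B's axis toward +y = +skew
            rows.append({"particle": i, "body": 2, "rot": -90.0, "tilt": -sk,
                         "psi": 90.0, "ox": 0.0, "oy": 0.0, "oz": 0.0})
        table = PoseTable(pd.DataFrame(rows))
        out = per_particle_geometry(table, self._refs())
        np.testing.assert_allclose(out["skew"].to_numpy(), skews, atol=1e-9)


class TestDocking:
    def test_self_docking_identity(self, protomer):
        from filbundle.synthgen import build_decorated_volume

        tpl = build_decorated_volume(protomer, n_protomers=5, voxel_size=4.4,
                                     resolution=12.0)
        t, corr, low = dock_model_into_map(tpl, tpl, rot_range=5.0)
        assert corr > 0.99
        assert not low
        from filbundle.structmath import rotation_angle

        assert rotation_angle(t) < 0.2
        assert np.linalg.norm(t.translation) < 0.2

    def test_known_perturbation_recovered(self, protomer):
        from filbundle.bundlegeom import _resample
        from filbundle.structmath import rotation_angle
        from filbundle.synthgen import build_decorated_volume
        from scipy.spatial.transform import Rotation

        tpl = build_decorated_volume(protomer, n_protomers=5, voxel_size=4.4,
                                     resolution=12.0)
        R = Rotation.from_rotvec([2.0, -3.0, 3.0], degrees=True).as_matrix()
        t_true = np.array([2.5, -1.0, 3.0])
        target = VolumeMap(
            _resample(tpl, tpl.shape, tpl.voxel_size,
                      RigidTransform(R, t_true)).astype(np.float32),
            tpl.voxel_size)
        found, corr, _ = dock_model_into_map(tpl, target, rot_range=5.0)
        d_ang = rotation_angle(found.rotation @ R.T)
        assert d_ang < 0.5
        assert np.linalg.norm(found.translation - t_true) < 0.5

    def test_in_radius_start_wins_two_basin(self, protomer):
        # a start inside the search radius of the truth must out-correlate one
        # stranded in a wrong basin outside it
        from filbundle.bundlegeom import _resample
        from filbundle.synthgen import build_decorated_volume
        from scipy.spatial.transform import Rotation

        tpl = build_decorated_volume(protomer, n_protomers=5, voxel_size=4.4,
                                     resolution=12.0)
        R = Rotation.from_rotvec([0.0, 0.0, 40.0], degrees=True).as_matrix()
        target = VolumeMap(
            _resample(tpl, tpl.shape, tpl.voxel_size,
                      RigidTransform(R, np.zeros(3))).astype(np.float32),
            tpl.voxel_size)
        good_start = RigidTransform(
            Rotation.from_rotvec([0, 0, 36.0], degrees=True).as_matrix(), np.zeros(3))
        _, corr_good, _ = dock_model_into_map(tpl, target, initial=good_start,
                                              rot_range=5.0)
        _, corr_bad, _ = dock_model_into_map(tpl, target, rot_range=5.0)
        assert corr_good > corr_bad


class TestSummarize:
    def test_matches_brute_force(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"skew": rng.normal(2, 9, 500),
                           "splay": rng.normal(-1, 8, 500),
                           "interfilament_distance": rng.normal(146, 6, 500)})
        s = summarize(df)
        for col in df.columns:
            x = df[col].to_numpy()
            mean = sum(x) / len(x)
            sd = np.sqrt(sum((v - mean) ** 2 for v in x) / (len(x) - 1))
            assert s.mean[col] == pytest.approx(mean, abs=1e-12)
            assert s.sd[col] == pytest.approx(sd, abs=1e-12)
        # brute-force Pearson correlation
        a, b = df["skew"].to_numpy(), df["splay"].to_numpy()
        r = (sum((a - a.mean()) * (b - b.mean()))
             / np.sqrt(sum((a - a.mean()) ** 2) * sum((b - b.mean()) ** 2)))
        assert s.correlation.loc["skew", "splay"] == pytest.approx(r, abs=1e-12)
        assert s.n == 500

    def test_constant_column_flagged(self):
        df = pd.DataFrame({"skew": [1.0, 1.0, 1.0], "splay": [0.0, 1.0, 2.0]})
        s = summarize(df, columns=["skew", "splay"])
        assert s.sd["skew"] == 0.0
        assert "skew" in s.constant_columns
        assert np.isnan(s.correlation.loc["skew", "splay"])

    def test_independent_draws_uncorrelated(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame({"skew": rng.normal(2.4, 9.7, 10_000),
                           "splay": rng.normal(-1.0, 9.1, 10_000)})
        s = summarize(df, columns=["skew", "splay"])
        assert abs(s.correlation.loc["skew", "splay"]) < 0.05

    def test_too_few_rows(self):
        with pytest.raises(DegenerateGeometryError):
            summarize(pd.DataFrame({"skew": [1.0]}))
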