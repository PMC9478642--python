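"""Synthetic scene generation: sampling, rendering, projection, corruption."""

import numpy as np
import pytest
from scipy.signal import find_peaks
from scipy.stats import kstest

from filbundle.errors import BoxSizeError, ConfigError
from filbundle.formats import Micrograph
from filbundle.synthgen import (
    CLASS_BUNDLE2,
    CLASS_HIGHER,
    CLASS_SINGLE,
    BundleConfig,
    CTFParams,
    SampleRanges,
    build_decorated_volume,
    compose_scene,
    corrupt,
    ctf_2d,
    emit_dataset,
    make_training_patches,
    place_pair,
    project,
    project_bundle,
    sample_bundle_config,
    view_rotation,
)

from conftest import toy_model


class TestSampling:
    def test_zero_width_ranges_give_constants(self):
        r = SampleRanges(interfilament_distance=(150.0, 150.0), skew=(5.0, 5.0),
                         splay=(-3.0, -3.0), axial_offset=(0.0, 0.0),
                         spin=(10.0, 10.0), view_tilt=(0.0, 0.0),
                         view_psi=(0.0, 0.0), view_shift=(0.0, 0.0),
                         parallel_fraction=1.0)
        c = sample_bundle_config(0, r)
        assert c.interfilament_distance == 150.0
        assert c.skew == 5.0 and c.splay == -3.0
        assert c.polarity == "parallel"

    def test_uniformity_of_distance_draws(self):
        rng = np.random.default_rng(123)
        draws = np.array([sample_bundle_config(rng).interfilament_distance
                          for _ in range(10_000)])
        assert draws.mean() == pytest.approx(150.0, abs=1.0)
        assert kstest(draws, "uniform", args=(120.0, 60.0)).pvalue > 0.01

    def test_seed_determinism(self):
        a = [sample_bundle_config(np.random.default_rng(9)) for _ in range(1)]
        b = [sample_bundle_config(np.random.default_rng(9)) for _ in range(1)]
        assert a == b

    def test_invalid_range_rejected(self):
        with pytest.raises(ConfigError, match="min"):
            SampleRanges(skew=(10.0, -10.0))


class TestPlacePair:
    def test_parallel_ideal(self):
        pa, pb = place_pair(BundleConfig(interfilament_distance=150.0))
        np.testing.assert_allclose(pa.direction, [0, 0, 1], atol=1e-12)
        np.testing.assert_allclose(pb.direction, [0, 0, 1], atol=1e-12)
        np.testing.assert_allclose(pb.origin, [150, 0, 0], atol=1e-12)

    def test_antiparallel_ideal_flips_direction(self):
        _, pb = place_pair(BundleConfig(polarity="antiparallel"))
        np.testing.assert_allclose(pb.direction, [0, 0, -1], atol=1e-12)


class TestVolumeRendering:
    def test_single_atom_gaussian_integral(self):
        one = toy_model(np.zeros((1, 3)))
        vol = build_decorated_volume(one, n_protomers=1, voxel_size=4.4,
                                     resolution=12.0)
        integral = vol.data.sum() * vol.voxel_size ** 3
        assert integral == pytest.approx(1.0, rel=0.01)
        # peak at the box center
        idx = np.unravel_index(np.argmax(vol.data), vol.shape)
        assert idx == tuple((np.array(vol.shape) - 1) // 2)

    def test_density_additivity_with_protomers(self, protomer):
        v1 = build_decorated_volume(protomer, n_protomers=1, voxel_size=4.4, box=41)
        v2 = build_decorated_volume(protomer, n_protomers=2, voxel_size=4.4, box=41)
        assert v2.data.sum() == pytest.approx(2 * v1.data.sum(), rel=1e-3)

    def test_axial_autocorrelation_peaks_at_rise(self, protomer):
        vol = build_decorated_volume(protomer, n_protomers=13, voxel_size=2.75,
                                     resolution=8.0)
        prof = vol.data.sum(axis=(1, 2)).astype(float)
        prof -= prof.mean()
        ac = np.correlate(prof, prof, mode="full")[len(prof) - 1:]
        peaks, _ = find_peaks(ac)
        rise_vox = 27.5 / 2.75
        # first three peaks at multiples of the rise, within one voxel
        for k, p in enumerate(peaks[:3], start=1):
            assert p == pytest.approx(k * rise_vox, abs=1.0)

    def test_box_too_small_raises(self, protomer):
        with pytest.raises(BoxSizeError):
            build_decorated_volume(protomer, n_protomers=13, voxel_size=4.4, box=20)


class TestProjection:
    def test_intensity_conservation(self, filament_volume):
        box = filament_volume.shape[0] + 20
        mic = project([(filament_volume, None)], None, pixel_size=4.4,
                      box=box, depth=box)
        lhs = mic.data.sum() * 4.4 ** 2
        rhs = filament_volume.data.sum() * 4.4 ** 3
        assert lhs == pytest.approx(rhs, rel=1e-3)

    def test_spherical_gaussian_projects_circular(self):
        g = np.zeros((33, 33, 33), np.float32)
        z, y, x = np.mgrid[:33, :33, :33] - 16.0
        g = np.exp(-(x * x + y * y + z * z) / (2 * 3.0 ** 2)).astype(np.float32)
        from filbundle.formats import VolumeMap

        mic = project([(VolumeMap(g, 2.0), None)], None, pixel_size=2.0,
                      box=33, depth=33)
        assert np.argmax(mic.data) == np.ravel_multi_index((16, 16), (33, 33))
        # circular symmetry: x- and y-profiles through the center agree
        np.testing.assert_allclose(mic.data[16, :], mic.data[:, 16], rtol=1e-4)

    def test_shift_theorem(self, filament_volume):
        m0 = project([(filament_volume, None)], view_rotation(0, 0), 4.4, 128, order=3)
        m1 = project([(filament_volume, None)], view_rotation(0, 0), 4.4, 128,
                     shift=(3.3, -2.7), order=3)

        def centroid(d):
            w = np.clip(d - d.mean(), 0, None)
            ys, xs = np.mgrid[: d.shape[0], : d.shape[1]]
            return (w * xs).sum() / w.sum(), (w * ys).sum() / w.sum()

        c0, c1 = centroid(m0.data), centroid(m1.data)
        assert c1[0] - c0[0] == pytest.approx(3.3, abs=0.05)
        assert c1[1] - c0[1] == pytest.approx(-2.7, abs=0.05)

    def test_top_view_resolves_two_ridges_side_view_merges(self, filament_volume):
        def transverse_peaks(tilt):
            cfg = BundleConfig(interfilament_distance=150.0, view=(tilt, 0, 0, 0))
            mic = project_bundle(filament_volume, cfg, 4.4, 128)
            prof = mic.data.sum(axis=1)  # transverse to the in-plane axes
            prof = prof - prof.mean()
            peaks, _ = find_peaks(prof, height=0.3 * prof.max(), distance=8)
            return len(peaks)

        assert transverse_peaks(0.0) == 2
        assert transverse_peaks(90.0) == 1


class TestCorruption:
    def test_ctf_zero_frequency_is_amplitude_contrast(self):
        ctf = CTFParams(defocus_um=1.5, amplitude_contrast=0.07)
        arr = ctf_2d((64, 64), 4.4, ctf)
        assert arr[0, 0] == pytest.approx(-0.07, abs=1e-12)

    def test_infinite_snr_returns_filtered_image(self):
        rng = np.random.default_rng(0)
        mic = Micrograph(rng.normal(size=(64, 64)).astype(np.float32), 4.4)
        a = corrupt(mic, CTFParams(), snr=np.inf)
        b = corrupt(mic, CTFParams(), snr=np.inf, rng=99)
        np.testing.assert_array_equal(a.data, b.data)

    def test_requested_snr_achieved(self):
        rng = np.random.default_rng(0)
        mic = Micrograph(rng.normal(size=(256, 256)).astype(np.float32), 4.4)
        filt = corrupt(mic, CTFParams(), snr=np.inf)
        noisy = corrupt(mic, CTFParams(), snr=0.5, rng=1)
        noise = noisy.data - filt.data
        assert filt.data.var() / noise.var() == pytest.approx(0.5, rel=0.05)

    def test_invalid_snr(self):
        mic = Micrograph(np.ones((8, 8)), 1.0)
        with pytest.raises(ConfigError):
            corrupt(mic, None, snr=0.0)


class TestComposeScene:
    def test_empty_scene(self):
        mic, truth = compose_scene([], shape=(128, 128), rng=0)
        assert mic.data.sum() == 0
        assert truth.labels.max() == 0
        assert len(truth.picks) == 0

    def test_pick_count_along_bundle(self):
        # one bundle of known length fully inside a large frame
        rng = np.random.default_rng(3)
        cfg = BundleConfig(interfilament_distance=150.0)
        mic, truth = compose_scene([("bundle2", cfg)], shape=(2048, 2048),
                                   rng=rng, length_px=(400.0, 400.0),
                                   pick_step=50.0)
        assert len(truth.picks) == 8
        # picks lie on bundle2-labeled pixels
        for _, row in truth.picks.iterrows():
            assert truth.labels[int(round(row.y)), int(round(row.x))] == CLASS_BUNDLE2

    def test_component_count_and_classes(self):
        from scipy import ndimage

        mic, truth = compose_scene(["single", "single", "bundle2", "higher"],
                                   shape=(1024, 1024), rng=7)
        assert len(truth.objects) == 4
        n_comp = 0
        for cls in (CLASS_SINGLE, CLASS_BUNDLE2, CLASS_HIGHER):
            lab, n = ndimage.label(truth.labels == cls, structure=np.ones((3, 3)))
            n_comp += n
        assert n_comp == 4
        kinds = sorted(o.kind for o in truth.objects)
        assert kinds == ["bundle2", "higher", "single", "single"]


class TestDatasets:
    def test_training_patches_reproducible_and_labeled(self):
        a = make_training_patches(n_patches=4, patch=96, snr=0.5, seed=3)
        b = make_training_patches(n_patches=4, patch=96, snr=0.5, seed=3)
        for (na, ca, la), (nb, cb, lb) in zip(a, b):
            np.testing.assert_array_equal(na, nb)
            np.testing.assert_array_equal(la, lb)
        assert any((lab > 0).any() for _, _, lab in a)

    def test_emit_dataset_deterministic(self, tmp_path):
        m1 = emit_dataset(2, tmp_path / "d1", seed=1, shape=(256, 256))
        m2 = emit_dataset(2, tmp_path / "d2", seed=1, shape=(256, 256))
        assert m1["hash"] == m2["hash"]
        from filbundle import formats

        for stem in ("scene_0000", "scene_0001"):
            a = formats.read_micrograph(tmp_path / "d1" / f"{stem}_noisy.mrc")
            b = formats.read_micrograph(tmp_path / "d2" / f"{stem}_noisy.mrc")
            np.testing.assert_array_equal(a.data, b.data)
        # manifest consistency: every recorded bundle config has its scene
        assert len(m1["scenes"]) == 2
        for scene in m1["scenes"]:
            assert len(scene["bundle_configs"]) <= scene["n_objects_placed"]
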