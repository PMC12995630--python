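"""Scene container invariants and file-format round trips."""

import numpy as np
import pytest

from mdpcnet.scene import (HsiScene, SceneFormatError, SceneValidationError,
                           load_label_png, load_scene, save_label_png,
                           save_scene, scene_summary)

from conftest import random_scene


class TestValidation:
    def test_label_shape_mismatch_rejected(self, rng):
        cube = rng.random((8, 6, 12))
        with pytest.raises(SceneValidationError, match="labels shape"):
            HsiScene(cube=cube, labels=np.zeros((7, 6), dtype=int),
                     class_names=["a"])

    def test_non_finite_cube_rejected_with_pixel_location(self, rng):
        cube = rng.random((4, 4, 3))
        cube[2, 1, 0] = np.nan
        with pytest.raises(SceneValidationError, match=r"row=2, col=1"):
            HsiScene(cube=cube, labels=np.zeros((4, 4), dtype=int),
                     class_names=["a"])

    def test_out_of_range_labels_listed(self, rng):
        cube = rng.random((4, 4, 3))
        labels = np.zeros((4, 4), dtype=int)
        labels[0, 0] = 5
        with pytest.raises(SceneValidationError, match="5"):
            HsiScene(cube=cube, labels=labels, class_names=["a", "b"])

    def test_wavelengths_must_increase(self, rng):
        cube = rng.random((4, 4, 3))
        with pytest.raises(SceneValidationError, match="increasing"):
            HsiScene(cube=cube, labels=np.zeros((4, 4), dtype=int),
                     class_names=["a"], wavelengths_nm=[500.0, 499.0, 600.0])


class TestArchiveRoundTrip:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_round_trip_identity(self, tmp_path, seed):
        scene = random_scene(np.random.default_rng(seed))
        path = save_scene(scene, tmp_path / "scene.npz", format="archive")
        back = load_scene(path)
        np.testing.assert_array_equal(back.cube, scene.cube)
        np.testing.assert_array_equal(back.labels, scene.labels)
        assert back.class_names == scene.class_names
        assert back.class_colors == scene.class_colors

    def test_wavelengths_and_provenance_survive(self, tmp_path, rng):
        scene = random_scene(rng, bands=4)
        scene.wavelengths_nm = [400.0, 500.0, 600.0, 700.0]
        scene.provenance = "unit-test"
        back = load_scene(save_scene(scene, tmp_path / "s.npz"))
        assert back.wavelengths_nm == scene.wavelengths_nm
        assert back.provenance == "unit-test"


class TestEnvi:
    def test_envi_files_exist_and_load(self, tmp_path, rng):
        scene = random_scene(rng)
        hdr = save_scene(scene, tmp_path / "scene", format="envi")
        assert hdr.exists() and hdr.with_suffix(".img").exists()
        back = load_scene(hdr)
        np.testing.assert_allclose(back.cube, scene.cube, rtol=1e-6)
        np.testing.assert_array_equal(back.labels, scene.labels)

    @pytest.mark.parametrize("interleaves", [("bsq", "bil"), ("bsq", "bip")])
    def test_interleave_normalization(self, tmp_path, rng, interleaves):
        scene = random_scene(rng)
        cubes = []
        for il in interleaves:
            p = save_scene(scene, tmp_path / f"scene_{il}", format="envi",
                           interleave=il)
            cubes.append(load_scene(p).cube)
        np.testing.assert_array_equal(cubes[0], cubes[1])

    def test_missing_label_pair_is_format_error(self, tmp_path, rng):
        scene = random_scene(rng)
        hdr = save_scene(scene, tmp_path / "scene", format="envi")
        hdr_gt = tmp_path / "scene_gt.hdr"
        hdr_gt.unlink()
        with pytest.raises(SceneFormatError, match="_gt"):
            load_scene(hdr)

    def test_truncated_raw_is_format_error(self, tmp_path, rng):
        scene = random_scene(rng)
        hdr = save_scene(scene, tmp_path / "scene", format="envi")
        img = hdr.with_suffix(".img")
        img.write_bytes(img.read_bytes()[:-16])
        with pytest.raises(SceneFormatError, match="expected"):
            load_scene(hdr)


class TestGeoTiff:
    def test_geotiff_round_trip(self, tmp_path, rng):
        scene = random_scene(rng)
        path = save_scene(scene, tmp_path / "scene.tif", format="geotiff")
        back = load_scene(path)
        np.testing.assert_allclose(back.cube, scene.cube, rtol=1e-6)
        np.testing.assert_array_equal(back.labels, scene.labels)
        assert back.class_names == scene.class_names


class TestMat:
    def test_classic_mat_container(self, tmp_path, rng):
        from scipy.io import savemat

        scene = random_scene(rng)
        path = tmp_path / "scene.mat"
        savemat(path, {"data": scene.cube, "gt": scene.labels})
        back = load_scene(path)
        np.testing.assert_allclose(back.cube, scene.cube)
        np.testing.assert_array_equal(back.labels, scene.labels)

    def test_hdf5_mat_container(self, tmp_path, rng):
        import h5py

        scene = random_scene(rng)
        path = tmp_path / "scene73.mat"
        with h5py.File(path, "w") as f:  # v7.3-style layout: column-major
            f.create_dataset("cube", data=scene.cube.T)
            f.create_dataset("gt", data=scene.labels.T)
        back = load_scene(path, format_hint="mat")
        np.testing.assert_allclose(back.cube, scene.cube)
        np.testing.assert_array_equal(back.labels, scene.labels)

    def test_explicit_variable_names(self, tmp_path, rng):
        from scipy.io import savemat

        scene = random_scene(rng)
        path = tmp_path / "scene.mat"
        # decoy 3-D array sorts first alphabetically; explicit name overrides
        savemat(path, {"aaa_decoy": rng.random((2, 2, 2)),
                       "cube": scene.cube, "gt": scene.labels})
        back = load_scene(path, cube_var="cube", labels_var="gt")
        np.testing.assert_allclose(back.cube, scene.cube)


class TestSummary:
    def test_all_unlabeled(self, rng):
        scene = HsiScene(cube=rng.random((4, 4, 3)),
                         labels=np.zeros((4, 4), dtype=int),
                         class_names=["a", "b"])
        s = scene_summary(scene)
        assert s.per_class_pixel_counts == [0, 0]
        assert s.n_unlabeled == 16

    def test_exact_counts(self, rng):
        labels = np.repeat([1, 2], 8).reshape(4, 4)
        scene = HsiScene(cube=rng.random((4, 4, 3)), labels=labels,
                         class_names=["a", "b"])
        assert scene_summary(scene).per_class_pixel_counts == [8, 8]

    def test_counts_invariant_under_transposition(self, rng):
        scene = random_scene(rng)
        t = HsiScene(cube=scene.cube.transpose(1, 0, 2),
                     labels=scene.labels.T, class_names=scene.class_names)
        assert (scene_summary(scene).per_class_pixel_counts
                == scene_summary(t).per_class_pixel_counts)

    def test_counts_permute_under_relabeling(self, rng):
        scene = random_scene(rng, n_classes=3)
        perm = {0: 0, 1: 3, 2: 1, 3: 2}
        relabeled = HsiScene(cube=scene.cube,
                             labels=np.vectorize(perm.get)(scene.labels),
                             class_names=scene.class_names)
        orig = scene_summary(scene).per_class_pixel_counts
        new = scene_summary(relabeled).per_class_pixel_counts
        # class value v was relabeled to perm[v], so new class perm[v] count
        # equals the old class v count
        assert new == [orig[1], orig[2], orig[0]]
        assert (scene_summary(scene).n_unlabeled
                == scene_summary(relabeled).n_unlabeled)


class TestLabelPng:
    def test_palette_round_trip(self, tmp_path, rng):
        labels = rng.integers(0, 3, size=(10, 12))
        colors = [(255, 0, 0), (0, 255, 0)]
        path = save_label_png(labels, colors, tmp_path / "m.png")
        np.testing.assert_array_equal(load_label_png(path), labels)

    def test_missing_color_rejected(self, tmp_path):
        labels = np.full((4, 4), 3)
        with pytest.raises(SceneValidationError, match="color"):
            save_label_png(labels, [(1, 2, 3)], tmp_path / "m.png")
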