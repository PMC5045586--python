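"""Landmark alignment, exterior-air removal, coronal slicing and file I/O."""

import numpy as np
import pytest

from nasalmorph.io_alignment import (
    CrossSection,
    DegenerateLandmarksError,
    LandmarkPair,
    MissingMetadataError,
    PreprocessConfig,
    SchemaError,
    SurfaceMesh,
    VolumeMask,
    apply_alignment,
    compute_alignment,
    read_landmarks,
    read_nifti_mask,
    read_section_stack,
    read_transform,
    remove_exterior_air,
    slice_coronal,
    write_landmarks,
    write_nifti_mask,
    write_section_stack,
    write_transform,
)
from nasalmorph.synthetic import SynthParams, make_volume


class TestAlignment:
    def test_already_aligned_pair_gives_identity(self):
        t = compute_alignment(LandmarkPair([0, 0, 0], [0, 60, 0]), 60.0)
        assert np.allclose(t.rotation, np.eye(3))
        assert np.allclose(t.translation, 0)
        assert t.scale == pytest.approx(1.0)

    def test_scaling_translation_example(self):
        lm = LandmarkPair([1, 2, 3], [1, 2, 33])
        t = compute_alignment(lm, 60.0)
        assert t.scale == pytest.approx(2.0)
        assert np.allclose(t.apply_points(lm.ams), [0, 0, 0], atol=1e-9)
        assert np.allclose(t.apply_points(lm.choana), [0, 60, 0], atol=1e-9)

    def test_coincident_landmarks_raise(self):
        with pytest.raises(DegenerateLandmarksError):
            compute_alignment(LandmarkPair([5, 5, 5], [5, 5, 5]), 60.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_postconditions_on_random_pairs(self, seed):
        rng = np.random.default_rng(seed)
        ams, choana = rng.uniform(-100, 100, (2, 3))
        t = compute_alignment(LandmarkPair(ams, choana), 60.0)
        assert np.linalg.norm(t.apply_points(ams)) < 1e-9
        assert np.allclose(t.apply_points(choana), [0, 60, 0], atol=1e-9)
        # similarity: pairwise distance ratios preserved
        pts = rng.uniform(-50, 50, (8, 3))
        out = t.apply_points(pts)
        din = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        dout = np.linalg.norm(out[:, None] - out[None, :], axis=-1)
        iu = np.triu_indices(8, 1)
        assert np.allclose(dout[iu] / din[iu], t.scale, rtol=1e-9)
        # proper rotation (no reflection)
        assert np.linalg.det(t.rotation) == pytest.approx(1.0)

    def test_mesh_transform_scales_edges(self):
        mesh = SurfaceMesh([[0, 0, 0], [3, 0, 0], [0, 4, 0]], [[0, 1, 2]])
        t = compute_alignment(LandmarkPair([0, 0, 0], [0, 30, 0]), 60.0)
        out = apply_alignment(t, mesh)
        e = np.linalg.norm(out.vertices[1] - out.vertices[0])
        assert e == pytest.approx(6.0, abs=1e-9)

    def test_volume_voxel_count_preserved_under_rotation(self):
        # solid cube, rotated 90 degrees about z via landmark choice
        vox = np.zeros((30, 30, 30), bool)
        vox[5:25, 5:25, 5:25] = True
        vol = VolumeMask(vox, (1.0, 1.0, 1.0), origin=[0, 0, 0])
        t = compute_alignment(LandmarkPair([0, 0, 0], [60, 0, 0]), 60.0)  # +x -> +y
        out = apply_alignment(t, vol)
        assert out.voxels.sum() == pytest.approx(vox.sum(), rel=0.02)

    def test_empty_volume_passthrough(self):
        vol = VolumeMask(np.zeros((4, 4, 4), bool), (1, 1, 1))
        t = compute_alignment(LandmarkPair([0, 0, 0], [0, 60, 0]), 60.0)
        assert not apply_alignment(t, vol).voxels.any()


class TestExteriorAir:
    def test_thin_slab_unchanged(self):
        vox = np.zeros((40, 40, 8), bool)
        vox[:, :, 3:5] = True  # 2 mm slab at 1 mm spacing
        vol = VolumeMask(vox, (1, 1, 1))
        out = remove_exterior_air(vol, PreprocessConfig(opening_radius=10))
        assert np.array_equal(out.voxels, vox)

    def test_cube_removed_channel_kept(self):
        vox = np.zeros((60, 80, 60), bool)
        vox[10:50, 5:45, 10:50] = True  # 40 mm cube (exterior air)
        vox[29:31, 45:75, 29:31] = True  # 2 mm channel
        vol = VolumeMask(vox, (1, 1, 1))
        cfg = PreprocessConfig(opening_radius=10, capture_erosion_radius=0)
        out = remove_exterior_air(vol, cfg)
        # opening of the cube by a radius-10 ball: erosion then dilation
        from scipy import ndimage

        d_in = ndimage.distance_transform_edt(vox)
        eroded = d_in > 10
        d_out = ndimage.distance_transform_edt(~eroded)
        opened = eroded | (d_out <= 10)
        expected = vox & ~opened
        assert np.array_equal(out.voxels, expected)
        assert out.voxels[30, 50, 30]  # channel survives
        assert not out.voxels[30, 25, 30]  # cube interior removed

    def test_idempotent_and_anti_extensive(self):
        rng = np.random.default_rng(4)
        vox = np.zeros((40, 40, 40), bool)
        rr, cc, ss = np.mgrid[:40, :40, :40]
        for _ in range(4):
            c = rng.uniform(8, 32, 3)
            rad = rng.uniform(3, 12)
            vox |= (rr - c[0]) ** 2 + (cc - c[1]) ** 2 + (ss - c[2]) ** 2 <= rad**2
        vol = VolumeMask(vox, (1, 1, 1))
        cfg = PreprocessConfig(opening_radius=6, capture_erosion_radius=1)
        once = remove_exterior_air(vol, cfg)
        twice = remove_exterior_air(once, cfg)
        assert np.array_equal(once.voxels, twice.voxels)
        assert not (once.voxels & ~vox).any()


class TestSlicing:
    def test_box_mesh_slice_matches_analytic_rectangle(self):
        import trimesh

        box = trimesh.creation.box(extents=[20.0, 30.0, 10.0])
        mesh = SurfaceMesh(np.array(box.vertices), np.array(box.faces))
        (sec,) = slice_coronal(mesh, [0.0], pixel_spacing=0.5)
        area = sec.area_mm2()
        assert area == pytest.approx(20.0 * 10.0, rel=0.05)
        xz = sec.pixel_to_xz(np.argwhere(sec.mask))
        assert xz[:, 0].min() == pytest.approx(-10.0, abs=0.6)
        assert xz[:, 0].max() == pytest.approx(10.0, abs=0.6)

    def test_plane_outside_mesh_is_empty(self):
        import trimesh

        box = trimesh.creation.box(extents=[10, 10, 10])
        mesh = SurfaceMesh(np.array(box.vertices), np.array(box.faces))
        (sec,) = slice_coronal(mesh, [40.0])
        assert not sec.mask.any()

    def test_volume_slicing_reproduces_generator_sections(self):
        params = SynthParams(y_positions=(28.0, 30.0, 32.0))
        vol, _ = make_volume(params, y_spacing=1.0)
        from nasalmorph.synthetic import make_section
        from nasalmorph.metrics import jaccard

        secs = slice_coronal(
            vol, [30.0], pixel_spacing=params.pixel_spacing, extent=params.extent
        )
        truth_sec, _ = make_section(params, 30.0)
        assert jaccard(secs[0].mask, truth_sec.mask) >= 0.99


class TestIO:
    def test_section_stack_roundtrip_bitwise(self, tmp_path, base_section):
        sec, _ = base_section
        stack = [sec, CrossSection(~sec.mask, sec.pixel_spacing, 31.0, sec.extent)]
        write_section_stack(tmp_path / "s", stack)
        back = read_section_stack(tmp_path / "s")
        assert len(back) == 2
        for a, b in zip(stack, back):
            assert np.array_equal(a.mask, b.mask)
            assert a.pixel_spacing == b.pixel_spacing
            assert a.y_position == b.y_position
            assert a.extent == b.extent

    def test_tiff_stack_roundtrip(self, tmp_path, base_section):
        sec, _ = base_section
        write_section_stack(tmp_path / "t", [sec], fmt="tiff")
        (back,) = read_section_stack(tmp_path / "t")
        assert np.array_equal(back.mask, sec.mask)

    def test_missing_sidecar_is_an_error(self, tmp_path):
        (tmp_path / "broken").mkdir()
        with pytest.raises(MissingMetadataError):
            read_section_stack(tmp_path / "broken")

    def test_landmark_schema_error(self, tmp_path):
        p = tmp_path / "lm.json"
        p.write_text('{"ams": [0, 0, 0]}')
        with pytest.raises(SchemaError):
            read_landmarks(p)

    def test_landmark_and_transform_roundtrip(self, tmp_path):
        lm = LandmarkPair([1.5, -2.0, 3.25], [4.0, 5.5, -6.0])
        write_landmarks(tmp_path / "lm.json", lm)
        back = read_landmarks(tmp_path / "lm.json")
        assert np.array_equal(back.ams, lm.ams) and np.array_equal(back.choana, lm.choana)
        t = compute_alignment(lm, 60.0)
        write_transform(tmp_path / "t.json", t)
        t2 = read_transform(tmp_path / "t.json")
        assert np.array_equal(t2.rotation, t.rotation)
        assert t2.scale == t.scale

    def test_nifti_roundtrip_preserves_anisotropic_spacing(self, tmp_path):
        vox = np.zeros((8, 9, 10), bool)
        vox[2:5, 3:6, 4:7] = True
        vol = VolumeMask(vox, (0.43, 0.6, 0.43), origin=[1.0, 2.0, 3.0])
        write_nifti_mask(tmp_path / "v.nii.gz", vol)
        back = read_nifti_mask(tmp_path / "v.nii.gz")
        assert np.array_equal(back.voxels, vox)
        assert back.spacing == pytest.approx(vol.spacing)
        assert np.allclose(back.origin, vol.origin)
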