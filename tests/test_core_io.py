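import numpy as np
import pytest

from embryoheart.core_io import (
    DisplacementField,
    FieldSeries,
    Image4D,
    MotionModel,
    Region,
    Waveform,
    check_manifold,
    fourier_basis,
    read_displacement_field,
    read_field_series,
    read_image4d,
    read_motion_model,
    read_surface,
    read_waveform,
    write_displacement_field,
    write_field_series,
    write_image4d,
    write_motion_model,
    write_surface,
    write_waveform,
)


def _image(rng, n_frames=4, shape=(6, 7, 8)):
    data = rng.uniform(0, 200, size=(n_frames, *shape))
    return Image4D(
        data=data, spacing=(0.03, 0.04, 0.05), origin=(1.0, 2.0, 3.0), frame_interval=0.06
    )


class TestImage4D:
    def test_cycle_duration_and_times(self, rng):
        img = _image(rng)
        assert img.cycle_duration == pytest.approx(4 * 0.06)
        assert np.allclose(img.frame_times, [0, 0.06, 0.12, 0.18])

    def test_rejects_too_few_frames(self, rng):
        with pytest.raises(ValueError, match="frames"):
            _image(rng, n_frames=2)

    def test_rejects_bad_spacing(self, rng):
        with pytest.raises(ValueError, match="spacing"):
            Image4D(
                data=rng.uniform(size=(3, 4, 4, 4)),
                spacing=(0.0, 0.03, 0.03),
                origin=(0, 0, 0),
                frame_interval=0.05,
            )

    @pytest.mark.parametrize("suffix", [".nii.gz", ".tif", ".nrrd"])
    def test_roundtrip(self, rng, tmp_path, suffix):
        img = _image(rng)
        p = tmp_path / f"img{suffix}"
        write_image4d(img, p)
        back = read_image4d(p)
        assert np.allclose(back.data, img.data)
        assert np.allclose(back.spacing, img.spacing)
        assert back.frame_interval == pytest.approx(img.frame_interval)

    def test_tiff_requires_sidecar(self, rng, tmp_path):
        img = _image(rng)
        p = tmp_path / "img.tif"
        write_image4d(img, p)
        p.with_suffix(p.suffix + ".json").unlink()
        with pytest.raises(ValueError, match="sidecar"):
            read_image4d(p)


class TestSurface:
    def test_manifold_check_rejects_open_mesh(self, icosphere_surface):
        faces = icosphere_surface.faces[:-5]
        with pytest.raises(ValueError):
            check_manifold(icosphere_surface.vertices0, faces)

    def test_manifold_check_rejects_flipped_face(self, icosphere_surface):
        faces = icosphere_surface.faces.copy()
        faces[0] = faces[0][::-1]
        with pytest.raises(ValueError):
            check_manifold(icosphere_surface.vertices0, faces)

    @pytest.mark.parametrize("suffix", [".ply", ".stl", ".vtk"])
    def test_roundtrip(self, icosphere_surface, tmp_path, suffix):
        p = tmp_path / f"s{suffix}"
        write_surface(icosphere_surface, p)
        back = read_surface(p)
        assert back.n_faces == icosphere_surface.n_faces
        # vertex order may change (STL); compare enclosed volume instead
        import trimesh

        v0 = trimesh.Trimesh(
            icosphere_surface.vertices0, icosphere_surface.faces, process=False
        ).volume
        v1 = trimesh.Trimesh(back.vertices0, back.faces, process=False).volume
        assert v1 == pytest.approx(v0, rel=1e-6)

    def test_vtk_preserves_region_labels(self, icosphere_surface, tmp_path):
        labels = np.full(icosphere_surface.n_faces, int(Region.RV))
        labels[: icosphere_surface.n_faces // 2] = int(Region.LV)
        surf = icosphere_surface.with_labels(labels)
        p = tmp_path / "s.vtk"
        write_surface(surf, p)
        back = read_surface(p)
        assert np.array_equal(back.labels, labels)

    def test_vertex_labels_majority(self, icosphere_surface):
        labels = np.full(icosphere_surface.n_faces, int(Region.RV))
        surf = icosphere_surface.with_labels(labels)
        assert np.all(surf.vertex_labels() == int(Region.RV))


class TestDisplacementField:
    def test_roundtrip(self, rng, tmp_path):
        f = DisplacementField(
            vectors=rng.normal(size=(5, 6, 7, 3)),
            spacing=(0.03, 0.03, 0.03),
            origin=(0.1, 0.2, 0.3),
            from_frame=0,
            to_frame=3,
        )
        p = tmp_path / "d.vtk"
        write_displacement_field(f, p)
        back = read_displacement_field(p, from_frame=0, to_frame=3)
        assert np.allclose(back.vectors, f.vectors, atol=1e-6)
        assert np.allclose(back.spacing, f.spacing)
        assert np.allclose(back.origin, f.origin)


class TestFieldSeries:
    def test_wss_roundtrip(self, rng, tmp_path):
        t = np.arange(4) * 0.1
        s = FieldSeries(kind="wss", frame_times=t, samples=rng.normal(size=(4, 30, 3)))
        write_field_series(s, tmp_path / "wss")
        back = read_field_series(tmp_path / "wss")
        assert back.kind == "wss"
        assert np.allclose(back.samples, s.samples, atol=1e-6)
        assert np.allclose(back.frame_times, t)

    def test_velocity_roundtrip_with_lumen(self, rng, tmp_path):
        t = np.arange(3) * 0.1
        masks = rng.uniform(size=(3, 4, 5, 6)) > 0.5
        s = FieldSeries(
            kind="velocity",
            frame_times=t,
            samples=rng.normal(size=(3, 4, 5, 6, 3)),
            spacing=(0.05, 0.05, 0.05),
            origin=(0, 0, 0),
            lumen_masks=masks,
        )
        write_field_series(s, tmp_path / "vel")
        back = read_field_series(tmp_path / "vel")
        assert np.allclose(back.samples, s.samples, atol=1e-6)
        assert np.array_equal(back.lumen_masks, masks)

    def test_rejects_nonincreasing_times(self, rng):
        with pytest.raises(ValueError):
            FieldSeries(
                kind="wss",
                frame_times=np.array([0.0, 0.0, 0.1]),
                samples=rng.normal(size=(3, 5, 3)),
            )


class TestWaveform:
    def test_roundtrip(self, tmp_path):
        wf = Waveform(times=np.arange(5) * 0.1, values=np.sin(np.arange(5.0)), kind="volume")
        p = tmp_path / "w.csv"
        write_waveform(wf, p)
        back = read_waveform(p)
        assert np.allclose(back.times, wf.times)
        assert np.allclose(back.values, wf.values)

    def test_missing_header_rejected(self, tmp_path):
        p = tmp_path / "w.csv"
        p.write_text("a,b\n0,1\n")
        with pytest.raises(ValueError):
            read_waveform(p)

    def test_rejects_nonmonotone_times(self):
        with pytest.raises(ValueError):
            Waveform(times=np.array([0.0, 0.2, 0.1]), values=np.zeros(3))


class TestMotionModel:
    def test_roundtrip(self, rng, tmp_path):
        m = MotionModel(
            coeffs=rng.normal(size=(5, 3, 6, 6, 6)),
            grid_origin=(0.0, 0.1, 0.2),
            grid_spacing=0.1,
            cycle_duration=0.48,
        )
        p = tmp_path / "m.npz"
        write_motion_model(m, p)
        back = read_motion_model(p)
        assert np.allclose(back.coeffs, m.coeffs)
        assert back.cycle_duration == pytest.approx(0.48)
        pts = np.array([[0.3, 0.35, 0.4]])
        assert np.allclose(back.displacement(pts, 0.1), m.displacement(pts, 0.1))

    def test_periodicity(self, rng):
        m = MotionModel(
            coeffs=rng.normal(size=(3, 3, 6, 6, 6)),
            grid_origin=(0.0, 0.0, 0.0),
            grid_spacing=0.1,
            cycle_duration=0.5,
        )
        pts = np.array([[0.25, 0.25, 0.25]])
        assert np.allclose(m.displacement(pts, 0.1), m.displacement(pts, 0.6), atol=1e-12)

    def test_outside_support_errors(self, rng):
        m = MotionModel(
            coeffs=rng.normal(size=(3, 3, 6, 6, 6)),
            grid_origin=(0.0, 0.0, 0.0),
            grid_spacing=0.1,
            cycle_duration=0.5,
        )
        with pytest.raises(ValueError):
            m.displacement(np.array([[5.0, 5.0, 5.0]]), 0.0)


def test_fourier_basis_shape_and_values():
    t = np.array([0.0, 0.125, 0.25])
    B = fourier_basis(t, 2, 0.5)
    assert B.shape == (3, 5)
    assert np.allclose(B[:, 0], 1.0)
    assert np.allclose(B[0], [1, 1, 0, 1, 0])
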