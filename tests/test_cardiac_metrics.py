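import numpy as np
import pytest
import trimesh

from embryoheart.cardiac_metrics import (
    area_stretch,
    mesh_volume,
    stretch_rate,
    stroke_and_ef,
    structure_report,
    volume_waveform,
)
from embryoheart.core_io import Region, TrackedSurface


def _tracked_scaling(base: trimesh.Trimesh, scales, labels=None):
    v = np.asarray(base.vertices, dtype=float)
    pos = np.stack([v * s for s in scales])
    return TrackedSurface(
        vertices0=pos[0],
        faces=np.asarray(base.faces),
        positions=pos,
        frame_times=np.arange(len(scales)) * 0.1,
        labels=labels,
    )


class TestMeshVolume:
    def test_unit_cube(self):
        box = trimesh.creation.box(extents=(1, 1, 1))
        s = TrackedSurface(vertices0=np.asarray(box.vertices), faces=np.asarray(box.faces))
        assert mesh_volume(s) == pytest.approx(1.0)

    def test_icosphere_close_to_closed_form(self):
        ico = trimesh.creation.icosphere(subdivisions=4)
        s = TrackedSurface(vertices0=np.asarray(ico.vertices), faces=np.asarray(ico.faces))
        assert mesh_volume(s) == pytest.approx(4 / 3 * np.pi, rel=5e-3)

    def test_orientation_independent(self):
        box = trimesh.creation.box(extents=(1, 1, 1))
        faces = np.asarray(box.faces)[:, ::-1]  # flip all normals inward
        s = TrackedSurface(vertices0=np.asarray(box.vertices), faces=faces)
        assert mesh_volume(s) == pytest.approx(1.0)

    def test_labelled_partition_is_additive(self):
        ico = trimesh.creation.icosphere(subdivisions=3)
        fc = np.asarray(ico.triangles_center)
        labels = np.where(fc[:, 2] >= 0, int(Region.RV), int(Region.LV))
        s = TrackedSurface(
            vertices0=np.asarray(ico.vertices), faces=np.asarray(ico.faces), labels=labels
        )
        whole = mesh_volume(s)
        parts = mesh_volume(s, structure=Region.RV) + mesh_volume(s, structure=Region.LV)
        assert parts == pytest.approx(whole, rel=1e-12)

    def test_three_way_partition_additive(self):
        ico = trimesh.creation.icosphere(subdivisions=3)
        fc = np.asarray(ico.triangles_center)
        labels = np.full(len(fc), int(Region.RA))
        labels[fc[:, 2] > 0.3] = int(Region.RV)
        labels[fc[:, 2] < -0.3] = int(Region.LV)
        s = TrackedSurface(
            vertices0=np.asarray(ico.vertices), faces=np.asarray(ico.faces), labels=labels
        )
        total = sum(
            mesh_volume(s, structure=r) for r in (Region.RA, Region.RV, Region.LV)
        )
        assert total == pytest.approx(mesh_volume(s), rel=1e-12)

    def test_absent_label_rejected(self):
        ico = trimesh.creation.icosphere(subdivisions=2)
        s = TrackedSurface(vertices0=np.asarray(ico.vertices), faces=np.asarray(ico.faces))
        with pytest.raises(ValueError, match="absent"):
            mesh_volume(s, structure=Region.AVJ)


class TestStrokeAndEF:
    def test_contracting_sphere(self):
        ico = trimesh.creation.icosphere(subdivisions=3)
        alpha = 0.25
        scales = 1 - alpha * (1 - np.cos(2 * np.pi * np.arange(16) / 16)) / 2
        s = _tracked_scaling(ico, scales)
        vol = volume_waveform(s)
        sv, ef = stroke_and_ef(vol)
        assert ef == pytest.approx(1 - (1 - alpha) ** 3, rel=1e-9)

    def test_constant_volume_warns(self):
        ico = trimesh.creation.icosphere(subdivisions=2)
        s = _tracked_scaling(ico, [1.0, 1.0, 1.0])
        with pytest.warns(UserWarning, match="constant"):
            sv, ef = stroke_and_ef(volume_waveform(s))
        assert sv == 0.0 and ef == 0.0


class TestAreaStretch:
    def test_uniform_scaling_gives_square(self):
        ico = trimesh.creation.icosphere(subdivisions=3)
        s = _tracked_scaling(ico, [1.0, 1.2])
        f = area_stretch(s, reference="frame0")
        assert np.allclose(f.values[1], 1.44, atol=1e-12)

    def test_matches_svd_oracle(self, rng):
        # area ratio of the per-triangle affine map equals lambda1*lambda2 of
        # its in-plane deformation gradient (SVD of the 3x2 edge map)
        ico = trimesh.creation.icosphere(subdivisions=2)
        A = np.eye(3) + 0.1 * rng.normal(size=(3, 3))
        v0 = np.asarray(ico.vertices)
        s = TrackedSurface(
            vertices0=v0,
            faces=np.asarray(ico.faces),
            positions=np.stack([v0, v0 @ A.T]),
            frame_times=np.array([0.0, 0.1]),
        )
        f = area_stretch(s, reference="frame0")
        tri0 = v0[s.faces]
        tri1 = (v0 @ A.T)[s.faces]
        for k in range(len(s.faces)):
            E0 = np.stack([tri0[k, 1] - tri0[k, 0], tri0[k, 2] - tri0[k, 0]], axis=1)
            E1 = np.stack([tri1[k, 1] - tri1[k, 0], tri1[k, 2] - tri1[k, 0]], axis=1)
            # orthonormal bases of the two triangle planes
            q0, _ = np.linalg.qr(E0)
            q1, _ = np.linalg.qr(E1)
            F = (q1.T @ E1) @ np.linalg.inv(q0.T @ E0)  # in-plane 2x2 gradient
            lam = np.linalg.svd(F, compute_uv=False)
            assert f.values[1, k] == pytest.approx(lam[0] * lam[1], abs=1e-10)

    def test_per_face_max_reference_bounds(self):
        ico = trimesh.creation.icosphere(subdivisions=2)
        s = _tracked_scaling(ico, [1.0, 0.8, 0.9])
        f = area_stretch(s)  # per-face-max default
        assert np.all(f.values <= 1.0 + 1e-12)
        assert np.allclose(f.values.max(axis=0), 1.0)

    def test_unknown_reference_rejected(self):
        ico = trimesh.creation.icosphere(subdivisions=1)
        s = _tracked_scaling(ico, [1.0, 0.9])
        with pytest.raises(ValueError):
            area_stretch(s, reference="nope")


class TestStretchRate:
    def test_sinusoidal_rate(self):
        ico = trimesh.creation.icosphere(subdivisions=2)
        nt, T = 32, 0.5
        t = np.arange(nt) * T / nt
        scales = 1 + 0.05 * np.sin(2 * np.pi * t / T)
        s = _tracked_scaling(ico, scales)
        s.frame_times = t
        f = area_stretch(s, reference="frame0")
        r = stretch_rate(f, t)
        # d(s^2)/dt = 2 s s'; centred difference converges to it
        expected = np.gradient(scales**2, t, edge_order=2)
        assert np.allclose(r.mean(axis=1)[2:-2], expected[2:-2], rtol=0.05)


class TestStructureReport:
    def test_volume_and_sv_fractions(self):
        ico = trimesh.creation.icosphere(subdivisions=3)
        fc = np.asarray(ico.triangles_center)
        labels = np.where(fc[:, 2] >= 0, int(Region.RAA), int(Region.RA))
        s = _tracked_scaling(ico, [1.0, 0.9, 0.8, 0.9], labels=labels)
        rep = structure_report(s, parents={Region.RAA: (Region.RAA, Region.RA)})
        raa = rep.structures["RAA"]
        whole_max = mesh_volume(s, 0)
        assert raa["volume_fraction_of_parent"] == pytest.approx(
            raa["max_volume_mm3"] / whole_max, rel=1e-9
        )
        assert 0 < raa["stroke_volume_fraction_of_parent"] < 1.5

    def test_end_diastolic_frame_is_argmax(self):
        ico = trimesh.creation.icosphere(subdivisions=2)
        s = _tracked_scaling(ico, [0.9, 1.0, 0.8])
        rep = structure_report(s)
        (metrics,) = rep.structures.values()
        assert metrics["end_diastolic_frame"] == 1

    def test_unknown_parent_label_rejected(self):
        ico = trimesh.creation.icosphere(subdivisions=2)
        s = _tracked_scaling(ico, [1.0, 0.9])
        with pytest.raises(ValueError, match="absent"):
            structure_report(s, parents={Region.NONE: Region.LV})
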