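import numpy as np
import pytest
from scipy import ndimage

from embryoheart.core_io import DisplacementField
from embryoheart.registration import (
    RegistrationConfig,
    bending_energy,
    compose_chain,
    compose_displacements,
    invert_displacement,
    register_pair,
)


def _blob(shape, center, radius, amplitude=100.0):
    g = np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
    r2 = sum((gi - ci) ** 2 for gi, ci in zip(g, center))
    return amplitude * np.exp(-r2 / (2 * radius**2))


class TestBendingEnergy:
    def test_zero_for_affine_field(self, rng):
        g = np.meshgrid(*[np.arange(12, dtype=float)] * 3, indexing="ij")
        A = rng.normal(size=(3, 3))
        u = np.stack([sum(A[c, i] * g[i] for i in range(3)) for c in range(3)], axis=-1)
        be, _ = bending_energy(u, with_gradient=True)
        # second derivatives of an affine field vanish (interior; boundary
        # kernel truncation contributes only at the faces)
        assert be == pytest.approx(0.0, abs=1e-18)

    def test_positive_for_curved_field(self, rng):
        u = rng.normal(size=(10, 10, 10, 3))
        be = bending_energy(u)
        assert be > 0

    def test_gradient_matches_finite_differences(self, rng):
        u = 0.1 * rng.normal(size=(7, 7, 7, 3))
        be, grad = bending_energy(u, with_gradient=True)
        eps = 1e-6
        for idx in [(3, 3, 3, 0), (2, 4, 1, 1), (5, 2, 6, 2)]:
            up = u.copy()
            up[idx] += eps
            um = u.copy()
            um[idx] -= eps
            fd = (bending_energy(up) - bending_energy(um)) / (2 * eps)
            assert grad[idx] == pytest.approx(fd, rel=1e-4, abs=1e-8)


def _register_translation(metric, shift=(1.2, 0.0, -0.8)):
    shape = (24, 24, 24)
    fixed = _blob(shape, (12, 12, 12), 4.0) + _blob(shape, (7, 16, 10), 2.5, 60.0)
    coords = np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
    moving = ndimage.map_coordinates(
        fixed, [c - s for c, s in zip(coords, shift)], order=3, mode="nearest"
    )
    spacing = (0.05, 0.05, 0.05)
    cfg = RegistrationConfig(
        grid_spacing=0.4, metric=metric, pyramid_levels=1, max_iterations=120
    )
    fld, info = register_pair(fixed, moving, cfg, spacing, (0.0, 0.0, 0.0))
    return fld, info, np.asarray(shift) * np.asarray(spacing), fixed


class TestRegisterPair:
    def test_identity_gives_near_zero_field(self):
        shape = (20, 20, 20)
        img = _blob(shape, (10, 10, 10), 4.0)
        cfg = RegistrationConfig(grid_spacing=0.4, pyramid_levels=1, max_iterations=40)
        fld, info = register_pair(img, img, cfg, (0.05,) * 3, (0, 0, 0))
        assert np.max(np.abs(fld.vectors)) < 0.05 * 0.05  # < 0.05 voxels

    def test_recovers_translation_inside_object(self):
        fld, info, true_mm, fixed = _register_translation("ssd")
        inside = fixed > 30.0
        err = np.linalg.norm(fld.vectors[inside] - true_mm, axis=-1)
        assert err.mean() < 0.3 * 0.05  # mean EPE < 0.3 voxels

    def test_mutual_information_discriminates_across_intensity_remap(self):
        # MI must prefer the true alignment even when the moving image has a
        # nonlinearly remapped (inverted) contrast, where SSD prefers misalignment
        from embryoheart.registration import _neg_mutual_information, _ssd

        shape = (24, 24, 24)
        fixed = _blob(shape, (12, 12, 12), 4.0) + _blob(shape, (7, 16, 10), 2.5, 60.0)
        coords = np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
        shift = (1.2, 0.0, -0.8)
        shifted = ndimage.map_coordinates(
            fixed, [c - s for c, s in zip(coords, shift)], order=3, mode="nearest"
        )
        moving = 160.0 - shifted
        lo = min(fixed.min(), moving.min())
        hi = max(fixed.max(), moving.max())
        f = (fixed - lo) / (hi - lo)
        m = (moving - lo) / (hi - lo)
        aligned = ndimage.map_coordinates(
            m, [c + s for c, s in zip(coords, shift)], order=3, mode="nearest"
        )
        mi_id, _ = _neg_mutual_information(m, f, 32)
        mi_tr, _ = _neg_mutual_information(aligned, f, 32)
        assert mi_tr < mi_id  # true alignment has higher MI
        assert _ssd(aligned, f)[0] > _ssd(m, f)[0]  # while SSD prefers misalignment

    def test_mutual_information_gradient_matches_finite_differences(self, rng):
        from embryoheart.registration import _neg_mutual_information

        f = rng.uniform(0.1, 0.9, size=(10, 10, 10))
        m = np.clip(f + 0.05 * rng.normal(size=f.shape), 0.05, 0.95)
        _, grad = _neg_mutual_information(m, f, 16)
        eps = 1e-5
        for idx in [(5, 5, 5), (2, 7, 4), (8, 1, 6)]:
            mp = m.copy()
            mp[idx] += eps
            mm = m.copy()
            mm[idx] -= eps
            fd = (
                _neg_mutual_information(mp, f, 16)[0]
                - _neg_mutual_information(mm, f, 16)[0]
            ) / (2 * eps)
            assert grad[idx] == pytest.approx(fd, rel=5e-2, abs=1e-7)

    def test_objective_decreases_within_each_level(self):
        fld, info, _, _ = _register_translation("ssd")
        for hist in info["objective_history"]:
            diffs = np.diff(hist)
            assert np.all(diffs <= 1e-12)

    def test_more_regularization_never_increases_bending(self):
        # smaller rho = relatively heavier bending term = smoother field
        shape = (20, 20, 20)
        fixed = _blob(shape, (10, 10, 10), 4.0)
        rng = np.random.default_rng(3)
        moving = fixed + 5.0 * rng.normal(size=shape)
        bes = []
        for rho in (1.0, 0.1, 0.01):
            cfg = RegistrationConfig(
                grid_spacing=0.3, rho=rho, pyramid_levels=1, max_iterations=60
            )
            _, info = register_pair(fixed, moving, cfg, (0.05,) * 3, (0, 0, 0))
            bes.append(info["bending_energy"])
        assert bes[1] <= bes[0] + 1e-12
        assert bes[2] <= bes[1] + 1e-12

    def test_rejects_unknown_metric(self):
        with pytest.raises(ValueError):
            RegistrationConfig(metric="nope")


def _affine_field(scale, shape, spacing, from_frame, to_frame):
    g = np.meshgrid(*[np.arange(s, dtype=float) * spacing for s in shape], indexing="ij")
    c = (np.asarray(shape) - 1) * spacing / 2
    u = np.stack([(scale - 1) * (g[i] - c[i]) for i in range(3)], axis=-1)
    return DisplacementField(
        vectors=u, spacing=(spacing,) * 3, origin=(0, 0, 0),
        from_frame=from_frame, to_frame=to_frame,
    )


class TestComposition:
    def test_compose_two_scalings_is_product(self):
        shape, sp = (16, 16, 16), 0.05
        f1 = _affine_field(0.9, shape, sp, 0, 1)
        f2 = _affine_field(0.95, shape, sp, 1, 2)
        comp = compose_displacements([f1, f2], target_frame=2)
        truth = _affine_field(0.9 * 0.95, shape, sp, 0, 2)
        # interior comparison (edge voxels clamp in trilinear sampling)
        s = (slice(3, -3),) * 3
        assert np.allclose(comp.vectors[s], truth.vectors[s], atol=1e-10)

    def test_invert_displacement_roundtrip(self):
        shape, sp = (16, 16, 16), 0.05
        f = _affine_field(0.9, shape, sp, 0, 1)
        finv = invert_displacement(f)
        assert finv.from_frame == 1 and finv.to_frame == 0
        ident = compose_displacements(
            [f, DisplacementField(vectors=finv.vectors, spacing=f.spacing,
                                  origin=f.origin, from_frame=1, to_frame=2)],
            target_frame=2,
        )
        s = (slice(3, -3),) * 3
        assert np.max(np.abs(ident.vectors[s])) < 1e-8

    def test_cyclic_chain_matches_truth(self):
        # ring of per-step scalings around a cycle; composed fields must match
        # the analytic cumulative scaling whichever way around they are built
        shape, sp, n = (16, 16, 16), 0.05, 6
        scales = np.array([0.95, 0.9, 1.02, 1.05, 1.1, 1.0])
        cum = np.cumprod(scales)
        assert cum[-1] == pytest.approx(0.95 * 0.9 * 1.02 * 1.05 * 1.1)
        pairs = [_affine_field(scales[i], shape, sp, i, i + 1) for i in range(n - 1)]
        # closing pair maps frame n-1 back to frame 0: scale 1/cum[n-2]
        pairs.append(_affine_field(1.0 / cum[n - 2], shape, sp, n - 1, 0))
        chain = compose_chain(pairs)
        s = (slice(4, -4),) * 3
        for f in chain:
            truth = _affine_field(cum[f.to_frame - 1], shape, sp, 0, f.to_frame)
            assert np.allclose(f.vectors[s], truth.vectors[s], atol=1e-6), f.to_frame

    def test_open_chain_still_supported(self):
        shape, sp, n = (12, 12, 12), 0.05, 4
        pairs = [_affine_field(0.98, shape, sp, i, i + 1) for i in range(n - 1)]
        chain = compose_chain(pairs)
        assert [f.to_frame for f in chain] == [1, 2, 3]

    def test_gap_in_chain_rejected(self):
        shape, sp = (12, 12, 12), 0.05
        pairs = [_affine_field(0.98, shape, sp, 0, 1), _affine_field(0.98, shape, sp, 2, 3)]
        with pytest.raises(ValueError, match="gap"):
            compose_chain(pairs)
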