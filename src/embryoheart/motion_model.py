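"""Fit the cyclic Fourier/B-spline motion model and track the endocardial surface.

The displacement of a material point with reference position x is modelled as

    u(x, t) = a0(x) + sum_{k=1..K} [ a_k(x) cos(2 pi k t / T) + b_k(x) sin(2 pi k t / T) ]

with every coefficient field a tensor-product cubic B-spline on a regular
lattice (default knot spacing 0.1 mm).  Given frame-0-referenced displacement
fields d_j(x) from registration, the coefficients minimise

    sum_j sum_x || u(x, t_j) - d_j(x) ||^2 .

With samples fixed at the voxel grid the problem is linear and separable: a
shared (2K+1)-column temporal regression per voxel, followed by an
independent spatial B-spline least-squares fit per Fourier component and
vector component.  The outer loop re-evaluates residuals until the relative
coefficient change falls below ``tol``; in the default ("eulerian") mode the
first pass is already the exact linear solution.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage

from ._bspline import BSplineLattice, basis_matrix_1d, fit_separable
from .core_io import DisplacementField, MotionModel, TrackedSurface, fourier_basis

__all__ = ["fit_motion_model", "evaluate_motion", "track_surface"]


def _stack_fields(fields, n_frames):
    """Assemble (n_frames, nx, ny, nz, 3) data, inserting a zero frame-0 field."""
    by_frame = {}
    ref = None
    for f in fields:
        if not isinstance(f, DisplacementField):
            raise TypeError("fields must be DisplacementField instances")
        if ref is None:
            ref = f
        elif not f.same_grid(ref):
            raise ValueError("all displacement fields must share one grid geometry")
        by_frame[f.to_frame] = f
    missing = [j for j in range(1, n_frames) if j not in by_frame]
    if missing:
        raise ValueError(f"missing frame-0-referenced field(s) for frame(s) {missing}")
    data = np.zeros((n_frames,) + ref.grid_shape + (3,))
    for j, f in by_frame.items():
        data[j] = f.vectors
    return data, ref


def fit_motion_model(
    fields,
    cycle_duration: float,
    n_frames: int | None = None,
    grid_spacing: float = 0.1,
    n_harmonics: int | None = None,
    tol: float = 1e-6,
    max_iter: int = 20,
    sample_mode: str = "eulerian",
) -> tuple[MotionModel, dict]:
    """Fit the cyclic motion model to frame-0-referenced displacement fields.

    Parameters
    ----------
    fields
        DisplacementFields with ``to_frame`` in 1..n_frames-1 (frame 0 is the
        implicit zero field), all on one voxel grid, frame times
        t_j = j * T / n_frames.
    cycle_duration
        Cardiac period T in seconds.
    grid_spacing
        B-spline lattice knot spacing in mm (default 0.1).
    n_harmonics
        Fourier harmonic count K; default min(5, (n_frames - 1) // 2).
    sample_mode
        "eulerian" (default): fields are functions of the reference position.
        "tracked": the input samples are pulled back through the current
        model between outer iterations (flagged alternative reading).

    Returns
    -------
    (MotionModel, info) with info["residual_rms"] the per-iteration fit RMS
    (mm), monotonically non-increasing.
    """
    fields = list(fields)
    if n_frames is None:
        n_frames = max(f.to_frame for f in fields) + 1
    data, ref = _stack_fields(fields, n_frames)
    times = np.arange(n_frames) * (cycle_duration / n_frames)
    if n_harmonics is None:
        n_harmonics = min(5, (n_frames - 1) // 2)
    n_basis = 2 * n_harmonics + 1
    if n_frames < n_basis:
        raise ValueError(
            f"under-determined fit: {n_frames} frames cannot constrain K={n_harmonics} "
            f"harmonics (need at least {n_basis})"
        )
    phi = fourier_basis(times, n_harmonics, cycle_duration)  # (n_frames, 2K+1)
    if np.linalg.matrix_rank(phi) < n_basis:
        raise ValueError("singular temporal design; reduce the harmonic count")
    phi_pinv = np.linalg.pinv(phi)

    ax = tuple(ref.origin[i] + np.arange(ref.grid_shape[i]) * ref.spacing[i] for i in range(3))
    lo = np.asarray([a[0] for a in ax])
    hi = np.asarray([a[-1] for a in ax])
    lat = BSplineLattice.covering(lo, hi, grid_spacing)
    Bs = [basis_matrix_1d(u, lat.shape[i]) for i, u in enumerate(lat.axis_coordinates(ax))]
    for i, B in enumerate(Bs):
        # lattice-edge coefficients are always weakly supported (handled by the
        # minimum-norm pseudo-inverse); an *interior* coefficient with no
        # supporting sample means the lattice is finer than the data
        zero_cols = ~np.any(B != 0.0, axis=0)
        if np.any(zero_cols[1:-1]):
            raise ValueError(
                f"singular normal equations along axis {i}: lattice spacing "
                f"{grid_spacing} mm leaves interior coefficients unsupported; "
                "use a larger grid spacing"
            )

    def fit_once(samples):
        tc = np.einsum("bf,f...->b...", phi_pinv, samples)  # (2K+1, nx, ny, nz, 3)
        coeffs = np.empty((n_basis, 3) + lat.shape)
        for j in range(n_basis):
            for comp in range(3):
                coeffs[j, comp] = fit_separable(tc[..., comp][j], *Bs)
        return coeffs

    samples = data
    coeffs = None
    residuals = []
    for it in range(max_iter):
        new_coeffs = fit_once(samples)
        # dense prediction: (2K+1, 3, nx, ny, nz) -> per frame via phi
        dense = np.einsum("ax,jcxyz->jcayz", Bs[0], new_coeffs)
        dense = np.einsum("by,jcayz->jcabz", Bs[1], dense)
        dense = np.einsum("dz,jcabz->jcabd", Bs[2], dense)
        pred = np.einsum("fb,bcxyz->fxyzc", phi, dense)
        resid = float(np.sqrt(np.mean(np.sum((pred - data) ** 2, axis=-1))))
        if residuals and resid > residuals[-1] + 1e-15:
            # keep the best-so-far model; the alternating scheme should not diverge
            residuals.append(residuals[-1])
            break
        residuals.append(resid)
        if coeffs is not None:
            denom = max(np.max(np.abs(coeffs)), 1e-300)
            if np.max(np.abs(new_coeffs - coeffs)) / denom < tol:
                coeffs = new_coeffs
                break
        coeffs = new_coeffs
        if sample_mode == "eulerian":
            break
        elif sample_mode == "tracked":
            # pull the input samples back through the current model
            samples = np.empty_like(data)
            model = MotionModel(
                coeffs=coeffs,
                grid_origin=lat.origin,
                grid_spacing=lat.spacing,
                cycle_duration=cycle_duration,
            )
            X = np.meshgrid(*ax, indexing="ij")
            pts = np.stack([g.ravel() for g in X], axis=1)
            for j, t in enumerate(times):
                u = model.displacement(pts, float(t)).reshape(data.shape[1:4] + (3,))
                idx = [
                    (X[i] - u[..., i] - ref.origin[i]) / ref.spacing[i] for i in range(3)
                ]
                for comp in range(3):
                    samples[j, ..., comp] = ndimage.map_coordinates(
                        data[j, ..., comp], idx, order=1, mode="nearest"
                    )
        else:
            raise ValueError(f"unknown sample_mode {sample_mode!r}")

    model = MotionModel(
        coeffs=coeffs,
        grid_origin=lat.origin,
        grid_spacing=lat.spacing,
        cycle_duration=cycle_duration,
    )
    return model, {"residual_rms": residuals, "n_harmonics": n_harmonics}


def evaluate_motion(model: MotionModel, points: np.ndarray, t: float) -> np.ndarray:
    """Displacement u(points, t) in mm; T-periodic, errors on points outside support."""
    return model.displacement(points, t)


def track_surface(
    surface: TrackedSurface,
    model: MotionModel,
    frame_times: np.ndarray,
    check_self_intersection: bool = False,
) -> TrackedSurface:
    """Propagate a single-frame segmentation through the cycle.

    positions[j] = vertices0 + u(vertices0, t_j) - u(vertices0, 0): subtracting
    the model's own t=0 value anchors frame 0 exactly to the input segmentation.
    Connectivity and labels are unchanged.
    """
    frame_times = np.asarray(frame_times, dtype=float)
    v0 = surface.vertices0
    u0 = model.displacement(v0, 0.0)
    positions = np.empty((len(frame_times), len(v0), 3))
    for j, t in enumerate(frame_times):
        positions[j] = v0 + model.displacement(v0, float(t)) - u0
    tracked = TrackedSurface(
        vertices0=v0,
        faces=surface.faces,
        positions=positions,
        labels=surface.labels,
        frame_times=frame_times,
    )
    if check_self_intersection:
        import trimesh

        for j in range(tracked.n_frames):
            m = trimesh.Trimesh(positions[j], surface.faces, process=False)
            if getattr(m, "is_self_intersecting", False):
                warnings.warn(f"tracked surface self-intersects at frame {j}", stacklevel=2)
    return tracked
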