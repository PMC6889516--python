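"""Synthetic beating-heart phantoms: images, ground-truth motion, analytic flow.

The default phantom is an ellipsoidal blood-filled chamber inside a tissue
shell, contracting radially about its centre with a prescribed cyclic scale

    s(t) = 1 - alpha * (1 - cos(2 pi t / T)) / 2            ("contraction")

so the reference frame (t = 0) is end-diastole, s ranges over [1-alpha, 1]
and the chamber's ejection fraction is exactly 1 - (1-alpha)^3.  A symmetric
mode s(t) = 1 + alpha * sin(2 pi t / T) is available as "sin".  Because the
motion is affine in space it is represented *exactly* by the cubic-B-spline
Fourier motion model, which makes the phantom a closed-form oracle for the
whole tracking pipeline.

Additional generators provide analytic flow fields that stand in for an
external Navier-Stokes solver: an oscillatory Poiseuille tube (closed-form
wall shear 4*mu*Q/(pi R^3)) and a channel with a sheltered side-branch
"appendage", the minimal geometry in which appendage particle retention and
oscillatory shear contrasts emerge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._bspline import BSplineLattice
from .core_io import FieldSeries, Image4D, MotionModel, Region, Waveform

__all__ = [
    "PhantomSpec",
    "make_ground_truth_motion",
    "render_image_series",
    "make_analytic_flow",
    "poiseuille_tube_flow",
    "channel_with_appendage_flow",
]


@dataclass
class PhantomSpec:
    """Parameters of the contracting-ellipsoid phantom.

    Geometry is in mm, time in s, intensities in arbitrary ultrasound-like
    units.  Defaults emulate an HH25-scale chick heart chamber (~1.5 mm organ,
    0.48 s cycle) imaged on an isotropic grid.
    """

    semi_axes: tuple[float, float, float] = (0.55, 0.45, 0.4)  # mm
    wall_thickness: float = 0.12  # mm
    alpha: float = 0.25  # contraction amplitude, fraction of linear size
    cycle_duration: float = 0.48  # s
    n_frames: int = 16
    motion_mode: str = "contraction"  # or "sin"
    blood_mean: float = 140.0
    blood_sd: float = 8.0
    tissue_mean: float = 60.0
    tissue_sd: float = 8.0
    background_mean: float = 10.0
    noise_seed: int = 0
    grid_shape: tuple[int, int, int] = (48, 48, 48)
    spacing: float = 0.03  # mm, isotropic
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha < 1.0:
            raise ValueError("contraction amplitude alpha must be in [0, 1)")
        if self.motion_mode not in ("contraction", "sin"):
            raise ValueError(f"unknown motion mode {self.motion_mode!r}")
        if self.blood_mean == self.tissue_mean:
            raise ValueError("blood and tissue intensity means must differ")
        if np.any(np.asarray(self.semi_axes) <= 0) or self.wall_thickness < 0:
            raise ValueError("geometry must be positive")

    @property
    def center(self) -> np.ndarray:
        return np.asarray(self.origin) + (np.asarray(self.grid_shape) - 1) * self.spacing / 2.0

    @property
    def frame_interval(self) -> float:
        return self.cycle_duration / self.n_frames

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval

    def scale(self, t) -> np.ndarray:
        """Prescribed cyclic linear scale factor s(t)."""
        t = np.asarray(t, dtype=float)
        w = 2.0 * np.pi * t / self.cycle_duration
        if self.motion_mode == "contraction":
            return 1.0 - self.alpha * (1.0 - np.cos(w)) / 2.0
        return 1.0 + self.alpha * np.sin(w)

    def scale_rate(self, t) -> np.ndarray:
        """ds/dt."""
        t = np.asarray(t, dtype=float)
        w0 = 2.0 * np.pi / self.cycle_duration
        if self.motion_mode == "contraction":
            return -self.alpha * w0 * np.sin(w0 * t) / 2.0
        return self.alpha * w0 * np.cos(w0 * t)

    def lumen_volume(self, t) -> np.ndarray:
        """Analytic chamber volume (4/3) pi a b c s(t)^3, mm^3."""
        a, b, c = self.semi_axes
        return 4.0 / 3.0 * np.pi * a * b * c * self.scale(t) ** 3

    def cross_section_area(self, t, axis: int = 2) -> np.ndarray:
        """Analytic area of the mid-plane cross section normal to ``axis``, mm^2."""
        ax = [a for i, a in enumerate(self.semi_axes) if i != axis]
        return np.pi * ax[0] * ax[1] * self.scale(t) ** 2

    def ejection_fraction(self) -> float:
        s = self.scale(np.linspace(0, self.cycle_duration, 512, endpoint=False))
        vmax, vmin = np.max(s) ** 3, np.min(s) ** 3
        return float(1.0 - vmin / vmax)

    def voxel_centers(self):
        ax = [self.origin[i] + np.arange(self.grid_shape[i]) * self.spacing for i in range(3)]
        return ax


def make_ground_truth_motion(spec: PhantomSpec, grid_spacing: float = 0.1) -> MotionModel:
    """Exact motion-model representation of the phantom's prescribed motion.

    The displacement u(x, t) = (s(t) - 1) (x - c) is affine in x, so the
    cubic-B-spline coefficient fields reproduce it to machine precision; the
    temporal dependence is a single Fourier harmonic in either mode.
    """
    c = spec.center
    T = spec.cycle_duration
    ax = spec.voxel_centers()
    lo, hi = np.asarray([a[0] for a in ax]), np.asarray([a[-1] for a in ax])
    lat = BSplineLattice.covering(lo, hi, grid_spacing)

    # temporal coefficients of (s(t) - 1): [const, cos, sin]
    if spec.motion_mode == "contraction":
        tcoef = np.array([-spec.alpha / 2.0, spec.alpha / 2.0, 0.0])
    else:
        tcoef = np.array([0.0, 0.0, spec.alpha])

    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    rel = np.stack([X - c[0], Y - c[1], Z - c[2]], axis=0)  # (3, nx, ny, nz)
    coeffs = np.zeros((3, 3) + lat.shape)  # (temporal, component, lattice)
    for j in range(3):
        if tcoef[j] == 0.0:
            continue
        for comp in range(3):
            coeffs[j, comp] = lat.fit_gridded(tcoef[j] * rel[comp], tuple(ax))
    return MotionModel(
        coeffs=coeffs,
        grid_origin=lat.origin,
        grid_spacing=lat.spacing,
        cycle_duration=T,
    )


def _ellipsoid_level(ax_pts, center, semi_axes, s: float) -> np.ndarray:
    X, Y, Z = np.meshgrid(*ax_pts, indexing="ij")
    a, b, c = (np.asarray(semi_axes) * s)
    return (
        ((X - center[0]) / a) ** 2 + ((Y - center[1]) / b) ** 2 + ((Z - center[2]) / c) ** 2
    )


def render_image_series(spec: PhantomSpec, motion: MotionModel | None = None) -> Image4D:
    """Rasterize the tissue shell and blood lumen per frame with Gaussian noise.

    Rendering uses the phantom's analytic shapes (lumen: scaled ellipsoid,
    tissue: shell of constant ``wall_thickness`` outside it).  If a motion
    model is given it is checked for consistency: the deformed outer wall must
    stay inside the image grid at every frame.
    """
    ax = spec.voxel_centers()
    c = spec.center
    lo = np.asarray([a[0] for a in ax])
    hi = np.asarray([a[-1] for a in ax])
    outer = np.asarray(spec.semi_axes) * np.max(spec.scale(spec.frame_times)) + spec.wall_thickness
    if np.any(c - outer < lo - 1e-9) or np.any(c + outer > hi + 1e-9):
        raise ValueError("phantom motion carries the wall outside the image grid")
    if motion is not None and abs(motion.cycle_duration - spec.cycle_duration) > 1e-12:
        raise ValueError("motion model cycle duration disagrees with the phantom spec")

    rng = np.random.default_rng(spec.noise_seed)
    frames = np.empty((spec.n_frames,) + tuple(spec.grid_shape))
    for j, t in enumerate(spec.frame_times):
        s = float(spec.scale(t))
        lum = _ellipsoid_level(ax, c, spec.semi_axes, s) <= 1.0
        outer_axes = np.asarray(spec.semi_axes) * s + spec.wall_thickness
        shell = (_ellipsoid_level(ax, c, outer_axes, 1.0) <= 1.0) & ~lum
        img = np.full(spec.grid_shape, spec.background_mean)
        img[shell] = spec.tissue_mean
        img[lum] = spec.blood_mean
        noise = rng.standard_normal(spec.grid_shape)
        img = img + noise * np.where(lum, spec.blood_sd, np.where(shell, spec.tissue_sd, 0.0))
        frames[j] = img
    return Image4D(
        data=frames,
        spacing=np.full(3, spec.spacing),
        origin=np.asarray(spec.origin, dtype=float),
        frame_interval=spec.frame_interval,
        spans_cycle=True,
    )


def lumen_masks(spec: PhantomSpec) -> np.ndarray:
    """Analytic blood-pool mask per frame (voxel centre inside the scaled ellipsoid)."""
    ax = spec.voxel_centers()
    masks = np.empty((spec.n_frames,) + tuple(spec.grid_shape), dtype=bool)
    for j, t in enumerate(spec.frame_times):
        masks[j] = _ellipsoid_level(ax, spec.center, spec.semi_axes, float(spec.scale(t))) <= 1.0
    return masks


def make_analytic_flow(
    spec: PhantomSpec,
    motion: MotionModel | None = None,
    outlet_radius: float = 0.1,
    outlet_area: float | None = None,
    mu: float = 0.0015,
) -> tuple[FieldSeries, FieldSeries, Waveform]:
    """Wall-consistent analytic flow for the contracting chamber.

    Inside the lumen the velocity is the motion's own expansion field
    v(x,t) = (ds/dt / s) (x - c), whose flux through the wall equals dV/dt
    exactly, so the volumetric outflow rate is Q(t) = -dV/dt.  The outlet is
    an idealized Poiseuille tube of radius ``outlet_radius`` carrying Q(t):
    its wall shear is 4 mu Q / (pi R^3) and the Doppler trace is the
    parabolic-profile centreline velocity 2 Q / (pi R^2).

    Returns (velocity series on the image grid, WSS series on the outlet-tube
    wall nodes, outlet Doppler waveform).
    """
    times = spec.frame_times
    ax = spec.voxel_centers()
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    c = spec.center
    masks = lumen_masks(spec)
    vel = np.zeros((spec.n_frames,) + tuple(spec.grid_shape) + (3,))
    for j, t in enumerate(times):
        beta = float(spec.scale_rate(t) / spec.scale(t))  # 1/s
        for comp, G in enumerate((X, Y, Z)):
            vel[j, ..., comp] = np.where(masks[j], beta * (G - c[comp]), 0.0)
    velocity = FieldSeries(
        kind="velocity",
        frame_times=times,
        samples=vel,
        spacing=np.full(3, spec.spacing),
        origin=np.asarray(spec.origin, dtype=float),
        lumen_masks=masks,
    )

    # exact analytic rate: V(t) = V0 s^3 => dV/dt = 3 V(t) s'/s
    q_out = -3.0 * spec.lumen_volume(times) * spec.scale_rate(times) / spec.scale(times)
    R = outlet_radius
    area = np.pi * R**2 if outlet_area is None else outlet_area
    wss_mag = 4.0 * mu * q_out / (np.pi * R**3)  # Pa.s * (mm^3/s)/mm^3 = Pa
    # a ring of wall nodes around the outlet tube; shear is axial
    n_nodes = 32
    wss = np.zeros((spec.n_frames, n_nodes, 3))
    wss[..., 0] = wss_mag[:, None]
    wss_series = FieldSeries(kind="wss", frame_times=times, samples=wss)
    doppler = Waveform(times=times, values=2.0 * q_out / area, kind="doppler")
    return velocity, wss_series, doppler


# ---------------------------------------------------------------------------
# stand-alone analytic flow benches
# ---------------------------------------------------------------------------


def poiseuille_tube_flow(
    radius: float,
    length: float,
    flow_rate,
    mu: float = 0.0015,
    n_grid: int = 24,
    n_frames: int = 8,
    cycle_duration: float = 0.48,
    n_wall_nodes: int = 64,
):
    """Oscillatory Poiseuille flow in a tube along x; closed-form oracle bench.

    ``flow_rate`` is a scalar Q (mm^3/s) or a callable Q(t).  The velocity
    profile is v_x(r, t) = 2 Q(t) / (pi R^2) * (1 - r^2/R^2); the wall shear
    stress magnitude is computed from the profile derivative mu * |dv/dr| at
    r = R by one-sided finite difference (the closed form is 4 mu Q/(pi R^3);
    units mm/s / mm * Pa.s = mPa, converted to Pa).

    Returns (velocity FieldSeries, wss FieldSeries on tube-wall nodes,
    centreline Doppler Waveform, wall TrackedSurface-compatible node array).
    """
    times = np.arange(n_frames) * cycle_duration / n_frames
    Q = np.asarray([flow_rate(t) if callable(flow_rate) else flow_rate for t in times], float)
    h = 2.2 * radius / (n_grid - 1)
    ys = np.linspace(-1.1 * radius, 1.1 * radius, n_grid)
    xs = np.linspace(0.0, length, max(4, int(length / h) + 1))
    X, Y, Z = np.meshgrid(xs, ys, ys, indexing="ij")
    r2 = Y**2 + Z**2
    inside = r2 <= radius**2
    vel = np.zeros((n_frames,) + X.shape + (3,))
    for j in range(n_frames):
        vpk = 2.0 * Q[j] / (np.pi * radius**2)
        vel[j, ..., 0] = np.where(inside, vpk * (1.0 - r2 / radius**2), 0.0)
    velocity = FieldSeries(
        kind="velocity",
        frame_times=times,
        samples=vel,
        spacing=np.array([xs[1] - xs[0], ys[1] - ys[0], ys[1] - ys[0]]),
        origin=np.array([xs[0], ys[0], ys[0]]),
        lumen_masks=np.broadcast_to(inside, (n_frames,) + inside.shape).copy(),
    )

    # wall shear from the prescribed profile by one-sided finite difference at r = R
    eps = 1e-6 * radius
    wss_nodes = np.zeros((n_frames, n_wall_nodes, 3))
    theta = np.linspace(0, 2 * np.pi, n_wall_nodes, endpoint=False)
    for j in range(n_frames):
        vpk = 2.0 * Q[j] / (np.pi * radius**2)

        def prof(r):
            return vpk * (1.0 - r**2 / radius**2)

        dvdr = (prof(radius) - prof(radius - eps)) / eps  # (mm/s)/mm = 1/s
        tau_pa = mu * dvdr  # Pa.s * 1/s = Pa (mm cancels)
        wss_nodes[j, :, 0] = -tau_pa  # traction on the wall opposes dv/dr sign
    wall_nodes = np.stack(
        [np.full(n_wall_nodes, length / 2), radius * np.cos(theta), radius * np.sin(theta)], axis=1
    )
    wss = FieldSeries(kind="wss", frame_times=times, samples=wss_nodes)
    doppler = Waveform(times=times, values=2.0 * Q / (np.pi * radius**2), kind="doppler")
    return velocity, wss, doppler, wall_nodes


def channel_with_appendage_flow(
    n_frames: int = 20,
    cycle_duration: float = 0.48,
    grid_shape: tuple[int, int, int] = (48, 24, 24),
    spacing: float = 0.05,
    mean_speed: float = 4.0,  # mm/s along the channel
    oscillation: float = 4.0,  # mm/s oscillatory component
    appendage_oscillation: float = 1.0,  # mm/s zero-mean sloshing in the branch
):
    """A straight channel with a sheltered side-branch "appendage".

    The main channel (labelled RV) carries pulsatile through-flow with a
    positive mean, so tracers wash out; the blind side branch (labelled RAA)
    only sees a zero-mean oscillation, so tracers slosh in place — the
    minimal geometry reproducing the appendage-retention contrast.

    Returns (velocity FieldSeries with lumen masks, structure label volume,
    outlet mask) where the label volume assigns Region values per voxel.
    """
    nx, ny, nz = grid_shape
    times = np.arange(n_frames) * cycle_duration / n_frames
    ax = [np.arange(n) * spacing for n in grid_shape]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    Lx, Ly, Lz = [(n - 1) * spacing for n in grid_shape]

    # main channel: a slab 0.15 Lz < z < 0.5 Lz spanning all x, middle in y
    chan = (Z > 0.15 * Lz) & (Z < 0.5 * Lz) & (Y > 0.2 * Ly) & (Y < 0.8 * Ly)
    # appendage: blind pocket branching upward (z) from the channel mid-length
    app = (
        (Z >= 0.5 * Lz)
        & (Z < 0.9 * Lz)
        & (np.abs(X - 0.5 * Lx) < 0.12 * Lx)
        & (Y > 0.35 * Ly)
        & (Y < 0.65 * Ly)
    )
    lumen = chan | app

    labels = np.zeros(grid_shape, dtype=np.int32)
    labels[chan] = int(Region.RV)
    labels[app] = int(Region.RAA)
    outlet = chan & (X >= Lx - 1.5 * spacing)

    vel = np.zeros((n_frames,) + grid_shape + (3,))
    depth = np.clip((0.9 * Lz - Z) / (0.4 * Lz), 0.0, 1.0)  # 1 at branch mouth, 0 at apex
    for j, t in enumerate(times):
        w = 2.0 * np.pi * t / cycle_duration
        u_chan = mean_speed + oscillation * np.sin(w)
        vel[j, ..., 0] = np.where(chan, u_chan, 0.0)
        # zero-mean sloshing along z inside the appendage, dying out to the apex
        vel[j, ..., 2] = np.where(app, appendage_oscillation * np.sin(w) * depth, 0.0)
    velocity = FieldSeries(
        kind="velocity",
        frame_times=times,
        samples=vel,
        spacing=np.full(3, spacing),
        origin=np.zeros(3),
        lumen_masks=np.broadcast_to(lumen, (n_frames,) + grid_shape).copy(),
    )
    return velocity, labels, outlet
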