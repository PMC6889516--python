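"""Blood-pool threshold segmentation, surface extraction, and the
velocity-matched threshold search.

The initial segmentation is a plain intensity threshold (largest connected
component, interior holes filled).  Because the segmented boundary — and
hence every downstream volume and velocity — depends strongly on the chosen
threshold, the threshold is selected by a physiological criterion: for each
candidate, the frame-0 surface is extracted, tracked through the cycle with
the motion model, and the atrioventricular-junction velocity implied by
ventricular volume conservation is compared against a reference waveform;
the candidate minimising the normalised RMS error wins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh
from scipy import ndimage
from skimage import measure

from .core_io import Image4D, MotionModel, TrackedSurface, Waveform

__all__ = [
    "ThresholdSearchResult",
    "threshold_segment",
    "extract_surface",
    "av_junction_velocity",
    "optimize_threshold",
    "nrmse",
    "cross_section_area",
]


def threshold_segment(
    frame: np.ndarray, threshold: float, blood_bright: bool = True
) -> np.ndarray:
    """Binary blood-pool mask: threshold, keep largest component, fill holes.

    ``blood_bright`` selects the intensity polarity (contrast-enhanced scans
    make blood bright; phantoms may differ).
    """
    frame = np.asarray(frame)
    mask = frame >= threshold if blood_bright else frame <= threshold
    if not mask.any():
        raise ValueError(f"threshold {threshold} produces an empty blood mask")
    lab, n = ndimage.label(mask)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
        mask = lab == (1 + int(np.argmax(sizes)))
    return ndimage.binary_fill_holes(mask)


def extract_surface(
    mask: np.ndarray,
    spacing,
    origin=(0.0, 0.0, 0.0),
    smooth_iterations: int = 0,
    smooth_lambda: float = 0.5,
) -> TrackedSurface:
    """Closed manifold triangle mesh of the mask boundary, in physical mm.

    Marching cubes runs on the zero-padded binary volume so the surface is
    always closed; optional Laplacian smoothing regularises the staircase
    boundary (0 iterations leaves vertices untouched).
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("cannot extract a surface from an empty mask")
    spacing = np.asarray(spacing, dtype=float).reshape(3)
    origin = np.asarray(origin, dtype=float).reshape(3)
    padded = np.pad(mask, 1).astype(float)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5)
    verts = (verts - 1.0) * spacing + origin  # undo pad, to physical mm
    mesh = trimesh.Trimesh(verts, faces, process=True, validate=True)
    if smooth_iterations > 0:
        trimesh.smoothing.filter_laplacian(
            mesh, lamb=smooth_lambda, iterations=smooth_iterations, volume_constraint=True
        )
    # marching cubes on a padded volume yields closed surfaces; orientation:
    # make normals outward (positive enclosed volume)
    if mesh.volume < 0:
        mesh.invert()
    surf = TrackedSurface(vertices0=np.asarray(mesh.vertices), faces=np.asarray(mesh.faces))
    surf.validate()
    return surf


# ---------------------------------------------------------------------------
# junction velocity from volume conservation
# ---------------------------------------------------------------------------


def _cycle_derivative(values: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Centred finite difference with periodic wrap over one half-open cycle."""
    dt = np.diff(times)
    period = times[-1] - times[0] + dt[-1]
    ext_t = np.concatenate([[times[0] - dt[-1]], times, [times[0] + period]])
    ext_v = np.concatenate([[values[-1]], values, [values[0]]])
    return (ext_v[2:] - ext_v[:-2]) / (ext_t[2:] - ext_t[:-2])


def av_junction_velocity(
    ventricle_volume: Waveform,
    outlet_doppler: Waveform,
    junction_area: Waveform,
    outlet_area: float,
) -> Waveform:
    """Peak AV-junction velocity implied by ventricular volume conservation.

    Volume conservation of the ventricle gives the junction inflow rate
    Q_j(t) = dV/dt + Q_out(t); the Doppler trace is converted to a flow rate
    under an idealized parabolic profile (mean = peak / 2), and the junction
    peak velocity uses the same parabolic factor: v_peak = 2 Q_j(t) / A(t).
    """
    if len(ventricle_volume) != len(junction_area) or not np.allclose(
        ventricle_volume.times, junction_area.times
    ):
        raise ValueError("volume and junction-area waveforms must share a time base")
    A = junction_area.values
    if np.any(A <= 0):
        raise ValueError("junction cross-section area must be positive everywhere")
    dvdt = _cycle_derivative(ventricle_volume.values, ventricle_volume.times)
    q_out = 0.5 * outlet_doppler.values * outlet_area  # mm^3/s, parabolic factor
    if len(outlet_doppler) != len(ventricle_volume):
        raise ValueError("Doppler and volume waveforms must share a time base")
    q_j = dvdt + q_out
    return Waveform(times=ventricle_volume.times, values=2.0 * q_j / A, kind="velocity")


def nrmse(computed: Waveform, reference: Waveform, align_phase: bool = True) -> float:
    """Range-normalised RMS error after optional cyclic phase alignment.

    The reference waveform has its own time origin, so the computed waveform
    is circularly shifted to the lag maximising cross-correlation before
    comparison; the error is normalised by the reference's peak-to-peak range.
    """
    a = np.asarray(computed.values, dtype=float)
    b = np.asarray(reference.values, dtype=float)
    if a.shape != b.shape:
        raise ValueError("waveforms must have equal length for NRMSE")
    rng = b.max() - b.min()
    if rng == 0:
        rng = np.abs(b).max() or 1.0
    if align_phase and len(a) > 1:
        ac = a - a.mean()
        bc = b - b.mean()
        xc = np.array([np.dot(np.roll(ac, s), bc) for s in range(len(a))])
        a = np.roll(a, int(np.argmax(xc)))
    return float(np.sqrt(np.mean((a - b) ** 2)) / rng)


def cross_section_area(surface: TrackedSurface, frame: int, plane_origin, plane_normal) -> float:
    """Area of the mesh cross-section cut by a plane, mm^2."""
    mesh = surface.to_trimesh(frame)
    sec = mesh.section(plane_origin=np.asarray(plane_origin), plane_normal=np.asarray(plane_normal))
    if sec is None:
        raise ValueError(f"plane misses the surface at frame {frame}")
    planar, _ = sec.to_2D()
    return float(planar.area)


# ---------------------------------------------------------------------------
# threshold optimization
# ---------------------------------------------------------------------------


@dataclass
class ThresholdSearchResult:
    thresholds: np.ndarray
    nrmse: np.ndarray
    selected_threshold: float
    junction_velocity: Waveform  # at the optimum
    volume_waveform: Waveform  # at the optimum

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        self.nrmse = np.asarray(self.nrmse, dtype=float)


@dataclass
class ThresholdPipelineConfig:
    """Everything the per-candidate pipeline needs besides the image."""

    motion_model: MotionModel
    junction_plane_origin: tuple[float, float, float]
    junction_plane_normal: tuple[float, float, float]
    outlet_doppler: Waveform
    outlet_area: float  # mm^2
    blood_bright: bool = True
    smooth_iterations: int = 0


def optimize_threshold(
    image: Image4D,
    thresholds,
    reference: Waveform,
    cfg: ThresholdPipelineConfig,
) -> ThresholdSearchResult:
    """Velocity-matched threshold search.

    For each candidate threshold: segment frame 0, extract the surface, track
    it with the motion model, build the volume waveform and the implied
    AV-junction velocity, and score it against the reference by NRMSE.
    Returns the argmin candidate; deterministic given image and config.
    """
    from .cardiac_metrics import volume_waveform

    thresholds = np.atleast_1d(np.asarray(thresholds, dtype=float))
    if len(thresholds) < 1:
        raise ValueError("need at least one candidate threshold")
    times = image.frame_times
    errors = np.full(len(thresholds), np.nan)
    best = None
    n_failed = 0
    for i, thr in enumerate(thresholds):
        try:
            mask = threshold_segment(image.frame(0), thr, blood_bright=cfg.blood_bright)
            surf = extract_surface(
                mask, image.spacing, image.origin, smooth_iterations=cfg.smooth_iterations
            )
            from .motion_model import track_surface

            tracked = track_surface(surf, cfg.motion_model, times)
            vol = volume_waveform(tracked)
            area = Waveform(
                times=times,
                values=np.array(
                    [
                        cross_section_area(
                            tracked, j, cfg.junction_plane_origin, cfg.junction_plane_normal
                        )
                        for j in range(len(times))
                    ]
                ),
                kind="area",
            )
            vel = av_junction_velocity(vol, cfg.outlet_doppler, area, cfg.outlet_area)
            errors[i] = nrmse(vel, reference)
        except ValueError:
            n_failed += 1
            continue
        if best is None or errors[i] < best[1]:
            best = (thr, errors[i], vel, vol)
    if best is None:
        raise ValueError("segmentation failed for every candidate threshold")
    return ThresholdSearchResult(
        thresholds=thresholds,
        nrmse=errors,
        selected_threshold=float(best[0]),
        junction_velocity=best[2],
        volume_waveform=best[3],
    )
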