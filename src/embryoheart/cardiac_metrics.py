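"""Volumes, stroke volume, ejection fraction, per-structure partitioning and
deformational area stretch from the tracked endocardial surface.

Volumes use the divergence theorem (signed tetrahedra to the origin); a
labelled sub-structure is closed by fanning its boundary loops to the loop
centroid, so a partition of the closed surface has exactly additive volumes
(the shared caps cancel pairwise).  Area stretch is the per-triangle ratio of
current to reference area, which equals the determinant of the in-plane 2D
deformation gradient of the (affine) per-triangle map.  Following the
convention used for embryonic wall-deformation maps, the default stretch
reference is each face's own maximally stretched state over the cycle, so
stretch <= 1 with 1 meaning "no contractile stretch"; the frame-0 reference
remains available for model validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core_io import Region, TrackedSurface, Waveform

__all__ = [
    "StructureReport",
    "StretchField",
    "mesh_volume",
    "volume_waveform",
    "stroke_and_ef",
    "area_stretch",
    "stretch_rate",
    "structure_report",
]


# ---------------------------------------------------------------------------
# volumes
# ---------------------------------------------------------------------------


def _signed_volume(vertices: np.ndarray, faces: np.ndarray) -> float:
    p = vertices[faces]
    return float(np.einsum("ij,ij->", p[:, 0], np.cross(p[:, 1], p[:, 2]))) / 6.0


def _boundary_loops(faces: np.ndarray) -> list[np.ndarray]:
    """Ordered vertex loops of the boundary of an oriented face subset."""
    edges = np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    seen = {}
    for a, b in edges.tolist():
        key = (min(a, b), max(a, b))
        seen[key] = seen.get(key, 0) + 1
    boundary = [e for e in edges.tolist() if seen[(min(e), max(e))] == 1]
    nxt = {a: b for a, b in boundary}
    loops = []
    while nxt:
        start, cur = next(iter(nxt.items()))
        loop = [start]
        while cur != start:
            loop.append(cur)
            cur = nxt.pop(cur)
        nxt.pop(start, None)
        loops.append(np.asarray(loop))
    return loops


def mesh_volume(
    surface: TrackedSurface, frame: int = 0, structure: Region | None = None
) -> float:
    """Enclosed volume in mm^3 by the divergence theorem.

    For the whole (closed, oriented) surface the result is the absolute
    enclosed volume, independent of global orientation.  For a labelled
    ``structure``, the open boundary of the labelled patch is capped by a
    triangle fan to each boundary loop's centroid; a partition of the surface
    into labelled patches then sums exactly to the whole volume because the
    shared caps cancel pairwise.
    """
    verts = surface.positions[frame]
    if structure is None:
        return abs(_signed_volume(verts, surface.faces))
    sel = surface.labels == int(structure)
    if not sel.any():
        raise ValueError(f"label {Region(structure).name} absent from the mesh")
    faces = surface.faces[sel]
    vol = _signed_volume(verts, faces)
    for loop in _boundary_loops(faces):
        c = verts[loop].mean(axis=0)
        p = verts[loop]
        q = verts[np.roll(loop, -1)]
        # fan of triangles (p_i, p_{i+1}, centroid), oriented to close the patch
        vol += float(np.einsum("ij,ij->", p, np.cross(q, np.broadcast_to(c, p.shape)))) / 6.0
    return abs(vol)


def volume_waveform(tracked: TrackedSurface, structure: Region | None = None) -> Waveform:
    """Per-frame enclosed volume of the whole surface or a capped sub-structure."""
    if tracked.frame_times is not None:
        times = tracked.frame_times
    else:
        times = np.arange(tracked.n_frames, dtype=float)
    vols = np.array([mesh_volume(tracked, j, structure) for j in range(tracked.n_frames)])
    return Waveform(times=times, values=vols, kind="volume")


def stroke_and_ef(volume: Waveform) -> tuple[float, float]:
    """Stroke volume (Vmax - Vmin, mm^3) and ejection fraction SV / Vmax."""
    vmax, vmin = float(volume.values.max()), float(volume.values.min())
    sv = vmax - vmin
    if sv == 0.0:
        warnings.warn("constant volume waveform: SV = 0, EF = 0", stacklevel=2)
        return 0.0, 0.0
    return sv, sv / vmax


# ---------------------------------------------------------------------------
# deformational area stretch
# ---------------------------------------------------------------------------


@dataclass
class StretchField:
    """Per-face, per-frame area stretch ratio (det of the in-plane deformation gradient)."""

    values: np.ndarray  # (n_frames, n_faces)
    reference: str  # "frame0" | "per-face-max"
    frame_times: np.ndarray | None = None


def area_stretch(tracked: TrackedSurface, reference: str = "per-face-max") -> StretchField:
    """Area stretch ratio per face per frame.

    For the affine map of each triangle the determinant of the in-plane 2D
    deformation gradient equals (current area) / (reference area).  With the
    "per-face-max" policy each face is normalised by its own maximum over the
    cycle (stretch <= 1, 1 = maximally stretched state); "frame0" divides by
    the reference-frame area.
    """
    if reference not in ("frame0", "per-face-max"):
        raise ValueError(f"unknown stretch reference {reference!r}")
    areas = np.stack([tracked.face_areas(j) for j in range(tracked.n_frames)])
    a0 = areas[0]
    if np.any(a0 <= 0):
        bad = np.flatnonzero(a0 <= 0)
        raise ValueError(f"zero-area reference face(s): {bad[:10].tolist()}")
    ref = areas.max(axis=0) if reference == "per-face-max" else a0
    return StretchField(
        values=areas / ref, reference=reference, frame_times=tracked.frame_times
    )


def stretch_rate(field: StretchField, frame_times: np.ndarray | None = None) -> np.ndarray:
    """d(stretch)/dt per face per frame, centred differences with periodic wrap, 1/s."""
    times = np.asarray(frame_times if frame_times is not None else field.frame_times, dtype=float)
    v = field.values
    if v.shape[0] < 3:
        raise ValueError("need at least 3 frames for a centred stretch rate")
    dt = np.diff(times)
    period = times[-1] - times[0] + dt[-1]
    ext_t = np.concatenate([[times[0] - dt[-1]], times, [times[0] + period]])
    ext_v = np.concatenate([v[-1:], v, v[:1]], axis=0)
    return (ext_v[2:] - ext_v[:-2]) / (ext_t[2:] - ext_t[:-2])[:, None]


# ---------------------------------------------------------------------------
# per-structure report
# ---------------------------------------------------------------------------


@dataclass
class StructureReport:
    """Per-structure volume extrema, stroke volume, EF and fractions of a parent."""

    structures: dict  # Region name -> metrics dict


def structure_report(
    tracked: TrackedSurface,
    parents: dict[Region, Region] | None = None,
) -> StructureReport:
    """Volumes, SV, EF per labelled structure, plus fractions of a declared parent.

    ``parents`` maps a structure to the structure whose end-diastolic volume
    and stroke volume it is expressed against (e.g. appendage within atria).
    End-diastole is each structure's own Vmax time.
    """
    present = [Region(v) for v in np.unique(tracked.labels) if v != int(Region.NONE)]
    if not present:
        present = [Region.NONE]
        waves = {Region.NONE: volume_waveform(tracked)}
    else:
        waves = {r: volume_waveform(tracked, r) for r in present}
    report: dict = {}
    for r in present:
        wf = waves[r]
        sv, ef = stroke_and_ef(wf)
        report[r.name] = {
            "max_volume_mm3": float(wf.values.max()),
            "min_volume_mm3": float(wf.values.min()),
            "end_diastolic_frame": int(np.argmax(wf.values)),
            "stroke_volume_mm3": sv,
            "ejection_fraction": ef,
        }
    for child, parent in (parents or {}).items():
        parts = [parent] if isinstance(parent, (int, Region)) else list(parent)
        if child not in waves or any(p not in waves for p in parts):
            raise ValueError("parent map references a label absent from the mesh")
        pvals = np.sum([waves[p].values for p in parts], axis=0)
        psv, _ = stroke_and_ef(Waveform(times=waves[child].times, values=pvals))
        c = report[Region(child).name]
        c["volume_fraction_of_parent"] = c["max_volume_mm3"] / float(pvals.max())
        c["stroke_volume_fraction_of_parent"] = (
            c["stroke_volume_mm3"] / psv if psv else np.nan
        )
    return StructureReport(structures=report)
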