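"""Data model and readers/writers for every artifact the pipeline touches.

Conventions
-----------
* All coordinates are physical millimetres in a right-handed frame; a voxel
  index maps to a physical position as ``origin + index * spacing``
  (0-based indices, node-centred samples).
* ``Image4D.data`` is indexed ``(t, x, y, z)``.
* Frame 0 is the reference configuration; one cardiac cycle is the half-open
  interval [0, T).
* Region labels live on mesh faces.  For node-wise reductions a vertex
  inherits the majority label of its incident faces (ties broken by the
  lowest enum value).

Formats: NIfTI / multi-page TIFF / NRRD for images, legacy-ASCII VTK
polydata / PLY / STL for meshes, a JSON-indexed directory of legacy VTK
files for field series, two-column CSV (``time_s,value``) for waveforms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from enum import IntEnum
from pathlib import Path

import numpy as np
import trimesh

__all__ = [
    "Region",
    "Image4D",
    "TrackedSurface",
    "MotionModel",
    "DisplacementField",
    "FieldSeries",
    "Waveform",
    "read_image4d",
    "write_image4d",
    "read_surface",
    "write_surface",
    "read_waveform",
    "write_waveform",
    "read_field_series",
    "write_field_series",
    "read_displacement_field",
    "write_displacement_field",
    "read_motion_model",
    "write_motion_model",
    "fourier_basis",
]


class Region(IntEnum):
    """Cardiac structure labels carried on surface faces."""

    NONE = 0
    RA = 1
    LA = 2
    RAA = 3
    LAA = 4
    RV = 5
    LV = 6
    AVJ = 7
    INLET = 8
    OUTLET = 9


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class Image4D:
    """A scalar 3D image series: intensities on a regular grid over time."""

    data: np.ndarray  # (t, x, y, z) float
    spacing: np.ndarray  # (3,) mm
    origin: np.ndarray  # (3,) mm
    frame_interval: float  # s
    spans_cycle: bool = True  # series covers exactly one cardiac cycle [0, T)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if self.data.ndim != 4:
            raise ValueError(f"Image4D.data must be 4D (t,x,y,z); got shape {self.data.shape}")
        if not np.all(self.spacing > 0):
            raise ValueError(f"voxel spacing must be positive; got {self.spacing}")
        if not self.frame_interval > 0:
            raise ValueError("frame_interval must be positive")
        if self.n_frames < 3:
            raise ValueError(f"need at least 3 frames, got {self.n_frames}")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    @property
    def cycle_duration(self) -> float:
        """Cardiac period T.  Defined as n_frames * frame_interval when the
        series spans exactly one (half-open) cycle."""
        if not self.spans_cycle:
            raise ValueError("cycle_duration undefined: series does not span one cycle")
        return self.n_frames * self.frame_interval

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval

    def frame(self, j: int) -> np.ndarray:
        return self.data[j]

    def physical_extent(self) -> tuple[np.ndarray, np.ndarray]:
        lo = self.origin.copy()
        hi = self.origin + (np.asarray(self.grid_shape) - 1) * self.spacing
        return lo, hi

    def index_to_mm(self, idx: np.ndarray) -> np.ndarray:
        return self.origin + np.asarray(idx, dtype=float) * self.spacing

    def mm_to_index(self, mm: np.ndarray) -> np.ndarray:
        return (np.asarray(mm, dtype=float) - self.origin) / self.spacing


def _edge_face_counts(faces: np.ndarray):
    edges = np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    und = np.sort(edges, axis=1)
    uniq, counts = np.unique(und, axis=0, return_counts=True)
    return edges, uniq, counts


def check_manifold(vertices: np.ndarray, faces: np.ndarray) -> None:
    """Raise if the triangle mesh is not a closed, consistently oriented 2-manifold."""
    if faces.ndim != 2 or faces.shape[1] != 3:
        raise ValueError("faces must be (m, 3) vertex-index triples")
    edges, uniq, counts = _edge_face_counts(faces)
    bad = uniq[counts != 2]
    if len(bad):
        raise ValueError(
            f"mesh is not a closed 2-manifold: {len(bad)} edge(s) not shared by exactly "
            f"2 faces, e.g. {bad[:10].tolist()}"
        )
    # consistent orientation: every undirected edge appears once per direction
    directed, dcounts = np.unique(edges, axis=0, return_counts=True)
    if np.any(dcounts != 1):
        bad_d = directed[dcounts != 1]
        raise ValueError(
            f"mesh orientation inconsistent: directed edge(s) repeated, e.g. {bad_d[:10].tolist()}"
        )


def _triangle_areas(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    p = vertices[faces]
    return 0.5 * np.linalg.norm(np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1)


@dataclass
class TrackedSurface:
    """One triangulated reference mesh plus per-frame node positions and region labels."""

    vertices0: np.ndarray  # (n, 3) mm at the reference frame
    faces: np.ndarray  # (m, 3) int
    positions: np.ndarray | None = None  # (n_frames, n, 3) mm; None => single frame
    labels: np.ndarray | None = None  # (m,) Region per face
    frame_times: np.ndarray | None = None  # (n_frames,) s

    def __post_init__(self) -> None:
        self.vertices0 = np.asarray(self.vertices0, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.positions is None:
            self.positions = self.vertices0[None]
        self.positions = np.asarray(self.positions, dtype=float)
        if self.labels is None:
            self.labels = np.full(len(self.faces), int(Region.NONE), dtype=np.int32)
        self.labels = np.asarray(self.labels, dtype=np.int32)
        if self.labels.shape != (len(self.faces),):
            raise ValueError("labels must be one Region per face")
        if not np.allclose(self.positions[0], self.vertices0):
            raise ValueError("positions[frame 0] must equal vertices0")
        if self.frame_times is not None:
            self.frame_times = np.asarray(self.frame_times, dtype=float)

    def validate(self) -> None:
        check_manifold(self.vertices0, self.faces)
        a0 = _triangle_areas(self.vertices0, self.faces)
        if np.any(a0 <= 0):
            bad = np.flatnonzero(a0 <= 0)
            raise ValueError(f"degenerate zero-area face(s) at reference frame: {bad[:10].tolist()}")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_vertices(self) -> int:
        return len(self.vertices0)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def vertices(self, frame: int) -> np.ndarray:
        return self.positions[frame]

    def face_areas(self, frame: int = 0) -> np.ndarray:
        return _triangle_areas(self.positions[frame], self.faces)

    def face_normals(self, frame: int = 0) -> np.ndarray:
        p = self.positions[frame][self.faces]
        n = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
        nrm = np.linalg.norm(n, axis=1, keepdims=True)
        nrm[nrm == 0] = 1.0
        return n / nrm

    def face_centroids(self, frame: int = 0) -> np.ndarray:
        return self.positions[frame][self.faces].mean(axis=1)

    def vertex_labels(self) -> np.ndarray:
        """Per-vertex label: majority over incident faces, ties -> lowest enum value."""
        n = self.n_vertices
        counts = np.zeros((n, max(Region) + 1), dtype=np.int64)
        for c in range(3):
            np.add.at(counts, (self.faces[:, c], self.labels), 1)
        return counts.argmax(axis=1).astype(np.int32)

    def to_trimesh(self, frame: int = 0) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.positions[frame], self.faces, process=False)

    def with_labels(self, labels: np.ndarray) -> "TrackedSurface":
        return replace(self, labels=np.asarray(labels, dtype=np.int32))


def fourier_basis(t: np.ndarray, n_harmonics: int, period: float) -> np.ndarray:
    """Temporal design row(s) [1, cos(w t), sin(w t), cos(2w t), sin(2w t), ...]."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    cols = [np.ones_like(t)]
    for k in range(1, n_harmonics + 1):
        w = 2.0 * np.pi * k / period
        cols.append(np.cos(w * t))
        cols.append(np.sin(w * t))
    return np.stack(cols, axis=-1)


@dataclass
class MotionModel:
    """Cyclic displacement field u(x, t): Fourier in time, cubic B-splines in space.

    ``u(x,t) = a0(x) + sum_k a_k(x) cos(2 pi k t / T) + b_k(x) sin(2 pi k t / T)``
    with every coefficient field a tensor-product cubic B-spline expansion on a
    regular lattice.  Evaluation is T-periodic in t by construction.
    """

    coeffs: np.ndarray  # (2K+1, 3, nx, ny, nz): [a0, a1, b1, a2, b2, ...] x component
    grid_origin: np.ndarray  # (3,) mm
    grid_spacing: float  # mm
    cycle_duration: float  # s
    spline_order: int = 3

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        self.grid_origin = np.asarray(self.grid_origin, dtype=float).reshape(3)
        if self.coeffs.ndim != 5 or self.coeffs.shape[1] != 3 or self.coeffs.shape[0] % 2 != 1:
            raise ValueError("coeffs must have shape (2K+1, 3, nx, ny, nz)")
        if self.spline_order != 3:
            raise NotImplementedError("only cubic B-splines are implemented")

    @property
    def n_harmonics(self) -> int:
        return (self.coeffs.shape[0] - 1) // 2

    @property
    def lattice(self):
        from ._bspline import BSplineLattice

        return BSplineLattice(
            origin=self.grid_origin, spacing=self.grid_spacing, shape=self.coeffs.shape[2:]
        )

    def displacement(self, points: np.ndarray, t: float) -> np.ndarray:
        """Evaluate u(points, t) in mm.  Points must lie inside the lattice support."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        lat = self.lattice
        inside = lat.contains(points)
        if not np.all(inside):
            bad = points[~inside][:5]
            raise ValueError(f"point(s) outside motion-model grid support, e.g. {bad.tolist()}")
        phi = fourier_basis(np.asarray([t]), self.n_harmonics, self.cycle_duration)[0]
        combined = np.tensordot(phi, self.coeffs, axes=(0, 0))  # (3, nx, ny, nz)
        out = np.empty((len(points), 3))
        for c in range(3):
            out[:, c] = lat.evaluate(combined[c], points)
        return out


@dataclass
class DisplacementField:
    """Dense displacement vectors sampled on the image voxel grid, mm."""

    vectors: np.ndarray  # (nx, ny, nz, 3) mm
    spacing: np.ndarray  # (3,) mm
    origin: np.ndarray  # (3,) mm
    from_frame: int = 0
    to_frame: int = 0

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if self.vectors.ndim != 4 or self.vectors.shape[-1] != 3:
            raise ValueError("vectors must have shape (nx, ny, nz, 3)")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("displacement field contains non-finite values")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.vectors.shape[:3]

    def same_grid(self, other: "DisplacementField") -> bool:
        return (
            self.grid_shape == other.grid_shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )


@dataclass
class FieldSeries:
    """Time-resolved vector samples: WSS on surface nodes or velocity on a grid.

    kind == "wss":      samples (n_frames, n_nodes, 3) Pa, node-aligned with a
                        TrackedSurface.
    kind == "velocity": samples (n_frames, nx, ny, nz, 3) mm/s on a regular
                        grid (spacing/origin set); ``lumen_masks`` optionally
                        marks the fluid region per frame.
    """

    kind: str
    frame_times: np.ndarray  # (n_frames,) s
    samples: np.ndarray
    spacing: np.ndarray | None = None
    origin: np.ndarray | None = None
    lumen_masks: np.ndarray | None = None  # (n_frames, nx, ny, nz) bool

    def __post_init__(self) -> None:
        if self.kind not in ("wss", "velocity"):
            raise ValueError(f"unknown FieldSeries kind {self.kind!r}")
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.samples = np.asarray(self.samples, dtype=float)
        if np.any(np.diff(self.frame_times) <= 0):
            raise ValueError("frame times must be strictly increasing")
        if self.kind == "wss" and self.samples.ndim != 3:
            raise ValueError("wss samples must be (n_frames, n_nodes, 3)")
        if self.kind == "velocity":
            if self.samples.ndim != 5:
                raise ValueError("velocity samples must be (n_frames, nx, ny, nz, 3)")
            if self.spacing is None or self.origin is None:
                raise ValueError("velocity series needs grid spacing and origin")
            self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
            self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if len(self.frame_times) != self.samples.shape[0]:
            raise ValueError("frame_times and samples disagree on frame count")

    @property
    def n_frames(self) -> int:
        return self.samples.shape[0]


@dataclass
class Waveform:
    """A scalar function of time (volume, flow rate, pressure, Doppler velocity)."""

    times: np.ndarray  # s
    values: np.ndarray
    kind: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be equal-length 1D arrays")
        if len(self.times) >= 2 and np.any(np.diff(self.times) <= 0):
            raise ValueError("waveform times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def period(self) -> float:
        """Cycle duration assuming uniformly sampled half-open cycle [0, T)."""
        dt = np.diff(self.times)
        return float(self.times[-1] - self.times[0] + dt[-1])


# ---------------------------------------------------------------------------
# images
# ---------------------------------------------------------------------------


def _load_sidecar(path: Path, sidecar: str | Path | None) -> dict:
    if sidecar is not None:
        p = Path(sidecar)
    else:
        p = path.with_suffix(path.suffix + ".json")
        if not p.exists():
            return {}
    with open(p) as f:
        return json.load(f)


def read_image4d(path, format: str | None = None, sidecar=None) -> Image4D:
    """Read a 4D image (NIfTI, multi-page TIFF, or NRRD) with physical metadata.

    TIFF carries no spacing metadata: a JSON sidecar (``<file>.json`` or the
    ``sidecar`` argument) must supply ``spacing_mm`` and ``frame_interval_s``.
    """
    path = Path(path)
    fmt = format or _guess_image_format(path)
    meta = _load_sidecar(path, sidecar)
    if fmt == "nifti":
        import nibabel as nib

        img = nib.load(str(path))
        arr = np.asarray(img.dataobj, dtype=float)
        if arr.ndim != 4:
            raise ValueError(f"expected 4D NIfTI, got shape {arr.shape}")
        zooms = img.header.get_zooms()
        spacing = np.asarray(zooms[:3], dtype=float)
        frame_interval = float(meta.get("frame_interval_s", zooms[3] if len(zooms) > 3 else 0))
        origin = np.asarray(img.affine[:3, 3], dtype=float)
        data = np.moveaxis(arr, 3, 0)
    elif fmt == "tiff":
        import tifffile

        arr = tifffile.imread(str(path))
        if arr.ndim != 4:
            raise ValueError(f"expected 4D TIFF (t,z,y,x pages), got shape {arr.shape}")
        if "spacing_mm" not in meta:
            raise ValueError("TIFF image lacks voxel 'spacing_mm'; provide a JSON sidecar")
        if "frame_interval_s" not in meta:
            raise ValueError("TIFF image lacks 'frame_interval_s'; provide a JSON sidecar")
        sp = meta["spacing_mm"]
        spacing = np.full(3, float(sp)) if np.isscalar(sp) else np.asarray(sp, dtype=float)
        frame_interval = float(meta["frame_interval_s"])
        origin = np.asarray(meta.get("origin_mm", (0.0, 0.0, 0.0)), dtype=float)
        data = np.moveaxis(arr.astype(float), (1, 2, 3), (3, 2, 1))  # (t,z,y,x) -> (t,x,y,z)
    elif fmt == "nrrd":
        import SimpleITK as sitk

        img = sitk.ReadImage(str(path))
        if img.GetDimension() != 4:
            raise ValueError("expected a 4D NRRD image")
        arr = sitk.GetArrayFromImage(img)  # (t, z, y, x)
        spacing4 = img.GetSpacing()  # (x, y, z, t)
        spacing = np.asarray(spacing4[:3], dtype=float)
        frame_interval = float(meta.get("frame_interval_s", spacing4[3]))
        origin = np.asarray(img.GetOrigin()[:3], dtype=float)
        data = np.moveaxis(arr.astype(float), (1, 2, 3), (3, 2, 1))
    else:
        raise ValueError(f"unknown image format {fmt!r}")
    if frame_interval <= 0:
        raise ValueError("missing or non-positive frame interval; supply 'frame_interval_s'")
    return Image4D(
        data=data,
        spacing=spacing,
        origin=origin,
        frame_interval=frame_interval,
        spans_cycle=bool(meta.get("spans_cycle", True)),
    )


def _guess_image_format(path: Path) -> str:
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    if name.endswith((".tif", ".tiff")):
        return "tiff"
    if name.endswith((".nrrd", ".nhdr")):
        return "nrrd"
    raise ValueError(f"cannot infer image format from {path.name!r}")


def write_image4d(img: Image4D, path, format: str | None = None) -> None:
    path = Path(path)
    fmt = format or _guess_image_format(path)
    meta = {
        "frame_interval_s": img.frame_interval,
        "spans_cycle": img.spans_cycle,
        "origin_mm": img.origin.tolist(),
        "spacing_mm": img.spacing.tolist(),
    }
    if fmt == "nifti":
        import nibabel as nib

        arr = np.moveaxis(img.data, 0, 3)
        affine = np.eye(4)
        affine[:3, :3] = np.diag(img.spacing)
        affine[:3, 3] = img.origin
        out = nib.Nifti1Image(arr, affine)
        out.header.set_zooms((*img.spacing, img.frame_interval))
        nib.save(out, str(path))
    elif fmt == "tiff":
        import tifffile

        arr = np.moveaxis(img.data, (3, 2, 1), (1, 2, 3))  # (t,x,y,z) -> (t,z,y,x)
        tifffile.imwrite(str(path), arr.astype(np.float32))
    elif fmt == "nrrd":
        import SimpleITK as sitk

        arr = np.moveaxis(img.data, (3, 2, 1), (1, 2, 3))
        out = sitk.GetImageFromArray(arr.astype(np.float64), isVector=False)
        out.SetSpacing((*[float(s) for s in img.spacing], float(img.frame_interval)))
        out.SetOrigin((*[float(o) for o in img.origin], 0.0))
        sitk.WriteImage(out, str(path))
    else:
        raise ValueError(f"unknown image format {fmt!r}")
    with open(path.with_suffix(path.suffix + ".json"), "w") as f:
        json.dump(meta, f, indent=1)


# ---------------------------------------------------------------------------
# meshes (PLY / STL via trimesh, legacy ASCII VTK polydata hand-rolled)
# ---------------------------------------------------------------------------


def read_surface(path, format: str | None = None) -> TrackedSurface:
    """Read a single-frame triangle mesh (VTK legacy polydata, PLY, or STL).

    Manifoldness and orientation are validated; labels default to NONE.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt in ("ply", "stl"):
        mesh = trimesh.load(str(path), file_type=fmt, process=fmt == "stl")
        if not isinstance(mesh, trimesh.Trimesh):
            raise ValueError(f"{path} did not parse as a triangle mesh")
        verts, faces = np.asarray(mesh.vertices, dtype=float), np.asarray(mesh.faces)
        labels = None
    elif fmt == "vtk":
        verts, faces, point_data, cell_data = _read_vtk_polydata(path)
        labels = cell_data.get("region_labels")
        labels = labels.astype(np.int32) if labels is not None else None
    else:
        raise ValueError(f"unsupported mesh format {fmt!r}")
    if faces.shape[1] != 3:
        raise ValueError("mesh must be triangular")
    surf = TrackedSurface(vertices0=verts, faces=faces, labels=labels)
    surf.validate()
    return surf


def write_surface(surf: TrackedSurface, path, frame: int = 0, format: str | None = None) -> None:
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    verts = surf.positions[frame]
    if fmt in ("ply", "stl"):
        mesh = trimesh.Trimesh(verts, surf.faces, process=False)
        mesh.export(str(path))
    elif fmt == "vtk":
        _write_vtk_polydata(
            path, verts, surf.faces, cell_data={"region_labels": surf.labels.astype(float)}
        )
    else:
        raise ValueError(f"unsupported mesh format {fmt!r}")


def _write_vtk_polydata(path, verts, faces, point_data=None, cell_data=None, point_vectors=None):
    verts = np.asarray(verts, dtype=float)
    faces = np.asarray(faces, dtype=np.int64)
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\nembryoheart surface\nASCII\nDATASET POLYDATA\n")
        f.write(f"POINTS {len(verts)} double\n")
        np.savetxt(f, verts, fmt="%.17g")
        f.write(f"POLYGONS {len(faces)} {4 * len(faces)}\n")
        np.savetxt(f, np.column_stack([np.full(len(faces), 3), faces]), fmt="%d")
        if point_data or point_vectors:
            f.write(f"POINT_DATA {len(verts)}\n")
            for name, vals in (point_vectors or {}).items():
                f.write(f"VECTORS {name} double\n")
                np.savetxt(f, np.asarray(vals, dtype=float), fmt="%.17g")
            for name, vals in (point_data or {}).items():
                f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                np.savetxt(f, np.asarray(vals, dtype=float)[:, None], fmt="%.17g")
        if cell_data:
            f.write(f"CELL_DATA {len(faces)}\n")
            for name, vals in cell_data.items():
                f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                np.savetxt(f, np.asarray(vals, dtype=float)[:, None], fmt="%.17g")


def _read_tokens(path):
    with open(path) as f:
        lines = f.readlines()
    return lines


def _read_vtk_polydata(path):
    lines = _read_tokens(path)
    i = 0
    verts = faces = None
    point_data: dict = {}
    cell_data: dict = {}
    n_pts = n_cells = 0
    section = None

    def read_floats(count, width):
        nonlocal i
        vals: list[float] = []
        while len(vals) < count * width:
            vals.extend(float(v) for v in lines[i].split())
            i += 1
        return np.asarray(vals).reshape(count, width)

    while i < len(lines):
        parts = lines[i].split()
        if not parts:
            i += 1
            continue
        key = parts[0].upper()
        if key == "POINTS":
            n_pts = int(parts[1])
            i += 1
            verts = read_floats(n_pts, 3)
        elif key == "POLYGONS":
            n_cells = int(parts[1])
            i += 1
            rows = read_floats(n_cells, 4).astype(np.int64)
            if np.any(rows[:, 0] != 3):
                raise ValueError("non-triangular faces in VTK polydata")
            faces = rows[:, 1:]
        elif key == "POINT_DATA":
            section = "point"
            i += 1
        elif key == "CELL_DATA":
            section = "cell"
            i += 1
        elif key == "SCALARS":
            name = parts[1]
            i += 2  # skip LOOKUP_TABLE line
            n = n_pts if section == "point" else n_cells
            vals = read_floats(n, 1)[:, 0]
            (point_data if section == "point" else cell_data)[name] = vals
        elif key == "VECTORS":
            name = parts[1]
            i += 1
            n = n_pts if section == "point" else n_cells
            vals = read_floats(n, 3)
            (point_data if section == "point" else cell_data)[name] = vals
        else:
            i += 1
    if verts is None or faces is None:
        raise ValueError(f"{path} is not a VTK polydata triangle mesh")
    return verts, faces, point_data, cell_data


# ---------------------------------------------------------------------------
# dense vector images (displacement fields, velocity frames) as legacy VTK
# ---------------------------------------------------------------------------


def write_displacement_field(fld: DisplacementField, path) -> None:
    _write_vtk_vector_image(path, fld.vectors, fld.spacing, fld.origin)


def read_displacement_field(path, from_frame: int = 0, to_frame: int = 0) -> DisplacementField:
    """Adapter for externally produced dense displacement fields (VTK vector image)."""
    vec, spacing, origin = _read_vtk_vector_image(path)
    return DisplacementField(
        vectors=vec, spacing=spacing, origin=origin, from_frame=from_frame, to_frame=to_frame
    )


def _write_vtk_vector_image(path, vectors, spacing, origin, mask=None):
    nx, ny, nz = vectors.shape[:3]
    flat = vectors.transpose(2, 1, 0, 3).reshape(-1, 3)  # VTK is x-fastest
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\nembryoheart vector image\nASCII\n")
        f.write("DATASET STRUCTURED_POINTS\n")
        f.write(f"DIMENSIONS {nx} {ny} {nz}\n")
        f.write(f"ORIGIN {origin[0]:.17g} {origin[1]:.17g} {origin[2]:.17g}\n")
        f.write(f"SPACING {spacing[0]:.17g} {spacing[1]:.17g} {spacing[2]:.17g}\n")
        f.write(f"POINT_DATA {nx * ny * nz}\n")
        f.write("VECTORS field double\n")
        np.savetxt(f, flat, fmt="%.17g")
        if mask is not None:
            f.write("SCALARS lumen double 1\nLOOKUP_TABLE default\n")
            np.savetxt(f, mask.transpose(2, 1, 0).reshape(-1, 1).astype(float), fmt="%g")


def _read_vtk_vector_image(path):
    lines = _read_tokens(path)
    dims = spacing = origin = None
    vectors = mask = None
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if not parts:
            i += 1
            continue
        key = parts[0].upper()
        if key == "DIMENSIONS":
            dims = tuple(int(v) for v in parts[1:4])
            i += 1
        elif key == "ORIGIN":
            origin = np.asarray([float(v) for v in parts[1:4]])
            i += 1
        elif key == "SPACING":
            spacing = np.asarray([float(v) for v in parts[1:4]])
            i += 1
        elif key == "VECTORS":
            n = dims[0] * dims[1] * dims[2]
            i += 1
            vals: list[float] = []
            while len(vals) < 3 * n:
                vals.extend(float(v) for v in lines[i].split())
                i += 1
            vectors = np.asarray(vals).reshape(dims[2], dims[1], dims[0], 3).transpose(2, 1, 0, 3)
        elif key == "SCALARS":
            n = dims[0] * dims[1] * dims[2]
            i += 2
            vals = []
            while len(vals) < n:
                vals.extend(float(v) for v in lines[i].split())
                i += 1
            mask = np.asarray(vals).reshape(dims[2], dims[1], dims[0]).transpose(2, 1, 0)
        else:
            i += 1
    if vectors is None:
        raise ValueError(f"{path} is not a VTK vector image")
    return (vectors, spacing, origin) if mask is None else (vectors, spacing, origin, mask)


# ---------------------------------------------------------------------------
# field series (directory of per-frame VTK files + JSON index)
# ---------------------------------------------------------------------------


def write_field_series(series: FieldSeries, out_dir) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = []
    for j in range(series.n_frames):
        fname = f"frame_{j:04d}.vtk"
        files.append(fname)
        if series.kind == "wss":
            # points are not stored with the series; write node vectors only
            _write_vtk_polydata(
                out_dir / fname,
                np.zeros((series.samples.shape[1], 3)),
                np.zeros((0, 3), dtype=int),
                point_vectors={"wss": series.samples[j]},
            )
        else:
            mask = None if series.lumen_masks is None else series.lumen_masks[j]
            _write_vtk_vector_image(
                out_dir / fname, series.samples[j], series.spacing, series.origin, mask=mask
            )
    index = {"kind": series.kind, "times_s": series.frame_times.tolist(), "files": files}
    with open(out_dir / "series.json", "w") as f:
        json.dump(index, f, indent=1)


def read_field_series(in_dir) -> FieldSeries:
    in_dir = Path(in_dir)
    with open(in_dir / "series.json") as f:
        index = json.load(f)
    kind = index["kind"]
    times = np.asarray(index["times_s"], dtype=float)
    frames = []
    masks = []
    spacing = origin = None
    for fname in index["files"]:
        if kind == "wss":
            _, _, pdata, _ = _read_vtk_polydata(in_dir / fname)
            frames.append(pdata["wss"])
        else:
            out = _read_vtk_vector_image(in_dir / fname)
            if len(out) == 4:
                vec, spacing, origin, m = out
                masks.append(m > 0.5)
            else:
                vec, spacing, origin = out
            frames.append(vec)
    return FieldSeries(
        kind=kind,
        frame_times=times,
        samples=np.stack(frames),
        spacing=spacing,
        origin=origin,
        lumen_masks=np.stack(masks) if masks else None,
    )


# ---------------------------------------------------------------------------
# waveforms (CSV, two columns `time_s,value`, header mandatory)
# ---------------------------------------------------------------------------


def read_waveform(path, kind: str = "") -> Waveform:
    import pandas as pd

    df = pd.read_csv(path)
    if list(df.columns[:2]) != ["time_s", "value"]:
        raise ValueError(
            f"waveform CSV must have header 'time_s,value'; got {list(df.columns)[:2]}"
        )
    return Waveform(times=df["time_s"].to_numpy(float), values=df["value"].to_numpy(float), kind=kind)


def write_waveform(wf: Waveform, path) -> None:
    import pandas as pd

    pd.DataFrame({"time_s": wf.times, "value": wf.values}).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# motion model container (flat binary arrays + JSON header via npz)
# ---------------------------------------------------------------------------


def write_motion_model(model: MotionModel, path) -> None:
    header = json.dumps(
        {
            "cycle_duration_s": model.cycle_duration,
            "grid_spacing_mm": model.grid_spacing,
            "n_harmonics": model.n_harmonics,
            "spline_order": model.spline_order,
        }
    )
    np.savez(
        path,
        header=np.frombuffer(header.encode(), dtype=np.uint8),
        coeffs=model.coeffs,
        grid_origin=model.grid_origin,
    )


def read_motion_model(path) -> MotionModel:
    with np.load(path) as z:
        header = json.loads(bytes(z["header"]).decode())
        return MotionModel(
            coeffs=z["coeffs"],
            grid_origin=z["grid_origin"],
            grid_spacing=float(header["grid_spacing_mm"]),
            cycle_duration=float(header["cycle_duration_s"]),
            spline_order=int(header["spline_order"]),
        )
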