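"""Tensor-product cubic B-spline lattices on regular grids.

A field f(x) is represented by coefficients ``c[i,j,k]`` on a regular lattice
(origin ``g0``, isotropic spacing ``h``) and evaluated as

    f(x) = sum_ijk c[i,j,k] * B3(u_x - i) * B3(u_y - j) * B3(u_z - k),

with ``u = (x - g0)/h`` the continuous lattice coordinate and ``B3`` the
cardinal cubic B-spline.  Because ``scipy.ndimage.map_coordinates`` with
``order=3, prefilter=False`` evaluates exactly this expansion, evaluation is
delegated to it; fitting uses the separable structure of the least-squares
problem (the pseudo-inverse of a Kronecker product is the Kronecker product
of the pseudo-inverses).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["bspline3", "BSplineLattice", "basis_matrix_1d", "fit_separable"]


def bspline3(u: np.ndarray) -> np.ndarray:
    """Cardinal cubic B-spline, support (-2, 2), unit integral and partition of unity."""
    u = np.abs(np.asarray(u, dtype=float))
    out = np.zeros_like(u)
    m1 = u < 1.0
    m2 = (u >= 1.0) & (u < 2.0)
    out[m1] = 2.0 / 3.0 - u[m1] ** 2 + 0.5 * u[m1] ** 3
    out[m2] = (2.0 - u[m2]) ** 3 / 6.0
    return out


def basis_matrix_1d(u: np.ndarray, n_coeff: int) -> np.ndarray:
    """Dense basis matrix B with B[p, i] = B3(u[p] - i).

    ``u`` are continuous lattice coordinates; rows sum to 1 whenever
    ``1 <= u <= n_coeff - 2`` (all four supporting coefficients exist).
    """
    u = np.asarray(u, dtype=float)
    B = np.zeros((u.size, n_coeff))
    base = np.floor(u).astype(int)
    for off in (-1, 0, 1, 2):
        idx = base + off
        ok = (idx >= 0) & (idx < n_coeff)
        w = bspline3(u - idx)
        B[np.arange(u.size)[ok], idx[ok]] = w[ok]
    return B


def fit_separable(
    data: np.ndarray, Bx: np.ndarray, By: np.ndarray, Bz: np.ndarray, rcond: float = 1e-10
) -> np.ndarray:
    """Minimum-norm least-squares lattice coefficients for gridded samples.

    ``data`` has shape (nx, ny, nz) sampled on the tensor grid whose axis
    basis matrices are Bx, By, Bz; returns coefficients with shape
    (Bx.shape[1], By.shape[1], Bz.shape[1]).
    """
    Px = np.linalg.pinv(Bx, rcond=rcond)
    Py = np.linalg.pinv(By, rcond=rcond)
    Pz = np.linalg.pinv(Bz, rcond=rcond)
    c = np.einsum("ax,xyz->ayz", Px, data)
    c = np.einsum("by,ayz->abz", Py, c)
    c = np.einsum("cz,abz->abc", Pz, c)
    return c


@dataclass(frozen=True)
class BSplineLattice:
    """Geometry of a coefficient lattice: physical origin, spacing and shape."""

    origin: np.ndarray  # (3,) mm, position of coefficient index (0,0,0)
    spacing: float  # mm between neighbouring coefficients
    shape: tuple[int, int, int]

    @staticmethod
    def covering(lo: np.ndarray, hi: np.ndarray, spacing: float) -> "BSplineLattice":
        """Smallest lattice whose cubic support covers the box [lo, hi].

        The origin is one knot below ``lo`` so every point in the box has its
        full 4-coefficient support inside the lattice (u in [1, n-3]).
        """
        lo = np.asarray(lo, dtype=float)
        hi = np.asarray(hi, dtype=float)
        origin = lo - spacing
        n = np.ceil((hi - origin) / spacing).astype(int) + 3
        n = np.maximum(n, 4)
        return BSplineLattice(origin=origin, spacing=float(spacing), shape=tuple(int(v) for v in n))

    def to_lattice(self, points: np.ndarray) -> np.ndarray:
        """Physical mm -> continuous lattice coordinates."""
        return (np.asarray(points, dtype=float) - self.origin) / self.spacing

    def contains(self, points: np.ndarray) -> np.ndarray:
        u = self.to_lattice(points)
        n = np.asarray(self.shape)
        return np.all((u >= 1.0 - 1e-9) & (u <= n - 3.0 + 1e-9), axis=-1)

    def evaluate(self, coeffs: np.ndarray, points: np.ndarray) -> np.ndarray:
        """Evaluate the spline expansion of ``coeffs`` (shape == self.shape) at mm points (N,3)."""
        u = self.to_lattice(points)
        return ndimage.map_coordinates(
            coeffs, u.T, order=3, prefilter=False, mode="nearest"
        )

    def axis_coordinates(self, axis_points_mm: tuple[np.ndarray, np.ndarray, np.ndarray]):
        return tuple(
            (np.asarray(p, dtype=float) - self.origin[a]) / self.spacing
            for a, p in enumerate(axis_points_mm)
        )

    def fit_gridded(
        self, data: np.ndarray, axis_points_mm: tuple[np.ndarray, np.ndarray, np.ndarray]
    ) -> np.ndarray:
        """Least-squares fit of values sampled on a tensor grid of mm coordinates."""
        ux, uy, uz = self.axis_coordinates(axis_points_mm)
        Bx = basis_matrix_1d(ux, self.shape[0])
        By = basis_matrix_1d(uy, self.shape[1])
        Bz = basis_matrix_1d(uz, self.shape[2])
        return fit_separable(data, Bx, By, Bz)
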