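"""Shared rotation conventions.

Euler angles are (rot, tilt, psi) in degrees, intrinsic ZYZ. The matrix
returned by :func:`rotation_matrix` maps reference-frame coordinates to
imaging-frame coordinates (beam along +z of the imaging frame):

    r_img = R @ r_ref,   rho_img(r) = rho_ref(R^{-1} r)

Arrays are indexed [z, y, x]; matrices act on (x, y, z) vectors, so helpers
that touch arrays perform the axis reversal internally.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import affine_transform, map_coordinates
from scipy.spatial.transform import Rotation

__all__ = ["rotation_matrix", "euler_from_matrix", "rotate_volume_data"]


def rotation_matrix(euler: tuple[float, float, float]) -> np.ndarray:
    """3x3 matrix for intrinsic-ZYZ Euler angles in degrees."""
    return Rotation.from_euler("ZYZ", euler, degrees=True).as_matrix()


def euler_from_matrix(matrix: np.ndarray) -> tuple[float, float, float]:
    """Inverse of :func:`rotation_matrix`; tilt returned in [0, 180]."""
    import warnings
    with warnings.catch_warnings():
        # tilt ~ 0/180 leaves rot+psi degenerate; any split reproduces the matrix
        warnings.filterwarnings("ignore", message="Gimbal lock")
        rot, tilt, psi = Rotation.from_matrix(matrix).as_euler("ZYZ", degrees=True)
    if tilt < 0:  # scipy may return tilt in [-180, 0]; fold into [0, 180]
        rot, tilt, psi = rot + 180.0, -tilt, psi + 180.0
    return float(rot % 360.0), float(tilt), float(psi % 360.0)


def _as_index_matrix(matrix_xyz: np.ndarray) -> np.ndarray:
    """Re-express an (x,y,z)-acting matrix for [z,y,x] index vectors."""
    return matrix_xyz[::-1, ::-1]


def rotate_volume_data(data: np.ndarray, matrix: np.ndarray, order: int = 1) -> np.ndarray:
    """Resample ``data`` so the output is the input rotated by ``matrix``.

    The rotation centre is the integer grid centre N//2. Tri-linear
    interpolation by default (order=1); values outside the grid are zero.
    """
    n = data.shape[0]
    centre = np.full(3, n // 2, dtype=float)
    m = _as_index_matrix(np.asarray(matrix).T)  # pull-back: input = R^{-1} output
    offset = centre - m @ centre
    return affine_transform(data, m, offset=offset, order=order,
                            mode="constant", cval=0.0, prefilter=(order > 1))


def sample_volume(data: np.ndarray, points_xyz: np.ndarray, order: int = 1) -> np.ndarray:
    """Tri-linear sample of ``data`` at (x,y,z) voxel coordinates (shape (3,M))."""
    coords = points_xyz[::-1]  # -> (z,y,x) index order
    return map_coordinates(data, coords, order=order, mode="constant", cval=0.0,
                           prefilter=(order > 1))
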