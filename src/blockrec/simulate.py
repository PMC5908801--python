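"""Phantom generation and depth-of-field ("layered") image simulation.

The layered simulator is the package's forward model for the Ewald-sphere /
depth-of-field effect: the rotated object is partitioned into slabs along the
beam axis, each slab is projected and filtered by the CTF at its own local
mean defocus (particle defocus plus the slab centre's beam-axis offset), and
the filtered projections are summed. A conventional single-defocus projection
(:func:`simulate_image_flat`) is the control; it is the exact single-slab
limit of the layered model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._geometry import rotation_matrix, rotate_volume_data
from .iometa import ImageStack, ParticleRecord, ParticleTable, VolumeGrid
from .optics import CTFParams, OpticsModel, ctf_2d

__all__ = [
    "Phantom",
    "SimulationConfig",
    "make_phantom",
    "euler_coverage",
    "simulate_image_flat",
    "simulate_image_layered",
    "simulate_dataset",
]

_SPHERE_AREA_DEG2 = 41252.96  # 4 pi steradians in square degrees


@dataclass
class Phantom:
    """A synthetic density model: a VolumeGrid whose support lies inside a
    sphere of the stated diameter (the thickness t of the resolution-limit
    formula)."""

    volume: VolumeGrid
    diameter: float  # Å
    seed: int = 0


@dataclass
class SimulationConfig:
    """Study conditions for a simulated dataset.

    Defaults mirror typical 300 kV single-particle imaging: ~2 nm layers and
    particle defoci drawn uniformly between 1.0 and 3.0 um (underfocus).
    """

    layer_thickness: float = 20.0                  # Å
    defocus_range: tuple[float, float] = (10000.0, 30000.0)  # Å
    euler_step: float = 15.0                       # degrees
    psi_step: float | None = None                  # defaults to euler_step
    noise_sigma: float = 0.0                       # fraction of image RMS
    seed: int = 0
    hand_sign: int = 1

    def __post_init__(self) -> None:
        if self.layer_thickness <= 0:
            raise ValueError("layer_thickness must be positive")
        lo, hi = self.defocus_range
        if not lo < hi:
            raise ValueError("defocus_range must be increasing")


def make_phantom(diameter: float, n_atoms: int, voxel_size: float, box: int,
                 seed: int = 0, blob_sigma: float | None = None,
                 inner_fraction: float = 0.0) -> Phantom:
    """Sum of isotropic Gaussian pseudo-atoms drawn uniformly in a sphere.

    ``inner_fraction > 0`` hollows the sphere (atoms drawn from a spherical
    shell), emulating a viral capsid. Blob width defaults to 0.75 voxels so
    the model carries signal out to the Nyquist frequency. Density outside
    radius ``diameter/2`` is clipped to zero; the construction is
    deterministic per seed.
    """
    if diameter > box * voxel_size * 0.8:
        raise ValueError("phantom diameter exceeds 80% of the box extent")
    if not 0.0 <= inner_fraction < 1.0:
        raise ValueError("inner_fraction must lie in [0, 1)")
    sigma = (0.75 * voxel_size) if blob_sigma is None else blob_sigma
    rng = np.random.default_rng(seed)
    data = np.zeros((box, box, box), dtype=np.float64)
    r_out = diameter / 2.0 - 2.0 * sigma
    r_in = inner_fraction * diameter / 2.0
    if n_atoms > 0 and r_out > 0:
        u = rng.random(n_atoms)
        radii = (r_in ** 3 + u * (max(r_out, r_in) ** 3 - r_in ** 3)) ** (1 / 3)
        dirs = rng.normal(size=(n_atoms, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        pos_px = dirs * radii[:, None] / voxel_size + box // 2  # (x,y,z) voxels
        sig_px = sigma / voxel_size
        half = max(2, int(math.ceil(4 * sig_px)))
        ax = np.arange(-half, half + 1, dtype=float)
        for x, y, z in pos_px:
            ix, iy, iz = int(round(x)), int(round(y)), int(round(z))
            gx = np.exp(-((ax + ix - x) ** 2) / (2 * sig_px ** 2))
            gy = np.exp(-((ax + iy - y) ** 2) / (2 * sig_px ** 2))
            gz = np.exp(-((ax + iz - z) ** 2) / (2 * sig_px ** 2))
            data[iz - half:iz + half + 1,
                 iy - half:iy + half + 1,
                 ix - half:ix + half + 1] += (
                gz[:, None, None] * gy[None, :, None] * gx[None, None, :])
    # hard support mask at the nominal radius
    grid = (np.arange(box) - box // 2) * voxel_size
    r2 = (grid[:, None, None] ** 2 + grid[None, :, None] ** 2
          + grid[None, None, :] ** 2)
    data[r2 > (diameter / 2.0) ** 2] = 0.0
    return Phantom(VolumeGrid(data, voxel_size), diameter, seed)


def euler_coverage(step_deg: float,
                   psi_step: float | None = None) -> list[tuple[float, float, float]]:
    """Quasi-uniform Euler triples covering the sphere at a given step.

    Viewing directions follow a golden-angle spiral from pole to pole with a
    count matched to ``step_deg`` (area per direction ~ step^2); the in-plane
    angle psi is sampled at ``psi_step`` (default: the same step).
    """
    if step_deg <= 0:
        raise ValueError("step must be positive")
    n_dir = max(6, int(round(_SPHERE_AREA_DEG2 / step_deg ** 2)))
    golden = 180.0 * (3.0 - math.sqrt(5.0))
    psis = np.arange(0.0, 360.0, psi_step if psi_step is not None else step_deg)
    triples = []
    for i in range(n_dir):
        z = 1.0 - 2.0 * i / (n_dir - 1)      # includes both poles
        tilt = math.degrees(math.acos(np.clip(z, -1, 1)))
        rot = (i * golden) % 360.0
        for psi in psis:
            triples.append((rot, tilt, float(psi)))
    return triples


def _project(data: np.ndarray) -> np.ndarray:
    return data.sum(axis=0)


def simulate_image_flat(phantom: Phantom, euler: tuple[float, float, float],
                        defocus: float | None, optics: OpticsModel) -> np.ndarray:
    """Single-defocus (no depth of field) projection image.

    Projects the rotated volume along the beam and applies one CTF at the
    particle defocus — the conventional central-projection forward model.
    ``defocus=None`` skips the CTF entirely (pure projection control).
    """
    vol = phantom.volume
    rotated = rotate_volume_data(vol.data.astype(np.float64), rotation_matrix(euler))
    proj = _project(rotated)
    if defocus is None:
        return proj
    opt = optics.with_pixel_size(vol.voxel_size)
    ctf = ctf_2d(opt, CTFParams(defocus), proj.shape)
    return np.fft.ifft2(np.fft.fft2(proj) * ctf).real


def _slab_indices(n: int, voxel_size: float, layer_thickness: float) -> np.ndarray:
    """Slab id per voxel plane; slab k spans z in [(k-1/2)t, (k+1/2)t)."""
    z = (np.arange(n) - n // 2) * voxel_size
    return np.floor(z / layer_thickness + 0.5).astype(int)


def simulate_image_layered(phantom: Phantom, euler: tuple[float, float, float],
                           particle_defocus: float, optics: OpticsModel,
                           layer_thickness: float = 20.0,
                           hand_sign: int = 1) -> np.ndarray:
    """Depth-of-field image: per-slab projections filtered by per-slab CTFs.

    The rotated volume is cut into slabs of ``layer_thickness`` Å along the
    beam axis (slab mid-planes at integer multiples of the thickness, the
    plane z = 0 passing through the grid centre; partial end slabs allowed).
    Slab k centred at z_k receives the CTF at defocus
    ``particle_defocus + hand_sign * z_k``, and all filtered projections are
    summed. A single slab reproduces :func:`simulate_image_flat` exactly.
    """
    if layer_thickness <= 0:
        raise ValueError("layer_thickness must be positive")
    if particle_defocus <= 0:
        raise ValueError("particle defocus must be positive (underfocus)")
    vol = phantom.volume
    n = vol.n
    rotated = rotate_volume_data(vol.data.astype(np.float64), rotation_matrix(euler))
    slab_of_plane = _slab_indices(n, vol.voxel_size, layer_thickness)
    opt = optics.with_pixel_size(vol.voxel_size)
    total_mass = np.abs(rotated).sum() + 1e-300
    acc = np.zeros((n, n), dtype=np.complex128)
    for k in np.unique(slab_of_plane):
        slab = rotated[slab_of_plane == k]
        if np.abs(slab).sum() < 1e-12 * total_mass:
            continue
        proj = _project(slab)
        z_k = k * layer_thickness
        ctf = ctf_2d(opt, CTFParams(particle_defocus + hand_sign * z_k), proj.shape)
        acc += np.fft.fft2(proj) * ctf
    return np.fft.ifft2(acc).real


def simulate_dataset(phantom: Phantom, config: SimulationConfig,
                     optics: OpticsModel) -> tuple[ImageStack, ParticleTable]:
    """One layered image per Euler triple of the configured angular coverage.

    Particle defoci are drawn uniformly from ``config.defocus_range`` with
    ``config.seed``; optional additive Gaussian noise has standard deviation
    ``noise_sigma`` times each image's RMS. Records carry the true Euler
    angles, zero shifts and the true particle defoci.
    """
    rng = np.random.default_rng(config.seed)
    triples = euler_coverage(config.euler_step, config.psi_step)
    defoci = rng.uniform(*config.defocus_range, size=len(triples))
    images, records = [], []
    for i, (euler, df) in enumerate(zip(triples, defoci)):
        img = simulate_image_layered(phantom, euler, df, optics,
                                     config.layer_thickness, config.hand_sign)
        if config.noise_sigma > 0:
            rms = float(np.sqrt(np.mean(img ** 2)))
            img = img + rng.normal(scale=config.noise_sigma * rms, size=img.shape)
        images.append(img.astype(np.float32))
        records.append(ParticleRecord(euler=euler, shift=(0.0, 0.0),
                                      particle_defocus=float(df),
                                      hand_sign=config.hand_sign, image_index=i))
    stack = ImageStack(np.stack(images), phantom.volume.voxel_size)
    return stack, ParticleTable.from_records(records)
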