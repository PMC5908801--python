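"""Direct Fourier-inversion reconstruction, FSC, and the resolution-limit
experiment.

Each particle image's 2-D Fourier transform is a central section of the 3-D
transform of the object at the particle's orientation (central projection
theorem). Sections are spread into a padded 3-D grid with a tri-linear
kernel, data weighted by the CTF and weights by CTF^2, and the grid is
normalised by a Wiener-regularised division before inverse transformation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._geometry import rotation_matrix
from .iometa import ImageStack, ParticleTable, VolumeGrid
from .optics import CTFParams, OpticsModel, ctf_2d

__all__ = [
    "FourierAccumulator",
    "FSCCurve",
    "insert_slice",
    "finalize",
    "reconstruct",
    "fsc",
    "resolution_at",
    "limit_experiment",
]


@dataclass
class FourierAccumulator:
    """Padded centred 3-D Fourier grid holding CTF-weighted section sums."""

    n: int                      # unpadded box size (voxels)
    voxel_size: float
    pad_factor: int = 2
    data: np.ndarray | None = None     # complex sums, centred spectrum
    weights: np.ndarray | None = None  # accumulated CTF^2 insertion weights

    def __post_init__(self) -> None:
        if self.pad_factor < 1:
            raise ValueError("pad_factor must be >= 1")
        m = self.m
        if self.data is None:
            self.data = np.zeros((m, m, m), dtype=np.complex128)
        if self.weights is None:
            self.weights = np.zeros((m, m, m), dtype=np.float64)

    @property
    def m(self) -> int:
        return self.n * self.pad_factor


@dataclass
class FSCCurve:
    """Per-shell correlation; ``freq`` in Å^-1, increasing from shell 0."""

    freq: np.ndarray
    fsc: np.ndarray
    voxel_size: float


def _centred_image_ft(image: np.ndarray, m: int,
                      shift_px: tuple[float, float]) -> np.ndarray:
    """Padded, centred 2-D FT with the phase origin on the object centre.

    The image (box n) is embedded in an m x m frame; the object centre sits
    at pixel ``m//2 + shift`` and a phase ramp moves it to the Fourier phase
    origin. The returned spectrum is fftshifted (DC at index m//2) with its
    Nyquist row/column zeroed to preserve Hermitian symmetry on insertion.
    """
    n = image.shape[0]
    frame = np.zeros((m, m), dtype=np.float64)
    off = (m - n) // 2
    frame[off:off + n, off:off + n] = image
    ft = np.fft.fft2(frame)
    fy = np.fft.fftfreq(m)[:, None]
    fx = np.fft.fftfreq(m)[None, :]
    cy = m // 2 + shift_px[1]
    cx = m // 2 + shift_px[0]
    ft = ft * np.exp(2j * np.pi * (fx * cx + fy * cy))
    ft = np.fft.fftshift(ft)
    ft[0, :] = 0.0
    ft[:, 0] = 0.0
    return ft


def insert_slice(acc: FourierAccumulator, image: np.ndarray,
                 euler: tuple[float, float, float],
                 shift: tuple[float, float] = (0.0, 0.0),
                 ctf: np.ndarray | None = None) -> FourierAccumulator:
    """Spread one oriented central section into the accumulator.

    ``shift`` is the record's (dx, dy) in Å (object centre relative to the
    box centre); ``ctf`` is the 2-D CTF on the *padded* fftshifted grid, or
    None for CTF == 1. Data are weighted by the CTF and the weights by CTF^2,
    so :func:`finalize` performs the usual Wiener-style CTF correction.
    """
    m = acc.m
    shift_px = (shift[0] / acc.voxel_size, shift[1] / acc.voxel_size)
    ft = _centred_image_ft(np.asarray(image, float), m, shift_px)
    if ctf is None:
        ctf = np.ones((m, m))
    data2d = (ft * ctf).ravel()
    w2d = (ctf.astype(float) ** 2).ravel()

    k = np.arange(m) - m // 2
    kx, ky = np.meshgrid(k, k, indexing="xy")    # kx varies along axis 1
    plane = np.stack([kx.ravel(), ky.ravel(), np.zeros(m * m)])  # (3, m*m)
    rmat = rotation_matrix(euler)
    pos = rmat.T @ plane                          # reference-frame (x,y,z)
    pos += m // 2

    base = np.floor(pos).astype(int)
    frac = pos - base
    keep = np.all((base >= 0) & (base < m - 1), axis=0)
    base, frac = base[:, keep], frac[:, keep]
    data2d, w2d = data2d[keep], w2d[keep]
    for dx in (0, 1):
        wx = frac[0] if dx else 1 - frac[0]
        for dy in (0, 1):
            wy = frac[1] if dy else 1 - frac[1]
            for dz in (0, 1):
                wz = frac[2] if dz else 1 - frac[2]
                w = wx * wy * wz
                idx = (base[2] + dz, base[1] + dy, base[0] + dx)  # [z,y,x]
                np.add.at(acc.data, idx, data2d * w)
                np.add.at(acc.weights, idx, w2d * w)
    return acc


def finalize(acc: FourierAccumulator, wiener_floor: float = 1e-4) -> VolumeGrid:
    """Normalise, inverse-transform and crop the padding.

    The divisor is ``weights + wiener_floor * max(weights)``; the relative
    floor guards poorly covered voxels. It must stay well below the smallest
    CTF^2 amplitude of interest (about A^2 at low frequency), otherwise the
    regulariser, not the data, sets the low-frequency values.
    """
    wmax = float(acc.weights.max())
    if wmax == 0.0:
        return VolumeGrid(np.zeros((acc.n,) * 3, np.float32), acc.voxel_size)
    grid = acc.data / (acc.weights + wiener_floor * wmax)
    vol = np.fft.fftshift(np.fft.ifftn(np.fft.ifftshift(grid)).real)
    m, n = acc.m, acc.n
    lo = m // 2 - n // 2
    return VolumeGrid(vol[lo:lo + n, lo:lo + n, lo:lo + n].astype(np.float32),
                      acc.voxel_size)


def reconstruct(stack: ImageStack, table: ParticleTable, optics: OpticsModel,
                defocus_source: str = "true", pad_factor: int = 2,
                wiener_floor: float = 1e-4,
                defocus_override: np.ndarray | None = None) -> VolumeGrid:
    """Direct-inversion reconstruction using the chosen per-record defocus.

    ``defocus_source`` selects the table column ('true'/'measured');
    ``defocus_override`` supplies explicit per-record defoci instead (used by
    the block pipeline for local mean defoci).
    """
    if len(table) == 0:
        raise ValueError("cannot reconstruct from an empty particle table")
    if len(table) != len(stack):
        raise ValueError("stack and table lengths differ")
    defoci = (np.asarray(defocus_override, float) if defocus_override is not None
              else table.defoci(defocus_source))
    acc = FourierAccumulator(stack.box, stack.voxel_size, pad_factor)
    opt = optics.with_pixel_size(stack.voxel_size)
    for i, rec in enumerate(table.records()):
        ctf = np.fft.fftshift(ctf_2d(opt, CTFParams(float(defoci[i])),
                                     (acc.m, acc.m)))
        insert_slice(acc, stack.data[i], rec.euler, rec.shift, ctf)
    return finalize(acc, wiener_floor)


# --------------------------------------------------------------------------
# Fourier shell correlation
# --------------------------------------------------------------------------

def _shell_ids(n: int) -> np.ndarray:
    k = np.fft.fftfreq(n) * n
    r = np.sqrt(k[:, None, None] ** 2 + k[None, :, None] ** 2
                + k[None, None, :] ** 2)
    return np.rint(r).astype(int)


def fsc(vol_a: VolumeGrid, vol_b: VolumeGrid) -> FSCCurve:
    """Per-shell normalised complex correlation of two equal-size volumes."""
    if vol_a.n != vol_b.n:
        raise ValueError("volumes differ in size")
    n = vol_a.n
    fa = np.fft.fftn(vol_a.data.astype(np.float64))
    fb = np.fft.fftn(vol_b.data.astype(np.float64))
    shells = _shell_ids(n).ravel()
    nshell = n // 2 + 1
    sel = shells < nshell
    shells = shells[sel]
    cross = np.bincount(shells, weights=(fa.ravel()[sel]
                                         * np.conj(fb.ravel()[sel])).real,
                        minlength=nshell)
    pa = np.bincount(shells, weights=np.abs(fa.ravel()[sel]) ** 2, minlength=nshell)
    pb = np.bincount(shells, weights=np.abs(fb.ravel()[sel]) ** 2, minlength=nshell)
    denom = np.sqrt(pa * pb)
    curve = np.where(denom > 0, cross / np.maximum(denom, 1e-300), 0.0)
    freq = np.arange(nshell) / (n * vol_a.voxel_size)
    return FSCCurve(freq, curve, vol_a.voxel_size)


def resolution_at(curve: FSCCurve, threshold: float = 0.5) -> float:
    """Resolution (Å) at the first downward threshold crossing.

    Linear interpolation between shells; returns the Nyquist resolution
    (2 x voxel size) when the curve never drops below the threshold.
    """
    vals, freq = curve.fsc, curve.freq
    for i in range(1, len(vals)):
        if vals[i] < threshold <= vals[i - 1]:
            f = freq[i - 1] + (freq[i] - freq[i - 1]) * (
                (vals[i - 1] - threshold) / (vals[i - 1] - vals[i]))
            return float(1.0 / f)
    return 2.0 * curve.voxel_size


# --------------------------------------------------------------------------
# resolution-limit experiment
# --------------------------------------------------------------------------

def limit_experiment(diameter: float, optics: OpticsModel, euler_step: float,
                     layer_thickness: float = 20.0, defocus_mode: str = "true",
                     box: int = 96, n_atoms: int = 1200,
                     defocus_range: tuple[float, float] = (10000.0, 30000.0),
                     psi_step: float | None = 360.0, seed: int = 0,
                     sim_mode: str = "layered") -> float:
    """Measure the depth-of-field resolution limit on noise-free data.

    Builds a phantom of the given diameter, simulates a full angular
    coverage of layered (or flat, as control) images, reconstructs with the
    known orientations and the chosen defocus source ('true' or 'measured',
    the latter via Thon-ring fitting), and reads the FSC-0.5 resolution
    against the phantom. With error-free parameters and no noise this
    resolution isolates the depth-of-field effect.
    """
    from .simulate import SimulationConfig, make_phantom, simulate_dataset
    from .simulate import simulate_image_flat
    from .iometa import ImageStack
    from .optics import fit_defocus

    phantom = make_phantom(diameter, n_atoms, optics.pixel_size, box, seed=seed)
    config = SimulationConfig(layer_thickness=layer_thickness,
                              defocus_range=defocus_range,
                              euler_step=euler_step, psi_step=psi_step,
                              seed=seed)
    stack, table = simulate_dataset(phantom, config, optics)
    if sim_mode == "flat":
        imgs = [simulate_image_flat(phantom, rec.euler, rec.particle_defocus,
                                    optics) for rec in table.records()]
        stack = ImageStack(np.stack(imgs).astype(np.float32), stack.voxel_size)
    elif sim_mode != "layered":
        raise ValueError("sim_mode must be 'layered' or 'flat'")

    if defocus_mode == "measured":
        lo, hi = defocus_range
        measured = [fit_defocus(img, optics.with_pixel_size(stack.voxel_size),
                                search_min=0.7 * lo, search_max=1.3 * hi,
                                step=50.0)
                    for img in stack.data]
        table.df["measured_defocus"] = measured
        recon = reconstruct(stack, table, optics, defocus_source="measured")
    elif defocus_mode == "true":
        recon = reconstruct(stack, table, optics, defocus_source="true")
    else:
        raise ValueError("defocus_mode must be 'true' or 'measured'")
    return resolution_at(fsc(recon, phantom.volume), 0.5)
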