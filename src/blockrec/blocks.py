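"""Block-based reconstruction: local mean defoci, symmetry expansion,
sub-image extraction, local refinement, per-block reconstruction and
reassembly.

A large object spans a range of defoci along the beam (the depth-of-field /
Ewald-sphere effect). Dividing it into blocks small enough that one defocus
per block is accurate, reconstructing each block with its *local mean
defocus*

    LDF_ij = PDF_i + LDFV_ij,      LDFV_ij = hand_sign * (R_i c_j)_z

(particle defocus plus the beam-axis offset of block j's centre under
particle i's orientation), and reassembling the blocks in real space removes
most of the resolution loss without any Ewald-corrected insertion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from ._geometry import euler_from_matrix, rotation_matrix, sample_volume
from .iometa import ImageStack, ParticleTable, VolumeGrid
from .optics import CTFParams, OpticsModel, ctf_2d, phase_flip
from .reconstruct import reconstruct

__all__ = [
    "BlockSpec",
    "BlockSet",
    "SymmetryGroup",
    "local_defocus_offset",
    "local_mean_defocus",
    "expand_by_symmetry",
    "extract_block_images",
    "extract_block_volume",
    "local_refine",
    "reconstruct_block",
    "combine_blocks",
    "symmetrize",
]


@dataclass(frozen=True)
class BlockSpec:
    """One block: centre (Å, reference frame, relative to the object centre),
    spherical radius (Å) and the even sub-box edge length (pixels)."""

    center: tuple[float, float, float]
    radius: float
    sub_box: int

    def __post_init__(self) -> None:
        if self.sub_box % 2:
            raise ValueError("sub_box must be even")
        if self.radius <= 0:
            raise ValueError("block radius must be positive")

    def check_fits(self, voxel_size: float) -> None:
        if 2 * self.radius > self.sub_box * voxel_size:
            raise ValueError("block diameter exceeds the sub-box extent")


class SymmetryGroup:
    """A rotational point group (C1, Cn, Dn, T, O, I) as explicit matrices."""

    def __init__(self, name: str):
        self.name = name.upper()
        if self.name == "C1":
            self.matrices = np.eye(3)[None]
        else:
            self.matrices = Rotation.create_group(self.name).as_matrix()

    def __len__(self) -> int:
        return len(self.matrices)


@dataclass
class BlockSet:
    """Blocks plus the assembly parameters used by :func:`combine_blocks`."""

    blocks: list[BlockSpec]
    symmetry: str = "C1"
    r_keep: float = 0.0    # Å kept verbatim around each block centre
    r_blend: float = 20.0  # Å over which neighbouring blocks are blended
    group: SymmetryGroup = field(init=False)

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("BlockSet needs at least one block")
        if self.r_blend <= 0:
            raise ValueError("r_blend must be positive")
        self.group = SymmetryGroup(self.symmetry)

    def centers(self) -> np.ndarray:
        return np.array([b.center for b in self.blocks], dtype=float)


# --------------------------------------------------------------------------
# local mean defocus
# --------------------------------------------------------------------------

def local_defocus_offset(euler: tuple[float, float, float],
                         center: tuple[float, float, float] | np.ndarray,
                         hand_sign: int = 1) -> float:
    """LDFV: beam-axis offset (Å) of a block centre under an orientation.

    ``hand_sign * (R(euler) @ c)_z`` with R mapping the reference frame to
    the imaging frame and z along the beam; positive offsets increase the
    local defocus for hand_sign = +1.
    """
    return float(hand_sign * (rotation_matrix(euler) @ np.asarray(center, float))[2])


def local_mean_defocus(particle_defocus: float, ldfv: float) -> float:
    """LDF = PDF + LDFV (Å): the defocus assigned to one block in one image."""
    return particle_defocus + ldfv


# --------------------------------------------------------------------------
# symmetry expansion
# --------------------------------------------------------------------------

def expand_by_symmetry(table: ParticleTable, group: SymmetryGroup) -> ParticleTable:
    """Replicate each record once per symmetry operator.

    A symmetric object looks identical after any group rotation G, so the
    record with orientation R also images the asymmetric unit at orientation
    R @ G. Expanded records keep the parent's shift/defocus and are annotated
    with (particle_id, sym_op).
    """
    rows = []
    for pid, rec in enumerate(table.records()):
        r_base = rotation_matrix(rec.euler)
        for gid, g in enumerate(group.matrices):
            rot, tilt, psi = euler_from_matrix(r_base @ g)
            row = dict(rot=rot, tilt=tilt, psi=psi,
                       shift_x=rec.shift[0], shift_y=rec.shift[1],
                       defocus=rec.particle_defocus, hand_sign=rec.hand_sign,
                       image_index=rec.image_index, particle_id=pid, sym_op=gid)
            rows.append(row)
    import pandas as pd
    return ParticleTable(pd.DataFrame(rows))


# --------------------------------------------------------------------------
# sub-image extraction
# --------------------------------------------------------------------------

def extract_block_images(stack: ImageStack, expanded_table: ParticleTable,
                         block: BlockSpec,
                         hand_sign: int | None = None
                         ) -> tuple[ImageStack, ParticleTable]:
    """Window out each record's view of one block and assign its LDF.

    The block centre projects to ``centre + (R c)_xy / apix + shift_px`` in
    the full image; a ``sub_box`` window is cropped about the nearest pixel
    (windows running off the edge are padded with the image mean and the
    record flagged). The residual sub-pixel offset is carried in the record's
    shift and the record defocus becomes the block's local mean defocus.
    """
    block.check_fits(stack.voxel_size)
    apix = stack.voxel_size
    n, sb = stack.box, block.sub_box
    images, rows = [], []
    for rec in expanded_table.records():
        sign = rec.hand_sign if hand_sign is None else hand_sign
        rmat = rotation_matrix(rec.euler)
        proj = rmat @ np.asarray(block.center, float)   # imaging-frame Å
        cx = n // 2 + (proj[0] + rec.shift[0]) / apix
        cy = n // 2 + (proj[1] + rec.shift[1]) / apix
        ix, iy = int(round(cx)), int(round(cy))
        x0, y0 = ix - sb // 2, iy - sb // 2
        img = stack.data[rec.image_index]
        padded = not (0 <= x0 and x0 + sb <= n and 0 <= y0 and y0 + sb <= n)
        if padded:
            frame = np.full((sb, sb), float(img.mean()), dtype=np.float32)
            ys = slice(max(y0, 0), min(y0 + sb, n))
            xs = slice(max(x0, 0), min(x0 + sb, n))
            frame[ys.start - y0:ys.stop - y0, xs.start - x0:xs.stop - x0] = \
                img[ys, xs]
            sub = frame
        else:
            sub = img[y0:y0 + sb, x0:x0 + sb]
        ldfv = sign * proj[2]
        rows.append(dict(rot=rec.euler[0], tilt=rec.euler[1], psi=rec.euler[2],
                         shift_x=(cx - ix) * apix, shift_y=(cy - iy) * apix,
                         defocus=local_mean_defocus(rec.particle_defocus, ldfv),
                         hand_sign=sign, image_index=len(images),
                         flag=int(padded), **rec.annotations))
        images.append(np.asarray(sub, dtype=np.float32))
    import pandas as pd
    return (ImageStack(np.stack(images), apix),
            ParticleTable(pd.DataFrame(rows)))


def extract_block_volume(volume: VolumeGrid, block: BlockSpec) -> VolumeGrid:
    """Resample a spherical block out of a full volume into its sub-box frame
    (block centre at ``sub_box // 2``); used for reference block densities."""
    block.check_fits(volume.voxel_size)
    sb, apix = block.sub_box, volume.voxel_size
    ax = (np.arange(sb) - sb // 2) * apix
    zz, yy, xx = np.meshgrid(ax, ax, ax, indexing="ij")
    pts = np.stack([xx.ravel(), yy.ravel(), zz.ravel()])  # (x,y,z) Å, block frame
    pts_full = (pts + np.asarray(block.center, float)[:, None]) / apix \
        + volume.n // 2
    vals = sample_volume(volume.data.astype(np.float64), pts_full)
    out = vals.reshape(sb, sb, sb)
    r2 = xx ** 2 + yy ** 2 + zz ** 2
    out[r2 > block.radius ** 2] = 0.0
    return VolumeGrid(out, apix)


# --------------------------------------------------------------------------
# local refinement
# --------------------------------------------------------------------------

def _project_volume(volume: VolumeGrid, euler: tuple[float, float, float]) -> np.ndarray:
    from ._geometry import rotate_volume_data
    rot = rotate_volume_data(volume.data.astype(np.float64), rotation_matrix(euler))
    return rot.sum(axis=0)


def _band_mask(n: int, apix: float, band: tuple[float, float]) -> np.ndarray:
    f = np.fft.fftfreq(n, d=apix)
    s = np.hypot(f[:, None], f[None, :])
    return (s >= band[0]) & (s <= min(band[1], 0.5 / apix))


def local_refine(sub_stack: ImageStack, sub_table: ParticleTable,
                 block_volume: VolumeGrid, optics: OpticsModel,
                 angle_range: float = 2.0, angle_step: float = 1.0,
                 shift_range: float = 3.0, shift_step: float = 1.0,
                 band: tuple[float, float] = (1 / 40.0, 1 / 6.0)
                 ) -> ParticleTable:
    """Exhaustive local grid search of orientations and shifts per record.

    The objective is the normalised cross-correlation, over a frequency
    band, between the phase-flipped sub-image and the CTF-amplitude-weighted
    projection of the block volume. ``angle_range/step`` are in degrees
    (applied to all three Euler angles), ``shift_range/step`` in pixels.
    Empty search ranges return the table unchanged.
    """
    if angle_range < 0 or shift_range < 0:
        raise ValueError("search ranges must be non-negative")
    apix = sub_stack.voxel_size
    opt = optics.with_pixel_size(apix)
    sb = sub_stack.box
    mask = _band_mask(sb, apix, band)
    deltas = (np.arange(-angle_range, angle_range + 0.5 * angle_step, angle_step)
              if angle_range >= angle_step > 0 else np.array([0.0]))
    shifts = (np.arange(-shift_range, shift_range + 0.5 * shift_step, shift_step)
              if shift_range >= shift_step > 0 else np.array([0.0]))
    fy = np.fft.fftfreq(sb)[:, None]
    fx = np.fft.fftfreq(sb)[None, :]

    out = sub_table.df.copy()
    for i, rec in enumerate(sub_table.records()):
        ctf = ctf_2d(opt, CTFParams(rec.particle_defocus), (sb, sb))
        img_ft = phase_flip(np.fft.fft2(sub_stack.data[i].astype(float)), ctf)
        img_ft = img_ft * np.exp(2j * np.pi * (fx * rec.shift[0] / apix
                                               + fy * rec.shift[1] / apix))
        wctf = np.abs(ctf) * mask
        best = (-np.inf, rec.euler, (0.0, 0.0))
        for da in deltas:
            for db in deltas:
                for dc in deltas:
                    euler = (rec.euler[0] + da, min(max(rec.euler[1] + db, 0.0),
                                                    180.0), rec.euler[2] + dc)
                    proj_ft = np.fft.fft2(_project_volume(block_volume, euler))
                    ref = wctf * proj_ft
                    rnorm = np.linalg.norm(ref[mask])
                    if rnorm == 0:
                        continue
                    for sx in shifts:
                        for sy in shifts:
                            ramp = np.exp(2j * np.pi * (fx * sx + fy * sy))
                            cand = img_ft * ramp
                            score = float(np.real(np.vdot(ref[mask], cand[mask])))
                            score /= rnorm * (np.linalg.norm(cand[mask]) + 1e-300)
                            if score > best[0]:
                                best = (score, euler,
                                        (rec.shift[0] + sx * apix,
                                         rec.shift[1] + sy * apix))
        _, euler, shift = best
        out.loc[i, ["rot", "tilt", "psi"]] = euler
        out.loc[i, ["shift_x", "shift_y"]] = shift
    return ParticleTable(out)


# --------------------------------------------------------------------------
# block reconstruction and reassembly
# --------------------------------------------------------------------------

def reconstruct_block(sub_stack: ImageStack, sub_table: ParticleTable,
                      optics: OpticsModel, pad_factor: int = 2,
                      wiener_floor: float = 1e-4) -> VolumeGrid:
    """Reconstruct one block from its sub-images with per-record LDF defoci
    (already stored in the sub-table's defocus column by extraction)."""
    return reconstruct(sub_stack, sub_table, optics, defocus_source="true",
                       pad_factor=pad_factor, wiener_floor=wiener_floor)


def combine_blocks(block_volumes: list[VolumeGrid], block_set: BlockSet,
                   full_box: int, voxel_size: float) -> VolumeGrid:
    """Reassemble block volumes into the full frame.

    Every voxel within ``r_keep`` of its nearest block centre copies that
    block's (tri-linearly resampled) value. Outside the kept cores, blocks
    within ``r_keep + r_blend`` contribute with weights linear in
    ``distance - r_keep`` over ``r_blend``, normalised to sum to one; voxels
    beyond every blend region fall back to the nearest block.
    """
    if len(block_volumes) != len(block_set.blocks):
        raise ValueError("one volume per block required")
    centers = block_set.centers()
    ax = (np.arange(full_box) - full_box // 2) * voxel_size
    zz, yy, xx = np.meshgrid(ax, ax, ax, indexing="ij")
    pts = np.stack([xx.ravel(), yy.ravel(), zz.ravel()])   # (x,y,z) Å
    npts = pts.shape[1]
    dists = np.empty((len(centers), npts))
    samples = np.empty((len(centers), npts))
    for j, (vol, block) in enumerate(zip(block_volumes, block_set.blocks)):
        local = (pts - centers[j][:, None]) / voxel_size + block.sub_box // 2
        samples[j] = sample_volume(vol.data.astype(np.float64), local)
        dists[j] = np.linalg.norm(pts - centers[j][:, None], axis=0)

    nearest = np.argmin(dists, axis=0)
    w = np.clip(1.0 - (dists - block_set.r_keep) / block_set.r_blend, 0.0, 1.0)
    wsum = w.sum(axis=0)
    out = np.take_along_axis(samples, nearest[None], axis=0)[0]  # fallback
    ok = wsum > 0
    out[ok] = (w[:, ok] * samples[:, ok]).sum(axis=0) / wsum[ok]
    keep = np.take_along_axis(dists, nearest[None], axis=0)[0] <= block_set.r_keep
    out[keep] = np.take_along_axis(samples, nearest[None], axis=0)[0][keep]
    return VolumeGrid(out.reshape(full_box, full_box, full_box), voxel_size)


def symmetrize(volume: VolumeGrid, group: SymmetryGroup) -> VolumeGrid:
    """Average the volume over all group rotations (tri-linear sampling)."""
    if len(group) == 1:
        return volume.copy()
    n, apix = volume.n, volume.voxel_size
    ax = np.arange(n, dtype=float) - n // 2
    zz, yy, xx = np.meshgrid(ax, ax, ax, indexing="ij")
    pts = np.stack([xx.ravel(), yy.ravel(), zz.ravel()])
    acc = np.zeros(pts.shape[1])
    data = volume.data.astype(np.float64)
    for g in group.matrices:
        rotated = g @ pts + n // 2
        acc += sample_volume(data, rotated)
    return VolumeGrid((acc / len(group)).reshape(n, n, n), apix)
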