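"""Volumes, image stacks and particle metadata.

Containers
----------
:class:`VolumeGrid`
    A cubic real-space density map with a physical voxel size, stored and
    exchanged as an MRC2014 mode-2 (32-bit float) file.
:class:`ImageStack`
    A stack of square real-valued particle images sharing one pixel size.
:class:`ParticleRecord` / :class:`ParticleTable`
    Per-particle orientation (ZYZ intrinsic Euler angles, degrees), in-plane
    shift (Å), particle defocus (Å, underfocus positive) and handedness sign,
    stored as a single-block STAR-dialect text table so that standard cryo-EM
    tooling can inspect it.

Coordinate conventions used throughout the package:

* voxel/pixel ``(0, 0, ...)`` is the array origin; the rotation centre is the
  integer grid centre ``N // 2`` (the FFT centre for even ``N``);
* shifts are expressed in Å relative to that centre, positive shift meaning
  the object centre lies at ``centre + shift/voxel_size`` pixels;
* the beam travels along +z of the imaging frame; underfocus is positive.
"""

from __future__ import annotations

import io
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("blockrec")

__all__ = [
    "FormatError",
    "SchemaError",
    "VolumeGrid",
    "ImageStack",
    "ParticleRecord",
    "ParticleTable",
    "read_volume",
    "write_volume",
    "read_stack",
    "write_stack",
    "read_particles",
    "write_particles",
    "load_config",
    "configure_logging",
]


class FormatError(ValueError):
    """Raised for malformed or unsupported on-disk volume/stack files."""


class SchemaError(ValueError):
    """Raised when a particle table lacks a mandatory column."""


def configure_logging(verbose: bool = False) -> None:
    """Route package logging to stderr; ``verbose`` enables DEBUG records."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(logging.DEBUG if verbose else logging.INFO)


def load_config(path: str | Path) -> dict:
    """Read a YAML (or plain ``key: value`` INI-style) config file to a dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        return {}
    if not isinstance(cfg, dict):
        raise FormatError(f"config file {path} must contain a mapping")
    return cfg


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------

@dataclass
class VolumeGrid:
    """Cubic density grid with an even edge length and positive voxel size."""

    data: np.ndarray            # indexed [z, y, x]
    voxel_size: float           # Å per voxel
    origin: np.ndarray | None = None   # Å; defaults to the grid centre N//2

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3 or len(set(self.data.shape)) != 1:
            raise FormatError(f"volume must be cubic, got shape {self.data.shape}")
        if self.data.shape[0] % 2:
            raise FormatError("volume edge length must be even")
        if not (np.isfinite(self.voxel_size) and self.voxel_size > 0):
            raise FormatError("voxel_size must be finite and positive")
        if self.origin is None:
            self.origin = np.full(3, self.n // 2 * self.voxel_size, dtype=float)

    @property
    def n(self) -> int:
        return self.data.shape[0]

    def copy(self) -> "VolumeGrid":
        return VolumeGrid(self.data.copy(), self.voxel_size, np.array(self.origin))


@dataclass
class ImageStack:
    """M square images of identical shape and pixel size (Å/px)."""

    data: np.ndarray            # indexed [image, y, x]
    voxel_size: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim == 2:
            self.data = self.data[None]
        if self.data.ndim != 3 or self.data.shape[1] != self.data.shape[2]:
            raise FormatError(f"stack images must be square, got {self.data.shape}")
        if self.data.shape[0] < 1:
            raise FormatError("stack must hold at least one image")
        if not (np.isfinite(self.voxel_size) and self.voxel_size > 0):
            raise FormatError("voxel_size must be finite and positive")

    def __len__(self) -> int:
        return self.data.shape[0]

    @property
    def box(self) -> int:
        return self.data.shape[1]


@dataclass
class ParticleRecord:
    """Orientation/shift/defocus metadata for a single particle image.

    ``euler`` is (rot, tilt, psi) in degrees, ZYZ intrinsic; ``shift`` is
    (dx, dy) in Å relative to the box centre; ``particle_defocus`` is the
    defocus of the plane through the particle's centre of mass in Å
    (underfocus positive); ``hand_sign`` fixes the sign relating +z offsets
    to defocus increases.
    """

    euler: tuple[float, float, float]
    shift: tuple[float, float] = (0.0, 0.0)
    particle_defocus: float = 0.0
    hand_sign: int = 1
    image_index: int = 0
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.euler[1] <= 180.0:
            raise ValueError(f"tilt must lie in [0, 180], got {self.euler[1]}")
        if self.hand_sign not in (+1, -1):
            raise ValueError("hand_sign must be +1 or -1")


# STAR tags: mandatory first, optional annotation columns afterwards.
_MANDATORY = ["rot", "tilt", "psi", "shift_x", "shift_y", "defocus", "image_index"]
_OPTIONAL = ["hand_sign", "measured_defocus", "block_id", "sym_op", "particle_id", "flag"]
_TAG_PREFIX = "_brc"


class ParticleTable:
    """Ordered particle metadata backed by a :class:`pandas.DataFrame`."""

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in _MANDATORY if c not in df.columns]
        if missing:
            raise SchemaError(f"particle table missing mandatory column(s): {missing}")
        self.df = df.reset_index(drop=True)
        if "hand_sign" not in self.df.columns:
            self.df["hand_sign"] = 1

    # -- construction -----------------------------------------------------
    @classmethod
    def from_records(cls, records: Iterable[ParticleRecord]) -> "ParticleTable":
        rows = []
        for rec in records:
            row = {
                "rot": rec.euler[0], "tilt": rec.euler[1], "psi": rec.euler[2],
                "shift_x": rec.shift[0], "shift_y": rec.shift[1],
                "defocus": rec.particle_defocus, "image_index": rec.image_index,
                "hand_sign": rec.hand_sign,
            }
            row.update(rec.annotations)
            rows.append(row)
        return cls(pd.DataFrame(rows))

    def records(self) -> Iterator[ParticleRecord]:
        extra = [c for c in self.df.columns if c not in _MANDATORY + ["hand_sign"]]
        for row in self.df.itertuples(index=False):
            d = row._asdict()
            yield ParticleRecord(
                euler=(d["rot"], d["tilt"], d["psi"]),
                shift=(d["shift_x"], d["shift_y"]),
                particle_defocus=d["defocus"],
                hand_sign=int(d.get("hand_sign", 1)),
                image_index=int(d["image_index"]),
                annotations={k: d[k] for k in extra},
            )

    def __len__(self) -> int:
        return len(self.df)

    def copy(self) -> "ParticleTable":
        return ParticleTable(self.df.copy())

    def defoci(self, source: str = "true") -> np.ndarray:
        """Per-record defocus in Å; ``source`` is 'true' or 'measured'."""
        if source in ("true", "table"):
            return self.df["defocus"].to_numpy(float)
        if source == "measured":
            if "measured_defocus" not in self.df.columns:
                raise SchemaError("table has no 'measured_defocus' column")
            return self.df["measured_defocus"].to_numpy(float)
        raise ValueError(f"unknown defocus source {source!r}")


# --------------------------------------------------------------------------
# MRC2014 mode-2 I/O (header: 1024 bytes, 56 int32/float32 words + labels)
# --------------------------------------------------------------------------

_MRC_MODE_FLOAT32 = 2


def _mrc_header(nx: int, ny: int, nz: int, voxel_size: float) -> bytes:
    h = np.zeros(256, dtype="<i4")
    f = h.view("<f4")
    h[0:3] = (nx, ny, nz)
    h[3] = _MRC_MODE_FLOAT32
    h[7:10] = (nx, ny, nz)                     # mx, my, mz
    f[10:13] = (nx * voxel_size, ny * voxel_size, nz * voxel_size)  # cella
    f[13:16] = 90.0                            # cellb
    h[16:19] = (1, 2, 3)                       # mapc, mapr, maps
    f[19:22] = (0.0, 0.0, 0.0)                 # dmin/dmax/dmean placeholders
    h[23] = 0                                  # nsymbt
    h[52] = int.from_bytes(b"MAP ", "little")
    h[53] = int.from_bytes(b"\x44\x44\x00\x00", "little")  # LE machine stamp
    return h.tobytes()


def _write_mrc(data: np.ndarray, voxel_size: float, path: str | Path) -> None:
    data = np.ascontiguousarray(data, dtype="<f4")
    if not np.all(np.isfinite(data)):
        raise FormatError("refusing to write non-finite densities")
    nz, ny, nx = data.shape
    header = bytearray(_mrc_header(nx, ny, nz, voxel_size))
    stats = np.array([data.min(), data.max(), data.mean()], dtype="<f4")
    header[19 * 4:22 * 4] = stats.tobytes()
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(data.tobytes())


def _read_mrc(path: str | Path) -> tuple[np.ndarray, float]:
    raw = Path(path).read_bytes()
    if len(raw) < 1024:
        raise FormatError(f"{path}: truncated MRC header")
    if raw[208:212] not in (b"MAP ", b"MAP\x00"):
        raise FormatError(f"{path}: missing MRC2014 'MAP ' signature")
    # machine stamp decides endianness of the numeric header words
    order = ">" if raw[212] == 0x11 else "<"
    h = np.frombuffer(raw[:1024], dtype=f"{order}i4")
    f = np.frombuffer(raw[:1024], dtype=f"{order}f4")
    nx, ny, nz, mode = int(h[0]), int(h[1]), int(h[2]), int(h[3])
    if mode != _MRC_MODE_FLOAT32:
        raise FormatError(f"{path}: only MRC mode 2 (float32) supported, got {mode}")
    nsymbt = int(h[23])
    mx = int(h[7]) or nx
    voxel_size = float(f[10]) / mx if f[10] > 0 else 1.0
    count = nx * ny * nz
    start = 1024 + nsymbt
    data = np.frombuffer(raw[start:start + 4 * count], dtype=f"{order}f4")
    if data.size != count:
        raise FormatError(f"{path}: data block shorter than header promises")
    return data.reshape(nz, ny, nx).astype(np.float32), voxel_size


def read_volume(path: str | Path) -> VolumeGrid:
    """Read a cubic MRC mode-2 volume; non-cubic files are a format error."""
    data, voxel_size = _read_mrc(path)
    if len(set(data.shape)) != 1:
        raise FormatError(f"{path}: volume is not cubic ({data.shape})")
    return VolumeGrid(data, voxel_size)


def write_volume(vol: VolumeGrid, path: str | Path) -> None:
    _write_mrc(vol.data, vol.voxel_size, path)


def read_stack(path: str | Path) -> ImageStack:
    """Read an MRC mode-2 image stack (nz = number of images)."""
    data, voxel_size = _read_mrc(path)
    return ImageStack(data, voxel_size)


def write_stack(stack: ImageStack, path: str | Path) -> None:
    _write_mrc(stack.data, stack.voxel_size, path)


# --------------------------------------------------------------------------
# STAR-dialect particle table
# --------------------------------------------------------------------------

def write_particles(table: ParticleTable, path: str | Path) -> None:
    """Write the table as one STAR data block with a loop_ of named tags."""
    df = table.df
    if df.isna().any().any():
        raise SchemaError("refusing to write a table containing NaNs")
    cols = [c for c in _MANDATORY + _OPTIONAL if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    buf = io.StringIO()
    buf.write("\ndata_particles\n\nloop_\n")
    for i, c in enumerate(cols, start=1):
        buf.write(f"{_TAG_PREFIX}_{c} #{i}\n")
    df[cols].to_csv(buf, sep="\t", header=False, index=False,
                    float_format="%.8g", lineterminator="\n")
    Path(path).write_text(buf.getvalue())


def read_particles(path: str | Path) -> ParticleTable:
    """Parse a single-block STAR-dialect table back into a ParticleTable."""
    lines = Path(path).read_text().splitlines()
    cols: list[str] = []
    body_start = None
    in_loop = False
    for i, raw in enumerate(lines):
        line = raw.strip()
        if not line or line.startswith("#") or line.startswith("data_"):
            continue
        if line == "loop_":
            in_loop = True
            continue
        if in_loop and line.startswith("_"):
            tag = line.split()[0]
            name = tag[len(_TAG_PREFIX) + 1:] if tag.startswith(_TAG_PREFIX + "_") \
                else tag.lstrip("_")
            cols.append(name)
            continue
        if in_loop and cols:
            body_start = i
            break
    if not cols or body_start is None:
        raise SchemaError(f"{path}: no loop_ header / data rows found")
    body = "\n".join(l for l in lines[body_start:] if l.strip())
    df = pd.read_csv(io.StringIO(body), sep=r"\s+", names=cols)
    int_cols = [c for c in ("image_index", "hand_sign", "block_id", "sym_op",
                            "particle_id", "flag") if c in df.columns]
    df[int_cols] = df[int_cols].astype(int)
    return ParticleTable(df)
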