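"""The empirical depth-of-field resolution limit and handedness
determination.

The limiting spatial frequency of a conventional single-defocus
reconstruction of an object of thickness t imaged with electrons of
wavelength lambda is

    d ~ sqrt(2 / (t lambda))      [Å^-1]

NOTE on units: d is a *frequency*; the corresponding real-space resolution,
which is what this module returns, is 1/d = sqrt(t lambda / 2) in Å. Both
quantities are conventionally called "resolution", so callers should check
which one they hold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .iometa import ImageStack, ParticleTable, VolumeGrid
from .optics import OpticsModel, electron_wavelength

__all__ = [
    "LimitQuery",
    "IndeterminateHandednessError",
    "empirical_limit",
    "limiting_frequency",
    "handedness_test",
]


@dataclass(frozen=True)
class LimitQuery:
    """Object thickness t (Å) and acceleration voltage (kV).

    For spherical particles t is the diameter; for non-spherical objects it
    is taken as the extent along the beam axis (either reading is accepted —
    for most particles they coincide to within the accuracy of the formula).
    """

    t: float
    voltage: float

    def __post_init__(self) -> None:
        if self.t <= 0:
            raise ValueError("thickness must be positive")
        if self.voltage <= 0:
            raise ValueError("voltage must be positive")


class IndeterminateHandednessError(RuntimeError):
    """Raised when the two handedness choices give indistinguishable maps."""


def limiting_frequency(t: float, voltage: float,
                       wavelength: float | None = None) -> float:
    """d = sqrt(2/(t lambda)) in Å^-1; ``wavelength`` (Å) overrides the
    voltage-derived value for scaled regimes."""
    LimitQuery(t, voltage)
    lam = electron_wavelength(voltage) if wavelength is None else wavelength
    return math.sqrt(2.0 / (t * lam))


def empirical_limit(t: float, voltage: float,
                    wavelength: float | None = None) -> float:
    """Resolution limit 1/d = sqrt(t lambda / 2) in Å.

    Scales as sqrt(t) at fixed voltage and sqrt(lambda) at fixed t; lower
    voltages (longer wavelengths) give coarser limits. As t -> 0 the limit
    vanishes: small particles are not depth-of-field limited.
    """
    return 1.0 / limiting_frequency(t, voltage, wavelength)


def handedness_test(stack: ImageStack, table: ParticleTable, block_set,
                    reference: VolumeGrid, optics: OpticsModel,
                    threshold: float = 0.5) -> int:
    """Determine handedness by comparing both signs of the block offsets.

    Runs the block pipeline (extract -> per-block reconstruction -> combine)
    twice, once with the local mean defoci computed as PDF + d and once as
    PDF - d, and returns the sign whose assembled map crosses ``threshold``
    in its FSC against ``reference`` at the finer resolution. If the two
    crossings fall within one Fourier shell of each other the test is
    inconclusive (small objects show no usable depth-of-field contrast) and
    :class:`IndeterminateHandednessError` is raised.
    """
    from .blocks import combine_blocks, extract_block_images, reconstruct_block
    from .reconstruct import fsc, resolution_at

    freqs = {}
    for sign in (+1, -1):
        vols = []
        for block in block_set.blocks:
            sub_stack, sub_table = extract_block_images(stack, table, block,
                                                        hand_sign=sign)
            vols.append(reconstruct_block(sub_stack, sub_table, optics))
        combined = combine_blocks(vols, block_set, reference.n,
                                  reference.voxel_size)
        res = resolution_at(fsc(combined, reference), threshold)
        freqs[sign] = 1.0 / res
    shell = 1.0 / (reference.n * reference.voxel_size)
    if abs(freqs[+1] - freqs[-1]) < shell:
        raise IndeterminateHandednessError(
            "handedness indeterminate: resolutions within one shell "
            f"({1/freqs[+1]:.2f} Å vs {1/freqs[-1]:.2f} Å)")
    return +1 if freqs[+1] > freqs[-1] else -1
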