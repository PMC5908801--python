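"""Shared fixtures.

The heavy end-to-end depth-of-field benchmark is session-scoped: it simulates
one noise-free layered dataset of a large phantom in a regime where the
empirical resolution limit falls mid-band, then reconstructs it
conventionally and with blocks under both handedness signs. Several
acceptance-level tests read different aspects of the same run.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import blockrec as br

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_optics():
    return br.OpticsModel(voltage=300.0, cs=2.7, amplitude_contrast=0.07,
                          pixel_size=2.0)


@pytest.fixture(scope="session")
def small_phantom():
    return br.make_phantom(diameter=70.0, n_atoms=300, voxel_size=2.0,
                           box=48, seed=1)


# ---------------------------------------------------------------------------
# desk-scale Ewald benchmark (shared by several acceptance tests)
# ---------------------------------------------------------------------------

BENCH = dict(
    box=96,
    apix=2.0,
    diameter=120.0,          # Å; the object thickness t
    n_atoms=1200,
    # wavelength chosen so the empirical limit sqrt(t*lambda/2) = 5.0 Å,
    # i.e. 2.5 voxels — mid-band for this box
    wavelength=2 * 5.0 ** 2 / 120.0,
    # defocus scaled with the exaggerated wavelength so chi = pi*lambda*df*s^2
    # stays at physical magnitudes (CTF resolvable on this grid)
    defocus_range=(150.0, 250.0),
    layer=2.0,               # Å; sub-voxel slabs approximate the continuum
    euler_step=10.0,
    seed=11,
)


def benchmark_block_set() -> br.BlockSet:
    a1, a2 = 45.0, 32.0
    centers = [(0.0, 0.0, 0.0)]
    for i in range(3):
        for s in (+1.0, -1.0):
            c = [0.0, 0.0, 0.0]
            c[i] = s * a1
            centers.append(tuple(c))
    centers += [(sx * a2, sy * a2, sz * a2)
                for sx in (1, -1) for sy in (1, -1) for sz in (1, -1)]
    blocks = [br.BlockSpec(c, radius=40.0, sub_box=48) for c in centers]
    return br.BlockSet(blocks, "C1", r_keep=18.0, r_blend=14.0)


@pytest.fixture(scope="session")
def ewald_benchmark():
    b = BENCH
    optics = br.OpticsModel(voltage=300.0, cs=0.0, amplitude_contrast=0.07,
                            pixel_size=b["apix"], wavelength=b["wavelength"])
    phantom = br.make_phantom(b["diameter"], b["n_atoms"], b["apix"],
                              b["box"], seed=b["seed"])
    config = br.SimulationConfig(layer_thickness=b["layer"],
                                 defocus_range=b["defocus_range"],
                                 euler_step=b["euler_step"], psi_step=360.0,
                                 seed=b["seed"])
    stack, table = br.simulate_dataset(phantom, config, optics)

    conventional = br.reconstruct(stack, table, optics, "true")
    res_conv = br.resolution_at(br.fsc(conventional, phantom.volume), 0.5)

    block_set = benchmark_block_set()
    res_block = {}
    for sign in (+1, -1):
        vols = []
        for block in block_set.blocks:
            ss, st = br.extract_block_images(stack, table, block,
                                             hand_sign=sign)
            vols.append(br.reconstruct_block(ss, st, optics))
        combined = br.combine_blocks(vols, block_set, b["box"], b["apix"])
        res_block[sign] = br.resolution_at(br.fsc(combined, phantom.volume), 0.5)

    return dict(
        optics=optics, phantom=phantom, stack=stack, table=table,
        block_set=block_set,
        limit=br.empirical_limit(b["diameter"], 300.0,
                                 wavelength=b["wavelength"]),
        res_conventional=res_conv,
        res_block_plus=res_block[+1],
        res_block_minus=res_block[-1],
    )
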