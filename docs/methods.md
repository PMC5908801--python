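# Methods

## The problem

Single-particle reconstruction conventionally treats each cryo-EM image as a
projection of the object filtered by one contrast transfer function (CTF) at
one defocus — the central-projection approximation. A particle of thickness
`t` along the beam, however, spans a defocus range of `t`: its upper and
lower parts are imaged at measurably different defoci. Equivalently, the
Ewald sphere is not flat. The error grows with spatial frequency `s` (the
extra wave phase of a layer at height `z` is `pi * lambda * z * s^2`), so the
approximation imposes a size-dependent resolution limit

    d ~ sqrt(2 / (t * lambda))        (limiting frequency, 1/Å)
    1/d = sqrt(t * lambda / 2)        (resolution, Å)

with `lambda` the relativistic electron wavelength. `limits.empirical_limit`
returns the resolution `1/d`; both quantities are conventionally called
"resolution", so the API docstrings flag the units prominently. For a 1200 Å
particle at 300 kV the limit is ~3.4 Å; particles under ~300 Å are unaffected
at resolutions reported to date.

## Block-based reconstruction

The package implements the block-based correction: split the object into
blocks small enough that a single defocus per block is accurate. For particle
`i` with orientation matrix `R_i` (intrinsic-ZYZ Euler angles; `R_i` maps the
reference frame to the imaging frame, beam along +z) and block `j` centred at
`c_j` (Å, reference frame):

    LDFV_ij = hand_sign * (R_i @ c_j)_z      # beam-axis offset of the block
    LDF_ij  = PDF_i + LDFV_ij                # local mean defocus

where `PDF_i` is the particle defocus — the defocus of the plane through the
particle's centre of mass, underfocus positive. Each block is windowed out of
every (symmetry-expanded) image at its projected centre, reconstructed by
direct Fourier inversion using `LDF_ij` as the defocus, and the block maps
are reassembled in real space and symmetrised. No Ewald-corrected insertion
is performed anywhere; the correction is entirely in the per-block defoci.

Key choices, where the design was genuinely open:

* **Block geometry.** Spherical blocks given by centres and radii. Counts and
  placement are user configuration; the bundled benchmark uses 15 blocks
  (centre, six face positions, eight corner positions) for a solid 120 Å
  sphere.
* **Reassembly.** A voxel within `r_keep` of its nearest block centre copies
  that block's tri-linearly resampled value. Outside the kept cores, blocks
  within `r_keep + r_blend` are averaged with weights `max(0, 1 - (d_j -
  r_keep)/r_blend)`, normalised to sum to one; voxels beyond every blend
  region fall back to the nearest block. This "linear-in-distance blend" is
  one concrete reading of distance-based tri-linear interpolation between
  neighbouring blocks; any blend that is exact in the kept cores and
  partition-of-unity outside them behaves equivalently at the tested scales.
* **Sub-pixel positions.** Block windows are cropped at the nearest integer
  pixel; the residual sub-pixel offset is carried in the record's shift
  metadata and applied as a Fourier phase ramp at insertion, avoiding a
  second real-space interpolation.
* **Density above/below a block is not subtracted.** Out-of-block density in
  a window is orientation-dependent clutter; the 3-D average over
  orientations suppresses it.

## Forward model (simulator)

`simulate.simulate_image_layered` produces depth-of-field images directly
from the definition: rotate the density (tri-linear resampling), partition it
into slabs along the beam (slab mid-planes at integer multiples of the layer
thickness, the `z = 0` plane through the grid centre; partial end slabs
allowed), project each slab, filter by the CTF at `PDF + hand_sign * z_k`,
and sum. The defaults are standard imaging conditions: 2 nm layers and
particle defoci uniform in 1.0–3.0 um. A single slab reproduces the
single-defocus (flat) simulator exactly, which serves as the no-effect
control. Noise, when requested, is plain additive Gaussian scaled to the
image RMS; the resolution-limit experiments are noise-free by construction.
The simulator rotates volumes with tri-linear interpolation, matching the
interpolation order used everywhere else.

Phantoms are sums of isotropic Gaussian pseudo-atoms (default width 0.75
voxels) drawn uniformly in a sphere — or a spherical shell
(`inner_fraction > 0`) to emulate a capsid — hard-masked at the stated
diameter and deterministic per seed. What the generator does **not** emulate:
structural noise (solvent, carbon film), detector MTF/DQE, beam-induced
motion, astigmatism, and amplitude decay envelopes. Passing tests therefore
demonstrate the geometry and defocus bookkeeping of the method, not its
behaviour under experimental noise.

## CTF and defocus measurement

One CTF convention is shared by the simulator and the reconstruction
(underfocus positive, no astigmatism):

    CTF(s) = -sqrt(1 - A^2) sin(chi) - A cos(chi)
    chi(s) = pi lambda df s^2 - (pi/2) Cs lambda^3 s^4 + phase_shift

`optics.fit_defocus` measures defocus the conventional way: the rotationally
averaged power spectrum is background-subtracted (moving-minimum envelope
followed by box smoothing, on a log scale) and correlated against the
shell-averaged model `CTF^2` over a frequency band (default 1/30–1/5 1/Å) on
a defocus grid, with parabolic refinement of the optimum. The model profile
is averaged *within* each shell exactly as the data are, which keeps the fit
faithful where rings oscillate faster than the shell width. A fit is rejected
(`DefocusFitError`) when the best correlation is below 0.3 or when it is not
an outlier (z < 3.3) of the correlation scores over a broad fixed defocus
grid — pure noise correlates moderately with *some* member of a large
oscillatory model family, but its best score is not exceptional within the
family. On noise-free layered images of a centred 300 Å phantom the fitted
defocus lands on the centre-of-mass layer within a few nm (median ~2–3 nm,
bound 8 nm in the acceptance run).

## Reconstruction

Direct Fourier inversion: each image is zero-padded (pad factor 2), its
centred FFT phase-corrected for the recorded shift, weighted by its CTF, and
spread onto the padded 3-D grid with a tri-linear kernel along the central
section `R^T (kx, ky, 0)`; weights accumulate `CTF^2` times the kernel. The
grid is normalised by `weights + wiener_floor * max(weights)` and inverse
transformed.

* **Wiener floor.** Default `1e-4` of the maximum weight. The floor must stay
  well below the smallest `CTF^2` of interest — at low frequency `|CTF| ~ A =
  0.07`, so `CTF^2 ~ 5e-3` times coverage; a floor of `1e-2`, plausible at
  first sight, dominates there and measurably depresses low-frequency
  agreement with the reference on noise-free data.
* **Hermitian symmetry** is preserved by zeroing the padded Nyquist row and
  column before insertion; the accumulated grid is then conjugate-symmetric
  and the inverse transform is real to round-off.
* **FSC** uses one-voxel shells and normalised complex correlation;
  resolution is read at the first downward crossing of the threshold (0.5
  against a reference model, 0.143 between half-maps) with linear
  interpolation, returning the Nyquist resolution when the curve never
  crosses. Degenerate empty shells report zero correlation.
* **CTF sampling caveat.** On small boxes with micrometre defoci the CTF
  oscillates faster than the Fourier grid spacing; reconstruction quality
  then degrades for reasons unrelated to depth of field. The benchmark
  regimes below keep `chi` resolvable by scaling defocus together with the
  wavelength.

## Desk-scale benchmark regimes

The full-scale regime of the resolution-limit experiments (thousands of Å of
object in ≥500-voxel boxes) is out of reach of a test suite, so the bundled
benchmark applies an exact rescaling of the physics: the limit formula and
the layer phase error depend on the products `t * lambda` and `lambda * df *
s^2`, so an exaggerated wavelength with correspondingly reduced defocus
reproduces the same mathematics in a small box. Concretely: a 120 Å phantom
in a 96-voxel box at 2 Å/px, `lambda = 0.4167 Å` chosen so the predicted
limit is 5.0 Å (2.5 voxels), defoci 150–250 Å so `chi` stays at physical
magnitudes, and one-voxel layers to approximate the continuum. On ~400
noise-free images with exact orientations this yields, in one session:

* conventional reconstruction: FSC-0.5 resolution ~5.1 Å (predicted 5.0 Å);
* flat-simulated control: 4.0 Å (Nyquist — no depth-of-field effect);
* block-based map (15 blocks, correct hand): ~4.05 Å, beating both;
* block-based map with the wrong hand: ~9.3 Å.

The wrong-hand degradation is the handedness test: `limits.handedness_test`
assembles both signs and returns the finer one, declaring the result
indeterminate when the two FSC crossings fall within one Fourier shell (the
situation for small particles with no usable depth-of-field contrast).

## Defocus refinement

When the measured defocus does not represent the particle defocus, the
per-particle defocus is refined cooperatively across blocks: for each
candidate `PDF`, every block is phase-flipped at `LDF = PDF + LDFV` and
scored against the projection of its reference density by the phase residual

    PR_ij = sum_s w(s) cos(delta_theta(s)) / sum_s w(s),   w(s) = |CTF(s)|

summed over blocks (`PR_i = sum_j PR_ij`); the candidate maximising `|PR_i|`
wins, ties resolving toward the current value. The per-pixel `|CTF|` weight
normalised per band is our reading of a per-band "CTF amplitude weight"; with
`CTF == 1` it reduces to the unweighted mean phase agreement. Scoring uses
the absolute value so contrast-inverted data still localise the defocus.
Defaults: 200 nm search span, 10 nm step, band 1/20–1/6 1/Å.

One scale constraint matters at desk size: CTF fringe delocalisation
(`~ lambda * df * s`) must fit inside the block window, as it does in
full-scale data (hundreds of Å of window at 1–3 um). With 96 Å windows this
dictates sub-micrometre defoci; the refinement demonstration therefore runs
at 0.3–0.6 um, where 20 particles mis-recorded by ±80 nm are restored to a
median error of ~1 nm at a 10 nm scan step.

## Numerical conventions

* Arrays are `[z, y, x]`; matrices act on `(x, y, z)` vectors; voxel `(0,0,0)`
  is the array origin and the rotation centre is the integer grid centre
  `N//2` (FFT centre, even `N` enforced).
* Shifts are in Å, "object centre minus box centre"; angles in degrees;
  defocus in Å, underfocus positive.
* All randomness flows through `numpy.random.default_rng(seed)`; identical
  seeds give bit-identical tables and FFT-round-off-identical maps on one
  platform.
* MRC I/O is MRC2014 mode 2 (32-bit float) with both endiannesses accepted on
  read; the particle table is a single-block STAR-dialect text file.

## Known limitations

* Tri-linear gridding without a kernel correction loses a few percent FSC in
  the top shells; the benchmark thresholds account for it.
* The defocus fitter is a bespoke 1-D scheme for synthetic, astigmatism-free
  data; it is not a replacement for a production CTF estimator on
  experimental micrographs.
* `local_refine` is an exhaustive grid search — appropriate for the small
  perturbations it is asked to absorb, combinatorially expensive beyond that.
* Block windows padded at image edges use the image mean, which adds a weak
  artefact for blocks projecting near the boundary; the benchmark geometry
  keeps windows inside the frame.
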