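# blockrec

Block-based single-particle cryo-EM reconstruction that corrects the
depth-of-field (Ewald sphere) effect, together with the layered image
simulator and the resolution-limit calculus needed to demonstrate it on
synthetic data.

## The problem

Conventional single-particle analysis treats every image as a projection
filtered by one CTF at one defocus. A particle of thickness `t` along the
beam actually spans a defocus range of `t`, which limits the attainable
resolution to

    1/d = sqrt(t * lambda / 2)     [Å]

(`lambda` the electron wavelength; `d` the limiting spatial frequency). At
300 kV this is ~3.4 Å for a 1200 Å virus — right where modern maps of large
particles stall. The package implements the block-based correction: split
the object into blocks, assign block `j` in image `i` the *local mean
defocus*

    LDF_ij = PDF_i + LDFV_ij,   LDFV_ij = hand_sign * (R_i c_j)_z

(particle defocus plus the beam-axis offset of the block centre under the
particle's orientation), reconstruct each block separately with its own
defoci, and reassemble the blocks in real space with symmetry. A cooperative
per-particle defocus refinement (maximising the summed block phase residual
`PR_i = sum_j PR_ij` over a defocus scan) and a handedness test (the wrong
sign of `LDFV` gives a visibly worse map) round out the procedure. It is
aimed at people processing large particles — viruses especially — and at
anyone wanting a compact, fully synthetic testbed for Ewald-sphere
corrections.

## Worked example

```python
import blockrec as br

# the regime: a 120 Å particle, wavelength chosen so the predicted limit
# lands at 5.0 Å, defocus scaled to keep the CTF resolvable in a 96-px box
optics  = br.OpticsModel(voltage=300, cs=0.0, amplitude_contrast=0.07,
                         pixel_size=2.0, wavelength=2 * 5.0**2 / 120.0)
phantom = br.make_phantom(diameter=120, n_atoms=1200, voxel_size=2.0,
                          box=96, seed=11)
print(f"predicted limit {br.empirical_limit(120, 300, wavelength=optics.wavelength):.1f} A")

cfg = br.SimulationConfig(layer_thickness=2.0, defocus_range=(150, 250),
                          euler_step=10.0, psi_step=360.0, seed=11)
stack, table = br.simulate_dataset(phantom, cfg, optics)   # 413 images

conv = br.reconstruct(stack, table, optics, "true")
print(f"conventional  {br.resolution_at(br.fsc(conv, phantom.volume), 0.5):.2f} A")

blocks = [br.BlockSpec(c, radius=40, sub_box=48) for c in
          [(0,0,0), (45,0,0), (-45,0,0), (0,45,0), (0,-45,0), (0,0,45),
           (0,0,-45)] + [(sx*32, sy*32, sz*32) for sx in (1,-1)
                         for sy in (1,-1) for sz in (1,-1)]]
bset = br.BlockSet(blocks, "C1", r_keep=18, r_blend=14)
vols = []
for b in bset.blocks:
    ss, st = br.extract_block_images(stack, table, b, hand_sign=+1)
    vols.append(br.reconstruct_block(ss, st, optics))
combined = br.combine_blocks(vols, bset, 96, 2.0)
print(f"block-based   {br.resolution_at(br.fsc(combined, phantom.volume), 0.5):.2f} A")
```

Output from this configuration:

```
predicted limit 5.0 A
conventional  5.11 A
block-based   4.05 A
```

The conventional map stalls at the predicted depth-of-field limit (5.11 vs
5.0 Å) even though orientations and defoci are exact and the data are
noise-free; the block-based map passes it. Re-running the block step with
`hand_sign=-1` gives ~9.3 Å — the handedness signature — and re-simulating
with one slab per image (no depth of field) reconstructs to Nyquist (4.0 Å).

The same pipeline is available as a shell tool:

```
blockrec limit --t 1200 --kv 300
blockrec simulate --diameter 90 --box 64 --apix 2 --step 45 --seed 1 \
         --out stack.mrcs --table particles.star
blockrec reconstruct --stack stack.mrcs --table particles.star --out map.mrc
blockrec block-reconstruct --stack stack.mrcs --table particles.star \
         --blocks blocks.yaml --out block_map.mrc
blockrec fsc --a map.mrc --b block_map.mrc --threshold 0.5
```

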