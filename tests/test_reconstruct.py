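"""Fourier insertion, reconstruction, FSC and resolution read-out."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import blockrec as br
from blockrec._geometry import rotation_matrix, rotate_volume_data


def _band_limited_blob(box=32, apix=2.0, kmax=10, seed=3):
    """Localized band-limited test object (support well inside the box)."""
    rng = np.random.default_rng(seed)
    ft = np.fft.fftn(rng.normal(size=(box, box, box)))
    k = np.fft.fftfreq(box) * box
    r2 = k[:, None, None] ** 2 + k[None, :, None] ** 2 + k[None, None, :] ** 2
    ft[r2 > kmax ** 2] = 0
    v = np.fft.fftshift(np.fft.ifftn(ft).real)
    ax = np.arange(box) - box // 2
    r = np.sqrt(ax[:, None, None] ** 2 + ax[None, :, None] ** 2
                + ax[None, None, :] ** 2)
    v *= np.clip((0.34 * box - r) / 4.0, 0.0, 1.0)
    return br.VolumeGrid(v, apix)


def _project(vol, euler, order=3):
    return rotate_volume_data(vol.data.astype(float), rotation_matrix(euler),
                              order=order).sum(axis=0)


class TestInsertFinalize:
    def test_single_slice_round_trips_through_the_grid(self, rng):
        # insert one centred section at the identity orientation, finalize,
        # and re-project: the image comes back (scaled by the padded z-extent)
        box, apix = 32, 2.0
        vol0 = _band_limited_blob(box, apix)
        img = vol0.data.astype(float).sum(axis=0)
        acc = br.FourierAccumulator(box, apix, 2)
        br.insert_slice(acc, img, (0.0, 0.0, 0.0))
        out = br.finalize(acc, wiener_floor=1e-9)
        reproj = out.data.astype(float).sum(axis=0) * acc.pad_factor
        fa, fb = np.fft.fft2(img), np.fft.fft2(reproj)
        k = np.fft.fftfreq(box) * box
        band = (np.abs(k)[:, None] < 12) & (np.abs(k)[None, :] < 12)
        np.testing.assert_allclose(fb[band], fa[band],
                                   atol=2e-2 * np.abs(fa).max())

    def test_duplicate_slices_change_nothing(self):
        box, apix = 32, 2.0
        vol0 = _band_limited_blob(box, apix)
        img = vol0.data.astype(float).sum(axis=0)
        acc1 = br.FourierAccumulator(box, apix, 2)
        br.insert_slice(acc1, img, (0.0, 0.0, 0.0))
        one = br.finalize(acc1, 1e-9)
        acc2 = br.FourierAccumulator(box, apix, 2)
        for _ in range(2):
            br.insert_slice(acc2, img, (0.0, 0.0, 0.0))
        two = br.finalize(acc2, 1e-9)
        np.testing.assert_allclose(two.data, one.data, atol=2e-5)

    def test_orthogonal_sections_of_gaussian_ball_match_analytic_transform(self):
        # central sections of a Gaussian ball are Gaussians; check inserted
        # grid values on each section against the closed form
        box, apix, sig = 32, 1.0, 3.0
        ax = np.arange(box) - box // 2
        r2 = (ax[:, None, None] ** 2 + ax[None, :, None] ** 2
              + ax[None, None, :] ** 2)
        ball = np.exp(-r2 / (2 * sig ** 2))
        proj = ball.sum(axis=0)
        acc = br.FourierAccumulator(box, apix, 2)
        eulers = [(0.0, 0.0, 0.0), (0.0, 90.0, 0.0)]
        for e in eulers:
            br.insert_slice(acc, proj, e)
        m = acc.m
        kk = np.arange(m) - m // 2
        # analytic: FT of the projected ball (2D Gaussian of width sig px)
        amp = 2 * np.pi * sig ** 2 * np.sqrt(2 * np.pi) * sig
        expected = amp * np.exp(-2 * np.pi ** 2 * sig ** 2 * (kk / m) ** 2)
        centre = m // 2
        # plane z=0 (first euler): radial line along x
        line = acc.data[centre, centre, :] / np.maximum(acc.weights[centre, centre, :], 1e-12)
        sel = slice(centre - 8, centre + 9)
        np.testing.assert_allclose(line[sel].real, expected[sel], rtol=0.15)
        # plane from the tilted euler holds the same values along its own axis
        line2 = acc.data[:, centre, centre] / np.maximum(acc.weights[:, centre, centre], 1e-12)
        np.testing.assert_allclose(line2[sel].real, expected[sel], rtol=0.15)

    def test_zero_data_gives_zero_volume(self):
        acc = br.FourierAccumulator(16, 1.0, 2)
        out = br.finalize(acc)
        assert not np.any(out.data)

    def test_stronger_wiener_floor_shrinks_the_volume(self):
        box = 32
        vol0 = _band_limited_blob(box, 2.0)
        img = vol0.data.astype(float).sum(axis=0)
        acc = br.FourierAccumulator(box, 2.0, 2)
        br.insert_slice(acc, img, (0.0, 0.0, 0.0))
        norms = [np.linalg.norm(br.finalize(acc, w).data)
                 for w in (1e-6, 1e-2, 1.0, 100.0)]
        assert all(a > b for a, b in zip(norms, norms[1:]))

    def test_full_coverage_recovers_phantom_to_high_frequency(self):
        # CTF == 1 projections from an even cover: FSC > 0.99 to 0.9 Nyquist.
        # The object is a Gaussian mixture whose projections have a closed
        # form, so the only error source is the insertion itself.
        box, apix, sig = 32, 2.0, 1.0
        rng = np.random.default_rng(8)
        pos = rng.uniform(-8.0, 8.0, size=(25, 3))          # voxels
        amp = rng.uniform(0.5, 1.5, size=25)
        ax = np.arange(box) - box // 2
        zz, yy, xx = np.meshgrid(ax, ax, ax, indexing="ij")
        ref = np.zeros((box, box, box))
        for (px, py, pz), a in zip(pos, amp):
            ref += a * np.exp(-((xx - px) ** 2 + (yy - py) ** 2
                                + (zz - pz) ** 2) / (2 * sig ** 2))
        vol0 = br.VolumeGrid(ref, apix)
        yy2, xx2 = np.meshgrid(ax, ax, indexing="ij")
        acc = br.FourierAccumulator(box, apix, 2)
        for e in br.euler_coverage(12.0, 360.0):
            rot_pos = (rotation_matrix(e) @ pos.T).T
            img = np.zeros((box, box))
            for (px, py, _), a in zip(rot_pos, amp):
                img += (a * np.sqrt(2 * np.pi) * sig
                        * np.exp(-((xx2 - px) ** 2 + (yy2 - py) ** 2)
                                 / (2 * sig ** 2)))
            br.insert_slice(acc, img, e)
        recon = br.finalize(acc, 1e-6)
        curve = br.fsc(recon, vol0)
        kmax_check = int(0.9 * box / 2)
        assert np.all(np.real(curve.fsc[1:kmax_check]) > 0.99)


class TestReconstruct:
    def test_empty_table_rejected(self, small_optics):
        stack = br.ImageStack(np.zeros((1, 16, 16), np.float32), 2.0)
        table = br.ParticleTable.from_records(
            [br.ParticleRecord(euler=(0, 0, 0), image_index=0)])
        empty = br.ParticleTable(table.df.iloc[:0].copy())
        with pytest.raises(ValueError, match="empty"):
            br.reconstruct(stack, empty, small_optics)

    def test_shift_metadata_is_honoured(self, small_optics):
        # translating an image while recording the shift leaves the map intact
        box, apix = 32, 2.0
        vol0 = _band_limited_blob(box, apix)
        eulers = br.euler_coverage(24.0, 360.0)
        shifts_px = [(2, -1)] * len(eulers)
        imgs, recs = [], []
        for i, (e, sh) in enumerate(zip(eulers, shifts_px)):
            img = _project(vol0, e)
            img = np.roll(np.roll(img, sh[1], axis=0), sh[0], axis=1)
            imgs.append(img.astype(np.float32))
            recs.append(br.ParticleRecord(
                euler=e, shift=(sh[0] * apix, sh[1] * apix),
                particle_defocus=1.0, image_index=i))
        stack = br.ImageStack(np.stack(imgs), apix)
        table = br.ParticleTable.from_records(recs)
        acc = br.FourierAccumulator(box, apix, 2)
        for i, r in enumerate(table.records()):
            br.insert_slice(acc, stack.data[i], r.euler, r.shift)
        rec = br.finalize(acc, 1e-6)
        curve = br.fsc(rec, vol0)
        assert np.all(np.real(curve.fsc[1:10]) > 0.98)

    def test_rotational_equivariance(self):
        # rotating every record by a fixed rotation rotates the output map
        box, apix = 32, 2.0
        vol0 = _band_limited_blob(box, apix, kmax=9)
        extra = (0.0, 90.0, 0.0)
        g = rotation_matrix(extra)
        eulers = br.euler_coverage(20.0, 360.0)
        acc1 = br.FourierAccumulator(box, apix, 2)
        acc2 = br.FourierAccumulator(box, apix, 2)
        from blockrec._geometry import euler_from_matrix
        for e in eulers:
            img = _project(vol0, e)
            br.insert_slice(acc1, img, e)
            br.insert_slice(acc2, img, euler_from_matrix(rotation_matrix(e) @ g))
        v1 = br.finalize(acc1, 1e-6)
        v2 = br.finalize(acc2, 1e-6)
        # v2 should equal v1 rotated by g^-1 in the reference frame
        v1r = rotate_volume_data(v1.data.astype(float), g.T)
        curve = br.fsc(br.VolumeGrid(v1r, apix), v2)
        assert np.all(np.real(curve.fsc[1:int(0.7 * box / 2)]) > 0.95)


class TestFSC:
    def test_self_correlation_is_unity(self, rng):
        v = br.VolumeGrid(rng.normal(size=(32, 32, 32)), 2.0)
        curve = br.fsc(v, v)
        np.testing.assert_allclose(np.real(curve.fsc), 1.0, atol=1e-10)

    def test_independent_noise_decorrelates(self, rng):
        a = br.VolumeGrid(rng.normal(size=(48, 48, 48)), 1.0)
        b = br.VolumeGrid(rng.normal(size=(48, 48, 48)), 1.0)
        curve = br.fsc(a, b)
        n = 48
        k = np.fft.fftfreq(n) * n
        r = np.rint(np.sqrt(k[:, None, None] ** 2 + k[None, :, None] ** 2
                            + k[None, None, :] ** 2)).astype(int)
        for shell in range(2, n // 2):
            n_vox = int(np.sum(r == shell))
            assert abs(np.real(curve.fsc[shell])) < 3.0 / np.sqrt(n_vox)

    def test_low_pass_filtered_copy_reads_out_the_filter_edge(self):
        # oracle: a sharp 10 Å low-pass of a noise volume crosses FSC 0.5
        # at the filter edge
        box, apix = 64, 2.0
        rng = np.random.default_rng(12)
        v = rng.normal(size=(box, box, box))
        ft = np.fft.fftn(v)
        f = np.fft.fftfreq(box, d=apix)
        s = np.sqrt(f[:, None, None] ** 2 + f[None, :, None] ** 2
                    + f[None, None, :] ** 2)
        lp = np.fft.ifftn(ft * (s <= 0.1)).real
        curve = br.fsc(br.VolumeGrid(v, apix), br.VolumeGrid(lp, apix))
        assert br.resolution_at(curve, 0.5) == pytest.approx(10.0, rel=0.06)

    @given(st.floats(min_value=0.1, max_value=50.0))
    def test_invariant_under_common_scaling(self, scale):
        rng = np.random.default_rng(7)
        a = br.VolumeGrid(rng.normal(size=(16,) * 3), 1.0)
        b = br.VolumeGrid(a.data + 0.5 * rng.normal(size=(16,) * 3), 1.0)
        c1 = br.fsc(a, b)
        c2 = br.fsc(br.VolumeGrid(a.data * scale, 1.0),
                    br.VolumeGrid(b.data * scale, 1.0))
        np.testing.assert_allclose(np.real(c1.fsc), np.real(c2.fsc), atol=1e-9)
        c3 = br.fsc(b, a)   # symmetry in the arguments
        np.testing.assert_allclose(np.real(c1.fsc), np.real(c3.fsc), atol=1e-9)

    def test_never_crossing_returns_nyquist(self, rng):
        v = br.VolumeGrid(rng.normal(size=(16,) * 3), 2.0)
        assert br.resolution_at(br.fsc(v, v), 0.5) == 2.0 * 2.0


class TestLimitExperiment:
    def test_flat_control_is_sampling_limited(self):
        opt = br.OpticsModel(voltage=300, cs=0.0, amplitude_contrast=0.07,
                             pixel_size=2.0, wavelength=0.41667)
        res = br.limit_experiment(70.0, opt, euler_step=16.0, box=48,
                                  n_atoms=400, defocus_range=(150.0, 250.0),
                                  layer_thickness=2.0, sim_mode="flat")
        assert res <= 1.15 * 2.0 * 2.0     # near Nyquist

    def test_layered_resolution_tracks_the_formula(self):
        # scaled-wavelength regime: the measured limit follows sqrt(t*lambda/2)
        lam = 0.625
        opt = br.OpticsModel(voltage=300, cs=0.0, amplitude_contrast=0.07,
                             pixel_size=2.0, wavelength=lam)
        t = 76.0
        res = br.limit_experiment(t, opt, euler_step=14.0, box=48,
                                  n_atoms=400, defocus_range=(120.0, 200.0),
                                  layer_thickness=2.0)
        predicted = br.empirical_limit(t, 300.0, wavelength=lam)
        assert res == pytest.approx(predicted, rel=0.25)
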