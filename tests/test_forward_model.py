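"""Hartley transforms, CTF, slicing, translation, tomography weighting."""

import numpy as np
import pytest
from scipy.optimize import brentq
from scipy.spatial.transform import Rotation

from cryofield import forward_model as fm
from cryofield import simulate as sim
from cryofield.io_formats import CtfParams, TiltMetadata


class TestDht:
    def test_involution(self, rng):
        x = rng.normal(size=(8, 8))
        assert np.abs(fm.dht(fm.dht(x)) - x).max() < 1e-6

    def test_constant_image_is_pure_dc(self):
        h = fm.dht(np.full((16, 16), 3.0))
        dc = h[8, 8]
        h[8, 8] = 0.0
        assert np.abs(h).max() < 1e-10
        assert dc == pytest.approx(3.0 * 16)

    def test_matches_dft_re_minus_im(self, rng):
        x = rng.normal(size=(4, 4))
        F = np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(x), norm="ortho"))
        assert np.abs(fm.dht(x) - (F.real - F.imag)).max() < 1e-12

    def test_parseval(self, rng):
        x = rng.normal(size=(16, 16))
        assert np.linalg.norm(fm.dht(x)) == pytest.approx(
            np.linalg.norm(x), rel=1e-5)

    def test_rejects_complex(self):
        with pytest.raises(TypeError):
            fm.dht(np.ones((4, 4), dtype=complex))


class TestLattice:
    def test_coords_bounded_and_symmetric(self):
        lat = fm.FrequencyLattice(16)
        c = lat.coords
        assert c.min() >= -0.5 and c.max() < 0.5
        py, px = lat.neg_index()[:2]
        # every lattice point has an exact -k partner under mod-D negation
        neg = c[py[:, None], px[None, :]]
        wrapped = (-c + 0.5) % 1.0 - 0.5  # -k folded back into [-0.5, 0.5)
        assert np.abs(neg - wrapped).max() < 1e-12

    def test_odd_size_rejected(self):
        with pytest.raises(ValueError):
            fm.FrequencyLattice(15)


class TestCtf:
    CTF = CtfParams(10000.0, 10000.0, 0.0, 300.0, 2.7, 0.07)

    def test_dc_value_is_minus_amplitude_contrast(self):
        lat = fm.FrequencyLattice(16)
        c = fm.eval_ctf(self.CTF, lat, 1.0)
        assert c[8, 8] == pytest.approx(-0.07, abs=1e-12)

    def test_even_function(self):
        lat = fm.FrequencyLattice(16)
        ctf = CtfParams(12000.0, 9000.0, 30.0, 300.0, 2.7, 0.07)
        c = fm.eval_ctf(ctf, lat, 2.0)
        py, px = lat.neg_index()[:2]
        diff = np.abs(c - c[py[:, None], px[None, :]])
        # the Nyquist row/col aliases -k onto a different physical frequency
        assert diff[1:, 1:].max() < 1e-10

    def test_bounded(self):
        lat = fm.FrequencyLattice(32)
        c = fm.eval_ctf(self.CTF, lat, 1.0)
        assert np.all(np.abs(c) <= 1.0 + 1e-12)

    def test_first_zero_matches_root_find(self):
        # 300 kV, 1.0 um defocus, Cs 2.7, w 0.07: root of the phase equation
        lam = fm._wavelength_angstrom(300.0)
        w = 0.07

        def c1d(k):
            gamma = np.pi * lam * 1e4 * k**2 - 0.5 * np.pi * 2.7e7 * lam**3 * k**4
            return -(np.sqrt(1 - w * w) * np.sin(gamma) + w * np.cos(gamma))

        k_root = brentq(c1d, 1e-4, 0.09)
        # locate the first sign change of the 2D CTF along the kx axis
        D, pix = 256, 1.0
        lat = fm.FrequencyLattice(D)
        c = fm.eval_ctf(self.CTF, lat, pix)
        row = c[D // 2, D // 2:]
        j = np.where(np.diff(np.sign(row)))[0][0]
        # refine the crossing by linear interpolation between grid samples
        f = row[j] / (row[j] - row[j + 1])
        k_grid = (j + f) / (D * pix)
        assert abs(k_grid - k_root) / k_root < 0.005


class TestSliceTheorem:
    def test_identity_slice_is_central_plane(self, phantom32):
        _, vhat = phantom32
        s = fm.slice_volume(vhat, np.eye(3))
        assert np.abs(s - vhat[16]).max() < 1e-10

    def test_radial_volume_slice_rotation_invariant(self):
        D = 32
        g = np.arange(D) - D // 2
        zz, yy, xx = np.meshgrid(g, g, g, indexing="ij")
        V = np.exp(-(xx**2 + yy**2 + zz**2) / 32.0)
        vhat = fm.dht(V)
        s0 = fm.slice_volume(vhat, np.eye(3))
        R = Rotation.random(rng=np.random.default_rng(3)).as_matrix()
        s1 = fm.slice_volume(vhat, R)
        rel = np.abs(s0 - s1).max() / np.abs(s0).max()
        assert rel < 0.02  # interpolation tolerance

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_hartley_slice_matches_real_projection(self, seed):
        D = 32
        spec = sim.PhantomSpec([
            sim.GaussianBlob((0.09, -0.06, 0.0), 0.095, 1.0),
            sim.GaussianBlob((-0.12, 0.03, 0.09), 0.08, 0.7),
            sim.GaussianBlob((0.06, 0.16, -0.12), 0.085, 0.9),
        ])
        V = sim.make_phantom(spec, D)
        vhat = fm.dht(V)
        R = Rotation.random(rng=np.random.default_rng(seed)).as_matrix()
        proj = fm.project_real(V, fm.Pose(R, (0.0, 0.0)))
        hs = np.sqrt(D) * fm.slice_volume(vhat, R)
        err = np.linalg.norm(fm.dht(proj) - hs) / np.linalg.norm(fm.dht(proj))
        assert err < 0.02

    def test_out_of_band_points_are_zero(self, gridded32):
        pts = np.array([[0.7, 0.0, 0.0], [0.0, -0.9, 0.2]])
        assert np.all(gridded32.evaluate(None, pts) == 0.0)


class TestTranslateHartley:
    def test_zero_shift_is_identity(self, rng):
        h = rng.normal(size=(16, 16))
        assert np.abs(fm.translate_hartley(h, (0.0, 0.0)) - h).max() == 0.0

    @pytest.mark.parametrize("shift", [(3, 0), (0, -2), (5, 7)])
    def test_integer_shift_matches_circular_roll(self, rng, shift):
        img = rng.normal(size=(16, 16))
        h = fm.dht(img)
        sh = fm.translate_hartley(h, shift)
        rolled = np.roll(img, (shift[1], shift[0]), axis=(0, 1))
        assert np.abs(fm.idht(sh) - rolled).max() < 1e-5

    def test_composition_is_additive(self, rng):
        h = rng.normal(size=(16, 16))
        h[0, :] = 0.0  # Nyquist lines are self-partnered; fractional
        h[:, 0] = 0.0  # shifts there are inherently ambiguous
        a, b = rng.uniform(-3, 3, 2), rng.uniform(-3, 3, 2)
        h1 = fm.translate_hartley(fm.translate_hartley(h, a), b)
        h2 = fm.translate_hartley(h, a + b)
        assert np.abs(h1 - h2).max() < 1e-10

    def test_orthogonal_below_nyquist(self, rng):
        # the operator is an exact isometry off the self-partnered
        # Nyquist lines (where fractional shifts are inherently ambiguous)
        D = 16
        lat = fm.FrequencyLattice(D)
        h = rng.normal(size=(D, D))
        h[0, :] = 0.0
        h[:, 0] = 0.0
        sh = fm.translate_hartley(h, (1.3, -0.7), lat)
        sh[0, :] = 0.0
        sh[:, 0] = 0.0
        assert np.linalg.norm(sh) == pytest.approx(np.linalg.norm(h), rel=1e-9)


class TestProjectReal:
    def test_identity_pose_is_axis_sum(self, phantom32):
        V, _ = phantom32
        proj = fm.project_real(V, fm.Pose(np.eye(3), (0.0, 0.0)))
        assert np.abs(proj - V.sum(axis=0)).max() < 1e-12

    def test_centered_sphere_projection_rotation_invariant(self):
        D = 32
        g = np.arange(D) - D // 2
        zz, yy, xx = np.meshgrid(g, g, g, indexing="ij")
        V = np.exp(-(xx**2 + yy**2 + zz**2) / 50.0)
        R = Rotation.random(rng=np.random.default_rng(7)).as_matrix()
        p0 = fm.project_real(V, fm.Pose(np.eye(3), (0, 0)))
        p1 = fm.project_real(V, fm.Pose(R, (0, 0)))
        assert np.linalg.norm(p0 - p1) / np.linalg.norm(p0) < 0.02


class TestTiltWeights:
    CTF = CtfParams(15000.0, 15000.0)

    def test_zero_tilt_zero_dose_is_plain_ctf(self):
        lat = fm.FrequencyLattice(32)
        w = fm.tilt_weights(self.CTF, TiltMetadata(0.0, 0.0, 0), lat, 2.0)
        c = fm.eval_ctf(self.CTF, lat, 2.0)
        assert np.abs(w - c).max() < 1e-12

    def test_sixty_degrees_halves_ctf(self):
        lat = fm.FrequencyLattice(32)
        w = fm.tilt_weights(self.CTF, TiltMetadata(60.0, 0.0, 1), lat, 2.0)
        c = fm.eval_ctf(self.CTF, lat, 2.0)
        assert np.abs(w - 0.5 * c).max() < 1e-12

    def test_weight_decreases_with_dose(self):
        lat = fm.FrequencyLattice(32)
        prev = None
        for dose in [0.0, 10.0, 30.0, 90.0]:
            w = fm.dose_weights(lat, 2.0, dose)
            val = w[16, 20]  # fixed non-DC frequency
            if prev is not None:
                assert val < prev
            prev = val

    def test_steep_tilt_rejected(self):
        lat = fm.FrequencyLattice(16)
        with pytest.raises(ValueError):
            fm.tilt_weights(self.CTF, TiltMetadata(90.0, 0.0, 0), lat, 1.0)


class TestSimulateObservation:
    def test_noiseless_identity_is_inverse_slice(self, gridded32):
        rng = np.random.default_rng(0)
        img = fm.simulate_observation(
            gridded32, fm.Pose(np.eye(3), (0, 0)), None, 0.0, rng)
        # dht of the image equals the scaled central slice
        h = fm.dht(img)
        central = np.sqrt(32) * fm.slice_volume(gridded32, np.eye(3))
        assert np.abs(h - central).max() < 1e-8

    def test_noise_std_matches_request(self, gridded32):
        rng = np.random.default_rng(0)
        D = 32
        pose = fm.Pose(np.eye(3), (0, 0))
        clean = fm.simulate_observation(gridded32, pose, None, 0.0,
                                        np.random.default_rng(0))
        noisy = fm.simulate_observation(gridded32, pose, None, 0.5,
                                        np.random.default_rng(0))
        resid = noisy - clean
        assert abs(resid.std() - 0.5) / 0.5 < 3 / D


class TestTranslationProperties:
    """Property-based checks of the Hartley shift operator."""

    def test_shift_group_property_random_shifts(self):
        from hypothesis import given, settings, strategies as st

        rng = np.random.default_rng(99)
        h = rng.normal(size=(16, 16))
        h[0, :] = 0.0
        h[:, 0] = 0.0

        @settings(max_examples=25, deadline=None, derandomize=True)
        @given(st.tuples(st.floats(-4, 4), st.floats(-4, 4)),
               st.tuples(st.floats(-4, 4), st.floats(-4, 4)))
        def check(a, b):
            ta = np.asarray(a)
            tb = np.asarray(b)
            once = fm.translate_hartley(h, ta + tb)
            twice = fm.translate_hartley(fm.translate_hartley(h, ta), tb)
            assert np.abs(once - twice).max() < 1e-9
            # isometry off the Nyquist lines
            assert np.linalg.norm(fm.translate_hartley(h, ta)[1:, 1:]) == \
                pytest.approx(np.linalg.norm(h[1:, 1:]), rel=1e-9)

        check()
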