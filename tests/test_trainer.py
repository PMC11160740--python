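"""Trainer mechanics: loss identities, phase bookkeeping, determinism.

End-to-end optimization quality (pose recovery, heterogeneity separation)
is exercised separately in the acceptance suite at larger problem sizes;
these tests pin down the bookkeeping and the cross-module identities at
small, fast scales.
"""

import json

import numpy as np
import pytest

from cryofield import forward_model as fm
from cryofield import pose_search as ps
from cryofield import simulate as sim
from cryofield import trainer as tr
from cryofield.nn import Adam
from cryofield.volume_model import VolumeField


@pytest.fixture(scope="module")
def tiny_dataset():
    return sim.simulate_spa(sim.default_body(), 24, D=32, noise_std=0.1,
                            seed=5)


class TestLoss:
    def test_matches_reprojection_error_at_full_band(self, tiny_dataset):
        ds = tiny_dataset
        field = VolumeField(8, 0, coord_scale=8.0)
        z = np.zeros(8, np.float32)
        bands = tr._Bands(ds.stack)
        rows = bands.ctf_rows(ds.stack, ds.stack.pixel_size)
        i = 3
        lv = tr.loss(field, 1.0, ds.stack, bands, rows, np.array([i]),
                     ds.rotations[[i]], ds.translations[[i]], z[None])
        e = ps.reprojection_error(
            ds.stack.images[i], field, z,
            fm.Pose(ds.rotations[i], ds.translations[i]),
            bands.ctf_full[i], None, gain=1.0)
        assert lv == pytest.approx(e, rel=1e-6)

    def test_zero_for_perfect_model(self):
        # noiseless images rendered from the field itself, true poses
        D = 32
        field = VolumeField(4, 1, coord_scale=8.0)
        z = np.zeros(4, np.float32)
        lat = fm.FrequencyLattice(D)
        from scipy.spatial.transform import Rotation

        rots = Rotation.random(4, random_state=np.random.RandomState(2)).as_matrix()
        imgs = np.stack([
            fm.simulate_observation(field, fm.Pose(rots[i], (0, 0)), None,
                                    0.0, np.random.default_rng(0),
                                    lattice=lat, z=z)
            for i in range(4)
        ]).astype(np.float32)
        from cryofield.io_formats import CtfParams, ParticleStack

        stack = ParticleStack(imgs, 4.0, [CtfParams(1e4, 1e4)] * 4)
        bands = tr._Bands(stack)
        rows = np.ones((4, int(bands.mask.sum())), np.float32)
        lv = tr.loss(field, 1.0, stack, bands, rows, np.arange(4), rots,
                     np.zeros((4, 2)), np.zeros((4, 4), np.float32))
        energy = float(np.sum(bands.h.astype(np.float64) ** 2))
        assert lv / energy < 1e-8

    def test_white_noise_raises_loss_by_sigma2_coeffs(self, tiny_dataset):
        ds = tiny_dataset
        field = VolumeField(8, 0, coord_scale=8.0)
        z = np.zeros((8, 8), np.float32)
        clean = sim.simulate_spa(sim.default_body(), 24, D=32,
                                 noise_std=0.0, seed=5)
        sigma = 0.2
        noisy_imgs = clean.stack.images + np.random.default_rng(3).normal(
            0, sigma, clean.stack.images.shape).astype(np.float32)
        from cryofield.io_formats import ParticleStack

        noisy = ParticleStack(noisy_imgs, clean.stack.pixel_size,
                              clean.stack.ctf)
        idx = np.arange(8)
        args = (idx, clean.rotations[idx], clean.translations[idx], z)

        def batch_loss_for(stack):
            bands = tr._Bands(stack)
            rows = bands.ctf_rows(stack, stack.pixel_size)
            return tr.loss(field, 1.0, stack, bands, rows, *args)

        delta = batch_loss_for(noisy) - batch_loss_for(clean.stack)
        bands = tr._Bands(clean.stack)
        n_coeff = int(bands.mask.sum()) * len(idx)
        # E[delta] = sigma^2 * n_coeff + cross terms ~ 0; Monte-Carlo 10%
        assert delta == pytest.approx(sigma**2 * n_coeff, rel=0.10)


class TestConfig:
    def test_hps_phase_default_is_paper_rule(self):
        cfg = tr.TrainConfig(n_images=100_000)
        assert cfg.hps_images == 500_000
        cfg = tr.TrainConfig(n_images=300_000)
        assert cfg.hps_images == 600_000

    def test_paper_default_hyperparameters(self):
        cfg = tr.TrainConfig(n_images=1000)
        assert (cfg.pretrain_images, cfg.batch_pretrain) == (10_000, 32)
        assert (cfg.lr_field, cfg.lr_latent, cfg.lr_pose) == (1e-4, 1e-2, 1e-3)
        assert (cfg.batch_hps, cfg.batch_sgd) == (8, 256)
        assert (cfg.k_min, cfg.k_max) == (6, 16)
        assert (cfg.lr_pose_sta, cfg.batch_sgd_sta) == (1e-5, 32)
        assert cfg.n_tilts == 11

    def test_invalid_phase_lengths_rejected(self):
        with pytest.raises(ValueError):
            tr.TrainConfig(n_images=100, hps_images=50)


class TestPretrain:
    def test_poses_untouched_and_loss_decreases(self, tiny_dataset):
        ds = tiny_dataset
        cfg = tr.TrainConfig(n_images=24, d=8, seed=0, pretrain_images=640,
                             hps_images=24, sgd_images=0, lr_field=1e-3,
                             log_interval=64)
        state = tr.init_state(ds.stack, cfg)
        rot_before = state.rotations.copy()
        bands = tr._Bands(ds.stack)
        rows = bands.ctf_rows(ds.stack, ds.stack.pixel_size)
        opt = Adam(state.field.params, cfg.lr_field)
        tr.pretrain(state, ds.stack, cfg, bands, rows, opt)
        assert np.array_equal(state.rotations, rot_before)
        losses = [h["loss_per_image"] for h in state.history]
        assert losses[-1] < losses[0]
        assert state.images_processed == 640

    def test_deterministic_under_seed(self, tiny_dataset):
        ds = tiny_dataset

        def run():
            cfg = tr.TrainConfig(n_images=24, d=4, seed=3,
                                 pretrain_images=96, hps_images=24,
                                 sgd_images=0, log_interval=10**9)
            state = tr.init_state(ds.stack, cfg)
            bands = tr._Bands(ds.stack)
            rows = bands.ctf_rows(ds.stack, ds.stack.pixel_size)
            opt = Adam(state.field.params, cfg.lr_field)
            tr.pretrain(state, ds.stack, cfg, bands, rows, opt)
            return state

        a, b = run(), run()
        for k in a.field.params:
            assert np.array_equal(a.field.params[k], b.field.params[k])
        assert a.gain == b.gain


class TestFullRunDeterminism:
    def test_identical_seeds_identical_final_loss(self):
        ds = sim.simulate_spa(sim.default_body(), 16, D=32, noise_std=0.1,
                              seed=7)
        cfg = dict(n_images=16, d=4, seed=1, pretrain_images=64,
                   hps_images=16, sgd_images=32, k_min=3, k_max=8,
                   freq_subsample=0.5, log_interval=10**9)

        def final_loss():
            state = tr.train_spa(ds.stack, tr.TrainConfig(**cfg))
            bands = tr._Bands(ds.stack)
            rows = bands.ctf_rows(ds.stack, ds.stack.pixel_size)
            idx = np.arange(16)
            return tr.loss(state.field, state.gain, ds.stack, bands, rows,
                           idx, state.rotations, state.translations,
                           state.latents.z)

        assert final_loss() == final_loss()


class TestStaMechanics:
    @pytest.fixture(scope="class")
    def tilt_ds(self):
        return sim.simulate_tilt_series(sim.default_body(), n_particles=4,
                                        J=3, D=32, noise_std=0.05, seed=9)

    def test_requires_tilt_metadata(self, tiny_dataset):
        cfg = tr.TrainConfig(n_images=24)
        with pytest.raises(ValueError):
            tr.train_sta(tiny_dataset.stack, cfg)

    def test_spa_rejects_tilt_stack(self, tilt_ds):
        cfg = tr.TrainConfig(n_images=tilt_ds.stack.n_images)
        with pytest.raises(ValueError):
            tr.train_spa(tilt_ds.stack, cfg)

    def test_subtilt_poses_composed_from_particle_pose(self, tilt_ds):
        ds = tilt_ds
        cfg = tr.TrainConfig(
            n_images=ds.stack.n_images, d=4, seed=0, pretrain_images=32,
            hps_images=ds.stack.n_images, hps_particles=4, sgd_images=0,
            k_min=3, k_max=8, n_tilts=3, sta_resample_particles=0,
            freq_subsample=0.5, log_interval=10**9)
        state = tr.train_sta(ds.stack, cfg)
        # within each particle, subtilt rotations differ by the known tilt
        # rotations: R_ij (R_i0)^T == tilt_j for the HPS-tied solution
        from cryofield.simulate import tilt_rotation

        for p in range(4):
            base = state.rotations[3 * p]
            for j in range(1, 3):
                rel = state.rotations[3 * p + j] @ base.T
                expect = tilt_rotation(ds.stack.tilt[3 * p + j].tilt_angle)
                assert np.abs(rel - expect).max() < 1e-9

    def test_logging_is_parseable_jsonl(self, tiny_dataset, tmp_path):
        ds = tiny_dataset
        log = tmp_path / "train.jsonl"
        cfg = tr.TrainConfig(n_images=24, d=4, seed=0, pretrain_images=64,
                             hps_images=24, sgd_images=24, k_min=3, k_max=8,
                             freq_subsample=0.5, log_path=str(log),
                             log_interval=16)
        tr.train_spa(ds.stack, cfg)
        records = [json.loads(line) for line in log.read_text().splitlines()]
        assert records
        phases = {r["phase"] for r in records}
        assert phases <= {"pretrain", "hps", "sgd"}
        counters = [r["images_processed"] for r in records]
        assert counters == sorted(counters)


class TestLatentSeparation:
    """Conformational heterogeneity is recovered when poses are known.

    Fixed-pose heterogeneous training (the standard known-consensus-poses
    regime) on a two-state phantom: the per-particle latents must separate
    the states, and decoded maps must match their own ground truth better
    than the other state's.
    """

    @pytest.fixture(scope="class")
    def run(self):
        full, partial = sim.two_state_bodies()
        N = 12
        ds = sim.simulate_spa([full, partial], N, D=24, noise_std=0.0,
                              seed=5)
        cfg = tr.TrainConfig(n_images=N, d=2, seed=0, pretrain_images=1600,
                             hps_images=14_400, sgd_images=0, lr_field=2e-3,
                             lr_latent=3e-2, log_interval=10**9)
        state = tr.train_spa(ds.stack, cfg,
                             poses=(ds.rotations, ds.translations))
        return ds, state

    def test_two_cluster_purity(self, run):
        from sklearn.cluster import KMeans

        ds, state = run
        km = KMeans(2, n_init=10, random_state=0).fit(state.latents.z)
        purity = max((km.labels_ == ds.state_labels).mean(),
                     (km.labels_ != ds.state_labels).mean())
        assert purity >= 0.90

    def test_matched_per_image_fsc_beats_shuffled(self, run):
        from cryofield.metrics import per_image_fsc

        ds, state = run
        N = ds.stack.n_images
        matched = per_image_fsc(
            lambda i: ds.state_maps[ds.state_labels[i]], state.field,
            state.latents.z, 24, gain=state.gain)
        perm = np.roll(np.arange(N), 1)  # round-robin labels: state flips
        shuffled = per_image_fsc(
            lambda i: ds.state_maps[ds.state_labels[perm[i]]], state.field,
            state.latents.z, 24, gain=state.gain)
        assert matched.correlation.mean() > shuffled.correlation.mean()
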