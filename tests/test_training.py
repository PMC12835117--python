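"""2.5D batch assembly, forward-chain pair sampling, GAN losses and the
train loop (determinism, update contracts, resumability)."""

import math

import numpy as np
import pytest

import fieldlift as fl
from fieldlift.networks import Discriminator, Generator
from fieldlift.training import (Adam, TrainConfig, discriminator_loss,
                                draw_timestep, fit, generator_loss,
                                make_2p5d_stacks, sample_training_pair,
                                train_step)


class ProbeDiscriminator:
    """Fixed-score stand-in for loss arithmetic checks."""

    def __init__(self, score_real, score_fake=None):
        self.scores = [score_real] if score_fake is None else [score_real, score_fake]
        self.calls = 0

    def score(self, candidate, x_t, t):
        s = self.scores[min(self.calls, len(self.scores) - 1)]
        self.calls += 1
        return np.full(np.shape(candidate)[0] if np.ndim(candidate) == 3 else 1, s)


class TestStacks:
    def test_one_stack_per_slice(self, t1_pair):
        stacks = make_2p5d_stacks(t1_pair, 3)
        assert len(stacks) == t1_pair.target.shape[2]
        assert [s.slice_index for s in stacks] == list(range(len(stacks)))
        assert stacks[0].y_stack.shape == t1_pair.target.shape[:2] + (3,)

    def test_edge_replication(self, t1_pair):
        stacks = make_2p5d_stacks(t1_pair, 3)
        np.testing.assert_array_equal(stacks[0].y_stack[:, :, 0],
                                      t1_pair.conditioning[:, :, 0])
        np.testing.assert_array_equal(stacks[-1].y_stack[:, :, 2],
                                      t1_pair.conditioning[:, :, -1])

    def test_center_reassembly_round_trip(self, t1_pair):
        stacks = make_2p5d_stacks(t1_pair, 5)
        rebuilt = np.stack([s.x0_center for s in stacks], axis=2)
        np.testing.assert_array_equal(rebuilt, np.asarray(t1_pair.target, np.float32))

    def test_even_k_rejected(self, t1_pair):
        with pytest.raises(ValueError):
            make_2p5d_stacks(t1_pair, 4)


class TestTrainingPair:
    def test_t1_gives_clean_previous(self, default_schedule, rng):
        x0 = rng.standard_normal((8, 8)).astype(np.float32)
        x_prev, x_t = sample_training_pair(x0, 1, default_schedule, rng)
        np.testing.assert_array_equal(x_prev, x0)

    def test_zero_noise_deterministic(self, default_schedule):
        x0 = np.full((4, 4), 0.8)
        for t in (1, 2, 3, 4):
            x_prev, x_t = sample_training_pair(x0, t, default_schedule,
                                               noises=(np.zeros((4, 4)), np.zeros((4, 4))))
            ab_prev = default_schedule.alpha_bar[t - 1]
            ab = default_schedule.alpha_bar[t]
            np.testing.assert_allclose(x_prev, math.sqrt(ab_prev) * x0, rtol=1e-6)
            np.testing.assert_allclose(x_t, math.sqrt(ab) * x0, rtol=1e-6)

    @pytest.mark.parametrize("t", [2, 3, 4])
    def test_joint_covariance(self, default_schedule, t, rng):
        """Cov(x_{t-1}, x_t) = sqrt(1-beta_t)(1-ab_{t-1}) at 3 SE."""
        n = 100_000
        x0 = np.zeros(n)
        x_prev, x_t = sample_training_pair(x0, t, default_schedule, rng)
        cov = np.mean(x_prev * x_t)
        expected = math.sqrt(1 - default_schedule.beta[t - 1]) * \
            (1 - default_schedule.alpha_bar[t - 1])
        se = math.sqrt((x_prev.var() * x_t.var() + cov**2) / n)
        assert abs(cov - expected) < 3 * se

    def test_uniform_t_coverage(self, rng):
        draws = np.array([draw_timestep(rng, 4) for _ in range(10_000)])
        freq = np.bincount(draws, minlength=5)[1:] / 10_000
        se = math.sqrt(0.25 * 0.75 / 10_000)
        assert np.all(np.abs(freq - 0.25) < 3 * se)


class TestLossArithmetic:
    def test_indifferent_discriminator(self):
        D = ProbeDiscriminator(0.5, 0.5)
        x = np.zeros((1, 8, 8))
        assert discriminator_loss(D, x, x, x, 1) == pytest.approx(2 * math.log(2), rel=1e-12)

    def test_hand_computed_probe_scores(self):
        D = ProbeDiscriminator(0.8, 0.3)
        x = np.zeros((1, 8, 8))
        expected = -(math.log(0.8) + math.log(1 - 0.3))
        assert discriminator_loss(D, x, x, x, 2) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.5798, abs=2e-4)

    def test_perfect_discriminator_limit(self):
        x = np.zeros((1, 8, 8))
        losses = [discriminator_loss(ProbeDiscriminator(1 - e, e), x, x, x, 1)
                  for e in (1e-2, 1e-4, 1e-6)]
        assert losses[0] > losses[1] > losses[2]
        assert losses[2] < 1e-5

    def test_real_and_fake_terms_separate(self):
        """Real pairs contribute only the log D term, fakes only log(1-D)."""
        x = np.zeros((1, 8, 8))
        # varying the fake score with a perfect real score changes only the fake term
        base = discriminator_loss(ProbeDiscriminator(1 - 1e-12, 0.3), x, x, x, 1)
        assert base == pytest.approx(-math.log(0.7), rel=1e-6)
        moved = discriminator_loss(ProbeDiscriminator(1 - 1e-12, 0.6), x, x, x, 1)
        assert moved == pytest.approx(-math.log(0.4), rel=1e-6)

    def test_generator_loss_probe(self):
        x = np.zeros((1, 8, 8))
        x0_hat = np.full((1, 8, 8), 0.2)
        loss = generator_loss(ProbeDiscriminator(0.5), x, x, 1, x0_hat,
                              np.zeros((1, 8, 8)), lambda1=0.5)
        assert loss == pytest.approx(math.log(2) + 0.5 * 0.2, rel=1e-12)

    def test_generator_loss_degenerate_cases(self):
        x = np.zeros((1, 8, 8))
        # exact prediction: pure adversarial term
        assert generator_loss(ProbeDiscriminator(0.5), x, x, 1, x, x, 0.5) == \
            pytest.approx(math.log(2), rel=1e-12)
        # lambda1 = 0: adversarial term only
        x0_hat = np.full((1, 8, 8), 3.0)
        assert generator_loss(ProbeDiscriminator(0.25), x, x, 1, x0_hat, x, 0.0) == \
            pytest.approx(-math.log(0.25), rel=1e-12)
        with pytest.raises(ValueError):
            generator_loss(ProbeDiscriminator(0.5), x, x, 1, x, x, -1.0)


def _tiny_setup(tiny_cfg, t1_pair, n=4):
    stacks = make_2p5d_stacks(t1_pair, tiny_cfg.k_adjacent)[10:10 + n]
    sched = tiny_cfg.schedule()
    G = Generator(tiny_cfg.generator_config(), rng=1)
    D = Discriminator(tiny_cfg.discriminator_config(), rng=2)
    return stacks, sched, G, D


class TestTrainStep:
    def test_identical_seeds_identical_records(self, tiny_cfg, t1_pair):
        records = []
        params = []
        for _ in range(2):
            stacks, sched, G, D = _tiny_setup(tiny_cfg, t1_pair)
            og = Adam(tiny_cfg.lr_generator)
            od = Adam(tiny_cfg.lr_discriminator)
            r1 = train_step(stacks[:2], G, D, og, od, sched, tiny_cfg,
                            np.random.default_rng(0), step=0)
            r2 = train_step(stacks[2:], G, D, og, od, sched, tiny_cfg,
                            np.random.default_rng(1), step=1)
            records.append((r1, r2))
            params.append((G.params, D.params))
        assert records[0] == records[1]
        for k in params[0][0]:
            np.testing.assert_array_equal(params[0][0][k], params[1][0][k])

    def test_update_contract_and_isolation(self, tiny_cfg, t1_pair):
        stacks, sched, G, D = _tiny_setup(tiny_cfg, t1_pair)
        g_before = {k: v.copy() for k, v in G.params.items()}
        d_before = {k: v.copy() for k, v in D.params.items()}
        # zero generator learning rate: only the discriminator may move
        train_step(stacks[:2], G, D, Adam(0.0), Adam(1e-4), sched, tiny_cfg,
                   np.random.default_rng(0))
        assert all(np.array_equal(G.params[k], g_before[k]) for k in g_before)
        assert any(not np.array_equal(D.params[k], d_before[k]) for k in d_before)
        # and vice versa
        stacks, sched, G, D = _tiny_setup(tiny_cfg, t1_pair)
        d_before = {k: v.copy() for k, v in D.params.items()}
        g_before = {k: v.copy() for k, v in G.params.items()}
        train_step(stacks[:2], G, D, Adam(1e-4), Adam(0.0), sched, tiny_cfg,
                   np.random.default_rng(0))
        assert all(np.array_equal(D.params[k], d_before[k]) for k in d_before)
        assert any(not np.array_equal(G.params[k], g_before[k]) for k in g_before)

    def test_empty_batch_rejected(self, tiny_cfg, t1_pair):
        stacks, sched, G, D = _tiny_setup(tiny_cfg, t1_pair)
        with pytest.raises(ValueError):
            train_step([], G, D, Adam(1e-4), Adam(1e-4), sched, tiny_cfg,
                       np.random.default_rng(0))

    def test_losses_finite(self, tiny_cfg, t1_pair):
        stacks, sched, G, D = _tiny_setup(tiny_cfg, t1_pair)
        rec = train_step(stacks, G, D, Adam(1e-4), Adam(1e-4), sched, tiny_cfg,
                         np.random.default_rng(3))
        assert all(map(math.isfinite, (rec.d_loss, rec.g_adv_loss, rec.g_l1_loss)))
        assert 1 <= rec.t_drawn <= 4


class TestFit:
    def test_zero_epochs_keeps_initialization(self, dataset_dir, tiny_cfg):
        import dataclasses
        _, manifest = dataset_dir
        cfg = dataclasses.replace(tiny_cfg, epochs=0)
        G, D, hist = fit(manifest, cfg, contrast="T1")
        G0 = Generator(cfg.generator_config(), rng=np.random.default_rng(cfg.seed))
        # same rng stream: identical initialization, untouched by training
        ref = Generator(cfg.generator_config(),
                        rng=np.random.default_rng(cfg.seed))
        assert len(hist) == 0
        for k in G.params:
            np.testing.assert_array_equal(G.params[k], ref.params[k])

    def test_history_rows_match_steps(self, dataset_dir, tiny_cfg):
        import dataclasses
        _, manifest = dataset_dir
        cfg = dataclasses.replace(tiny_cfg, max_steps=3, epochs=10)
        _, _, hist = fit(manifest, cfg, contrast="T1")
        assert list(hist.columns) == ["step", "d_loss", "g_adv_loss", "g_l1_loss", "t_drawn"]
        assert len(hist) == 3

    def test_resume_is_bit_identical(self, dataset_dir, tiny_cfg, tmp_path):
        import dataclasses
        _, manifest = dataset_dir
        straight = dataclasses.replace(tiny_cfg, max_steps=4, epochs=10)
        G_full, _, hist_full = fit(manifest, straight, contrast="T1")

        half = dataclasses.replace(tiny_cfg, max_steps=2, epochs=10)
        fit(manifest, half, contrast="T1", out_dir=tmp_path)
        G_res, _, hist_res = fit(manifest, half, contrast="T1",
                                 resume=tmp_path / "T1_checkpoint.npz")
        assert len(hist_res) == 4
        for k in G_full.params:
            np.testing.assert_array_equal(G_full.params[k], G_res.params[k])
        assert hist_res.d_loss.tolist() == hist_full.d_loss.tolist()

    def test_empty_manifest_and_missing_contrast(self, dataset_dir, tiny_cfg):
        import pandas as pd
        _, manifest = dataset_dir
        with pytest.raises(ValueError):
            fit(manifest.iloc[:0], tiny_cfg, contrast="T1")
        with pytest.raises(ValueError, match="no rows"):
            fit(manifest[manifest.contrast == "T1"], tiny_cfg, contrast="T2")
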