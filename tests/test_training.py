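"""Initialisation statistics, optimiser arithmetic and alternation protocol."""

import numpy as np
import pytest

from ganseg.autodiff import Tensor
from ganseg.training import (TrainConfig, _BatchStream, gradient_check,
                             init_state, mbgd_step, train,
                             train_discriminator_round, train_generator_round,
                             truncated_normal)


class TestInit:
    def test_truncation_bound(self, rng):
        v = truncated_normal(rng, 10_000, 0.02)
        assert np.abs(v).max() <= 2 * 0.02 + 1e-12

    def test_seed_reproducibility(self, tiny_configs):
        gcfg, dcfg = tiny_configs
        a = init_state(gcfg, dcfg, TrainConfig(seed=3, epochs=0))
        b = init_state(gcfg, dcfg, TrainConfig(seed=3, epochs=0))
        for name in a.gen_params:
            np.testing.assert_array_equal(a.gen_params[name].data,
                                          b.gen_params[name].data)
        for name in a.disc_params:
            np.testing.assert_array_equal(a.disc_params[name].data,
                                          b.disc_params[name].data)

    def test_empirical_stddev_matches_closed_form(self, rng):
        # truncation at +-2 sigma shrinks the sd to sigma * 0.8796
        v = truncated_normal(rng, 100_000, 1.0)
        assert v.std() == pytest.approx(0.8796, rel=0.05)

    def test_biases_start_at_zero(self, tiny_state):
        for name, t in tiny_state.gen_params.items():
            if name.endswith(".b") or name.endswith("beta"):
                np.testing.assert_array_equal(t.data, 0.0)


class TestMBGD:
    def test_zero_gradient_is_fixed_point(self):
        p = {"w": Tensor(np.array([1.0, 2.0]), requires_grad=True)}
        p["w"].grad = np.zeros(2)
        mbgd_step(p, 0.5)
        np.testing.assert_array_equal(p["w"].data, [1.0, 2.0])

    def test_hand_arithmetic(self):
        p = {"w": Tensor(np.array([1.0]), requires_grad=True)}
        p["w"].grad = np.array([0.5])
        mbgd_step(p, 0.01)
        assert p["w"].data[0] == pytest.approx(0.995)

    def test_batch_averaged_update_matches_hand_sum(self):
        # two weights, two per-sample gradients listed by hand
        g1 = np.array([0.2, -0.4])
        g2 = np.array([0.6, 0.0])
        p = {"w": Tensor(np.array([1.0, 1.0]), requires_grad=True)}
        p["w"].grad = (g1 + g2) / 2
        mbgd_step(p, 0.1)
        np.testing.assert_allclose(p["w"].data,
                                   [1.0 - 0.1 * 0.4, 1.0 + 0.1 * 0.2])

    def test_missing_gradient_raises(self):
        p = {"w": Tensor(np.zeros(2), requires_grad=True)}
        with pytest.raises(ValueError, match="no gradient"):
            mbgd_step(p, 0.1)


class TestRounds:
    def test_discriminator_round_leaves_generator_untouched(
            self, tiny_state, tiny_batch):
        imgs, labs = tiny_batch
        before = {n: t.data.copy() for n, t in tiny_state.gen_params.items()}
        train_discriminator_round(tiny_state, imgs, labs)
        for n, t in tiny_state.gen_params.items():
            np.testing.assert_array_equal(t.data, before[n])
        assert tiny_state.n_disc_updates == 1
        assert np.isfinite(tiny_state.history[-1]["D_loss"])

    def test_generator_round_leaves_discriminator_untouched(
            self, tiny_state, tiny_batch):
        imgs, labs = tiny_batch
        before = {n: t.data.copy() for n, t in tiny_state.disc_params.items()}
        train_generator_round(tiny_state, imgs, labs)
        for n, t in tiny_state.disc_params.items():
            np.testing.assert_array_equal(t.data, before[n])
        assert tiny_state.n_gen_updates == 1

    def test_discriminator_learns_separable_toy(self, tiny_configs,
                                                tiny_batch):
        """On fixed real/fake inputs the D loss strictly decreases."""
        from ganseg.adversarial import discriminator_forward
        from ganseg.objectives import binary_ce, onehot
        from ganseg.adversarial import mask_with_segmentation
        gcfg, dcfg = tiny_configs
        st = init_state(gcfg, dcfg, TrainConfig(seed=2, epochs=0))
        rng = np.random.default_rng(0)
        imgs = Tensor(rng.uniform(size=(4, 1, 32, 32)))
        real = onehot(rng.integers(0, 3, (4, 32, 32)), 3)
        fake = np.full((4, 3, 32, 32), 1 / 3)
        losses = []
        for _ in range(20):
            for p in st.disc_params.values():
                p.grad = None
            d_r = discriminator_forward(
                mask_with_segmentation(imgs, Tensor(real)), st.disc_params,
                dcfg)
            d_f = discriminator_forward(
                mask_with_segmentation(imgs, Tensor(fake)), st.disc_params,
                dcfg)
            loss = binary_ce(1.0, d_r) + binary_ce(0.0, d_f)
            losses.append(loss.item())
            loss.backward()
            mbgd_step(st.disc_params, 0.01)
        assert losses[-1] < losses[0]
        assert all(b <= a + 1e-6 for a, b in zip(losses[:-1], losses[1:]))

    def test_segmentation_ce_decreases_on_toy(self, tiny_configs, tiny_batch):
        gcfg, dcfg = tiny_configs
        st = init_state(gcfg, dcfg,
                        TrainConfig(seed=4, epochs=0, lam=0.0,
                                    pixel_reduction="mean"))
        imgs, labs = tiny_batch
        first = last = None
        for i in range(25):
            train_generator_round(st, imgs, labs)
            if i == 0:
                first = st.history[-1]["L_mec"]
        last = st.history[-1]["L_mec"]
        assert last < first


class TestTrainLoop:
    def test_alternation_ratio(self, tiny_configs, tiny_batch):
        gcfg, dcfg = tiny_configs
        imgs, labs = tiny_batch
        cfg = TrainConfig(seed=0, epochs=2, batch_size=2, k=6)
        st = train(imgs, labs, cfg, gcfg, dcfg)
        assert st.n_gen_updates == 2
        assert st.n_disc_updates == 6 * st.n_gen_updates

    def test_zero_epochs_is_noop(self, tiny_configs, tiny_batch):
        gcfg, dcfg = tiny_configs
        imgs, labs = tiny_batch
        cfg = TrainConfig(seed=0, epochs=0)
        ref = init_state(gcfg, dcfg, cfg)
        st = train(imgs, labs, cfg, gcfg, dcfg)
        for n, t in st.gen_params.items():
            np.testing.assert_array_equal(t.data, ref.gen_params[n].data)
        assert st.history == []

    def test_seeded_determinism_of_loss_history(self, tiny_configs,
                                                tiny_batch):
        gcfg, dcfg = tiny_configs
        imgs, labs = tiny_batch
        cfg = TrainConfig(seed=9, epochs=1, batch_size=2, k=2,
                          deterministic=True)
        h1 = train(imgs, labs, cfg, gcfg, dcfg).history
        h2 = train(imgs, labs, cfg, gcfg, dcfg).history
        assert h1 == h2

    def test_empty_dataset_rejected(self, tiny_configs):
        gcfg, dcfg = tiny_configs
        with pytest.raises(ValueError, match="empty|matching"):
            train(np.zeros((0, 32, 32)), np.zeros((0, 32, 32), dtype=int),
                  TrainConfig(epochs=1), gcfg, dcfg)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(learning_rate=0.0)
        with pytest.raises(ValueError):
            TrainConfig(k=0)


class TestBatchStream:
    def test_without_replacement_within_pass(self):
        s = _BatchStream(6, 2, np.random.default_rng(0))
        seen = np.concatenate([s.next() for _ in range(3)])
        assert sorted(seen.tolist()) == list(range(6))


class TestGradientCheck:
    def test_quadratic_toy(self, rng):
        w = Tensor(np.array([3.0]), requires_grad=True)
        err = gradient_check(lambda: (w * w).sum(), {"w": w}, rng, n_coords=1)
        assert err < 1e-8

    def test_attention_head_gradients(self, rng):
        """Spot-check the attention path specifically (float64)."""
        from ganseg.attention import AttentionParams, dual_attention_t
        p = AttentionParams.init(8, rng)
        pt = {k: Tensor(getattr(p, k), requires_grad=True)
              for k in ("theta_w", "phi_w", "g_w", "wz_w", "wc_w")}
        x = Tensor(rng.normal(size=(1, 8, 3, 3)))
        err = gradient_check(
            lambda: (dual_attention_t(x, pt) ** 2.0).sum(), pt, rng,
            n_coords=20)
        assert err < 1e-3
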