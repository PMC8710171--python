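"""Backbone, fusion and branch-head contracts of the segmentation generator."""

import numpy as np
import pytest

from ganseg.autodiff import Tensor, concat, no_grad
from ganseg.attention import dual_attention_t
from ganseg.generator import (GeneratorConfig, backbone_forward,
                              branch_predict, fuse_features,
                              generator_forward, init_generator_params,
                              upsample_bilinear)
from ganseg.nnops import conv2d, bilinear_upsample, softmax


@pytest.fixture(scope="module")
def small_model():
    cfg = GeneratorConfig(base_width=8, num_classes=5,
                          block_counts=(1, 1, 1, 1))
    params, state = init_generator_params(cfg, np.random.default_rng(7))
    return cfg, params, state


def test_stage_strides_and_widths(small_model):
    cfg, params, state = small_model
    x = Tensor(np.random.default_rng(0).uniform(size=(1, 1, 64, 64)))
    with no_grad():
        stages = backbone_forward(x, params, state, cfg)
    dims = [s.shape[2] for s in stages]
    widths = [s.shape[1] for s in stages]
    assert dims == [16, 8, 4, 2]
    assert widths == [32, 64, 128, 256]  # EXPANSION * (w, 2w, 4w, 8w)


def test_indivisible_input_rejected(small_model):
    cfg, params, state = small_model
    with pytest.raises(ValueError, match="divisible by 32"):
        backbone_forward(Tensor(np.zeros((1, 1, 48, 48))), params, state, cfg)


def test_backbone_determinism(small_model):
    cfg, params, state = small_model
    x = np.random.default_rng(3).uniform(size=(1, 1, 32, 32))
    with no_grad():
        a = backbone_forward(Tensor(x.copy()), params, state, cfg,
                             training=False)
        b = backbone_forward(Tensor(x.copy()), params, state, cfg,
                             training=False)
    for sa, sb in zip(a, b):
        np.testing.assert_array_equal(sa.data, sb.data)


def test_zeroed_blocks_reduce_to_shortcut_path():
    """With residual-block weights zeroed, each block passes its shortcut."""
    cfg = GeneratorConfig(base_width=4, num_classes=2,
                          block_counts=(1, 1, 1, 1), use_batch_norm=False)
    params, state = init_generator_params(cfg, np.random.default_rng(0))
    for name, t in params.items():
        if ".conv" in name:           # zero the residual path only
            t.data[:] = 0.0
    x = Tensor(np.random.default_rng(1).uniform(size=(1, 1, 32, 32)))
    with no_grad():
        stages = backbone_forward(x, params, state, cfg)
    # residual path contributes nothing; outputs are ReLU(projected shortcut)
    # with zeroed projections too the whole output must be exactly zero
    for name, t in params.items():
        if ".proj" in name or "stem" in name:
            t.data[:] = 0.0
    with no_grad():
        stages0 = backbone_forward(x, params, state, cfg)
    for s in stages0:
        np.testing.assert_array_equal(s.data, 0.0)
    del stages


def test_upsample_wrapper_unbatched():
    f = np.array([[[1.0, 2.0], [3.0, 4.0]]])
    out = upsample_bilinear(f, 4, 4)
    assert out.shape == (1, 4, 4)
    assert out[0, 0, 0] == 1.0 and out[0, 3, 3] == 4.0


def test_fuse_features_zero_inputs(small_model):
    cfg, params, state = small_model
    zeros = [Tensor(np.zeros((1, 8, 4, 4))) for _ in range(4)]
    saved = {n: params[n].data.copy() for n in
             ("fuse.w2.b", "fuse.w3.b")}
    for n in saved:
        params[n].data[:] = 0.0
    with no_grad():
        out = fuse_features(*zeros, params)
    np.testing.assert_array_equal(out.data, 0.0)
    for n, v in saved.items():
        params[n].data = v


def test_fuse_features_channel_arithmetic(small_model):
    cfg, params, state = small_model
    maps = [Tensor(np.random.default_rng(i).uniform(size=(1, 8, 4, 4)))
            for i in range(4)]
    cat = concat(maps, axis=1)
    assert cat.shape[1] == 32  # 4c channels before w2


def test_fuse_features_matches_recomposition(small_model):
    cfg, params, state = small_model
    rng = np.random.default_rng(5)
    maps = [Tensor(rng.uniform(size=(1, 8, 4, 4))) for _ in range(4)]
    with no_grad():
        fused = fuse_features(*maps, params)
        inner = conv2d(concat(maps, axis=1), params["fuse.w2.w"],
                       params["fuse.w2.b"], pad=1).relu()
        outer = conv2d(inner, params["fuse.w3.w"],
                       params["fuse.w3.b"]).relu()
    np.testing.assert_allclose(fused.data, outer.data, atol=1e-12)


def test_fuse_features_mismatched_dims_raise(small_model):
    cfg, params, state = small_model
    a = Tensor(np.zeros((1, 8, 4, 4)))
    b = Tensor(np.zeros((1, 8, 2, 2)))
    with pytest.raises(ValueError, match="spatial dims"):
        fuse_features(a, a, a, b, params)


def test_branch_predict_contract_and_composition(small_model):
    cfg, params, state = small_model
    rng = np.random.default_rng(2)
    f = Tensor(rng.uniform(size=(2, 8, 8, 8)))
    fi = Tensor(rng.uniform(size=(2, 8, 8, 8)))
    with no_grad():
        p = branch_predict(f, fi, params, 0, 32, 32, cfg.num_classes)
    assert p.shape == (2, cfg.num_classes, 32, 32)
    np.testing.assert_allclose(p.data.sum(axis=1), 1.0, atol=1e-5)
    # step-by-step recomposition with the attention module's own ops
    att_p = {k: params[f"head0.att.{k}"]
             for k in ("theta_w", "phi_w", "g_w", "wz_w", "wc_w")}
    with no_grad():
        att = dual_attention_t(concat([f, fi], axis=1), att_p)
        logits = conv2d(att, params["head0.w4.w"], params["head0.w4.b"])
        expect = softmax(bilinear_upsample(logits, 32, 32), axis=1)
    np.testing.assert_allclose(p.data, expect.data, atol=1e-12)


class TestGeneratorForward:
    def test_probability_map_contract(self, small_model):
        cfg, params, state = small_model
        x = np.random.default_rng(0).uniform(size=(1, 1, 64, 64))
        with no_grad():
            maps = generator_forward(Tensor(x), params, state, cfg,
                                     training=False)
        assert maps.P.shape == (1, cfg.num_classes, 64, 64)
        assert (maps.P >= 0).all()
        np.testing.assert_allclose(maps.P.sum(axis=1), 1.0, atol=1e-5)

    def test_probability_averaging_is_convex_combination(self):
        cfg = GeneratorConfig(base_width=4, num_classes=3,
                              block_counts=(1, 1, 1, 1),
                              average_logits=False)
        params, state = init_generator_params(cfg, np.random.default_rng(3))
        x = np.random.default_rng(0).uniform(size=(1, 1, 32, 32))
        with no_grad():
            maps = generator_forward(Tensor(x), params, state, cfg,
                                     training=False)
        stack = np.stack([maps.P0, maps.P1, maps.P2, maps.P3])
        assert (maps.P <= stack.max(axis=0) + 1e-12).all()
        assert (maps.P >= stack.min(axis=0) - 1e-12).all()
        np.testing.assert_allclose(
            maps.P, (maps.P0 + maps.P1 + maps.P2 + maps.P3) / 4, atol=1e-12)

    def test_branch_spatial_dims_agree(self, small_model):
        cfg, params, state = small_model
        x = np.random.default_rng(1).uniform(size=(1, 1, 64, 64))
        with no_grad():
            maps = generator_forward(Tensor(x), params, state, cfg,
                                     training=False)
        for f in (maps.F1, maps.F2, maps.F3, maps.F):
            assert f.shape[-2:] == maps.F0.shape[-2:]

    def test_forward_determinism(self, small_model):
        cfg, params, state = small_model
        x = np.random.default_rng(4).uniform(size=(1, 1, 64, 64))
        with no_grad():
            a = generator_forward(Tensor(x.copy()), params, state, cfg,
                                  training=False)
            b = generator_forward(Tensor(x.copy()), params, state, cfg,
                                  training=False)
        np.testing.assert_array_equal(a.P, b.P)

    def test_forward_finite_across_seeds(self, small_model):
        cfg, params, state = small_model
        for seed in range(10):
            x = np.random.default_rng(seed).uniform(size=(1, 1, 32, 32))
            with no_grad():
                maps = generator_forward(Tensor(x), params, state, cfg,
                                         training=False)
            assert np.isfinite(maps.P).all()

    def test_logit_averaging_mode(self):
        cfg = GeneratorConfig(base_width=4, num_classes=3,
                              block_counts=(1, 1, 1, 1), average_logits=True)
        params, state = init_generator_params(cfg, np.random.default_rng(0))
        x = np.random.default_rng(0).uniform(size=(1, 1, 32, 32))
        with no_grad():
            maps = generator_forward(Tensor(x), params, state, cfg,
                                     training=False)
        np.testing.assert_allclose(maps.P.sum(axis=1), 1.0, atol=1e-5)
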