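"""Multi-branch residual segmentation generator with dual-attention heads.

The backbone is a bottleneck residual network (stem: 7x7 stride-2
convolution + 3x3 stride-2 max pool; four stages of 1x1-reduce / 3x3 /
1x1-expand blocks with shortcut connections, expansion factor 4, default
block counts 3/4/6/3).  The four stage outputs, at strides 4/8/16/32, are
each reduced to a common branch width by a 1x1 convolution (+ BN + ReLU),
bilinearly upsampled to the stride-4 grid, and fused by channel
concatenation followed by a 3x3 and a 1x1 convolution.

Each of the four branches then concatenates the fused map with its own
stage map, applies the dual (spatial + channel) non-local attention head,
projects to the K class channels with a 1x1 convolution, upsamples to the
input resolution and applies a per-pixel softmax.  The four branch
predictions are averaged on the *logit* scale by default
(``GeneratorConfig.average_logits``): averaging probabilities instead
vetoes any class until a majority of branches has learned it, which
suppresses small organ classes long after the strongest branch segments
them correctly — set ``average_logits=False`` for the probability-mean
variant, whose output is then a convex combination of the branch maps.

Parameters live in a flat name -> Tensor registry so the optimiser,
checkpointing and gradient checks can enumerate every trainable array
exactly once.  Batch-norm running statistics are kept in a separate
non-trainable state dict.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, concat
from .attention import AttentionParams, reduced_channels, dual_attention_t
from .nnops import batch_norm, bilinear_upsample, conv2d, maxpool2d, softmax

__all__ = ["GeneratorConfig", "BranchMaps", "init_generator_params",
           "backbone_forward", "fuse_features", "branch_predict",
           "generator_forward", "upsample_bilinear"]

EXPANSION = 4  # bottleneck output channels = EXPANSION * stage width


@dataclass
class GeneratorConfig:
    in_channels: int = 1
    num_classes: int = 5
    base_width: int = 64
    block_counts: tuple[int, int, int, int] = (3, 4, 6, 3)
    use_batch_norm: bool = True
    average_logits: bool = True
    dtype: type = np.float64

    def __post_init__(self):
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")
        if self.base_width < 4:
            raise ValueError("base_width must be >= 4")
        if any(b < 1 for b in self.block_counts):
            raise ValueError("block_counts must all be >= 1")

    @property
    def stage_widths(self) -> tuple[int, ...]:
        w = self.base_width
        return (w, 2 * w, 4 * w, 8 * w)


@dataclass
class BranchMaps:
    """All intermediate maps of one generator pass (numpy views)."""
    F0: np.ndarray
    F1: np.ndarray
    F2: np.ndarray
    F3: np.ndarray
    F: np.ndarray
    P0: np.ndarray
    P1: np.ndarray
    P2: np.ndarray
    P3: np.ndarray
    P: np.ndarray
    P_tensor: Tensor | None = field(default=None, repr=False)


def _truncated_normal(rng: np.random.Generator, shape, std: float, dtype):
    v = rng.normal(0.0, std, size=shape)
    while True:
        bad = np.abs(v) > 2 * std
        if not bad.any():
            return v.astype(dtype)
        v[bad] = rng.normal(0.0, std, size=int(bad.sum()))


def he_std(shape, scale: float = 1.0) -> float:
    """Fan-in-scaled std for ReLU networks: scale * sqrt(2 / fan_in).

    ``shape`` is (out, in) for projections or (out, in, kh, kw) for
    convolution kernels.
    """
    fan_in = int(np.prod(shape[1:])) if len(shape) > 1 else int(shape[0])
    return float(scale * np.sqrt(2.0 / max(1, fan_in)))


class _ParamBuilder:
    def __init__(self, rng, std, dtype, scheme="fan_in"):
        self.rng, self.std, self.dtype = rng, std, dtype
        self.scheme = scheme
        self.params: dict[str, Tensor] = {}
        self.state: dict[str, dict] = {}

    def _std(self, shape):
        return he_std(shape) if self.scheme == "fan_in" else self.std

    def conv(self, name, oc, ic, k):
        shape = (oc, ic, k, k)
        self.params[f"{name}.w"] = Tensor(
            _truncated_normal(self.rng, shape, self._std(shape), self.dtype),
            requires_grad=True)
        self.params[f"{name}.b"] = Tensor(
            np.zeros(oc, dtype=self.dtype), requires_grad=True)

    def bn(self, name, c):
        self.params[f"{name}.gamma"] = Tensor(np.ones(c, dtype=self.dtype),
                                              requires_grad=True)
        self.params[f"{name}.beta"] = Tensor(np.zeros(c, dtype=self.dtype),
                                             requires_grad=True)
        self.state[name] = {"mean": np.zeros(c, dtype=self.dtype),
                            "var": np.ones(c, dtype=self.dtype)}

    def attention(self, name, c):
        t = reduced_channels(c)
        for pname, shape in (("theta_w", (t, c)), ("phi_w", (t, c)),
                             ("g_w", (t, c)), ("wz_w", (c, t)),
                             ("wc_w", (c, c))):
            self.params[f"{name}.{pname}"] = Tensor(
                _truncated_normal(self.rng, shape, self._std(shape),
                                  self.dtype),
                requires_grad=True)


def init_generator_params(cfg: GeneratorConfig, rng: np.random.Generator,
                          init_stddev: float = 0.02,
                          init_scheme: str = "fan_in"):
    """Build the full trainable registry (params) and BN state for ``cfg``.

    ``init_scheme="fan_in"`` draws each weight from a truncated normal with
    fan-in-scaled std (sqrt(2/fan_in), clipped at two sigma); ``"fixed"``
    uses ``init_stddev`` for every array.
    """
    b = _ParamBuilder(rng, init_stddev, cfg.dtype, init_scheme)
    w = cfg.base_width
    b.conv("stem", w, cfg.in_channels, 7)
    b.bn("stem.bn", w)
    in_c = w
    for s, (width, blocks) in enumerate(zip(cfg.stage_widths, cfg.block_counts)):
        out_c = width * EXPANSION
        for blk in range(blocks):
            pre = f"stage{s}.block{blk}"
            b.conv(f"{pre}.conv1", width, in_c, 1)
            b.bn(f"{pre}.bn1", width)
            b.conv(f"{pre}.conv2", width, width, 3)
            b.bn(f"{pre}.bn2", width)
            b.conv(f"{pre}.conv3", out_c, width, 1)
            b.bn(f"{pre}.bn3", out_c)
            if blk == 0:
                b.conv(f"{pre}.proj", out_c, in_c, 1)
                b.bn(f"{pre}.bnp", out_c)
            in_c = out_c
    # per-stage 1x1 reductions to the common branch width (w1, b1 of each branch)
    for s in range(4):
        b.conv(f"reduce{s}", w, cfg.stage_widths[s] * EXPANSION, 1)
        b.bn(f"reduce{s}.bn", w)
    # fusion (w2, b2, w3, b3)
    b.conv("fuse.w2", 4 * w, 4 * w, 3)
    b.conv("fuse.w3", w, 4 * w, 1)
    # branch heads: dual attention on concat(F, Fi) (2w channels) + 1x1 to K
    for s in range(4):
        b.attention(f"head{s}.att", 2 * w)
        b.conv(f"head{s}.w4", cfg.num_classes, 2 * w, 1)
    return b.params, b.state


def _bn(x, params, state, name, cfg, training):
    if not cfg.use_batch_norm:
        return x
    return batch_norm(x, params[f"{name}.gamma"], params[f"{name}.beta"],
                      state[name], training=training)


def _bottleneck(x, params, state, pre, stride, cfg, training):
    out = conv2d(x, params[f"{pre}.conv1.w"], params[f"{pre}.conv1.b"])
    out = _bn(out, params, state, f"{pre}.bn1", cfg, training).relu()
    out = conv2d(out, params[f"{pre}.conv2.w"], params[f"{pre}.conv2.b"],
                 stride=stride, pad=1)
    out = _bn(out, params, state, f"{pre}.bn2", cfg, training).relu()
    out = conv2d(out, params[f"{pre}.conv3.w"], params[f"{pre}.conv3.b"])
    out = _bn(out, params, state, f"{pre}.bn3", cfg, training)
    if f"{pre}.proj.w" in params:
        sc = conv2d(x, params[f"{pre}.proj.w"], params[f"{pre}.proj.b"],
                    stride=stride)
        sc = _bn(sc, params, state, f"{pre}.bnp", cfg, training)
    else:
        sc = x
    return (out + sc).relu()


def backbone_forward(image: Tensor, params, state, cfg: GeneratorConfig,
                     training: bool = True):
    """Run the residual backbone; returns the four stage outputs.

    Spatial strides are 4, 8, 16 and 32 relative to the input, with
    channel widths EXPANSION * (w, 2w, 4w, 8w).
    """
    n, c, h, w = image.shape
    if h % 32 or w % 32:
        raise ValueError(
            f"input spatial dims must be divisible by 32, got {h}x{w}")
    x = conv2d(image, params["stem.w"], params["stem.b"], stride=2, pad=3)
    x = _bn(x, params, state, "stem.bn", cfg, training).relu()
    x = maxpool2d(x, 3, 2, 1)
    outs = []
    for s, blocks in enumerate(cfg.block_counts):
        for blk in range(blocks):
            stride = 2 if (s > 0 and blk == 0) else 1
            x = _bottleneck(x, params, state, f"stage{s}.block{blk}",
                            stride, cfg, training)
        outs.append(x)
    return tuple(outs)


def upsample_bilinear(f, target_h: int, target_w: int):
    """Bilinear upsampling; accepts (C,H,W) numpy or (N,C,H,W) Tensor."""
    if isinstance(f, Tensor):
        return bilinear_upsample(f, target_h, target_w)
    arr = np.asarray(f, dtype=float)
    return bilinear_upsample(Tensor(arr[None]), target_h, target_w).data[0]


def fuse_features(f0: Tensor, f1: Tensor, f2: Tensor, f3: Tensor, params) -> Tensor:
    """F = ReLU(w3 . ReLU(w2 . cat(F0..F3) + b2) + b3)."""
    shapes = {t.shape[2:] for t in (f0, f1, f2, f3)}
    if len(shapes) != 1:
        raise ValueError(f"branch maps disagree on spatial dims: {shapes}")
    cat = concat([f0, f1, f2, f3], axis=1)
    x = conv2d(cat, params["fuse.w2.w"], params["fuse.w2.b"], pad=1).relu()
    return conv2d(x, params["fuse.w3.w"], params["fuse.w3.b"]).relu()


def _head_att_params(params, s) -> dict[str, Tensor]:
    return {k: params[f"head{s}.att.{k}"]
            for k in ("theta_w", "phi_w", "g_w", "wz_w", "wc_w")}


def branch_predict(f: Tensor, fi: Tensor, params, s: int, out_h: int,
                   out_w: int, num_classes: int,
                   return_logits: bool = False) -> Tensor:
    """One branch head: dual attention on cat(F, Fi), 1x1 to K classes,
    upsample to the input grid, per-pixel softmax."""
    if f.shape[2:] != fi.shape[2:]:
        raise ValueError("fused map and branch map disagree on spatial dims")
    att = dual_attention_t(concat([f, fi], axis=1), _head_att_params(params, s))
    logits = conv2d(att, params[f"head{s}.w4.w"], params[f"head{s}.w4.b"])
    logits = bilinear_upsample(logits, out_h, out_w)
    if return_logits:
        return logits
    return softmax(logits, axis=1)


def generator_forward(image, params, state, cfg: GeneratorConfig,
                      training: bool = True) -> BranchMaps:
    """Full forward pass producing all intermediate and final maps.

    ``image`` is (N, C, H, W) Tensor/array or (C, H, W) array.  The returned
    :class:`BranchMaps` holds numpy copies plus ``P_tensor``, the final
    prediction still attached to the tape for loss computation.
    """
    squeeze = False
    if not isinstance(image, Tensor):
        arr = np.asarray(image, dtype=cfg.dtype)
        if arr.ndim == 3:
            arr = arr[None]
            squeeze = True
        image = Tensor(arr)
    n, c, h, w = image.shape
    stages = backbone_forward(image, params, state, cfg, training)
    feats = []
    for s, stage_out in enumerate(stages):
        x = conv2d(stage_out, params[f"reduce{s}.w"], params[f"reduce{s}.b"])
        x = _bn(x, params, state, f"reduce{s}.bn", cfg, training).relu()
        if s > 0:
            x = bilinear_upsample(x, stages[0].shape[2], stages[0].shape[3])
        feats.append(x)
    f0, f1, f2, f3 = feats
    fused = fuse_features(f0, f1, f2, f3, params)
    if cfg.average_logits:
        logits = [branch_predict(fused, fi, params, s, h, w, cfg.num_classes,
                                 return_logits=True)
                  for s, fi in enumerate(feats)]
        mean_logits = (logits[0] + logits[1] + logits[2] + logits[3]) * 0.25
        p = softmax(mean_logits, axis=1)
        branch_probs = [softmax(l, axis=1) for l in logits]
    else:
        branch_probs = [branch_predict(fused, fi, params, s, h, w,
                                       cfg.num_classes)
                        for s, fi in enumerate(feats)]
        p = (branch_probs[0] + branch_probs[1]
             + branch_probs[2] + branch_probs[3]) * 0.25

    def _np(t):
        return t.data[0] if squeeze else t.data

    return BranchMaps(
        F0=_np(f0), F1=_np(f1), F2=_np(f2), F3=_np(f3), F=_np(fused),
        P0=_np(branch_probs[0]), P1=_np(branch_probs[1]),
        P2=_np(branch_probs[2]), P3=_np(branch_probs[3]),
        P=_np(p), P_tensor=p)
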