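"""Organ masking and the convolutional discriminator.

The discriminator never sees a raw segmentation: the segmentation first
*masks* the grayscale image (element-wise product of the image with each
foreground class channel), producing one isolated-organ image per class.
Gold-standard label maps are masked as one-hot stacks; generator
predictions are masked with their soft probabilities, which keeps the
operation differentiable so adversarial gradients reach the generator.

The discriminator is a plain CNN: five [3x3 conv (stride 1, padding 1) ->
ReLU -> 2x2 max pool] blocks that halve the resolution five times, then
two fully connected layers and a sigmoid.  Its output is clamped away from
exactly 0/1 before any logarithm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, as_tensor
from .nnops import conv2d, linear, maxpool2d

__all__ = ["DiscriminatorConfig", "init_discriminator_params",
           "mask_with_segmentation", "discriminator_forward", "PROB_EPS"]

PROB_EPS = 1e-7  # sigmoid/probability clamp before logarithms


@dataclass
class DiscriminatorConfig:
    in_channels: int = 4            # K - 1 masked organ channels
    conv_widths: tuple[int, ...] = (16, 32, 64, 128, 256)
    fc_width: int = 64
    input_size: int = 64
    include_image: bool = False     # optionally concatenate the raw image
    dtype: type = np.float64

    def __post_init__(self):
        if self.input_size % 32:
            raise ValueError("input_size must be divisible by 32 "
                             "(five 2x2 poolings)")
        if len(self.conv_widths) != 5:
            raise ValueError("exactly five convolutional widths expected")

    @property
    def flat_features(self) -> int:
        side = self.input_size // 32
        return self.conv_widths[-1] * side * side


def init_discriminator_params(cfg: DiscriminatorConfig,
                              rng: np.random.Generator,
                              init_stddev: float = 0.02,
                              init_scheme: str = "fan_in"):
    """Trainable registry for the discriminator (truncated-normal weights).

    With ``init_scheme="fan_in"`` each layer's std is sqrt(2/fan_in), which
    keeps activations at unit scale through the five conv layers; a fixed
    small std attenuates the signal ~5 orders of magnitude by the sigmoid,
    freezing the discriminator at 0.5 for the whole of a short run.
    """
    from .generator import he_std

    def tn(shape):
        std = he_std(shape) if init_scheme == "fan_in" else init_stddev
        v = rng.normal(0.0, std, size=shape)
        while True:
            bad = np.abs(v) > 2 * std
            if not bad.any():
                return v.astype(cfg.dtype)
            v[bad] = rng.normal(0.0, std, size=int(bad.sum()))

    params: dict[str, Tensor] = {}
    in_c = cfg.in_channels + (1 if cfg.include_image else 0)
    for i, width in enumerate(cfg.conv_widths):
        params[f"conv{i}.w"] = Tensor(tn((width, in_c, 3, 3)), requires_grad=True)
        params[f"conv{i}.b"] = Tensor(np.zeros(width, dtype=cfg.dtype),
                                      requires_grad=True)
        in_c = width
    params["fc1.w"] = Tensor(tn((cfg.flat_features, cfg.fc_width)),
                             requires_grad=True)
    params["fc1.b"] = Tensor(np.zeros(cfg.fc_width, dtype=cfg.dtype),
                             requires_grad=True)
    params["fc2.w"] = Tensor(tn((cfg.fc_width, 1)), requires_grad=True)
    params["fc2.b"] = Tensor(np.zeros(1, dtype=cfg.dtype), requires_grad=True)
    return params


def mask_with_segmentation(image, seg) -> Tensor:
    """Per-organ dot-product masks: channel c-1 = image * seg[c], c = 1..K-1.

    ``image``: (1, H, W) / (H, W) array or (N, 1, H, W) Tensor;
    ``seg``: matching (K, H, W) / (N, K, H, W) probability or one-hot map.
    The background channel (class 0) is dropped.
    """
    image = as_tensor(image)
    seg = as_tensor(seg)
    batched = seg.ndim == 4
    if not batched:
        if seg.ndim != 3:
            raise ValueError("segmentation must be (K, H, W) or (N, K, H, W)")
        seg = seg.reshape(1, *seg.shape)
        img = image.data
        if img.ndim == 2:
            img = img[None]
        image = Tensor(img[None])
    if image.shape[-2:] != seg.shape[-2:]:
        raise ValueError(
            f"image {image.shape[-2:]} and segmentation {seg.shape[-2:]} "
            "spatial dims differ")
    if (seg.data < -1e-6).any():
        raise ValueError("segmentation has negative entries")
    if (seg.data.sum(axis=1) > 1.0 + 1e-5).any():
        raise ValueError("segmentation pixel class-sums exceed 1")
    organs = seg[:, 1:]                      # drop background channel
    masked = organs * image                  # broadcast over organ channels
    return masked if batched else masked.reshape(*masked.shape[1:])


def discriminator_forward(masked, params, cfg: DiscriminatorConfig) -> Tensor:
    """Probability that the masked stack comes from the gold standard.

    Returns an (N, 1) tensor strictly inside (0, 1) (epsilon-clamped).
    """
    x = as_tensor(masked)
    if x.ndim == 3:
        x = x.reshape(1, *x.shape)
    n, c, h, w = x.shape
    if h != cfg.input_size or w != cfg.input_size:
        raise ValueError(
            f"discriminator expects {cfg.input_size}x{cfg.input_size} input, "
            f"got {h}x{w}")
    for i in range(5):
        x = conv2d(x, params[f"conv{i}.w"], params[f"conv{i}.b"], pad=1).relu()
        x = maxpool2d(x, 2, 2)
    x = x.reshape(n, cfg.flat_features)
    x = linear(x, params["fc1.w"], params["fc1.b"]).relu()
    x = linear(x, params["fc2.w"], params["fc2.b"])
    return x.sigmoid().clip(PROB_EPS, 1.0 - PROB_EPS)
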