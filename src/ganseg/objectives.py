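"""Loss functions of the adversarial segmentation model.

The generator minimises a multi-class pixel cross-entropy against the
gold-standard label map plus, weighted by the balance coefficient
``lambda``, a binary cross-entropy that asks the discriminator to call its
masked prediction real:

    G_loss = L_mec(g(x), y) + lambda * L_bec(d(mask(x, g(x))), 1)

The discriminator minimises the usual real/fake binary cross-entropy:

    D_loss = L_bec(d(mask(x, y)), 1) + L_bec(d(mask(x, g(x))), 0)

Gradient isolation is enforced structurally: ``discriminator_loss``
detaches the generator output before masking, and the training loop only
steps the parameter set a loss was differentiated for.

``multiclass_ce`` defaults to the pixel-summed form (batch-averaged); the
training loop uses ``pixel_reduction="mean"`` so that the loss scale is
independent of image resolution and commensurate with the O(1) adversarial
term that ``lambda`` balances (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .adversarial import PROB_EPS, discriminator_forward, mask_with_segmentation
from .autodiff import Tensor, as_tensor, concat, no_grad
from .generator import generator_forward

__all__ = ["LossReport", "multiclass_ce", "binary_ce", "generator_loss",
           "discriminator_loss", "total_objective", "gan_value_function"]


@dataclass
class LossReport:
    """Structured record of one loss evaluation."""
    L_mec: float = 0.0
    L_bec_real: float = 0.0
    L_bec_fake: float = 0.0
    L_bec_adv: float = 0.0
    G_loss: float = 0.0
    D_loss: float = 0.0
    lam: float = 0.0

    @property
    def V(self) -> float:
        return self.G_loss + self.D_loss


def multiclass_ce(label_onehot, pred_probs, pixel_reduction: str = "sum") -> Tensor:
    """Multi-class cross-entropy  -sum_pixels sum_classes x * ln(y).

    Accepts (K, H, W) or batched (N, K, H, W) inputs; batched inputs are
    averaged over the batch.  ``pixel_reduction`` chooses whether the pixel
    dimension is summed (the classical definition) or averaged.
    """
    x = as_tensor(label_onehot)
    y = as_tensor(pred_probs)
    if x.shape != y.shape:
        raise ValueError(f"label {x.shape} and prediction {y.shape} differ")
    batched = y.ndim == 4
    y = y.clip(PROB_EPS, 1.0)
    ll = x.detach() * y.log()
    if batched:
        per_sample = ll.sum(axis=(1, 2, 3)) * -1.0
        loss = per_sample.mean()
        n_px = y.shape[2] * y.shape[3]
    else:
        loss = ll.sum() * -1.0
        n_px = y.shape[1] * y.shape[2]
    if pixel_reduction == "mean":
        loss = loss * (1.0 / n_px)
    elif pixel_reduction != "sum":
        raise ValueError("pixel_reduction must be 'sum' or 'mean'")
    return loss


def binary_ce(x: float, y) -> Tensor:
    """Binary cross-entropy  -[x ln y + (1-x) ln(1-y)] for target x in {0,1}.

    ``y`` may be a scalar or an (N, 1) tensor of probabilities; batched
    inputs are averaged.
    """
    y = as_tensor(y)
    if y.data.size == 1 and y.ndim == 0:
        y = y.reshape(1)
    y = y.clip(PROB_EPS, 1.0 - PROB_EPS)
    x = float(x)
    loss = (y.log() * -x + (1.0 - y).log() * -(1.0 - x))
    return loss.mean()


def onehot(labels: np.ndarray, num_classes: int, dtype=float) -> np.ndarray:
    """(H, W) or (N, H, W) integer labels -> (.., K, H, W) one-hot float map."""
    labels = np.asarray(labels)
    eye = np.eye(num_classes, dtype=dtype)
    oh = eye[labels]                         # (.., H, W, K)
    return np.moveaxis(oh, -1, -3)


def generator_loss(images, labels, gen, disc, lam: float = 0.2,
                   pixel_reduction: str = "sum", gain: float = 1.0):
    """Segmentation + adversarial loss of the generator (scalar, report).

    ``gen``/``disc`` are (params, state, cfg) / (params, cfg) bundles; the
    discriminator parameters participate in the graph but the training loop
    never steps them from this loss.
    """
    gparams, gstate, gcfg = gen
    dparams, dcfg = disc
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    imgs = np.asarray(images, dtype=gcfg.dtype)
    if imgs.ndim == 3:             # (n, H, W) grayscale batch
        imgs = imgs[:, None]
    maps = generator_forward(imgs, gparams, gstate, gcfg, training=True)
    y_onehot = onehot(np.asarray(labels), gcfg.num_classes, dtype=gcfg.dtype)
    if maps.P_tensor.ndim == 4 and y_onehot.ndim == 3:
        y_onehot = y_onehot[None]
    l_mec = multiclass_ce(y_onehot, maps.P_tensor, pixel_reduction)
    report = LossReport(L_mec=l_mec.item(), lam=lam)
    if lam > 0:
        masked = mask_with_segmentation(Tensor(imgs), maps.P_tensor)
        d_fake = discriminator_forward(masked, dparams, dcfg)
        l_adv = binary_ce(1.0, d_fake)
        report.L_bec_adv = l_adv.item()
        # under "mean" the whole objective is the pixel-summed loss divided
        # by H*W, so the adversarial term is scaled identically and lambda
        # keeps its balancing role between the two terms
        adv_scale = lam
        if pixel_reduction == "mean":
            adv_scale = lam / (imgs.shape[-2] * imgs.shape[-1])
        loss = l_mec + l_adv * adv_scale
    else:
        loss = l_mec
    if gain != 1.0:
        # overall objective scale (see docs/methods.md, "Loss scale"):
        # reports stay on the unscaled component scale
        loss = loss * float(gain)
    report.G_loss = l_mec.item() + (lam * report.L_bec_adv if lam > 0 else 0.0)
    return loss, report


def discriminator_loss(images, labels, gen, disc):
    """Real/fake binary cross-entropy of the discriminator (scalar, report).

    The generator output is detached: this loss has exactly zero gradient
    with respect to the generator parameters.
    """
    gparams, gstate, gcfg = gen
    dparams, dcfg = disc
    imgs = np.asarray(images, dtype=gcfg.dtype)
    if imgs.ndim == 3:
        imgs = imgs[:, None]
    # generator output is a constant for this loss: skip tape construction
    with no_grad():
        maps = generator_forward(imgs, gparams, gstate, gcfg, training=True)
    fake_seg = maps.P_tensor.detach()
    real_seg = onehot(np.asarray(labels), gcfg.num_classes, dtype=gcfg.dtype)
    img_t = Tensor(imgs)
    # one discriminator pass over the stacked real+fake batch
    masked_real = mask_with_segmentation(img_t, Tensor(real_seg))
    masked_fake = mask_with_segmentation(img_t, fake_seg)
    both = concat([masked_real, masked_fake], axis=0)
    d_both = discriminator_forward(both, dparams, dcfg)
    n = imgs.shape[0]
    d_real = d_both[:n]
    d_fake = d_both[n:]
    l_real = binary_ce(1.0, d_real)
    l_fake = binary_ce(0.0, d_fake)
    loss = l_real + l_fake
    report = LossReport(L_bec_real=l_real.item(), L_bec_fake=l_fake.item(),
                        D_loss=loss.item())
    return loss, report


def total_objective(g_report: LossReport, d_report: LossReport) -> float:
    """Combined objective V = G_loss + D_loss of one alternation step."""
    return g_report.G_loss + d_report.D_loss


def gan_value_function(d_real, d_fake) -> float:
    """Classical GAN value  E[log D(x)] + E[log(1 - D(G(z)))].

    Documentation-level diagnostic only; training optimises the explicit
    generator/discriminator losses above.
    """
    d_real = np.clip(np.asarray(d_real, dtype=float), PROB_EPS, 1 - PROB_EPS)
    d_fake = np.clip(np.asarray(d_fake, dtype=float), PROB_EPS, 1 - PROB_EPS)
    return float(np.mean(np.log(d_real)) + np.mean(np.log(1.0 - d_fake)))
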