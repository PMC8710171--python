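"""Alternating adversarial training with minibatch gradient descent.

One *meta-cycle* performs ``k`` discriminator updates followed by a single
generator update (default 6:1, the ratio that keeps the discriminator
ahead during adversarial play).  Both networks are updated with plain
minibatch gradient descent — ``w <- w - eta * mean-gradient`` — with no
momentum.  Weights are initialised from a truncated normal clipped at two
standard deviations; by default the per-layer sigma is fan-in-scaled
(sqrt(2/fan_in), the ReLU-preserving choice), with a fixed-sigma variant
behind ``TrainConfig.init_scheme="fixed"``.  Biases start at zero and
batch-norm scales at one.

An *epoch* is one pass over the generator's shuffled batch stream; each
generator batch triggers ``k`` discriminator rounds drawn from a separate
shuffled stream, so both networks see data without replacement within
their own passes.

Backpropagation is performed by the package's autodiff tape;
:func:`gradient_check` provides the central-difference conformance test
that pins the analytic gradients to the loss surfaces.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .adversarial import DiscriminatorConfig, init_discriminator_params
from .autodiff import Tensor
from .generator import GeneratorConfig, init_generator_params
from .objectives import discriminator_loss, generator_loss

logger = logging.getLogger(__name__)

__all__ = ["TrainConfig", "TrainState", "init_params", "mbgd_step",
           "train_discriminator_round", "train_generator_round", "train",
           "gradient_check", "truncated_normal"]


@dataclass
class TrainConfig:
    learning_rate: float = 0.01
    epochs: int = 200
    batch_size: int = 10
    k: int = 6                      # discriminator rounds per generator round
    lam: float = 0.2                # adversarial balance coefficient
    seed: int = 0
    init_stddev: float = 0.02
    deterministic: bool = False
    pixel_reduction: str = "mean"   # loss scale used by the training loop
    loss_gain: float = 32.0         # objective gain (see docs/methods.md)
    init_scheme: str = "fan_in"     # "fan_in" (He-scaled) or "fixed"

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")


@dataclass
class TrainState:
    gen_params: dict
    gen_state: dict
    disc_params: dict
    gen_cfg: GeneratorConfig
    disc_cfg: DiscriminatorConfig
    cfg: TrainConfig
    rng: np.random.Generator
    epoch: int = 0
    n_disc_updates: int = 0
    n_gen_updates: int = 0
    history: list = field(default_factory=list)
    best_val_dice: float = -1.0
    best_epoch: int = -1
    best_gen_params: dict | None = None
    best_gen_state: dict | None = None

    def snapshot_best(self, val_dice: float) -> None:
        """Keep a copy of the generator if validation Dice improved."""
        if val_dice > self.best_val_dice:
            self.best_val_dice = float(val_dice)
            self.best_epoch = self.epoch
            self.best_gen_params = {n: Tensor(t.data.copy())
                                    for n, t in self.gen_params.items()}
            self.best_gen_state = {n: {k: v.copy() for k, v in s.items()}
                                   for n, s in self.gen_state.items()}


def truncated_normal(rng: np.random.Generator, shape, std: float,
                     dtype=np.float64) -> np.ndarray:
    """Normal(0, std^2) truncated at +-2 std."""
    return stats.truncnorm.rvs(-2.0, 2.0, scale=std, size=shape,
                               random_state=rng).astype(dtype)


def init_params(gen_cfg: GeneratorConfig, disc_cfg: DiscriminatorConfig,
                cfg: TrainConfig):
    """Seeded initialisation of both parameter sets."""
    rng = np.random.default_rng(cfg.seed)
    gp, gs = init_generator_params(gen_cfg, rng, cfg.init_stddev,
                                   cfg.init_scheme)
    dp = init_discriminator_params(disc_cfg, rng, cfg.init_stddev,
                                   cfg.init_scheme)
    return gp, gs, dp


def mbgd_step(params: dict[str, Tensor], eta: float) -> None:
    """One plain gradient-descent step over a parameter registry.

    Gradients must already be minibatch means (the losses average over the
    batch).  Parameters without a gradient raise, so a registry/graph
    mismatch cannot pass silently.
    """
    for name, p in params.items():
        if p.grad is None:
            raise ValueError(f"parameter {name!r} has no gradient")
        if p.grad.shape != p.data.shape:
            raise ValueError(f"gradient shape mismatch for {name!r}")
        p.data -= eta * p.grad


def _zero_grads(params: dict[str, Tensor]) -> None:
    for p in params.values():
        p.grad = None


def train_discriminator_round(state: TrainState, images, labels) -> None:
    """One discriminator update; the generator is bit-for-bit untouched."""
    gen = (state.gen_params, state.gen_state, state.gen_cfg)
    disc = (state.disc_params, state.disc_cfg)
    _zero_grads(state.disc_params)
    _zero_grads(state.gen_params)
    loss, report = discriminator_loss(images, labels, gen, disc)
    loss.backward()
    mbgd_step(state.disc_params, state.cfg.learning_rate)
    state.n_disc_updates += 1
    state.history.append({"role": "disc", "epoch": state.epoch,
                          "n_update": state.n_disc_updates,
                          "D_loss": report.D_loss,
                          "L_bec_real": report.L_bec_real,
                          "L_bec_fake": report.L_bec_fake})


def train_generator_round(state: TrainState, images, labels) -> None:
    """One generator update; the discriminator parameters are untouched."""
    gen = (state.gen_params, state.gen_state, state.gen_cfg)
    disc = (state.disc_params, state.disc_cfg)
    _zero_grads(state.gen_params)
    _zero_grads(state.disc_params)
    loss, report = generator_loss(images, labels, gen, disc,
                                  lam=state.cfg.lam,
                                  pixel_reduction=state.cfg.pixel_reduction,
                                  gain=state.cfg.loss_gain)
    loss.backward()
    mbgd_step(state.gen_params, state.cfg.learning_rate)
    _zero_grads(state.disc_params)  # adversarial term touched them; discard
    state.n_gen_updates += 1
    state.history.append({"role": "gen", "epoch": state.epoch,
                          "n_update": state.n_gen_updates,
                          "G_loss": report.G_loss, "L_mec": report.L_mec,
                          "L_bec_adv": report.L_bec_adv})


class _BatchStream:
    """Endless without-replacement batch sampler (reshuffles per pass)."""

    def __init__(self, n: int, batch_size: int, rng: np.random.Generator):
        self.n, self.bs, self.rng = n, batch_size, rng
        self._order: list[int] = []

    def next(self) -> np.ndarray:
        while len(self._order) < self.bs:
            self._order.extend(self.rng.permutation(self.n).tolist())
        batch, self._order = self._order[:self.bs], self._order[self.bs:]
        return np.asarray(batch)


def init_state(gen_cfg: GeneratorConfig, disc_cfg: DiscriminatorConfig,
               cfg: TrainConfig) -> TrainState:
    gp, gs, dp = init_params(gen_cfg, disc_cfg, cfg)
    return TrainState(gen_params=gp, gen_state=gs, disc_params=dp,
                      gen_cfg=gen_cfg, disc_cfg=disc_cfg, cfg=cfg,
                      rng=np.random.default_rng(cfg.seed + 1))


def train(images: np.ndarray, labels: np.ndarray, cfg: TrainConfig,
          gen_cfg: GeneratorConfig | None = None,
          disc_cfg: DiscriminatorConfig | None = None,
          state: TrainState | None = None,
          validation: tuple[np.ndarray, np.ndarray] | None = None,
          callback=None) -> TrainState:
    """Run the alternating schedule over a (n, H, W) image/label dataset.

    An epoch iterates the generator batch stream once (``n // batch_size``
    meta-cycles, each of ``k`` discriminator rounds plus one generator
    round).  ``state`` may be a previously saved state to resume from.
    When ``validation`` image/label arrays are given, mean foreground Dice
    is measured after every epoch and the best generator snapshot is kept
    on the state (``best_gen_params``, ``best_epoch``).
    """
    images = np.asarray(images, dtype=float)
    labels = np.asarray(labels)
    if images.ndim != 3 or images.shape != labels.shape:
        raise ValueError("expected matching (n, H, W) images and labels")
    n = images.shape[0]
    if n == 0:
        raise ValueError("empty dataset")
    if state is None:
        if gen_cfg is None:
            gen_cfg = GeneratorConfig()
        if disc_cfg is None:
            disc_cfg = DiscriminatorConfig(
                in_channels=gen_cfg.num_classes - 1,
                input_size=images.shape[1])
        state = init_state(gen_cfg, disc_cfg, cfg)
    gen_stream = _BatchStream(n, cfg.batch_size, state.rng)
    disc_stream = _BatchStream(n, cfg.batch_size, state.rng)
    cycles_per_epoch = max(1, n // cfg.batch_size)
    start_epoch = state.epoch
    if cfg.deterministic:
        # single-threaded BLAS for bitwise-reproducible reductions
        from threadpoolctl import threadpool_limits
        ctx = threadpool_limits(limits=1)
    else:
        import contextlib
        ctx = contextlib.nullcontext()
    with ctx:
        _run_epochs(state, images, labels, cfg, gen_stream, disc_stream,
                    cycles_per_epoch, start_epoch, validation, callback)
    return state


def validation_dice(state: TrainState, images: np.ndarray,
                    labels: np.ndarray) -> float:
    """Mean foreground Dice of the current generator on a dataset."""
    from .autodiff import no_grad
    from .evaluation import evaluate_predictions, label_map_from_probs
    from .generator import generator_forward
    preds = []
    bs = state.cfg.batch_size
    with no_grad():
        for i in range(0, len(images), bs):
            batch = np.asarray(images[i:i + bs],
                               dtype=state.gen_cfg.dtype)[:, None]
            maps = generator_forward(Tensor(batch), state.gen_params,
                                     state.gen_state, state.gen_cfg,
                                     training=False)
            preds += [label_map_from_probs(p) for p in maps.P]
    report = evaluate_predictions(preds, labels, state.gen_cfg.num_classes)
    return report.mean_foreground_dice


def _run_epochs(state, images, labels, cfg, gen_stream, disc_stream,
                cycles_per_epoch, start_epoch, validation, callback):
    for epoch in range(start_epoch, cfg.epochs):
        state.epoch = epoch
        t0 = time.time()
        for _ in range(cycles_per_epoch):
            for _ in range(cfg.k):
                idx = disc_stream.next()
                train_discriminator_round(state, images[idx], labels[idx])
            idx = gen_stream.next()
            train_generator_round(state, images[idx], labels[idx])
        state.epoch = epoch + 1
        last = [h for h in state.history if h["role"] == "gen"][-1]
        logger.info("epoch %d: L_mec=%.4f G_loss=%.4f (%.1fs)", epoch,
                    last["L_mec"], last["G_loss"], time.time() - t0)
        if validation is not None:
            state.snapshot_best(validation_dice(state, *validation))
        if callback is not None:
            callback(state)


def gradient_check(loss_fn, params: dict[str, Tensor], rng: np.random.Generator,
                   n_coords: int = 50, eps: float = 1e-6,
                   atol_floor: float = 1e-6) -> float:
    """Worst relative error of analytic vs central-difference gradients.

    ``loss_fn()`` must rebuild the graph from ``params`` on every call.
    ``n_coords`` coordinates are sampled size-weighted across the registry.

    The step size is adapted per coordinate (``eps`` down to ``eps/1000``,
    best agreement kept): deep networks mix stiff, high-curvature directions
    — where the truncation error of a fixed step dominates — with nearly
    flat ones, where a too-small step drowns in round-off.  ``atol_floor``
    bounds the relative-error denominator so that coordinates whose
    gradient is essentially zero are compared absolutely, the same
    convention numerical grad-checkers in mainstream frameworks use.
    """
    loss = loss_fn()
    for p in params.values():
        p.grad = None
    loss.backward()
    names = list(params)
    sizes = np.array([params[k].data.size for k in names], dtype=float)
    worst = 0.0
    for _ in range(n_coords):
        name = names[rng.choice(len(names), p=sizes / sizes.sum())]
        p = params[name]
        i = int(rng.integers(p.data.size))
        flat = p.data.reshape(-1)
        analytic = p.grad.reshape(-1)[i]
        best = np.inf
        for step in (eps, eps / 10, eps / 100, eps / 1000):
            old = flat[i]
            flat[i] = old + step
            lp = loss_fn().item()
            flat[i] = old - step
            lm = loss_fn().item()
            flat[i] = old
            numeric = (lp - lm) / (2 * step)
            denom = max(abs(numeric), abs(analytic), atol_floor)
            best = min(best, abs(numeric - analytic) / denom)
            if best < 1e-4:
                break
        worst = max(worst, best)
    return worst
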