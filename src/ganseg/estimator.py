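"""Scikit-learn style estimator wrapping the adversarial segmenter.

:class:`GANSegmenter` exposes the whole pipeline — parameter
initialisation, alternating adversarial training, label-map inference and
Dice scoring — through the familiar ``fit`` / ``predict`` / ``score``
surface, so it composes with sklearn model selection and pipelines.  All
hyperparameters are constructor arguments recoverable via ``get_params``;
fitted state lives in trailing-underscore attributes.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .adversarial import DiscriminatorConfig
from .autodiff import Tensor, no_grad
from .evaluation import evaluate_predictions, label_map_from_probs
from .generator import GeneratorConfig, generator_forward
from .training import TrainConfig, init_state, train

__all__ = ["GANSegmenter"]


class GANSegmenter(BaseEstimator):
    """Adversarial multi-organ segmenter with dual-attention generator.

    Parameters mirror the library's generator/discriminator/training
    configurations.  ``X`` is an (n, H, W) float array of grayscale images
    in [0, 1] with H = W divisible by 32; ``y`` is the matching (n, H, W)
    integer label-map array.

    Examples
    --------
    >>> seg = GANSegmenter(base_width=8, epochs=2, seed=0)
    >>> seg.fit(images, labels).predict(images[:3])  # doctest: +SKIP
    """

    def __init__(self, num_classes: int = 5, base_width: int = 8,
                 block_counts: tuple = (3, 4, 6, 3),
                 use_batch_norm: bool = True, average_logits: bool = True,
                 disc_widths: tuple = (16, 32, 64, 128, 256),
                 fc_width: int = 64, learning_rate: float = 0.01,
                 epochs: int = 30, batch_size: int = 10, k: int = 6,
                 lam: float = 0.2, init_stddev: float = 0.02,
                 pixel_reduction: str = "mean", loss_gain: float = 32.0,
                 deterministic: bool = False,
                 float32: bool = True, seed: int = 0):
        self.num_classes = num_classes
        self.base_width = base_width
        self.block_counts = block_counts
        self.use_batch_norm = use_batch_norm
        self.average_logits = average_logits
        self.disc_widths = disc_widths
        self.fc_width = fc_width
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.k = k
        self.lam = lam
        self.init_stddev = init_stddev
        self.pixel_reduction = pixel_reduction
        self.loss_gain = loss_gain
        self.deterministic = deterministic
        self.float32 = float32
        self.seed = seed

    # -- configuration assembly ----------------------------------------------

    def _dtype(self):
        return np.float32 if self.float32 else np.float64

    def _configs(self, image_size: int):
        gen_cfg = GeneratorConfig(
            in_channels=1, num_classes=self.num_classes,
            base_width=self.base_width,
            block_counts=tuple(self.block_counts),
            use_batch_norm=self.use_batch_norm,
            average_logits=self.average_logits, dtype=self._dtype())
        disc_cfg = DiscriminatorConfig(
            in_channels=self.num_classes - 1,
            conv_widths=tuple(self.disc_widths), fc_width=self.fc_width,
            input_size=image_size, dtype=self._dtype())
        train_cfg = TrainConfig(
            learning_rate=self.learning_rate, epochs=self.epochs,
            batch_size=self.batch_size, k=self.k, lam=self.lam,
            seed=self.seed, init_stddev=self.init_stddev,
            deterministic=self.deterministic,
            pixel_reduction=self.pixel_reduction, loss_gain=self.loss_gain)
        return gen_cfg, disc_cfg, train_cfg

    @staticmethod
    def _check_X(X):
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise ValueError("X must be (n_samples, H, W)")
        if X.shape[1] % 32 or X.shape[2] % 32:
            raise ValueError("image dims must be divisible by 32")
        return X

    # -- sklearn surface ------------------------------------------------------

    def fit(self, X, y, validation=None, callback=None):
        """Train on an image/label-map dataset.

        ``validation``: optional (images, labels) pair; when given, the
        generator snapshot with the best validation Dice is kept and used
        for prediction (early-stopping-style checkpoint selection).
        """
        X = self._check_X(X)
        y = np.asarray(y)
        if y.shape != X.shape:
            raise ValueError("y must match X's (n, H, W) shape")
        gen_cfg, disc_cfg, train_cfg = self._configs(X.shape[1])
        state = init_state(gen_cfg, disc_cfg, train_cfg)
        train(X.astype(gen_cfg.dtype), y, train_cfg, gen_cfg, disc_cfg,
              state=state, validation=validation, callback=callback)
        self.state_ = state
        self.generator_params_ = state.gen_params
        self.discriminator_params_ = state.disc_params
        self.history_ = state.history
        self.n_features_in_ = X.shape[1] * X.shape[2]
        return self

    def predict_proba(self, X):
        """Class-probability maps, (n, K, H, W)."""
        check_is_fitted(self, "state_")
        X = self._check_X(X)
        st = self.state_
        params = st.best_gen_params or st.gen_params
        bn_state = st.best_gen_state or st.gen_state
        out = []
        with no_grad():
            for i in range(0, len(X), self.batch_size):
                batch = X[i:i + self.batch_size].astype(st.gen_cfg.dtype)
                maps = generator_forward(Tensor(batch[:, None]),
                                         params, bn_state,
                                         st.gen_cfg, training=False)
                out.append(maps.P)
        return np.concatenate(out, axis=0)

    def predict(self, X):
        """Per-pixel argmax label maps, (n, H, W)."""
        probs = self.predict_proba(X)
        return np.stack([label_map_from_probs(p) for p in probs])

    def score(self, X, y):
        """Mean foreground Dice coefficient over the dataset."""
        preds = self.predict(X)
        report = evaluate_predictions(preds, np.asarray(y), self.num_classes)
        return report.mean_foreground_dice

    def report(self, X, y):
        """Full metrics report (confusion matrix, per-class, aggregates)."""
        preds = self.predict(X)
        return evaluate_predictions(preds, np.asarray(y), self.num_classes)
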