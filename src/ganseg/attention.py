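"""Non-local spatial and channel attention heads.

The non-local operator replaces each feature vector by a normalised,
affinity-weighted average of value features over *all* positions (or all
channels), giving every output a global receptive field:

    y_j = sum_i  A[i, j] * g(x_i),        A = column-softmax(f(x_i, x_j))

where ``f`` scores the compatibility of two positions.  Four classical
choices of ``f`` are provided (Gaussian, embedded Gaussian, projected dot
product, and a cascaded/concatenation form).  The model path uses projected
dot-product scores followed by a column softmax — mathematically the
normalised embedded-Gaussian — with the query/key/value projections reducing
the channel count to ``T = max(1, C // 4)``.

Each head is a residual block: a 1x1 output projection (``wz_w`` spatial,
``wc_w`` channel) restores the channel count and the input is added back,
so zeroed output weights make the head an exact identity.

Two implementations are maintained deliberately: the vectorised heads used
by the generator, and :func:`attention_oracle`, an explicit per-position /
per-channel loop kept free of matrix shortcuts, used by the test suite as
an independent reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, as_tensor, concat
from .nnops import conv2d, softmax

logger = logging.getLogger(__name__)

__all__ = [
    "AttentionParams", "affinity_matrix", "softmax_columns",
    "spatial_attention", "channel_attention", "dual_attention_head",
    "attention_oracle", "reduced_channels",
]


def reduced_channels(c: int) -> int:
    """Default bottleneck width of the attention projections: max(1, C // 4)."""
    t = c // 4
    if t < 1:
        logger.warning("attention: C=%d < 4; clamping projection width to 1", c)
        t = 1
    return t


@dataclass
class AttentionParams:
    """Projection weights of one dual-attention head.

    ``theta_w``/``phi_w``/``g_w`` map C -> T channels (1x1 convolutions,
    stored as (T, C) matrices); ``wz_w`` (C, T) restores the channel count
    on the spatial value path; ``wc_w`` (C, C) is the channel head's output
    weight; ``wf_w`` (2T,) is the cascade-mode score vector.
    """

    theta_w: np.ndarray
    phi_w: np.ndarray
    g_w: np.ndarray
    wz_w: np.ndarray
    wc_w: np.ndarray
    wf_w: np.ndarray | None = None

    @property
    def T(self) -> int:
        return self.theta_w.shape[0]

    @property
    def C(self) -> int:
        return self.theta_w.shape[1]

    @classmethod
    def init(cls, c: int, rng: np.random.Generator, scale: float = 0.02,
             t: int | None = None, dtype=np.float64) -> "AttentionParams":
        t = reduced_channels(c) if t is None else t
        def tn(*shape):
            v = rng.normal(0.0, scale, size=shape)
            while True:
                bad = np.abs(v) > 2 * scale
                if not bad.any():
                    return v.astype(dtype)
                v[bad] = rng.normal(0.0, scale, size=int(bad.sum()))
        return cls(theta_w=tn(t, c), phi_w=tn(t, c), g_w=tn(t, c),
                   wz_w=tn(c, t), wc_w=tn(c, c), wf_w=tn(2 * t))


def _flatten(f) -> np.ndarray:
    """(C, H, W) feature map -> (C, N) matrix of position vectors."""
    arr = f.data if isinstance(f, Tensor) else np.asarray(f)
    if arr.ndim != 3:
        raise ValueError(f"expected (C, H, W) feature map, got shape {arr.shape}")
    if not np.isfinite(arr).all():
        raise ValueError("feature map contains non-finite values")
    c = arr.shape[0]
    return arr.reshape(c, -1)


def affinity_matrix(f, params: AttentionParams, mode: str = "dot") -> np.ndarray:
    """Pairwise position-affinity matrix; entry (i, j) scores x_i against x_j.

    Modes: ``gaussian`` exp(x_i . x_j) on raw vectors; ``embedded``
    exp(theta(x_i) . phi(x_j)); ``dot`` theta(x_i) . phi(x_j); ``cascade``
    ReLU(wf . [theta(x_i), phi(x_j)]).  The result is unnormalised.
    """
    x = _flatten(f)                          # (C, N)
    if mode == "gaussian":
        return np.exp(x.T @ x)
    if params.theta_w.shape[1] != x.shape[0]:
        raise ValueError(
            f"projection expects {params.theta_w.shape[1]} channels, "
            f"feature map has {x.shape[0]}")
    q = params.theta_w @ x                   # (T, N)
    k = params.phi_w @ x
    if mode == "embedded":
        return np.exp(q.T @ k)
    if mode == "dot":
        return q.T @ k
    if mode == "cascade":
        if params.wf_w is None:
            raise ValueError("cascade mode requires wf_w")
        t = params.T
        s = params.wf_w[:t] @ q              # (N,) contribution of theta(x_i)
        r = params.wf_w[t:] @ k              # (N,) contribution of phi(x_j)
        return np.maximum(s[:, None] + r[None, :], 0.0)
    raise ValueError(f"unknown affinity mode {mode!r}")


def softmax_columns(m: np.ndarray) -> np.ndarray:
    """Normalise every column of ``m`` to a softmax distribution."""
    m = np.asarray(m, dtype=float)
    if not np.isfinite(m).all():
        raise ValueError("affinity matrix contains non-finite values")
    z = m - m.max(axis=0, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=0, keepdims=True)


# -- batched tensor heads (used inside the generator) -------------------------

def _as_param_tensors(params: AttentionParams) -> dict[str, Tensor]:
    return {k: as_tensor(getattr(params, k))
            for k in ("theta_w", "phi_w", "g_w", "wz_w", "wc_w")}


def spatial_attention_t(x: Tensor, p: dict[str, Tensor]) -> Tensor:
    """Spatial head on an (N, C, H, W) tensor; output shape equals input."""
    n, c, h, w = x.shape
    hw = h * w
    t = p["theta_w"].shape[0]
    flat = x.reshape(n, c, hw)                       # (N, C, HW)
    q = p["theta_w"] @ flat                          # (N, T, HW)
    k = p["phi_w"] @ flat
    v = p["g_w"] @ flat
    scores = q.transpose(0, 2, 1) @ k                # (N, HW, HW); (i, j)
    aff = softmax(scores, axis=1)                    # columns sum to 1
    y = v @ aff                                      # y[:, j] = sum_i aff[i,j] v[:, i]
    z = p["wz_w"] @ y                                # restore C channels
    return z.reshape(n, c, h, w) + x


def channel_attention_t(x: Tensor, p: dict[str, Tensor]) -> Tensor:
    """Channel head: affinity over channels of the raw reshaped features."""
    n, c, h, w = x.shape
    flat = x.reshape(n, c, h * w)                    # (N, C, HW)
    scores = flat @ flat.transpose(0, 2, 1)          # (N, C, C); (i, j) = x_i . x_j
    aff = softmax(scores, axis=1)
    y = aff.transpose(0, 2, 1) @ flat                # y[j] = sum_i aff[i,j] x_i
    z = p["wc_w"] @ y
    return z.reshape(n, c, h, w) + x


def dual_attention_t(x: Tensor, p: dict[str, Tensor]) -> Tensor:
    return spatial_attention_t(x, p) + channel_attention_t(x, p)


# -- unbatched numpy wrappers (the module's public operations) ----------------

def _apply_head(f, params: AttentionParams, head) -> np.ndarray:
    arr = np.asarray(f.data if isinstance(f, Tensor) else f, dtype=float)
    _flatten(arr)  # validation
    out = head(Tensor(arr[None]), _as_param_tensors(params))
    return out.data[0]


def spatial_attention(f, params: AttentionParams) -> np.ndarray:
    """Non-local spatial attention with residual connection, (C, H, W) in/out."""
    return _apply_head(f, params, spatial_attention_t)


def channel_attention(f, params: AttentionParams) -> np.ndarray:
    """Non-local channel attention with residual connection, (C, H, W) in/out."""
    return _apply_head(f, params, channel_attention_t)


def dual_attention_head(f, params: AttentionParams) -> np.ndarray:
    """Sum of the spatial and channel heads (each already residual)."""
    return spatial_attention(f, params) + channel_attention(f, params)


# -- loop oracle --------------------------------------------------------------

def attention_oracle(f, params: AttentionParams, mode: str = "spatial") -> np.ndarray:
    """Explicit-loop recomputation of one head; test reference only, O(N^2 T).

    No matrix algebra over positions: every pairwise score, every softmax
    column and every weighted average is accumulated with Python loops.
    """
    arr = np.asarray(f.data if isinstance(f, Tensor) else f, dtype=float)
    c, h, w = arr.shape
    n = h * w
    if n > 256 and mode == "spatial":
        raise ValueError("oracle is for small inputs only (N <= 256)")
    x = arr.reshape(c, n)

    if mode == "spatial":
        q = [params.theta_w @ x[:, i] for i in range(n)]
        k = [params.phi_w @ x[:, j] for j in range(n)]
        v = [params.g_w @ x[:, j] for j in range(n)]
        out = np.zeros((c, n))
        for j in range(n):
            scores = np.array([float(q[i] @ k[j]) for i in range(n)])
            e = np.exp(scores - scores.max())
            wgt = e / e.sum()
            y_j = np.zeros(params.T)
            for i in range(n):
                y_j += wgt[i] * v[i]
            out[:, j] = params.wz_w @ y_j + x[:, j]
        return out.reshape(c, h, w)

    if mode == "channel":
        out = np.zeros((c, n))
        agg = np.zeros((c, n))
        for j in range(c):
            scores = np.array([float(x[i] @ x[j]) for i in range(c)])
            e = np.exp(scores - scores.max())
            wgt = e / e.sum()
            for i in range(c):
                agg[j] += wgt[i] * x[i]
        for j in range(c):
            out[j] = params.wc_w[j] @ agg + x[j]
        return out.reshape(c, h, w)

    if mode == "dual":
        return (attention_oracle(arr, params, "spatial")
                + attention_oracle(arr, params, "channel"))
    raise ValueError(f"unknown oracle mode {mode!r}")
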