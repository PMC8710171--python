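"""Structured network operations on :class:`~ganseg.autodiff.Tensor`.

All operations take and return NCHW tensors (batch, channel, row, col) and
register exact backward rules on the autodiff tape:

* ``conv2d`` — im2col + BLAS matmul; backward via col2im scatter.
* ``maxpool2d`` — windowed max with argmax routing in the backward pass.
* ``bilinear_upsample`` — separable 1-D interpolation matrices
  (half-pixel-centre / align-corners-false convention), so both directions
  are plain matmuls.
* ``softmax`` — numerically stabilised (max subtraction) fused op.
* ``batch_norm`` — composed from differentiable primitives; running
  statistics are updated in-place as non-differentiable state.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, _bind

__all__ = [
    "conv2d", "linear", "maxpool2d", "bilinear_upsample",
    "softmax", "batch_norm", "interp_matrix",
]


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    """(N,C,H,W) -> (N, C*kh*kw, OH*OW) patch matrix."""
    n, c, h, w = x.shape
    oh = (h + 2 * pad - kh) // stride + 1
    ow = (w + 2 * pad - kw) // stride + 1
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    cols = np.empty((n, c, kh, kw, oh, ow), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = x[:, :, i:i + stride * oh:stride,
                                 j:j + stride * ow:stride]
    return cols.reshape(n, c * kh * kw, oh * ow), oh, ow


def _col2im(cols: np.ndarray, shape, kh: int, kw: int, stride: int, pad: int):
    """Adjoint of :func:`_im2col`: scatter-add patches back to (N,C,H,W)."""
    n, c, h, w = shape
    oh = (h + 2 * pad - kh) // stride + 1
    ow = (w + 2 * pad - kw) // stride + 1
    xp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=cols.dtype)
    cols6 = cols.reshape(n, c, kh, kw, oh, ow)
    for i in range(kh):
        for j in range(kw):
            xp[:, :, i:i + stride * oh:stride,
               j:j + stride * ow:stride] += cols6[:, :, i, j]
    if pad:
        xp = xp[:, :, pad:pad + h, pad:pad + w]
    return xp


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, pad: int = 0) -> Tensor:
    """2-D cross-correlation. ``w``: (OC, C, kh, kw); ``b``: (OC,) or None."""
    n, c, h, wdt = x.shape
    oc, ci, kh, kw = w.shape
    if ci != c:
        raise ValueError(f"conv2d: input has {c} channels, kernel expects {ci}")
    cols, oh, ow = _im2col(x.data, kh, kw, stride, pad)
    w2d = w.data.reshape(oc, -1)
    out = np.matmul(w2d[None], cols)                  # (N, OC, OH*OW)
    if b is not None:
        out = out + b.data[None, :, None]
    out = out.reshape(n, oc, oh, ow)

    parents = (x, w) if b is None else (x, w, b)

    def backward(g, out_ref=[None]):
        node = out_ref[0]
        g2 = g.reshape(n, oc, oh * ow)
        if w.requires_grad:
            # single GEMM over the fused (batch, position) axes
            gw = np.tensordot(g2, cols, axes=([0, 2], [0, 2]))
            node._send(w, gw.reshape(w.shape))
        if b is not None and b.requires_grad:
            node._send(b, g2.sum(axis=(0, 2)))
        if x.requires_grad:
            gcols = np.matmul(w2d.T[None], g2)
            node._send(x, _col2im(gcols, x.shape, kh, kw, stride, pad))

    return _bind(Tensor._make(out, parents, lambda g: None), backward)


def linear(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Fully connected layer: (N, D) @ (D, M) + b."""
    out = x @ w
    if b is not None:
        out = out + b
    return out


def maxpool2d(x: Tensor, k: int = 2, stride: int | None = None,
              pad: int = 0) -> Tensor:
    """Max pooling with a k x k window."""
    stride = k if stride is None else stride
    n, c, h, w = x.shape
    xpad = x.data
    if pad:
        xpad = np.pad(xpad, ((0, 0), (0, 0), (pad, pad), (pad, pad)),
                      constant_values=-np.inf)
    oh = (h + 2 * pad - k) // stride + 1
    ow = (w + 2 * pad - k) // stride + 1
    # window axis kept last and contiguous so argmax runs at memory speed
    win = np.empty((n, c, oh, ow, k * k), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            win[..., i * k + j] = xpad[:, :, i:i + stride * oh:stride,
                                       j:j + stride * ow:stride]
    arg = win.argmax(axis=-1)
    out = np.take_along_axis(win, arg[..., None], axis=-1)[..., 0]

    def backward(g, out_ref=[None]):
        gcols = np.zeros((n, c, oh, ow, k * k), dtype=g.dtype)
        np.put_along_axis(gcols, arg[..., None], g[..., None], axis=-1)
        # scatter windows back (adjoint of the gather above)
        hp, wp = h + 2 * pad, w + 2 * pad
        gx = np.zeros((n, c, hp, wp), dtype=g.dtype)
        for i in range(k):
            for j in range(k):
                gx[:, :, i:i + stride * oh:stride,
                   j:j + stride * ow:stride] += gcols[..., i * k + j]
        if pad:
            gx = gx[:, :, pad:pad + h, pad:pad + w]
        out_ref[0]._send(x, gx)

    return _bind(Tensor._make(out, (x,), lambda g: None), backward)


def interp_matrix(n_out: int, n_in: int, dtype=np.float64) -> np.ndarray:
    """1-D bilinear interpolation matrix (half-pixel centres, edges clamped).

    ``y = R @ x`` resamples a length-``n_in`` signal to ``n_out`` samples,
    matching the align-corners-false convention of mainstream frameworks.
    """
    r = np.zeros((n_out, n_in), dtype=dtype)
    scale = n_in / n_out
    for o in range(n_out):
        src = (o + 0.5) * scale - 0.5
        src = min(max(src, 0.0), n_in - 1.0)
        i0 = int(np.floor(src))
        i1 = min(i0 + 1, n_in - 1)
        frac = src - i0
        r[o, i0] += 1.0 - frac
        r[o, i1] += frac
    return r


def bilinear_upsample(x: Tensor, target_h: int, target_w: int) -> Tensor:
    """Channel-wise bilinear resampling of (N,C,H,W) to (N,C,target_h,target_w)."""
    n, c, h, w = x.shape
    if target_h < h or target_w < w:
        raise ValueError(
            f"bilinear_upsample: target ({target_h}x{target_w}) smaller than "
            f"source ({h}x{w})")
    if (target_h, target_w) == (h, w):
        return x
    rh = interp_matrix(target_h, h, dtype=x.dtype)
    rw = interp_matrix(target_w, w, dtype=x.dtype)
    out = np.matmul(np.matmul(rh, x.data), rw.T)

    def backward(g, out_ref=[None]):
        out_ref[0]._send(x, np.matmul(np.matmul(rh.T, g), rw))

    return _bind(Tensor._make(out, (x,), lambda g: None), backward)


def softmax(x: Tensor, axis: int = 1) -> Tensor:
    """Numerically stabilised softmax along ``axis``."""
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)

    def backward(g, out_ref=[None]):
        dot = (g * y).sum(axis=axis, keepdims=True)
        out_ref[0]._send(x, y * (g - dot))

    return _bind(Tensor._make(y, (x,), lambda g: None), backward)


def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor,
               running: dict | None = None, training: bool = True,
               momentum: float = 0.1, eps: float = 1e-5) -> Tensor:
    """Per-channel batch normalisation of an NCHW tensor.

    ``running`` is a dict with float arrays ``mean``/``var`` of length C,
    updated in-place during training and used verbatim in eval mode.
    """
    c = x.shape[1]
    axes = (0, 2, 3)
    if training:
        m_count = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
        mu = x.data.mean(axis=axes, keepdims=True)
        centered = x.data - mu
        var = (centered * centered).mean(axis=axes, keepdims=True)
        if running is not None:
            m = float(momentum)
            running["mean"] = (1 - m) * running["mean"] + m * mu.reshape(c)
            running["var"] = (1 - m) * running["var"] + m * var.reshape(c)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = centered * inv
        gam = gamma.data.reshape(1, c, 1, 1)
        out = gam * xhat + beta.data.reshape(1, c, 1, 1)

        def backward(g, out_ref=[None]):
            node = out_ref[0]
            if gamma.requires_grad:
                node._send(gamma, (g * xhat).sum(axis=axes))
            if beta.requires_grad:
                node._send(beta, g.sum(axis=axes))
            if x.requires_grad:
                gmean = g.mean(axis=axes, keepdims=True)
                gxmean = (g * xhat).mean(axis=axes, keepdims=True)
                node._send(x, (gam * inv) * (g - gmean - xhat * gxmean))

        return _bind(Tensor._make(out, (x, gamma, beta), lambda g: None),
                     backward)
    gam = gamma.reshape(1, c, 1, 1)
    bet = beta.reshape(1, c, 1, 1)
    mu = running["mean"].reshape(1, c, 1, 1)
    inv = (running["var"].reshape(1, c, 1, 1) + eps) ** -0.5
    return gam * ((x - Tensor(mu)) * Tensor(inv)) + bet
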