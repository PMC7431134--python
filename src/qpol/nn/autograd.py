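"""Minimal reverse-mode autodiff on NumPy arrays.

Supports exactly the operations the residual U-Net variants need: dense
n-d convolution (with stride and zero/reflect padding), fixed-kernel
average pooling, linear interpolation upsampling, batch normalization,
ReLU, channel concatenation/slicing/padding and (masked) L1 loss.  All
feature tensors are laid out ``(batch, channels, z, y, x)``; the 2D
variants simply keep a singleton z axis.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Tensor:
    """A node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def zero_grad(self):
        self.grad = None

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(node):
            if id(node) in seen:
                return
            seen.add(id(node))
            for parent in node._parents:
                visit(parent)
            topo.append(node)

        visit(self)
        for node in topo:
            if node.requires_grad:
                node.grad = np.zeros_like(node.data)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.requires_grad:
                node._backward(node.grad)


def parameter(data):
    return Tensor(np.asarray(data, dtype=np.float64), requires_grad=True)


def _accumulate(tensor, grad):
    if tensor.requires_grad:
        tensor.grad += grad


# -- elementwise ------------------------------------------------------------


def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def backward(grad):
        _accumulate(a, grad)
        _accumulate(b, grad)

    return Tensor(out_data, parents=(a, b), backward=backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def backward(grad):
        _accumulate(x, grad * mask)

    return Tensor(x.data * mask, parents=(x,), backward=backward)


# -- channel plumbing -------------------------------------------------------


def concat_channels(tensors) -> Tensor:
    sizes = [t.data.shape[1] for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=1)

    def backward(grad):
        start = 0
        for t, size in zip(tensors, sizes):
            _accumulate(t, grad[:, start : start + size])
            start += size

    return Tensor(out_data, parents=tuple(tensors), backward=backward)


def match_channels(x: Tensor, n: int) -> Tensor:
    """Parameter-free channel matching for residual shortcuts: zero-pad
    when growing, keep the leading channels when shrinking."""
    c = x.data.shape[1]
    if c == n:
        return x
    if c < n:
        pad = [(0, 0)] * x.data.ndim
        pad[1] = (0, n - c)
        out_data = np.pad(x.data, pad)

        def backward(grad):
            _accumulate(x, grad[:, :c])

        return Tensor(out_data, parents=(x,), backward=backward)
    out_data = x.data[:, :n]

    def backward(grad):
        full = np.zeros_like(x.data)
        full[:, :n] = grad
        _accumulate(x, full)

    return Tensor(out_data, parents=(x,), backward=backward)


# -- padding ----------------------------------------------------------------


def pad_spatial(x: Tensor, pad, mode="constant") -> Tensor:
    """Pad the three spatial axes; ``pad`` is ((d0,d1),(h0,h1),(w0,w1))."""
    widths = [(0, 0), (0, 0)] + list(pad)
    if all(lo == 0 and hi == 0 for lo, hi in pad):
        return x
    out_data = np.pad(x.data, widths, mode=mode)

    def backward(grad):
        # Unpad axis by axis (reverse of np.pad's application order),
        # folding reflected border gradients back onto their sources.
        g = grad
        for ax in reversed(range(3)):
            lo, hi = pad[ax]
            if lo == 0 and hi == 0:
                continue
            axis = 2 + ax
            n = g.shape[axis]
            core = g[_ax_slice(g.ndim, axis, slice(lo, n - hi))].copy()
            if mode == "reflect":
                if lo:
                    border = np.flip(
                        g[_ax_slice(g.ndim, axis, slice(0, lo))], axis=axis
                    )
                    core[_ax_slice(core.ndim, axis, slice(1, lo + 1))] += border
                if hi:
                    border = np.flip(
                        g[_ax_slice(g.ndim, axis, slice(n - hi, n))], axis=axis
                    )
                    s = core.shape[axis]
                    core[_ax_slice(core.ndim, axis, slice(s - hi - 1, s - 1))] += border
            g = core
        _accumulate(x, g)

    return Tensor(out_data, parents=(x,), backward=backward)


def _ax_slice(ndim, axis, sl):
    index = [slice(None)] * ndim
    index[axis] = sl
    return tuple(index)


# -- convolution ------------------------------------------------------------


def conv(x: Tensor, w: Tensor, b: Tensor = None, stride=(1, 1, 1), padding="same") -> Tensor:
    """Dense 3D convolution (cross-correlation) over (z, y, x).

    ``padding`` is "same" (zero pad, odd kernels) or "valid".
    """
    kd, kh, kw = w.data.shape[2:]
    if padding == "same":
        pads = ((kd // 2,) * 2, (kh // 2,) * 2, (kw // 2,) * 2)
        xp = pad_spatial(x, pads, mode="constant")
    elif padding == "valid":
        xp = x
    else:
        raise ValueError(f"unknown padding {padding!r}")
    return _conv_valid(xp, w, b, stride)


def _conv_valid(x: Tensor, w: Tensor, b, stride) -> Tensor:
    sd, sh, sw = stride
    kshape = w.data.shape[2:]
    for ax, k in enumerate(kshape):
        if x.data.shape[2 + ax] < k:
            raise ValueError(
                f"input spatial shape {x.data.shape[2:]} smaller than kernel {kshape}"
            )
    windows = sliding_window_view(x.data, kshape, axis=(2, 3, 4))
    windows = windows[:, :, ::sd, ::sh, ::sw]
    out_data = np.einsum("bcdhwijk,ocijk->bodhw", windows, w.data, optimize=True)
    if b is not None:
        out_data = out_data + b.data[None, :, None, None, None]

    parents = (x, w) if b is None else (x, w, b)

    def backward(grad):
        kd, kh, kw = kshape
        if b is not None:
            _accumulate(b, grad.sum(axis=(0, 2, 3, 4)))
        if w.requires_grad:
            gw = np.einsum("bcdhwijk,bodhw->ocijk", windows, grad, optimize=True)
            _accumulate(w, gw)
        if x.requires_grad:
            gx = np.zeros_like(x.data)
            nd, nh, nw = grad.shape[2:]
            for i in range(kd):
                for j in range(kh):
                    for k in range(kw):
                        contrib = np.einsum(
                            "bodhw,oc->bcdhw", grad, w.data[:, :, i, j, k], optimize=True
                        )
                        gx[
                            :,
                            :,
                            i : i + nd * sd : sd,
                            j : j + nh * sh : sh,
                            k : k + nw * sw : sw,
                        ] += contrib
            _accumulate(x, gx)

    return Tensor(out_data, parents=parents, backward=backward)


def avg_pool(x: Tensor, kernel, stride) -> Tensor:
    """Fixed uniform-kernel pooling (a stride-s convolution with constant
    weights); input must already be padded as desired."""
    kd, kh, kw = kernel
    sd, sh, sw = stride
    windows = sliding_window_view(x.data, kernel, axis=(2, 3, 4))
    windows = windows[:, :, ::sd, ::sh, ::sw]
    out_data = windows.mean(axis=(5, 6, 7))
    scale = 1.0 / (kd * kh * kw)

    def backward(grad):
        if not x.requires_grad:
            return
        gx = np.zeros_like(x.data)
        nd, nh, nw = grad.shape[2:]
        g = grad * scale
        for i in range(kd):
            for j in range(kh):
                for k in range(kw):
                    gx[
                        :,
                        :,
                        i : i + nd * sd : sd,
                        j : j + nh * sh : sh,
                        k : k + nw * sw : sw,
                    ] += g
        _accumulate(x, gx)

    return Tensor(out_data, parents=(x,), backward=backward)


# -- linear upsampling ------------------------------------------------------


def _linear_upsample_matrix(n_in: int, factor: int) -> np.ndarray:
    """Interpolation matrix for linear upsampling (edge-aligned sampling:
    output pixel centres at (i + 0.5)/factor - 0.5 in input coordinates)."""
    n_out = n_in * factor
    mat = np.zeros((n_out, n_in))
    for i in range(n_out):
        src = (i + 0.5) / factor - 0.5
        lo = int(np.floor(src))
        frac = src - lo
        lo_c = min(max(lo, 0), n_in - 1)
        hi_c = min(max(lo + 1, 0), n_in - 1)
        mat[i, lo_c] += 1.0 - frac
        mat[i, hi_c] += frac
    return mat


_upsample_cache: dict = {}


def upsample_linear(x: Tensor, factors) -> Tensor:
    """Separable linear interpolation upsampling along (z, y, x)."""
    out = x
    for ax, factor in enumerate(factors):
        if factor == 1:
            continue
        n_in = out.data.shape[2 + ax]
        key = (n_in, factor)
        if key not in _upsample_cache:
            _upsample_cache[key] = _linear_upsample_matrix(n_in, factor)
        out = _apply_axis_matrix(out, _upsample_cache[key], 2 + ax)
    return out


def _apply_axis_matrix(x: Tensor, mat: np.ndarray, axis: int) -> Tensor:
    out_data = np.moveaxis(
        np.tensordot(mat, np.moveaxis(x.data, axis, 0), axes=(1, 0)), 0, axis
    )

    def backward(grad):
        if x.requires_grad:
            gx = np.moveaxis(
                np.tensordot(mat.T, np.moveaxis(grad, axis, 0), axes=(1, 0)), 0, axis
            )
            _accumulate(x, gx)

    return Tensor(out_data, parents=(x,), backward=backward)


# -- batch normalization ----------------------------------------------------


def batch_norm(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Per-channel batch normalization with affine parameters.

    Running statistics are updated in place during training and used
    verbatim in evaluation mode.
    """
    axes = (0, 2, 3, 4)
    shape = (1, -1, 1, 1, 1)
    if training:
        mean = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        n = x.data.size / x.data.shape[1]
        running_mean *= 1 - momentum
        running_mean += momentum * mean
        running_var *= 1 - momentum
        running_var += momentum * var * (n / max(n - 1, 1))
    else:
        mean = running_mean
        var = running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    x_hat = (x.data - mean.reshape(shape)) * inv_std.reshape(shape)
    out_data = gamma.data.reshape(shape) * x_hat + beta.data.reshape(shape)

    def backward(grad):
        _accumulate(beta, grad.sum(axis=axes))
        _accumulate(gamma, (grad * x_hat).sum(axis=axes))
        if not x.requires_grad:
            return
        g = grad * gamma.data.reshape(shape)
        if not training:
            _accumulate(x, g * inv_std.reshape(shape))
            return
        n = x.data.size / x.data.shape[1]
        sum_g = g.sum(axis=axes).reshape(shape)
        sum_gx = (g * x_hat).sum(axis=axes).reshape(shape)
        gx = (g - sum_g / n - x_hat * sum_gx / n) * inv_std.reshape(shape)
        _accumulate(x, gx)

    return Tensor(out_data, parents=(x, gamma, beta), backward=backward)


# -- losses -----------------------------------------------------------------


def l1_loss(pred: Tensor, target: np.ndarray, mask: np.ndarray = None) -> Tensor:
    """Mean absolute error, optionally restricted to foreground pixels."""
    target = np.asarray(target, dtype=np.float64)
    diff = pred.data - target
    if mask is not None:
        mask = np.broadcast_to(np.asarray(mask, dtype=bool), diff.shape)
        count = int(mask.sum())
        if count == 0:
            raise ValueError("masked L1 loss with an empty foreground mask")
        out_data = np.abs(diff[mask]).sum() / count
    else:
        count = diff.size
        out_data = np.abs(diff).mean()

    def backward(grad):
        g = np.sign(diff) / count
        if mask is not None:
            g = np.where(mask, g, 0.0)
        _accumulate(pred, grad * g)

    return Tensor(out_data, parents=(pred,), backward=backward)
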