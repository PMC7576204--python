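"""Reverse-mode automatic differentiation on numpy arrays.

A deliberately small tape-based engine: :class:`Tensor` wraps an ndarray and
records a backward closure per operation.  Elementwise ops, matmul and the
composite blocks the trajectory classifier needs (same-padded 1D convolution,
LSTM, masked softmax attention, masked temporal mean, dropout, weighted
cross-entropy) are provided as functions returning new tensors.  The fused
conv/LSTM backward passes are hand-derived and checked against central finite
differences in the test suite.

Tensors keep whatever float dtype (float32/float64) they are given; the
network trains in float32 for memory-bandwidth reasons while the test
oracles run the same ops in float64.  ``no_grad()`` disables tape recording
for evaluation-only passes.  CPU-only.
"""

from __future__ import annotations

import contextlib

import numpy as np
from scipy.special import expit

__all__ = [
    "Tensor",
    "add",
    "mul",
    "matmul",
    "tanh",
    "sigmoid",
    "reshape",
    "slice_",
    "concat",
    "conv1d_same",
    "lstm",
    "masked_softmax",
    "masked_mean",
    "dropout",
    "cross_entropy_logits",
    "Adam",
    "no_grad",
]

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable tape recording (evaluation-mode passes)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum *grad* down to *shape* (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An ndarray with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        data = np.asarray(data)
        if data.dtype not in (np.float32, np.float64):
            data = data.astype(np.float64)
        self.data = data
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev: tuple = ()

    @property
    def shape(self):
        return self.data.shape

    def accumulate(self, g: np.ndarray) -> None:
        # no op mutates .grad in place, so aliasing the incoming array is safe
        if self.grad is None:
            self.grad = g if isinstance(g, np.ndarray) else np.asarray(g, dtype=self.data.dtype)
        else:
            self.grad = self.grad + g

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the tape."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs unroll hundreds of time steps
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for child in node._prev:
                if id(child) not in seen:
                    stack.append((child, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def _make(data, children: tuple, backward) -> Tensor:
    out = Tensor(data)
    out.requires_grad = _GRAD_ENABLED and any(c.requires_grad for c in children)
    if out.requires_grad:
        out._prev = tuple(c for c in children if c.requires_grad)
        out._backward = backward
    return out


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)

    def backward(g):
        if a.requires_grad:
            a.accumulate(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(g, b.shape))

    return _make(a.data + b.data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)

    def backward(g):
        if a.requires_grad:
            a.accumulate(_unbroadcast(g * b.data, a.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(g * a.data, b.shape))

    return _make(a.data * b.data, (a, b), backward)


def matmul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)

    def backward(g):
        if a.requires_grad:
            a.accumulate(_unbroadcast(g @ np.swapaxes(b.data, -1, -2), a.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(np.swapaxes(a.data, -1, -2) @ g, b.shape))

    return _make(a.data @ b.data, (a, b), backward)


def tanh(a) -> Tensor:
    a = _as_tensor(a)
    y = np.tanh(a.data)

    def backward(g):
        a.accumulate(g * (1.0 - y * y))

    return _make(y, (a,), backward)


def sigmoid(a) -> Tensor:
    a = _as_tensor(a)
    y = expit(a.data)

    def backward(g):
        a.accumulate(g * y * (1.0 - y))

    return _make(y, (a,), backward)


def reshape(a, shape) -> Tensor:
    a = _as_tensor(a)
    old = a.shape

    def backward(g):
        a.accumulate(g.reshape(old))

    return _make(a.data.reshape(shape), (a,), backward)


def slice_(a, sl) -> Tensor:
    """``a[sl]`` with scatter-add backward."""
    a = _as_tensor(a)

    def backward(g):
        full = np.zeros(a.shape)
        full[sl] = g
        a.accumulate(full)

    return _make(a.data[sl], (a,), backward)


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t.accumulate(g[tuple(idx)])

    return _make(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), backward)


def conv1d_same(x, w, b) -> Tensor:
    """1D convolution over time with stride 1 and 'same' zero padding.

    x: (B, T, C_in); w: (K, C_in, C_out); b: (C_out,). Output (B, T, C_out).
    For even K, one more zero is padded on the right than on the left.
    """
    x, w, b = _as_tensor(x), _as_tensor(w), _as_tensor(b)
    B, T, Cin = x.shape
    K, _, Cout = w.shape
    pl = (K - 1) // 2
    xp = np.pad(x.data, ((0, 0), (pl, K - 1 - pl), (0, 0)))
    out = np.broadcast_to(b.data, (B, T, Cout)).copy()
    for k in range(K):
        out += xp[:, k:k + T, :] @ w.data[k]

    def backward(g):
        if b.requires_grad:
            b.accumulate(g.sum(axis=(0, 1)))
        gf = g.reshape(B * T, Cout)
        if w.requires_grad:
            dw = np.empty_like(w.data)
            for k in range(K):
                dw[k] = xp[:, k:k + T, :].reshape(B * T, Cin).T @ gf
            w.accumulate(dw)
        if x.requires_grad:
            gp = np.zeros_like(xp)
            for k in range(K):
                gp[:, k:k + T, :] += g @ w.data[k].T
            x.accumulate(gp[:, pl:pl + T, :])

    return _make(out, (x, w, b), backward)


def lstm(x, Wx, Wh, b) -> Tensor:
    """Single LSTM layer returning the full hidden sequence.

    x: (B, T, C_in); Wx: (C_in, 4H); Wh: (H, 4H); b: (4H,).  Gate order in the
    fused weight matrices is input, forget, cell, output.  Initial hidden and
    cell states are zero; forget-gate bias should be folded into ``b``.
    """
    from ._lstm_kernels import lstm_backward, lstm_forward, lstm_forward_nograd

    x, Wx, Wh, b = _as_tensor(x), _as_tensor(Wx), _as_tensor(Wh), _as_tensor(b)
    B, T, Cin = x.shape
    H = Wh.shape[0]
    dt = x.data.dtype
    xW = x.data.reshape(B * T, Cin) @ Wx.data
    xW = np.ascontiguousarray((xW.reshape(B, T, 4 * H) + b.data), dtype=dt)
    h_s = np.empty((B, T, H), dt)
    needs_grad = _GRAD_ENABLED and (x.requires_grad or Wx.requires_grad
                                    or Wh.requires_grad or b.requires_grad)
    if not needs_grad:
        lstm_forward_nograd(xW, Wh.data, h_s)
        return _make(h_s, (x, Wx, Wh, b), None)
    caches = [np.empty((B, T, H), dt) for _ in range(6)]
    i_s, f_s, g_s, o_s, c_s, tc_s = caches
    lstm_forward(xW, Wh.data, i_s, f_s, g_s, o_s, c_s, tc_s, h_s)

    def backward(g):
        dZ = np.empty((B, T, 4 * H), dt)
        lstm_backward(np.ascontiguousarray(g, dtype=dt),
                      i_s, f_s, g_s, o_s, c_s, tc_s, Wh.data, dZ)
        dZf = dZ.reshape(B * T, 4 * H)
        if b.requires_grad:
            b.accumulate(dZf.sum(axis=0))
        if Wx.requires_grad:
            Wx.accumulate(x.data.reshape(B * T, Cin).T @ dZf)
        if Wh.requires_grad:
            h_prev = np.zeros((B, T, H))
            h_prev[:, 1:] = h_s[:, :-1]
            Wh.accumulate(h_prev.reshape(B * T, H).T @ dZf)
        if x.requires_grad:
            x.accumulate((dZf @ Wx.data.T).reshape(B, T, Cin))

    return _make(h_s, (x, Wx, Wh, b), backward)


def masked_softmax(scores, mask: np.ndarray) -> Tensor:
    """Softmax over axis 1 restricted to ``mask`` (bool, same shape).

    Masked-out positions get probability exactly 0 and receive no gradient.
    Raises if any row of the mask is all false.
    """
    scores = _as_tensor(scores)
    if not mask.any(axis=-1).all():
        raise ValueError("masked_softmax: at least one row is fully masked")
    s = np.where(mask, scores.data, -np.inf)
    s = s - s.max(axis=-1, keepdims=True)
    e = np.exp(s)
    e = np.where(mask, e, 0.0)
    a = e / e.sum(axis=-1, keepdims=True)

    def backward(g):
        dot = (g * a).sum(axis=-1, keepdims=True)
        scores.accumulate(np.where(mask, a * (g - dot), 0.0))

    return _make(a, (scores,), backward)


def masked_mean(x, mask: np.ndarray) -> Tensor:
    """Mean of x (B, T, C) over valid time steps of mask (B, T) -> (B, C)."""
    x = _as_tensor(x)
    m = mask.astype(x.data.dtype)
    counts = m.sum(axis=1)  # (B,)
    out = (x.data * m[:, :, None]).sum(axis=1) / counts[:, None]

    def backward(g):
        x.accumulate(m[:, :, None] * (g / counts[:, None])[:, None, :])

    return _make(out, (x,), backward)


def dropout(x, rate: float, rng: np.random.Generator, training: bool) -> Tensor:
    """Inverted dropout; identity when not training or rate == 0."""
    x = _as_tensor(x)
    if not training or rate == 0.0:
        return x
    keep = ((rng.random(x.shape) >= rate) / (1.0 - rate)).astype(x.data.dtype)

    def backward(g):
        x.accumulate(g * keep)

    return _make(x.data * keep, (x,), backward)


def cross_entropy_logits(logits, labels: np.ndarray, weights: np.ndarray | None = None) -> Tensor:
    """Weighted mean cross-entropy of (B, K) logits against integer labels."""
    logits = _as_tensor(logits)
    B = logits.shape[0]
    if weights is None:
        weights = np.ones(B)
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    wsum = weights.sum()
    loss = -(weights * logp[np.arange(B), labels]).sum() / wsum

    def backward(g):
        p = np.exp(logp)
        onehot = np.zeros_like(p)
        onehot[np.arange(B), labels] = 1.0
        logits.accumulate(g * (weights[:, None] * (p - onehot)) / wsum)

    return _make(loss, (logits,), backward)


class Adam:
    """Adam optimizer over a list of parameter tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[k] = b1 * self.m[k] + (1 - b1) * p.grad
            self.v[k] = b2 * self.v[k] + (1 - b2) * p.grad ** 2
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
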