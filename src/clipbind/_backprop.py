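"""Batched forward pass and hand-derived gradients for training.

The public per-sequence operations in :mod:`clipbind.network` define the
model; this module re-expresses the same computation over a whole batch
(B, L, 4) and adds reverse-mode gradients: backprop through the fixed
sigmoid output node, the dropout mask on H, both LSTM directions (BPTT),
the track reconstruction, the WTA enhancement (subgradient at the doubled
maximum) and the rectified convolutions.  Agreement with the per-sequence
path and with finite differences is enforced by the test suite.

Gradient conventions: loss is mean binary cross-entropy over the batch;
with p = sigmoid(z) the gradient at the pre-sigmoid sum is (p - y) / B.
The output weight is fixed (1.0) and receives no gradient by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from clipbind.encoding import encode_batch, stack_batch
from clipbind.network import ModelParams, sigmoid
from clipbind.seq_io import NamedSequence


@dataclass
class _LSTMCache:
    xs: np.ndarray        # (L, B, D) inputs in processing order
    i: np.ndarray         # (L, B, n) gate activations
    f: np.ndarray
    g: np.ndarray
    o: np.ndarray
    c: np.ndarray         # (L, B, n) cell states
    h: np.ndarray         # (L, B, n) hidden outputs


@dataclass
class ForwardCache:
    X: np.ndarray                     # (B, L, 4)
    M: np.ndarray                     # (B, L)
    conv_pre: list[np.ndarray]        # per filter (B, P_k)
    conv_s: list[np.ndarray]          # rectified scores
    conv_argmax: list[np.ndarray]     # (B,) WTA winner indices
    fwd: _LSTMCache
    bwd: _LSTMCache
    H: np.ndarray                     # (B, L, 2n) pre-dropout
    drop_mask: Optional[np.ndarray]   # (B, L, 2n) inverted-scaled or None
    z: np.ndarray                     # (B,) pre-sigmoid sums
    score: np.ndarray                 # (B,)


def _lstm_direction(xs_seq: np.ndarray, mask_seq: np.ndarray, p) -> _LSTMCache:
    """Run one LSTM direction over xs_seq of shape (L, B, D).

    ``mask_seq`` (L, B): padded time steps (mask 0) are skipped — hidden
    and cell state carry through unchanged, so outputs are invariant to
    the amount of padding.
    """
    L, B, _ = xs_seq.shape
    n = p.hidden_size
    I = np.empty((L, B, n)); F = np.empty((L, B, n))
    G = np.empty((L, B, n)); O = np.empty((L, B, n))
    C = np.empty((L, B, n)); H = np.empty((L, B, n))
    h = np.zeros((B, n)); c = np.zeros((B, n))
    for t in range(L):
        a = xs_seq[t] @ p.W_x + h @ p.W_h + p.b
        i = sigmoid(a[:, 0 * n : 1 * n])
        f = sigmoid(a[:, 1 * n : 2 * n])
        g = np.tanh(a[:, 2 * n : 3 * n])
        o = sigmoid(a[:, 3 * n : 4 * n])
        c_new = f * c + i * g
        h_new = o * np.tanh(c_new)
        mt = mask_seq[t][:, None]
        c = mt * c_new + (1.0 - mt) * c
        h = mt * h_new + (1.0 - mt) * h
        I[t], F[t], G[t], O[t], C[t], H[t] = i, f, g, o, c, h
    return _LSTMCache(xs=xs_seq, i=I, f=F, g=G, o=O, c=C, h=H)


def batch_forward(
    X: np.ndarray,
    M: np.ndarray,
    params: ModelParams,
    drop_rng: Optional[np.random.Generator] = None,
    dropout: float = 0.0,
) -> ForwardCache:
    """Forward pass over a batch.  Dropout (inverted scaling) is applied to
    H only when ``drop_rng`` is given and ``dropout > 0``."""
    B, L, _ = X.shape
    nf = params.n_filters
    A = np.zeros((B, L, nf))
    conv_pre, conv_s, conv_argmax = [], [], []
    for k, W in enumerate(params.conv.filters):
        m = W.shape[0]
        P = L - m + 1
        pre = np.zeros((B, P))
        for i in range(m):
            pre += X[:, i : i + P, :] @ W[i]
        s = np.maximum(pre, 0.0)
        idx = np.argmax(s, axis=1)  # first occurrence on ties
        d = s.copy()
        d[np.arange(B), idx] *= 2.0
        A[:, :P, k] = d * d
        conv_pre.append(pre); conv_s.append(s); conv_argmax.append(idx)
    tracks = X[:, :, None, :] * A[:, :, :, None]          # (B, L, nf, 4)
    xs = np.concatenate([tracks.reshape(B, L, nf * 4), X], axis=2)
    xs_t = np.ascontiguousarray(xs.transpose(1, 0, 2))     # (L, B, D)
    mask_t = np.ascontiguousarray(M.T)                     # (L, B)
    fwd_cache = _lstm_direction(xs_t, mask_t, params.fwd)
    bwd_cache = _lstm_direction(xs_t[::-1], mask_t[::-1], params.bwd)
    n = params.hidden_size
    H = np.empty((B, L, 2 * n))
    H[:, :, :n] = fwd_cache.h.transpose(1, 0, 2)
    H[:, :, n:] = bwd_cache.h[::-1].transpose(1, 0, 2)
    drop_mask = None
    Hd = H
    if drop_rng is not None and dropout > 0.0:
        keep = 1.0 - dropout
        drop_mask = (drop_rng.random(H.shape) < keep) / keep
        Hd = H * drop_mask
    z = (Hd * M[:, :, None]).sum(axis=(1, 2)) * params.output_weight
    return ForwardCache(
        X=X, M=M, conv_pre=conv_pre, conv_s=conv_s, conv_argmax=conv_argmax,
        fwd=fwd_cache, bwd=bwd_cache, H=H, drop_mask=drop_mask,
        z=z, score=sigmoid(z),
    )


def _lstm_backward(cache: _LSTMCache, mask_seq: np.ndarray, dH_dir: np.ndarray, p):
    """BPTT through one direction with state carry at masked steps.

    ``dH_dir``: (L, B, n) gradients at the direction's hidden outputs, in
    processing order.  At masked (padding) steps h_t = h_{t-1} and
    c_t = c_{t-1}, so incoming gradient passes straight through to the
    previous step.  Returns (grads dict, dxs (L, B, D) in processing
    order).
    """
    L, B, n = dH_dir.shape
    dW_x = np.zeros_like(p.W_x)
    dW_h = np.zeros_like(p.W_h)
    db = np.zeros_like(p.b)
    dxs = np.empty_like(cache.xs)
    dh_next = np.zeros((B, n))
    dc_next = np.zeros((B, n))
    da = np.empty((B, 4 * n))
    for t in range(L - 1, -1, -1):
        i, f, g, o = cache.i[t], cache.f[t], cache.g[t], cache.o[t]
        mt = mask_seq[t][:, None]
        dh_total = dH_dir[t] + dh_next
        dc_total = dc_next
        # through the cell only where the step was real
        dh = mt * dh_total
        # the cached state is post-carry; recompute the cell's own c_new
        c_prev = cache.c[t - 1] if t > 0 else np.zeros((B, n))
        h_prev = cache.h[t - 1] if t > 0 else np.zeros((B, n))
        c_new = f * c_prev + i * g
        tanh_c = np.tanh(c_new)
        do = dh * tanh_c
        dc = mt * dc_total + dh * o * (1.0 - tanh_c * tanh_c)
        di = dc * g
        df = dc * c_prev
        dg = dc * i
        da[:, 0 * n : 1 * n] = di * i * (1.0 - i)
        da[:, 1 * n : 2 * n] = df * f * (1.0 - f)
        da[:, 2 * n : 3 * n] = dg * (1.0 - g * g)
        da[:, 3 * n : 4 * n] = do * o * (1.0 - o)
        dW_x += cache.xs[t].T @ da
        dW_h += h_prev.T @ da
        db += da.sum(axis=0)
        dxs[t] = da @ p.W_x.T
        dh_next = da @ p.W_h.T + (1.0 - mt) * dh_total
        dc_next = dc * f + (1.0 - mt) * dc_total
    return {"W_x": dW_x, "W_h": dW_h, "b": db}, dxs


def batch_backward(cache: ForwardCache, params: ModelParams, dz: np.ndarray):
    """Gradients of the loss w.r.t. every trainable parameter.

    ``dz``: (B,) gradient at the pre-sigmoid sum z (e.g. (p - y)/B for mean
    binary cross-entropy).  Returns a dict with keys ``conv`` (list of
    per-filter gradients), ``fwd`` and ``bwd`` (per-direction dicts).
    """
    B, L, _ = cache.X.shape
    n = params.hidden_size
    dH = (dz[:, None, None] * cache.M[:, :, None]) * params.output_weight
    dH = np.broadcast_to(dH, cache.H.shape).copy()
    if cache.drop_mask is not None:
        dH *= cache.drop_mask
    dH_fwd = np.ascontiguousarray(dH[:, :, :n].transpose(1, 0, 2))
    dH_bwd = np.ascontiguousarray(dH[:, :, n:].transpose(1, 0, 2))[::-1]
    mask_t = np.ascontiguousarray(cache.M.T)
    fwd_grads, dxs_f = _lstm_backward(cache.fwd, mask_t, dH_fwd, params.fwd)
    bwd_grads, dxs_b = _lstm_backward(cache.bwd, mask_t[::-1], dH_bwd, params.bwd)
    dxs = dxs_f + dxs_b[::-1]                      # (L, B, D)
    dxs = dxs.transpose(1, 0, 2)                   # (B, L, D)
    nf = params.n_filters
    dtracks = dxs[:, :, : nf * 4].reshape(B, L, nf, 4)
    # raw one-hot columns are inputs, not parameters: gradient discarded
    dA = (dtracks * cache.X[:, :, None, :]).sum(axis=3)   # (B, L, nf)
    conv_grads = []
    rows = np.arange(B)
    for k, W in enumerate(params.conv.filters):
        m = W.shape[0]
        P = L - m + 1
        de = dA[:, :P, k]
        s = cache.conv_s[k]
        ds = 2.0 * s * de
        idx = cache.conv_argmax[k]
        ds[rows, idx] *= 4.0            # winner: e = 4 s^2 -> de/ds = 8 s
        ds *= cache.conv_pre[k] > 0.0   # rectifier subgradient (0 at 0)
        dW = np.empty_like(W)
        for i in range(m):
            dW[i] = np.tensordot(ds, cache.X[:, i : i + P, :], axes=([0, 1], [0, 1]))
        conv_grads.append(dW)
    return {"conv": conv_grads, "fwd": fwd_grads, "bwd": bwd_grads}


def bce_loss(scores: np.ndarray, labels: np.ndarray, eps: float = 1e-12) -> float:
    p = np.clip(scores, eps, 1.0 - eps)
    return float(-np.mean(labels * np.log(p) + (1 - labels) * np.log(1 - p)))


class AdamOptimizer:
    """ADAM over the model's trainable arrays (conv filters + both LSTM
    directions); the fixed output weight is not a slot."""

    def __init__(self, params: ModelParams, alpha=0.0002, beta1=0.9,
                 beta2=0.999, eps=1e-8):
        self.alpha, self.beta1, self.beta2, self.eps = alpha, beta1, beta2, eps
        self.t = 0
        self._m = [np.zeros_like(a) for a in self._flatten(params)]
        self._v = [np.zeros_like(a) for a in self._flatten(params)]

    @staticmethod
    def _flatten(params: ModelParams):
        arrs = list(params.conv.filters)
        for p in (params.fwd, params.bwd):
            arrs += [p.W_x, p.W_h, p.b]
        return arrs

    @staticmethod
    def _flatten_grads(grads):
        arrs = list(grads["conv"])
        for tag in ("fwd", "bwd"):
            g = grads[tag]
            arrs += [g["W_x"], g["W_h"], g["b"]]
        return arrs

    def step(self, params: ModelParams, grads) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for arr, g, m, v in zip(
            self._flatten(params), self._flatten_grads(grads), self._m, self._v
        ):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * (g * g)
            arr -= self.alpha * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def encode_dataset(seqs: Sequence[NamedSequence], filter_sizes, max_length):
    """Encode sequences once into stacked arrays (X, M, y)."""
    encoded = encode_batch(seqs, filter_sizes, max_length=max_length)
    X, M = stack_batch(encoded)
    y = np.array(
        [s.label if s.label is not None else 0 for s in seqs], dtype=np.float64
    )
    return X, M, y


def batch_predict(
    seqs: Sequence[NamedSequence], params: ModelParams, max_length: int,
    chunk: int = 256,
) -> np.ndarray:
    """Deterministic classification scores (no dropout) for many sequences."""
    X, M, _ = encode_dataset(seqs, params.filter_sizes, max_length)
    out = np.empty(X.shape[0])
    for lo in range(0, X.shape[0], chunk):
        cache = batch_forward(X[lo : lo + chunk], M[lo : lo + chunk], params)
        out[lo : lo + chunk] = cache.score
    return out
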