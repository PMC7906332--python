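"""Network building blocks for the annotating generator and the critic.

The sequence front end (embedding -> dropout -> 1-D convolution ->
average pooling) is algebraically fused: a one-hot trigram times the
embedding matrix is a row lookup, and the convolution over embedded trigrams
is therefore a sum of per-offset lookups into ``E @ W``.  Both the lookup-sum
and the average pooling are expressed as constant sparse matrices applied to
dense parameter-dependent matrices, which keeps a CPU training step cheap
without changing the mathematics.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import scipy.sparse as sp

from .autodiff import Tensor, add, leaky_relu, matmul, reshape, spmm, tanh

__all__ = [
    "Adam",
    "Dense",
    "TrigramConvEncoder",
    "LEAKY_SLOPE",
]

LEAKY_SLOPE = 0.2


def he_normal(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Dense:
    """Fully connected layer ``x @ W + b`` with optional activation."""

    def __init__(self, rng, n_in: int, n_out: int, activation: str | None = "leaky_relu"):
        self.W = Tensor(he_normal(rng, n_in, (n_in, n_out)), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)
        self.activation = activation

    def __call__(self, x: Tensor) -> Tensor:
        z = add(matmul(x, self.W), self.b)
        if self.activation == "leaky_relu":
            return leaky_relu(z, LEAKY_SLOPE)
        if self.activation == "tanh":
            return tanh(z)
        return z

    @property
    def params(self):
        return [self.W, self.b]


def conv_csr(indices: np.ndarray, kernel_size: int, vocab: int,
             keep_mask: np.ndarray | None = None) -> sp.csr_matrix:
    """Sparse operator applying a fused embed+conv to a batch of index rows.

    ``indices`` is the (batch, positions) integer matrix of trigram codes
    (0 = padding).  The returned matrix has shape
    ``(batch * positions, vocab * kernel_size)`` and, multiplied by the
    ``(vocab * kernel_size, filters)`` combined weight matrix, yields the
    convolution output at every position ('same' length; the right edge reads
    the padding code).  ``keep_mask`` (batch, positions) carries the dropout
    scaling applied to whole input-position embeddings.
    """
    B, P = indices.shape
    K = kernel_size
    padded = np.zeros((B, P + K - 1), dtype=np.int64)
    padded[:, :P] = indices
    windows = np.lib.stride_tricks.sliding_window_view(padded, K, axis=1)  # (B,P,K)
    cols = (windows * K + np.arange(K)).reshape(-1)
    if keep_mask is None:
        data = np.ones(cols.size)
    else:
        m = np.ones((B, P + K - 1))
        m[:, :P] = keep_mask
        data = np.lib.stride_tricks.sliding_window_view(m, K, axis=1).reshape(-1).copy()
    indptr = np.arange(B * P + 1, dtype=np.int64) * K
    return sp.csr_matrix((data, cols, indptr), shape=(B * P, vocab * K))


@lru_cache(maxsize=32)
def pool_csr(batch: int, positions: int, size: int, stride: int) -> sp.csr_matrix:
    """Block-diagonal average-pooling operator over the length axis."""
    W = (positions - size) // stride + 1
    if W < 1:
        raise ValueError("pooling window larger than input length")
    rows = batch * W
    cols = (
        np.arange(batch)[:, None, None] * positions
        + np.arange(W)[None, :, None] * stride
        + np.arange(size)[None, None, :]
    ).reshape(-1)
    data = np.full(cols.size, 1.0 / size)
    indptr = np.arange(rows + 1, dtype=np.int64) * size
    return sp.csr_matrix((data, cols, indptr), shape=(rows, batch * positions))


class TrigramConvEncoder:
    """Fused embedding / dropout / 1-D conv / LeakyReLU / average-pool stack."""

    def __init__(self, rng, vocab: int, embed_dim: int, n_filters: int,
                 kernel_size: int, pool_size: int, pool_stride: int,
                 dropout_rate: float = 0.0):
        self.vocab = vocab
        self.kernel_size = kernel_size
        self.n_filters = n_filters
        self.pool_size = pool_size
        self.pool_stride = pool_stride
        self.dropout_rate = dropout_rate
        # scaled embedding init: rows have ~unit norm
        E = rng.normal(0.0, 1.0 / np.sqrt(embed_dim), size=(vocab, embed_dim))
        E[0] = 0.0  # padding code starts at the zero vector
        self.E = Tensor(E, requires_grad=True)
        self.Wc = Tensor(
            he_normal(rng, kernel_size * embed_dim, (embed_dim, kernel_size * n_filters)),
            requires_grad=True,
        )
        self.bc = Tensor(np.zeros(n_filters), requires_grad=True)

    def out_dim(self, positions: int) -> int:
        W = (positions - self.pool_size) // self.pool_stride + 1
        return W * self.n_filters

    def __call__(self, indices: np.ndarray, rng: np.random.Generator | None = None) -> Tensor:
        B, P = indices.shape
        keep = None
        if rng is not None and self.dropout_rate > 0.0:
            keep = (rng.random((B, P)) >= self.dropout_rate) / (1.0 - self.dropout_rate)
        S = conv_csr(indices, self.kernel_size, self.vocab, keep)
        M = reshape(matmul(self.E, self.Wc), (self.vocab * self.kernel_size, self.n_filters))
        conv = leaky_relu(add(spmm(S, M), self.bc), LEAKY_SLOPE)  # (B*P, F)
        pooled = spmm(pool_csr(B, P, self.pool_size, self.pool_stride), conv)
        W = (P - self.pool_size) // self.pool_stride + 1
        return reshape(pooled, (B, W * self.n_filters))

    @property
    def params(self):
        return [self.E, self.Wc, self.bc]


class Adam:
    """Adam optimizer over a list of parameter tensors."""

    def __init__(self, params, lr: float, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self, grads) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            gd = g.data if isinstance(g, Tensor) else g
            m *= b1
            m += (1 - b1) * gd
            v *= b2
            v += (1 - b2) * gd * gd
            p.data = p.data - self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
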