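"""NumPy neural-network core: spectral graph convolution, dense heads,
softmax cross-entropy and Adam.

The networks here are small enough (two 32-channel graph-convolution
layers per scale plus a three-layer dense head) that full-batch training
on a CPU is fast, so the forward and backward passes are written
directly against BLAS-backed batched matrix products.  Conventions:

* graph convolution layers follow H^{l+1} = ReLU(Â H^l W^l) with the
  self-looped symmetric normalization Â = D̃^{-1/2}(A + I)D̃^{-1/2} and
  no bias, matching the one-hop spectral approximation;
* the readout concatenates the column-wise node mean with the node max;
* dense layers carry biases, ReLU on hidden layers, inverted dropout on
  hidden activations at training time only;
* Adam uses the coupled L2 form (weight decay added to the gradient).

All initialization is Glorot-uniform from a caller-supplied generator,
so training is bit-reproducible given a seed.
"""

from __future__ import annotations

import numpy as np

from .errors import DataError

__all__ = [
    "glorot_uniform", "relu", "softmax", "softmax_cross_entropy",
    "Adam", "DenseStack", "GCNEncoder", "MultiScaleGCNNet", "FeedForwardNet",
]


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def glorot_uniform(rng: np.random.Generator, shape: tuple[int, int],
                   dtype=np.float64) -> np.ndarray:
    limit = np.sqrt(6.0 / (shape[0] + shape[1]))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = logits.shape[0]
    eps = 1e-12
    loss = -np.log(p[np.arange(n), y] + eps).mean()
    dlogits = p.copy()
    dlogits[np.arange(n), y] -= 1.0
    return float(loss), dlogits / n


class Adam:
    """Adaptive-moment estimation with coupled L2 weight decay."""

    def __init__(self, params: list[np.ndarray], lr: float = 0.01,
                 weight_decay: float = 1e-5, betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.weight_decay = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]

    def step(self, grads: list[np.ndarray]) -> None:
        if len(grads) != len(self.params):
            raise DataError("gradient list does not match parameter list")
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            g = g + self.weight_decay * p
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class DenseStack:
    """Fully-connected stack: ReLU + dropout on hidden layers, linear output."""

    def __init__(self, dims: list[int], dropout: float, rng: np.random.Generator,
                 dtype=np.float64):
        if len(dims) < 2:
            raise DataError("a dense stack needs at least input and output widths")
        self.dims = list(dims)
        self.dropout = float(dropout)
        self.W = [glorot_uniform(rng, (dims[i], dims[i + 1]), dtype)
                  for i in range(len(dims) - 1)]
        self.b = [np.zeros(dims[i + 1], dtype=dtype) for i in range(len(dims) - 1)]
        self._cache = None

    @property
    def params(self) -> list[np.ndarray]:
        return self.W + self.b

    def forward(self, x: np.ndarray, train: bool = False,
                drop_rng: np.random.Generator | None = None) -> np.ndarray:
        if x.shape[1] != self.dims[0]:
            raise DataError(f"dense stack expects width {self.dims[0]}, got {x.shape[1]}")
        acts, masks, pre = [x], [], []
        h = x
        last = len(self.W) - 1
        for l, (w, b) in enumerate(zip(self.W, self.b)):
            z = h @ w + b
            if l == last:
                h = z
            else:
                h = relu(z)
                if train and self.dropout > 0.0:
                    if drop_rng is None:
                        raise DataError("training with dropout requires a generator")
                    mask = (drop_rng.random(h.shape) >= self.dropout) / (1.0 - self.dropout)
                    h = h * mask
                else:
                    mask = None
                masks.append(mask)
            pre.append(z)
            acts.append(h)
        self._cache = (acts, pre, masks)
        return h

    def backward(self, dout: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        """Gradient of the cached forward pass; returns (dx, grads aligned with params)."""
        acts, pre, masks = self._cache
        dW = [None] * len(self.W)
        db = [None] * len(self.b)
        last = len(self.W) - 1
        d = dout
        for l in range(last, -1, -1):
            if l != last:
                if masks[l] is not None:
                    d = d * masks[l]
                d = d * (pre[l] > 0)
            dW[l] = acts[l].T @ d
            db[l] = d.sum(axis=0)
            d = d @ self.W[l].T
        return d, dW + db


def _flat2d(t: np.ndarray) -> np.ndarray:
    """(batch, n, d) -> (batch * n, d) without copying."""
    return t.reshape(-1, t.shape[-1])


class GCNEncoder:
    """Two-layer graph convolution plus mean‖max readout for one scale.

    ``forward`` takes the precomputed first-hop product ÂX (constant per
    subject across epochs) together with Â itself, and returns the
    graph-level representation of shape (batch, 2 * width).
    """

    def __init__(self, n_features: int, widths: tuple[int, int],
                 rng: np.random.Generator, dtype=np.float64):
        self.widths = tuple(widths)
        self.W0 = glorot_uniform(rng, (n_features, widths[0]), dtype)
        self.W1 = glorot_uniform(rng, (widths[0], widths[1]), dtype)
        self._cache = None

    @property
    def params(self) -> list[np.ndarray]:
        return [self.W0, self.W1]

    @property
    def out_dim(self) -> int:
        return 2 * self.widths[1]

    def node_embeddings(self, ax: np.ndarray, ahat: np.ndarray) -> np.ndarray:
        """f(X, A) for a batch: (batch, n, width) node embedding tensor."""
        if ax.shape[2] != self.W0.shape[0]:
            raise DataError(
                f"conv layer 0 expects {self.W0.shape[0]} input features, got {ax.shape[2]}")
        z1 = ax @ self.W0
        h1 = relu(z1)
        ah1 = ahat @ h1
        z2 = ah1 @ self.W1
        h2 = relu(z2)
        self._cache = (ax, ahat, z1, h1, ah1, z2, h2)
        return h2

    def forward(self, ax: np.ndarray, ahat: np.ndarray) -> np.ndarray:
        h2 = self.node_embeddings(ax, ahat)
        n = h2.shape[1]
        fmean = h2.mean(axis=1)
        fmax = h2.max(axis=1)
        argmax = h2.argmax(axis=1)
        self._readout_cache = (n, argmax, h2.shape)
        return np.concatenate([fmean, fmax], axis=1)

    def backward(self, dF: np.ndarray) -> list[np.ndarray]:
        ax, ahat, z1, h1, ah1, z2, h2 = self._cache
        n, argmax, shape = self._readout_cache
        d = self.widths[1]
        dmean, dmax = dF[:, :d], dF[:, d:]
        dh2 = np.repeat(dmean[:, None, :] / n, n, axis=1)
        batch_idx = np.arange(shape[0])[:, None]
        chan_idx = np.arange(d)[None, :]
        dh2[batch_idx, argmax, chan_idx] += dmax
        dz2 = dh2 * (z2 > 0)
        # contract over (batch, node): free reshape on contiguous tensors + one GEMM
        dW1 = _flat2d(ah1).T @ _flat2d(dz2)
        dah1 = dz2 @ self.W1.T
        dh1 = ahat @ dah1  # Â is symmetric
        dz1 = dh1 * (z1 > 0)
        dW0 = _flat2d(ax).T @ _flat2d(dz1)
        return [dW0, dW1]


def _default_head_widths(in_dim: int, n_scales: int) -> list[int]:
    # single-scale networks use the narrower 64/16/8 head; fused ones in/32/16
    return [in_dim, 16, 8] if n_scales == 1 else [in_dim, 32, 16]


class MultiScaleGCNNet:
    """Per-scale GCN encoders + ratio-weighted fusion + dense softmax head.

    With K scales, each 64-dim readout F_k is rescaled by K·α_k (equal
    weights leave it unchanged), concatenated in scale order, and passed
    through fully-connected layers of the configured hidden widths
    followed by a 2-class softmax.
    """

    def __init__(self, scale_features: dict[str, int],
                 conv_widths: tuple[int, int] = (32, 32),
                 head_widths: list[int] | None = None,
                 dropout: float = 0.5,
                 alpha: dict[str, float] | None = None,
                 n_classes: int = 2,
                 seed: int = 0,
                 dtype=np.float64):
        if not scale_features:
            raise DataError("at least one scale is required")
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(0,)))
        self.scales = list(scale_features)
        self.encoders = {s: GCNEncoder(nf, conv_widths, rng, dtype)
                         for s, nf in scale_features.items()}
        k = len(self.scales)
        if alpha is None:
            alpha = {s: 1.0 / k for s in self.scales}
        if set(alpha) != set(self.scales):
            raise DataError("fusion weights must cover exactly the declared scales")
        weights = np.array([alpha[s] for s in self.scales], dtype=float)
        if np.any(weights < 0) or abs(weights.sum() - 1.0) > 1e-8:
            raise DataError("fusion weights must be non-negative and sum to 1")
        self.alpha = {s: float(a) for s, a in zip(self.scales, weights)}
        in_dim = sum(e.out_dim for e in self.encoders.values())
        widths = _default_head_widths(in_dim, k) if head_widths is None else list(head_widths)
        self.head = DenseStack([in_dim] + widths + [n_classes], dropout, rng, dtype)
        self._block_slices = None

    @property
    def params(self) -> list[np.ndarray]:
        out = []
        for s in self.scales:
            out.extend(self.encoders[s].params)
        out.extend(self.head.params)
        return out

    def get_state(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.params, state):
            p[...] = s

    def fuse(self, reps: dict[str, np.ndarray]) -> np.ndarray:
        """Ratio-weighted concatenation of per-scale representations."""
        k = len(self.scales)
        blocks, slices, start = [], [], 0
        for s in self.scales:
            f = reps[s] * (k * self.alpha[s])
            blocks.append(f)
            slices.append(slice(start, start + f.shape[1]))
            start += f.shape[1]
        self._block_slices = slices
        return np.concatenate(blocks, axis=1)

    def forward(self, batch: dict[str, tuple[np.ndarray, np.ndarray]],
                train: bool = False,
                drop_rng: np.random.Generator | None = None) -> np.ndarray:
        missing = [s for s in self.scales if s not in batch]
        if missing:
            raise DataError(f"batch is missing scales {missing}")
        reps = {s: self.encoders[s].forward(*batch[s]) for s in self.scales}
        fused = self.fuse(reps)
        return self.head.forward(fused, train=train, drop_rng=drop_rng)

    def backward(self, dlogits: np.ndarray) -> list[np.ndarray]:
        dfused, head_grads = self.head.backward(dlogits)
        k = len(self.scales)
        grads = []
        for s, sl in zip(self.scales, self._block_slices):
            dF = dfused[:, sl] * (k * self.alpha[s])
            grads.extend(self.encoders[s].backward(dF))
        return grads + head_grads

    def predict_proba(self, batch) -> np.ndarray:
        return softmax(self.forward(batch, train=False))


class FeedForwardNet:
    """Plain dense softmax classifier over precomputed feature vectors."""

    def __init__(self, in_dim: int, head_widths: list[int] | None = None,
                 dropout: float = 0.2, n_classes: int = 2, seed: int = 0,
                 dtype=np.float64):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(0,)))
        widths = [in_dim, 32, 16] if head_widths is None else list(head_widths)
        self.head = DenseStack([in_dim] + widths + [n_classes], dropout, rng, dtype)

    @property
    def params(self) -> list[np.ndarray]:
        return self.head.params

    def get_state(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.params, state):
            p[...] = s

    def forward(self, x: np.ndarray, train: bool = False,
                drop_rng: np.random.Generator | None = None) -> np.ndarray:
        return self.head.forward(x, train=train, drop_rng=drop_rng)

    def backward(self, dlogits: np.ndarray) -> list[np.ndarray]:
        _, grads = self.head.backward(dlogits)
        return grads

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward(x, train=False))
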