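"""Graph-network building blocks as standalone operations.

These functions expose the algebra of the classifier one step at a time
— self-looped symmetric adjacency normalization, the two-layer graph
convolution, the mean‖max readout, and ratio-weighted fusion with the
dense softmax head — operating on plain arrays.  The trainable network
objects live in :mod:`msgcn.nn`; :func:`prepare_batch` converts
:class:`~msgcn.fcn.MultiScaleSample` lists into the stacked tensors both
APIs consume.
"""

from __future__ import annotations

import numpy as np

from .errors import DataError
from .nn import MultiScaleGCNNet, relu, softmax

__all__ = [
    "normalize_adjacency", "gcn_forward", "readout", "fuse_and_classify",
    "mgrl_forward", "prepare_batch", "save_params", "load_params",
]


def normalize_adjacency(a: np.ndarray) -> np.ndarray:
    """Self-looped symmetric normalization Â = D̃^{-1/2}(A + I)D̃^{-1/2}.

    Accepts a single n × n matrix or a stacked (batch, n, n) tensor; the
    input must be symmetric and non-negative.  Isolated nodes reduce to
    identity rows (Â = I when A = 0).
    """
    a = np.asarray(a, dtype=float)
    single = a.ndim == 2
    if single:
        a = a[None]
    if a.shape[-1] != a.shape[-2]:
        raise DataError("adjacency must be square")
    if np.abs(a - np.swapaxes(a, -1, -2)).max() > 1e-10:
        raise DataError("adjacency must be symmetric")
    if a.min() < 0:
        raise DataError("adjacency must be non-negative")
    n = a.shape[-1]
    atil = a + np.eye(n)
    dtil = atil.sum(axis=-1)
    inv_sqrt = 1.0 / np.sqrt(dtil)
    ahat = atil * inv_sqrt[..., :, None] * inv_sqrt[..., None, :]
    return ahat[0] if single else ahat


def gcn_forward(x: np.ndarray, ahat: np.ndarray, w0: np.ndarray,
                w1: np.ndarray) -> np.ndarray:
    """Two-layer graph convolution f(X, A) = ReLU(Â ReLU(Â X W0) W1)."""
    x, ahat = np.asarray(x, float), np.asarray(ahat, float)
    if x.shape[-2] != ahat.shape[-1]:
        raise DataError("conv layer 0: node counts of X and Â disagree")
    if x.shape[-1] != w0.shape[0]:
        raise DataError("conv layer 0: feature width does not match W0")
    if w0.shape[1] != w1.shape[0]:
        raise DataError("conv layer 1: W1 input width does not match W0 output")
    h = relu(ahat @ x @ w0)
    return relu(ahat @ h @ w1)


def readout(embeddings: np.ndarray) -> np.ndarray:
    """Graph-level vector: node-wise mean concatenated with node-wise max.

    An (n, d) embedding matrix yields a 2d vector (first the mean block,
    then the max block); a (batch, n, d) tensor yields (batch, 2d).
    """
    e = np.asarray(embeddings, dtype=float)
    single = e.ndim == 2
    if single:
        e = e[None]
    if e.shape[1] < 1:
        raise DataError("readout requires at least one node")
    out = np.concatenate([e.mean(axis=1), e.max(axis=1)], axis=1)
    return out[0] if single else out


def fuse_and_classify(reps: dict[str, np.ndarray], net: MultiScaleGCNNet) -> np.ndarray:
    """Ratio-weighted fusion of per-scale representations + softmax head.

    ``reps`` maps scale name to a (batch, 2d) representation; evaluation
    mode (no dropout). Rows of the result sum to 1.
    """
    missing = [s for s in net.scales if s not in reps]
    if missing:
        raise DataError(f"representations missing for scales {missing}")
    fused = net.fuse({s: np.atleast_2d(reps[s]) for s in net.scales})
    return softmax(net.head.forward(fused, train=False))


def prepare_batch(samples, scales: list[str] | None = None, dtype=np.float64,
                  ) -> tuple[dict[str, tuple[np.ndarray, np.ndarray]], np.ndarray]:
    """Stack MultiScaleSamples into per-scale (ÂX, Â) tensors + label vector.

    ÂX is precomputed here because the node-feature matrix is constant
    across training epochs; both tensors have shape (batch, n, n).
    ``dtype`` controls the tensor precision (training is typically run
    in float32 for speed).
    """
    if not samples:
        raise DataError("empty sample list")
    use_scales = scales if scales is not None else samples[0].scales
    batch = {}
    for scale in use_scales:
        ahat = np.stack([normalize_adjacency(s.graphs[scale].A) for s in samples])
        x = np.stack([s.graphs[scale].X for s in samples])
        batch[scale] = ((ahat @ x).astype(dtype), ahat.astype(dtype))
    labels = np.array([s.label for s in samples], dtype=int)
    return batch, labels


def mgrl_forward(sample, net: MultiScaleGCNNet) -> np.ndarray:
    """Class probabilities for one multi-scale sample, evaluation mode.

    Composes normalization → convolution → readout per scale, then the
    weighted fusion and dense head; deterministic (dropout off).
    """
    batch, _ = prepare_batch([sample], scales=net.scales)
    return net.predict_proba(batch)[0]


_FORMAT_VERSION = 1


def save_params(net, path) -> None:
    """Serialize network parameters to a single .npz with a version tag."""
    arrays = {f"p{i:03d}": p for i, p in enumerate(net.params)}
    np.savez(path, version=np.array([_FORMAT_VERSION]), **arrays)


def load_params(net, path) -> None:
    """Load parameters saved by :func:`save_params` into ``net`` (shapes must match)."""
    data = np.load(path)
    if int(data["version"][0]) != _FORMAT_VERSION:
        raise DataError(f"unsupported parameter file version in {path}")
    keys = sorted(k for k in data.files if k.startswith("p"))
    if len(keys) != len(net.params):
        raise DataError("parameter count mismatch when loading model")
    for p, k in zip(net.params, keys):
        if p.shape != data[k].shape:
            raise DataError(f"parameter shape mismatch for {k}")
        p[...] = data[k]
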