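"""Training, repeated random splits, classification metrics and sweeps.

The evaluation protocol draws repeated unstratified 80/10/10
train/validation/test partitions (train = floor(0.8 n), validation =
floor(0.1 n), test = remainder), trains a fresh network per repetition
with Adam under cross-entropy, keeps the checkpoint with the best
validation accuracy (ties favor the later epoch), and reports accuracy,
recall, precision, F1 and AUC as mean ± SD over repetitions.  Compared
methods always consume bit-identical split index sets.  The positive
class is label 1 (cases) throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import DataError
from .features import handcrafted_feature_table
from .fcn import graphs_from_cohort
from .model import prepare_batch
from .nn import Adam, FeedForwardNet, MultiScaleGCNNet, softmax_cross_entropy

logger = logging.getLogger(__name__)

__all__ = [
    "SplitScheme", "TrainConfig", "MetricsReport", "TrainRecord",
    "make_splits", "train", "evaluate", "run_protocol", "compare_methods",
    "sparsity_sweep", "fusion_ratio_sweep", "auc_score", "roc_points",
    "metrics_from_counts", "METHODS",
]

#: canonical method identifiers; aliases map the field's usual acronyms
METHODS = ("multiscale_gcn", "gcn_coarse", "gcn_fine", "dc", "lcc", "cc")
_ALIASES = {
    "mgrl": "multiscale_gcn",
    "gcna": "gcn_coarse",  # the 116-ROI atlas is the coarse scale
    "gcnc": "gcn_fine",
    "dcf": "dc", "lccf": "lcc", "ccf": "cc",
}
_METRIC_NAMES = ("accuracy", "recall", "precision", "f1", "auc")


def canonical_method(name: str) -> str:
    m = name.lower()
    m = _ALIASES.get(m, m)
    if m not in METHODS:
        raise DataError(f"unknown method {name!r}; choose from {METHODS} or aliases {tuple(_ALIASES)}")
    return m


@dataclass(frozen=True)
class SplitScheme:
    train: np.ndarray
    val: np.ndarray
    test: np.ndarray
    repetition: int
    seed: int


@dataclass(frozen=True)
class TrainConfig:
    """Optimizer settings shared by every method in a comparison."""

    lr: float = 0.01
    weight_decay: float = 1e-5
    epochs: int = 50
    seed: int = 0

    def validate(self) -> None:
        if self.lr < 0 or self.weight_decay < 0:
            raise DataError("learning rate and weight decay must be non-negative")
        if self.epochs < 1:
            raise DataError("epochs must be >= 1")


def make_splits(labels: np.ndarray, reps: int = 100, seed: int = 0,
                fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
                ) -> list[SplitScheme]:
    """Repeated random 80/10/10 partitions, deterministic given the seed.

    A repetition whose train, validation or test set misses one of the
    classes present in ``labels`` is redrawn (logged); stratification is
    not imposed.
    """
    labels = np.asarray(labels)
    n = labels.size
    if n < 10:
        raise DataError("need at least 10 subjects to partition")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise DataError("split fractions must sum to 1")
    n_train = int(np.floor(fractions[0] * n))
    n_val = int(np.floor(fractions[1] * n))
    classes = np.unique(labels)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(90,)))

    def both(part):
        return np.isin(classes, labels[part]).all()

    splits = []
    for rep in range(reps):
        candidate = None
        for attempt in range(1000):
            perm = rng.permutation(n)
            tr, va, te = perm[:n_train], perm[n_train:n_train + n_val], perm[n_train + n_val:]
            if both(tr) and candidate is None:
                candidate = (tr, va, te)  # fallback: training set covers both classes
            if both(tr) and both(va) and both(te):
                candidate = (tr, va, te)
                if attempt:
                    logger.info("repetition %d redrawn %d time(s) (degenerate split)",
                                rep, attempt)
                break
        else:
            # tiny or imbalanced parts may never cover both classes; the
            # training set still must
            if candidate is None:
                raise DataError(f"could not draw a usable split for repetition {rep}")
            logger.info("repetition %d: validation/test too small to hold both "
                        "classes; kept first training-complete draw", rep)
        tr, va, te = candidate
        splits.append(SplitScheme(np.sort(tr), np.sort(va), np.sort(te), rep, seed))
    return splits


# ---------------------------------------------------------------------------
# metrics

def metrics_from_counts(tp: int, fn: int, fp: int, tn: int) -> dict[str, float]:
    """Accuracy, recall, precision and F1 from confusion counts (positive = 1)."""
    total = tp + fn + fp + tn
    if total == 0:
        raise DataError("empty confusion table")
    accuracy = (tp + tn) / total
    recall = tp / (tp + fn) if tp + fn else 0.0
    precision = tp / (tp + fp) if tp + fp else 0.0
    f1 = (2 * precision * recall / (precision + recall)) if precision + recall else 0.0
    return {"accuracy": accuracy, "recall": recall, "precision": precision, "f1": f1}


def auc_score(y: np.ndarray, scores: np.ndarray) -> float | None:
    """Mann–Whitney AUC with midrank tie handling; None if one class is absent."""
    y = np.asarray(y)
    pos, neg = int((y == 1).sum()), int((y == 0).sum())
    if pos == 0 or neg == 0:
        return None
    ranks = rankdata(scores)
    return float((ranks[y == 1].sum() - pos * (pos + 1) / 2) / (pos * neg))


def roc_points(y: np.ndarray, scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """ROC polyline (FPR, TPR) over descending score thresholds."""
    y = np.asarray(y)
    order = np.argsort(-np.asarray(scores), kind="stable")
    ys = y[order]
    tp = np.concatenate([[0], np.cumsum(ys == 1)])
    fp = np.concatenate([[0], np.cumsum(ys == 0)])
    pos, neg = max(tp[-1], 1), max(fp[-1], 1)
    return fp / neg, tp / pos


# ---------------------------------------------------------------------------
# training

@dataclass
class TrainRecord:
    loss_trace: np.ndarray
    val_accuracy_trace: np.ndarray
    best_epoch: int
    best_val_accuracy: float


def _subset(inputs, idx):
    if isinstance(inputs, dict):
        return {s: (ax[idx], a[idx]) for s, (ax, a) in inputs.items()}
    return inputs[idx]


def _accuracy(net, inputs, y) -> float:
    pred = net.predict_proba(inputs).argmax(axis=1)
    return float((pred == y).mean())


def train(net, inputs, labels: np.ndarray, train_idx: np.ndarray,
          val_idx: np.ndarray, config: TrainConfig) -> TrainRecord:
    """Full-batch Adam training with best-validation-accuracy checkpointing.

    ``inputs`` is either a per-scale tensor dict (graph networks) or a
    feature matrix (dense baselines). The retained parameters are those
    of the epoch with the highest validation accuracy; among ties the
    later epoch wins. Deterministic given ``config.seed``.
    """
    config.validate()
    y_train = labels[train_idx]
    if np.unique(y_train).size < 2:
        raise DataError("degenerate single-class training set")
    train_in = _subset(inputs, train_idx)
    val_in = _subset(inputs, val_idx) if len(val_idx) else None
    opt = Adam(net.params, lr=config.lr, weight_decay=config.weight_decay)
    drop_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(7,)))
    losses, val_accs = [], []
    best_val, best_epoch, best_state = -np.inf, -1, net.get_state()
    for epoch in range(config.epochs):
        logits = net.forward(train_in, train=True, drop_rng=drop_rng)
        loss, dlogits = softmax_cross_entropy(logits, y_train)
        if not np.isfinite(loss):
            raise DataError(f"non-finite loss at epoch {epoch}; last losses {losses[-3:]}")
        grads = net.backward(dlogits)
        opt.step(grads)
        losses.append(loss)
        val_acc = _accuracy(net, val_in, labels[val_idx]) if val_in is not None \
            else _accuracy(net, train_in, y_train)
        val_accs.append(val_acc)
        if val_acc >= best_val:
            best_val, best_epoch, best_state = val_acc, epoch, net.get_state()
    net.set_state(best_state)
    return TrainRecord(np.array(losses), np.array(val_accs), best_epoch, float(best_val))


def evaluate(net, inputs, labels: np.ndarray, test_idx: np.ndarray) -> dict:
    """Per-repetition test metrics with positive class = 1.

    AUC is computed on the predicted class-1 probability and recorded as
    None (excluded from report means) when the test set is single-class.
    """
    if len(test_idx) == 0:
        raise DataError("empty test set")
    y = labels[test_idx]
    probs = net.predict_proba(_subset(inputs, test_idx))
    pred = probs.argmax(axis=1)
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    out = metrics_from_counts(tp, fn, fp, tn)
    auc = auc_score(y, probs[:, 1])
    if auc is None:
        logger.info("single-class test set: AUC recorded as missing")
    out.update({"auc": auc, "tp": tp, "fn": fn, "fp": fp, "tn": tn})
    out["roc"] = roc_points(y, probs[:, 1])
    return out


# ---------------------------------------------------------------------------
# reports and the repeated-split protocol

@dataclass
class MetricsReport:
    """Per-repetition metric records with mean ± SD summaries."""

    method: str
    records: list[dict] = field(default_factory=list)
    roc: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)
    train_records: list[TrainRecord] = field(default_factory=list)

    @property
    def n_reps(self) -> int:
        return len(self.records)

    def values(self, metric: str) -> np.ndarray:
        vals = [r[metric] for r in self.records if r[metric] is not None]
        return np.asarray(vals, dtype=float)

    def mean(self, metric: str) -> float:
        return float(self.values(metric).mean())

    def sd(self, metric: str) -> float:
        v = self.values(metric)
        return 0.0 if v.size < 2 else float(v.std(ddof=1))

    def summary_frame(self) -> pd.DataFrame:
        rows = {m: {"mean": self.mean(m), "sd": self.sd(m)} for m in _METRIC_NAMES}
        return pd.DataFrame(rows).T

    def records_frame(self) -> pd.DataFrame:
        cols = list(_METRIC_NAMES) + ["tp", "fn", "fp", "tn"]
        df = pd.DataFrame([{k: r[k] for k in cols} for r in self.records])
        df.insert(0, "repetition", np.arange(len(self.records)))
        df.insert(0, "method", self.method)
        return df


def _rep_seed(seed: int, rep: int) -> int:
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(rep,))
    return int(ss.generate_state(1, np.uint32)[0] & 0x7FFFFFFF)


#: training precision; float32 halves the BLAS cost of the conv layers
_TRAIN_DTYPE = np.float32


def _build_net(method: str, inputs, samples, alpha, dropout, conv_widths, seed):
    if method == "multiscale_gcn" or method.startswith("gcn_"):
        scale_features = {s: ax.shape[2] for s, (ax, a) in inputs.items()}
        return MultiScaleGCNNet(scale_features, conv_widths=conv_widths,
                                dropout=0.5 if dropout is None else dropout,
                                alpha=alpha, seed=seed, dtype=_TRAIN_DTYPE)
    return FeedForwardNet(inputs.shape[1],
                          dropout=0.2 if dropout is None else dropout, seed=seed,
                          dtype=_TRAIN_DTYPE)


def _method_inputs(samples, method: str):
    if method == "multiscale_gcn":
        return prepare_batch(samples, dtype=_TRAIN_DTYPE)
    if method.startswith("gcn_"):
        scale = method[len("gcn_"):]
        if scale not in samples[0].graphs:
            raise DataError(f"scale {scale!r} absent from samples")
        return prepare_batch(samples, scales=[scale], dtype=_TRAIN_DTYPE)
    return handcrafted_feature_table(samples, method)


def run_protocol(samples, method: str, reps: int = 100, seed: int = 0,
                 splits: list[SplitScheme] | None = None,
                 config: TrainConfig | None = None,
                 alpha: dict[str, float] | None = None,
                 dropout: float | None = None,
                 conv_widths: tuple[int, int] = (32, 32),
                 standardize_features: bool = True) -> MetricsReport:
    """Repeated-split evaluation of one method on one cohort of samples.

    Handcrafted-feature baselines are z-scored with training-split
    statistics inside each repetition (no test leakage); graph methods
    consume the (ÂX, Â) tensors unchanged.  Pass the same ``splits`` to
    every method for a fair comparison.
    """
    method = canonical_method(method)
    inputs, labels = _method_inputs(samples, method)
    if splits is None:
        splits = make_splits(labels, reps=reps, seed=seed)
    base_cfg = config or TrainConfig()
    report = MetricsReport(method=method)
    dense = not isinstance(inputs, dict)
    for split in splits:
        rep_inputs = inputs
        if dense and standardize_features:
            mu = inputs[split.train].mean(axis=0)
            sd = inputs[split.train].std(axis=0)
            sd[sd == 0] = 1.0
            rep_inputs = (inputs - mu) / sd
        rs = _rep_seed(base_cfg.seed if config is not None else seed, split.repetition)
        net = _build_net(method, rep_inputs if dense else inputs, samples,
                         alpha, dropout, conv_widths, rs)
        cfg = TrainConfig(lr=base_cfg.lr, weight_decay=base_cfg.weight_decay,
                          epochs=base_cfg.epochs, seed=rs)
        rec = train(net, rep_inputs, labels, split.train, split.val, cfg)
        res = evaluate(net, rep_inputs, labels, split.test)
        report.roc.append(res.pop("roc"))
        report.records.append(res)
        report.train_records.append(rec)
    return report


def compare_methods(samples, methods=METHODS, reps: int = 100, seed: int = 0,
                    config: TrainConfig | None = None) -> dict[str, MetricsReport]:
    """Run several methods on bit-identical splits; returns method → report."""
    labels = np.array([s.label for s in samples], dtype=int)
    splits = make_splits(labels, reps=reps, seed=seed)
    return {m: run_protocol(samples, m, seed=seed, splits=splits, config=config)
            for m in (canonical_method(m) for m in methods)}


def sparsity_sweep(cohort, retains=(1.0, 0.9, 0.8, 0.7, 0.6),
                   method: str = "multiscale_gcn", reps: int = 100, seed: int = 0,
                   fcn_method: str = "pearson", lam: float = 0.1,
                   config: TrainConfig | None = None) -> dict[float, MetricsReport]:
    """Edge-retention sweep: rebuild graphs per retention level, same splits."""
    splits = make_splits(cohort.labels, reps=reps, seed=seed)
    out = {}
    for r in retains:
        samples = graphs_from_cohort(cohort, method=fcn_method, lam=lam,
                                     retain_fraction=float(r))
        out[float(r)] = run_protocol(samples, method, seed=seed, splits=splits,
                                     config=config)
    return out


def fusion_ratio_sweep(samples, ratios=tuple(np.round(np.arange(0.1, 1.0, 0.1), 1)),
                       reps: int = 100, seed: int = 0,
                       config: TrainConfig | None = None) -> pd.DataFrame:
    """Accuracy as the first scale's fusion weight α varies (second gets 1-α).

    Requires two-scale samples; returns one row per ratio with mean ± SD
    accuracy, all ratios evaluated on identical splits.
    """
    scales = samples[0].scales
    if len(scales) != 2:
        raise DataError("fusion-ratio sweep requires exactly two scales")
    labels = np.array([s.label for s in samples], dtype=int)
    splits = make_splits(labels, reps=reps, seed=seed)
    rows = []
    for r in ratios:
        alpha = {scales[0]: float(r), scales[1]: float(1.0 - r)}
        rep = run_protocol(samples, "multiscale_gcn", seed=seed, splits=splits,
                           config=config, alpha=alpha)
        rows.append({"ratio": float(r), "accuracy_mean": rep.mean("accuracy"),
                     "accuracy_sd": rep.sd("accuracy")})
    return pd.DataFrame(rows)
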