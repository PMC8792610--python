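"""Functional-connectivity network construction and graph assembly.

A subject's ROI time-series matrix becomes an n × n connectivity matrix
either by Pearson correlation of ROI signal pairs or by sparse
representation (an L1-penalized regression of each ROI's signal on all
the others).  The connectivity can be sparsified by proportional
thresholding — keeping the top fraction of edges by absolute weight —
before it is split into the two graph inputs the classifier consumes:
the signed node-feature matrix X (row i = node i's correlation profile)
and the non-negative adjacency A = |X| (connection *strength*, where the
magnitude of positive or negative coupling alike measures the edge).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import DataError

__all__ = [
    "TimeSeriesMatrix", "ConnectivityMatrix", "SubjectGraph", "MultiScaleSample",
    "pearson_fcn", "sparse_representation_fcn", "proportional_threshold",
    "build_graph", "assemble_multiscale", "graphs_from_cohort",
]

_SYM_TOL = 1e-10


@dataclass
class TimeSeriesMatrix:
    """t × n matrix of ROI mean signals: column i is ROI i's series."""

    values: np.ndarray
    subject_id: str = ""
    scale: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] < 2:
            raise DataError("time series must be a t x n matrix with t >= 2")
        if not np.all(np.isfinite(self.values)):
            raise DataError("time series contains non-finite entries")

    @property
    def t(self) -> int:
        return self.values.shape[0]

    @property
    def n(self) -> int:
        return self.values.shape[1]


@dataclass
class ConnectivityMatrix:
    """Symmetric n × n edge-weight matrix with its construction metadata."""

    values: np.ndarray
    method: str  # "pearson" | "sparse_representation"
    retain_fraction: float = 1.0
    subject_id: str = ""
    scale: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise DataError("connectivity must be square")
        if not np.all(np.isfinite(v)):
            raise DataError("connectivity contains non-finite entries")
        if np.abs(v - v.T).max() > _SYM_TOL:
            raise DataError("connectivity must be symmetric")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class SubjectGraph:
    """Graph inputs for one subject at one scale: signed X, A = |X|."""

    X: np.ndarray
    A: np.ndarray
    label: int
    scale: str = ""
    subject_id: str = ""

    @property
    def n(self) -> int:
        return self.A.shape[0]


@dataclass
class MultiScaleSample:
    """One subject's SubjectGraphs across all declared scales, in fusion order."""

    subject_id: str
    label: int
    graphs: dict[str, SubjectGraph]

    @property
    def scales(self) -> list[str]:
        return list(self.graphs)


def pearson_fcn(ts: TimeSeriesMatrix) -> ConnectivityMatrix:
    """Pearson-correlation connectivity: e_ij = corr(s_i, s_j), diag = 1."""
    dead = np.flatnonzero(np.ptp(ts.values, axis=0) == 0)
    if dead.size:
        raise DataError(f"zero-variance ROI column(s): {dead.tolist()}")
    e = np.corrcoef(ts.values, rowvar=False)
    e = np.clip((e + e.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(e, 1.0)
    return ConnectivityMatrix(e, method="pearson",
                              subject_id=ts.subject_id, scale=ts.scale)


def sparse_representation_fcn(ts: TimeSeriesMatrix, lam: float) -> ConnectivityMatrix:
    """Sparse-representation connectivity via per-ROI lasso regressions.

    Each z-scored ROI signal s_i is regressed on all other columns under

        min_w  0.5 * ||s_i - S_{-i} w||^2  +  lam * ||w||_1

    (self-coefficient fixed at zero), solved by cyclic coordinate descent.
    The coefficient matrix is symmetrized as (|W| + |W^T|) / 2, so the
    result is non-negative with zero diagonal; larger ``lam`` gives a
    sparser network.
    """
    from sklearn.exceptions import ConvergenceWarning
    from sklearn.linear_model import Lasso

    if lam <= 0:
        raise DataError("lam must be positive")
    dead = np.flatnonzero(np.ptp(ts.values, axis=0) == 0)
    if dead.size:
        raise DataError(f"zero-variance ROI column(s): {dead.tolist()}")
    s = (ts.values - ts.values.mean(axis=0)) / ts.values.std(axis=0)
    t, n = s.shape
    w = np.zeros((n, n))
    # sklearn's lasso objective is (1/2t)||y - Xw||^2 + alpha ||w||_1
    model = Lasso(alpha=lam / t, fit_intercept=False, tol=1e-6, max_iter=1000)
    for i in range(n):
        others = np.delete(np.arange(n), i)
        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            try:
                model.fit(s[:, others], s[:, i])
            except ConvergenceWarning as exc:
                raise DataError(f"sparse representation failed to converge for ROI {i}") from exc
        w[i, others] = model.coef_
    sym = (np.abs(w) + np.abs(w.T)) / 2.0
    np.fill_diagonal(sym, 0.0)
    return ConnectivityMatrix(sym, method="sparse_representation",
                              subject_id=ts.subject_id, scale=ts.scale)


def proportional_threshold(c: ConnectivityMatrix, retain_fraction: float) -> ConnectivityMatrix:
    """Keep the top ``ceil(retain_fraction * m)`` edges by |weight|, zero the rest.

    Operates on the m = n(n-1)/2 upper-triangle entries, mirrors the
    result to preserve symmetry and leaves the diagonal untouched.
    Boundary ties are broken deterministically by (|weight| descending,
    row index, column index). ``retain_fraction=1`` is the identity.
    """
    if not (0.0 < retain_fraction <= 1.0):
        raise DataError("retain_fraction must lie in (0, 1]")
    v = c.values.copy()
    if retain_fraction == 1.0 or c.n < 2:
        return ConnectivityMatrix(v, method=c.method, retain_fraction=retain_fraction,
                                  subject_id=c.subject_id, scale=c.scale)
    iu, ju = np.triu_indices(c.n, k=1)
    m = iu.size
    keep = math.ceil(retain_fraction * m)
    mag = np.abs(v[iu, ju])
    # lexsort: last key is primary -> |w| desc, then row, then column
    order = np.lexsort((ju, iu, -mag))
    drop = order[keep:]
    v[iu[drop], ju[drop]] = 0.0
    v[ju[drop], iu[drop]] = 0.0
    return ConnectivityMatrix(v, method=c.method, retain_fraction=retain_fraction,
                              subject_id=c.subject_id, scale=c.scale)


def build_graph(c: ConnectivityMatrix, label: int) -> SubjectGraph:
    """Split a connectivity matrix into signed features X and adjacency A = |X|."""
    if np.abs(c.values - c.values.T).max() > _SYM_TOL:
        raise DataError("connectivity must be symmetric to build a graph")
    x = c.values.copy()
    return SubjectGraph(X=x, A=np.abs(x), label=int(label),
                        scale=c.scale, subject_id=c.subject_id)


def assemble_multiscale(graphs: list[SubjectGraph]) -> MultiScaleSample:
    """Bundle one subject's per-scale graphs; list order fixes fusion order."""
    if not graphs:
        raise DataError("no graphs to assemble")
    sid, label = graphs[0].subject_id, graphs[0].label
    out: dict[str, SubjectGraph] = {}
    for g in graphs:
        if g.subject_id != sid:
            raise DataError(f"subject mismatch across scales: {g.subject_id!r} vs {sid!r}")
        if g.label != label:
            raise DataError(f"label mismatch across scales for subject {sid!r}")
        if g.scale in out:
            raise DataError(f"duplicate scale {g.scale!r} for subject {sid!r}")
        out[g.scale] = g
    return MultiScaleSample(subject_id=sid, label=label, graphs=out)


def graphs_from_cohort(ds, method: str = "pearson", lam: float = 0.1,
                       retain_fraction: float = 1.0,
                       scales: list[str] | None = None) -> list[MultiScaleSample]:
    """Cohort → per-subject multi-scale graph samples.

    Thresholding (when ``retain_fraction < 1``) is applied to the
    connectivity before X and A are formed, so zeroed edges vanish from
    features and adjacency alike.
    """
    from .cohort import CohortDataset  # noqa: F401  (type reference)

    use_scales = scales if scales is not None else list(ds.scales)
    missing = [s for s in use_scales if s not in ds.scales]
    if missing:
        raise DataError(f"unknown scales requested: {missing}")
    samples = []
    for s, sid in enumerate(ds.subject_ids):
        per_scale = []
        for scale in use_scales:
            ts = TimeSeriesMatrix(ds.series[scale][s], subject_id=sid, scale=scale)
            if method == "pearson":
                c = pearson_fcn(ts)
            elif method in ("sr", "sparse_representation"):
                c = sparse_representation_fcn(ts, lam)
            else:
                raise DataError(f"unknown connectivity method {method!r}")
            if retain_fraction < 1.0:
                c = proportional_threshold(c, retain_fraction)
            per_scale.append(build_graph(c, ds.labels[s]))
        samples.append(assemble_multiscale(per_scale))
    return samples
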