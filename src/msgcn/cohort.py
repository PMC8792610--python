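"""Synthetic multi-subject, multi-scale BOLD-like cohorts.

The generator emulates the situation the classifier is built for: each
subject carries one ROI time-series matrix per brain-parcellation scale
(a fine scale, e.g. 200 parcels, and a coarse scale, e.g. 116 parcels),
and the two diagnostic classes differ only through a planted perturbation
of the fine-scale inter-ROI covariance on a seeded subset of edges.

Within a class, subject time series are i.i.d. draws from a zero-mean
multivariate normal whose covariance is a random factor-model correlation
matrix; class 1 additionally receives a signed perturbation of magnitude
``effect_size`` on ``effect_edge_fraction`` of the off-diagonal entries,
after which the matrix is projected back to the positive-definite cone by
eigenvalue clipping.  The coarse scale is not simulated independently:
coarse ROI signals are exact means of disjoint contiguous groups of fine
ROIs, so the two scales view the same underlying activity with the
redundancy-plus-complementarity structure that multi-atlas fusion relies
on.  All randomness flows from a single seed through named substreams, so
a cohort is bit-reproducible from its spec.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import DataError

__all__ = ["CohortSpec", "CohortDataset", "generate_cohort", "write_cohort", "read_cohort"]

#: order matters: coarse first, matching the conventional 116+200 concatenation
COARSE, FINE = "coarse", "fine"

_EIG_FLOOR = 1e-4  # smallest eigenvalue kept after positive-definite projection


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of one synthetic cohort.

    ``effect_size`` is the magnitude added to (a seeded subset of)
    off-diagonal covariance entries of class 1; ``noise_sd`` is the
    standard deviation of white observation noise added on top of the
    correlated signal; ``class_balance`` is the fraction of class-1
    (case) subjects.
    """

    n_subjects: int
    n_timepoints: int = 175
    fine_rois: int = 200
    coarse_rois: int = 116
    effect_edge_fraction: float = 0.1
    effect_size: float = 0.6
    noise_sd: float = 0.25
    class_balance: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise DataError("n_subjects must be >= 1")
        if self.n_timepoints < 2:
            raise DataError("n_timepoints must be >= 2")
        if not (1 <= self.coarse_rois <= self.fine_rois):
            raise DataError("need 1 <= coarse_rois <= fine_rois")
        if not (0.0 <= self.effect_edge_fraction <= 1.0):
            raise DataError("effect_edge_fraction must lie in [0, 1]")
        if self.effect_size < 0:
            raise DataError("effect_size must be non-negative")
        if self.noise_sd <= 0:
            raise DataError("noise_sd must be positive")
        if not (0.0 < self.class_balance < 1.0):
            raise DataError("class_balance must lie in (0, 1)")


@dataclass
class CohortDataset:
    """A generated (or loaded) cohort.

    ``series[scale]`` is an array of shape (n_subjects, t, n_rois); the
    scale order of ``scales`` fixes the concatenation order downstream.
    """

    subject_ids: list[str]
    labels: np.ndarray  # shape (n_subjects,), values in {0, 1}
    scales: dict[str, int]  # ordered: scale name -> ROI count
    series: dict[str, np.ndarray]
    coarse_groups: list[np.ndarray] | None = None  # fine-ROI indices per coarse ROI
    spec: CohortSpec | None = None

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def validate(self) -> None:
        for name, n in self.scales.items():
            if name not in self.series:
                raise DataError(f"scale {name!r} declared but has no series")
            arr = self.series[name]
            if arr.shape[0] != self.n_subjects or arr.shape[2] != n:
                raise DataError(f"series for scale {name!r} has shape {arr.shape}")


def _random_correlation(n: int, rng: np.random.Generator, n_factors: int = 10) -> np.ndarray:
    """Random correlation matrix from a low-rank factor model B Bᵀ + δI."""
    k = min(n_factors, max(1, n // 2))
    b = rng.normal(size=(n, k))
    cov = b @ b.T + np.eye(n)
    d = np.sqrt(np.diag(cov))
    return cov / np.outer(d, d)


def _project_pd(sigma: np.ndarray, floor: float = _EIG_FLOOR) -> np.ndarray:
    """Nearest-by-clipping symmetric positive-definite matrix."""
    sym = (sigma + sigma.T) / 2.0
    w, v = np.linalg.eigh(sym)
    proj = (v * np.clip(w, floor, None)) @ v.T
    proj = (proj + proj.T) / 2.0
    if np.linalg.eigvalsh(proj).min() < floor / 2:
        raise DataError("covariance projection failed to reach positive definiteness")
    return proj


def _perturbation(n: int, fraction: float, magnitude: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Symmetric matrix adding ±magnitude on a random fraction of edges."""
    iu, ju = np.triu_indices(n, k=1)
    m = iu.size
    n_pick = int(round(fraction * m))
    delta = np.zeros((n, n))
    if n_pick == 0 or magnitude == 0.0:
        return delta
    picked = rng.choice(m, size=n_pick, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_pick)
    delta[iu[picked], ju[picked]] = signs * magnitude
    return delta + delta.T


def _coarse_partition(n_fine: int, n_coarse: int,
                      rng: np.random.Generator) -> list[np.ndarray]:
    """Disjoint contiguous groups of fine ROIs, one per coarse ROI."""
    if n_coarse == n_fine:
        cuts = np.arange(1, n_fine)
    else:
        cuts = np.sort(rng.choice(np.arange(1, n_fine), size=n_coarse - 1, replace=False))
    bounds = np.concatenate([[0], cuts, [n_fine]])
    return [np.arange(bounds[i], bounds[i + 1]) for i in range(n_coarse)]


def planted_edges(spec: CohortSpec) -> tuple[np.ndarray, np.ndarray]:
    """(i, j) upper-triangle indices of the fine-scale edges perturbed in class 1.

    Re-derives the seeded subset used by :func:`generate_cohort`, so
    analyses can locate the planted effect without regenerating data.
    """
    ss = np.random.SeedSequence(entropy=spec.seed, spawn_key=(1,))
    rng = np.random.default_rng(ss)
    iu, ju = np.triu_indices(spec.fine_rois, k=1)
    n_pick = int(round(spec.effect_edge_fraction * iu.size))
    picked = rng.choice(iu.size, size=n_pick, replace=False) if n_pick else np.array([], int)
    return iu[picked], ju[picked]


def generate_cohort(spec: CohortSpec) -> CohortDataset:
    """Draw a cohort from the planted-effect generative model.

    Deterministic given ``spec`` (including its seed): the base
    correlation, the perturbed edge subset, labels, the coarse grouping
    and every subject's series each consume a named substream of the
    root seed.
    """
    spec.validate()
    if spec.effect_edge_fraction == 0.0 and spec.effect_size > 0:
        warnings.warn("effect_edge_fraction=0 with effect_size>0: generating a null cohort",
                      stacklevel=2)

    streams = {
        name: np.random.default_rng(np.random.SeedSequence(entropy=spec.seed, spawn_key=(k,)))
        for k, name in enumerate(["base", "edges", "labels", "groups", "series"])
    }

    sigma0 = _project_pd(_random_correlation(spec.fine_rois, streams["base"]))
    delta = _perturbation(spec.fine_rois, spec.effect_edge_fraction,
                          spec.effect_size, streams["edges"])
    sigma1 = _project_pd(sigma0 + delta)
    chol = {0: np.linalg.cholesky(sigma0), 1: np.linalg.cholesky(sigma1)}

    n1 = int(round(spec.n_subjects * spec.class_balance))
    labels = np.zeros(spec.n_subjects, dtype=int)
    labels[:n1] = 1
    streams["labels"].shuffle(labels)

    groups = _coarse_partition(spec.fine_rois, spec.coarse_rois, streams["groups"])

    rng = streams["series"]
    fine = np.empty((spec.n_subjects, spec.n_timepoints, spec.fine_rois))
    for s in range(spec.n_subjects):
        z = rng.standard_normal((spec.n_timepoints, spec.fine_rois))
        noise = rng.standard_normal((spec.n_timepoints, spec.fine_rois))
        fine[s] = z @ chol[labels[s]].T + spec.noise_sd * noise

    coarse = np.stack([fine[:, :, g].mean(axis=2) for g in groups], axis=2)

    ids = [f"sub{idx:04d}" for idx in range(spec.n_subjects)]
    return CohortDataset(
        subject_ids=ids,
        labels=labels,
        scales={COARSE: spec.coarse_rois, FINE: spec.fine_rois},
        series={COARSE: coarse, FINE: fine},
        coarse_groups=groups,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# plain-text persistence

_MANIFEST = "manifest.yaml"
_LABELS = "labels.tsv"


def write_cohort(ds: CohortDataset, out_dir, overwrite: bool = False) -> dict:
    """Write one TSV matrix per subject per scale, a labels table and a manifest.

    Matrix rows are time points, columns are ROIs. Refuses to clobber an
    existing manifest unless ``overwrite`` is set. Returns the manifest dict.
    """
    import yaml
    from pathlib import Path

    if ds.n_subjects == 0:
        raise DataError("refusing to write an empty cohort")
    ds.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / _MANIFEST
    if manifest_path.exists() and not overwrite:
        raise DataError(f"{manifest_path} exists; pass overwrite=True to replace it")

    for k, scale in enumerate(ds.scales):
        arr = ds.series[scale]
        for s, sid in enumerate(ds.subject_ids):
            np.savetxt(out / f"{sid}_{scale}.tsv", arr[s], fmt="%.10e", delimiter="\t")
    with open(out / _LABELS, "w") as fh:
        fh.write("subject\tlabel\n")
        for sid, y in zip(ds.subject_ids, ds.labels):
            fh.write(f"{sid}\t{int(y)}\n")

    manifest = {
        "n_subjects": ds.n_subjects,
        "n_timepoints": int(next(iter(ds.series.values())).shape[1]),
        "scales": {name: int(n) for name, n in ds.scales.items()},
        "file_pattern": "{subject}_{scale}.tsv",
        "labels_file": _LABELS,
    }
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest


def read_cohort(in_dir) -> CohortDataset:
    """Load a cohort written by :func:`write_cohort` (round-trips to text precision)."""
    import yaml
    from pathlib import Path

    from .io import read_labels, read_timeseries

    src = Path(in_dir)
    manifest_path = src / _MANIFEST
    if not manifest_path.exists():
        raise DataError(f"no manifest at {manifest_path}")
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)

    label_map = read_labels(src / manifest["labels_file"])
    ids = sorted(label_map)
    labels = np.array([label_map[s] for s in ids], dtype=int)
    scales = {name: int(n) for name, n in manifest["scales"].items()}
    series = {}
    for scale, n in scales.items():
        mats = []
        for sid in ids:
            ts = read_timeseries(src / f"{sid}_{scale}.tsv", subject_id=sid, scale=scale)
            if ts.n != n:
                raise DataError(f"{sid}_{scale}: expected {n} ROIs, found {ts.n}")
            mats.append(ts.values)
        series[scale] = np.stack(mats)
    return CohortDataset(subject_ids=ids, labels=labels, scales=scales, series=series)
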