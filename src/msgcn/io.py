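"""File I/O and run configuration.

Time series, labels and metrics travel as delimited text; configuration
is YAML with the training defaults (learning rate 0.01, weight decay
1e-5, 50 epochs, dropout 0.5) filled in for absent keys and unknown keys
rejected.  Every run can emit a reproducibility record containing the
config hash, the seeds and the package versions used.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigError, DataError
from .fcn import TimeSeriesMatrix

__all__ = [
    "RunConfig", "load_config", "dump_config", "read_timeseries", "read_labels",
    "write_metrics", "reproducibility_record",
]


def read_timeseries(path, subject_id: str = "", scale: str = "") -> TimeSeriesMatrix:
    """Parse a delimited-text t × n matrix (rows = time points, columns = ROIs).

    Ragged rows and non-numeric cells are reported with 1-based line
    numbers; an empty file is an error.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such time-series file: {path}")
    rows, width = [], None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if width is None:
                width = len(parts)
            elif len(parts) != width:
                raise DataError(f"{path}:{lineno}: ragged row "
                                f"({len(parts)} columns, expected {width})")
            try:
                rows.append([float(v) for v in parts])
            except ValueError as exc:
                raise DataError(f"{path}:{lineno}: non-numeric cell ({exc})") from None
    if not rows:
        raise DataError(f"{path}: empty time-series file")
    return TimeSeriesMatrix(np.asarray(rows), subject_id=subject_id, scale=scale)


def read_labels(path) -> dict[str, int]:
    """Two-column TSV (subject, label) with header; labels must be 0/1."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such labels file: {path}")
    out: dict[str, int] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise DataError(f"{path}: empty labels file")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 2:
                raise DataError(f"{path}:{lineno}: expected two columns")
            sid, raw = parts
            if sid in out:
                raise DataError(f"{path}:{lineno}: duplicate subject id {sid!r}")
            if raw not in ("0", "1"):
                raise DataError(f"{path}:{lineno}: label must be 0 or 1, got {raw!r}")
            out[sid] = int(raw)
    if not out:
        raise DataError(f"{path}: no label rows")
    return out


def write_metrics(report, path) -> None:
    """Write per-repetition records as TSV plus a human-readable summary sidecar."""
    path = Path(path)
    report.records_frame().to_csv(path, sep="\t", index=False)
    summary = path.with_suffix(path.suffix + ".summary.txt")
    with open(summary, "w") as fh:
        fh.write(f"method: {report.method}\nrepetitions: {report.n_reps}\n\n")
        fh.write(report.summary_frame().to_string(float_format=lambda v: f"{v:.4f}"))
        fh.write("\n")


# ---------------------------------------------------------------------------
# configuration

_SCHEMA: dict[str, dict] = {
    "method": {"default": "multiscale_gcn"},
    "scales": {"default": None},  # optional list of {name, rois}
    "fcn": {"default": {"method": "pearson", "lam": 0.1, "retain_fraction": 1.0}},
    "model": {"default": {"conv_widths": [32, 32], "head_widths": None,
                          "dropout": 0.5, "alpha": None}},
    "train": {"default": {"lr": 0.01, "weight_decay": 1.0e-5, "epochs": 50, "seed": 0}},
    "eval": {"default": {"reps": 100, "seed": 0}},
    "out_dir": {"default": "."},
}


@dataclass
class RunConfig:
    method: str = "multiscale_gcn"
    scales: list | None = None
    fcn: dict = field(default_factory=lambda: dict(_SCHEMA["fcn"]["default"]))
    model: dict = field(default_factory=lambda: dict(_SCHEMA["model"]["default"]))
    train: dict = field(default_factory=lambda: dict(_SCHEMA["train"]["default"]))
    eval: dict = field(default_factory=lambda: dict(_SCHEMA["eval"]["default"]))
    out_dir: str = "."

    def to_dict(self) -> dict:
        return asdict(self)


def _merge_section(name: str, user: dict, problems: list[str]) -> dict:
    base = dict(_SCHEMA[name]["default"])
    for k, v in user.items():
        if k not in base:
            problems.append(f"unknown key {name}.{k}")
        else:
            base[k] = v
    return base


def validate_config(cfg: RunConfig) -> None:
    """Range-check every numeric option; all violations in one message."""
    problems = []
    if cfg.fcn["retain_fraction"] is not None and not (0.0 < cfg.fcn["retain_fraction"] <= 1.0):
        problems.append("fcn.retain_fraction must lie in (0, 1]")
    if cfg.fcn["method"] not in ("pearson", "sr", "sparse_representation"):
        problems.append(f"fcn.method unknown: {cfg.fcn['method']!r}")
    if cfg.fcn["lam"] is not None and cfg.fcn["lam"] <= 0:
        problems.append("fcn.lam must be positive")
    if not (0.0 <= cfg.model["dropout"] < 1.0):
        problems.append("model.dropout must lie in [0, 1)")
    if cfg.model["alpha"] is not None:
        vals = list(cfg.model["alpha"].values())
        if any(v < 0 for v in vals) or abs(sum(vals) - 1.0) > 1e-8:
            problems.append("model.alpha weights must be non-negative and sum to 1")
    if cfg.train["lr"] < 0:
        problems.append("train.lr must be non-negative")
    if cfg.train["weight_decay"] < 0:
        problems.append("train.weight_decay must be non-negative")
    if cfg.train["epochs"] < 1:
        problems.append("train.epochs must be >= 1")
    if cfg.eval["reps"] < 1:
        problems.append("eval.reps must be >= 1")
    if problems:
        raise ConfigError("invalid configuration: " + "; ".join(problems))


def load_config(path) -> RunConfig:
    """YAML → validated RunConfig with defaults filled; unknown keys are errors."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"no such config file: {path}")
    with open(path) as fh:
        try:
            raw = yaml.safe_load(fh) or {}
        except yaml.YAMLError as exc:
            raise ConfigError(f"{path}: not parseable YAML ({exc})") from None
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    problems: list[str] = []
    unknown = [k for k in raw if k not in _SCHEMA]
    problems += [f"unknown key {k}" for k in unknown]
    cfg = RunConfig()
    if "method" in raw:
        cfg.method = raw["method"]
    if "scales" in raw:
        cfg.scales = raw["scales"]
    if "out_dir" in raw:
        cfg.out_dir = str(raw["out_dir"])
    for section in ("fcn", "model", "train", "eval"):
        if section in raw:
            if not isinstance(raw[section], dict):
                problems.append(f"section {section} must be a mapping")
            else:
                setattr(cfg, section, _merge_section(section, raw[section], problems))
    if problems:
        raise ConfigError("invalid configuration: " + "; ".join(problems))
    validate_config(cfg)
    return cfg


def dump_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)


def config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def reproducibility_record(cfg: RunConfig | None = None, seeds: dict | None = None) -> dict:
    """Config hash, seeds and package versions: enough to re-run bit-identically."""
    import importlib.metadata as md

    import numpy
    import scipy
    import sklearn

    record = {
        "config_hash": config_hash(cfg) if cfg is not None else None,
        "seeds": seeds or {},
        "versions": {
            "msgcn": md.version("msgcn"),
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "scikit-learn": sklearn.__version__,
        },
    }
    return record
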