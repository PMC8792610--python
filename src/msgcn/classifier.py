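"""Model/Results front end for connectome classification.

`ConnectomeClassifier` wraps the full pipeline — connectivity
construction, optional proportional thresholding, the chosen classifier
(multi-scale GCN, single-scale GCN, or a handcrafted-statistic dense
baseline) — behind a fit interface:

    >>> ds = generate_cohort(CohortSpec(n_subjects=60, seed=3))
    >>> model = ConnectomeClassifier.from_cohort(ds, method="multiscale_gcn")
    >>> res = model.fit(reps=10, seed=3)
    >>> print(res.summary())

`fit` runs the repeated-split protocol and returns a `ProtocolResults`
object carrying per-repetition metrics, their mean ± SD, training
diagnostics, a text `summary()` and ROC plotting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError
from .evaluation import (MetricsReport, SplitScheme, TrainConfig, canonical_method,
                         make_splits, run_protocol)
from .fcn import MultiScaleSample, graphs_from_cohort

__all__ = ["ConnectomeClassifier", "ProtocolResults"]


class ConnectomeClassifier:
    """A classification method bound to a cohort of multi-scale graph samples."""

    def __init__(self, samples: list[MultiScaleSample], method: str = "multiscale_gcn",
                 alpha: dict[str, float] | None = None,
                 conv_widths: tuple[int, int] = (32, 32),
                 dropout: float | None = None,
                 train_config: TrainConfig | None = None):
        if not samples:
            raise DataError("no samples")
        self.samples = samples
        self.method = canonical_method(method)
        self.alpha = alpha
        self.conv_widths = conv_widths
        self.dropout = dropout
        self.train_config = train_config
        self.labels = np.array([s.label for s in samples], dtype=int)

    @classmethod
    def from_cohort(cls, cohort, method: str = "multiscale_gcn",
                    fcn_method: str = "pearson", lam: float = 0.1,
                    retain_fraction: float = 1.0, **kwargs) -> "ConnectomeClassifier":
        """Build the classifier straight from a cohort of time series."""
        samples = graphs_from_cohort(cohort, method=fcn_method, lam=lam,
                                     retain_fraction=retain_fraction)
        return cls(samples, method=method, **kwargs)

    def fit(self, reps: int = 100, seed: int = 0,
            splits: list[SplitScheme] | None = None) -> "ProtocolResults":
        """Run the repeated-split protocol and return its results object."""
        if splits is None:
            splits = make_splits(self.labels, reps=reps, seed=seed)
        report = run_protocol(self.samples, self.method, seed=seed, splits=splits,
                              config=self.train_config, alpha=self.alpha,
                              dropout=self.dropout, conv_widths=self.conv_widths)
        return ProtocolResults(model=self, report=report, splits=splits, seed=seed)


@dataclass
class ProtocolResults:
    """Fitted-protocol results: estimates, uncertainties and diagnostics."""

    model: ConnectomeClassifier
    report: MetricsReport
    splits: list[SplitScheme]
    seed: int

    @property
    def metrics(self) -> pd.DataFrame:
        """Mean ± SD of the five metrics over repetitions."""
        return self.report.summary_frame()

    @property
    def records(self) -> pd.DataFrame:
        """One row per repetition with raw metric values and confusion counts."""
        return self.report.records_frame()

    @property
    def accuracy(self) -> float:
        return self.report.mean("accuracy")

    def summary(self) -> str:
        df = self.metrics
        lines = [
            f"Connectome classification protocol ({self.model.method})",
            f"  subjects: {len(self.model.labels)}   repetitions: {self.report.n_reps}"
            f"   seed: {self.seed}",
            "  metric       mean      sd",
        ]
        for name, row in df.iterrows():
            lines.append(f"  {name:<10} {row['mean']:7.3f} {row['sd']:7.3f}")
        return "\n".join(lines)

    def plot_roc(self, ax=None):
        """Overlay per-repetition ROC polylines (thin) and the chance line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for fpr, tpr in self.report.roc:
            ax.plot(fpr, tpr, color="C0", alpha=0.2, lw=0.8)
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.set_title(f"ROC over {self.report.n_reps} repetitions "
                     f"({self.model.method}, AUC {self.report.mean('auc'):.3f})")
        return ax
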