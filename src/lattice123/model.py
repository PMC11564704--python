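"""Model / Results front end over the channel-wise pipeline.

:class:`Lattice123Model` binds an epoch collection (or a plain epoch
array + labels) to a pipeline configuration; :meth:`Lattice123Model.fit`
runs feature extraction, selection, classification and the two fusion
stages for every channel and returns a :class:`Lattice123Results` holding
channel-wise and overall prediction vectors, their accuracies, the metric
suite and a printable summary table.
"""

from __future__ import annotations

import time
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .classify import ChannelResult, OverallResult, make_folds, run_channel, run_overall
from .config import PipelineConfig, log_run
from .data import EpochCollection
from .metrics import MetricsReport, compute_metrics

__all__ = ["Lattice123Model", "Lattice123Results"]


class Lattice123Model:
    """Two-class EEG classifier over lattice walking-path histogram features.

    Parameters
    ----------
    epochs : (n_epochs, n_channels, n_samples) array or EpochCollection
    labels : per-epoch class labels (ignored when an EpochCollection is given)
    config : pipeline settings; defaults follow the canonical parameterization
    """

    def __init__(
        self,
        epochs: np.ndarray | EpochCollection,
        labels: Sequence | None = None,
        config: PipelineConfig | None = None,
        topology=None,
    ) -> None:
        if isinstance(epochs, EpochCollection):
            self.epochs = epochs.epochs
            self.labels = np.asarray(epochs.labels)
            self.channel_names = epochs.channel_names
        else:
            self.epochs = np.asarray(epochs, dtype=np.float64)
            if labels is None:
                raise ValueError("labels are required with a plain epoch array")
            self.labels = np.asarray(labels)
            self.channel_names = tuple(
                f"ch{i + 1:02d}" for i in range(self.epochs.shape[1])
            )
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be (n_epochs, n_channels, n_samples)")
        if self.labels.shape != (self.epochs.shape[0],):
            raise ValueError("labels must align with epochs")
        self.config = config or PipelineConfig()
        self.topology = topology

    @classmethod
    def from_collection(
        cls, collection: EpochCollection, config: PipelineConfig | None = None
    ) -> "Lattice123Model":
        return cls(collection, config=config)

    def fit(self, verbose: bool = False) -> "Lattice123Results":
        """Run the full self-organized pipeline on every channel."""
        cfg = self.config
        fold_ids = make_folds(self.labels, cfg.folds, cfg.seed)
        channel_results: list[ChannelResult] = []
        timings: dict[str, float] = {}
        t0 = time.perf_counter()
        for c in range(self.epochs.shape[1]):
            tc = time.perf_counter()
            cr = run_channel(
                self.epochs[:, c, :],
                self.labels,
                channel_id=c + 1,
                iv=cfg.iv,
                fv=cfg.fv,
                folds=cfg.folds,
                seed=cfg.seed,
                nca_max_iter=cfg.nca_max_iter,
                topology=self.topology,
                fold_ids=fold_ids,
            )
            channel_results.append(cr)
            timings[f"channel_{c + 1}"] = time.perf_counter() - tc
            if verbose:
                print(
                    f"channel {c + 1}/{self.epochs.shape[1]}: "
                    f"acc={cr.best_accuracy:.4f} ({cr.chosen_source})"
                )
        overall = run_overall(channel_results, self.labels)
        timings["total"] = time.perf_counter() - t0
        return Lattice123Results(
            model=self,
            channel_results=tuple(channel_results),
            overall=overall,
            metrics=compute_metrics(overall.best_vector.labels, self.labels),
            fold_ids=fold_ids,
            timings=timings,
        )


@dataclass(frozen=True)
class Lattice123Results:
    """Fitted pipeline outcome: per-channel and fused overall predictions."""

    model: Lattice123Model
    channel_results: tuple[ChannelResult, ...]
    overall: OverallResult
    metrics: MetricsReport
    fold_ids: np.ndarray
    timings: dict

    @property
    def overall_accuracy(self) -> float:
        return self.overall.best_accuracy

    @property
    def channel_accuracies(self) -> np.ndarray:
        return np.array([cr.best_accuracy for cr in self.channel_results])

    def channel_frame(self) -> pd.DataFrame:
        rows = [
            {
                "channel": cr.channel_id,
                "name": self.model.channel_names[cr.channel_id - 1],
                "best_accuracy": cr.best_accuracy,
                "chosen": cr.chosen_source,
                "selected_sizes": list(cr.selected_sizes),
            }
            for cr in self.channel_results
        ]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        m = self.metrics
        lines = [
            "Lattice123 self-organized classification results",
            "=" * 48,
            f"epochs: {self.model.epochs.shape[0]}   "
            f"channels: {self.model.epochs.shape[1]}   "
            f"samples/epoch: {self.model.epochs.shape[2]}",
            f"overall accuracy: {m.accuracy:.2f}%   "
            f"geometric mean: {m.geometric_mean:.2f}%",
            f"winning candidate: {self.overall.chosen_source} "
            f"of {self.overall.n_candidates}",
            f"contributing channels: {list(self.overall.contributing_channels)}",
            f"best single channel: "
            f"{float(self.channel_accuracies.max()) * 100:.2f}%",
            "",
            m.to_frame().to_string(index=False),
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "overall_accuracy": self.overall.best_accuracy,
            "overall_source": self.overall.chosen_source,
            "n_candidates": self.overall.n_candidates,
            "contributing_channels": list(self.overall.contributing_channels),
            "channel_accuracies": self.channel_accuracies.tolist(),
            "metrics": self.metrics.to_dict(),
        }

    def manifest(self, out_dir=None) -> dict:
        return log_run(self.model.config, self.to_dict(), out_dir, self.timings)
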