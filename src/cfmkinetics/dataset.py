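"""Tabular containers shared across the pipeline.

A :class:`DissociationDataset` is the per-experiment table of single-tether
dissociation times with right-censoring flags; it is what the bead tracker
emits, what the synthetic generator samples, and what the survival-curve
fitting consumes.  :class:`GroundTruth` is the generator's sidecar table used
only for validation.  Both are thin wrappers over pandas DataFrames with a
fixed column schema and CSV round-trip helpers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["DissociationDataset", "GroundTruth", "DATASET_COLUMNS", "TRUTH_COLUMNS"]

DATASET_COLUMNS = ["bead_id", "time_s", "censored", "construct", "replicate", "force_pN"]
TRUTH_COLUMNS = ["bead_id", "x_px", "y_px", "class", "true_time_s", "censored"]


@dataclass
class DissociationDataset:
    """Dissociation times of one constant-force experiment.

    Attributes
    ----------
    data : pandas.DataFrame
        Columns ``bead_id, time_s, censored, construct, replicate, force_pN``.
        ``censored`` is 0/1; censored rows carry the censoring time (the
        experiment end) in ``time_s``.
    frame_interval : float or None
        Seconds between saved frames; set when times live on a frame grid.
    duration : float or None
        Experiment end time in seconds (the right-censoring horizon).
    """

    data: pd.DataFrame
    frame_interval: float | None = None
    duration: float | None = None

    def __post_init__(self) -> None:
        missing = [c for c in DATASET_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"dataset missing columns {missing}")
        self.data = self.data.reset_index(drop=True)

    # -- basic views ------------------------------------------------------
    @property
    def n_total(self) -> int:
        return len(self.data)

    @property
    def n_censored(self) -> int:
        return int(self.data["censored"].sum())

    @property
    def n_events(self) -> int:
        return self.n_total - self.n_censored

    @property
    def event_times(self) -> np.ndarray:
        """Sorted dissociation-event times (censored rows excluded)."""
        t = self.data.loc[self.data["censored"] == 0, "time_s"].to_numpy(float)
        return np.sort(t)

    @property
    def censoring_times(self) -> np.ndarray:
        return self.data.loc[self.data["censored"] == 1, "time_s"].to_numpy(float)

    def end_time(self) -> float:
        """Censoring horizon: explicit duration, else the latest time seen."""
        if self.duration is not None:
            return float(self.duration)
        return float(self.data["time_s"].max())

    # -- I/O --------------------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        frame_interval: float | None = None,
        duration: float | None = None,
    ) -> "DissociationDataset":
        return cls(pd.read_csv(path), frame_interval=frame_interval, duration=duration)


@dataclass
class GroundTruth:
    """Generator sidecar: one record per rendered or sampled bead.

    Columns: ``bead_id, x_px, y_px, class, true_time_s, censored`` with
    ``class`` in {normal, stuck, slow}.  Position columns are NaN for
    datasets that were sampled without rendering a movie.
    """

    data: pd.DataFrame
    frame_interval: float | None = None

    def __post_init__(self) -> None:
        missing = [c for c in TRUTH_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"ground truth missing columns {missing}")
        self.data = self.data.reset_index(drop=True)

    def dissociation_frame(self, frame_interval: float | None = None) -> pd.Series:
        """First saved-frame index at which each bead is absent.

        A bead drawn to dissociate at true time t is rendered in every frame
        acquired strictly before t, so it first disappears at frame
        ceil(t / frame_interval).  Censored beads get -1.
        """
        dt = frame_interval if frame_interval is not None else self.frame_interval
        if dt is None:
            raise ValueError("frame_interval required")
        f = np.ceil(self.data["true_time_s"].to_numpy(float) / dt).astype(int)
        f[self.data["censored"].to_numpy(int) == 1] = -1
        return pd.Series(f, index=self.data.index, name="dissociation_frame")

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, frame_interval: float | None = None) -> "GroundTruth":
        return cls(pd.read_csv(path), frame_interval=frame_interval)
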