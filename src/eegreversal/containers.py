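"""In-memory containers for epoched EEG and single-trial decoder output.

The two central objects are :class:`EpochSet` — a trials × channels ×
timepoints voltage cube with a millisecond time axis, a 2-D channel layout
and a per-trial metadata table — and :class:`DValueSeries`, the per-trial,
per-timepoint signed classifier confidence produced by the decoding stage.

Both persist as a NumPy ``.npz`` array store plus a JSON metadata sidecar;
trial metadata is additionally exportable as TSV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

#: canonical per-trial metadata columns
TRIAL_COLUMNS = (
    "participant_id",
    "perceptual_label",
    "semantic_label",
    "rt_ms",
    "correct",
    "lock",
)

PERCEPTUAL_LEVELS = ("photograph", "drawing")
SEMANTIC_LEVELS = ("animate", "inanimate")
LOCK_LEVELS = ("stimulus_onset", "button_press")


class ContainerError(ValueError):
    """Raised for structurally invalid epoch or d-value containers."""


@dataclass
class EpochSet:
    """Epoched multichannel EEG with per-trial metadata.

    Parameters
    ----------
    data:
        Voltages in µV, shaped ``(n_trials, n_channels, n_times)``.
    times:
        Time axis in ms relative to the lock event (stimulus onset or
        button press), strictly increasing and uniformly spaced.
    channel_labels:
        One identifier per channel.
    channel_positions:
        2-D layout coordinates, shape ``(n_channels, 2)``; used for
        spatial-neighbourhood computation in the ERP cluster stage.
    trials:
        Per-trial metadata table with at least the :data:`TRIAL_COLUMNS`.
    """

    data: np.ndarray
    times: np.ndarray
    channel_labels: list
    channel_positions: np.ndarray
    trials: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.channel_positions = np.asarray(self.channel_positions, dtype=float)
        self.channel_labels = list(self.channel_labels)
        self.validate()

    # -- structural checks -------------------------------------------------
    def validate(self) -> None:
        if self.data.ndim != 3:
            raise ContainerError(
                f"data must be (trials, channels, times), got shape {self.data.shape}"
            )
        n_trials, n_channels, n_times = self.data.shape
        if self.times.shape != (n_times,):
            raise ContainerError("times length does not match data")
        if len(self.channel_labels) != n_channels:
            raise ContainerError("channel_labels length does not match data")
        if self.channel_positions.shape != (n_channels, 2):
            raise ContainerError("channel_positions must be (n_channels, 2)")
        if len(self.trials) != n_trials:
            raise ContainerError("trials table length does not match data")
        if not np.all(np.isfinite(self.data)):
            raise ContainerError("data contains non-finite values")
        if n_times > 1:
            steps = np.diff(self.times)
            if np.any(steps <= 0):
                raise ContainerError("times must be strictly increasing")
            if not np.allclose(steps, steps[0], rtol=1e-9):
                raise ContainerError("times must be uniformly spaced")
        missing = [c for c in ("participant_id",) if c not in self.trials.columns]
        if missing:
            raise ContainerError(f"trials table missing columns: {missing}")

    # -- basic properties --------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    @property
    def sample_rate(self) -> float:
        """Sampling rate in Hz inferred from the (uniform) time axis."""
        if self.n_times < 2:
            raise ContainerError("cannot infer sample rate from a single timepoint")
        return 1000.0 / float(self.times[1] - self.times[0])

    @property
    def participants(self) -> list:
        return sorted(self.trials["participant_id"].unique().tolist())

    # -- derived views -----------------------------------------------------
    def with_data(self, data: np.ndarray) -> "EpochSet":
        """Copy of this set with the voltage cube replaced (same metadata)."""
        return EpochSet(
            data=data,
            times=self.times,
            channel_labels=self.channel_labels,
            channel_positions=self.channel_positions,
            trials=self.trials,
        )

    def select_trials(self, index) -> "EpochSet":
        """Subset of trials by boolean mask or integer index array."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return EpochSet(
            data=self.data[index],
            times=self.times,
            channel_labels=self.channel_labels,
            channel_positions=self.channel_positions,
            trials=self.trials.iloc[index].reset_index(drop=True),
        )

    def time_indices(self, window_ms) -> np.ndarray:
        """Integer indices of timepoints falling inside ``[start, end]`` ms."""
        start, end = window_ms
        if start > end:
            raise ContainerError(f"empty time window {window_ms}")
        mask = (self.times >= start) & (self.times <= end)
        if not mask.any():
            raise ContainerError(
                f"window {window_ms} ms lies outside the epoch extent "
                f"[{self.times[0]}, {self.times[-1]}] ms"
            )
        return np.flatnonzero(mask)

    def per_participant(self):
        """Iterate ``(participant_id, EpochSet)`` in sorted participant order."""
        for pid in self.participants:
            yield pid, self.select_trials(
                (self.trials["participant_id"] == pid).to_numpy()
            )

    # -- persistence -------------------------------------------------------
    def save(self, path) -> None:
        """Write as ``<path>.npz`` + ``<path>.json`` + ``<path>.trials.tsv``."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        np.savez_compressed(
            path.with_suffix(".npz"),
            data=self.data,
            times=self.times,
            channel_positions=self.channel_positions,
        )
        meta = {
            "kind": "EpochSet",
            "channel_labels": self.channel_labels,
            "shape": list(self.data.shape),
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
        self.trials.to_csv(path.with_suffix(".trials.tsv"), sep="\t", index=False)

    @classmethod
    def load(cls, path) -> "EpochSet":
        path = Path(path)
        arrays = np.load(path.with_suffix(".npz"))
        meta = json.loads(path.with_suffix(".json").read_text())
        trials = pd.read_csv(path.with_suffix(".trials.tsv"), sep="\t")
        return cls(
            data=arrays["data"],
            times=arrays["times"],
            channel_labels=meta["channel_labels"],
            channel_positions=arrays["channel_positions"],
            trials=trials,
        )


@dataclass
class DValueSeries:
    """Per-trial, per-timepoint signed classifier confidence.

    ``values[i, t]`` is the geometric distance of trial *i*'s channel
    vector at timepoint *t* from the LDA separating hyperplane (positive on
    the positive-class side). After :func:`eegreversal.decoding.align_signs`
    the ``aligned`` flag is set and a positive value always means the trial
    was classified on its correct side.
    """

    values: np.ndarray
    times: np.ndarray
    trials: pd.DataFrame = field(repr=False)
    classifier_kind: str
    aligned: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.values.ndim != 2:
            raise ContainerError("values must be (trials, times)")
        if self.values.shape[1] != self.times.shape[0]:
            raise ContainerError("times length does not match values")
        if self.values.shape[0] != len(self.trials):
            raise ContainerError("trials table length does not match values")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    def with_values(self, values: np.ndarray, aligned: bool | None = None) -> "DValueSeries":
        return replace(
            self,
            values=values,
            aligned=self.aligned if aligned is None else aligned,
        )

    def time_indices(self, window_ms) -> np.ndarray:
        start, end = window_ms
        mask = (self.times >= start) & (self.times <= end)
        if not mask.any():
            raise ContainerError(f"window {window_ms} outside d-value extent")
        return np.flatnonzero(mask)

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format (trial, time_ms, d) table for export."""
        n_trials, n_times = self.values.shape
        return pd.DataFrame(
            {
                "trial": np.repeat(np.arange(n_trials), n_times),
                "participant_id": np.repeat(
                    self.trials["participant_id"].to_numpy(), n_times
                ),
                "time_ms": np.tile(self.times, n_trials),
                "d": self.values.ravel(),
            }
        )

    def save(self, path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        np.savez_compressed(path.with_suffix(".npz"), values=self.values, times=self.times)
        meta = {
            "kind": "DValueSeries",
            "classifier_kind": self.classifier_kind,
            "aligned": bool(self.aligned),
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
        self.trials.to_csv(path.with_suffix(".trials.tsv"), sep="\t", index=False)

    @classmethod
    def load(cls, path) -> "DValueSeries":
        path = Path(path)
        arrays = np.load(path.with_suffix(".npz"))
        meta = json.loads(path.with_suffix(".json").read_text())
        trials = pd.read_csv(path.with_suffix(".trials.tsv"), sep="\t")
        return cls(
            values=arrays["values"],
            times=arrays["times"],
            trials=trials,
            classifier_kind=meta["classifier_kind"],
            aligned=meta["aligned"],
        )


def label_vector(trials: pd.DataFrame, label_dim: str) -> np.ndarray:
    """Binary label vector (0/1) for a trial table along one factor.

    ``label_dim='perceptual'`` maps photograph→0, drawing→1;
    ``label_dim='semantic'`` maps animate→0, inanimate→1.
    """
    if label_dim == "perceptual":
        col, levels = "perceptual_label", PERCEPTUAL_LEVELS
    elif label_dim == "semantic":
        col, levels = "semantic_label", SEMANTIC_LEVELS
    else:
        raise ValueError(f"unknown label dimension {label_dim!r}")
    values = trials[col].to_numpy()
    unknown = set(values) - set(levels)
    if unknown:
        raise ContainerError(f"unknown {label_dim} labels: {sorted(unknown)}")
    return (values == levels[1]).astype(int)
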