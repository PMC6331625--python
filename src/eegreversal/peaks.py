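"""Single-trial peak latencies and within-trial perceptual−semantic differences.

For every trial the moment of maximal classifier fidelity is the time of
the maximum *positive* aligned d value inside the selection window
(encoding: 0–500 ms post-stimulus; retrieval: the 3 s before the button
press). Peaks must exceed the 95th-percentile chance threshold — strictly —
to enter further analysis; trials whose peak fails for either classifier
are dropped from the paired comparison. The paired quantity is

    delta_ms = perceptual peak time − semantic peak time,

negative when the perceptual representation peaked first (the expected
encoding pattern) and positive when the semantic one did (the expected
retrieval pattern). Because the difference is formed within a trial, it is
invariant to trial-to-trial shifts of overall processing latency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ContainerError, DValueSeries, EpochSet

logger = logging.getLogger(__name__)

def _trial_ids(trials: pd.DataFrame) -> np.ndarray:
    """Stable per-trial identifiers; falls back to positional indices.

    Stable IDs matter because the two classifiers may be undersampled to
    different trial subsets — pairing must refer to the source trial, not
    to a position within a subset.
    """
    if "trial_id" in trials.columns:
        return trials["trial_id"].to_numpy()
    return np.arange(len(trials))


PEAK_COLUMNS = (
    "trial_id",
    "participant_id",
    "classifier_kind",
    "peak_time_ms",
    "peak_d",
    "present",
    "passed_threshold",
)


@dataclass
class PeakRecord:
    trial_id: int
    participant_id: str
    classifier_kind: str
    peak_time_ms: float
    peak_d: float
    present: bool = True
    passed_threshold: bool = False


def find_peak(dvals: DValueSeries, trial: int, window: tuple) -> PeakRecord:
    """Latency and height of one trial's maximum positive d value.

    Ties are broken toward the earliest time. If no positive d value
    exists in the window the record is returned with ``present=False``.
    """
    if not dvals.aligned:
        raise ContainerError("peak extraction requires sign-aligned d values")
    idx = dvals.time_indices(window)
    series = dvals.values[trial, idx]
    j = int(np.argmax(series))  # argmax returns the first (earliest) maximum
    pid = dvals.trials["participant_id"].iloc[trial]
    tid = _trial_ids(dvals.trials)[trial]
    if series[j] <= 0:
        return PeakRecord(tid, pid, dvals.classifier_kind, np.nan, np.nan, present=False)
    return PeakRecord(
        tid, pid, dvals.classifier_kind, float(dvals.times[idx[j]]), float(series[j])
    )


def find_peaks_table(dvals: DValueSeries, window: tuple) -> pd.DataFrame:
    """Vectorized :func:`find_peak` over all trials; one row per trial."""
    if not dvals.aligned:
        raise ContainerError("peak extraction requires sign-aligned d values")
    idx = dvals.time_indices(window)
    block = dvals.values[:, idx]
    j = np.argmax(block, axis=1)
    heights = block[np.arange(block.shape[0]), j]
    present = heights > 0
    return pd.DataFrame(
        {
            "trial_id": _trial_ids(dvals.trials),
            "participant_id": dvals.trials["participant_id"].to_numpy(),
            "classifier_kind": dvals.classifier_kind,
            "peak_time_ms": np.where(present, dvals.times[idx[j]], np.nan),
            "peak_d": np.where(present, heights, np.nan),
            "present": present,
            "passed_threshold": False,
        }
    )


def filter_retrieval_trials(epochs: EpochSet, min_rt_ms: float = 3000.0) -> EpochSet:
    """Keep only trials with reaction time ≥ ``min_rt_ms`` (boundary included).

    The retrieval peak-selection window covers the 3 s before the button
    press, so trials answered faster than that would mix pre-cue signal
    into the analysed window. The number of removed trials is logged.
    """
    rt = epochs.trials["rt_ms"].to_numpy(dtype=float)
    keep = rt >= min_rt_ms
    n_removed = int((~keep).sum())
    logger.info(
        "RT filter (>= %.0f ms): removed %d of %d trials", min_rt_ms, n_removed, len(rt)
    )
    if not keep.any():
        logger.warning("RT filter removed every trial")
    return epochs.select_trials(keep)


def apply_threshold(peaks: pd.DataFrame, d_star: float) -> pd.DataFrame:
    """Flag peaks strictly exceeding the chance threshold.

    ``passed_threshold`` is true iff the peak exists and ``peak_d > d_star``
    (a peak exactly at the threshold does not pass).
    """
    if not np.isfinite(d_star) and d_star > 0:
        raise ValueError("threshold must be finite or -inf")
    out = peaks.copy()
    out["passed_threshold"] = out["present"] & (out["peak_d"] > d_star)
    return out


def pair_differences(
    perceptual_peaks: pd.DataFrame, semantic_peaks: pd.DataFrame
) -> pd.DataFrame:
    """Within-trial perceptual − semantic peak-latency differences.

    Only trials whose peaks are present *and* passed the threshold for
    both classifiers contribute; each output row maps to exactly one
    source trial.
    """
    merged = perceptual_peaks.merge(
        semantic_peaks,
        on=("trial_id", "participant_id"),
        suffixes=("_perc", "_sem"),
        validate="one_to_one",
    )
    ok = (
        merged["present_perc"]
        & merged["present_sem"]
        & merged["passed_threshold_perc"]
        & merged["passed_threshold_sem"]
    )
    kept = merged[ok]
    return pd.DataFrame(
        {
            "trial_id": kept["trial_id"].to_numpy(),
            "participant_id": kept["participant_id"].to_numpy(),
            "delta_ms": (kept["peak_time_ms_perc"] - kept["peak_time_ms_sem"]).to_numpy(),
        }
    )
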