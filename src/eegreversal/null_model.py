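"""Empirical chance distribution of d values and peak-acceptance thresholds.

The classifier's true chance level is estimated empirically rather than
assumed: the full decoding procedure (including leave-one-out
cross-validation) is repeated per participant with randomly shuffled
labels, under the constraint that each pseudo-class stays close to
balanced in both true factors (difference in trial numbers below 8% of the
pseudo-class size). A bootstrap then draws, per participant, one of the
``n_runs + 1`` available classification outputs — the shuffled runs *plus
the real one*, which makes the null conservative — and records the group
average d value per timepoint. The 95th percentile of that distribution is
the threshold below which single-trial peaks are discarded as noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import DValueSeries, EpochSet, label_vector
from .decoding import LoocvEngine, align_signs, loocv_dvalues


class NullModelError(ValueError):
    pass


BALANCE_TOLERANCE = 0.08  # max within-pseudo-class count imbalance per factor


@dataclass
class ParticipantNull:
    """Compressed shuffled-label outputs for one participant.

    ``mean_curves[r]`` is run *r*'s trial-average aligned d per timepoint;
    ``trial_peaks[r]`` the per-trial maximum aligned d over the analysed
    window. Both are what the two thresholding modes consume downstream.
    """

    participant_id: str
    mean_curves: np.ndarray  # (n_runs, T)
    trial_peaks: np.ndarray  # (n_runs, n_trials)
    times: np.ndarray


@dataclass
class NullDistribution:
    """Empirical chance distribution of d values.

    ``mode='group_average'``: ``samples`` is (n_bootstrap, T) of bootstrap
    group-average curves. ``mode='single_trial_pool'``: ``samples`` is a
    flat pool of per-trial peak d values from the shuffled runs.
    """

    samples: np.ndarray
    mode: str
    n_shuffles_per_participant: int
    n_bootstrap: int
    times: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.samples.size == 0:
            raise NullModelError("null distribution has no samples")
        if self.n_bootstrap < 1:
            raise NullModelError("n_bootstrap must be >= 1")


def balanced_random_split(trials: pd.DataFrame, seed, max_tries: int = 10000) -> np.ndarray:
    """Random binary pseudo-labels, balanced in both true factors.

    Trials are randomly divided into two pseudo-classes of (near-)equal
    size such that each true category (photograph, drawing, animate,
    inanimate) is split about evenly between the two pseudo-classes: the
    difference in trial numbers per category is below 8% of that
    category's count (with a floor of one trial, the unavoidable remainder
    of an odd count). This keeps both pseudo-classes representative of the
    true label composition even when the parent set is itself imbalanced.
    """
    n = len(trials)
    if n < 4:
        raise NullModelError("balanced split needs at least 4 trials")
    perc = label_vector(trials, "perceptual")
    sem = label_vector(trials, "semantic")
    rng = np.random.default_rng(seed)
    half = n // 2
    for _ in range(max_tries):
        order = rng.permutation(n)
        pseudo = np.zeros(n, dtype=int)
        pseudo[order[half:]] = 1
        ok = True
        for factor in (perc, sem):
            for level in (0, 1):
                members = factor == level
                n_level = int(members.sum())
                diff = abs(
                    int(np.sum(members & (pseudo == 0)))
                    - int(np.sum(members & (pseudo == 1)))
                )
                if diff >= max(BALANCE_TOLERANCE * n_level, 1.0 + 1e-9):
                    ok = False
                    break
            if not ok:
                break
        if ok:
            return pseudo
    raise NullModelError(
        f"no balanced pseudo-split found in {max_tries} tries for {n} trials"
    )


def shuffled_label_run(
    epochs: EpochSet,
    time_window: tuple,
    seed,
    stride: int = 1,
    lam: float | None = None,
    engine: LoocvEngine | None = None,
) -> DValueSeries:
    """One decoding run under a balanced random relabelling.

    Identical procedure to the real analysis (including leave-one-out);
    output is sign-aligned to the pseudo-labels. An existing
    :class:`LoocvEngine` on the same epochs may be passed to reuse its
    label-independent precomputation.
    """
    pseudo = balanced_random_split(epochs.trials, seed)
    if engine is None:
        engine = LoocvEngine(epochs, time_window, stride=stride)
    values = engine.run(pseudo, lam=lam)
    series = DValueSeries(
        values=values,
        times=engine.times,
        trials=epochs.trials,
        classifier_kind="pseudo",
        aligned=False,
    )
    return align_signs(series, pseudo)


def build_participant_nulls(
    participant_epochs: dict,
    time_window: tuple,
    n_runs: int = 150,
    seed=0,
    stride: int = 1,
    lam: float | None = None,
    peak_window: tuple | None = None,
) -> dict:
    """``n_runs`` shuffled-label outputs per participant.

    Returns ``{participant_id: ParticipantNull}``. Together with the one
    real-label run this makes ``n_runs + 1`` classification outputs per
    participant available to the bootstrap.
    """
    if n_runs < 1:
        raise NullModelError("n_runs must be >= 1")
    root = np.random.SeedSequence([_as_entropy(seed), 7])
    out = {}
    pids = sorted(participant_epochs)
    streams = root.spawn(len(pids))
    for pid, stream in zip(pids, streams):
        epochs = participant_epochs[pid]
        engine = LoocvEngine(epochs, time_window, stride=stride)
        if peak_window is None:
            peak_idx = slice(None)
        else:
            peak_idx = np.flatnonzero(
                (engine.times >= peak_window[0]) & (engine.times <= peak_window[1])
            )
        curves = np.empty((n_runs, engine.times.shape[0]))
        peaks = np.empty((n_runs, epochs.n_trials))
        run_seeds = stream.spawn(n_runs)
        for r, run_seed in enumerate(run_seeds):
            series = shuffled_label_run(
                epochs, time_window, run_seed, stride=stride, lam=lam, engine=engine
            )
            curves[r] = series.values.mean(axis=0)
            peaks[r] = series.values[:, peak_idx].max(axis=1)
        out[pid] = ParticipantNull(
            participant_id=pid,
            mean_curves=curves,
            trial_peaks=peaks,
            times=engine.times,
        )
    return out


def bootstrap_group_null(
    participant_nulls: dict,
    real_runs: dict,
    n_boot: int = 10000,
    seed=0,
    mode: str = "group_average",
) -> NullDistribution:
    """Bootstrap the chance distribution from shuffled + real outputs.

    ``mode='group_average'`` (the literal procedure): each draw selects,
    per participant, one of that participant's ``n_runs + 1`` outputs (the
    real run included) uniformly at random and records the group-average
    trial-mean d per timepoint. ``mode='single_trial_pool'`` instead pools
    the shuffled runs' single-trial peak d values across runs and
    participants, matching the variance of the quantity being thresholded.
    """
    pids = sorted(participant_nulls)
    missing = [p for p in pids if p not in real_runs]
    if missing:
        raise NullModelError(f"missing real-label runs for participants {missing}")
    first = participant_nulls[pids[0]]
    n_runs = first.mean_curves.shape[0]

    if mode == "single_trial_pool":
        pool = np.concatenate(
            [participant_nulls[p].trial_peaks.ravel() for p in pids]
        )
        return NullDistribution(
            samples=pool,
            mode=mode,
            n_shuffles_per_participant=n_runs,
            n_bootstrap=max(int(n_boot), 1),
        )
    if mode != "group_average":
        raise NullModelError(f"unknown null mode {mode!r}")

    rng = np.random.default_rng(_as_entropy(seed))
    n_times = first.mean_curves.shape[1]
    total = np.zeros((n_boot, n_times))
    for pid in pids:
        null = participant_nulls[pid]
        real = real_runs[pid]
        if not real.aligned:
            raise NullModelError(f"real run for {pid} must be sign-aligned")
        stack = np.vstack([null.mean_curves, real.values.mean(axis=0)[None, :]])
        choice = rng.integers(0, stack.shape[0], size=n_boot)
        total += stack[choice]
    return NullDistribution(
        samples=total / len(pids),
        mode=mode,
        n_shuffles_per_participant=n_runs,
        n_bootstrap=int(n_boot),
        times=first.times,
    )


def percentile_threshold(
    null: NullDistribution, q: float = 95.0, per_timepoint: bool = False
):
    """q-th percentile of the null (linear interpolation between order stats).

    For a group-average null the default is the *window-maximum*
    convention: one scalar threshold, the maximum over timepoints of the
    per-timepoint percentile. ``per_timepoint=True`` returns the full
    per-timepoint threshold curve instead.
    """
    if not 0.0 < q < 100.0:
        raise NullModelError(f"percentile q={q} outside (0, 100)")
    if null.samples.ndim == 1:
        return float(np.percentile(null.samples, q, method="linear"))
    per_tp = np.percentile(null.samples, q, axis=0, method="linear")
    if per_timepoint:
        return per_tp
    return float(per_tp.max())


def real_label_run(
    epochs: EpochSet,
    label_dim: str,
    time_window: tuple,
    stride: int = 1,
    lam: float | None = None,
    engine: LoocvEngine | None = None,
) -> DValueSeries:
    """Aligned real-label decoding run (convenience for the null pipeline)."""
    y = label_vector(epochs.trials, label_dim)
    if engine is None:
        series = loocv_dvalues(
            epochs, label_dim, time_window, stride=stride, lam=lam
        )
    else:
        series = DValueSeries(
            values=engine.run(y, lam=lam),
            times=engine.times,
            trials=epochs.trials,
            classifier_kind=label_dim,
            aligned=False,
        )
    return align_signs(series, y)


def _as_entropy(seed) -> int:
    if isinstance(seed, (int, np.integer)):
        return int(seed)
    return int(np.random.default_rng(seed).integers(0, 2**31))
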