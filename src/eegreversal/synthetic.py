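"""Synthetic EEG epochs and behavioural trial tables with known ground truth.

The generators emulate the statistical structure that the decoding and
inference stages assume:

* multichannel noise epochs (white or a 50/50 pink+white mix) with two
  crossed binary label factors — a *perceptual* factor (photograph vs.
  line drawing) and a *semantic* factor (animate vs. inanimate);
* a transient spatially fixed discriminative component per factor, planted
  as an additive ±½·SNR · pattern deflection inside a temporal Gaussian
  window, with the perceptual component preceding the semantic one in
  stimulus-locked (encoding) epochs and the reverse order in
  button-press-locked (retrieval) epochs;
* gamma-distributed reaction times with a task × question crossover
  interaction and participant-level random intercepts.

Ground-truth parameters (spatial patterns, per-trial jittered component
centres) are returned alongside the epochs so that every downstream stage
can be validated by parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import EpochSet

# deterministic sub-stream tags so that encoding / retrieval / behaviour
# calls with the same seed draw from disjoint streams
_STREAM_ENCODING = 1
_STREAM_RETRIEVAL = 2
_STREAM_BEHAVIOR = 3

TASKS = ("visual", "memory")
QUESTIONS = ("perceptual", "semantic")


def gamma_from_mean_sd(mean: float, sd: float) -> tuple:
    """Gamma (shape, scale) matching a target mean and standard deviation."""
    if mean <= 0 or sd <= 0:
        raise ValueError("gamma mean and sd must be positive")
    shape = (mean / sd) ** 2
    return shape, mean / shape


#: default per-cell RT gamma parameters, matched to the reported group
#: descriptives of the behavioural design this generator emulates
DEFAULT_RT_CELLS = {
    ("visual", "perceptual"): gamma_from_mean_sd(795.0, 235.0),
    ("visual", "semantic"): gamma_from_mean_sd(842.0, 185.0),
    ("memory", "perceptual"): gamma_from_mean_sd(2502.0, 561.0),
    ("memory", "semantic"): gamma_from_mean_sd(2334.0, 534.0),
}

DEFAULT_ACCURACY = {
    ("visual", "perceptual"): 0.974,
    ("visual", "semantic"): 0.963,
    ("memory", "perceptual"): 0.826,
    ("memory", "semantic"): 0.858,
}


@dataclass
class SyntheticConfig:
    """Parameters of one synthetic generation call.

    ``component_width_ms`` is the standard deviation of the temporal
    Gaussian envelope of the planted components. ``component_snr`` is the
    peak pattern amplitude relative to the (unit) per-channel noise SD.
    """

    n_participants: int = 20
    n_trials_per_participant: int = 96
    n_channels: int = 32
    sample_rate: float = 256.0
    epoch_window: tuple = (-500.0, 1000.0)
    perceptual_latency_ms: float = 150.0
    semantic_latency_ms: float = 300.0
    component_width_ms: float = 50.0
    component_snr: float = 1.0
    latency_jitter_sd_ms: float = 50.0
    noise_model: str = "pink_white"  # 'white' or 'pink_white'
    pink_exponent: float = 1.0
    rt_distribution: dict = field(default_factory=lambda: dict(DEFAULT_RT_CELLS))
    accuracy_prob: dict = field(default_factory=lambda: dict(DEFAULT_ACCURACY))
    rt_participant_sd_ms: float = 150.0
    accuracy_participant_sd: float = 0.5
    retrieval_rt_gamma: tuple = gamma_from_mean_sd(3046.0, 830.0)
    seed: int = 0

    @classmethod
    def encoding_defaults(cls, **overrides) -> "SyntheticConfig":
        """Stimulus-locked defaults: perceptual 150 ms before semantic 300 ms."""
        return cls(**overrides)

    @classmethod
    def retrieval_defaults(cls, **overrides) -> "SyntheticConfig":
        """Button-press-locked defaults: semantic −1800 ms before perceptual −1600 ms.

        Retrieval components are broader and carry more trial-to-trial
        latency jitter than encoding ones, reflecting the variable timing
        of memory reinstatement relative to the response.
        """
        params = dict(
            epoch_window=(-3200.0, 100.0),
            perceptual_latency_ms=-1600.0,
            semantic_latency_ms=-1800.0,
            component_width_ms=100.0,
            latency_jitter_sd_ms=200.0,
        )
        params.update(overrides)
        return cls(**params)

    def validate(self) -> None:
        if min(self.n_participants, self.n_trials_per_participant, self.n_channels) < 1:
            raise ValueError("participant, trial and channel counts must be >= 1")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        start, end = self.epoch_window
        if not start < end:
            raise ValueError("epoch_window start must precede end")
        for name in ("perceptual_latency_ms", "semantic_latency_ms"):
            lat = getattr(self, name)
            if not (start <= lat <= end):
                raise ValueError(
                    f"{name}={lat} ms lies outside epoch_window {self.epoch_window}"
                )
            margin = 2.0 * self.component_width_ms
            if lat - margin < start or lat + margin > end:
                raise ValueError(
                    f"component at {name}={lat} ms (±{margin} ms support) extends "
                    f"beyond epoch_window {self.epoch_window}"
                )
        if self.component_width_ms <= 0:
            raise ValueError("component_width_ms must be positive")
        if self.component_snr < 0:
            raise ValueError("component_snr must be non-negative")
        if self.latency_jitter_sd_ms < 0:
            raise ValueError("latency_jitter_sd_ms must be non-negative")
        if self.noise_model not in ("white", "pink_white"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")
        for cell, (shape, scale) in self.rt_distribution.items():
            if shape <= 0 or scale <= 0:
                raise ValueError(f"non-positive gamma parameters for cell {cell}")
        for cell, p in self.accuracy_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"accuracy_prob for cell {cell} outside [0, 1]")
        if any(v <= 0 for v in self.retrieval_rt_gamma):
            raise ValueError("non-positive gamma parameters for retrieval RTs")

    # -- config file plumbing ---------------------------------------------
    @classmethod
    def from_dict(cls, payload: dict) -> "SyntheticConfig":
        payload = dict(payload)
        if "epoch_window" in payload:
            payload["epoch_window"] = tuple(payload["epoch_window"])
        if "retrieval_rt_gamma" in payload:
            payload["retrieval_rt_gamma"] = tuple(payload["retrieval_rt_gamma"])
        for key in ("rt_distribution", "accuracy_prob"):
            if key in payload:
                converted = {}
                for cell, v in payload[key].items():
                    if isinstance(cell, str):
                        cell = tuple(cell.split("/"))
                    converted[tuple(cell)] = (
                        tuple(v) if isinstance(v, (list, tuple)) else v
                    )
                payload[key] = converted
        return cls(**payload)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class GroundTruth:
    """Planted parameters recorded for parameter-recovery tests."""

    pattern_perceptual: np.ndarray
    pattern_semantic: np.ndarray
    #: per-trial jittered component centres (columns perceptual_ms, semantic_ms)
    centers: pd.DataFrame


def channel_layout(n_channels: int) -> tuple:
    """Deterministic 2-D sensor layout on a unit disc (sunflower spiral)."""
    idx = np.arange(n_channels)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    radius = np.sqrt((idx + 0.5) / n_channels)
    theta = idx * golden
    positions = np.column_stack([radius * np.cos(theta), radius * np.sin(theta)])
    labels = [f"CH{i + 1:03d}" for i in idx]
    return labels, positions


def _crossed_labels(n_trials: int, rng: np.random.Generator) -> tuple:
    """Crossed, balanced perceptual × semantic labels in shuffled order."""
    cells = [
        ("photograph", "animate"),
        ("photograph", "inanimate"),
        ("drawing", "animate"),
        ("drawing", "inanimate"),
    ]
    reps = [n_trials // 4 + (1 if i < n_trials % 4 else 0) for i in range(4)]
    rows = [cell for cell, r in zip(cells, reps) for _ in range(r)]
    order = rng.permutation(n_trials)
    perc = np.array([rows[i][0] for i in order])
    sem = np.array([rows[i][1] for i in order])
    return perc, sem


def _pink_filter(n_times: int, sample_rate: float, exponent: float) -> np.ndarray:
    """rfft amplitude response with power ∝ 1/f^exponent, unit output variance."""
    freqs = np.fft.rfftfreq(n_times, d=1.0 / sample_rate)
    h = np.zeros_like(freqs)
    h[1:] = freqs[1:] ** (-exponent / 2.0)
    # unit-variance normalization over the full (Hermitian) spectrum
    weights = np.full_like(h, 2.0)
    weights[0] = 1.0
    if n_times % 2 == 0:
        weights[-1] = 1.0
    h /= np.sqrt(np.sum(weights * h**2) / n_times)
    return h


def _noise(rng: np.random.Generator, shape: tuple, config: SyntheticConfig) -> np.ndarray:
    """Stationary unit-variance noise cube (trials, channels, times)."""
    white = rng.standard_normal(shape)
    if config.noise_model == "white":
        return white
    n_times = shape[-1]
    h = _pink_filter(n_times, config.sample_rate, config.pink_exponent)
    pink_src = rng.standard_normal(shape)
    pink = np.fft.irfft(np.fft.rfft(pink_src, axis=-1) * h, n=n_times, axis=-1)
    # 50/50 variance mix keeps overall per-channel variance at 1
    return np.sqrt(0.5) * white + np.sqrt(0.5) * pink


def _orthonormal_patterns(n_channels: int, rng: np.random.Generator) -> tuple:
    """Two unit-norm, mutually orthogonal spatial patterns."""
    p_perc = rng.standard_normal(n_channels)
    p_perc /= np.linalg.norm(p_perc)
    p_sem = rng.standard_normal(n_channels)
    p_sem -= p_perc * (p_perc @ p_sem)
    p_sem /= np.linalg.norm(p_sem)
    return p_perc, p_sem


def _generate_epochs(config: SyntheticConfig, lock: str, stream_tag: int) -> tuple:
    config.validate()
    root = np.random.SeedSequence([int(config.seed), stream_tag])
    pattern_rng = np.random.default_rng(root.spawn(1)[0])
    participant_seeds = root.spawn(config.n_participants)

    start, end = config.epoch_window
    step = 1000.0 / config.sample_rate
    n_times = int(round((end - start) / step)) + 1
    times = start + step * np.arange(n_times)
    labels, positions = channel_layout(config.n_channels)
    p_perc, p_sem = _orthonormal_patterns(config.n_channels, pattern_rng)

    data_blocks, trial_rows, center_rows = [], [], []
    rt_shape, rt_scale = config.retrieval_rt_gamma
    for p_idx, seed in enumerate(participant_seeds):
        rng = np.random.default_rng(seed)
        n = config.n_trials_per_participant
        perc, sem = _crossed_labels(n, rng)
        cube = _noise(rng, (n, config.n_channels, n_times), config)

        centers = {
            "perceptual": config.perceptual_latency_ms
            + rng.normal(0.0, config.latency_jitter_sd_ms, size=n),
            "semantic": config.semantic_latency_ms
            + rng.normal(0.0, config.latency_jitter_sd_ms, size=n),
        }
        if config.component_snr > 0:
            for kind, pattern, lab in (
                ("perceptual", p_perc, perc),
                ("semantic", p_sem, sem),
            ):
                sign = np.where(np.isin(lab, ("drawing", "inanimate")), 1.0, -1.0)
                envelope = np.exp(
                    -0.5
                    * ((times[None, :] - centers[kind][:, None]) / config.component_width_ms)
                    ** 2
                )
                # snr is the per-channel RMS deflection relative to the (unit)
                # per-channel noise SD; the unit-norm pattern is therefore
                # scaled by sqrt(n_channels), so that adding sensors raises
                # multichannel discriminability as for a fixed scalp topography
                amp = 0.5 * config.component_snr * np.sqrt(config.n_channels) * sign
                cube += amp[:, None, None] * pattern[None, :, None] * envelope[:, None, :]
        data_blocks.append(cube)

        if lock == "button_press":
            rt = rng.gamma(rt_shape, rt_scale, size=n)
        else:
            rt = np.full(n, np.nan)
        pid = f"P{p_idx + 1:02d}"
        trial_rows.append(
            pd.DataFrame(
                {
                    "trial_id": np.arange(n),
                    "participant_id": pid,
                    "perceptual_label": perc,
                    "semantic_label": sem,
                    "rt_ms": rt,
                    "correct": 1,
                    "lock": lock,
                }
            )
        )
        center_rows.append(
            pd.DataFrame(
                {
                    "participant_id": pid,
                    "perceptual_ms": centers["perceptual"],
                    "semantic_ms": centers["semantic"],
                }
            )
        )

    epochs = EpochSet(
        data=np.concatenate(data_blocks, axis=0),
        times=times,
        channel_labels=labels,
        channel_positions=positions,
        trials=pd.concat(trial_rows, ignore_index=True),
    )
    truth = GroundTruth(
        pattern_perceptual=p_perc,
        pattern_semantic=p_sem,
        centers=pd.concat(center_rows, ignore_index=True),
    )
    return epochs, truth


def generate_encoding_epochs(config: SyntheticConfig) -> tuple:
    """Stimulus-locked epochs with the perceptual component before the semantic.

    Returns ``(EpochSet, GroundTruth)``.
    """
    return _generate_epochs(config, lock="stimulus_onset", stream_tag=_STREAM_ENCODING)


def generate_retrieval_epochs(config: SyntheticConfig) -> tuple:
    """Button-press-locked epochs with the semantic component first.

    Component latencies are negative (before the press); per-trial RTs are
    drawn from ``config.retrieval_rt_gamma``. Returns
    ``(EpochSet, GroundTruth)``.
    """
    if not config.semantic_latency_ms < config.perceptual_latency_ms:
        raise ValueError(
            "retrieval epochs require the semantic latency "
            f"({config.semantic_latency_ms} ms) to precede the perceptual one "
            f"({config.perceptual_latency_ms} ms)"
        )
    return _generate_epochs(config, lock="button_press", stream_tag=_STREAM_RETRIEVAL)


def generate_behavior(config: SyntheticConfig) -> pd.DataFrame:
    """Behavioural trial table for the 2 × 2 mixed design.

    Task (visual vs. memory) is between-participants — ``n_participants``
    per task — and question type (perceptual vs. semantic) varies within
    participant. RTs are gamma per cell with a participant-level additive
    random intercept; accuracy is Bernoulli per cell with a participant
    intercept on the logit scale.
    """
    config.validate()
    root = np.random.SeedSequence([int(config.seed), _STREAM_BEHAVIOR])
    rows = []
    for t_idx, task in enumerate(TASKS):
        task_seeds = root.spawn(config.n_participants)
        for p_idx, seed in enumerate(task_seeds):
            rng = np.random.default_rng(seed)
            pid = f"{task[0]}{t_idx * config.n_participants + p_idx + 1:03d}"
            rt_shift = rng.normal(0.0, config.rt_participant_sd_ms)
            acc_shift = rng.normal(0.0, config.accuracy_participant_sd)
            n = config.n_trials_per_participant
            half = n // 2
            questions = np.array(
                ["perceptual"] * half + ["semantic"] * (n - half)
            )[rng.permutation(n)]
            for question in QUESTIONS:
                m = int(np.sum(questions == question))
                if m == 0:
                    continue
                shape, scale = config.rt_distribution[(task, question)]
                cell_mean = shape * scale
                mean_p = max(cell_mean + rt_shift, 0.05 * cell_mean)
                rt = rng.gamma(shape, mean_p / shape, size=m)
                p_cell = config.accuracy_prob[(task, question)]
                p_cell = min(max(p_cell, 1e-9), 1 - 1e-9)
                logit = np.log(p_cell / (1 - p_cell)) + acc_shift
                p_part = 1.0 / (1.0 + np.exp(-logit))
                if config.accuracy_prob[(task, question)] >= 1.0:
                    p_part = 1.0
                elif config.accuracy_prob[(task, question)] <= 0.0:
                    p_part = 0.0
                correct = (rng.random(m) < p_part).astype(int)
                rows.append(
                    pd.DataFrame(
                        {
                            "participant_id": pid,
                            "task": task,
                            "question": question,
                            "rt_ms": rt,
                            "correct": correct,
                        }
                    )
                )
    table = pd.concat(rows, ignore_index=True)
    return table.sample(frac=1.0, random_state=config.seed % (2**31)).reset_index(
        drop=True
    )
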