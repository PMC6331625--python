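"""End-to-end orchestration: simulate → preprocess → decode → null → peaks →
group statistics → ERP clusters, under one declarative configuration.

Every stochastic stage draws its seed deterministically from the single
``RunConfig.seed``, so a run is fully reproducible: identical
configuration implies identical report (wall-clock timings aside).
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import EpochSet, label_vector
from .decoding import LoocvEngine, align_signs, undersample
from .erp_cluster import (
    ChannelNeighbourhood,
    cluster_permutation,
    participant_difference_maps,
    participant_peak_times,
    windowed_retrieval_scan,
)
from .group_stats import (
    GlmmDegenerateError,
    StatsError,
    clustered_signrank,
    filter_rt_outliers,
    fit_glmm,
    rm_anova_interaction,
    standardize_for_joint_model,
)
from .null_model import (
    bootstrap_group_null,
    build_participant_nulls,
    percentile_threshold,
    real_label_run,
)
from .peaks import apply_threshold, filter_retrieval_trials, find_peaks_table, pair_differences
from .preprocess import (
    BaselineSpec,
    FilterSpec,
    baseline_correct,
    common_average_reference,
    filter_epochs,
    gaussian_smooth,
)
from .synthetic import SyntheticConfig, generate_behavior, generate_encoding_epochs, generate_retrieval_epochs

CLASSIFIERS = ("perceptual", "semantic")


@dataclass
class Finding:
    level: str  # 'error' or 'warning'
    message: str


@dataclass
class RunConfig:
    """Declarative configuration of a full pipeline run.

    Null-model defaults follow the full-scale procedure (150 shuffled runs
    per participant, 10,000 bootstrap draws); :meth:`desk_scale` switches
    to the reduced configuration (30 runs, 1,000 draws) used for
    desk-scale validation runs.
    """

    seed: int = 0
    encoding: SyntheticConfig = field(default_factory=SyntheticConfig.encoding_defaults)
    retrieval: SyntheticConfig = field(default_factory=SyntheticConfig.retrieval_defaults)
    # stage toggles
    run_behavior: bool = True
    run_erp: bool = True
    # preprocessing
    apply_filters: bool = False
    filter_spec: FilterSpec = field(default_factory=FilterSpec)
    smoothing_fwhm_ms: float = 24.0
    encoding_baseline_window: tuple = (-500.0, 0.0)
    # decoding
    encoding_decode_window: tuple = (-100.0, 500.0)
    retrieval_decode_window: tuple = (-3000.0, 0.0)
    encoding_stride: int = 2
    retrieval_stride: int = 4
    shrinkage_lambda: float | None = None  # None = analytic Ledoit–Wolf
    # empirical null
    n_null_runs: int = 150
    n_bootstrap: int = 10000
    threshold_percentile: float = 95.0
    threshold_mode: str = "group_average"
    # peak analysis
    encoding_peak_window: tuple = (0.0, 500.0)
    retrieval_peak_window: tuple = (-3000.0, 0.0)
    min_rt_ms: float = 3000.0
    # group statistics
    n_signrank_perm: int = 2000
    # ERP clusters
    erp_encoding_window: tuple = (0.0, 500.0)
    erp_retrieval_window: tuple = (-3000.0, 100.0)
    erp_sub_epoch_ms: float = 300.0
    erp_n_perm: int = 2000
    cluster_alpha: float = 0.05
    min_neighbours: int = 2

    def desk_scale(self) -> "RunConfig":
        cfg = RunConfig(**{**asdict_shallow(self)})
        cfg.n_null_runs = 30
        cfg.n_bootstrap = 1000
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(payload)

    @classmethod
    def from_dict(cls, payload: dict) -> "RunConfig":
        payload = dict(payload)
        for key in ("encoding", "retrieval"):
            if key in payload and isinstance(payload[key], dict):
                base = (
                    SyntheticConfig.encoding_defaults()
                    if key == "encoding"
                    else SyntheticConfig.retrieval_defaults()
                )
                merged = {**asdict_shallow(base), **payload[key]}
                payload[key] = SyntheticConfig.from_dict(merged)
        if "filter_spec" in payload and isinstance(payload["filter_spec"], dict):
            spec = dict(payload["filter_spec"])
            if "band_stop" in spec:
                spec["band_stop"] = tuple(spec["band_stop"])
            payload["filter_spec"] = FilterSpec(**spec)
        for key in (
            "encoding_baseline_window",
            "encoding_decode_window",
            "retrieval_decode_window",
            "encoding_peak_window",
            "retrieval_peak_window",
            "erp_encoding_window",
            "erp_retrieval_window",
        ):
            if key in payload:
                payload[key] = tuple(payload[key])
        return cls(**payload)


def asdict_shallow(obj) -> dict:
    """dataclass → dict without recursing into nested dataclasses."""
    return {k: getattr(obj, k) for k in obj.__dataclass_fields__}


def validate_config(config: RunConfig) -> list:
    """Schema and cross-field checks; returns error/warning findings."""
    findings = []

    def err(msg):
        findings.append(Finding("error", msg))

    def warn(msg):
        findings.append(Finding("warning", msg))

    if not isinstance(config.seed, (int, np.integer)):
        err("seed must be an explicit integer")
    for name, syn in (("encoding", config.encoding), ("retrieval", config.retrieval)):
        try:
            syn.validate()
        except ValueError as exc:
            err(f"{name} synthetic config invalid: {exc}")
    for name, window, epoch in (
        ("encoding_decode_window", config.encoding_decode_window, config.encoding.epoch_window),
        ("retrieval_decode_window", config.retrieval_decode_window, config.retrieval.epoch_window),
    ):
        if window[0] < epoch[0] or window[1] > epoch[1]:
            err(f"{name} {window} extends beyond the epoch window {epoch}")
    for name, peak, decode in (
        ("encoding_peak_window", config.encoding_peak_window, config.encoding_decode_window),
        ("retrieval_peak_window", config.retrieval_peak_window, config.retrieval_decode_window),
    ):
        if peak[0] < decode[0] or peak[1] > decode[1]:
            err(f"{name} {peak} extends beyond the decode window {decode}")
    if config.threshold_mode not in ("group_average", "single_trial_pool"):
        err(f"unknown threshold_mode {config.threshold_mode!r}")
    if not 0 < config.threshold_percentile < 100:
        err("threshold_percentile must lie in (0, 100)")
    if config.n_null_runs < 1 or config.n_bootstrap < 1 or config.n_signrank_perm < 1:
        err("n_null_runs, n_bootstrap and n_signrank_perm must be >= 1")
    epoch_len = config.retrieval.epoch_window[1] - config.retrieval.epoch_window[0]
    if config.min_rt_ms < -config.retrieval_peak_window[0]:
        warn(
            f"min_rt_ms {config.min_rt_ms} is below the retrieval peak window length "
            f"{-config.retrieval_peak_window[0]:.0f} ms; fast trials may contaminate peaks"
        )
    if config.min_rt_ms > epoch_len:
        warn("min_rt_ms exceeds the retrieval epoch length")
    if config.shrinkage_lambda is not None and not 0 <= config.shrinkage_lambda <= 1:
        err("shrinkage_lambda must be in [0, 1] or null for analytic selection")
    return findings


@dataclass
class PhaseOutput:
    """Decoding-side artifacts of one phase (encoding or retrieval)."""

    dvalues: dict  # classifier -> {pid: aligned DValueSeries}
    thresholds: dict  # classifier -> float
    peaks: dict  # classifier -> DataFrame
    diffs: pd.DataFrame
    n_trials_decoded: int
    n_trials_removed_rt: int
    threshold_exclusion_rate: float


@dataclass
class RunReport:
    config: dict
    version: str
    stage_seconds: dict
    results: dict

    def to_json(self) -> str:
        return json.dumps(
            {
                "version": self.version,
                "config": self.config,
                "stage_seconds": self.stage_seconds,
                "results": self.results,
            },
            indent=2,
            default=_jsonable,
        )

    def to_markdown(self) -> str:
        r = self.results
        lines = [
            "# Pipeline run report",
            "",
            f"package version {self.version}, seed {self.config['seed']}",
            "",
            "## Headline results",
            "",
            f"- encoding median within-trial delta (perceptual − semantic): "
            f"{r['encoding']['median_delta_ms']:.1f} ms over {r['encoding']['n_pairs']} pairs",
            f"- retrieval median within-trial delta: "
            f"{r['retrieval']['median_delta_ms']:.1f} ms over {r['retrieval']['n_pairs']} pairs",
            f"- encoding clustered signed-rank: T = {r['encoding']['signrank']['statistic']:.1f}, "
            f"p = {r['encoding']['signrank']['p_value']:.4f} ({r['encoding']['signrank']['tail']})",
            f"- retrieval clustered signed-rank: T = {r['retrieval']['signrank']['statistic']:.1f}, "
            f"p = {r['retrieval']['signrank']['p_value']:.4f} ({r['retrieval']['signrank']['tail']})",
        ]
        if "peak_glmm" in r:
            g = r["peak_glmm"]
            lines.append(
                f"- peak-latency GLMM classifier × phase interaction: "
                f"F({g['df'][0]},{g['df'][1]}) = {g['F']:.2f}, p = {g['p']:.4f}"
            )
        if "behavior" in r:
            for target, g in r["behavior"].items():
                lines.append(
                    f"- behavioural {target} GLMM task × question interaction: "
                    f"F({g['df'][0]},{g['df'][1]}) = {g['F']:.2f}, p = {g['p']:.4f}"
                )
        if "erp" in r and "anova" in r["erp"]:
            a = r["erp"]["anova"]
            lines.append(
                f"- ERP peak-time 2×2 ANOVA interaction: F({a['df'][0]},{a['df'][1]}) = "
                f"{a['F']:.2f}, p = {a['p']:.4f}"
            )
        lines += ["", "## Stage wall-clock (s)", ""]
        lines += [f"- {k}: {v:.1f}" for k, v in self.stage_seconds.items()]
        return "\n".join(lines) + "\n"

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(self.to_json())
        (out / "report.md").write_text(self.to_markdown())


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (SyntheticConfig, FilterSpec)):
        payload = asdict_shallow(obj)
        for key in ("rt_distribution", "accuracy_prob"):
            if key in payload:
                payload[key] = {"/".join(cell): v for cell, v in payload[key].items()}
        return payload
    if isinstance(obj, dict):
        return {str(k): v for k, v in obj.items()}
    return str(obj)


# ---------------------------------------------------------------------------
# stage implementations
# ---------------------------------------------------------------------------

def preprocess_phase(epochs: EpochSet, config: RunConfig, phase: str) -> EpochSet:
    """filter (optional) → baseline → CAR → Gaussian smoothing."""
    if config.apply_filters:
        epochs = filter_epochs(epochs, config.filter_spec)
    if phase == "encoding":
        spec = BaselineSpec(mode="window", window=config.encoding_baseline_window)
    else:
        # post-response signal still carries object information, so the
        # retrieval baseline is the whole trial rather than a pre-event window
        spec = BaselineSpec(mode="whole_trial")
    epochs = baseline_correct(epochs, spec)
    epochs = common_average_reference(epochs)
    return gaussian_smooth(epochs, config.smoothing_fwhm_ms)


def decode_phase(
    epochs: EpochSet, config: RunConfig, phase: str, seeds: np.random.SeedSequence
) -> PhaseOutput:
    """Decoding, empirical null, thresholds, peaks and paired differences."""
    if phase == "encoding":
        window = config.encoding_decode_window
        stride = config.encoding_stride
        peak_window = config.encoding_peak_window
    else:
        window = config.retrieval_decode_window
        stride = config.retrieval_stride
        peak_window = config.retrieval_peak_window
    lam = config.shrinkage_lambda

    n_before = epochs.n_trials
    if phase == "retrieval":
        epochs = filter_retrieval_trials(epochs, config.min_rt_ms)
    n_removed_rt = n_before - epochs.n_trials

    under_seed, null_seed, boot_seed = seeds.spawn(3)
    participant_epochs = dict(epochs.per_participant())

    # real-label runs; engines are shared across classifiers whenever
    # undersampling leaves the trial set unchanged (balanced designs)
    dvalues = {kind: {} for kind in CLASSIFIERS}
    under_streams = {
        kind: dict(zip(sorted(participant_epochs), s.spawn(len(participant_epochs))))
        for kind, s in zip(CLASSIFIERS, under_seed.spawn(2))
    }
    for pid, sub in participant_epochs.items():
        engine_full = LoocvEngine(sub, window, stride=stride)
        for kind in CLASSIFIERS:
            balanced = undersample(sub, kind, under_streams[kind][pid])
            if balanced.n_trials == sub.n_trials:
                engine = engine_full
                source = sub
            else:
                engine = LoocvEngine(balanced, window, stride=stride)
                source = balanced
            dvalues[kind][pid] = real_label_run(
                source, kind, window, stride=stride, lam=lam, engine=engine
            )

    nulls = build_participant_nulls(
        participant_epochs,
        window,
        n_runs=config.n_null_runs,
        seed=null_seed,
        stride=stride,
        lam=lam,
        peak_window=peak_window,
    )
    thresholds = {}
    for kind, stream in zip(CLASSIFIERS, boot_seed.spawn(2)):
        null = bootstrap_group_null(
            nulls,
            dvalues[kind],
            n_boot=config.n_bootstrap,
            seed=stream,
            mode=config.threshold_mode,
        )
        thresholds[kind] = percentile_threshold(null, config.threshold_percentile)

    peak_tables = {}
    for kind in CLASSIFIERS:
        tables = [
            find_peaks_table(series, peak_window) for series in dvalues[kind].values()
        ]
        table = pd.concat(tables, ignore_index=True)
        peak_tables[kind] = apply_threshold(table, thresholds[kind])

    n_peaks = sum(len(t) for t in peak_tables.values())
    n_failed = sum(int((~t["passed_threshold"]).sum()) for t in peak_tables.values())
    diffs = pair_differences(peak_tables["perceptual"], peak_tables["semantic"])
    return PhaseOutput(
        dvalues=dvalues,
        thresholds=thresholds,
        peaks=peak_tables,
        diffs=diffs,
        n_trials_decoded=epochs.n_trials,
        n_trials_removed_rt=n_removed_rt,
        threshold_exclusion_rate=n_failed / n_peaks if n_peaks else np.nan,
    )


def erp_stage(
    encoding: EpochSet, retrieval: EpochSet, config: RunConfig, seeds
) -> dict:
    """Cluster-permutation ERP contrasts and the 2×2 peak-time ANOVA."""
    neigh = ChannelNeighbourhood.from_positions(
        encoding.channel_positions, encoding.channel_labels
    )
    out = {"contrasts": {}}
    peak_rows = []
    streams = dict(
        zip(
            [(p, c) for p in ("encoding", "retrieval") for c in CLASSIFIERS],
            seeds.spawn(4),
        )
    )
    for phase, epochs, window in (
        ("encoding", encoding, config.erp_encoding_window),
        ("retrieval", retrieval, config.erp_retrieval_window),
    ):
        for contrast in CLASSIFIERS:
            diffs, times, _ = participant_difference_maps(epochs, contrast, window)
            if phase == "encoding":
                clusters = cluster_permutation(
                    diffs,
                    times,
                    neigh,
                    cluster_alpha=config.cluster_alpha,
                    min_neighbours=config.min_neighbours,
                    n_perm=config.erp_n_perm,
                    seed=streams[(phase, contrast)],
                )
            else:
                clusters = windowed_retrieval_scan(
                    epochs,
                    contrast,
                    neigh,
                    full_window=window,
                    sub_epoch_ms=config.erp_sub_epoch_ms,
                    cluster_alpha=config.cluster_alpha,
                    min_neighbours=config.min_neighbours,
                    n_perm=config.erp_n_perm,
                    seed=streams[(phase, contrast)],
                )
            key = f"{phase}_{contrast}"
            if clusters:
                best = clusters[0]  # lowest corrected p = the maximum cluster
                out["contrasts"][key] = {
                    "statistic": best.statistic,
                    "p_value": best.p_value,
                    "sign": best.sign,
                    "extent_ms": best.extent_ms,
                    "peak_time_ms": best.peak_time_ms,
                    "n_channels": int(best.channels.size),
                    "sub_epoch": best.sub_epoch,
                    "n_clusters_found": len(clusters),
                }
                times_pp = participant_peak_times(diffs, times, best.channels, window)
                for pid_idx, t_peak in enumerate(times_pp):
                    peak_rows.append(
                        {
                            "participant_id": pid_idx,
                            "feature": contrast,
                            "phase": phase,
                            "value": float(t_peak),
                        }
                    )
            else:
                out["contrasts"][key] = {"n_clusters_found": 0}
    table = pd.DataFrame(peak_rows)
    if not table.empty and table.groupby(["feature", "phase"]).ngroups == 4:
        anova = rm_anova_interaction(table)
        out["anova"] = {
            "F": anova.f_value,
            "df": anova.df,
            "p": anova.p_value,
            "n_participants": anova.n_participants,
        }
    else:
        out["note"] = "ANOVA skipped: not all four contrasts produced a cluster"
    return out


def run_pipeline(config: RunConfig, out_dir=None) -> RunReport:
    """Execute all enabled stages and return (and optionally save) the report."""
    findings = validate_config(config)
    errors = [f.message for f in findings if f.level == "error"]
    if errors:
        raise ValueError("invalid configuration: " + "; ".join(errors))

    root = np.random.SeedSequence([int(config.seed), 23])
    enc_seeds, ret_seeds, erp_seeds = root.spawn(3)
    timings, results = {}, {}

    t0 = time.perf_counter()
    enc_cfg = _with_seed(config.encoding, config.seed)
    ret_cfg = _with_seed(config.retrieval, config.seed)
    enc_raw, _ = generate_encoding_epochs(enc_cfg)
    ret_raw, _ = generate_retrieval_epochs(ret_cfg)
    behavior = generate_behavior(enc_cfg) if config.run_behavior else None
    timings["simulate"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    enc = preprocess_phase(enc_raw, config, "encoding")
    ret = preprocess_phase(ret_raw, config, "retrieval")
    timings["preprocess"] = time.perf_counter() - t0

    phase_out = {}
    for phase, epochs, seeds in (
        ("encoding", enc, enc_seeds),
        ("retrieval", ret, ret_seeds),
    ):
        t0 = time.perf_counter()
        phase_out[phase] = decode_phase(epochs, config, phase, seeds)
        timings[f"decode_null_peaks_{phase}"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    sr_seeds = np.random.SeedSequence([int(config.seed), 29]).spawn(2)
    for phase, tail, stream in (
        ("encoding", "one_tailed_neg", sr_seeds[0]),
        ("retrieval", "one_tailed_pos", sr_seeds[1]),
    ):
        out = phase_out[phase]
        test = clustered_signrank(
            out.diffs, tail=tail, n_perm=config.n_signrank_perm, seed=stream
        )
        results[phase] = {
            "median_delta_ms": float(np.median(out.diffs["delta_ms"]))
            if len(out.diffs)
            else np.nan,
            "n_pairs": int(len(out.diffs)),
            "n_trials_decoded": out.n_trials_decoded,
            "n_trials_removed_rt": out.n_trials_removed_rt,
            "threshold_exclusion_rate": out.threshold_exclusion_rate,
            "thresholds": out.thresholds,
            "signrank": {
                "statistic": test.statistic,
                "p_value": test.p_value,
                "tail": test.tail,
                "n_permutations": test.n_permutations,
                "n_clusters": test.n_clusters,
            },
        }

    peak_table = _joint_peak_table(phase_out)
    if peak_table is not None:
        try:
            glmm = fit_glmm(peak_table, "peak_time", fixed=("feature", "phase"))
            results["peak_glmm"] = _glmm_summary(glmm)
        except (StatsError, GlmmDegenerateError) as exc:
            results["peak_glmm_error"] = str(exc)
    timings["group_stats"] = time.perf_counter() - t0

    if behavior is not None:
        t0 = time.perf_counter()
        results["behavior"] = {}
        rt_table = filter_rt_outliers(behavior)
        for target, table in (("rt", rt_table), ("accuracy", behavior)):
            try:
                glmm = fit_glmm(table, target)
                results["behavior"][target] = _glmm_summary(glmm)
            except (StatsError, GlmmDegenerateError) as exc:
                results["behavior"][target] = {"error": str(exc)}
        timings["behavior_stats"] = time.perf_counter() - t0

    if config.run_erp:
        t0 = time.perf_counter()
        results["erp"] = erp_stage(enc, ret, config, erp_seeds)
        timings["erp"] = time.perf_counter() - t0

    report = RunReport(
        config=json.loads(json.dumps(asdict_shallow(config), default=_jsonable)),
        version=__version__,
        stage_seconds=timings,
        results=results,
    )
    if out_dir is not None:
        report.save(out_dir)
        out = Path(out_dir)
        for phase in ("encoding", "retrieval"):
            phase_out[phase].diffs.to_csv(
                out / f"paired_differences_{phase}.tsv", sep="\t", index=False
            )
            for kind in CLASSIFIERS:
                phase_out[phase].peaks[kind].to_csv(
                    out / f"peaks_{phase}_{kind}.tsv", sep="\t", index=False
                )
        if behavior is not None:
            behavior.to_csv(out / "behavior.tsv", sep="\t", index=False)
    return report


def _with_seed(syn: SyntheticConfig, seed: int) -> SyntheticConfig:
    params = asdict_shallow(syn)
    params["seed"] = int(seed)
    return SyntheticConfig(**params)


def _joint_peak_table(phase_out: dict) -> pd.DataFrame | None:
    """Threshold-passing peaks of both phases, z-scored within phase + 1000 ms."""
    rows = []
    for phase, out in phase_out.items():
        for kind in CLASSIFIERS:
            table = out.peaks[kind]
            passed = table[table["passed_threshold"]]
            if passed.empty:
                continue
            rows.append(
                pd.DataFrame(
                    {
                        "participant_id": passed["participant_id"].to_numpy(),
                        "feature": kind,
                        "phase": phase,
                        "peak_time_ms": passed["peak_time_ms"].to_numpy(),
                    }
                )
            )
    if not rows:
        return None
    table = pd.concat(rows, ignore_index=True)
    if table["phase"].nunique() < 2 or table["feature"].nunique() < 2:
        return None
    table["value"] = standardize_for_joint_model(
        table["peak_time_ms"].to_numpy(), table["phase"].to_numpy()
    )
    return table


def _glmm_summary(glmm) -> dict:
    return {
        "F": glmm.interaction_f,
        "df": glmm.interaction_df,
        "p": glmm.interaction_p,
        "interaction_term": glmm.interaction_term,
        "family": glmm.family,
        "random_structure": glmm.random_structure,
        "planned_contrasts": glmm.planned_contrasts,
    }
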