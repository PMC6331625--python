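"""Group-level inference for paired peak differences and behavioural tables.

Three inferential tools:

* a clustered Wilcoxon signed-rank permutation test for within-trial peak
  differences, which respects the dependence of trials within a
  participant by flipping signs at the *cluster* (participant) level;
* generalized linear mixed-type models for single-trial reaction times,
  accuracy and peak latencies — gamma family with identity link for
  latencies, binomial with logit link for accuracy — with the task ×
  question interaction as the hypothesis contrast and participant-level
  dependence absorbed by a compound-symmetry (exchangeable) working
  correlation;
* a classical 2 × 2 repeated-measures ANOVA interaction for
  per-participant ERP peak times.

The signed-rank statistic is the sum of signed ranks, with ranks of the
absolute differences pooled across clusters; its null is built by jointly
flipping the sign of all differences within a cluster (cluster-level
exchangeability), and the permutation p value includes the observed
statistic (add-one rule) so it is exactly valid.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)


class StatsError(ValueError):
    pass


class GlmmDegenerateError(StatsError):
    """A model cell is degenerate (e.g. accuracy constant within a cell)."""


@dataclass
class ClusteredTestResult:
    statistic: float
    p_value: float
    tail: str
    n_permutations: int
    n_clusters: int
    n_differences: int


@dataclass
class GlmmResult:
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    interaction_term: str
    interaction_f: float
    interaction_df: tuple
    interaction_p: float
    family: str
    random_structure: str
    planned_contrasts: dict = field(default_factory=dict)
    converged: bool = True


@dataclass
class AnovaResult:
    f_value: float
    df: tuple
    p_value: float
    n_participants: int


# ---------------------------------------------------------------------------
# clustered Wilcoxon signed rank
# ---------------------------------------------------------------------------

def clustered_signrank(
    diffs,
    tail: str = "two_tailed",
    n_perm: int = 2000,
    seed=0,
    cluster_col: str = "participant_id",
    value_col: str = "delta_ms",
) -> ClusteredTestResult:
    """Clustered Wilcoxon signed-rank test via cluster-level sign flips.

    ``diffs`` is a table with one row per paired difference and a cluster
    (participant) column, or a ``(clusters, values)`` tuple of arrays.
    ``tail`` ∈ {'one_tailed_pos', 'one_tailed_neg', 'two_tailed'}; the
    one-tailed variants test whether differences lean positive (semantic
    before perceptual) or negative (perceptual before semantic).
    """
    if isinstance(diffs, pd.DataFrame):
        clusters = diffs[cluster_col].to_numpy()
        values = diffs[value_col].to_numpy(dtype=float)
    else:
        clusters, values = diffs
        clusters = np.asarray(clusters)
        values = np.asarray(values, dtype=float)
    if tail not in ("one_tailed_pos", "one_tailed_neg", "two_tailed"):
        raise StatsError(f"unknown tail {tail!r}")
    if n_perm < 1:
        raise StatsError("n_perm must be >= 1")

    nonzero = values != 0
    clusters, values = clusters[nonzero], values[nonzero]
    uniq = np.unique(clusters)
    if values.size == 0:
        return ClusteredTestResult(0.0, 1.0, tail, n_perm, 0, 0)
    if uniq.size < 2:
        raise StatsError("clustered test needs at least 2 clusters")

    ranks = stats.rankdata(np.abs(values))  # pooled across clusters, ties averaged
    signed = np.sign(values) * ranks
    cluster_idx = np.searchsorted(uniq, clusters)
    cluster_sums = np.bincount(cluster_idx, weights=signed, minlength=uniq.size)
    t_obs = float(cluster_sums.sum())

    rng = np.random.default_rng(_entropy(seed))
    signs = rng.choice((-1.0, 1.0), size=(n_perm, uniq.size))
    t_perm = signs @ cluster_sums
    if tail == "one_tailed_pos":
        count = np.sum(t_perm >= t_obs)
    elif tail == "one_tailed_neg":
        count = np.sum(t_perm <= t_obs)
    else:
        count = np.sum(np.abs(t_perm) >= abs(t_obs))
    p = (1.0 + count) / (1.0 + n_perm)
    return ClusteredTestResult(
        statistic=t_obs,
        p_value=float(p),
        tail=tail,
        n_permutations=int(n_perm),
        n_clusters=int(uniq.size),
        n_differences=int(values.size),
    )


# ---------------------------------------------------------------------------
# RT outlier filtering
# ---------------------------------------------------------------------------

def filter_rt_outliers(
    table: pd.DataFrame, k: float = 2.5, by: str = "task"
) -> pd.DataFrame:
    """Correct-only trials within ±k SD of the group-mean RT per task.

    Incorrect trials are removed first; the mean and SD are then computed
    over the remaining trials of each task group, and trials whose RT
    deviates from the group mean by more than ``k`` SDs are excluded.
    With zero SD (all RTs identical) no trial can exceed the bound.
    """
    if len(table) < 2:
        raise StatsError("need at least 2 trials")
    correct = table[table["correct"] == 1]
    kept = []
    for _, group in correct.groupby(by, sort=False):
        rt = group["rt_ms"].to_numpy(dtype=float)
        mean, sd = rt.mean(), rt.std(ddof=1) if len(rt) > 1 else 0.0
        keep = np.abs(rt - mean) <= k * sd if sd > 0 else np.ones(len(rt), bool)
        kept.append(group[keep])
    out = pd.concat(kept).sort_index()
    logger.info(
        "RT outlier filter: %d incorrect and %d outlier trials removed of %d",
        len(table) - len(correct),
        len(correct) - len(out),
        len(table),
    )
    return out


# ---------------------------------------------------------------------------
# GLMM layer (GEE with compound-symmetry working correlation)
# ---------------------------------------------------------------------------

_TARGETS = {
    "rt": ("rt_ms", "gamma_identity"),
    "accuracy": ("correct", "binomial_logit"),
    "peak_time": ("value", "gamma_identity"),
}


def _family(name: str):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # identity link for Gamma is intentional
        if name == "gamma_identity":
            return sm.families.Gamma(link=sm.families.links.Identity())
        if name == "binomial_logit":
            return sm.families.Binomial(link=sm.families.links.Logit())
    raise StatsError(f"unknown family {name!r}")


def _fit_gee(formula, data, groups, family, cov_struct):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GEE.from_formula(
            formula, groups=groups, data=data, family=family, cov_struct=cov_struct
        )
        return model.fit(maxiter=100)


def fit_glmm(
    table: pd.DataFrame,
    target: str,
    fixed: tuple = ("task", "question"),
    groups: str = "participant_id",
) -> GlmmResult:
    """Mixed-model analysis of a single-trial table.

    Fixed effects are the two factors and their interaction; participant
    dependence is modelled by an exchangeable (compound-symmetry) working
    correlation with cluster-robust standard errors. If that fit fails the
    model falls back to an independence working correlation (the analogue
    of dropping the richer random structure when it cannot be estimated).
    Wald statistics are referred to t/F distributions with
    ``n_clusters − n_params`` denominator degrees of freedom.
    """
    if target not in _TARGETS:
        raise StatsError(f"unknown target {target!r}")
    response, family_name = _TARGETS[target]
    if response not in table.columns:
        raise StatsError(f"column {response!r} missing for target {target!r}")
    f1, f2 = fixed
    data = table.dropna(subset=[response]).copy()

    if family_name == "binomial_logit":
        cell_var = data.groupby([f1, f2])[response].nunique()
        if (cell_var < 2).any():
            bad = cell_var[cell_var < 2].index.tolist()
            raise GlmmDegenerateError(
                f"response is constant within cell(s) {bad}; "
                "the logit model is not identified"
            )

    formula = f"{response} ~ C({f1}) * C({f2})"
    family = _family(family_name)
    result, structure, converged = None, "exchangeable (compound symmetry)", True
    try:
        result = _fit_gee(formula, data, data[groups], family, sm.cov_struct.Exchangeable())
        converged = bool(getattr(result, "converged", True))
        if not converged:
            raise RuntimeError("exchangeable fit did not converge")
    except Exception as exc:  # noqa: BLE001 — fall back, then re-raise if that fails too
        logger.warning("exchangeable working correlation failed (%s); falling back", exc)
        structure = "independence (fallback)"
        result = _fit_gee(formula, data, data[groups], family, sm.cov_struct.Independence())
        converged = bool(getattr(result, "converged", True))

    n_clusters = data[groups].nunique()
    df_denom = max(n_clusters - len(result.params), 1)
    tvals = result.params / result.bse
    pvals = pd.Series(
        2.0 * stats.t.sf(np.abs(tvals), df_denom), index=tvals.index
    )
    inter = [name for name in result.params.index if ":" in name]
    if len(inter) != 1:
        raise StatsError(f"expected one interaction term, got {inter}")
    term = inter[0]
    f_val = float(tvals[term] ** 2)
    f_p = float(stats.f.sf(f_val, 1, df_denom))

    contrasts = {}
    for level in data[f1].unique():
        sub = data[data[f1] == level]
        try:
            sub_res = _fit_gee(
                f"{response} ~ C({f2})",
                sub,
                sub[groups],
                family,
                sm.cov_struct.Exchangeable(),
            )
        except Exception:  # noqa: BLE001
            sub_res = _fit_gee(
                f"{response} ~ C({f2})",
                sub,
                sub[groups],
                family,
                sm.cov_struct.Independence(),
            )
        slope = [n for n in sub_res.params.index if n != "Intercept"][0]
        t_sub = float(sub_res.params[slope] / sub_res.bse[slope])
        df_sub = max(sub[groups].nunique() - 2, 1)
        contrasts[str(level)] = {
            "B": float(sub_res.params[slope]),
            "t": t_sub,
            "p": float(2.0 * stats.t.sf(abs(t_sub), df_sub)),
            "term": slope,
        }

    return GlmmResult(
        params=result.params,
        bse=result.bse,
        tvalues=tvals,
        pvalues=pvals,
        interaction_term=term,
        interaction_f=f_val,
        interaction_df=(1, df_denom),
        interaction_p=f_p,
        family=family_name,
        random_structure=structure + ", participant clusters",
        planned_contrasts=contrasts,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# repeated-measures ANOVA and the joint-model transform
# ---------------------------------------------------------------------------

def rm_anova_interaction(
    table: pd.DataFrame,
    factor_a: str = "feature",
    factor_b: str = "phase",
    value: str = "value",
) -> AnovaResult:
    """2 × 2 within-subjects interaction F on per-participant cell values.

    Equivalent to a paired t test on the per-participant double-difference
    contrast, squared: F with (1, n − 1) degrees of freedom. Participants
    with missing cells are dropped (reported via logging).
    """
    wide = table.pivot_table(
        index="participant_id", columns=[factor_a, factor_b], values=value
    )
    if wide.shape[1] != 4:
        raise StatsError(
            f"expected a complete 2 × 2 design, found columns {list(wide.columns)}"
        )
    complete = wide.dropna()
    dropped = len(wide) - len(complete)
    if dropped:
        logger.warning("rm_anova: dropped %d participant(s) with missing cells", dropped)
    n = len(complete)
    if n < 2:
        raise StatsError("need at least 2 complete participants")
    a_levels = complete.columns.get_level_values(0).unique()
    b_levels = complete.columns.get_level_values(1).unique()
    c = (
        complete[(a_levels[0], b_levels[0])]
        - complete[(a_levels[0], b_levels[1])]
        - complete[(a_levels[1], b_levels[0])]
        + complete[(a_levels[1], b_levels[1])]
    ).to_numpy()
    mean, sd = c.mean(), c.std(ddof=1)
    if sd == 0:
        if mean == 0:
            return AnovaResult(0.0, (1, n - 1), 1.0, n)
        return AnovaResult(np.inf, (1, n - 1), 0.0, n)  # exact crossover, no error variance
    f_val = float((mean / (sd / np.sqrt(n))) ** 2)
    return AnovaResult(f_val, (1, n - 1), float(stats.f.sf(f_val, 1, n - 1)), n)


def standardize_for_joint_model(
    values: np.ndarray, phases: np.ndarray | None = None, add_ms: float = 1000.0
) -> np.ndarray:
    """z-score (within phase when given) and add a constant offset.

    Used before jointly modelling encoding and retrieval peak latencies,
    whose raw scales differ by an order of magnitude; the added constant
    keeps the transformed latencies positive for the gamma family.
    """
    values = np.asarray(values, dtype=float)
    out = np.empty_like(values)
    if phases is None:
        groups = [np.arange(values.size)]
    else:
        phases = np.asarray(phases)
        groups = [np.flatnonzero(phases == ph) for ph in np.unique(phases)]
    for idx in groups:
        sd = values[idx].std(ddof=1) if idx.size > 1 else 0.0
        if sd == 0:
            raise StatsError("cannot z-score a group with zero standard deviation")
        out[idx] = (values[idx] - values[idx].mean()) / sd
    return out + add_ms


def _entropy(seed) -> int:
    if isinstance(seed, (int, np.integer)):
        return int(seed)
    return int(np.random.default_rng(seed).integers(0, 2**31))
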