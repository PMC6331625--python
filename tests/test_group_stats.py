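import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from eegreversal.group_stats import (
    GlmmDegenerateError,
    StatsError,
    clustered_signrank,
    filter_rt_outliers,
    fit_glmm,
    rm_anova_interaction,
    standardize_for_joint_model,
)
from eegreversal.synthetic import SyntheticConfig, generate_behavior


def diff_table(clusters, values):
    return pd.DataFrame({"participant_id": clusters, "delta_ms": values})


class TestClusteredSignrank:
    def test_all_positive_gives_minimal_p(self):
        # enough clusters that a random sign assignment essentially never
        # reaches the maximal statistic: p ≈ 1/(n_perm + 1)
        table = diff_table(np.repeat([f"P{i}" for i in range(20)], 5), np.ones(100))
        res = clustered_signrank(table, tail="one_tailed_pos", n_perm=500, seed=0)
        assert res.p_value == pytest.approx(1.0 / 501.0, rel=0.01)

    def test_all_zero_input_gives_p_one(self):
        table = diff_table(["P1"] * 5 + ["P2"] * 5, np.zeros(10))
        res = clustered_signrank(table, tail="two_tailed", n_perm=100, seed=0)
        assert res.p_value == 1.0 and res.statistic == 0.0

    def test_singleton_clusters_reduce_to_ordinary_signed_rank(self):
        """With one difference per cluster, cluster flips are per-observation
        flips; p must agree with an exhaustive permutation signed-rank test."""
        rng = np.random.default_rng(3)
        values = rng.normal(0.6, 1.0, size=10)
        ranks = stats.rankdata(np.abs(values))
        signed = np.sign(values) * ranks
        t_obs = signed.sum()
        exact = [
            np.sum(np.array(signs) * np.abs(signed))
            for signs in itertools.product((-1, 1), repeat=10)
        ]
        p_exact = np.mean([t >= t_obs for t in exact])
        table = diff_table([f"P{i}" for i in range(10)], values)
        res = clustered_signrank(table, tail="one_tailed_pos", n_perm=20000, seed=1)
        assert res.p_value == pytest.approx(p_exact, abs=0.02)

    def test_type_one_error_calibrated_under_cluster_symmetry(self):
        """P(p <= alpha) ≈ alpha when cluster vectors are sign-symmetric."""
        rng = np.random.default_rng(0)
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            b = rng.normal(0.0, 1.0, size=8)  # cluster effects, symmetric
            values = (b[:, None] + rng.normal(0.0, 1.0, size=(8, 32))).ravel()
            clusters = np.repeat([f"P{i}" for i in range(8)], 32)
            res = clustered_signrank(
                diff_table(clusters, values), tail="two_tailed", n_perm=300, seed=rng
            )
            rejections += res.p_value <= 0.05
        assert 0.02 <= rejections / n_rep <= 0.09

    def test_invariance_to_scaling_and_relabelling(self):
        rng = np.random.default_rng(5)
        values = rng.normal(0.3, 1.0, size=24)
        clusters = np.repeat(["P1", "P2", "P3", "P4"], 6)
        base = clustered_signrank(diff_table(clusters, values), n_perm=400, seed=9)
        scaled = clustered_signrank(
            diff_table(clusters, values * 17.3), n_perm=400, seed=9
        )
        renamed = clustered_signrank(
            diff_table(np.char.add("X_", clusters.astype(str)), values),
            n_perm=400,
            seed=9,
        )
        assert base.p_value == scaled.p_value == renamed.p_value

    def test_single_cluster_rejected(self):
        with pytest.raises(StatsError):
            clustered_signrank(diff_table(["P1"] * 8, np.ones(8)), n_perm=10, seed=0)


class TestRtOutliers:
    def test_extreme_trial_removed(self):
        rt = np.array([500.0] * 99 + [10000.0])
        table = pd.DataFrame(
            {
                "participant_id": "P1",
                "task": "visual",
                "question": "perceptual",
                "rt_ms": rt,
                "correct": 1,
            }
        )
        # oracle on the constructed set: only the 10 s trial exceeds ±2.5 SD
        mean, sd = rt.mean(), rt.std(ddof=1)
        assert np.sum(np.abs(rt - mean) > 2.5 * sd) == 1
        out = filter_rt_outliers(table)
        assert len(out) == 99 and out["rt_ms"].max() == 500.0

    def test_identical_rts_kept(self):
        table = pd.DataFrame(
            {
                "participant_id": "P1",
                "task": "visual",
                "question": "perceptual",
                "rt_ms": np.full(20, 640.0),
                "correct": 1,
            }
        )
        assert len(filter_rt_outliers(table)) == 20

    def test_incorrect_trials_always_removed(self):
        table = pd.DataFrame(
            {
                "participant_id": "P1",
                "task": "visual",
                "question": "perceptual",
                "rt_ms": np.full(10, 500.0),
                "correct": [1] * 5 + [0] * 5,
            }
        )
        out = filter_rt_outliers(table)
        assert len(out) == 5 and (out["correct"] == 1).all()

    def test_output_is_subset_of_input(self):
        table = generate_behavior(
            SyntheticConfig(n_participants=4, n_trials_per_participant=32, seed=2)
        )
        out = filter_rt_outliers(table)
        assert out.index.isin(table.index).all() and len(out) <= len(table)


class TestGlmm:
    def test_rt_interaction_recovered_with_planted_crossover(self):
        cfg = SyntheticConfig(n_participants=12, n_trials_per_participant=96, seed=0)
        table = filter_rt_outliers(generate_behavior(cfg))
        res = fit_glmm(table, "rt")
        assert res.family == "gamma_identity"
        assert res.interaction_p < 0.05
        # question coded perceptual -> semantic: visual slope positive
        # (795 < 842 ms), memory slope negative (2502 > 2334 ms)
        assert res.planned_contrasts["visual"]["B"] > 0
        assert res.planned_contrasts["memory"]["B"] < 0

    def test_accuracy_family_and_interaction(self):
        cfg = SyntheticConfig(n_participants=16, n_trials_per_participant=128, seed=1)
        res = fit_glmm(generate_behavior(cfg), "accuracy")
        assert res.family == "binomial_logit"
        assert np.isfinite(res.interaction_f) and res.interaction_f >= 0

    def test_constant_accuracy_cell_raises_graceful_error(self):
        cfg = SyntheticConfig(
            n_participants=4,
            n_trials_per_participant=16,
            seed=2,
            accuracy_prob={
                ("visual", "perceptual"): 1.0,
                ("visual", "semantic"): 0.9,
                ("memory", "perceptual"): 0.9,
                ("memory", "semantic"): 0.9,
            },
        )
        with pytest.raises(GlmmDegenerateError, match="constant within cell"):
            fit_glmm(generate_behavior(cfg), "accuracy")

    def test_unknown_target_rejected(self):
        with pytest.raises(StatsError):
            fit_glmm(pd.DataFrame({"rt_ms": [1.0]}), "weight")


class TestRmAnova:
    @staticmethod
    def toy_table(values):
        rows = []
        for pid, cells in values.items():
            for (a, b), v in cells.items():
                rows.append(
                    {
                        "participant_id": pid,
                        "feature": a,
                        "phase": b,
                        "value": v,
                    }
                )
        return pd.DataFrame(rows)

    def test_matches_hand_computation(self):
        values = {
            "P1": {("p", "e"): 10.0, ("p", "r"): 14.0, ("s", "e"): 12.0, ("s", "r"): 11.0},
            "P2": {("p", "e"): 9.0, ("p", "r"): 15.0, ("s", "e"): 13.0, ("s", "r"): 10.0},
            "P3": {("p", "e"): 11.0, ("p", "r"): 13.0, ("s", "e"): 12.5, ("s", "r"): 12.0},
        }
        res = rm_anova_interaction(self.toy_table(values))
        # contrast c_i = (pe − pr) − (se − sr): −5, −9, −2.5
        c = np.array([-5.0, -9.0, -2.5])
        f_hand = (c.mean() / (c.std(ddof=1) / np.sqrt(3))) ** 2
        assert res.f_value == pytest.approx(f_hand, rel=1e-8)
        assert res.df == (1, 2)

    def test_matches_statsmodels_anova_rm(self):
        rng = np.random.default_rng(0)
        rows = []
        for pid in range(8):
            for a in ("perc", "sem"):
                for b in ("enc", "ret"):
                    rows.append(
                        {
                            "participant_id": f"P{pid}",
                            "feature": a,
                            "phase": b,
                            "value": rng.normal(),
                        }
                    )
        table = pd.DataFrame(rows)
        res = rm_anova_interaction(table)
        from statsmodels.stats.anova import AnovaRM

        oracle = (
            AnovaRM(table, "value", "participant_id", within=["feature", "phase"])
            .fit()
            .anova_table
        )
        assert res.f_value == pytest.approx(
            oracle.loc["feature:phase", "F Value"], rel=1e-6
        )

    def test_identical_cells_give_zero_f(self):
        values = {
            f"P{i}": {(a, b): 5.0 for a in "ps" for b in "er"} for i in range(4)
        }
        res = rm_anova_interaction(self.toy_table(values))
        assert res.f_value == 0.0 and res.p_value == 1.0

    def test_pure_crossover_without_noise_is_exact_fit(self):
        values = {
            f"P{i}": {("p", "e"): 0.0, ("p", "r"): 2.0, ("s", "e"): 2.0, ("s", "r"): 0.0}
            for i in range(4)
        }
        res = rm_anova_interaction(self.toy_table(values))
        assert np.isinf(res.f_value) and res.p_value == 0.0


class TestStandardize:
    def test_zscore_plus_offset(self):
        out = standardize_for_joint_model(np.array([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(out, np.array([-1.0, 0.0, 1.0]) + 1000.0)

    def test_positive_for_moderate_z(self, rng):
        out = standardize_for_joint_model(rng.normal(50.0, 5.0, size=200))
        assert (out > 0).all()

    def test_monotone_within_phase(self, rng):
        values = rng.normal(size=30)
        out = standardize_for_joint_model(values)
        assert (np.argsort(out) == np.argsort(values)).all()

    def test_zero_sd_rejected(self):
        with pytest.raises(StatsError):
            standardize_for_joint_model(np.ones(5))

    def test_within_phase_scaling(self):
        values = np.array([100.0, 200.0, 300.0, -1000.0, -2000.0, -3000.0])
        phases = np.array(["enc"] * 3 + ["ret"] * 3)
        out = standardize_for_joint_model(values, phases)
        np.testing.assert_allclose(out[:3], np.array([-1.0, 0.0, 1.0]) + 1000.0)
        np.testing.assert_allclose(out[3:], np.array([1.0, 0.0, -1.0]) + 1000.0)
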