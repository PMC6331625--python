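import numpy as np
import pytest

from eegreversal.containers import DValueSeries, label_vector
from eegreversal.decoding import (
    DecodingError,
    LoocvEngine,
    _loocv_reference,
    align_signs,
    dvalue,
    loocv_dvalues,
    train_lda_shrinkage,
    undersample,
)

from conftest import make_epochs


def random_instance(rng, n_channels=8, n_samples=40):
    X = rng.standard_normal((n_samples, n_channels))
    y = np.zeros(n_samples, dtype=int)
    y[n_samples // 2 :] = 1
    X[y == 1] += rng.standard_normal(n_channels) * 0.5
    return X, y


class TestTrainLda:
    def test_weights_match_dense_solver_oracle(self, rng):
        """Shrinkage-LDA weights solve ((1−λ)S + λνI) w ∝ μ₁ − μ₀ exactly."""
        for _ in range(10):
            X, y = random_instance(rng)
            lam = 0.2
            model = train_lda_shrinkage(X, y, lam=lam)
            X0, X1 = X[y == 0], X[y == 1]
            S = np.zeros((8, 8))
            for block in (X0, X1):
                centred = block - block.mean(axis=0)
                S += centred.T @ centred
            nu = np.trace(S) / 8
            w_oracle = np.linalg.solve(
                (1 - lam) * S + lam * nu * np.eye(8), X1.mean(0) - X0.mean(0)
            )
            w_oracle /= np.linalg.norm(w_oracle)
            np.testing.assert_allclose(model.weights, w_oracle, rtol=1e-8)

    def test_lambda_one_is_nearest_class_mean(self, rng):
        X, y = random_instance(rng)
        model = train_lda_shrinkage(X, y, lam=1.0)
        direction = X[y == 1].mean(0) - X[y == 0].mean(0)
        direction /= np.linalg.norm(direction)
        np.testing.assert_allclose(model.weights, direction, rtol=1e-10)

    def test_separable_clouds_classified_correctly(self, rng):
        X = np.concatenate(
            [
                np.array([-1.0, 0.0]) + 0.01 * rng.standard_normal((20, 2)),
                np.array([1.0, 0.0]) + 0.01 * rng.standard_normal((20, 2)),
            ]
        )
        y = np.repeat([0, 1], 20)
        model = train_lda_shrinkage(X, y)
        d = X @ model.weights + model.bias
        assert (np.sign(d) == np.where(y == 1, 1, -1)).all()

    def test_analytic_lambda_in_unit_interval(self, rng):
        for _ in range(20):
            n_ch = rng.integers(2, 10)
            n = int(rng.integers(6, 40))
            X, y = random_instance(rng, n_channels=n_ch, n_samples=n)
            model = train_lda_shrinkage(X, y)
            assert 0.0 <= model.shrinkage_lambda <= 1.0

    def test_matches_sklearn_lsqr_direction(self, rng):
        """Independent cross-check: sklearn's shrinkage LDA, same λ."""
        sklearn = pytest.importorskip("sklearn.discriminant_analysis")
        X, y = random_instance(rng, n_channels=6, n_samples=30)
        lam = 0.3
        ours = train_lda_shrinkage(X, y, lam=lam)
        theirs = sklearn.LinearDiscriminantAnalysis(
            solver="lsqr", shrinkage=lam
        ).fit(X, y)
        w = theirs.coef_.ravel() / np.linalg.norm(theirs.coef_)
        # same hyperplane direction (sklearn shrinks the biased covariance,
        # so magnitudes differ but the direction must agree closely)
        assert abs(ours.weights @ w) > 0.99

    def test_degenerate_inputs_rejected(self, rng):
        X = rng.standard_normal((6, 3))
        with pytest.raises(DecodingError):
            train_lda_shrinkage(X, np.zeros(6, dtype=int))
        with pytest.raises(DecodingError):
            train_lda_shrinkage(X, np.array([0, 0, 0, 0, 0, 1]))


class TestDvalue:
    def test_hyperplane_midpoint_and_class_means(self, rng):
        X, y = random_instance(rng)
        model = train_lda_shrinkage(X, y, lam=0.1)
        mu0, mu1 = X[y == 0].mean(0), X[y == 1].mean(0)
        assert dvalue(model, (mu0 + mu1) / 2) == pytest.approx(0.0, abs=1e-12)
        assert dvalue(model, mu1) > 0 > dvalue(model, mu0)

    def test_linearity_along_weights(self, rng):
        X, y = random_instance(rng)
        model = train_lda_shrinkage(X, y, lam=0.1)
        x = X[0]
        delta = 0.73
        assert dvalue(model, x + delta * model.weights) == pytest.approx(
            dvalue(model, x) + delta
        )

    def test_dimension_mismatch(self, rng):
        X, y = random_instance(rng)
        model = train_lda_shrinkage(X, y, lam=0.1)
        with pytest.raises(DecodingError):
            dvalue(model, np.zeros(3))


class TestUndersample:
    def test_majority_subsampled_to_minority(self):
        epochs = make_epochs(n_trials=20)
        # drop 4 drawing trials -> 10 photograph vs 6 drawing
        keep = np.ones(20, dtype=bool)
        keep[np.flatnonzero(epochs.trials["perceptual_label"] == "drawing")[:4]] = False
        unbalanced = epochs.select_trials(keep)
        out = undersample(unbalanced, "perceptual", seed=0)
        y = label_vector(out.trials, "perceptual")
        assert y.sum() == (1 - y).sum() == 6

    def test_balanced_input_is_identity(self, small_epochs):
        out = undersample(small_epochs, "perceptual", seed=0)
        assert out is small_epochs

    def test_seed_reproducibility(self):
        epochs = make_epochs(n_trials=20)
        keep = np.ones(20, dtype=bool)
        keep[np.flatnonzero(epochs.trials["perceptual_label"] == "drawing")[:4]] = False
        unbalanced = epochs.select_trials(keep)
        a = undersample(unbalanced, "perceptual", seed=5)
        b = undersample(unbalanced, "perceptual", seed=5)
        np.testing.assert_array_equal(a.data, b.data)


class TestAlignSigns:
    def test_negative_class_inverted_positive_kept(self, small_epochs):
        values = np.array([[-0.3], [0.5]] * 6)
        series = DValueSeries(values, np.array([0.0]), small_epochs.trials, "perceptual")
        y = np.array([0, 1] * 6)
        out = align_signs(series, y)
        assert out.aligned
        np.testing.assert_allclose(out.values[:2, 0], [0.3, 0.5])

    def test_double_alignment_rejected(self, small_epochs):
        series = DValueSeries(
            np.zeros((12, 1)), np.array([0.0]), small_epochs.trials, "perceptual"
        )
        once = align_signs(series, np.zeros(12, dtype=int))
        with pytest.raises(DecodingError):
            align_signs(once, np.zeros(12, dtype=int))


class TestLoocv:
    def test_hand_worked_example(self):
        """4 trials, 1 timepoint, λ=1: d values computed by hand."""
        data = np.array([[0.0, 0.0], [0.0, 2.0], [4.0, 0.0], [4.0, 2.0]])[:, :, None]
        epochs = make_epochs(n_trials=4, n_channels=2, n_times=1, data=data)
        y = np.array([0, 0, 1, 1])
        series = loocv_dvalues(
            epochs, "perceptual", (epochs.times[0], epochs.times[0]), lam=1.0, labels=y
        )
        expected = np.array([-6.5, -6.5, 6.5, 6.5]) / np.sqrt(17.0)
        np.testing.assert_allclose(series.values[:, 0], expected, rtol=1e-8)

    @pytest.mark.parametrize("lam", [0.0, 0.2, 1.0, None])
    def test_fast_path_matches_per_fold_reference(self, lam, rng):
        epochs = make_epochs(
            n_trials=14, n_channels=5, n_times=6, data=rng.standard_normal((14, 5, 6))
        )
        y = np.array([0, 1] * 7)
        window = (epochs.times[0], epochs.times[-1])
        fast = loocv_dvalues(epochs, "perceptual", window, lam=lam, labels=y).values
        ref = _loocv_reference(epochs, y, window, lam=lam)
        np.testing.assert_allclose(fast, ref, rtol=1e-8, atol=1e-10)

    def test_unbalanced_classes_match_reference(self, rng):
        epochs = make_epochs(
            n_trials=13, n_channels=4, n_times=4, data=rng.standard_normal((13, 4, 4))
        )
        y = np.array([0] * 5 + [1] * 8)
        window = (epochs.times[0], epochs.times[-1])
        fast = loocv_dvalues(epochs, "perceptual", window, labels=y).values
        ref = _loocv_reference(epochs, y, window)
        np.testing.assert_allclose(fast, ref, rtol=1e-8, atol=1e-10)

    def test_label_poisoning_leaves_heldout_d_unchanged(self, rng):
        """Leave-one-out never trains on the evaluated trial."""
        epochs = make_epochs(
            n_trials=12, n_channels=4, n_times=5, data=rng.standard_normal((12, 4, 5))
        )
        y = np.array([0, 1] * 6)
        window = (epochs.times[0], epochs.times[-1])
        base = loocv_dvalues(epochs, "perceptual", window, labels=y).values
        for trial in (0, 5, 11):
            poisoned = y.copy()
            poisoned[trial] = 1 - poisoned[trial]
            out = loocv_dvalues(epochs, "perceptual", window, labels=poisoned).values
            np.testing.assert_allclose(out[trial], base[trial], atol=1e-9)

    def test_trial_permutation_equivariance(self, rng):
        epochs = make_epochs(
            n_trials=12, n_channels=4, n_times=5, data=rng.standard_normal((12, 4, 5))
        )
        y = np.array([0, 1] * 6)
        window = (epochs.times[0], epochs.times[-1])
        base = loocv_dvalues(epochs, "perceptual", window, labels=y).values
        perm = rng.permutation(12)
        permuted = loocv_dvalues(
            epochs.select_trials(perm), "perceptual", window, labels=y[perm]
        ).values
        np.testing.assert_allclose(permuted, base[perm], rtol=1e-9, atol=1e-10)

    def test_voltage_scale_leaves_sign_unchanged(self, rng):
        data = rng.standard_normal((12, 4, 5))
        y = np.array([0, 1] * 6)
        a = make_epochs(n_trials=12, n_channels=4, n_times=5, data=data)
        b = make_epochs(n_trials=12, n_channels=4, n_times=5, data=data * 37.5)
        window = (a.times[0], a.times[-1])
        da = loocv_dvalues(a, "perceptual", window, labels=y).values
        db = loocv_dvalues(b, "perceptual", window, labels=y).values
        np.testing.assert_array_equal(np.sign(da), np.sign(db))

    def test_snr_zero_mean_aligned_d_near_zero(self):
        epochs = make_epochs(n_trials=48, n_channels=8, n_times=40, seed=3)
        y = label_vector(epochs.trials, "perceptual")
        series = align_signs(
            loocv_dvalues(epochs, "perceptual", (epochs.times[0], epochs.times[-1])), y
        )
        mean_d = series.values.mean(axis=0)
        se = series.values.std(axis=0, ddof=1) / np.sqrt(series.n_trials)
        assert (np.abs(mean_d) <= 2.5 * se).mean() > 0.9  # within ±2 SE at most timepoints

    def test_window_outside_epochs_rejected(self, small_epochs):
        with pytest.raises(ValueError):
            loocv_dvalues(small_epochs, "perceptual", (9000.0, 9999.0))
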