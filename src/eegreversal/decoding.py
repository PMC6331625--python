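"""Per-timepoint two-class LDA decoding with shrinkage and leave-one-out CV.

At every timepoint the raw channel amplitudes of that single timepoint are
the feature vector. A linear discriminant with a shrinkage-regularized
pooled within-class covariance,

    S* = (1 − λ) S + λ ν I,   ν = trace(S) / n_channels,

is trained on all trials but one and evaluated on the held-out trial,
yielding a signed decision value (*d* value) per trial and timepoint: the
geometric distance to the separating hyperplane (weights normalized to
unit length, hyperplane at 0). When λ is not fixed it is chosen
analytically per training fold by the Ledoit–Wolf rule for the νI target.

Exhaustive leave-one-out at every timepoint is made affordable by a single
eigendecomposition per timepoint of the label-independent *total* scatter
matrix; each fold's pooled within-class scatter then differs from it by
exactly two rank-one terms (the removed trial and the between-class
component), which are inverted in closed form (Woodbury identity) in the
shared eigenbasis. :func:`_loocv_reference` retrains a classifier from
scratch per fold and serves as the independent oracle in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import ContainerError, DValueSeries, EpochSet, label_vector


class DecodingError(ValueError):
    pass


@dataclass
class ClassifierModel:
    """Trained LDA with unit-norm weights (d values are geometric distances)."""

    weights: np.ndarray
    bias: float
    class_order: tuple = (0, 1)
    shrinkage_lambda: float = np.nan
    trained_time_ms: float = np.nan


# ---------------------------------------------------------------------------
# single-timepoint training and evaluation
# ---------------------------------------------------------------------------

def _lw_lambda(scatter_sq: float, trace: float, quartic_sum: float, n: int, p: int) -> float:
    """Ledoit–Wolf shrinkage intensity toward νI from sufficient statistics.

    ``scatter_sq`` = ‖scatter‖²_F, ``trace`` = tr(scatter), ``quartic_sum`` =
    Σ_k ‖y_k‖⁴ over class-centred samples, ``n`` samples, ``p`` channels.
    """
    d2 = (scatter_sq - trace**2 / p) / n**2
    if d2 <= np.finfo(float).tiny * max(1.0, scatter_sq):
        return 1.0
    b2 = (quartic_sum - scatter_sq / n) / n**2
    return float(np.clip(b2 / d2, 0.0, 1.0))


def train_lda_shrinkage(
    samples: np.ndarray,
    labels: np.ndarray,
    lam: float | None = None,
    trained_time_ms: float = np.nan,
) -> ClassifierModel:
    """Train a shrinkage-LDA on channel vectors with binary labels.

    Weights solve ``S* w = μ₁ − μ₀`` with ``S* = (1−λ)S + λνI`` built from
    the pooled within-class scatter; the decision value is zero at the
    class-mean midpoint. Weights and bias are returned scaled to unit
    weight norm so decision values are geometric distances.
    """
    X = np.asarray(samples, dtype=float)
    y = np.asarray(labels)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise DecodingError("samples must be (n, channels) matching labels")
    n, p = X.shape
    classes = np.unique(y)
    if classes.shape[0] != 2:
        raise DecodingError(f"need exactly 2 classes, got {classes.tolist()}")
    X0, X1 = X[y == classes[0]], X[y == classes[1]]
    if min(len(X0), len(X1)) < 2:
        raise DecodingError("need at least 2 samples per class")
    mu0, mu1 = X0.mean(axis=0), X1.mean(axis=0)
    Y = np.concatenate([X0 - mu0, X1 - mu1], axis=0)
    scatter = Y.T @ Y
    trace = float(np.trace(scatter))
    if lam is None:
        lam = _lw_lambda(
            float(np.sum(scatter**2)),
            trace,
            float(np.sum(np.sum(Y**2, axis=1) ** 2)),
            n,
            p,
        )
    if not 0.0 <= lam <= 1.0:
        raise DecodingError(f"shrinkage lambda {lam} outside [0, 1]")
    nu = trace / p
    s_star = (1.0 - lam) * scatter + lam * nu * np.eye(p)
    w = np.linalg.solve(s_star, mu1 - mu0)
    norm = np.linalg.norm(w)
    if norm == 0:
        raise DecodingError("degenerate classifier: zero weight vector")
    w = w / norm
    bias = -float(w @ (mu0 + mu1)) / 2.0
    return ClassifierModel(
        weights=w,
        bias=bias,
        class_order=(classes[0], classes[1]),
        shrinkage_lambda=float(lam),
        trained_time_ms=trained_time_ms,
    )


def dvalue(model: ClassifierModel, sample: np.ndarray) -> float:
    """Signed geometric distance of one channel vector from the hyperplane."""
    x = np.asarray(sample, dtype=float)
    if x.shape != model.weights.shape:
        raise DecodingError(
            f"sample shape {x.shape} does not match weights {model.weights.shape}"
        )
    return float(model.weights @ x + model.bias)


# ---------------------------------------------------------------------------
# trial-set operations
# ---------------------------------------------------------------------------

def undersample(epochs: EpochSet, label_dim: str, seed) -> EpochSet:
    """Randomly subsample the majority class to the minority count.

    Applied once per classifier per participant, at the trial-set level.
    Already-balanced input is returned unchanged (same trials, same order);
    otherwise the kept majority trials are drawn without replacement and
    the original trial order is preserved.
    """
    y = label_vector(epochs.trials, label_dim)
    n1, n0 = int(y.sum()), int((1 - y).sum())
    if n0 == 0 or n1 == 0:
        raise DecodingError(f"label dimension {label_dim!r} has an empty class")
    if n0 == n1:
        return epochs
    rng = np.random.default_rng(seed)
    majority = int(n1 > n0)
    keep_minority = np.flatnonzero(y != majority)
    majority_idx = np.flatnonzero(y == majority)
    keep_majority = rng.choice(majority_idx, size=min(n0, n1), replace=False)
    keep = np.sort(np.concatenate([keep_minority, keep_majority]))
    return epochs.select_trials(keep)


def align_signs(dvals: DValueSeries, true_labels: np.ndarray) -> DValueSeries:
    """Invert the d values of negative-class trials so positive = correct."""
    if dvals.aligned:
        raise DecodingError("d values are already sign-aligned")
    y = np.asarray(true_labels)
    if y.shape[0] != dvals.n_trials:
        raise DecodingError("labels do not match the number of trials")
    signs = np.where(y == 1, 1.0, -1.0)
    return dvals.with_values(dvals.values * signs[:, None], aligned=True)


# ---------------------------------------------------------------------------
# leave-one-out engine
# ---------------------------------------------------------------------------

class LoocvEngine:
    """Reusable per-participant LOOCV machinery over a fixed time grid.

    The label-independent precomputation (per-timepoint total-scatter
    eigendecomposition, trials in the eigenbasis, Gram matrices) is shared
    across the real-label run and all shuffled-label runs on the same
    epochs, which is what makes the empirical-null stage affordable.
    """

    def __init__(
        self,
        epochs: EpochSet,
        time_window: tuple,
        stride: int = 1,
        dtype=np.float64,
    ) -> None:
        idx = epochs.time_indices(time_window)[:: max(int(stride), 1)]
        self.times = epochs.times[idx]
        X = np.ascontiguousarray(
            epochs.data[:, :, idx].transpose(2, 0, 1).astype(dtype)
        )  # (T, N, C)
        self.n_trials, self.n_channels = X.shape[1], X.shape[2]
        if self.n_trials < 4:
            raise DecodingError("leave-one-out needs at least 4 trials")
        xbar = X.mean(axis=1, keepdims=True)
        Xc = X - xbar
        total_scatter = np.einsum("tnc,tnd->tcd", Xc, Xc)
        evals, evecs = np.linalg.eigh(total_scatter)
        self.evals = np.maximum(evals, 0.0)  # (T, C)
        self.Z = np.matmul(X, evecs)  # trials in per-timepoint eigenbasis
        self.zbar = np.matmul(xbar, evecs)
        n = self.n_trials
        self.A = np.sqrt(n / (n - 1.0)) * (self.Z - self.zbar)  # removed-trial vectors
        self.G = np.matmul(self.Z, self.Z.transpose(0, 2, 1))  # (T, N, N) Gram

    def run(self, labels: np.ndarray, lam: float | None = None) -> np.ndarray:
        """d value per (trial, timepoint) under the given binary labels."""
        y = np.asarray(labels)
        if y.shape != (self.n_trials,):
            raise DecodingError("labels must be one binary value per trial")
        counts = np.array([(y == 0).sum(), (y == 1).sum()])
        if counts.min() < 2:
            raise DecodingError("need at least 2 trials per class")
        Z, G, Lam = self.Z, self.G, self.evals
        T, N, C = Z.shape
        n_tr = N - 1
        mask = np.stack([(y == 0), (y == 1)]).astype(Z.dtype)  # (2, N)
        sums = np.einsum("kn,tnc->tkc", mask, Z)  # class sums
        mus = sums / counts[None, :, None]  # (T, 2, C)
        m_full = mus[:, 1] - mus[:, 0]  # (T, C)

        n_own = counts[y]  # class size of each trial's own class
        sign = np.where(y == 1, 1.0, -1.0).astype(Z.dtype)
        mu_own = mus[:, y, :]  # (T, N, C)
        zeta = (Z - mu_own) / (n_own[None, :, None] - 1.0)
        m_i = m_full[:, None, :] - sign[None, :, None] * zeta  # per-fold mean diff

        n0p = counts[0] - (y == 0)
        n1p = counts[1] - (y == 1)
        bcoef = np.sqrt(n0p * n1p / n_tr).astype(Z.dtype)  # (N,)
        a = self.A  # (T, N, C)
        b = bcoef[None, :, None] * m_i

        a_sq = np.sum(a**2, axis=2)
        b_sq = np.sum(b**2, axis=2)
        trace_full = np.sum(Lam, axis=1)  # (T,)
        tr_S = trace_full[:, None] - a_sq - b_sq  # per-fold pooled scatter trace
        nu = tr_S / C

        if lam is None:
            lam_i = self._analytic_lambda(y, counts, mus, a, b, a_sq, b_sq, tr_S)
        else:
            if not 0.0 <= lam <= 1.0:
                raise DecodingError(f"shrinkage lambda {lam} outside [0, 1]")
            lam_i = np.full((T, N), lam, dtype=Z.dtype)

        one_m = 1.0 - lam_i
        D = one_m[:, :, None] * Lam[:, None, :] + (lam_i * nu)[:, :, None]  # (T, N, C)
        ia, ib, im = a / D, b / D, m_i / D
        # Woodbury: (D − c(aaᵀ + bbᵀ))⁻¹ m  with c = 1 − λ
        c = one_m
        k11 = 1.0 - c * np.sum(a * ia, axis=2)
        k22 = 1.0 - c * np.sum(b * ib, axis=2)
        k12 = -c * np.sum(a * ib, axis=2)
        det = k11 * k22 - k12**2
        r1 = np.sum(a * im, axis=2)
        r2 = np.sum(b * im, axis=2)
        alpha = (k22 * r1 - k12 * r2) / det
        beta = (k11 * r2 - k12 * r1) / det
        w = im + c[:, :, None] * (ia * alpha[:, :, None] + ib * beta[:, :, None])

        mu_sum = (mus[:, 0] + mus[:, 1])[:, None, :] - zeta  # μ₀' + μ₁' per fold
        centred = Z - 0.5 * mu_sum
        d = np.sum(w * centred, axis=2) / np.sqrt(np.sum(w**2, axis=2))
        return np.ascontiguousarray(d.T)  # (N, T)

    def _analytic_lambda(self, y, counts, mus, a, b, a_sq, b_sq, tr_S):
        """Per-fold Ledoit–Wolf intensity from exact rank-one downdates."""
        Z, G, Lam = self.Z, self.G, self.evals
        T, N, C = Z.shape
        n_tr = N - 1
        # ‖S_i‖²_F of the fold's pooled scatter (Λ − aaᵀ − bbᵀ in eigenbasis)
        lam_sq = np.sum(Lam**2, axis=1)[:, None]
        aLa = np.einsum("tnc,tc,tnc->tn", a, Lam, a)
        bLb = np.einsum("tnc,tc,tnc->tn", b, Lam, b)
        ab = np.sum(a * b, axis=2)
        S_sq = lam_sq + a_sq**2 + b_sq**2 - 2.0 * aLa - 2.0 * bLb + 2.0 * ab**2

        # quartic sums over fold-centred samples, via the class-centred Gram
        mask = np.stack([(y == 0), (y == 1)]).astype(Z.dtype)
        R = np.einsum("tnm,km->tnk", G, mask) / counts[None, None, :]  # x_nᵀ μ_k
        M = np.einsum("tkc,tlc->tkl", mus, mus)  # μ_kᵀ μ_l
        P = (
            G
            - R[:, :, y]
            - R[:, :, y].transpose(0, 2, 1)
            + M[:, y[:, None], y[None, :]]
        )  # z_iᵀ z_k for same-class pairs (valid where y_i == y_k)
        same = (y[:, None] == y[None, :]).astype(Z.dtype)
        w_norm = np.einsum("tnn->tn", P).copy()  # ‖z_i‖²
        A_quad = np.einsum("tnm,nm->tn", P**2, same)  # z_iᵀ S_c z_i
        V_lin = np.einsum("tnm,tm,nm->tn", P, w_norm, same)  # v_cᵀ z_i
        F_class = np.einsum("tm,km->tk", w_norm**2, mask)  # Σ‖z‖⁴ per class
        F_total = F_class.sum(axis=1, keepdims=True)
        F_own = F_class[:, y]
        n_own = counts[y].astype(Z.dtype)
        s2_class = np.einsum("tm,km->tk", w_norm, mask)
        s2_own = s2_class[:, y]

        nm1 = n_own[None, :] - 1.0
        w2 = w_norm**2
        Q_own = (
            (F_own - w2)
            + 4.0 * (A_quad - w2) / nm1**2
            + w2 / nm1**3
            + 4.0 * (V_lin - w2) / nm1
            + 2.0 * w_norm * (s2_own - w_norm) / nm1**2
            - 4.0 * w2 / nm1**3
        )
        Q = (F_total - F_own) + Q_own

        d2 = (S_sq - tr_S**2 / C) / n_tr**2
        b2 = (Q - S_sq / n_tr) / n_tr**2
        tiny = np.finfo(Z.dtype).tiny
        with np.errstate(divide="ignore", invalid="ignore"):
            lam_i = np.where(
                d2 <= tiny * np.maximum(1.0, S_sq),
                1.0,
                np.clip(b2 / d2, 0.0, 1.0),
            )
        return lam_i.astype(Z.dtype)


def loocv_dvalues(
    epochs: EpochSet,
    label_dim: str,
    time_window: tuple,
    seed=None,
    lam: float | None = None,
    stride: int = 1,
    labels: np.ndarray | None = None,
    dtype=np.float64,
) -> DValueSeries:
    """Leave-one-out d values for every trial and timepoint in the window.

    For each timepoint and trial, a shrinkage-LDA is trained on all other
    trials at that timepoint and evaluated on the held-out trial. The
    output is unaligned (sign encodes the predicted class); pass it through
    :func:`align_signs` before peak analysis. ``labels`` overrides the
    trial-table labels (used for shuffled-label null runs). ``seed`` is
    accepted for interface symmetry; leave-one-out itself is deterministic.
    """
    if labels is None:
        y = label_vector(epochs.trials, label_dim)
        kind = label_dim
    else:
        y = np.asarray(labels)
        kind = label_dim
    engine = LoocvEngine(epochs, time_window, stride=stride, dtype=dtype)
    values = engine.run(y, lam=lam)
    return DValueSeries(
        values=values,
        times=engine.times,
        trials=epochs.trials,
        classifier_kind=kind,
        aligned=False,
    )


def _loocv_reference(
    epochs: EpochSet,
    labels: np.ndarray,
    time_window: tuple,
    lam: float | None = None,
    stride: int = 1,
) -> np.ndarray:
    """Direct leave-one-out: retrain per fold. Slow; oracle for tests."""
    idx = epochs.time_indices(time_window)[:: max(int(stride), 1)]
    y = np.asarray(labels)
    n = epochs.n_trials
    out = np.empty((n, idx.shape[0]))
    for j, t in enumerate(idx):
        X = epochs.data[:, :, t]
        for i in range(n):
            keep = np.arange(n) != i
            model = train_lda_shrinkage(X[keep], y[keep], lam=lam)
            out[i, j] = dvalue(model, X[i])
    return out
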