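"""Passive-BCI stage: ErrP feature extraction and Bayesian LDA.

The temporal chain realises the 3.5-8.5 Hz ErrP bandwidth as: second-order
Butterworth lowpass at 8.5 Hz at 256 Hz, decimation to 32 Hz, second-order
highpass at 3.5 Hz at 32 Hz. Epochs span [-1, 1) s around each key press
(64 samples per channel at 32 Hz); features are the concatenated samples of
the fronto-central channels, standardised with training-fold statistics.

The classifier is BLDA in its regression formulation: targets coded to
class-balanced values (+N/N+ for error, -N/N- for correct), posterior mean

    w = beta (beta X'X + alpha I')^{-1} X' y

with the bias column unpenalised (I' has a zero at the bias entry), and the
prior precision alpha and noise precision beta set by fixed-point evidence
(log marginal likelihood) maximisation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .containers import EEGSession
from .dsp import EpochSet, FilterSpec, apply_filter, decimate, design_butterworth, make_epochs

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureMatrix",
    "Standardizer",
    "BLDAModel",
    "CVResult",
    "build_features",
    "blda_fit",
    "blda_predict",
    "preprocess_errp",
    "crossvalidate_errp",
]

ERRP_FEATURE_CHANNELS = ("Fz", "Cz", "CPz")
ERROR_LABEL = "Pass"
#: variance floor; a constant feature standardises to exactly zero
_STD_FLOOR = 1e-12


@dataclass
class FeatureMatrix:
    """Per-trial feature vectors with binary labels (+1 error, -1 correct)."""

    X: np.ndarray
    y: np.ndarray
    feature_channels: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X rows must match label length")


@dataclass
class Standardizer:
    """Per-feature zero-mean unit-variance scaling, fitted on training data only."""

    mean: np.ndarray
    std: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "Standardizer":
        mean = X.mean(axis=0)
        std = np.maximum(X.std(axis=0), _STD_FLOOR)
        return cls(mean=mean, std=std)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.std


def build_features(
    epochs: EpochSet,
    channels: Sequence[str] = ERRP_FEATURE_CHANNELS,
) -> FeatureMatrix:
    """Concatenate the selected channels' epoch samples into one row per trial.

    Labels collapse to binary: the error label ("Pass") maps to +1, everything
    else ("Turn"/"Not") to -1. Standardisation is applied separately (see
    :class:`Standardizer`) so cross-validation can use training-fold statistics.
    """
    rows = [epochs.channel_index(ch) for ch in channels]
    X = epochs.data[:, rows, :].reshape(epochs.n_trials, -1)
    y = np.where(np.asarray(epochs.labels) == ERROR_LABEL, 1, -1)
    return FeatureMatrix(X=X, y=y, feature_channels=list(channels))


# --------------------------------------------------------------------- BLDA

@dataclass
class BLDAModel:
    """Bayesian LDA posterior: weights (bias last) and evidence-optimised
    precision hyperparameters."""

    w: np.ndarray
    alpha: float
    beta: float
    n_iterations: int
    evidence_trace: list[float] = field(default_factory=list)
    converged: bool = True

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("precisions must be positive")


def _balanced_targets(y: np.ndarray) -> np.ndarray:
    n = y.size
    n_pos = int((y == 1).sum())
    n_neg = n - n_pos
    if n_pos < 2 or n_neg < 2:
        raise ValueError("need at least 2 trials per class")
    t = np.where(y == 1, n / n_pos, -n / n_neg)
    return t.astype(float)


def blda_fit(
    features: FeatureMatrix,
    tol: float = 1e-4,
    max_iter: int = 300,
    update_hyperparameters: bool = True,
    alpha0: float = 1.0,
    beta0: float = 1.0,
) -> BLDAModel:
    """Fit BLDA by evidence maximisation.

    Fixed-point updates: with A = beta X'X + alpha I' and effective parameter
    count gamma = M - alpha * tr_penalised(A^{-1}),

        alpha <- gamma / (w'w)          (w without the bias entry)
        beta  <- (N - gamma) / ||y - Xw||^2

    iterated until the relative change of both precisions falls below ``tol``
    or ``max_iter`` is reached (then the last iterate is returned with
    ``converged=False``). With ``update_hyperparameters=False`` the posterior
    mean at (alpha0, beta0) is returned — identical to ridge regression with
    penalty alpha/beta and an unpenalised intercept.
    """
    X = np.column_stack([features.X, np.ones(features.X.shape[0])])
    t = _balanced_targets(features.y)
    n, m = X.shape
    m_pen = m - 1  # bias unpenalised

    H = X.T @ X
    Xty = X.T @ t
    pen_mask = np.ones(m)
    pen_mask[-1] = 0.0

    alpha, beta = float(alpha0), float(beta0)
    evidence_trace: list[float] = []
    w = np.zeros(m)
    converged = not update_hyperparameters
    n_iter = 0

    for n_iter in range(1, max_iter + 1):
        A = beta * H + alpha * np.diag(pen_mask)
        A_inv = np.linalg.inv(A)
        w = beta * (A_inv @ Xty)
        resid = t - X @ w
        sse = float(resid @ resid)
        wtw = float(w[:-1] @ w[:-1])

        sign, logdet = np.linalg.slogdet(A)
        evidence = 0.5 * (
            m_pen * np.log(alpha) + n * np.log(beta)
            - beta * sse - alpha * wtw - logdet - n * np.log(2 * np.pi)
        )
        evidence_trace.append(float(evidence))

        if not update_hyperparameters:
            break

        gamma = m_pen - alpha * float(np.sum(np.diag(A_inv)[:-1]))
        alpha_new = gamma / max(wtw, 1e-300)
        beta_new = (n - gamma) / max(sse, 1e-300)
        alpha_new = float(np.clip(alpha_new, 1e-10, 1e10))
        beta_new = float(np.clip(beta_new, 1e-10, 1e10))
        rel = max(abs(alpha_new - alpha) / alpha, abs(beta_new - beta) / beta)
        alpha, beta = alpha_new, beta_new
        if rel < tol:
            converged = True
            break

    if not converged and update_hyperparameters:
        logger.warning("BLDA evidence iteration did not converge in %d steps", max_iter)

    return BLDAModel(
        w=w, alpha=alpha, beta=beta, n_iterations=n_iter,
        evidence_trace=evidence_trace, converged=converged,
    )


def blda_predict(model: BLDAModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scores w'x + bias and hard labels; a tie (score exactly 0) is assigned
    to the correct/non-error class (-1)."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.w.size - 1:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match model ({model.w.size - 1})"
        )
    scores = X @ model.w[:-1] + model.w[-1]
    labels = np.where(scores > 0, 1, -1)
    return scores, labels


# ------------------------------------------------------------------ the chain

def preprocess_errp(
    session: EEGSession,
    window: tuple[float, float] = (-1.0, 1.0),
    lowpass_hz: float = 8.5,
    highpass_hz: float = 3.5,
    fs_out: float = 32.0,
) -> EpochSet:
    """Run the ErrP temporal chain and epoch around each key press.

    Lowpass at 256 Hz -> decimate to 32 Hz (events decimated by the same
    stride, preserving rising edges) -> highpass at 32 Hz -> [-1, 1) s epochs.
    """
    sos_lp = design_butterworth(FilterSpec("lowpass", lowpass_hz, fs=session.fs, order=2))
    low = apply_filter(session.data, sos_lp, zero_phase=True)
    factor = int(round(session.fs / fs_out))
    dec = decimate(low, session.fs, fs_out, anti_alias=False)
    # a 100 ms press spans >= 3 samples at 32 Hz, so the stride keeps every edge
    events = session.events[::factor]
    sos_hp = design_butterworth(FilterSpec("highpass", highpass_hz, fs=fs_out, order=2))
    high = apply_filter(dec, sos_hp, zero_phase=True)
    decimated = EEGSession(
        data=high, fs=fs_out, channel_labels=session.channel_labels,
        events=events, labels=session.labels, meta=session.meta,
    )
    return make_epochs(decimated, window)


@dataclass
class CVResult:
    """Cross-validation summary for one session."""

    fold_accuracy: list[float]
    fold_balanced_accuracy: list[float]
    mean_accuracy: float
    mean_balanced_accuracy: float
    n_trials: int
    n_dropped: int
    seed: int
    extras: dict = field(default_factory=dict)


def crossvalidate_errp(
    session: EEGSession,
    k: int = 5,
    seed: int = 0,
    channels: Sequence[str] = ERRP_FEATURE_CHANNELS,
) -> CVResult:
    """Stratified k-fold CV of the full ErrP chain.

    The temporal chain runs once on the continuous recording (it is trial
    independent); standardisation and BLDA fitting are redone inside each
    fold on the training trials only.
    """
    epochs = preprocess_errp(session)
    feats = build_features(epochs, channels)
    classes, counts = np.unique(feats.y, return_counts=True)
    if classes.size < 2 or counts.min() < k:
        raise ValueError(f"each class needs at least k={k} trials, have {dict(zip(classes, counts))}")

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_acc, fold_bacc, traces = [], [], []
    for train_idx, test_idx in skf.split(feats.X, feats.y):
        scaler = Standardizer.fit(feats.X[train_idx])
        model = blda_fit(
            FeatureMatrix(scaler.transform(feats.X[train_idx]), feats.y[train_idx],
                          feats.feature_channels)
        )
        _, pred = blda_predict(model, scaler.transform(feats.X[test_idx]))
        truth = feats.y[test_idx]
        fold_acc.append(float(np.mean(pred == truth)))
        per_class = [float(np.mean(pred[truth == c] == c)) for c in (-1, 1)]
        fold_bacc.append(float(np.mean(per_class)))
        traces.append({"alpha": model.alpha, "beta": model.beta,
                       "n_iterations": model.n_iterations, "converged": model.converged})

    return CVResult(
        fold_accuracy=fold_acc,
        fold_balanced_accuracy=fold_bacc,
        mean_accuracy=float(np.mean(fold_acc)),
        mean_balanced_accuracy=float(np.mean(fold_bacc)),
        n_trials=feats.y.size,
        n_dropped=epochs.n_dropped,
        seed=seed,
        extras={"folds": traces, "channels": list(channels)},
    )
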