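"""Active-BCI stage: narrowband filter bank, CSP, variance features, LDA.

Each flicker frequency f gets a second-order Butterworth bandpass with
cutoffs (f - 0.25, f + 0.25) Hz. One-vs-rest per frequency: the trials are
filtered in the class band, a CSP spatial filter is fitted between the
class and all remaining trials, the variance of the first and last CSP
components over the 4 s stimulation window forms a 2-D feature, and a
two-class LDA scores class membership. Multi-class fusion is argmax over
the per-frequency LDA scores, with a fallback to the rest class when no
score is positive; exact ties break toward the lowest frequency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import linalg as spla
from sklearn.model_selection import StratifiedKFold

from .containers import EEGSession
from .dsp import EpochSet, FilterSpec, apply_filter, design_butterworth, make_epochs
from .errp import CVResult

logger = logging.getLogger(__name__)

__all__ = [
    "FrequencyBank",
    "CSPModel",
    "LDAModel",
    "ClassModel",
    "bank_filter",
    "csp_fit",
    "variance_features",
    "lda_fit",
    "train_ssvep_models",
    "classify_frequency",
    "stimulation_epochs",
    "crossvalidate_ssvep",
]

REST_LABEL = "rest"


@dataclass
class FrequencyBank:
    """Per-class narrowband Butterworth specs plus a broadband rest spec."""

    frequencies: Sequence[float] = (12.0, 15.0, 20.0)
    margin: float = 0.25
    fs: float = 256.0
    order: int = 2
    rest_band: tuple[float, float] = (5.0, 30.0)

    def __post_init__(self) -> None:
        self.frequencies = sorted(float(f) for f in self.frequencies)
        edges = [(f - self.margin, f + self.margin) for f in self.frequencies]
        for (lo1, hi1), (lo2, hi2) in zip(edges, edges[1:]):
            if hi1 > lo2:
                # legal (e.g. deliberately inflated margins) but selectivity suffers
                logger.warning("narrow bands overlap: (%g, %g) and (%g, %g)", lo1, hi1, lo2, hi2)

    def spec(self, class_f: float) -> FilterSpec:
        if class_f not in self.frequencies:
            raise KeyError(f"unknown class frequency {class_f}; bank has {self.frequencies}")
        return FilterSpec(
            "bandpass", (class_f - self.margin, class_f + self.margin),
            fs=self.fs, order=self.order,
        )

    def rest_spec(self) -> FilterSpec:
        return FilterSpec("bandpass", self.rest_band, fs=self.fs, order=self.order)


def bank_filter(trials: EpochSet, bank: FrequencyBank, class_f: float) -> EpochSet:
    """Zero-phase narrowband filtering of every trial in the class-f band."""
    sos = design_butterworth(bank.spec(class_f))
    data = apply_filter(trials.data, sos, zero_phase=True)
    return EpochSet(
        data=data, window=trials.window, fs=trials.fs,
        labels=list(trials.labels), channel_labels=list(trials.channel_labels),
        n_dropped=trials.n_dropped,
    )


# ---------------------------------------------------------------------- CSP

@dataclass
class CSPModel:
    """Common-spatial-pattern filters for one binary contrast.

    ``W`` rows are spatial filters sorted by generalized eigenvalue
    lambda = w'C_A w / w'(C_A + C_B)w, descending; ``retained`` holds the
    indices kept for features (first and last by default).
    """

    W: np.ndarray
    eigenvalues: np.ndarray
    retained: tuple[int, ...]


def _mean_normalized_covariance(data: np.ndarray) -> np.ndarray:
    # per-trial covariance normalized by its trace, averaged over trials
    covs = []
    for trial in data:
        c = trial @ trial.T
        tr = np.trace(c)
        if tr <= 0:
            raise ValueError("zero-variance trial in CSP input")
        covs.append(c / tr)
    return np.mean(covs, axis=0)


def csp_fit(trials_a: EpochSet | np.ndarray, trials_b: EpochSet | np.ndarray) -> CSPModel:
    """Fit CSP between two trial sets by the generalized eigenproblem
    C_A w = lambda (C_A + C_B) w.

    A rank-deficient pooled covariance is ridge-regularized by
    1e-8 x trace/channels (logged). Retained components are the first and
    last filters — the two extremes of the variance-ratio spectrum.
    """
    a = trials_a.data if isinstance(trials_a, EpochSet) else np.asarray(trials_a, float)
    b = trials_b.data if isinstance(trials_b, EpochSet) else np.asarray(trials_b, float)
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least 2 trials per class")
    if a.shape[1] != b.shape[1] or a.shape[1] < 2:
        raise ValueError("classes must share >= 2 channels")
    c_a = _mean_normalized_covariance(a)
    c_b = _mean_normalized_covariance(b)
    pooled = c_a + c_b
    n_ch = pooled.shape[0]
    eigmin = float(np.linalg.eigvalsh(pooled).min())
    if eigmin < 1e-10 * np.trace(pooled) / n_ch:
        ridge = 1e-8 * np.trace(pooled) / n_ch
        pooled = pooled + ridge * np.eye(n_ch)
        logger.warning("rank-deficient pooled covariance; applied ridge %.3e", ridge)
    evals, evecs = spla.eigh(c_a, pooled)
    order = np.argsort(evals)[::-1]
    return CSPModel(
        W=evecs[:, order].T,
        eigenvalues=np.clip(evals[order], 0.0, 1.0),
        retained=(0, n_ch - 1),
    )


def variance_features(trials: EpochSet | np.ndarray, model: CSPModel) -> np.ndarray:
    """Variance of each retained CSP component per trial (raw variance;
    a normalized-log transform is available via ``log=True`` wrappers)."""
    data = trials.data if isinstance(trials, EpochSet) else np.asarray(trials, float)
    if data.ndim == 2:
        data = data[None, ...]
    if data.shape[2] == 0:
        raise ValueError("zero-length trials")
    if data.shape[1] != model.W.shape[1]:
        raise ValueError("channel count does not match CSP model")
    filt = model.W[list(model.retained)]
    proj = np.einsum("fc,tcs->tfs", filt, data)
    return proj.var(axis=-1)


# ---------------------------------------------------------------------- LDA

@dataclass
class LDAModel:
    """Two-class LDA on variance features (pooled-covariance form).

    The bias includes the log class-prior ratio, so score 0 is the Bayes
    boundary under the training class frequencies.
    """

    w: np.ndarray
    b: float
    class_means: np.ndarray
    pooled_covariance: np.ndarray


def lda_fit(F: np.ndarray, y: np.ndarray, reg: float = 1e-9) -> LDAModel:
    """Fit a binary LDA; y in {+1, -1}. Pooled covariance is regularized by
    ``reg x trace/dim`` to stay positive definite."""
    F = np.asarray(F, float)
    y = np.asarray(y)
    m_pos = F[y == 1].mean(axis=0)
    m_neg = F[y == -1].mean(axis=0)
    n_pos, n_neg = int((y == 1).sum()), int((y == -1).sum())
    centered = np.where((y == 1)[:, None], F - m_pos, F - m_neg)
    cov = centered.T @ centered / max(F.shape[0] - 2, 1)
    cov = cov + reg * max(np.trace(cov), 1e-30) / F.shape[1] * np.eye(F.shape[1])
    w = np.linalg.solve(cov, m_pos - m_neg)
    b = -0.5 * float(w @ (m_pos + m_neg)) + float(np.log(n_pos / n_neg))
    return LDAModel(w=w, b=b, class_means=np.stack([m_neg, m_pos]), pooled_covariance=cov)


def lda_score(model: LDAModel, F: np.ndarray) -> np.ndarray:
    return np.asarray(F, float) @ model.w + model.b


# -------------------------------------------------------------- multi-class

@dataclass
class ClassModel:
    """One-vs-rest model for a single flicker frequency."""

    frequency: float
    csp: CSPModel
    lda: LDAModel


def train_ssvep_models(
    trials: EpochSet, bank: FrequencyBank
) -> dict[float, ClassModel]:
    """Train a one-vs-rest CSP+LDA model per flicker frequency.

    For each frequency f all training trials are filtered in the f band; CSP
    contrasts the class-f trials against every other trial (other flicker
    classes and rest alike), and LDA separates the two variance-feature clouds.
    """
    labels = np.asarray(trials.labels)
    models: dict[float, ClassModel] = {}
    for f in bank.frequencies:
        name = f"{f:g}Hz"
        mask = labels == name
        if mask.sum() < 2 or (~mask).sum() < 2:
            raise ValueError(f"need >= 2 trials in and out of class {name}")
        filtered = bank_filter(trials, bank, f)
        csp = csp_fit(filtered.data[mask], filtered.data[~mask])
        feats = variance_features(filtered, csp)
        lda = lda_fit(feats, np.where(mask, 1, -1))
        models[f] = ClassModel(frequency=f, csp=csp, lda=lda)
    return models


def classify_frequency(
    trial: np.ndarray,
    models: Mapping[float, ClassModel],
    bank: FrequencyBank,
) -> str:
    """Classify one trial (channels x samples): argmax of the per-frequency
    LDA scores if any is positive, else the rest class; exact ties break
    toward the lowest frequency."""
    missing = [f for f in bank.frequencies if f not in models]
    if missing:
        raise KeyError(f"missing class models for frequencies {missing}")
    trial = np.asarray(trial, float)
    best_f, best_score = None, 0.0
    for f in bank.frequencies:  # ascending: ties keep the lowest frequency
        sos = design_butterworth(bank.spec(f))
        filtered = apply_filter(trial, sos, zero_phase=True)
        feats = variance_features(filtered[None, ...], models[f].csp)
        score = float(lda_score(models[f].lda, feats)[0])
        if score > best_score:
            best_f, best_score = f, score
    return f"{best_f:g}Hz" if best_f is not None else REST_LABEL


def stimulation_epochs(session: EEGSession, stim_duration: float | None = None) -> EpochSet:
    """Cut the [0, stim_duration) s stimulation window of every block."""
    if stim_duration is None:
        stim_duration = float(session.meta.get("config", {}).get("stim_duration", 4.0))
    return make_epochs(session, (0.0, stim_duration))


def crossvalidate_ssvep(
    session: EEGSession,
    k: int = 10,
    seed: int = 0,
    bank: FrequencyBank | None = None,
) -> CVResult:
    """Stratified k-fold CV of the full SSVEP chain over stimulation blocks.

    All per-frequency CSP+LDA models are refit inside each training fold;
    accuracy counts all classes (flicker frequencies and rest). The result's
    ``extras`` carry the confusion matrix and class order.
    """
    bank = bank or FrequencyBank(fs=session.fs)
    epochs = stimulation_epochs(session)
    labels = np.asarray(epochs.labels)
    classes = [f"{f:g}Hz" for f in bank.frequencies]
    if REST_LABEL in labels:
        classes.append(REST_LABEL)
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        raise ValueError(f"each class needs at least k={k} trials")

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    idx_of = {c: i for i, c in enumerate(classes)}
    confusion = np.zeros((len(classes), len(classes)), dtype=int)
    fold_acc, fold_bacc, eig_spectra = [], [], []
    for train_idx, test_idx in skf.split(epochs.data, labels):
        train = EpochSet(
            data=epochs.data[train_idx], window=epochs.window, fs=epochs.fs,
            labels=list(labels[train_idx]), channel_labels=epochs.channel_labels,
        )
        models = train_ssvep_models(train, bank)
        pred = np.array([
            classify_frequency(epochs.data[i], models, bank) for i in test_idx
        ])
        truth = labels[test_idx]
        fold_acc.append(float(np.mean(pred == truth)))
        per_class = [float(np.mean(pred[truth == c] == c)) for c in classes if (truth == c).any()]
        fold_bacc.append(float(np.mean(per_class)))
        for t_lab, p_lab in zip(truth, pred):
            confusion[idx_of[t_lab], idx_of[p_lab]] += 1
        eig_spectra.append({f"{f:g}Hz": models[f].csp.eigenvalues.tolist() for f in bank.frequencies})

    return CVResult(
        fold_accuracy=fold_acc,
        fold_balanced_accuracy=fold_bacc,
        mean_accuracy=float(np.mean(fold_acc)),
        mean_balanced_accuracy=float(np.mean(fold_bacc)),
        n_trials=labels.size,
        n_dropped=epochs.n_dropped,
        seed=seed,
        extras={"classes": classes, "confusion_matrix": confusion.tolist(),
                "eigenvalue_spectra": eig_spectra},
    )
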