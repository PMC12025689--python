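"""Mental-workload stage: cleaning, 5 s epochs, band powers, spectral indices.

Cleaning is a 0.5-20 Hz zero-phase Butterworth bandpass followed by average
referencing (the synthetic data carry no ocular/muscle artifacts, so the
cleaning hook is deliberately simple; an ICA step can be inserted before the
re-reference if real recordings are analysed). Each key-press/stimulus event
opens a [0, 5) s epoch; per epoch the Welch PSD of Fz, Cz and Oz yields
Theta/Alpha/Beta band powers, averaged across the three channels before
forming the four indices:

    MFI         = (alpha + theta) / beta
    theta_alpha = theta / alpha
    beta_alpha  = beta / alpha
    alpha_ratio = alpha / (alpha + beta + theta)

Session-level fatigue is summarised as the difference of index means between
the last and first 20% of epochs (configurable fraction).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import EEGSession
from .dsp import BandTable, EpochSet, FilterSpec, apply_filter, band_power, design_butterworth, make_epochs, welch_psd

logger = logging.getLogger(__name__)

__all__ = [
    "WORKLOAD_CHANNELS",
    "SessionDelta",
    "clean_for_workload",
    "workload_epochs",
    "indices_from_band_powers",
    "compute_indices",
    "start_end_delta",
]

WORKLOAD_CHANNELS = ("Fz", "Cz", "Oz")
INDEX_COLUMNS = ("mfi", "theta_alpha", "beta_alpha", "alpha_ratio")
_BETA_FLOOR = 1e-12


def clean_for_workload(session: EEGSession) -> EEGSession:
    """0.5-20 Hz zero-phase bandpass on all channels, then average reference."""
    sos = design_butterworth(FilterSpec("bandpass", (0.5, 20.0), fs=session.fs, order=2))
    out = session.copy()
    out.data = apply_filter(out.data, sos, zero_phase=True)
    out.data -= out.data.mean(axis=0, keepdims=True)
    return out


def workload_epochs(session: EEGSession, duration: float = 5.0) -> EpochSet:
    """One [0, duration) s epoch per event; epochs past the recording end are
    dropped with a warning."""
    onsets = session.event_onsets()
    if onsets.size == 0:
        logger.warning("session has no events; returning an empty epoch set")
    return make_epochs(session, (0.0, duration))


def indices_from_band_powers(
    theta: np.ndarray, alpha: np.ndarray, beta: np.ndarray
) -> pd.DataFrame:
    """The four spectral indices from (per-epoch) band powers.

    Beta below the floor is clamped and flagged rather than dropped, so the
    epoch count stays intact.
    """
    theta = np.atleast_1d(np.asarray(theta, float))
    alpha = np.atleast_1d(np.asarray(alpha, float))
    beta = np.atleast_1d(np.asarray(beta, float))
    flagged = beta < _BETA_FLOOR
    beta_safe = np.maximum(beta, _BETA_FLOOR)
    alpha_safe = np.maximum(alpha, _BETA_FLOOR)
    total = np.maximum(alpha + beta + theta, _BETA_FLOOR)
    return pd.DataFrame({
        "theta": theta,
        "alpha": alpha,
        "beta": beta,
        "mfi": (alpha + theta) / beta_safe,
        "theta_alpha": theta / alpha_safe,
        "beta_alpha": beta / alpha_safe,
        "alpha_ratio": alpha / total,
        "flagged": flagged,
    })


def compute_indices(
    epochs: EpochSet,
    channels: Sequence[str] = WORKLOAD_CHANNELS,
    bands: BandTable = BandTable(),
    segment_seconds: float = 1.0,
    overlap_fraction: float = 0.5,
) -> pd.DataFrame:
    """Per-epoch band powers (averaged over the requested channels) and the
    four workload indices, in temporal order."""
    rows = [epochs.channel_index(ch) for ch in channels]
    theta = np.empty(epochs.n_trials)
    alpha = np.empty(epochs.n_trials)
    beta = np.empty(epochs.n_trials)
    for i in range(epochs.n_trials):
        powers = np.zeros(3)
        for r in rows:
            psd = welch_psd(epochs.data[i, r], epochs.fs,
                            segment_seconds=segment_seconds,
                            overlap_fraction=overlap_fraction)
            powers += [band_power(psd, bands.theta),
                       band_power(psd, bands.alpha),
                       band_power(psd, bands.beta)]
        theta[i], alpha[i], beta[i] = powers / len(rows)
    df = indices_from_band_powers(theta, alpha, beta)
    df.insert(0, "epoch_index", np.arange(epochs.n_trials))
    return df


@dataclass
class SessionDelta:
    """End-minus-start means of each index over disjoint edge segments."""

    start_mean: dict[str, float]
    end_mean: dict[str, float]
    delta: dict[str, float]
    segment_fraction: float
    n_segment: int


def start_end_delta(indices: pd.DataFrame, segment_fraction: float = 0.2) -> SessionDelta:
    """Mean of each index over the first and last ``segment_fraction`` of
    epochs (temporal order) and their difference."""
    if not 0 < segment_fraction <= 0.5:
        raise ValueError("segment_fraction must lie in (0, 0.5] for disjoint segments")
    n = len(indices)
    n_seg = int(round(n * segment_fraction))
    if n_seg < 2:
        raise ValueError(f"need >= 2 epochs per segment, got {n_seg}")
    cols = [c for c in ("theta", "alpha", "beta", *INDEX_COLUMNS) if c in indices.columns]
    head = indices.iloc[:n_seg]
    tail = indices.iloc[n - n_seg:]
    start = {c: float(head[c].mean()) for c in cols}
    end = {c: float(tail[c].mean()) for c in cols}
    delta = {c: end[c] - start[c] for c in cols}
    return SessionDelta(start_mean=start, end_mean=end, delta=delta,
                        segment_fraction=segment_fraction, n_segment=n_seg)
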