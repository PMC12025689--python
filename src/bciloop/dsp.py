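"""Deterministic DSP primitives shared by all pipelines.

Butterworth design/application (zero-phase by default for offline analysis,
causal behind a flag), integer-factor decimation, event-locked epoching with
half-open ``[start, end)`` windows, Welch spectra (Hann, one-sided density)
and trapezoid band powers on half-open frequency bands.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .containers import EEGSession

logger = logging.getLogger(__name__)

__all__ = [
    "FilterSpec",
    "EpochSet",
    "PSD",
    "BandTable",
    "design_butterworth",
    "apply_filter",
    "decimate",
    "make_epochs",
    "welch_psd",
    "band_power",
]


# ---------------------------------------------------------------- filtering

@dataclass(frozen=True)
class FilterSpec:
    """Butterworth filter specification.

    ``cutoffs`` is a single frequency for lowpass/highpass or an ``(lo, hi)``
    pair for bandpass; all cutoffs must lie strictly inside ``(0, fs/2)``.
    """

    kind: str  # 'lowpass' | 'highpass' | 'bandpass'
    cutoffs: float | tuple[float, float]
    fs: float
    order: int = 2
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("lowpass", "highpass", "bandpass"):
            raise ValueError(f"unknown filter kind {self.kind!r}")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.order < 1:
            raise ValueError("order must be >= 1")
        nyq = self.fs / 2.0
        cut = np.atleast_1d(np.asarray(self.cutoffs, dtype=float))
        if self.kind == "bandpass":
            if cut.size != 2:
                raise ValueError("bandpass needs (low, high) cutoffs")
            if not cut[0] < cut[1]:
                raise ValueError("bandpass requires low < high")
        elif cut.size != 1:
            raise ValueError(f"{self.kind} takes a single cutoff")
        if np.any(cut <= 0) or np.any(cut >= nyq):
            raise ValueError(f"cutoffs {self.cutoffs} must lie strictly inside (0, {nyq})")


def design_butterworth(spec: FilterSpec) -> np.ndarray:
    """Design a Butterworth filter, returned as second-order sections.

    The returned SOS cascade is stable (all poles strictly inside the unit
    circle) and has the textbook -3 dB magnitude at each cutoff.
    """
    btype = {"lowpass": "lowpass", "highpass": "highpass", "bandpass": "bandpass"}[spec.kind]
    sos = sps.butter(spec.order, spec.cutoffs, btype=btype, fs=spec.fs, output="sos")
    return sos


def apply_filter(x: np.ndarray, sos: np.ndarray, zero_phase: bool = True) -> np.ndarray:
    """Filter along the last axis, per channel.

    Zero-phase mode runs forward-backward passes (no phase lag, squared
    magnitude response); causal mode is a single forward pass.
    """
    x = np.asarray(x, dtype=float)
    sos = np.atleast_2d(sos)
    eff_order = 2 * sos.shape[0]
    if x.shape[-1] <= 3 * eff_order:
        raise ValueError(
            f"signal length {x.shape[-1]} too short for order-{eff_order} filter "
            f"(need > {3 * eff_order} samples)"
        )
    if zero_phase:
        return sps.sosfiltfilt(sos, x, axis=-1)
    return sps.sosfilt(sos, x, axis=-1)


def decimate(
    x: np.ndarray,
    fs_in: float,
    fs_out: float,
    anti_alias: bool = False,
) -> np.ndarray:
    """Downsample by an integer factor, keeping every k-th sample from index 0.

    With ``anti_alias=True`` a zero-phase order-4 Butterworth lowpass at
    0.4 x fs_out is applied first; otherwise the caller is expected to have
    band-limited the signal already (as the ErrP chain does).
    """
    factor = fs_in / fs_out
    if abs(factor - round(factor)) > 1e-9 or factor < 1:
        raise ValueError(f"fs_in/fs_out must be a positive integer, got {factor}")
    factor = int(round(factor))
    x = np.asarray(x, dtype=float)
    if anti_alias and factor > 1:
        sos = design_butterworth(FilterSpec("lowpass", 0.4 * fs_out, fs=fs_in, order=4))
        x = apply_filter(x, sos, zero_phase=True)
    return x[..., ::factor]


# ----------------------------------------------------------------- epoching

@dataclass
class EpochSet:
    """Event-locked epochs: trials x channels x samples, window [start, end)."""

    data: np.ndarray
    window: tuple[float, float]
    fs: float
    labels: list[str]
    channel_labels: list[str] = field(default_factory=list)
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be 3-D (trials x channels x samples)")
        n_expected = int(round((self.window[1] - self.window[0]) * self.fs))
        if self.data.shape[2] != n_expected:
            raise ValueError(
                f"samples per epoch {self.data.shape[2]} != round((end-start)*fs) = {n_expected}"
            )
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("labels length must equal trial count")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"unknown channel label {label!r}") from None


def make_epochs(session: EEGSession, window: tuple[float, float]) -> EpochSet:
    """Cut one epoch per rising edge of the event channel.

    The epoch spans ``[event + window[0], event + window[1])`` seconds; labels
    are copied from the session's trial sequence in temporal order. Events
    whose window would cross a recording boundary are dropped with a logged
    warning, counted in ``n_dropped``.
    """
    start, end = window
    if not end > start:
        raise ValueError("window end must exceed start")
    fs = session.fs
    n_samp = int(round((end - start) * fs))
    off = int(round(start * fs))
    onsets = session.event_onsets()
    labels = list(session.labels)
    if labels and len(labels) != len(onsets):
        raise ValueError(
            f"label sequence length {len(labels)} does not match event count {len(onsets)}"
        )
    kept, kept_labels, dropped = [], [], 0
    for k, onset in enumerate(onsets):
        i0 = onset + off
        i1 = i0 + n_samp
        if i0 < 0 or i1 > session.n_samples:
            dropped += 1
            continue
        kept.append(session.data[:, i0:i1])
        kept_labels.append(labels[k] if labels else "")
    if dropped:
        logger.warning("dropped %d epoch(s) crossing the recording boundary", dropped)
    data = np.stack(kept) if kept else np.empty((0, session.n_channels, n_samp))
    return EpochSet(
        data=data,
        window=(start, end),
        fs=fs,
        labels=kept_labels,
        channel_labels=list(session.channel_labels),
        n_dropped=dropped,
    )


# ------------------------------------------------------------------ spectra

@dataclass
class PSD:
    """One-sided power spectral density (µV²/Hz) on an ascending grid."""

    freqs: np.ndarray
    power: np.ndarray
    resolution: float

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.freqs.shape != self.power.shape:
            raise ValueError("freqs and power must have the same shape")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly ascending")
        if np.any(self.power < -1e-30):
            raise ValueError("power must be non-negative")


@dataclass(frozen=True)
class BandTable:
    """Canonical EEG band edges, half-open ``[lo, hi)`` in Hz."""

    delta: tuple[float, float] = (0.5, 4.0)
    theta: tuple[float, float] = (4.0, 8.0)
    alpha: tuple[float, float] = (8.0, 13.0)
    beta: tuple[float, float] = (13.0, 30.0)


def welch_psd(
    x: np.ndarray,
    fs: float,
    segment_seconds: float = 1.0,
    overlap_fraction: float = 0.5,
    detrend: str | bool = "constant",
) -> PSD:
    """Welch PSD of a single channel: Hann windows, overlapping segments,
    one-sided density convention (integrates to the signal variance)."""
    x = np.asarray(x, dtype=float)
    nperseg = int(round(segment_seconds * fs))
    if nperseg < 2:
        raise ValueError("segment too short")
    if x.shape[-1] < nperseg:
        raise ValueError(
            f"epoch length {x.shape[-1]} shorter than segment length {nperseg}"
        )
    noverlap = int(round(overlap_fraction * nperseg))
    freqs, power = sps.welch(
        x,
        fs=fs,
        window="hann",
        nperseg=nperseg,
        noverlap=noverlap,
        detrend=detrend,
        scaling="density",
    )
    return PSD(freqs=freqs, power=np.maximum(power, 0.0), resolution=fs / nperseg)


def band_power(psd: PSD, band: tuple[float, float]) -> float:
    """Integrate the density over ``[lo, hi)`` by the trapezoid rule.

    Band edges are linearly interpolated onto the PSD grid so that flat unit
    density over a band of width W integrates to exactly W, and contiguous
    bands sum to the power of their union.
    """
    lo, hi = band
    if not hi > lo:
        raise ValueError("band must have positive width")
    if lo < 0 or hi > psd.freqs[-1] + 1e-12:
        raise ValueError(f"band {band} outside the PSD grid [0, {psd.freqs[-1]}]")
    inside = psd.freqs[(psd.freqs > lo) & (psd.freqs < hi)]
    grid = np.concatenate(([lo], inside, [hi]))
    dens = np.interp(grid, psd.freqs, psd.power)
    return float(np.trapezoid(dens, grid))
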