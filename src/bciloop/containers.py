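"""Core in-memory containers shared by every pipeline stage.

An :class:`EEGSession` is a continuous multichannel recording (µV) at a fixed
sampling rate, together with a binary event channel ("KeyDown"-style: 1 while
a key is pressed or a stimulus onset is flagged, 0 otherwise) and the ordered
per-trial label sequence. Events carry latency only; identity comes from the
label sequence, matched to rising edges in temporal order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np

__all__ = ["EEGSession"]


@dataclass
class EEGSession:
    """Continuous EEG recording with event channel and trial labels.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in µV.
    fs : float
        Sampling rate in Hz.
    channel_labels : sequence of str
        Unique electrode names, one per row of ``data``.
    events : ndarray, shape (n_samples,)
        Binary event channel; values must be exactly 0 or 1.
    labels : sequence of str
        Per-trial labels in the true trial order (one per rising edge).
    meta : dict
        Free-form provenance (generator config echo, seed, ...).
    """

    data: np.ndarray
    fs: float
    channel_labels: Sequence[str]
    events: np.ndarray
    labels: Sequence[str] = field(default_factory=list)
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        labels = list(self.channel_labels)
        if len(labels) != self.data.shape[0]:
            raise ValueError("channel_labels length must match data rows")
        if len(set(labels)) != len(labels):
            raise ValueError("channel_labels must be unique")
        self.channel_labels = labels
        self.events = np.asarray(self.events)
        if self.events.shape != (self.data.shape[1],):
            raise ValueError("events must be 1-D with one entry per sample")
        vals = np.unique(self.events)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"event channel must be binary 0/1, found values {vals}")
        self.events = self.events.astype(np.int8)
        self.labels = list(self.labels)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"unknown channel label {label!r}; have {self.channel_labels}") from None

    def event_onsets(self) -> np.ndarray:
        """Sample indices of rising edges of the event channel."""
        ev = self.events
        edges = np.flatnonzero(np.diff(ev.astype(np.int8)) == 1) + 1
        if ev[0] == 1:
            edges = np.concatenate(([0], edges))
        return edges

    def copy(self) -> "EEGSession":
        return EEGSession(
            data=self.data.copy(),
            fs=self.fs,
            channel_labels=list(self.channel_labels),
            events=self.events.copy(),
            labels=list(self.labels),
            meta=dict(self.meta),
        )
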