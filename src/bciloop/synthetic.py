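"""Synthetic EEG session generator for the two BCI protocols.

Emulates (i) an oddball passive protocol: 200 trials at a 6 s pace, 20% of
them error trials whose key-press event is followed by an error-related
potential (a negative ERN bump at 50-200 ms and a positive Pe bump at
200-500 ms) on the fronto-central channels; and (ii) an active SSVEP
protocol: 4 s flicker blocks at 12/15/20 Hz plus a rest condition, the
attended frequency (with a half-amplitude second harmonic) expressed on the
occipital channels. A linear within-session gain on Alpha/Theta band power
emulates rising fatigue.

Background noise is 1/f-shaped with a shared 10 Hz rhythm and fixed spatial
mixing; each channel is normalised to a configured RMS, and ``snr`` always
means template (or flicker) peak amplitude divided by that background RMS.
Realistic artifacts (blinks, EMG) and volume conduction are deliberately not
modelled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .containers import EEGSession
from .dsp import FilterSpec, apply_filter, design_butterworth

__all__ = [
    "DEFAULT_CHANNELS",
    "SessionConfig",
    "ErrPTemplate",
    "SSVEPConfig",
    "FatigueDrift",
    "make_background",
    "errp_waveform",
    "generate_errp_session",
    "generate_ssvep_session",
    "apply_fatigue_drift",
]

DEFAULT_CHANNELS = ("Fz", "Cz", "CPz", "Oz", "PO7", "O1", "O2", "Iz")

#: channels carrying the ErrP template (fronto-central locus)
ERRP_CHANNELS = ("Fz", "Cz", "CPz")

#: relative flicker gain of the occipital channels
DEFAULT_OCCIPITAL_GAIN = {"Oz": 1.0, "O1": 0.8, "O2": 0.8, "PO7": 0.6, "Iz": 0.6}


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


# ------------------------------------------------------------------ configs

@dataclass
class SessionConfig:
    """Passive (oddball / ErrP) protocol parameters.

    ``snr`` is the injected ErrP peak amplitude divided by the background
    per-channel RMS. The response ("KeyDown") time is drawn uniformly in
    ``response_window`` seconds within each trial; the press lasts
    ``press_duration`` seconds.
    """

    n_trials: int = 200
    error_rate: float = 0.2
    fs: float = 256.0
    channel_labels: Sequence[str] = DEFAULT_CHANNELS
    inter_trial_interval: float = 6.0
    snr: float = 1.0
    background_rms: float = 10.0
    response_window: tuple[float, float] = (2.5, 4.5)
    press_duration: float = 0.1
    tail_padding: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials <= 0:
            raise ValueError("n_trials must be positive")
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate must lie in [0, 1]")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        labels = list(self.channel_labels)
        if len(set(labels)) != len(labels):
            raise ValueError("channel_labels must be unique")
        self.channel_labels = labels
        lo, hi = self.response_window
        if not 0 < lo < hi < self.inter_trial_interval:
            raise ValueError("response_window must lie inside the trial")

    @property
    def n_error_trials(self) -> int:
        """Nearest-integer (half-up) error-trial count — enforced exactly."""
        return _round_half_up(self.n_trials * self.error_rate)


@dataclass
class ErrPTemplate:
    """Two-component error-related potential template (Gaussian bumps)."""

    ern_latency: float = 0.10  # s, must lie in [0.05, 0.20]
    ern_amplitude: float = -5.0  # µV, <= 0
    pe_latency: float = 0.30  # s, must lie in [0.20, 0.50]
    pe_amplitude: float = 5.0  # µV, >= 0
    component_width: float = 0.04  # s, Gaussian SD

    def __post_init__(self) -> None:
        if not 0.05 <= self.ern_latency <= 0.20:
            raise ValueError("ern_latency must lie in [0.05, 0.20] s")
        if not 0.20 <= self.pe_latency <= 0.50:
            raise ValueError("pe_latency must lie in [0.20, 0.50] s")
        if not self.ern_latency < self.pe_latency:
            raise ValueError("ern_latency must precede pe_latency")
        if self.ern_amplitude > 0 or self.pe_amplitude < 0:
            raise ValueError("require ern_amplitude <= 0 <= pe_amplitude")
        if self.component_width <= 0:
            raise ValueError("component_width must be positive")

    @property
    def peak(self) -> float:
        return max(abs(self.ern_amplitude), abs(self.pe_amplitude))


@dataclass
class SSVEPConfig:
    """Active (SSVEP) protocol parameters.

    Each block is ``stim_duration`` s of flicker followed by a
    ``break_duration`` s pause; the attended frequency plus a half-amplitude
    second harmonic is added to the occipital channels, weighted by
    ``occipital_gain`` and scaled so the Oz peak amplitude is
    ``snr x background_rms``.
    """

    frequencies: Sequence[float] = (12.0, 15.0, 20.0)
    stim_duration: float = 4.0
    break_duration: float = 2.0
    trials_per_class: int = 40
    rest_class: bool = True
    fs: float = 256.0
    channel_labels: Sequence[str] = DEFAULT_CHANNELS
    occipital_gain: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_OCCIPITAL_GAIN)
    )
    harmonic_amplitude: float = 0.5
    snr: float = 1.0
    background_rms: float = 10.0
    press_duration: float = 0.1
    tail_padding: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        freqs = [float(f) for f in self.frequencies]
        if len(set(freqs)) != len(freqs):
            raise ValueError("frequencies must be distinct")
        if any(f <= 0 or f >= self.fs / 2 for f in freqs):
            raise ValueError("frequencies must lie strictly below fs/2")
        self.frequencies = freqs
        if self.stim_duration <= 0:
            raise ValueError("stim_duration must be positive")
        if self.trials_per_class <= 0:
            raise ValueError("trials_per_class must be positive")
        self.channel_labels = list(self.channel_labels)

    @property
    def class_names(self) -> list[str]:
        names = [f"{f:g}Hz" for f in self.frequencies]
        if self.rest_class:
            names.append("rest")
        return names


@dataclass(frozen=True)
class FatigueDrift:
    """End-of-session multiplicative band-power gains (1.0 = no drift)."""

    alpha_gain: float = 1.0
    theta_gain: float = 1.0

    def __post_init__(self) -> None:
        if self.alpha_gain <= 0 or self.theta_gain <= 0:
            raise ValueError("band-power gains must be strictly positive")


# --------------------------------------------------------------- background

def make_background(
    n_channels: int,
    n_samples: int,
    fs: float,
    seed: int,
    rms: float = 10.0,
    alpha_fraction: float = 0.3,
    spatial_mix: float = 0.3,
) -> np.ndarray:
    """Zero-mean 1/f-shaped background EEG with a shared 10 Hz rhythm.

    White noise is spectrally shaped to a 1/f power law (flat below 1 Hz),
    mixed across channels with a fixed weight ``spatial_mix`` toward a common
    component, and a shared 10 Hz sinusoid of relative RMS ``alpha_fraction``
    is added. Every channel is normalised to exactly ``rms`` µV RMS.
    """
    if n_channels <= 0 or n_samples <= 0:
        raise ValueError("dimensions must be positive")
    if n_samples <= fs:
        raise ValueError("need more than one second of samples")
    rng = np.random.default_rng(seed)

    white = rng.standard_normal((n_channels + 1, n_samples))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    shaping = 1.0 / np.sqrt(np.maximum(freqs, 1.0))  # amplitude ~ f^-1/2 => power ~ 1/f
    shaping[0] = 0.0  # zero mean
    pink = np.fft.irfft(spec * shaping, n=n_samples, axis=-1)
    shared, channels = pink[0], pink[1:]

    mixed = np.sqrt(1.0 - spatial_mix) * channels + np.sqrt(spatial_mix) * shared
    mixed /= mixed.std(axis=-1, keepdims=True)

    t = np.arange(n_samples) / fs
    rhythm = np.sin(2 * np.pi * 10.0 * t + rng.uniform(0, 2 * np.pi))
    rhythm = alpha_fraction * rhythm / rhythm.std()

    out = mixed + rhythm[None, :]
    out -= out.mean(axis=-1, keepdims=True)
    out *= rms / out.std(axis=-1, keepdims=True)
    return out


# ----------------------------------------------------------------- passive

def errp_waveform(template: ErrPTemplate, fs: float, duration: float) -> np.ndarray:
    """ErrP time course from event onset: negative ERN bump plus positive Pe bump."""
    needed = template.pe_latency + 3 * template.component_width
    if duration < needed:
        raise ValueError(f"duration {duration} s must cover {needed:.3f} s")
    t = np.arange(int(round(duration * fs))) / fs
    sd = template.component_width
    wave = template.ern_amplitude * np.exp(-0.5 * ((t - template.ern_latency) / sd) ** 2)
    wave += template.pe_amplitude * np.exp(-0.5 * ((t - template.pe_latency) / sd) ** 2)
    return wave


def generate_errp_session(
    config: SessionConfig | None = None,
    template: ErrPTemplate | None = None,
) -> EEGSession:
    """Generate one passive (oddball) session.

    Exactly ``round(n_trials x error_rate)`` trials (half-up) are labelled
    "Pass" (error); the remaining correct trials are split as evenly as
    possible between "Turn" and "Not". The label multiset is fixed and
    shuffled under the seed, making the 80/20 split exact by construction.
    Each trial carries one key press (rising edge) at a uniformly drawn
    response time; error trials additionally carry the ErrP template on
    Fz/Cz/CPz, scaled so its peak is ``snr x background_rms``.
    """
    config = config or SessionConfig()
    template = template or ErrPTemplate()
    rng = np.random.default_rng(config.seed)
    fs = config.fs
    iti = config.inter_trial_interval
    n_samples = int(round((config.n_trials * iti + config.tail_padding) * fs))

    n_err = config.n_error_trials
    n_corr = config.n_trials - n_err
    labels = ["Pass"] * n_err + ["Turn"] * (n_corr // 2) + ["Not"] * (n_corr - n_corr // 2)
    rng.shuffle(labels)

    data = make_background(
        len(config.channel_labels), n_samples, fs, seed=int(rng.integers(2**31)),
        rms=config.background_rms,
    )
    events = np.zeros(n_samples, dtype=np.int8)
    press = max(1, int(round(config.press_duration * fs)))

    lo, hi = config.response_window
    wave = errp_waveform(template, fs, duration=template.pe_latency + 4 * template.component_width)
    scale = config.snr * config.background_rms / template.peak
    errp_rows = [config.channel_labels.index(ch)
                 for ch in ERRP_CHANNELS if ch in config.channel_labels]

    for k, label in enumerate(labels):
        onset = int(round((k * iti + rng.uniform(lo, hi)) * fs))
        events[onset:onset + press] = 1
        if label == "Pass" and config.snr > 0:
            seg = slice(onset, onset + wave.size)
            data[errp_rows, seg] += scale * wave[: n_samples - onset]

    return EEGSession(
        data=data,
        fs=fs,
        channel_labels=config.channel_labels,
        events=events,
        labels=labels,
        meta={"protocol": "errp", "seed": config.seed, "config": config.__dict__.copy()},
    )


# ------------------------------------------------------------------ active

def generate_ssvep_session(config: SSVEPConfig | None = None) -> EEGSession:
    """Generate one active (SSVEP) session.

    Blocks of ``stim_duration`` s flicker separated by ``break_duration`` s
    pauses; each class contributes ``trials_per_class`` blocks, shuffled
    under the seed. Attended blocks add a class-frequency sinusoid plus a
    half-amplitude second harmonic to the occipital channels; rest blocks
    are background only. Block onsets are marked on the event channel.
    """
    config = config or SSVEPConfig()
    rng = np.random.default_rng(config.seed)
    fs = config.fs
    block = config.stim_duration + config.break_duration

    sequence = [name for name in config.class_names for _ in range(config.trials_per_class)]
    rng.shuffle(sequence)
    n_blocks = len(sequence)
    n_samples = int(round((n_blocks * block + config.tail_padding) * fs))

    data = make_background(
        len(config.channel_labels), n_samples, fs, seed=int(rng.integers(2**31)),
        rms=config.background_rms,
    )
    events = np.zeros(n_samples, dtype=np.int8)
    press = max(1, int(round(config.press_duration * fs)))

    freq_of = {f"{f:g}Hz": f for f in config.frequencies}
    gains = [
        (config.channel_labels.index(ch), g)
        for ch, g in config.occipital_gain.items()
        if ch in config.channel_labels
    ]
    n_stim = int(round(config.stim_duration * fs))
    t = np.arange(n_stim) / fs

    for k, name in enumerate(sequence):
        onset = int(round(k * block * fs))
        events[onset:onset + press] = 1
        if name == "rest" or config.snr == 0:
            continue
        f = freq_of[name]
        phase = rng.uniform(0, 2 * np.pi)
        flicker = np.sin(2 * np.pi * f * t + phase)
        if 2 * f < fs / 2:
            flicker = flicker + config.harmonic_amplitude * np.sin(4 * np.pi * f * t + 2 * phase)
        amp = config.snr * config.background_rms
        for row, g in gains:
            data[row, onset:onset + n_stim] += amp * g * flicker

    return EEGSession(
        data=data,
        fs=fs,
        channel_labels=config.channel_labels,
        events=events,
        labels=sequence,
        meta={"protocol": "ssvep", "seed": config.seed,
              "config": {**config.__dict__, "frequencies": list(config.frequencies)}},
    )


# ------------------------------------------------------------------- drift

_ALPHA_BAND = (8.0, 13.0)
_THETA_BAND = (4.0, 8.0)


def apply_fatigue_drift(session: EEGSession, drift: FatigueDrift) -> EEGSession:
    """Ramp Alpha/Theta band power linearly from x1 at session start to the
    configured end gain, leaving broadband content otherwise unchanged.

    The band component is isolated with a zero-phase bandpass and re-added
    with amplitude factor sqrt(g(t)) - 1, where the *power* gain g(t)
    interpolates linearly over the session.
    """
    if session.n_samples == 0:
        raise ValueError("session is empty")
    out = session.copy()
    frac = np.arange(session.n_samples) / max(session.n_samples - 1, 1)
    for band, end_gain in ((_ALPHA_BAND, drift.alpha_gain), (_THETA_BAND, drift.theta_gain)):
        if end_gain == 1.0:
            continue
        sos = design_butterworth(FilterSpec("bandpass", band, fs=session.fs, order=2))
        component = apply_filter(session.data, sos, zero_phase=True)
        gain = 1.0 + (end_gain - 1.0) * frac
        out.data += (np.sqrt(gain) - 1.0)[None, :] * component
    out.meta = {**out.meta, "fatigue_drift": {"alpha_gain": drift.alpha_gain,
                                              "theta_gain": drift.theta_gain}}
    return out
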