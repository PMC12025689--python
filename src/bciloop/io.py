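"""Session container I/O, run configuration and report writing.

A session on disk is a directory with:

* ``session.json`` — fs, channel labels, trial label sequence, event onsets
  live in ``events.csv``, config echo, seed, format version;
* ``data.f32``    — little-endian IEEE-754 float32, channels x samples,
  row-major;
* ``events.csv``  — ``onset_sample,label`` per trial.

The binary event channel is reconstructed from the onsets and the press
duration recorded in the metadata, and validated on read.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, is_dataclass
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .containers import EEGSession

__all__ = ["FORMAT_VERSION", "write_session", "read_session", "write_report", "RunConfig"]

FORMAT_VERSION = 1
PACKAGE_VERSION = "0.1.0"


def _jsonable(obj: Any) -> Any:
    if is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_session(session: EEGSession, path: str | Path) -> Path:
    """Write a session directory (metadata JSON + float32 block + events CSV)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    onsets = session.event_onsets()
    press_samples = 1
    if onsets.size:
        # longest run of ones after the first onset = press duration
        first = onsets[0]
        run = np.argmin(session.events[first:]) or (session.n_samples - first)
        press_samples = int(run)
    meta = {
        "format_version": FORMAT_VERSION,
        "package_version": PACKAGE_VERSION,
        "fs": session.fs,
        "channel_labels": list(session.channel_labels),
        "n_channels": session.n_channels,
        "n_samples": session.n_samples,
        "labels": list(session.labels),
        "press_samples": press_samples,
        "meta": _jsonable(session.meta),
    }
    (path / "session.json").write_text(json.dumps(meta, indent=1, sort_keys=True))
    session.data.astype("<f4").tofile(path / "data.f32")
    pd.DataFrame({"onset_sample": onsets,
                  "label": list(session.labels) or [""] * onsets.size}
                 ).to_csv(path / "events.csv", index=False)
    return path


def read_session(path: str | Path) -> EEGSession:
    """Read a session directory, validating sizes and event-channel binarity."""
    path = Path(path)
    meta_file = path / "session.json"
    if not meta_file.exists():
        raise FileNotFoundError(f"no session.json under {path}")
    meta = json.loads(meta_file.read_text())
    version = meta.get("format_version")
    if version != FORMAT_VERSION:
        raise ValueError(f"unknown session format version {version!r}")
    n_ch, n_samp = meta["n_channels"], meta["n_samples"]
    raw = np.fromfile(path / "data.f32", dtype="<f4")
    if raw.size != n_ch * n_samp:
        raise ValueError(
            f"binary block holds {raw.size} floats, metadata promises {n_ch * n_samp}"
        )
    data = raw.reshape(n_ch, n_samp).astype(float)
    events = np.zeros(n_samp, dtype=np.int8)
    ev = pd.read_csv(path / "events.csv") if (path / "events.csv").exists() else None
    labels = meta.get("labels", [])
    if ev is not None and len(ev):
        press = int(meta.get("press_samples", 1))
        for onset in ev["onset_sample"].to_numpy():
            if not 0 <= onset < n_samp:
                raise ValueError(f"event onset {onset} outside the recording")
            events[onset:onset + press] = 1
    return EEGSession(
        data=data, fs=float(meta["fs"]), channel_labels=meta["channel_labels"],
        events=events, labels=labels, meta=meta.get("meta", {}),
    )


def write_report(results: Any, path: str | Path, table: pd.DataFrame | None = None) -> Path:
    """Write a machine-readable JSON report (sorted keys, config/seed echo);
    an optional tabular companion goes to the same stem with ``.csv``."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = _jsonable(results)
    if isinstance(payload, dict):
        payload.setdefault("package_version", PACKAGE_VERSION)
    path.write_text(json.dumps(payload, indent=1, sort_keys=True))
    if table is not None:
        table.to_csv(path.with_suffix(".csv"), index=False)
    return path


@dataclass
class RunConfig:
    """Top-level run configuration; round-trips losslessly through YAML."""

    protocol: str = "errp"  # 'errp' | 'ssvep'
    seed: int = 0
    folds: int = 5
    generator: dict[str, Any] = None  # type: ignore[assignment]
    out: str = "report.json"

    def __post_init__(self) -> None:
        if self.protocol not in ("errp", "ssvep"):
            raise ValueError("protocol must be 'errp' or 'ssvep'")
        if self.generator is None:
            self.generator = {}

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(_jsonable(asdict(self)), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))
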