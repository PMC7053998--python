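"""On-disk containers: time x channel matrices with JSON sidecars, WAV.

Signals are stored as plain CSV (one column per channel) next to a JSON
sidecar carrying the sampling rate, channel names and provenance, so every
artifact stays diffable and inspectable.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocessing import NeuralRecording

__all__ = ["save_recording", "load_recording", "write_envelope_wav"]


def save_recording(rec: NeuralRecording, path) -> None:
    """Write a recording as ``<path>.csv`` plus ``<path>.json`` sidecar."""
    path = Path(path)
    pd.DataFrame(rec.data, columns=list(rec.channel_names)).to_csv(
        path.with_suffix(".csv"), index=False, float_format="%.10g")
    sidecar = {
        "fs": rec.fs,
        "channel_names": list(rec.channel_names),
        "channel_kinds": list(rec.channel_kinds),
        "trial_id": rec.trial_id,
        "modality": rec.modality,
        "log": list(rec.log),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_recording(path) -> NeuralRecording:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    df = pd.read_csv(path.with_suffix(".csv"))
    return NeuralRecording(
        data=df[meta["channel_names"]].to_numpy(float),
        fs=float(meta["fs"]),
        channel_names=tuple(meta["channel_names"]),
        channel_kinds=tuple(meta["channel_kinds"]),
        trial_id=meta.get("trial_id", ""),
        modality=meta.get("modality", "raw"),
        log=tuple(meta.get("log", ())),
    )


def write_envelope_wav(envelope: np.ndarray, fs: float, path) -> None:
    """Write an envelope as a 16-bit mono PCM WAV (peak-normalized)."""
    from scipy.io import wavfile

    env = np.asarray(envelope, dtype=float)
    peak = np.abs(env).max()
    if peak > 0:
        env = env / peak
    wavfile.write(path, int(fs), (env * 32767).astype(np.int16))
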