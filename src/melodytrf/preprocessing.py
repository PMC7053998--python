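"""Neural-signal conditioning for EEG-like and intracranial-like recordings.

Low-rate analysis uses a 1-8 Hz zero-phase Butterworth band (order-2
high-pass then order-2 low-pass, both applied forward-backward), matching
the cortical-tracking band; intracranial analysis extracts 70-150 Hz
high-gamma power via the Hilbert transform.  Channel repair replaces
outlier-variance channels by the mean of their spatial neighbors, and
music-responsive electrodes are selected by a Cohen's d criterion between
stimulation and silence chunks.

All operations are pure: they return new recordings and append to the
provenance log rather than mutating their input.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import butter, filtfilt, hilbert, resample_poly

from .stats import cohens_d

__all__ = [
    "NeuralRecording",
    "bandpass_lowrate",
    "highgamma_power",
    "detect_and_repair_channels",
    "rereference_mastoids",
    "select_responsive_electrodes",
]


@dataclass
class NeuralRecording:
    """time x channel neural data with metadata and a provenance log."""

    data: np.ndarray
    fs: float
    channel_names: tuple
    channel_kinds: tuple | None = None  # scalp | intracranial | reference
    trial_id: str = ""
    modality: str = "raw"  # raw | low-rate | high-gamma
    log: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.channel_names = tuple(self.channel_names)
        if self.data.ndim != 2 or self.data.shape[1] != len(self.channel_names):
            raise ValueError("data must be time x channel matching names")
        if self.channel_kinds is None:
            self.channel_kinds = tuple("scalp" for _ in self.channel_names)
        else:
            self.channel_kinds = tuple(self.channel_kinds)

    def _derive(self, data: np.ndarray, step: str, **changes) -> "NeuralRecording":
        if not np.all(np.isfinite(data)):
            raise ValueError(f"non-finite samples produced by {step}")
        return replace(self, data=data, log=self.log + (step,), **changes)

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not found") from None


def _zero_phase_band(data: np.ndarray, fs: float, lo: float, hi: float,
                     order: int = 2) -> np.ndarray:
    bh, ah = butter(order, lo, btype="high", fs=fs)
    bl, al = butter(order, hi, btype="low", fs=fs)
    out = filtfilt(bh, ah, data, axis=0)
    return filtfilt(bl, al, out, axis=0)


def bandpass_lowrate(
    rec: NeuralRecording,
    lo: float = 1.0,
    hi: float = 8.0,
    fs_out: float | None = None,
) -> NeuralRecording:
    """1-8 Hz zero-phase Butterworth band-pass, optional downsampling.

    Order-2 high-pass then order-2 low-pass, both forward-backward, so no
    phase distortion.  ``fs_out`` (e.g. 64 Hz for scalp EEG streams)
    resamples after filtering.
    """
    if hi >= rec.fs / 2:
        raise ValueError(f"hi={hi} Hz must be below Nyquist ({rec.fs / 2} Hz)")
    out = _zero_phase_band(rec.data, rec.fs, lo, hi)
    fs = rec.fs
    if fs_out is not None and fs_out != rec.fs:
        up, down = _ratio(fs_out, rec.fs)
        out = resample_poly(out, up, down, axis=0)
        fs = fs_out
    return rec._derive(out, f"bandpass[{lo},{hi}]Hz->fs{fs:g}",
                       fs=fs, modality="low-rate")


def _ratio(fs_out: float, fs_in: float) -> tuple[int, int]:
    from fractions import Fraction

    frac = Fraction(fs_out / fs_in).limit_denominator(10000)
    return frac.numerator, frac.denominator


def highgamma_power(
    rec: NeuralRecording,
    band: tuple = (70.0, 150.0),
    fs_out: float = 100.0,
) -> NeuralRecording:
    """High-gamma (70-150 Hz) analytic-signal magnitude, resampled.

    Band-pass (zero-phase, order 4), Hilbert magnitude, then an
    anti-aliasing low-pass below ``fs_out/2`` and polyphase resampling to
    ``fs_out`` — a proxy for local population spiking activity.
    """
    if rec.fs <= 2 * band[1]:
        raise ValueError(
            f"fs={rec.fs} Hz too low for band up to {band[1]} Hz"
        )
    b, a = butter(4, band, btype="band", fs=rec.fs)
    narrow = filtfilt(b, a, rec.data, axis=0)
    power = np.abs(hilbert(narrow, axis=0))
    bl, al = butter(4, 0.45 * fs_out, btype="low", fs=rec.fs)
    power = filtfilt(bl, al, power, axis=0)
    up, down = _ratio(fs_out, rec.fs)
    power = resample_poly(power, up, down, axis=0)
    return rec._derive(power, f"highgamma[{band[0]},{band[1]}]Hz->fs{fs_out:g}",
                       fs=fs_out, modality="high-gamma")


def detect_and_repair_channels(
    rec: NeuralRecording,
    neighbors: dict | None = None,
    k_nearest: int = 4,
    coords: np.ndarray | None = None,
    threshold: float = 3.0,
    max_bad_fraction: float = 0.25,
) -> tuple[NeuralRecording, dict]:
    """Replace channels whose variance exceeds ``threshold`` x their neighbors'.

    A channel is bad when its variance exceeds ``threshold`` times the
    median variance of its neighborhood; it is replaced by the mean of its
    (good) neighbors.  Neighborhoods come from an explicit ``neighbors``
    map (name -> list of names) or from the ``k_nearest`` channels by
    sensor coordinates.  Aborts if more than ``max_bad_fraction`` of
    channels are bad.
    """
    names = rec.channel_names
    if neighbors is None:
        if coords is None:
            raise ValueError("supply either a neighbors map or coordinates")
        coords = np.asarray(coords, dtype=float)
        neighbors = {}
        for i, name in enumerate(names):
            d = np.linalg.norm(coords - coords[i], axis=1)
            order = np.argsort(d)
            neighbors[name] = [names[j] for j in order[1 : k_nearest + 1]]
    variances = rec.data.var(axis=0)
    bad = []
    for i, name in enumerate(names):
        nb = [rec.channel_index(m) for m in neighbors[name]]
        ref = np.median(variances[nb])
        if ref > 0 and variances[i] > threshold * ref:
            bad.append(i)
    if len(bad) > max_bad_fraction * len(names):
        raise RuntimeError(
            f"{len(bad)}/{len(names)} channels bad — exceeds "
            f"{max_bad_fraction:.0%}; aborting instead of repairing"
        )
    out = rec.data.copy()
    for i in bad:
        nb = [rec.channel_index(m) for m in neighbors[names[i]]
              if rec.channel_index(m) not in bad]
        if nb:
            out[:, i] = rec.data[:, nb].mean(axis=1)
    report = {
        "repaired": [names[i] for i in bad],
        "variances": variances,
        "threshold": threshold,
    }
    return rec._derive(out, f"repair[{len(bad)} channels]"), report


def rereference_mastoids(
    rec: NeuralRecording, mastoid_channels: tuple
) -> NeuralRecording:
    """Subtract the average of the two mastoid channels from every channel.

    Mastoids are retained and flagged as reference channels.  Idempotent:
    after one pass the mastoid average is identically zero.
    """
    if len(mastoid_channels) != 2:
        raise ValueError("exactly two mastoid channels required")
    idx = [rec.channel_index(m) for m in mastoid_channels]
    ref = rec.data[:, idx].mean(axis=1, keepdims=True)
    kinds = tuple(
        "reference" if name in mastoid_channels else kind
        for name, kind in zip(rec.channel_names, rec.channel_kinds)
    )
    return rec._derive(rec.data - ref, "rereference[mastoid-average]",
                       channel_kinds=kinds)


def select_responsive_electrodes(
    rec_music: NeuralRecording,
    rec_silence: NeuralRecording,
    chunk_ms: float = 200.0,
    n_chunks: int = 25,
    d_threshold: float = 0.5,
) -> tuple[list, np.ndarray]:
    """Mark channels whose response to music exceeds silence (Cohen's d > 0.5).

    From each condition, ``n_chunks`` evenly spaced chunks of ``chunk_ms``
    are taken, summarized by their RMS, and the unpaired Cohen's d between
    conditions is computed per channel.  Returns (selected channel names,
    effect sizes).
    """
    if rec_music.fs != rec_silence.fs:
        raise ValueError("recordings must share sampling rate")
    if rec_music.channel_names != rec_silence.channel_names:
        raise ValueError("recordings must share channels")
    chunk = int(round(chunk_ms / 1000.0 * rec_music.fs))

    def _chunk_rms(data: np.ndarray) -> np.ndarray:
        if data.shape[0] < n_chunks * chunk:
            raise ValueError(
                f"recording too short for {n_chunks} chunks of {chunk_ms} ms"
            )
        starts = np.linspace(0, data.shape[0] - chunk, n_chunks).astype(int)
        return np.stack(
            [np.sqrt((data[s : s + chunk] ** 2).mean(axis=0)) for s in starts]
        )

    rms_music = _chunk_rms(rec_music.data)
    rms_silence = _chunk_rms(rec_silence.data)
    d = np.array(
        [cohens_d(rms_music[:, c], rms_silence[:, c])
         for c in range(rms_music.shape[1])]
    )
    selected = [n for n, dd in zip(rec_music.channel_names, d) if dd > d_threshold]
    return selected, d
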