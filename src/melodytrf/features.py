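"""Stimulus feature encoding at the neural sampling rate.

Builds the regressor sets used by the encoding models:

* ``A`` — acoustics only: broadband envelope (Env) and its half-wave
  rectified first derivative (Env').
* ``AM`` — acoustics plus the four melodic-expectation impulse trains
  (S_p, H_p, S_o, H_o), each zero everywhere except at note-onset samples
  where it carries that note's expectation value in bits.
* ``AM_shu`` — same as AM but with the expectation values shuffled in time
  (onsets preserved): a dimensionality-matched control.
* ``AM_p`` / ``AM_o`` — acoustics plus only the pitch (or only the
  onset-time) expectation columns.

Column order is fixed: [env, env_deriv | s_pitch, h_pitch, s_onset, h_onset].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, hilbert, resample_poly, sosfiltfilt

from .melody import ExpectationSeries

__all__ = [
    "FeatureMatrix",
    "VARIANT_COLUMNS",
    "envelope_from_audio",
    "rectified_derivative",
    "impulse_train",
    "assemble",
]

ACOUSTIC_NAMES = ("env", "env_deriv")
EXPECTATION_NAMES = ("s_pitch", "h_pitch", "s_onset", "h_onset")

#: feature columns per variant, in fixed order
VARIANT_COLUMNS = {
    "A": ACOUSTIC_NAMES,
    "AM": ACOUSTIC_NAMES + EXPECTATION_NAMES,
    "AM_shu": ACOUSTIC_NAMES + EXPECTATION_NAMES,
    "AM_p": ACOUSTIC_NAMES + ("s_pitch", "h_pitch"),
    "AM_o": ACOUSTIC_NAMES + ("s_onset", "h_onset"),
}


@dataclass
class FeatureMatrix:
    """time x feature design signals for one piece/trial."""

    data: np.ndarray
    fs: float
    feature_names: tuple
    piece_id: str = "piece"
    variant: str = "AM"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.feature_names = tuple(self.feature_names)
        if self.data.ndim != 2 or self.data.shape[1] != len(self.feature_names):
            raise ValueError("data must be (time x feature) matching names")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.data[:, self.feature_names.index(name)]


def envelope_from_audio(
    waveform: np.ndarray, fs_audio: float, fs_out: float
) -> np.ndarray:
    """Broadband amplitude envelope via the Hilbert transform.

    Magnitude of the analytic signal, low-pass filtered below ``fs_out/2``
    (zero-phase Butterworth) and resampled to ``fs_out``.
    """
    waveform = np.asarray(waveform, dtype=float)
    if waveform.size == 0:
        raise ValueError("waveform is empty")
    if not fs_audio > 2 * fs_out:
        raise ValueError("fs_audio must exceed 2 * fs_out")
    env = np.abs(hilbert(waveform))
    sos = butter(4, 0.45 * fs_out, btype="low", fs=fs_audio, output="sos")
    env = sosfiltfilt(sos, env)
    up, down = _resample_ratio(fs_out, fs_audio)
    env = resample_poly(env, up, down)
    return np.maximum(env, 0.0)


def _resample_ratio(fs_out: float, fs_in: float) -> tuple[int, int]:
    from fractions import Fraction

    frac = Fraction(fs_out / fs_in).limit_denominator(10000)
    return frac.numerator, frac.denominator


def envelope_from_wav(path, fs_out: float) -> np.ndarray:
    """Read a PCM WAV file and extract its envelope at ``fs_out``.

    Stereo files are averaged to mono; integer PCM is scaled to [-1, 1].
    """
    from scipy.io import wavfile

    fs_audio, raw = wavfile.read(path)
    data = np.asarray(raw, dtype=float)
    if data.ndim == 2:
        data = data.mean(axis=1)
    if np.issubdtype(raw.dtype, np.integer):
        data = data / np.iinfo(raw.dtype).max
    return envelope_from_audio(data, float(fs_audio), fs_out)


def rectified_derivative(envelope: np.ndarray, fs: float) -> np.ndarray:
    """Half-wave rectified first derivative, same length (first sample 0)."""
    envelope = np.asarray(envelope, dtype=float)
    d = np.zeros_like(envelope)
    d[1:] = np.diff(envelope) * fs
    return np.maximum(d, 0.0)


def impulse_train(
    series: ExpectationSeries,
    feature: str,
    fs: float,
    duration_s: float,
) -> np.ndarray:
    """Note-onset vector whose impulses carry one expectation feature.

    Zeros everywhere except the sample nearest each note onset
    (round-half-up), which holds that note's feature value.
    """
    values = series.values(feature)
    n = int(round(duration_s * fs))
    out = np.zeros(n)
    idx = np.floor(series.onsets * fs + 0.5).astype(int)
    if np.any(series.onsets >= duration_s) or np.any(idx >= n):
        bad = int(np.flatnonzero((series.onsets >= duration_s) | (idx >= n))[0])
        raise ValueError(
            f"note {bad} onset {series.onsets[bad]:.3f}s beyond duration "
            f"{duration_s:.3f}s"
        )
    if len(np.unique(idx)) != len(idx):
        raise ValueError("two notes collide on one sample; fs too low")
    out[idx] = values
    return out


def assemble(
    variant: str,
    envelope: np.ndarray,
    series: ExpectationSeries,
    fs: float,
    shuffle_seed: int | None = None,
    piece_id: str | None = None,
) -> FeatureMatrix:
    """Build one variant's feature matrix from an envelope and a series.

    ``AM_shu`` requires ``shuffle_seed`` and applies the shared-permutation
    shuffle to the expectation columns before encoding.  Columns are raw
    (unscaled); standardization happens per training fold inside the
    encoding-model cross-validation.
    """
    if variant not in VARIANT_COLUMNS:
        raise ValueError(f"unknown variant {variant!r}; one of {sorted(VARIANT_COLUMNS)}")
    envelope = np.asarray(envelope, dtype=float)
    duration_s = len(envelope) / fs
    if variant == "AM_shu":
        if shuffle_seed is None:
            raise ValueError("AM_shu requires shuffle_seed")
        from .melody import shuffle_series

        series = shuffle_series(series, shuffle_seed)
    cols = []
    for name in VARIANT_COLUMNS[variant]:
        if name == "env":
            cols.append(envelope)
        elif name == "env_deriv":
            cols.append(rectified_derivative(envelope, fs))
        else:
            cols.append(impulse_train(series, name, fs, duration_s))
    return FeatureMatrix(
        data=np.column_stack(cols),
        fs=fs,
        feature_names=VARIANT_COLUMNS[variant],
        piece_id=piece_id or series.piece_id,
        variant=variant,
    )
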