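"""Note-locked event-related potential (ERP) analysis.

The key confound control: before contrasting high- vs low-surprise notes,
epochs are restricted to notes whose peak acoustic envelope lies within a
tolerance of the median peak envelope, so any response difference between
surprise groups cannot be explained by louder notes.  The contrast itself
compares group-mean traces latency-by-latency (permutation test, FDR
corrected) and total response power in the 0-200 ms window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .melody import ExpectationSeries
from .preprocessing import NeuralRecording
from .stats import fdr_bh, permutation_test

__all__ = [
    "EpochSet",
    "epoch",
    "peak_envelopes",
    "select_envelope_matched",
    "filter_min_preceding_ioi",
    "split_by_feature",
    "erp_contrast",
]


@dataclass
class EpochSet:
    """note x time x channel epochs with per-note metadata."""

    epochs: np.ndarray  # (n_notes, n_times, n_channels)
    fs: float
    window_ms: tuple  # (pre, post), pre >= 0 means pre-onset span
    meta: pd.DataFrame  # onset_s, peak_env, S/H columns, preceding IOI
    n_dropped: int = 0

    def __len__(self) -> int:
        return self.epochs.shape[0]

    @property
    def times_ms(self) -> np.ndarray:
        pre, _ = self.window_ms
        n_pre = int(round(pre / 1000.0 * self.fs))
        n = self.epochs.shape[1]
        return (np.arange(n) - n_pre) / self.fs * 1000.0

    def subset(self, mask: np.ndarray) -> "EpochSet":
        mask = np.asarray(mask)
        return replace(
            self,
            epochs=self.epochs[mask],
            meta=self.meta.iloc[mask].reset_index(drop=True),
        )


def epoch(
    rec: NeuralRecording,
    series: ExpectationSeries,
    window_ms: tuple = (200.0, 600.0),
    envelope: np.ndarray | None = None,
    peak_window_ms: float = 150.0,
) -> EpochSet:
    """Segment a recording around note onsets.

    ``window_ms = (pre, post)`` spans pre ms before to post ms after each
    onset; notes whose window would cross the recording edges are dropped
    (and counted).  When ``envelope`` (same fs) is given, each note's peak
    envelope within [onset, onset + peak_window_ms] is recorded for
    envelope matching.
    """
    pre, post = window_ms
    n_pre = int(round(pre / 1000.0 * rec.fs))
    n_post = int(round(post / 1000.0 * rec.fs))
    n_samples = rec.data.shape[0]
    rows = []
    segs = []
    dropped = 0
    peak_n = int(round(peak_window_ms / 1000.0 * rec.fs))
    for i, onset in enumerate(series.onsets):
        c = int(round(onset * rec.fs))
        if c - n_pre < 0 or c + n_post > n_samples:
            dropped += 1
            continue
        segs.append(rec.data[c - n_pre : c + n_post])
        if envelope is not None:
            peak = float(envelope[c : min(c + peak_n, len(envelope))].max())
        else:
            peak = np.nan
        prev_ioi = (series.onsets[i] - series.onsets[i - 1]) if i > 0 else np.nan
        rows.append(
            {
                "note_index": i,
                "onset_s": onset,
                "peak_env": peak,
                "s_pitch": series.s_pitch[i],
                "h_pitch": series.h_pitch[i],
                "s_onset": series.s_onset[i],
                "h_onset": series.h_onset[i],
                "preceding_ioi_s": prev_ioi,
            }
        )
    if not segs:
        raise ValueError("no eligible notes: every epoch crosses an edge")
    return EpochSet(
        epochs=np.stack(segs),
        fs=rec.fs,
        window_ms=window_ms,
        meta=pd.DataFrame(rows),
        n_dropped=dropped,
    )


def peak_envelopes(
    envelope: np.ndarray, onsets: np.ndarray, fs: float,
    peak_window_ms: float = 150.0,
) -> np.ndarray:
    """Per-note maximum of the envelope within [onset, onset+150 ms]."""
    n = int(round(peak_window_ms / 1000.0 * fs))
    out = np.empty(len(onsets))
    for i, t in enumerate(onsets):
        c = int(round(t * fs))
        out[i] = envelope[max(c, 0) : c + n].max() if c < len(envelope) else 0.0
    return out


def select_envelope_matched(
    epochs: EpochSet, tolerance: float = 0.05
) -> EpochSet:
    """Keep notes whose peak envelope is within ±tolerance of the median.

    This enforces acoustically matched groups before any surprise split;
    the retained fraction is reported in the returned set's metadata
    (``.meta.attrs['retained_fraction']``).
    """
    peaks = epochs.meta["peak_env"].to_numpy(float)
    if np.any(~np.isfinite(peaks)):
        raise ValueError("peak envelopes unavailable; epoch() needs envelope=")
    med = float(np.median(peaks))
    mask = np.abs(peaks - med) <= tolerance * med
    out = epochs.subset(mask)
    if len(out) < 20:
        warnings.warn(f"only {len(out)} envelope-matched notes retained")
    out.meta.attrs["retained_fraction"] = float(mask.mean())
    out.meta.attrs["median_peak_env"] = med
    return out


def filter_min_preceding_ioi(epochs: EpochSet, min_ioi_s: float = 0.2) -> EpochSet:
    """Keep notes whose preceding inter-onset interval exceeds ``min_ioi_s``.

    Removes pre-stimulus contamination from the previous note's response at
    the cost of epochs; off by default in the main contrast.
    """
    ioi = epochs.meta["preceding_ioi_s"].to_numpy(float)
    return epochs.subset(np.nan_to_num(ioi, nan=np.inf) > min_ioi_s)


def split_by_feature(
    epochs: EpochSet, feature: str = "s_pitch", quantile: float = 0.20
) -> tuple[EpochSet, EpochSet]:
    """Top/bottom quantile groups by one expectation feature (stable ties)."""
    if len(epochs) < 10:
        raise ValueError("need at least 10 epochs to split")
    vals = epochs.meta[feature].to_numpy(float)
    if np.all(vals == vals[0]):
        raise ValueError(f"feature {feature!r} is degenerate (all equal)")
    k = max(1, int(round(quantile * len(vals))))
    order = np.argsort(vals, kind="stable")
    low_idx = np.sort(order[:k])
    high_idx = np.sort(order[-k:])
    return epochs.subset(high_idx), epochs.subset(low_idx)


def erp_contrast(
    high: EpochSet,
    low: EpochSet,
    power_window_ms: tuple = (0.0, 200.0),
    n_perm: int = 2000,
    alpha: float = 0.05,
    seed: int = 0,
    baseline_correct: bool = False,
) -> dict:
    """Compare high- vs low-surprise ERPs.

    Returns group-mean traces with 95% confidence intervals, per-latency
    two-tailed permutation tests FDR-corrected across latencies (on the
    channel-averaged traces), and the total power (mean squared amplitude)
    in ``power_window_ms`` compared by an unpaired permutation test across
    epochs.  ``baseline_correct`` subtracts each epoch's mean pre-onset
    amplitude (off by default: with short inter-note intervals the
    "baseline" contains the previous note's response).
    """
    if len(high) == 0 or len(low) == 0:
        raise ValueError("both groups must be non-empty")
    if high.epochs.shape[1:] != low.epochs.shape[1:]:
        raise ValueError("mismatched epoch windows")
    t_ms = high.times_ms
    # channel-averaged per-epoch traces
    h_tr = high.epochs.mean(axis=2)
    l_tr = low.epochs.mean(axis=2)
    if baseline_correct:
        pre = t_ms < 0
        if pre.any():
            h_tr = h_tr - h_tr[:, pre].mean(axis=1, keepdims=True)
            l_tr = l_tr - l_tr[:, pre].mean(axis=1, keepdims=True)

    def _ci(tr):
        m = tr.mean(axis=0)
        se = tr.std(axis=0, ddof=1) / np.sqrt(tr.shape[0])
        return m, 1.96 * se

    h_mean, h_ci = _ci(h_tr)
    l_mean, l_ci = _ci(l_tr)

    rng = np.random.default_rng(seed)
    p_lat = np.array(
        [
            permutation_test(h_tr[:, j], l_tr[:, j], paired=False,
                             n_perm=n_perm, seed=int(rng.integers(2 ** 31))).p_value
            for j in range(h_tr.shape[1])
        ]
    )
    sig_lat = fdr_bh(p_lat, q=alpha)

    in_win = (t_ms >= power_window_ms[0]) & (t_ms < power_window_ms[1])
    h_pow = (h_tr[:, in_win] ** 2).mean(axis=1)
    l_pow = (l_tr[:, in_win] ** 2).mean(axis=1)
    power_test = permutation_test(h_pow, l_pow, paired=False, n_perm=n_perm,
                                  seed=seed + 1)
    env_ratio = np.nan
    if "peak_env" in high.meta and np.isfinite(high.meta["peak_env"]).all():
        mh = float(high.meta["peak_env"].mean())
        ml = float(low.meta["peak_env"].mean())
        env_ratio = abs(mh - ml) / ((mh + ml) / 2)
    return {
        "times_ms": t_ms,
        "high_mean": h_mean,
        "high_ci": h_ci,
        "low_mean": l_mean,
        "low_ci": l_ci,
        "p_per_latency": p_lat,
        "significant_latencies": sig_lat,
        "power_high": float(h_pow.mean()),
        "power_low": float(l_pow.mean()),
        "power_test": power_test,
        "envelope_mismatch": env_ratio,
    }
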