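"""Signal conditioning: filters, re-referencing, channel repair, selection."""

import numpy as np
import pytest

from melodytrf.preprocessing import (
    NeuralRecording,
    bandpass_lowrate,
    detect_and_repair_channels,
    highgamma_power,
    rereference_mastoids,
    select_responsive_electrodes,
)


def _rec(data, fs=512.0, names=None):
    data = np.atleast_2d(data)
    if data.shape[0] < data.shape[1]:
        data = data.T
    names = names or tuple(f"ch{i}" for i in range(data.shape[1]))
    return NeuralRecording(data, fs, names)


# ------------------------------------------------------------------ band-pass


def test_in_band_tone_passes_with_zero_phase():
    fs = 512.0
    t = np.arange(int(fs * 20)) / fs
    tone = np.sin(2 * np.pi * 4 * t)
    out = bandpass_lowrate(_rec(tone, fs)).data[:, 0]
    inner = slice(int(5 * fs), -int(5 * fs))
    gain = out[inner].std() / tone[inner].std()
    assert gain > 0.9
    lag = np.argmax(np.correlate(out, tone, "full")) - (len(t) - 1)
    assert lag == 0


def test_slow_drift_strongly_attenuated():
    fs = 512.0
    t = np.arange(int(fs * 60)) / fs
    drift = np.sin(2 * np.pi * 0.05 * t)
    out = bandpass_lowrate(_rec(drift, fs)).data[:, 0]
    inner = slice(int(10 * fs), -int(10 * fs))
    atten_db = 20 * np.log10(drift[inner].std() / max(out[inner].std(), 1e-12))
    assert atten_db > 20


def test_dc_offset_removed(rng):
    x = rng.normal(size=4096) + 17.0
    out = bandpass_lowrate(_rec(x, 512.0)).data[:, 0]
    assert abs(out.mean()) < 0.05


def test_nyquist_guard():
    with pytest.raises(ValueError, match="Nyquist"):
        bandpass_lowrate(_rec(np.zeros(100), fs=10.0), hi=8.0)


def test_downsampling_to_64hz(rng):
    x = rng.normal(size=(5120, 3))
    out = bandpass_lowrate(NeuralRecording(x, 512.0, ("a", "b", "c")),
                           fs_out=64.0)
    assert out.fs == 64.0
    assert out.data.shape == (640, 3)
    assert out.modality == "low-rate"


# ----------------------------------------------------------------- high gamma


def test_inband_tone_amplitude_recovered():
    fs = 1000.0
    t = np.arange(int(fs * 10)) / fs
    x = 0.8 * np.sin(2 * np.pi * 100 * t)
    out = highgamma_power(_rec(x, fs))
    assert out.fs == 100.0
    inner = out.data[100:-100, 0]
    np.testing.assert_allclose(inner.mean(), 0.8, rtol=0.05)


def test_out_of_band_tone_suppressed():
    fs = 1000.0
    t = np.arange(int(fs * 5)) / fs
    x = np.sin(2 * np.pi * 10 * t)
    out = highgamma_power(_rec(x, fs))
    assert out.data[50:-50, 0].mean() < 0.02


def test_tracks_amplitude_modulator():
    fs = 1200.0
    t = np.arange(int(fs * 10)) / fs
    mod = 1.0 + 0.5 * np.sin(2 * np.pi * 2 * t)
    x = mod * np.sin(2 * np.pi * 110 * t)
    out = highgamma_power(_rec(x, fs))
    mod100 = mod[:: 12][: out.data.shape[0]]
    inner = slice(100, -100)
    corr = np.corrcoef(out.data[inner, 0], mod100[inner])[0, 1]
    assert corr > 0.98


def test_low_fs_rejected():
    with pytest.raises(ValueError, match="too low"):
        highgamma_power(_rec(np.zeros(1000), fs=200.0))


# ------------------------------------------------------------ channel repair


def _neighbors(names):
    return {n: [m for m in names if m != n] for n in names}


def test_clean_recording_untouched(rng):
    data = rng.normal(size=(4000, 5))
    rec = _rec(data, 100.0)
    out, report = detect_and_repair_channels(rec, _neighbors(rec.channel_names))
    assert report["repaired"] == []
    np.testing.assert_array_equal(out.data, rec.data)


def test_injected_bad_channel_repaired(rng):
    data = rng.normal(size=(4000, 5))
    data[:, 2] *= np.sqrt(10)
    rec = _rec(data, 100.0)
    out, report = detect_and_repair_channels(rec, _neighbors(rec.channel_names))
    assert report["repaired"] == ["ch2"]
    assert out.data[:, 2].var() <= np.median(
        [out.data[:, j].var() for j in (0, 1, 3, 4)]
    ) * 1.5
    np.testing.assert_array_equal(out.data[:, 0], rec.data[:, 0])


def test_too_many_bad_channels_aborts(rng):
    data = rng.normal(size=(2000, 4))
    data[:, :2] *= 20
    rec = _rec(data, 100.0)
    with pytest.raises(RuntimeError, match="abort"):
        detect_and_repair_channels(rec, _neighbors(rec.channel_names))


def test_neighbors_from_coordinates(rng):
    data = rng.normal(size=(3000, 4))
    data[:, 3] *= 6
    rec = _rec(data, 100.0)
    coords = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]], float)
    out, report = detect_and_repair_channels(rec, coords=coords, k_nearest=3)
    assert report["repaired"] == ["ch3"]


# ---------------------------------------------------------------- re-reference


def test_zero_mastoids_leave_data_unchanged(rng):
    data = rng.normal(size=(1000, 4))
    data[:, 2:] = 0.0
    rec = _rec(data, 100.0, ("a", "b", "M1", "M2"))
    out = rereference_mastoids(rec, ("M1", "M2"))
    np.testing.assert_array_equal(out.data, rec.data)
    assert out.channel_kinds[2] == "reference"


def test_common_mode_rejected_exactly(rng):
    base = rng.normal(size=(1000, 4))
    common = rng.normal(size=1000)
    rec = _rec(base + common[:, None], 100.0, ("a", "b", "M1", "M2"))
    ref_only = rereference_mastoids(_rec(base, 100.0, ("a", "b", "M1", "M2")),
                                    ("M1", "M2"))
    out = rereference_mastoids(rec, ("M1", "M2"))
    np.testing.assert_allclose(out.data, ref_only.data, atol=1e-10)


def test_rereference_idempotent(rng):
    rec = _rec(rng.normal(size=(1000, 4)), 100.0, ("a", "b", "M1", "M2"))
    once = rereference_mastoids(rec, ("M1", "M2"))
    twice = rereference_mastoids(once, ("M1", "M2"))
    np.testing.assert_allclose(once.data, twice.data, atol=1e-12)


def test_missing_mastoid_errors(rng):
    rec = _rec(rng.normal(size=(100, 2)), 100.0, ("a", "b"))
    with pytest.raises(KeyError):
        rereference_mastoids(rec, ("M1", "M2"))


# ------------------------------------------------------- responsive electrodes


def test_injected_response_selected_null_not(rng):
    fs = 100.0
    n = int(fs * 30)
    silence = rng.normal(size=(n, 3))
    music = rng.normal(size=(n, 3))
    music[:, 1] *= 3.0  # strong response on one channel
    sel, d = select_responsive_electrodes(
        _rec(music, fs, ("x", "y", "z")), _rec(silence, fs, ("x", "y", "z"))
    )
    assert "y" in sel
    assert "x" not in sel and "z" not in sel
    assert d[1] > 0.5


def test_false_selection_rate_under_null(rng):
    fs = 100.0
    n = int(fs * 30)
    selections = 0
    trials = 0
    for rep in range(40):
        a = _rec(rng.normal(size=(n, 2)), fs, ("p", "q"))
        b = _rec(rng.normal(size=(n, 2)), fs, ("p", "q"))
        sel, _ = select_responsive_electrodes(a, b)
        selections += len(sel)
        trials += 2
    assert selections / trials < 0.1


def test_equal_samples_give_zero_d(rng):
    fs = 100.0
    x = rng.normal(size=(int(fs * 30), 1))
    a = _rec(x, fs, ("e",))
    b = _rec(x.copy(), fs, ("e",))
    _, d = select_responsive_electrodes(a, b)
    assert abs(d[0]) < 1e-9


def test_insufficient_silence_errors(rng):
    fs = 100.0
    a = _rec(rng.normal(size=(int(fs * 30), 1)), fs, ("e",))
    b = _rec(rng.normal(size=(int(fs * 2), 1)), fs, ("e",))
    with pytest.raises(ValueError, match="too short"):
        select_responsive_electrodes(a, b)
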