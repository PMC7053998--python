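"""Expectation series: ground-truth recovery, memory restriction, causality."""

import math

import numpy as np
import pytest

from melodytrf.expectation import (
    expectation_series,
    memory_restricted_series,
    shuffle_series,
)
from melodytrf.markov import generate_melody, random_markov_spec, true_expectations
from melodytrf.melody import MelodySequence, NoteEvent
from melodytrf.ppm import NGramModel, train_ngram


def test_exact_ltm_no_stm_recovers_ground_truth(small_spec, small_melody):
    """With the generator tables as LTM and no STM, the estimated series
    is the analytic ground truth."""
    series = expectation_series(
        small_melody, small_spec.pitch_model(), small_spec.ioi_model(),
        use_stm=False,
    )
    truth = true_expectations(small_spec, small_melody)
    for name in series.FEATURES:
        np.testing.assert_allclose(series.values(name), truth.values(name),
                                   atol=1e-9)


def test_first_note_uniform_ltm_gives_log_alphabet(small_spec, small_melody):
    ltm_p = NGramModel(small_spec.pitch_alphabet, viewpoint="pitch")
    ltm_i = NGramModel(small_spec.ioi_alphabet, viewpoint="onset")
    series = expectation_series(small_melody, ltm_p, ltm_i, use_stm=False)
    assert series.s_pitch[0] == pytest.approx(
        np.log2(len(small_spec.pitch_alphabet))
    )
    assert 0 in series.excluded  # first note's IOI has no preceding interval


def test_repeated_pitch_surprise_decreases():
    """STM counts accumulate: repeating one pitch drives its surprise down."""
    notes = [
        NoteEvent(onset_s=0.25 * i, duration_s=0.2, pitch=60, ioi_class=1,
                  bar_index=int(0.25 * i / 2.4))
        for i in range(100)
    ]
    notes[0] = NoteEvent(0.0, 0.2, 60, -1, 0)
    mel = MelodySequence(notes, piece_id="rep")
    ltm = NGramModel((60, 61, 62), viewpoint="pitch")
    ltm_i = NGramModel((1, 2), viewpoint="onset")
    series = expectation_series(mel, ltm, ltm_i, use_stm=True)
    tail = series.s_pitch[5:]
    assert np.all(np.diff(tail) <= 1e-12)
    assert tail[-1] < series.s_pitch[1]


def test_causality_changing_later_note_preserves_earlier_scores(small_spec):
    mel = generate_melody(small_spec, 60, seed=31)
    ltm_p = train_ngram(
        [[int(p) for p in generate_melody(small_spec, 200, seed=77).pitches]],
        small_spec.pitch_alphabet, viewpoint="pitch")
    ltm_i = NGramModel(small_spec.ioi_alphabet, viewpoint="onset")
    base = expectation_series(mel, ltm_p, ltm_i)
    j = 40
    altered_notes = list(mel.notes)
    old = altered_notes[j]
    new_pitch = small_spec.pitch_alphabet[
        (small_spec.pitch_alphabet.index(old.pitch) + 1)
        % len(small_spec.pitch_alphabet)
    ]
    altered_notes[j] = NoteEvent(old.onset_s, old.duration_s, new_pitch,
                                 old.ioi_class, old.bar_index)
    altered = expectation_series(
        MelodySequence(altered_notes, piece_id="alt"), ltm_p, ltm_i)
    np.testing.assert_allclose(altered.s_pitch[:j], base.s_pitch[:j],
                               atol=1e-12)
    np.testing.assert_allclose(altered.h_onset[:j], base.h_onset[:j],
                               atol=1e-12)


def test_distributions_full_support_everywhere(small_spec, small_melody):
    """Emitted series are finite: smoothing keeps every symbol possible."""
    ltm_p = NGramModel(small_spec.pitch_alphabet, viewpoint="pitch")
    ltm_i = NGramModel(small_spec.ioi_alphabet, viewpoint="onset")
    series = expectation_series(small_melody, ltm_p, ltm_i)
    for name in series.FEATURES:
        assert np.all(np.isfinite(series.values(name)))


# ---------------------------------------------------------- memory restriction


def test_memory_infinite_is_identity(small_spec, small_melody):
    ltm_p, ltm_i = small_spec.pitch_model(), small_spec.ioi_model()
    full = expectation_series(small_melody, ltm_p, ltm_i)
    inf = memory_restricted_series(small_melody, ltm_p, ltm_i, math.inf)
    for name in full.FEATURES:
        np.testing.assert_array_equal(full.values(name), inf.values(name))


def test_memory_value_validated(small_spec, small_melody):
    with pytest.raises(ValueError, match="memory_bars"):
        memory_restricted_series(small_melody, small_spec.pitch_model(),
                                 small_spec.ioi_model(), 3)


def test_chunk_start_has_empty_stm_context(small_spec):
    """At each 1-bar chunk boundary the STM restarts: the first note of a
    chunk scores as if the piece had just begun (LTM-only prediction)."""
    mel = generate_melody(small_spec, 150, seed=41)
    ltm_p, ltm_i = small_spec.pitch_model(), small_spec.ioi_model()
    restricted = expectation_series(mel, ltm_p, ltm_i, use_stm=False)
    one_bar = memory_restricted_series(mel, ltm_p, ltm_i, 1)
    bars = mel.bar_indices
    chunk_first = np.flatnonzero(np.diff(bars) > 0) + 1
    # STM contributes nothing at a chunk-opening note: the combined
    # distribution is the entropy-weighted merge of LTM with uniform
    assert len(chunk_first) > 10
    # within-chunk later notes generally differ from the LTM-only series
    interior = np.setdiff1d(np.arange(1, len(mel)), chunk_first)
    diffs = np.abs(one_bar.s_pitch[interior] - restricted.s_pitch[interior])
    assert diffs.max() > 0.01


def test_longer_memory_reduces_mean_surprise_on_structured_input():
    """On motif-repeating pieces, a 32-bar STM cannot code worse than 1-bar."""
    spec = random_markov_spec(n_pitches=8, n_iois=3, order=1, seed=13,
                              bars_per_phrase=2, perturb_prob=0.05,
                              concentration=2.0)
    mels = [generate_melody(spec, 250, seed=50 + i) for i in range(3)]
    ltm_p, ltm_i = spec.pitch_model(), spec.ioi_model()
    mean_s = {}
    for mem in (1, 32):
        vals = []
        for mel in mels:
            s = memory_restricted_series(mel, ltm_p, ltm_i, mem)
            vals.append(s.s_pitch[1:].mean())
        mean_s[mem] = np.mean(vals)
    assert mean_s[32] <= mean_s[1]


# ------------------------------------------------------------------- shuffle


def test_shuffle_preserves_multiset_and_onsets(small_spec, small_melody):
    series = expectation_series(small_melody, small_spec.pitch_model(),
                                small_spec.ioi_model())
    shuffled = shuffle_series(series, seed=3)
    np.testing.assert_array_equal(shuffled.onsets, series.onsets)
    for name in series.FEATURES:
        np.testing.assert_array_equal(np.sort(shuffled.values(name)),
                                      np.sort(series.values(name)))
    # one shared permutation: joint tuples preserved
    orig = set(zip(series.s_pitch, series.h_pitch, series.s_onset))
    new = set(zip(shuffled.s_pitch, shuffled.h_pitch, shuffled.s_onset))
    assert orig == new


def test_shuffle_deterministic(small_spec, small_melody):
    series = expectation_series(small_melody, small_spec.pitch_model(),
                                small_spec.ioi_model())
    a = shuffle_series(series, seed=9)
    b = shuffle_series(series, seed=9)
    np.testing.assert_array_equal(a.s_pitch, b.s_pitch)


def test_shuffle_single_note_unchanged():
    from melodytrf.melody import ExpectationSeries

    one = ExpectationSeries(onsets=np.array([0.0]), s_pitch=np.array([1.5]),
                            h_pitch=np.array([2.0]), s_onset=np.array([0.0]),
                            h_onset=np.array([0.0]))
    out = shuffle_series(one, seed=0)
    assert out.s_pitch[0] == 1.5
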