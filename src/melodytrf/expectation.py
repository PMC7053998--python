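"""Per-note melodic expectation estimation.

For every note of a piece, two predictors are consulted per viewpoint
(pitch and inter-onset interval): a long-term model (LTM) pretrained on a
corpus that excludes the analyzed piece, and a short-term model (STM)
grown online over the preceding notes of the piece only.  Their predictive
distributions are merged with entropy-based weights and the observed note
is scored by its surprise S = -log2 p and the context entropy H.  The STM
is updated strictly after prediction, so the series is causal: note j can
never influence the scores of earlier notes.

``memory_restricted_series`` rebuilds the STM from scratch at every chunk
boundary of ``memory_bars`` musical bars (the LTM is untouched) — degrading
only the local-context information available to the model while keeping
the feature dimensionality identical.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .melody import ExpectationSeries, MelodySequence
from .melody import shuffle_series  # re-export  # noqa: F401
from .ppm import NGramModel, combine_ltm_stm, entropy, surprise

__all__ = [
    "expectation_series",
    "memory_restricted_series",
    "shuffle_series",
    "MEMORY_LEVELS",
]

#: allowed STM memory restrictions, in musical bars
MEMORY_LEVELS = (1, 2, 4, 8, 16, 32, math.inf)


def _score_stream(
    symbols: Sequence,
    ltm,
    use_stm: bool,
    stm_max_order: int | None,
    viewpoint: str,
    chunk_ids: Sequence[int] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Walk one symbol stream causally, returning (surprise, entropy) arrays.

    ``chunk_ids`` (one int per symbol, non-decreasing) resets the STM and
    its context whenever the id changes; ``None`` means a single chunk.
    """
    n = len(symbols)
    s_out = np.zeros(n)
    h_out = np.zeros(n)
    alphabet = tuple(ltm.alphabet)
    stm = NGramModel(alphabet, stm_max_order, viewpoint, role="STM") if use_stm else None
    chunk_start = 0
    current_chunk = None
    history = list(symbols)
    for i, sym in enumerate(symbols):
        if chunk_ids is not None and chunk_ids[i] != current_chunk:
            current_chunk = chunk_ids[i]
            chunk_start = i
            if use_stm:
                stm = NGramModel(alphabet, stm_max_order, viewpoint, role="STM")
        dist = ltm.predict(tuple(history[:i]))
        if use_stm:
            local = tuple(history[chunk_start:i])
            dist = combine_ltm_stm(dist, stm.predict(local))
            stm.observe(local, sym)  # update strictly after prediction
        s_out[i] = surprise(dist, sym)
        h_out[i] = entropy(dist)
    return s_out, h_out


def expectation_series(
    melody: MelodySequence,
    pitch_ltm,
    ioi_ltm,
    use_stm: bool = True,
    stm_max_order: int | None = None,
) -> ExpectationSeries:
    """Per-note S_p, H_p, S_o, H_o in bits for one piece.

    ``pitch_ltm`` / ``ioi_ltm`` are any predictors exposing ``.alphabet``
    and ``.predict(context)`` (PPM count models or exact generator tables).
    The first note's IOI has no preceding interval: it scores S=H=0 for the
    onset viewpoint and is listed in ``excluded``.
    """
    return _series_impl(melody, pitch_ltm, ioi_ltm, use_stm, stm_max_order, None)


def memory_restricted_series(
    melody: MelodySequence,
    pitch_ltm,
    ioi_ltm,
    memory_bars: float,
    stm_max_order: int | None = None,
) -> ExpectationSeries:
    """Expectation series with the STM confined to chunks of ``memory_bars``.

    ``memory_bars`` must be one of :data:`MEMORY_LEVELS`; ``math.inf``
    reproduces :func:`expectation_series` exactly.
    """
    if memory_bars not in MEMORY_LEVELS:
        raise ValueError(
            f"memory_bars must be one of {MEMORY_LEVELS}, got {memory_bars!r}"
        )
    if math.isinf(memory_bars):
        return expectation_series(melody, pitch_ltm, ioi_ltm, use_stm=True,
                                  stm_max_order=stm_max_order)
    chunk_of_note = (melody.bar_indices // int(memory_bars)).astype(int)
    return _series_impl(melody, pitch_ltm, ioi_ltm, True, stm_max_order,
                        chunk_of_note)


def _series_impl(
    melody: MelodySequence,
    pitch_ltm,
    ioi_ltm,
    use_stm: bool,
    stm_max_order: int | None,
    chunk_of_note: np.ndarray | None,
) -> ExpectationSeries:
    pitches = [int(p) for p in melody.pitches]
    iois = [int(c) for c in melody.ioi_classes]
    sp, hp = _score_stream(pitches, pitch_ltm, use_stm, stm_max_order,
                           "pitch", chunk_of_note)
    # onset stream: skip the first note (no preceding interval)
    ioi_stream = iois[1:]
    chunks_o = None if chunk_of_note is None else chunk_of_note[1:]
    so_t, ho_t = _score_stream(ioi_stream, ioi_ltm, use_stm, stm_max_order,
                               "onset", chunks_o)
    so = np.zeros(len(melody))
    ho = np.zeros(len(melody))
    so[1:] = so_t
    ho[1:] = ho_t
    return ExpectationSeries(
        onsets=melody.onsets,
        s_pitch=sp,
        h_pitch=hp,
        s_onset=so,
        h_onset=ho,
        piece_id=melody.piece_id,
        excluded=np.array([0], dtype=int),
    )
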