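"""Synthetic melody generation from a known Markov source.

Melodies are drawn from explicit conditional probability tables over a
pitch alphabet and a quantized inter-onset-interval (IOI) alphabet, so
that the per-note surprise and entropy of every event are known in closed
form (:func:`true_expectations`).  This provides the ground-truth oracle
against which the estimated expectation models are validated.

Optionally a piece carries phrase-level structure: a motif spanning
``bars_per_phrase`` bars is generated once and then cycled for the rest of
the piece with sporadic perturbations.  Local (order-k) statistics still
follow the tables, but the long-range repetition can only be exploited by
a short-term model whose memory spans several bars — the construction used
to probe memory-restricted expectation models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .melody import INITIAL_IOI_CLASS, MelodySequence, NoteEvent
from .ppm import ExactModel

__all__ = [
    "MarkovSpec",
    "random_markov_spec",
    "generate_melody",
    "true_expectations",
]


@dataclass
class MarkovSpec:
    """Explicit Markov source over pitch and IOI symbols.

    ``pitch_transitions`` / ``ioi_transitions`` map context tuples (length
    0..``order``) to probability vectors over the respective alphabet.
    ``ioi_durations`` gives the duration in seconds of each IOI class.
    ``bars_per_phrase = 0`` disables phrase-level (cross-bar) structure.
    """

    pitch_alphabet: tuple
    ioi_alphabet: tuple
    ioi_durations: tuple  # seconds per IOI class, parallel to ioi_alphabet
    order: int
    pitch_transitions: dict
    ioi_transitions: dict
    bars_per_phrase: int = 0
    perturb_prob: float = 0.1  # per-note motif perturbation probability
    bar_duration_s: float = 2.4  # 4/4 at 100 bpm
    seed: int = 0

    def __post_init__(self) -> None:
        self.pitch_alphabet = tuple(self.pitch_alphabet)
        self.ioi_alphabet = tuple(self.ioi_alphabet)
        self.ioi_durations = tuple(float(d) for d in self.ioi_durations)
        if len(self.ioi_durations) != len(self.ioi_alphabet):
            raise ValueError("ioi_durations must parallel ioi_alphabet")
        if any(d <= 0 for d in self.ioi_durations):
            raise ValueError("IOI durations must be positive")
        if self.order < 0:
            raise ValueError("order must be non-negative")
        for name, table, alpha in (
            ("pitch_transitions", self.pitch_transitions, self.pitch_alphabet),
            ("ioi_transitions", self.ioi_transitions, self.ioi_alphabet),
        ):
            for ctx, row in table.items():
                if len(ctx) > self.order:
                    raise ValueError(
                        f"{name}: context {ctx!r} longer than order {self.order}"
                    )
                row = np.asarray(row, dtype=float)
                if row.shape != (len(alpha),):
                    raise ValueError(f"{name}: row for {ctx!r} has wrong length")
                if np.any(row < 0):
                    raise ValueError(f"{name}: negative probability for {ctx!r}")
                if abs(row.sum() - 1.0) > 1e-12:
                    raise ValueError(
                        f"{name}: row for context {ctx!r} sums to {row.sum()!r}, not 1"
                    )
                table[ctx] = row

    def pitch_model(self) -> ExactModel:
        return ExactModel(self.pitch_alphabet, self.order,
                          self.pitch_transitions, viewpoint="pitch")

    def ioi_model(self) -> ExactModel:
        return ExactModel(self.ioi_alphabet, self.order,
                          self.ioi_transitions, viewpoint="onset")

    def ioi_duration_of(self, ioi_symbol) -> float:
        return self.ioi_durations[self.ioi_alphabet.index(ioi_symbol)]


def _full_tables(alphabet, order, rng, concentration) -> dict:
    """Dirichlet-random conditional tables for every context length 0..order."""
    from itertools import product

    m = len(alphabet)
    tables: dict[tuple, np.ndarray] = {}
    for k in range(order + 1):
        for ctx in product(alphabet, repeat=k):
            tables[ctx] = rng.dirichlet(np.full(m, concentration))
    return tables


def random_markov_spec(
    n_pitches: int = 12,
    n_iois: int = 4,
    order: int = 1,
    seed: int = 0,
    concentration: float = 0.5,
    bars_per_phrase: int = 0,
    perturb_prob: float = 0.1,
    bar_duration_s: float = 2.4,
    base_pitch: int = 60,
) -> MarkovSpec:
    """Draw a random Markov source (Dirichlet rows for every context).

    ``concentration < 1`` yields peaked, melody-like transition rows;
    larger values approach uniform (maximally unpredictable) sources.
    """
    rng = np.random.default_rng(seed)
    pitches = tuple(range(base_pitch, base_pitch + n_pitches))
    # tatum grid: duple multiples of a 16th at the configured tempo; the IOI
    # symbol IS the tatum multiple, so MIDI round-trips reproduce it exactly
    tatum = bar_duration_s / 16.0
    durations = tuple(tatum * (2 ** i) for i in range(n_iois))
    iois = tuple(2 ** i for i in range(n_iois))
    return MarkovSpec(
        pitch_alphabet=pitches,
        ioi_alphabet=iois,
        ioi_durations=durations,
        order=order,
        pitch_transitions=_full_tables(pitches, order, rng, concentration),
        ioi_transitions=_full_tables(iois, order, rng, concentration),
        bars_per_phrase=bars_per_phrase,
        perturb_prob=perturb_prob,
        bar_duration_s=bar_duration_s,
        seed=seed,
    )


def _sample_chain(model: ExactModel, n: int, rng: np.random.Generator) -> list:
    out: list = []
    for _ in range(n):
        dist = model.predict(tuple(out))
        j = rng.choice(len(dist.alphabet), p=dist.probs)
        out.append(dist.alphabet[j])
    return out


def generate_melody(
    spec: MarkovSpec,
    n_notes: int,
    seed: int,
    piece_id: str = "piece",
) -> MelodySequence:
    """Sample a monophonic melody of ``n_notes`` events from the source.

    The first note starts at t=0 and carries the designated initial IOI
    class; each later note's onset advances by the duration of its sampled
    IOI class.  Bar indices follow from cumulative time and the spec's bar
    duration.  With ``bars_per_phrase > 0`` the piece cycles a motif (see
    module docstring); otherwise it is a plain order-k Markov stream.
    """
    if n_notes < 1:
        raise ValueError("n_notes must be >= 1")
    rng = np.random.default_rng(seed)
    pm, im = spec.pitch_model(), spec.ioi_model()

    if spec.bars_per_phrase > 0:
        # grow a motif spanning bars_per_phrase bars, then cycle it
        motif_pitch: list = []
        motif_ioi: list = []
        t = 0.0
        limit = spec.bars_per_phrase * spec.bar_duration_s
        while t < limit:
            p_dist = pm.predict(tuple(motif_pitch))
            motif_pitch.append(
                p_dist.alphabet[rng.choice(len(p_dist.alphabet), p=p_dist.probs)]
            )
            i_dist = im.predict(tuple(motif_ioi))
            sym = i_dist.alphabet[rng.choice(len(i_dist.alphabet), p=i_dist.probs)]
            motif_ioi.append(sym)
            t += spec.ioi_duration_of(sym)
        pitches, iois = [], []
        k = 0
        while len(pitches) < n_notes:
            p, s = motif_pitch[k % len(motif_pitch)], motif_ioi[k % len(motif_ioi)]
            if rng.random() < spec.perturb_prob:
                d = pm.predict(tuple(pitches))
                p = d.alphabet[rng.choice(len(d.alphabet), p=d.probs)]
            pitches.append(p)
            iois.append(s)
            k += 1
    else:
        pitches = _sample_chain(pm, n_notes, rng)
        iois = _sample_chain(im, n_notes, rng)

    notes: list[NoteEvent] = []
    t = 0.0
    for i in range(n_notes):
        if i == 0:
            ioi_class = INITIAL_IOI_CLASS
        else:
            ioi_class = iois[i]
            t += spec.ioi_duration_of(iois[i])
        gap = spec.ioi_duration_of(iois[i + 1]) if i + 1 < n_notes else \
            spec.ioi_durations[0]
        notes.append(
            NoteEvent(
                onset_s=t,
                duration_s=0.9 * gap,  # legato-ish, strictly before next onset
                pitch=int(pitches[i]),
                ioi_class=int(ioi_class),
                bar_index=int(t / spec.bar_duration_s + 1e-9),
            )
        )
    return MelodySequence(notes, piece_id=piece_id,
                          bar_duration_s=spec.bar_duration_s)


def true_expectations(spec: MarkovSpec, melody: MelodySequence):
    """Analytic per-note surprise and entropy under the generating tables.

    Uses the source's own conditional distributions (no estimation).  The
    first note's IOI has no preceding interval; it is assigned S=H=0 and
    listed in ``excluded``.  For phrase-structured pieces this is the
    expectation under the *local* Markov tables, i.e. what a listener
    ignorant of the motif repetition would experience.
    """
    from .melody import ExpectationSeries
    from .ppm import entropy as _H
    from .ppm import surprise as _S

    pm, im = spec.pitch_model(), spec.ioi_model()
    pitches = [int(p) for p in melody.pitches]
    iois = [int(c) for c in melody.ioi_classes]
    for i, p in enumerate(pitches):
        if p not in spec.pitch_alphabet:
            raise ValueError(f"pitch {p} at note {i} outside spec alphabet")
    for i, c in enumerate(iois[1:], start=1):
        if c not in spec.ioi_alphabet:
            raise ValueError(f"IOI class {c} at note {i} outside spec alphabet")

    n = len(melody)
    sp = np.zeros(n)
    hp = np.zeros(n)
    so = np.zeros(n)
    ho = np.zeros(n)
    for i in range(n):
        d = pm.predict(tuple(pitches[:i]))
        sp[i] = _S(d, pitches[i])
        hp[i] = _H(d)
        if i >= 1:
            d = im.predict(tuple(iois[1:i]))
            so[i] = _S(d, iois[i])
            ho[i] = _H(d)
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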