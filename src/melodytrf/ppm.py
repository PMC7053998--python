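"""Variable-order Markov prediction with PPM-C smoothing.

The model keeps n-gram counts for every context length up to ``max_order``
(or up to the full history length when unbounded) and predicts the next
symbol with the prediction-by-partial-matching escape recursion, escape
method C: after a context that has been seen ``n`` times with ``t`` distinct
continuations, the observed continuations share ``n / (n + t)`` of the mass
in proportion to their counts, and ``t / (n + t)`` escapes to the
next-shorter context.  The recursion terminates in the uniform "order -1"
distribution over the alphabet, so every symbol always has strictly
positive probability.

Two independently trained instances — a long-term model (LTM, trained on a
held-out corpus) and a short-term model (STM, grown online over the current
piece) — are merged by :func:`combine_ltm_stm` with entropy-based weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Sequence

import numpy as np

Symbol = Hashable


@dataclass
class PredictiveDistribution:
    """Probability mass over a finite ordered alphabet for the next event."""

    alphabet: tuple
    probs: np.ndarray
    viewpoint: str = "pitch"

    def __post_init__(self) -> None:
        self.alphabet = tuple(self.alphabet)
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (len(self.alphabet),):
            raise ValueError("probs length must match alphabet length")
        if np.any(self.probs < 0):
            raise ValueError("probabilities must be non-negative")
        s = self.probs.sum()
        if not np.isclose(s, 1.0, atol=1e-9):
            raise ValueError(f"probabilities must sum to 1, got {s}")

    def p(self, symbol: Symbol) -> float:
        try:
            i = self.alphabet.index(symbol)
        except ValueError:
            raise KeyError(f"symbol {symbol!r} not in alphabet") from None
        return float(self.probs[i])


def surprise(dist: PredictiveDistribution, observed: Symbol) -> float:
    """Information content -log2 p(observed) in bits."""
    p = max(dist.p(observed), 1e-12)  # guard: smoothing keeps support positive
    return float(-np.log2(p))


def entropy(dist: PredictiveDistribution) -> float:
    """Shannon entropy in bits: expected surprise over all continuations."""
    p = dist.probs
    nz = p > 0
    return float(-(p[nz] * np.log2(p[nz])).sum())


class NGramModel:
    """Count-based variable-order model over a fixed alphabet.

    Parameters
    ----------
    alphabet
        Ordered symbols; every training symbol must belong to it.
    max_order
        Longest context length used for prediction; ``None`` means
        unbounded (contexts up to the full available history).
    viewpoint
        Label carried into emitted distributions ("pitch" or "onset").
    role
        "LTM" or "STM"; informational.
    """

    def __init__(
        self,
        alphabet: Sequence[Symbol],
        max_order: int | None = None,
        viewpoint: str = "pitch",
        role: str = "LTM",
    ) -> None:
        if len(set(alphabet)) != len(tuple(alphabet)):
            raise ValueError("alphabet contains duplicates")
        if len(tuple(alphabet)) == 0:
            raise ValueError("alphabet is empty")
        if max_order is not None and max_order < 0:
            raise ValueError("max_order must be >= 0 or None")
        self.alphabet = tuple(alphabet)
        self._index = {s: i for i, s in enumerate(self.alphabet)}
        self.max_order = max_order
        self.viewpoint = viewpoint
        self.role = role
        # context tuple -> per-symbol count vector
        self._counts: dict[tuple, np.ndarray] = {}

    # ------------------------------------------------------------------ train
    def observe(self, history: Sequence[Symbol], symbol: Symbol) -> None:
        """Record one symbol after ``history`` (all usable context lengths)."""
        j = self._sym_index(symbol, position=len(history))
        hist = tuple(history)
        top = len(hist) if self.max_order is None else min(self.max_order, len(hist))
        for k in range(top + 1):
            ctx = hist[len(hist) - k :]
            vec = self._counts.get(ctx)
            if vec is None:
                vec = np.zeros(len(self.alphabet), dtype=np.int64)
                self._counts[ctx] = vec
            vec[j] += 1

    def fit(self, sequences: Sequence[Sequence[Symbol]]) -> "NGramModel":
        for seq in sequences:
            seq = tuple(seq)
            for i, sym in enumerate(seq):
                self.observe(seq[:i], sym)
        return self

    def _sym_index(self, symbol: Symbol, position: int | None = None) -> int:
        try:
            return self._index[symbol]
        except KeyError:
            where = "" if position is None else f" at position {position}"
            raise ValueError(
                f"symbol {symbol!r}{where} is outside the model alphabet"
            ) from None

    # ---------------------------------------------------------------- predict
    def predict(self, context: Sequence[Symbol]) -> PredictiveDistribution:
        """PPM-C escape recursion from the longest matching context.

        Starts at the longest usable suffix of ``context`` and interpolates
        each level's empirical distribution with the escape-weighted
        prediction of the next-shorter context, bottoming out at the uniform
        distribution over the alphabet.
        """
        ctx = tuple(context)
        if self.max_order is not None:
            ctx = ctx[len(ctx) - min(self.max_order, len(ctx)) :]
        # level order: shortest (empty) first so we can fold upwards
        m = len(self.alphabet)
        dist = np.full(m, 1.0 / m)  # order -1: uniform escape floor
        for k in range(len(ctx) + 1):
            sub = ctx[len(ctx) - k :]
            vec = self._counts.get(sub)
            if vec is None or vec.sum() == 0:
                continue  # unseen context: transparent, keep shorter-order dist
            n = float(vec.sum())
            t = float(np.count_nonzero(vec))
            esc = t / (n + t)
            dist = vec / (n + t) + esc * dist
        return PredictiveDistribution(self.alphabet, dist, self.viewpoint)

    # ------------------------------------------------------------------ intro
    def context_count(self, context: Sequence[Symbol]) -> int:
        vec = self._counts.get(tuple(context))
        return int(vec.sum()) if vec is not None else 0

    def n_contexts(self, order: int) -> int:
        """Number of distinct stored contexts of exactly this length."""
        return sum(1 for c in self._counts if len(c) == order)

    def copy(self) -> "NGramModel":
        new = NGramModel(self.alphabet, self.max_order, self.viewpoint, self.role)
        new._counts = {c: v.copy() for c, v in self._counts.items()}
        return new


def train_ngram(
    sequences: Sequence[Sequence[Symbol]],
    alphabet: Sequence[Symbol],
    max_order: int | None = None,
    viewpoint: str = "pitch",
    role: str = "LTM",
) -> NGramModel:
    """Train a PPM model on whole sequences (see :class:`NGramModel`)."""
    return NGramModel(alphabet, max_order, viewpoint, role).fit(sequences)


@dataclass
class ExactModel:
    """Oracle predictor that returns known conditional distributions.

    Used when the generating Markov tables are available (synthetic data):
    prediction bypasses count estimation entirely.  ``order`` is the true
    generator order; contexts longer than it are truncated.
    """

    alphabet: tuple
    order: int
    transitions: dict  # context tuple -> probability vector over alphabet
    viewpoint: str = "pitch"
    fallback_uniform: bool = True

    def predict(self, context: Sequence[Symbol]) -> PredictiveDistribution:
        ctx = tuple(context)
        ctx = ctx[len(ctx) - min(self.order, len(ctx)) :]
        probs = self.transitions.get(ctx)
        if probs is None:
            if not self.fallback_uniform:
                raise KeyError(f"no distribution for context {ctx!r}")
            probs = np.full(len(self.alphabet), 1.0 / len(self.alphabet))
        return PredictiveDistribution(self.alphabet, np.asarray(probs, float),
                                      self.viewpoint)


def combine_ltm_stm(
    p_ltm: PredictiveDistribution, p_stm: PredictiveDistribution
) -> PredictiveDistribution:
    """Merge long- and short-term predictions by entropy-weighted geometric mean.

    Each distribution receives weight ``w = 1 / (1 + H_rel)`` where
    ``H_rel = H(d) / log2 |E|`` is its entropy relative to the uniform
    maximum, so the more confident model dominates.  The combination is
    ``p ∝ p_ltm^(w_l/W) * p_stm^(w_s/W)`` with ``W = w_l + w_s``,
    renormalized; probabilities are floored at 1e-12 before the geometric
    step so the result keeps full support.
    """
    if p_ltm.alphabet != p_stm.alphabet:
        raise ValueError("LTM and STM alphabets differ")
    if p_ltm.viewpoint != p_stm.viewpoint:
        raise ValueError("LTM and STM viewpoints differ")
    m = len(p_ltm.alphabet)
    hmax = np.log2(m) if m > 1 else 1.0
    w = np.array([1.0 / (1.0 + entropy(p_ltm) / hmax),
                  1.0 / (1.0 + entropy(p_stm) / hmax)])
    w = w / w.sum()
    a = np.clip(p_ltm.probs, 1e-12, None)
    b = np.clip(p_stm.probs, 1e-12, None)
    log_p = w[0] * np.log(a) + w[1] * np.log(b)
    log_p -= log_p.max()
    p = np.exp(log_p)
    p /= p.sum()
    return PredictiveDistribution(p_ltm.alphabet, p, p_ltm.viewpoint)
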