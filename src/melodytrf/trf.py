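"""Temporal response function (TRF) estimation and evaluation.

A TRF is a lagged linear filter mapping stimulus features to each neural
channel, estimated by ridge regression: a stimulus sample at time t
contributes to the predicted response at times t+lag for every lag in the
model window.  Model quality is the Pearson correlation between predicted
and recorded signals on held-out trials (leave-one-out across trials), with
the ridge parameter chosen by nested cross-validation on training trials
only.  Model weights are inspected over a wide window (default -150..750 ms)
while prediction uses the compact 0..350 ms window.

Columns of the lagged design are feature-major, lag-minor:
``[f0@lag0, f0@lag1, ..., f1@lag0, ...]``.  Each column is standardized
with training-fold statistics before the ridge solve (all-zero training
columns are skipped and receive zero weight); reported weights are mapped
back to the raw column units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .stats import cohens_d, permutation_test

__all__ = [
    "TRFModel",
    "PredictionScore",
    "LagSelectionResult",
    "lag_samples",
    "build_lagged_design",
    "prepare_designs",
    "fit_trf",
    "crossval_predict",
    "compare_feature_sets",
    "backward_eliminate_lags",
    "trf_component_contrasts",
    "DEFAULT_LAMBDA_GRID",
]

DEFAULT_LAMBDA_GRID = tuple(float(x) for x in np.logspace(-3, 6, 10))


@dataclass
class TRFModel:
    """Fitted lagged encoding model."""

    weights: np.ndarray  # (n_lags, n_features, n_channels), raw-unit
    bias: np.ndarray  # (n_channels,)
    lag_window_ms: tuple
    fs: float
    lam: float
    feature_names: tuple
    metadata: dict = field(default_factory=dict)

    @property
    def lags_ms(self) -> np.ndarray:
        lo, hi = self.lag_window_ms
        return lag_samples(self.fs, lo, hi) / self.fs * 1000.0


@dataclass
class PredictionScore:
    """Per trial x channel held-out Pearson correlations."""

    r: np.ndarray  # (n_trials, n_channels)
    variant: str = ""
    lam_per_fold: np.ndarray | None = None

    @property
    def mean_r(self) -> float:
        return float(self.r.mean())

    @property
    def channel_mean(self) -> np.ndarray:
        """Per-trial r averaged over channels."""
        return self.r.mean(axis=1)


@dataclass
class LagSelectionResult:
    """Backward-elimination lag relevance (r_LOSS) per 50 ms window."""

    window_starts_ms: np.ndarray  # (n_windows,)
    window_ms: float
    r_loss: np.ndarray  # (n_windows, n_channels) mean over trials
    p_values: np.ndarray  # (n_windows, n_channels), uncorrected
    significant: np.ndarray  # (n_windows, n_channels), Bonferroni-corrected
    r_full: np.ndarray  # (n_trials, n_channels)


def lag_samples(fs: float, lo_ms: float, hi_ms: float) -> np.ndarray:
    """Integer sample lags covering [lo_ms, hi_ms]."""
    lo = int(round(lo_ms / 1000.0 * fs))
    hi = int(round(hi_ms / 1000.0 * fs))
    return np.arange(lo, hi + 1)


def build_lagged_design(
    features: np.ndarray, fs: float, lag_window_ms: tuple
) -> np.ndarray:
    """time x (feature*lag) design; zero-padded outside the trial."""
    lo_ms, hi_ms = lag_window_ms
    if not lo_ms < hi_ms:
        raise ValueError("lag window must satisfy min < max")
    features = np.asarray(features, dtype=float)
    if features.ndim == 1:
        features = features[:, None]
    T, F = features.shape
    lags = lag_samples(fs, lo_ms, hi_ms)
    if len(lags) > T:
        raise ValueError(
            f"lag span ({len(lags)} samples) exceeds trial length ({T})"
        )
    X = np.zeros((T, F * len(lags)))
    for f in range(F):
        col = features[:, f]
        for j, lag in enumerate(lags):
            dst = X[:, f * len(lags) + j]
            if lag >= 0:
                dst[lag:] = col[: T - lag] if lag > 0 else col
            else:
                dst[:lag] = col[-lag:]
    return X


def fit_trf(
    design: np.ndarray,
    response: np.ndarray,
    lam: float,
    fs: float = 1.0,
    lag_window_ms: tuple = (0.0, 0.0),
    feature_names: tuple = ("feature",),
) -> TRFModel:
    """Ridge solution w = (X'X + lam*I)^-1 X'y per channel.

    The intercept is unpenalized (columns and responses are centered; the
    bias absorbs the means).  With ``lam=0`` a singular system falls back
    to the pseudo-inverse with a warning.
    """
    X = np.asarray(design, dtype=float)
    Y = np.atleast_2d(np.asarray(response, dtype=float))
    if Y.shape[0] != X.shape[0]:
        Y = Y.T
    if Y.shape[0] != X.shape[0]:
        raise ValueError("design and response must be aligned in time")
    mx = X.mean(axis=0)
    my = Y.mean(axis=0)
    Xc = X - mx
    Yc = Y - my
    A = Xc.T @ Xc + lam * np.eye(X.shape[1])
    b = Xc.T @ Yc
    try:
        if lam == 0 and np.linalg.matrix_rank(A) < A.shape[0]:
            raise np.linalg.LinAlgError("singular")
        W = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        warnings.warn("singular system with lam=0; using pseudo-inverse")
        W = np.linalg.pinv(A) @ b
    bias = my - mx @ W
    n_feat = len(feature_names)
    n_lags = X.shape[1] // n_feat
    weights = W.reshape(n_feat, n_lags, -1).transpose(1, 0, 2)
    return TRFModel(weights, bias, lag_window_ms, fs, float(lam), tuple(feature_names))


# --------------------------------------------------------------------- CV core


class _TrialStats:
    """Sufficient statistics of one trial's lagged design and response.

    ``xtx``/``sx`` depend only on the stimulus and may be shared across
    subjects via ``precomputed``.
    """

    def __init__(self, X: np.ndarray, Y: np.ndarray,
                 precomputed: tuple | None = None):
        self.X = X
        self.Y = Y
        self.n = X.shape[0]
        if precomputed is None:
            self.sx = X.sum(axis=0)
            self.xtx = X.T @ X
        else:
            self.sx, self.xtx = precomputed
        self.sy = Y.sum(axis=0)
        self.xty = X.T @ Y
        self.syy = (Y ** 2).sum(axis=0)


def _combine(trials: list[_TrialStats], idx: list[int]) -> dict:
    n = sum(trials[i].n for i in idx)
    sx = sum(trials[i].sx for i in idx)
    sy = sum(trials[i].sy for i in idx)
    xtx = sum(trials[i].xtx for i in idx)
    xty = sum(trials[i].xty for i in idx)
    return {"n": n, "sx": sx, "sy": sy, "xtx": xtx, "xty": xty}


def _solve_fold(stats: dict, lam: float, cols: np.ndarray | None = None):
    """Standardized ridge solve on combined fold statistics.

    Returns (w_eff, mx, my): prediction is (X[:,cols]-mx) @ w_eff + my.
    """
    n, sx, sy = stats["n"], stats["sx"], stats["sy"]
    xtx, xty = stats["xtx"], stats["xty"]
    if cols is not None:
        sx = sx[cols]
        xtx = xtx[np.ix_(cols, cols)]
        xty = xty[cols]
    mx = sx / n
    my = sy / n
    G = xtx - n * np.outer(mx, mx)
    var = np.clip(np.diag(G) / n, 0.0, None)
    inv_sd = np.zeros_like(var)
    ok = var > 1e-300
    inv_sd[ok] = 1.0 / np.sqrt(var[ok])  # degenerate columns get zero weight
    Gs = G * inv_sd[:, None] * inv_sd[None, :]
    B = (xty - np.outer(mx, my)* n) * inv_sd[:, None]
    A = Gs + lam * np.eye(Gs.shape[0])
    w_std = np.linalg.solve(A, B)
    w_eff = w_std * inv_sd[:, None]
    return w_eff, mx, my


def _predict_r(trial: _TrialStats, w_eff, mx, my,
               cols: np.ndarray | None = None) -> np.ndarray:
    """Held-out Pearson r per channel from sufficient statistics only.

    With yhat = X w + b0 (b0 = my - mx w), all the moments of (yhat, y)
    follow from the trial's Gram statistics, avoiding any O(time) work.
    """
    if cols is None:
        sx, xtx, xty = trial.sx, trial.xtx, trial.xty
    else:
        sx = trial.sx[cols]
        xtx = trial.xtx[np.ix_(cols, cols)]
        xty = trial.xty[cols]
    n = trial.n
    b0 = my - mx @ w_eff  # (C,)
    sxw = sx @ w_eff  # (C,)
    s_hat = sxw + n * b0
    s_hat2 = np.sum(w_eff * (xtx @ w_eff), axis=0) + 2 * b0 * sxw + n * b0 ** 2
    s_hy = np.sum(w_eff * xty, axis=0) + b0 * trial.sy
    num = s_hy - s_hat * trial.sy / n
    var_hat = s_hat2 - s_hat ** 2 / n
    var_y = trial.syy - trial.sy ** 2 / n
    den = np.sqrt(np.clip(var_hat, 0, None) * np.clip(var_y, 0, None))
    out = np.zeros(len(num))
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    return np.clip(out, -1.0, 1.0)


def _loo_r(trials: list[_TrialStats], idx: list[int], lam: float,
           cols: np.ndarray | None = None) -> np.ndarray:
    """Leave-one-out r over the given trials at fixed lambda."""
    out = []
    for i in idx:
        train = [j for j in idx if j != i]
        w, mx, my = _solve_fold(_combine(trials, train), lam, cols)
        out.append(_predict_r(trials[i], w, mx, my, cols))
    return np.array(out)


def _select_lambda(trials: list[_TrialStats], idx: list[int],
                   grid, cols: np.ndarray | None = None) -> float:
    best_lam, best_score = None, -np.inf
    for lam in grid:
        score = _loo_r(trials, idx, lam, cols).mean()
        if score > best_score:
            best_lam, best_score = lam, score
    return best_lam


def prepare_designs(features, fs, lag_window_ms) -> list[tuple]:
    """Precompute per-trial lagged designs and their Gram statistics.

    The result can be passed to :func:`crossval_predict` as ``designs`` to
    share the stimulus-side computation across subjects.
    """
    out = []
    for X in features:
        D = build_lagged_design(X, fs, lag_window_ms)
        out.append((D, (D.sum(axis=0), D.T @ D)))
    return out


def _prepare_trials(features, responses, fs, lag_window_ms,
                    designs=None) -> list[_TrialStats]:
    if len(features) != len(responses):
        raise ValueError("features and responses must have equal trial counts")
    trials = []
    for i, (X, Y) in enumerate(zip(features, responses)):
        Y = np.atleast_2d(np.asarray(Y, dtype=float))
        if Y.shape[0] != np.asarray(X).shape[0]:
            Y = Y.T
        if designs is not None:
            D, pre = designs[i]
            trials.append(_TrialStats(D, Y, precomputed=pre))
        else:
            trials.append(_TrialStats(build_lagged_design(X, fs, lag_window_ms), Y))
    return trials


def crossval_predict(
    features: list[np.ndarray],
    responses: list[np.ndarray],
    fs: float,
    lag_window_ms: tuple = (0.0, 350.0),
    lambda_grid=DEFAULT_LAMBDA_GRID,
    feature_names: tuple | None = None,
    variant: str = "",
    designs: list | None = None,
) -> tuple[PredictionScore, TRFModel]:
    """Leave-one-out (across trials) TRF prediction with nested lambda choice.

    For each held-out trial the ridge parameter is selected by an inner
    leave-one-out over the remaining trials only, the model is refit on
    those trials, and per-channel Pearson r is computed on the held-out
    trial.  Also returns a final model fit on all trials with the lambda
    selected by leave-one-out over all trials.  ``designs`` (from
    :func:`prepare_designs`) shares stimulus-side computation across calls.
    """
    if len(features) < 3:
        raise ValueError("need at least 3 trials for cross-validation")
    trials = _prepare_trials(features, responses, fs, lag_window_ms, designs)
    n_trials = len(trials)
    all_idx = list(range(n_trials))
    r_rows = []
    lams = []
    for i in all_idx:
        train = [j for j in all_idx if j != i]
        lam_i = _select_lambda(trials, train, lambda_grid)
        w, mx, my = _solve_fold(_combine(trials, train), lam_i)
        r_rows.append(_predict_r(trials[i], w, mx, my))
        lams.append(lam_i)
    score = PredictionScore(np.array(r_rows), variant=variant,
                            lam_per_fold=np.array(lams))

    lam_all = _select_lambda(trials, all_idx, lambda_grid)
    w, mx, my = _solve_fold(_combine(trials, all_idx), lam_all)
    n_feat = np.asarray(features[0]).shape[1] if np.asarray(features[0]).ndim == 2 else 1
    names = tuple(feature_names) if feature_names else tuple(
        f"f{i}" for i in range(n_feat)
    )
    n_lags = trials[0].X.shape[1] // n_feat
    weights = w.reshape(n_feat, n_lags, -1).transpose(1, 0, 2)
    bias = my - mx @ w
    model = TRFModel(weights, bias, lag_window_ms, fs, lam_all, names,
                     metadata={"n_trials": n_trials, "variant": variant})
    return score, model


def crossval_predict_cohort(
    features: list[np.ndarray],
    responses_per_subject: list[list[np.ndarray]],
    fs: float,
    lag_window_ms: tuple = (0.0, 350.0),
    lambda_grid=DEFAULT_LAMBDA_GRID,
    variant: str = "",
    designs: list | None = None,
) -> list[PredictionScore]:
    """Leave-one-out TRF prediction for a cohort sharing its stimuli.

    Statistically identical to calling :func:`crossval_predict` per
    subject (nested per-subject lambda choice included), but each ridge
    system is factorized once with every subject's channels stacked as
    right-hand sides, since the stimulus-side Gram matrices are shared.
    """
    n_subj = len(responses_per_subject)
    n_trials = len(features)
    if n_trials < 3:
        raise ValueError("need at least 3 trials for cross-validation")
    t0 = np.asarray(features[0]).shape[0]
    offsets = [0]
    for resp in responses_per_subject:
        shape = np.atleast_2d(np.asarray(resp[0])).shape
        n_chan = shape[1] if shape[0] == t0 else shape[0]
        offsets.append(offsets[-1] + n_chan)
    stacked = []
    for t in range(n_trials):
        cols = []
        for resp in responses_per_subject:
            Y = np.atleast_2d(np.asarray(resp[t], dtype=float))
            if Y.shape[0] != np.asarray(features[t]).shape[0]:
                Y = Y.T
            cols.append(Y)
        stacked.append(np.hstack(cols))
    trials = _prepare_trials(features, stacked, fs, lag_window_ms, designs)
    grid = list(lambda_grid)
    all_idx = list(range(n_trials))

    def _subject_mean(r_row: np.ndarray) -> np.ndarray:
        return np.array([r_row[offsets[s]:offsets[s + 1]].mean()
                         for s in range(n_subj)])

    # inner LOO scores: M[g, i, j, s] = subject-mean r of trial j under the
    # fold that excludes {i, j}; each unordered pair is solved once
    M = np.full((len(grid), n_trials, n_trials, n_subj), np.nan)
    for i in range(n_trials):
        for j in range(i + 1, n_trials):
            train = [k for k in all_idx if k not in (i, j)]
            stats = _combine(trials, train)
            for g, lam in enumerate(grid):
                w, mx, my = _solve_fold(stats, lam)
                M[g, i, j] = _subject_mean(_predict_r(trials[j], w, mx, my))
                M[g, j, i] = _subject_mean(_predict_r(trials[i], w, mx, my))

    r_out = np.zeros((n_trials, offsets[-1]))
    lam_pick = np.zeros((n_trials, n_subj))
    for i in range(n_trials):
        inner = np.nanmean(M[:, i, [j for j in all_idx if j != i], :], axis=1)
        best_g = np.argmax(inner, axis=0)  # per subject
        lam_pick[i] = [grid[g] for g in best_g]
        train = [k for k in all_idx if k != i]
        stats = _combine(trials, train)
        for g in np.unique(best_g):
            w, mx, my = _solve_fold(stats, grid[g])
            row = _predict_r(trials[i], w, mx, my)
            for s in np.flatnonzero(best_g == g):
                r_out[i, offsets[s]:offsets[s + 1]] = \
                    row[offsets[s]:offsets[s + 1]]
    return [
        PredictionScore(r_out[:, offsets[s]:offsets[s + 1]], variant=variant,
                        lam_per_fold=lam_pick[:, s])
        for s in range(n_subj)
    ]


def compare_feature_sets(
    scores_a: PredictionScore,
    scores_b: PredictionScore,
    n_perm: int = 10000,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Paired comparison of two feature sets' prediction scores.

    ``scores_a``/``scores_b`` are either single-subject PredictionScores
    (compared across trials) or lists of them, one per subject (compared
    across subjects on channel- and trial-averaged r).  Reports the mean
    difference (b - a), a two-tailed paired permutation p-value and paired
    Cohen's d.

    ``detected`` is the package's decision rule for claiming an encoding
    enhancement: significant at ``alpha`` AND positive mean difference.
    The direction requirement matters because a richer-but-uninformative
    feature set carries a small systematic out-of-sample cost; a negative
    significant difference is a dimensionality effect, not evidence that
    the added features are encoded.
    """
    if isinstance(scores_a, PredictionScore):
        x = scores_a.channel_mean
        y = scores_b.channel_mean
        unit = "trial"
    else:
        x = np.array([s.r.mean() for s in scores_a])
        y = np.array([s.r.mean() for s in scores_b])
        unit = "subject"
    if x.shape != y.shape:
        raise ValueError("mismatched score shapes")
    res = permutation_test(y, x, paired=True, n_perm=n_perm, seed=seed)
    delta = float((y - x).mean())
    return {
        "delta_r": delta,
        "delta_r_per_unit": y - x,
        "unit": unit,
        "p_value": res.p_value,
        "cohens_d": cohens_d(y, x, paired=True),
        "n_positive": int(np.sum(y - x > 0)),
        "n": len(x),
        "detected": bool(res.p_value < alpha and delta > 0),
    }


def backward_eliminate_lags(
    features: list[np.ndarray],
    responses: list[np.ndarray],
    fs: float,
    window_ms: float = 50.0,
    outer_window_ms: tuple = (-150.0, 750.0),
    lambda_grid=DEFAULT_LAMBDA_GRID,
    n_perm: int = 10000,
    alpha: float = 0.05,
    seed: int = 0,
    min_shift_s: float = 2.0,
) -> LagSelectionResult:
    """First-pass backward elimination over 50 ms blocks of time lags.

    For every window [t_i, t_i + window_ms) tiling the outer lag window,
    the TRF is refit without the lags in that window (across all features)
    and the per-channel loss r_LOSS = r_full - r_without is measured on
    leave-one-out predictions.

    Significance is one-sided (relevance means loss > 0; removing an
    uninformative window slightly *improves* held-out prediction, so a
    two-sided test would flag irrelevant windows).  The null distribution
    of r_LOSS comes from circularly shifting each trial's response by at
    least ``min_shift_s`` seconds, which destroys the stimulus-response
    coupling while preserving the autocorrelation of both signals; the
    whole leave-one-out loss computation is replayed on every shifted
    surrogate.  P-values are Bonferroni-corrected over windows x channels.
    """
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives very coarse p-values")
    trials = _prepare_trials(features, responses, fs, outer_window_ms)
    n_trials = len(trials)
    all_idx = list(range(n_trials))
    lam = _select_lambda(trials, all_idx, lambda_grid)
    r_full = _loo_r(trials, all_idx, lam)  # (n_trials, n_channels)

    lags = lag_samples(fs, *outer_window_ms)
    lags_ms = lags / fs * 1000.0
    n_feat = trials[0].X.shape[1] // len(lags)
    lo, hi = outer_window_ms
    starts = np.arange(lo, hi, window_ms)
    col_sets: list = [None]
    for t0 in starts:
        in_win = (lags_ms >= t0) & (lags_ms < t0 + window_ms)
        col_sets.append(np.concatenate(
            [np.flatnonzero(~in_win) + f * len(lags) for f in range(n_feat)]
        ))
    n_chan = r_full.shape[1]
    r_loss = np.zeros((len(starts), n_chan))
    for wi in range(len(starts)):
        r_win = _loo_r(trials, all_idx, lam, col_sets[wi + 1])
        r_loss[wi] = (r_full - r_win).mean(axis=0)

    # circular-shift surrogates: (1 + K) response versions per trial, the
    # first being the observed one so its loss shares the exact code path
    rng = np.random.default_rng(seed)
    min_shift = int(round(min_shift_s * fs))
    xty_k = []  # per trial: (P, C, K) lagged-design / shifted-response products
    for tr in trials:
        n_t = tr.n
        if n_t <= 2 * min_shift:
            raise ValueError("trials too short for the requested minimum shift")
        shifts = rng.integers(min_shift, n_t - min_shift, size=n_perm)
        idx = (np.arange(n_t)[:, None] + shifts[None, :]) % n_t  # (n_t, K)
        prods = np.empty((tr.X.shape[1], tr.Y.shape[1], n_perm))
        for c in range(tr.Y.shape[1]):
            prods[:, c, :] = tr.X.T @ tr.Y[:, c][idx]
        xty_k.append(prods)

    # replay the LOO loss on every surrogate, reusing one factorization
    # per (fold, column-set)
    from scipy.linalg import cho_factor, cho_solve

    loss_null = np.zeros((n_perm, len(starts), n_chan))
    r_fold_null = np.zeros((n_trials, len(col_sets), n_perm, n_chan))
    for i in all_idx:
        train = [j for j in all_idx if j != i]
        stats = _combine(trials, train)
        xty_train = sum(xty_k[j] for j in train)  # (P, C, K)
        test = trials[i]
        for si, cols in enumerate(col_sets):
            if cols is None:
                sx, xtx, xtyk = stats["sx"], stats["xtx"], xty_train
                xtx_i, sx_i, xtyk_i = test.xtx, test.sx, xty_k[i]
            else:
                sx = stats["sx"][cols]
                xtx = stats["xtx"][np.ix_(cols, cols)]
                xtyk = xty_train[cols]
                xtx_i = test.xtx[np.ix_(cols, cols)]
                sx_i = test.sx[cols]
                xtyk_i = xty_k[i][cols]
            n = stats["n"]
            mx = sx / n
            my = stats["sy"] / n  # (C,)
            G = xtx - n * np.outer(mx, mx)
            var = np.clip(np.diag(G) / n, 0.0, None)
            inv_sd = np.zeros_like(var)
            ok = var > 1e-300
            inv_sd[ok] = 1.0 / np.sqrt(var[ok])
            Gs = G * inv_sd[:, None] * inv_sd[None, :]
            cho = cho_factor(Gs + lam * np.eye(Gs.shape[0]))
            P = len(mx)
            C = n_chan
            B = (xtyk - n * mx[:, None, None] * my[None, :, None]) \
                * inv_sd[:, None, None]
            W = cho_solve(cho, B.reshape(P, C * n_perm)).reshape(P, C, n_perm)
            W *= inv_sd[:, None, None]  # back to raw units
            # held-out r from sufficient statistics, vectorized over K
            b0 = my[:, None] - np.tensordot(mx, W, axes=(0, 0))
            sxw = np.tensordot(sx_i, W, axes=(0, 0))
            n_i = test.n
            xw = np.tensordot(xtx_i, W, axes=(1, 0))  # (P, C, K)
            s_hat = sxw + n_i * b0
            s_hat2 = np.sum(W * xw, axis=0) + 2 * b0 * sxw + n_i * b0 ** 2
            s_hy = np.sum(W * xtyk_i, axis=0) + b0 * test.sy[:, None]
            num = s_hy - s_hat * test.sy[:, None] / n_i
            var_hat = s_hat2 - s_hat ** 2 / n_i
            var_y = (test.syy - test.sy ** 2 / n_i)[:, None]
            den = np.sqrt(np.clip(var_hat, 0, None) * np.clip(var_y, 0, None))
            r = np.zeros_like(num)
            okd = den > 0
            r[okd] = num[okd] / den[okd]
            r_fold_null[i, si] = np.clip(r, -1, 1).T  # (K, C)
    full_null = r_fold_null[:, 0]  # (n_trials, K, C)
    for wi in range(len(starts)):
        loss_null[:, wi, :] = (full_null - r_fold_null[:, wi + 1]).mean(axis=0)

    eps = 1e-12
    exceed = (loss_null >= r_loss[None, :, :] - eps).sum(axis=0)
    p_vals = (1 + exceed) / (n_perm + 1)
    n_tests = len(starts) * n_chan
    significant = p_vals < (alpha / n_tests)
    return LagSelectionResult(
        window_starts_ms=starts,
        window_ms=window_ms,
        r_loss=r_loss,
        p_values=p_vals,
        significant=significant,
        r_full=r_full,
    )


def trf_component_contrasts(model: TRFModel) -> dict:
    """Weight contrasts: surprise vs entropy and pitch vs onset-time.

    Returns per (lag x channel) maps ``mean(S_p, S_o) - mean(H_p, H_o)``
    and ``mean(S_p, H_p) - mean(S_o, H_o)``.  Requires a model fit on the
    full AM feature set.
    """
    names = model.feature_names
    needed = ("s_pitch", "h_pitch", "s_onset", "h_onset")
    if not all(n in names for n in needed):
        raise ValueError("model lacks the four expectation features")
    w = {n: model.weights[:, names.index(n), :] for n in needed}
    return {
        "surprise_vs_entropy": (w["s_pitch"] + w["s_onset"]) / 2
        - (w["h_pitch"] + w["h_onset"]) / 2,
        "pitch_vs_onset": (w["s_pitch"] + w["h_pitch"]) / 2
        - (w["s_onset"] + w["h_onset"]) / 2,
        "lags_ms": model.lags_ms,
    }
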