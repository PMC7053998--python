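"""TRF estimation: design, ridge oracle, cross-validation, comparisons."""

import numpy as np
import pytest
from oracles import ridge_normal_equations_oracle

from melodytrf.synth import pink_noise
from melodytrf.trf import (
    backward_eliminate_lags,
    build_lagged_design,
    compare_feature_sets,
    crossval_predict,
    crossval_predict_cohort,
    fit_trf,
    lag_samples,
    trf_component_contrasts,
)

FS = 64.0


def _forward(X, kernels):
    T = X.shape[0]
    Y = np.zeros((T, kernels.shape[2]))
    for f in range(kernels.shape[1]):
        for c in range(kernels.shape[2]):
            Y[:, c] += np.convolve(X[:, f], kernels[:, f, c])[:T]
    return Y


# ------------------------------------------------------------------- design


def test_single_feature_zero_lag_is_identity(rng):
    x = rng.normal(size=(50, 1))
    D = build_lagged_design(x, FS, (0.0, 1.0))  # lags {0}
    np.testing.assert_array_equal(D, x)


def test_impulse_produces_shift_structure():
    x = np.zeros((30, 1))
    x[10, 0] = 1.0
    D = build_lagged_design(x, FS, (0.0, 1000 * 5 / FS))
    for j in range(6):
        col = D[:, j]
        assert col[10 + j] == 1.0
        assert np.count_nonzero(col) == 1


def test_column_count_is_features_times_lags(rng):
    x = rng.normal(size=(100, 3))
    lags = lag_samples(FS, -100, 300)
    D = build_lagged_design(x, FS, (-100, 300))
    assert D.shape == (100, 3 * len(lags))


def test_lag_window_longer_than_trial_rejected(rng):
    with pytest.raises(ValueError, match="exceeds trial length"):
        build_lagged_design(rng.normal(size=(10, 1)), FS, (0, 5000))


# ------------------------------------------------------------------ fit_trf


def test_noiseless_recovery_at_tiny_lambda(rng):
    X = rng.normal(size=(500, 8))
    w_true = rng.normal(size=(8, 2))
    Y = X @ w_true
    model = fit_trf(X, Y, lam=1e-10)
    np.testing.assert_allclose(model.weights.reshape(8, 2), w_true, rtol=1e-6)


def test_zero_response_gives_zero_weights(rng):
    X = rng.normal(size=(100, 4))
    model = fit_trf(X, np.zeros((100, 2)), lam=1.0)
    np.testing.assert_allclose(model.weights, 0.0, atol=1e-12)


def test_weight_norm_monotone_in_lambda(rng):
    X = rng.normal(size=(200, 6))
    Y = X @ rng.normal(size=(6, 1)) + 0.1 * rng.normal(size=(200, 1))
    norms = [
        np.linalg.norm(fit_trf(X, Y, lam).weights)
        for lam in (0.1, 1, 10, 100, 1000, 1e4)
    ]
    assert np.all(np.diff(norms) < 0)


def test_matches_normal_equations_oracle(rng):
    """Brute-force (X'X + lam I)^-1 X'y on a tiny problem to 1e-10."""
    for lam in (0.0, 0.5, 3.0):
        X = rng.normal(size=(20, 3))
        y = rng.normal(size=(20, 1))
        want = ridge_normal_equations_oracle(X, y, lam)
        got = fit_trf(X, y, lam).weights.reshape(3, 1)
        np.testing.assert_allclose(got, want, atol=1e-10)


def test_singular_lam_zero_falls_back_to_pinv(rng):
    X = rng.normal(size=(30, 4))
    X[:, 3] = X[:, 0]  # exact collinearity
    with pytest.warns(UserWarning, match="pseudo-inverse"):
        model = fit_trf(X, rng.normal(size=(30, 1)), lam=0.0)
    assert np.all(np.isfinite(model.weights))


# --------------------------------------------------------------- crossval


def _toy_trials(rng, n_trials=4, T=800, n_feat=2, n_chan=3, snr=np.inf,
                kernels=None):
    if kernels is None:
        kernels = rng.normal(size=(8, n_feat, n_chan))
    feats, resps = [], []
    for _ in range(n_trials):
        X = rng.normal(size=(T, n_feat))
        Y = _forward(X, kernels)
        if np.isfinite(snr):
            noise = rng.standard_normal(Y.shape)
            Y = Y + noise * Y.std(axis=0) / np.sqrt(snr)
        feats.append(X)
        resps.append(Y)
    return feats, resps, kernels


def test_noiseless_prediction_near_perfect(rng):
    feats, resps, _ = _toy_trials(rng)
    score, _ = crossval_predict(feats, resps, FS, (0.0, 1000 * 7 / FS),
                                lambda_grid=(1e-4, 1e-1, 1e2))
    assert score.mean_r > 0.999


def test_duplicated_trials_get_identical_scores(rng):
    feats, resps, _ = _toy_trials(rng, n_trials=2, snr=1.0)
    feats = feats + feats
    resps = resps + resps
    score, _ = crossval_predict(feats, resps, FS, (0.0, 1000 * 7 / FS),
                                lambda_grid=(1e0, 1e2))
    np.testing.assert_allclose(score.r[0], score.r[2], atol=1e-10)
    np.testing.assert_allclose(score.r[1], score.r[3], atol=1e-10)


def test_scores_independent_of_trial_order(rng):
    feats, resps, _ = _toy_trials(rng, n_trials=4, snr=2.0)
    score, _ = crossval_predict(feats, resps, FS, (0.0, 1000 * 7 / FS),
                                lambda_grid=(1e0, 1e2))
    perm = [2, 0, 3, 1]
    score_p, _ = crossval_predict([feats[i] for i in perm],
                                  [resps[i] for i in perm], FS,
                                  (0.0, 1000 * 7 / FS),
                                  lambda_grid=(1e0, 1e2))
    np.testing.assert_allclose(score_p.r, score.r[perm], atol=1e-10)


def test_r_invariant_to_affine_response_rescaling(rng):
    feats, resps, _ = _toy_trials(rng, snr=1.0)
    score_a, _ = crossval_predict(feats, resps, FS, (0.0, 1000 * 7 / FS),
                                  lambda_grid=(1e0,))
    resps_b = [3.5 * Y - 2.0 for Y in resps]
    score_b, _ = crossval_predict(feats, resps_b, FS, (0.0, 1000 * 7 / FS),
                                  lambda_grid=(1e0,))
    np.testing.assert_allclose(score_a.r, score_b.r, atol=1e-10)


def test_pure_noise_centers_near_zero(rng):
    means = []
    for rep in range(30):
        feats = [rng.normal(size=(400, 1)) for _ in range(3)]
        resps = [rng.normal(size=(400, 1)) for _ in range(3)]
        score, _ = crossval_predict(feats, resps, FS, (0.0, 1000 * 5 / FS),
                                    lambda_grid=(1e1,))
        means.append(score.mean_r)
    means = np.array(means)
    se = means.std(ddof=1) / np.sqrt(len(means))
    assert abs(means.mean()) < 3 * se + 0.01


def test_needs_three_trials(rng):
    feats, resps, _ = _toy_trials(rng, n_trials=2)
    with pytest.raises(ValueError, match="3 trials"):
        crossval_predict(feats, resps, FS, (0.0, 100.0))


def test_kernel_recovery_with_noise(rng):
    kernels = rng.normal(size=(8, 2, 2))
    feats, resps, _ = _toy_trials(rng, n_trials=6, T=3000, snr=1.0,
                                  kernels=kernels, n_chan=2)
    _, model = crossval_predict(feats, resps, FS, (0.0, 1000 * 7 / FS),
                                lambda_grid=(1e-2, 1e0, 1e2, 1e4))
    for f in range(2):
        c = np.corrcoef(model.weights[:, f, :].ravel(),
                        kernels[:, f, :].ravel())[0, 1]
        assert c > 0.95


def test_cohort_path_equals_single_subject_path(rng):
    feats, resps1, _ = _toy_trials(rng, snr=1.0)
    _, resps2, _ = _toy_trials(rng, snr=1.0)
    cohort = crossval_predict_cohort(feats, [resps1, resps2], FS,
                                     (0.0, 1000 * 7 / FS),
                                     lambda_grid=(1e0, 1e2))
    for resp, sc in zip((resps1, resps2), cohort):
        single, _ = crossval_predict(feats, resp, FS, (0.0, 1000 * 7 / FS),
                                     lambda_grid=(1e0, 1e2))
        np.testing.assert_allclose(sc.r, single.r, atol=1e-10)


# ------------------------------------------------------------- comparisons


def _fake_scores(r_matrices, variant=""):
    from melodytrf.trf import PredictionScore

    return [PredictionScore(np.asarray(r), variant=variant)
            for r in r_matrices]


def test_identical_scores_give_p_one(rng):
    rs = [rng.random((5, 3)) for _ in range(6)]
    out = compare_feature_sets(_fake_scores(rs), _fake_scores(rs), n_perm=999)
    assert out["delta_r"] == 0.0
    assert out["p_value"] == 1.0
    assert not out["detected"]


def test_consistent_positive_shift_detected(rng):
    base = [rng.random((5, 3)) for _ in range(8)]
    shifted = [r + 0.05 for r in base]
    out = compare_feature_sets(_fake_scores(base), _fake_scores(shifted),
                               n_perm=5000, seed=1)
    assert out["detected"]
    assert out["n_positive"] == 8
    assert out["p_value"] < 0.01


def test_negative_shift_not_detected(rng):
    """A significant but negative difference is not an encoding detection."""
    base = [rng.random((5, 3)) for _ in range(8)]
    worse = [r - 0.05 for r in base]
    out = compare_feature_sets(_fake_scores(base), _fake_scores(worse),
                               n_perm=5000, seed=1)
    assert out["p_value"] < 0.05
    assert not out["detected"]


# ------------------------------------------------------ backward elimination


def test_localized_kernel_found_only_near_its_support(rng):
    n_tr, T = 10, int(40 * FS)
    lagk = np.zeros(int(0.4 * FS))
    lagk[int(0.2 * FS) : int(0.25 * FS) + 1] = 1.0
    feats, resps = [], []
    for _ in range(n_tr):
        x = rng.normal(size=(T, 1))
        y = np.convolve(x[:, 0], lagk)[:T]
        y = y + pink_noise(T, 1, 1.0, rng)[:, 0] * y.std()
        feats.append(x)
        resps.append(y[:, None])
    res = backward_eliminate_lags(feats, resps, FS, n_perm=1000, seed=5,
                                  lambda_grid=(1e0, 1e2, 1e4))
    sig_windows = res.window_starts_ms[res.significant[:, 0]]
    assert len(sig_windows) > 0
    for t0 in sig_windows:
        assert t0 + 50 > 150 and t0 < 300  # overlaps 150-300 ms
    # the kernel's central window is the strongest
    assert res.window_starts_ms[np.argmax(res.r_loss[:, 0])] == 200.0


def test_zero_feature_window_loss_negligible(rng):
    """Removing lags of an all-zero feature costs (almost) nothing."""
    n_tr, T = 6, int(30 * FS)
    k = np.zeros((8, 2, 1))
    k[2:5, 0, 0] = 1.0  # only feature 0 drives the response
    feats, resps = [], []
    for _ in range(n_tr):
        x = rng.normal(size=(T, 2))
        x[:, 1] = 0.0
        y = _forward(x, k)
        y += rng.normal(size=y.shape) * y.std()
        feats.append(x)
        resps.append(y)
    res = backward_eliminate_lags(feats, resps, FS, n_perm=500, seed=2,
                                  outer_window_ms=(0.0, 350.0),
                                  lambda_grid=(1e0, 1e2))
    # windows past the kernel support: loss indistinguishable from zero
    late = res.window_starts_ms >= 150
    assert np.abs(res.r_loss[late, 0]).max() < 0.01


# ----------------------------------------------------------------- contrasts


def _model_with_weights(weights, names):
    from melodytrf.trf import TRFModel

    return TRFModel(weights, np.zeros(weights.shape[2]), (-150, 750), FS,
                    1.0, names)


AM_NAMES = ("env", "env_deriv", "s_pitch", "h_pitch", "s_onset", "h_onset")


def test_identical_surprise_entropy_kernels_cancel(rng):
    w = rng.normal(size=(10, 6, 4))
    w[:, 3, :] = w[:, 2, :]  # H_p == S_p
    w[:, 5, :] = w[:, 4, :]  # H_o == S_o
    maps = trf_component_contrasts(_model_with_weights(w, AM_NAMES))
    np.testing.assert_allclose(maps["surprise_vs_entropy"], 0.0, atol=1e-12)


def test_contrast_antisymmetric_under_group_swap(rng):
    w = rng.normal(size=(10, 6, 4))
    m1 = trf_component_contrasts(_model_with_weights(w, AM_NAMES))
    swapped = w[:, [0, 1, 3, 2, 5, 4], :]  # swap S<->H within viewpoints
    m2 = trf_component_contrasts(_model_with_weights(swapped, AM_NAMES))
    np.testing.assert_allclose(m1["surprise_vs_entropy"],
                               -m2["surprise_vs_entropy"], atol=1e-12)


def test_latency_split_recovered(rng):
    """Onset kernels confined below 200 ms, pitch kernels extending later:
    the pitch-vs-onset contrast is onset-dominated early, pitch-late."""
    fs = FS
    n_lags = int(0.4 * fs)
    w = np.zeros((n_lags, 6, 2))
    early = slice(0, int(0.2 * fs))
    late = slice(int(0.2 * fs), n_lags)
    w[early, 4, :] = 1.0  # s_onset early
    w[early, 5, :] = 1.0
    w[late, 2, :] = 1.0  # s_pitch late
    w[late, 3, :] = 1.0
    maps = trf_component_contrasts(_model_with_weights(w, AM_NAMES))
    pv = maps["pitch_vs_onset"]
    assert np.all(pv[early] <= 0)
    assert np.all(pv[late] >= 0)
    assert pv[early].min() < 0 and pv[late].max() > 0


def test_contrast_requires_expectation_features(rng):
    w = rng.normal(size=(5, 2, 2))
    with pytest.raises(ValueError, match="expectation"):
        trf_component_contrasts(_model_with_weights(w, ("env", "env_deriv")))
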