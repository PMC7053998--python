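"""Statistical toolkit: exactness, calibration, printed-formula identities."""

import numpy as np
import pytest
from oracles import rm_anova_f_oracle

from melodytrf.stats import (
    bonferroni,
    cohens_d,
    diss,
    fdr_bh,
    permutation_test,
    rm_anova,
    spearman,
)

# ------------------------------------------------------------ permutation


def test_identical_paired_samples_give_p_one(rng):
    x = rng.normal(size=10)
    res = permutation_test(x, x.copy(), paired=True, n_perm=2000)
    assert res.p_value == 1.0


def test_all_positive_differences_exhaustive():
    """10 strictly positive pairs, exhaustive sign-flip: p = 2/1024."""
    x = np.arange(1.0, 11.0)
    res = permutation_test(x, np.zeros(10), paired=True, n_perm=10000)
    assert res.n_permutations == 1024
    assert res.p_value == pytest.approx(2 / 1024)


def test_permutation_p_never_zero(rng):
    x = rng.normal(size=30) + 10
    y = rng.normal(size=30)
    res = permutation_test(x, y, paired=True, n_perm=500)
    assert res.p_value >= 1 / 501


def test_paired_null_p_uniform(rng):
    """Under the null, p-values are uniform (KS test over 1000 runs)."""
    from scipy import stats as sps

    ps = []
    for _ in range(1000):
        d = rng.normal(size=8)
        res = permutation_test(d, np.zeros(8), paired=True, n_perm=4000,
                               seed=0)
        ps.append(res.p_value)
    ks = sps.kstest(ps, "uniform")
    assert ks.pvalue > 0.01


def test_unpaired_detects_shift(rng):
    x = rng.normal(size=25) + 1.5
    y = rng.normal(size=25)
    res = permutation_test(x, y, paired=False, n_perm=2000, seed=1)
    assert res.p_value < 0.01


def test_too_few_pairs_rejected():
    with pytest.raises(ValueError):
        permutation_test(np.array([1.0, 2.0]), np.array([0.0, 0.0]),
                         paired=True)


# --------------------------------------------------------------------- FDR


def test_bh_textbook_example():
    """p = (0.01, 0.02, 0.5) at q=0.05: thresholds are 0.0167 / 0.0333 /
    0.05, so the first two are rejected."""
    np.testing.assert_array_equal(
        fdr_bh([0.01, 0.02, 0.5], 0.05), [True, True, False]
    )


def test_bh_all_ones_rejects_none():
    assert not fdr_bh(np.ones(20), 0.05).any()


def test_bh_empty_input():
    assert fdr_bh(np.array([])).shape == (0,)


def test_bonferroni_subset_of_bh(rng):
    """At the same level, Bonferroni rejections are a subset of BH's."""
    for _ in range(50):
        p = rng.random(30) ** 2
        bon = bonferroni(p, 0.05)
        bh = fdr_bh(p, 0.05)
        assert np.all(bh[bon])


def test_bh_realized_fdr_controlled(rng):
    """Independent nulls: realized false-discovery proportion <= q within
    Monte-Carlo error (2000 replicates, 10 true nulls each)."""
    q = 0.05
    fdp = []
    for _ in range(2000):
        p = rng.random(10)
        rej = fdr_bh(p, q)
        # all hypotheses are null, so FDP = 1 whenever anything is rejected
        fdp.append(1.0 if rej.any() else 0.0)
    realized = np.mean(fdp)
    mc_err = 3 * np.std(fdp) / np.sqrt(len(fdp))
    assert realized <= q + mc_err


# ------------------------------------------------------------------ Cohen's d


def test_cohens_d_unit_shift(rng):
    x = rng.normal(loc=1.0, size=20000)
    y = rng.normal(loc=0.0, size=20000)
    assert cohens_d(x, y) == pytest.approx(1.0, abs=0.05)


def test_cohens_d_identical_zero(rng):
    x = rng.normal(size=50)
    assert cohens_d(x, x.copy(), paired=True) == 0.0


def test_cohens_d_hand_fixture():
    """Four-point fixture against the pooled-SD formula by hand:
    x=(1,2,3,4) m=2.5 s2=5/3; y=(2,4,6,8) m=5 s2=20/3;
    pooled sd = sqrt(25/6); d = -2.5/sqrt(25/6)."""
    x = np.array([1.0, 2.0, 3.0, 4.0])
    y = np.array([2.0, 4.0, 6.0, 8.0])
    want = -2.5 / np.sqrt(25 / 6)
    assert cohens_d(x, y) == pytest.approx(want, abs=1e-12)


def test_cohens_d_zero_variance_flagged():
    with pytest.warns(UserWarning, match="zero variance"):
        d = cohens_d(np.array([1.0, 1.0, 1.0]), np.array([0.0, 0.0, 0.0]))
    assert np.isinf(d) and d > 0


# ---------------------------------------------------------------------- DISS


def test_diss_identical_maps_zero():
    m = np.array([1.0, 2.0, 3.0, 4.0])
    assert diss(m, m.copy()).statistic == pytest.approx(0.0, abs=1e-12)


def test_diss_anticorrelated_maps_four():
    m = np.array([1.0, 2.0, 3.0, 4.0])
    assert diss(m, -m).statistic == pytest.approx(4.0, abs=1e-12)


def test_diss_uncorrelated_maps_two(rng):
    a = rng.normal(size=2000)
    b = rng.normal(size=2000)
    assert diss(a, b).statistic == pytest.approx(2.0, abs=0.15)


def test_diss_sqrt_option():
    m = np.array([1.0, 2.0, 3.0, 4.0])
    assert diss(m, -m, sqrt=True).statistic == pytest.approx(2.0, abs=1e-12)


def test_diss_zero_variance_rejected():
    with pytest.raises(ValueError, match="variance"):
        diss(np.ones(5), np.arange(5.0))


# ------------------------------------------------------------------ Spearman


def test_spearman_perfect_monotone(rng):
    x = rng.normal(size=12)
    assert spearman(x, x, n_perm=200).statistic == pytest.approx(1.0)
    assert spearman(x, -x, n_perm=200).statistic == pytest.approx(-1.0)
    assert spearman(x, np.exp(x), n_perm=200).statistic == pytest.approx(1.0)


def test_spearman_significance(rng):
    x = np.arange(12.0)
    res = spearman(x, x + rng.normal(size=12) * 0.1, n_perm=2000, seed=0)
    assert res.p_value < 0.01


def test_spearman_constant_rejected():
    with pytest.raises(ValueError, match="constant"):
        spearman(np.ones(6), np.arange(6.0))


# ------------------------------------------------------------------ RM-ANOVA


def test_rm_anova_flat_conditions(rng):
    data = rng.normal(size=(8, 1)) + 0.001 * rng.normal(size=(8, 4))
    res = rm_anova(data)
    assert res.p_value > 0.2


def test_rm_anova_matches_hand_sums_of_squares(rng):
    """F statistic equals the explicit sums-of-squares computation."""
    data = rng.normal(size=(9, 4)) + np.array([0.0, 0.4, 0.9, 1.1])
    res = rm_anova(data)
    assert res.statistic == pytest.approx(rm_anova_f_oracle(data), rel=1e-9)


def test_rm_anova_textbook_fixture():
    """Small fixture with hand-checkable sums of squares."""
    data = np.array(
        [
            [30.0, 28.0, 16.0],
            [14.0, 18.0, 10.0],
            [24.0, 20.0, 18.0],
            [38.0, 34.0, 20.0],
            [26.0, 28.0, 14.0],
        ]
    )
    res = rm_anova(data)
    assert res.statistic == pytest.approx(rm_anova_f_oracle(data), rel=1e-9)
    assert res.p_value < 0.05


def test_rm_anova_gg_epsilon_bounds(rng):
    data = rng.normal(size=(10, 5)) + np.arange(5)
    res = rm_anova(data)
    k = 5
    assert 1 / (k - 1) - 1e-9 <= res.extras["epsilon"] <= 1.0 + 1e-9


def test_rm_anova_shape_guards(rng):
    with pytest.raises(ValueError):
        rm_anova(rng.normal(size=(3, 4)))  # too few subjects
    with pytest.raises(ValueError):
        rm_anova(rng.normal(size=(8, 2)))  # too few conditions
    bad = rng.normal(size=(6, 4))
    bad[0, 0] = np.nan
    with pytest.raises(ValueError, match="missing"):
        rm_anova(bad)
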