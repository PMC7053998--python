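"""Statistical machinery: permutation tests, FDR, effect sizes, DISS, RM-ANOVA.

Permutation p-values follow the add-one convention p = (1 + #{|T*| >= |T|})
/ (n_perm + 1) so they are never exactly zero; paired tests with few pairs
switch to exhaustive sign-flip enumeration (identity included), which makes
the test exact.  All randomized procedures are deterministic given a seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "permutation_test",
    "fdr_bh",
    "bonferroni",
    "cohens_d",
    "diss",
    "spearman",
    "rm_anova",
]


@dataclass
class TestResult:
    """Outcome of a single statistical test."""

    statistic: float
    p_value: float
    n_permutations: int = 0
    correction: str = "none"
    effect_size: float | None = None
    tails: str = "two"
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside (0, 1]")


def permutation_test(
    x: np.ndarray,
    y: np.ndarray,
    paired: bool = False,
    n_perm: int = 10000,
    tails: str = "two",
    seed: int = 0,
) -> TestResult:
    """Two-sample permutation test on the difference of means.

    Paired: sign-flip test on the differences x - y (exhaustive over all
    2^n patterns whenever that is no more work than ``n_perm`` draws,
    giving exact p-values).  Unpaired: random relabeling of the pooled
    sample.  ``tails='two'`` compares |T|; ``'greater'`` tests x > y.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if tails not in ("two", "greater"):
        raise ValueError("tails must be 'two' or 'greater'")
    rng = np.random.default_rng(seed)
    if paired:
        if x.shape != y.shape:
            raise ValueError("paired test requires equal lengths")
        d = x - y
        n = len(d)
        if n < 3:
            raise ValueError("need at least 3 pairs")
        t_obs = d.mean()
        if 2 ** n <= n_perm:
            signs = np.array(
                [[1 if (m >> i) & 1 else -1 for i in range(n)]
                 for m in range(2 ** n)], dtype=float)
            t_perm = signs @ d / n
            n_eff = 2 ** n
            exact = True
        else:
            signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
            t_perm = signs @ d / n
            n_eff = n_perm
            exact = False
    else:
        if len(x) < 2 or len(y) < 2:
            raise ValueError("need at least 2 observations per group")
        t_obs = x.mean() - y.mean()
        pooled = np.concatenate([x, y])
        nx = len(x)
        t_perm = np.empty(n_perm)
        for i in range(n_perm):
            rng.shuffle(pooled)
            t_perm[i] = pooled[:nx].mean() - pooled[nx:].mean()
        n_eff = n_perm
        exact = False

    eps = 1e-12 * (1.0 + abs(t_obs))
    if tails == "two":
        count = int(np.sum(np.abs(t_perm) >= abs(t_obs) - eps))
    else:
        count = int(np.sum(t_perm >= t_obs - eps))
    if exact:
        p = count / n_eff  # identity permutation included -> p >= 1/2^n
    else:
        p = (1 + count) / (n_eff + 1)
    return TestResult(float(t_obs), float(p), n_permutations=n_eff, tails=tails)


def fdr_bh(p_values: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask at FDR level q."""
    p_values = np.asarray(p_values, dtype=float)
    if p_values.size == 0:
        return np.zeros(0, dtype=bool)
    reject, *_ = multipletests(p_values, alpha=q, method="fdr_bh")
    return reject


def bonferroni(p_values: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    p_values = np.asarray(p_values, dtype=float)
    return p_values < (alpha / max(p_values.size, 1))


def cohens_d(x: np.ndarray, y: np.ndarray, paired: bool = False) -> float:
    """Cohen's d: mean difference over pooled SD (or SD of differences)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least 2 observations per group")
    if paired:
        if x.shape != y.shape:
            raise ValueError("paired d requires equal lengths")
        d = x - y
        sd = d.std(ddof=1)
        num = d.mean()
    else:
        nx, ny = len(x), len(y)
        sd = np.sqrt(
            ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
        )
        num = x.mean() - y.mean()
    if sd == 0:
        if num == 0:
            return 0.0
        warnings.warn("zero variance in Cohen's d; returning signed infinity")
        return float(np.sign(num) * np.inf)
    return float(num / sd)


def diss(
    map1: np.ndarray,
    map2: np.ndarray,
    n_perm: int = 100,
    seed: int = 0,
    sqrt: bool = False,
) -> TestResult:
    """Topographic dissimilarity between two channel-space maps.

    DISS = 2 * (1 - r) with r the Pearson correlation across channels
    (``sqrt=True`` gives the conventional global-dissimilarity variant
    sqrt(2 * (1 - r))).  The one-sided p-value comes from a randomization
    that swaps the two maps' values channel-wise at random, i.e. the null
    of no topographic difference between conditions.
    """
    map1 = np.asarray(map1, dtype=float)
    map2 = np.asarray(map2, dtype=float)
    if map1.shape != map2.shape or map1.ndim != 1:
        raise ValueError("maps must be equal-length 1-D channel vectors")
    if len(map1) < 3:
        raise ValueError("need at least 3 channels")
    if map1.std() == 0 or map2.std() == 0:
        raise ValueError("zero-variance map")

    def _diss(a, b):
        r = np.corrcoef(a, b)[0, 1]
        val = 2.0 * (1.0 - r)
        return float(np.sqrt(val)) if sqrt else float(val)

    obs = _diss(map1, map2)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        flip = rng.random(len(map1)) < 0.5
        a = np.where(flip, map2, map1)
        b = np.where(flip, map1, map2)
        if a.std() == 0 or b.std() == 0:
            continue
        if _diss(a, b) >= obs - 1e-12:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return TestResult(obs, float(p), n_permutations=n_perm, tails="one")


def spearman(
    x: np.ndarray, y: np.ndarray, n_perm: int = 10000, seed: int = 0
) -> TestResult:
    """Spearman rank correlation with a permutation p-value (two-tailed)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or len(x) < 4:
        raise ValueError("need equal-length vectors of at least 4 values")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant vector has no rank correlation")
    rho = float(sps.spearmanr(x, y).statistic)
    rng = np.random.default_rng(seed)
    count = 0
    yp = y.copy()
    for _ in range(n_perm):
        rng.shuffle(yp)
        if abs(float(sps.spearmanr(x, yp).statistic)) >= abs(rho) - 1e-12:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return TestResult(rho, float(p), n_permutations=n_perm,
                      effect_size=rho, tails="two")


def rm_anova(data: np.ndarray) -> TestResult:
    """One-way repeated-measures ANOVA on a subject x condition matrix.

    Reports F with (k-1, (k-1)(n-1)) degrees of freedom; when Mauchly's
    sphericity test rejects (p < 0.05), degrees of freedom and the p-value
    are Greenhouse-Geisser corrected.
    """
    import pingouin as pg

    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be subject x condition")
    n, k = data.shape
    if k < 3 or n < 4:
        raise ValueError("need >= 3 conditions and >= 4 subjects")
    if not np.all(np.isfinite(data)):
        raise ValueError("missing cells are not supported")
    long = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(n), k),
            "condition": np.tile(np.arange(k), n),
            "value": data.ravel(),
        }
    )
    aov = pg.rm_anova(data=long, dv="value", within="condition",
                      subject="subject", correction=True, detailed=True)
    row = aov.iloc[0]

    def _col(*names, default=np.nan):
        for nm in names:
            if nm in aov.columns:
                return row[nm]
        return default

    p_unc = float(_col("p_unc", "p-unc"))
    p_gg = float(_col("p_GG_corr", "p-GG-corr"))
    mauchly_p = float(_col("p_spher", default=np.nan))
    if not np.isfinite(mauchly_p):
        _, _, mauchly_p = _sphericity(long)
    eps = float(_col("eps", default=1.0))
    use_gg = mauchly_p < 0.05
    if use_gg and np.isfinite(p_gg):
        p = p_gg
        df1, df2 = eps * (k - 1), eps * (k - 1) * (n - 1)
    else:
        p = p_unc
        df1, df2 = float(k - 1), float((k - 1) * (n - 1))
    p = min(max(p, np.nextafter(0, 1)), 1.0)
    return TestResult(
        float(row["F"]), p,
        correction="greenhouse-geisser" if use_gg else "none",
        extras={
            "df": df1,
            "df_error": df2,
            "epsilon": eps,
            "mauchly_p": float(mauchly_p),
            "sphericity": bool(mauchly_p >= 0.05),
        },
    )


def _sphericity(long: pd.DataFrame):
    import pingouin as pg

    res = pg.sphericity(data=long, dv="value", within="condition",
                        subject="subject")
    return res.spher, res.W, res.pval
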