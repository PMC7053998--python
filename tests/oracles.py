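"""Independent reference implementations used as test oracles.

These deliberately use the most direct (brute-force) formulation available
— substring counting, explicit recursions, hand sums of squares — and are
never shared with the library code paths they check.
"""

import numpy as np


def ppm_c_oracle(corpora, alphabet, context):
    """Top-down PPM-C recursion via direct substring counting.

    p(s | ctx) = n(ctx,s)/(n+t) + t/(n+t) * p(s | ctx[1:]), bottoming out
    at the uniform distribution; a context never seen is transparent.
    """
    alphabet = tuple(alphabet)

    def count(ctx, sym):
        total = 0
        for seq in corpora:
            seq = tuple(seq)
            k = len(ctx)
            for i in range(k, len(seq)):
                if seq[i - k : i] == ctx and seq[i] == sym:
                    total += 1
        return total

    def rec(ctx):
        counts = {a: count(ctx, a) for a in alphabet}
        n = sum(counts.values())
        t = sum(1 for v in counts.values() if v > 0)
        base = rec(ctx[1:]) if len(ctx) > 0 else \
            {a: 1.0 / len(alphabet) for a in alphabet}
        if n == 0:
            return base
        return {
            a: counts[a] / (n + t) + t / (n + t) * base[a] for a in alphabet
        }

    return rec(tuple(context))


def rm_anova_f_oracle(data):
    """One-way repeated-measures F from explicit sums of squares."""
    data = np.asarray(data, dtype=float)
    n, k = data.shape
    grand = data.mean()
    subj_means = data.mean(axis=1)
    cond_means = data.mean(axis=0)
    ss_cond = n * np.sum((cond_means - grand) ** 2)
    ss_subj = k * np.sum((subj_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_cond - ss_subj
    df_cond = k - 1
    df_err = (k - 1) * (n - 1)
    return (ss_cond / df_cond) / (ss_err / df_err)


def ridge_normal_equations_oracle(X, y, lam):
    """Centered ridge solution by explicit normal equations."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    Xc = X - X.mean(axis=0)
    yc = y - y.mean(axis=0)
    return np.linalg.solve(Xc.T @ Xc + lam * np.eye(X.shape[1]), Xc.T @ yc)
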