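"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately avoid the code paths they check: ordinary least squares
via normal equations for the sequential ANOVA, the step-up definition for
Benjamini-Hochberg, exact term-by-term enumeration for the binomial tail,
and the textbook rank formula for Spearman.
"""

from math import comb

import numpy as np
from scipy import stats


def ols_rss(X: np.ndarray, y: np.ndarray) -> float:
    """Residual sum of squares via the normal equations."""
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    r = y - X @ beta
    return float(r @ r)


def sequential_anova_bruteforce(y, x1, x2):
    """Sequential (Type-I) ANOVA p-values for y ~ x1 * x2, term order
    x1, x2, x1:x2, each tested against the full-model residual MS."""
    y = np.asarray(y, float)
    n = len(y)
    one = np.ones(n)
    designs = [
        np.column_stack([one]),
        np.column_stack([one, x1]),
        np.column_stack([one, x1, x2]),
        np.column_stack([one, x1, x2, x1 * x2]),
    ]
    rss = [ols_rss(X, y) for X in designs]
    df_resid = n - 4
    ms = rss[-1] / df_resid
    ps = []
    for k in range(3):
        F = (rss[k] - rss[k + 1]) / ms
        ps.append(float(stats.f.sf(F, 1, df_resid)))
    return ps


def bh_bruteforce(p: np.ndarray) -> np.ndarray:
    """q_(i) = min_{j >= i} p_(j) * m / j, mapped back to input order."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    for i in range(m):
        q_sorted[i] = min(p[order[j]] * m / (j + 1) for j in range(i, m))
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def binom_upper_tail_enum(k: int, n: int, p0: float) -> float:
    """Exact enumeration of P(X >= k) for X ~ Binomial(n, p0)."""
    return float(sum(comb(n, j) * p0**j * (1 - p0) ** (n - j) for j in range(k, n + 1)))


def spearman_bruteforce(x, y) -> float:
    """Pearson correlation of average ranks."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry)))


def stouffer_bruteforce(ps):
    """Direct normal-quantile formula."""
    z = np.array([stats.norm.ppf(1 - p) for p in ps])
    Z = z.sum() / np.sqrt(len(z))
    return Z, float(1 - stats.norm.cdf(Z))
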