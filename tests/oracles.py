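"""Independent reference implementations used to cross-check the package.

These deliberately avoid the code paths under test: OLS is solved through
the normal equations in exact rational arithmetic (Python fractions), the
Kolmogorov-Smirnov statistic is accumulated from the empirical CDF by hand,
and divergence onset is re-derived by a plain backwards scan.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
from scipy import stats
from scipy.special import kolmogorov


def exact_ols(ages, values, degree):
    """Normal-equations OLS in exact rational arithmetic + closed-form tests.

    Returns (coefficients, se, p-values, f_p, rss, bic) with BIC computed as
    n*ln(rss/n) + (degree+2)*ln(n).  The linear algebra (X'X solve and
    inverse) is exact; only the final conversion to float and the t/F tail
    probabilities are floating point.
    """
    n, p = len(ages), degree + 1
    A = [[Fraction(float(a)) ** j for j in range(p)] for a in ages]
    y = [Fraction(float(v)) for v in values]
    xtx = [[sum(A[i][r] * A[i][c] for i in range(n)) for c in range(p)] for r in range(p)]
    xty = [sum(A[i][r] * y[i] for i in range(n)) for r in range(p)]
    # Gauss-Jordan on [X'X | I | X'y], exact
    M = [row[:] + [Fraction(int(r == c)) for c in range(p)] + [xty[r]]
         for r, row in enumerate(xtx)]
    for col in range(p):
        piv = max(range(col, p), key=lambda r: abs(M[r][col]))
        M[col], M[piv] = M[piv], M[col]
        pv = M[col][col]
        M[col] = [x / pv for x in M[col]]
        for r in range(p):
            if r != col and M[r][col] != 0:
                f = M[r][col]
                M[r] = [a - f * b for a, b in zip(M[r], M[col])]
    beta = [M[r][-1] for r in range(p)]
    inv = [[M[r][p + c] for c in range(p)] for r in range(p)]
    resid = [y[i] - sum(A[i][j] * beta[j] for j in range(p)) for i in range(n)]
    rss = sum(r * r for r in resid)
    ybar = sum(y) / n
    tss = sum((v - ybar) ** 2 for v in y)
    sigma2 = rss / (n - p)
    se = [float(sigma2 * inv[j][j]) ** 0.5 for j in range(p)]
    tstat = [float(beta[j]) / se[j] for j in range(p)]
    pvals = [2.0 * stats.t.sf(abs(t), n - p) for t in tstat]
    fstat = (float(tss - rss) / (p - 1)) / float(sigma2)
    f_p = float(stats.f.sf(fstat, p - 1, n - p))
    bic = n * np.log(float(rss) / n) + (degree + 2) * np.log(n)
    return (np.array([float(b) for b in beta]), np.array(se), np.array(pvals),
            f_p, float(rss), float(bic))


def ks_statistic_by_hand(z):
    """One-sample KS distance of standardized data to the standard normal,
    via the classic sup over the sorted empirical CDF; asymptotic p from the
    Kolmogorov distribution."""
    z = np.sort(np.asarray(z, float))
    n = z.size
    cdf = stats.norm.cdf(z)
    d_plus = np.max(np.arange(1, n + 1) / n - cdf)
    d_minus = np.max(cdf - np.arange(0, n) / n)
    d = max(d_plus, d_minus)
    return d, float(kolmogorov(d * np.sqrt(n)))


def sustained_onset_by_hand(healthy_lower, disease_upper, grid):
    """Backwards scan for the smallest grid age from which disease_upper <
    healthy_lower holds through the end of the grid."""
    onset = None
    for i in range(len(grid) - 1, -1, -1):
        if disease_upper[i] < healthy_lower[i]:
            onset = grid[i]
        else:
            break
    return onset
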