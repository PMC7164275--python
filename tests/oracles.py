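"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths (and where possible the library
calls) used by the implementation: explicit double-loop sums of squares,
numerical integration for the F tail, exhaustive pair counting for the
AUC, and a sort-and-interpolate percentile.
"""

import math

import numpy as np
from scipy.integrate import quad
from scipy.stats import f as f_dist


def anova_oracle(table):
    """One-way ANOVA mean squares by explicit double-loop sums of squares."""
    table = [list(map(float, row)) for row in table]
    n = len(table)
    k = len(table[0])
    grand = sum(sum(row) for row in table) / (n * k)
    ss_between = 0.0
    ss_within = 0.0
    for row in table:
        rm = sum(row) / k
        ss_between += k * (rm - grand) ** 2
        for v in row:
            ss_within += (v - rm) ** 2
    return ss_between / (n - 1), ss_within / (n * (k - 1))


def icc_oracle(table, rho0=0.20):
    """ICC estimate and one-sided p-value; tail probability by numerical
    integration of the F density (not the sf code path)."""
    msb, msw = anova_oracle(table)
    n, k = len(table), len(table[0])
    if msw == 0.0:
        return 1.0, 0.0
    est = (msb - msw) / (msb + (k - 1) * msw)
    fstat = (msb / msw) * (1 - rho0) / (1 + (k - 1) * rho0)
    p, _ = quad(lambda x: f_dist.pdf(x, n - 1, n * (k - 1)), fstat, np.inf)
    return est, p


def auc_pair_counting(scores, labels):
    """AUC by exhaustive case-control pair counting, ties half."""
    cases = [s for s, y in zip(scores, labels) if y]
    controls = [s for s, y in zip(scores, labels) if not y]
    total = 0.0
    for c in cases:
        for d in controls:
            total += 1.0 if c > d else (0.5 if c == d else 0.0)
    return total / (len(cases) * len(controls))


def delong_variance_oracle(scores, labels):
    """DeLong AUC variance by direct placement-value computation."""
    cases = [s for s, y in zip(scores, labels) if y]
    controls = [s for s, y in zip(scores, labels) if not y]
    m, n = len(cases), len(controls)
    v10 = []
    for c in cases:
        v10.append(sum(1.0 if c > d else (0.5 if c == d else 0.0)
                       for d in controls) / n)
    v01 = []
    for d in controls:
        v01.append(sum(1.0 if c > d else (0.5 if c == d else 0.0)
                       for c in cases) / m)
    def svar(xs):
        mu = sum(xs) / len(xs)
        return sum((x - mu) ** 2 for x in xs) / (len(xs) - 1)
    return svar(v10) / m + svar(v01) / n


def percentile_oracle(values, p):
    """Sort-and-interpolate percentile at rank 1 + (p/100)(m-1)."""
    xs = sorted(float(v) for v in values)
    m = len(xs)
    rank = (p / 100.0) * (m - 1)
    lo = math.floor(rank)
    frac = rank - lo
    if lo + 1 >= m:
        return xs[-1]
    return xs[lo] * (1 - frac) + xs[lo + 1] * frac


def chi2_oracle(observed):
    """Pearson chi-square statistic sum((O-E)^2/E) for a contingency table."""
    obs = np.asarray(observed, float)
    rows = obs.sum(axis=1, keepdims=True)
    cols = obs.sum(axis=0, keepdims=True)
    expected = rows @ cols / obs.sum()
    return float(((obs - expected) ** 2 / expected).sum())


def zou_n_from_power_equation(rho1, rho0, k, alpha, power, tails):
    """Independent re-derivation of the ICC sample size: solve the normal-
    approximation power equation based on the asymptotic variance of the
    log-transformed F ratio, var(ln F_hat) ~ 2k / ((k-1)(n-1))."""
    from scipy.optimize import brentq
    from scipy.stats import norm

    L = abs(math.log(((1 + (k - 1) * rho1) / (1 - rho1))
                     / ((1 + (k - 1) * rho0) / (1 - rho0))))
    za = norm.ppf(1 - alpha / tails)

    def g(n):
        se = math.sqrt(2.0 * k / ((k - 1) * (n - 1)))
        return norm.cdf(L / se - za) - power

    return brentq(g, 1.0 + 1e-9, 1e7, xtol=1e-12, rtol=1e-15)
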