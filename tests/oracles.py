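"""Independent brute-force oracles used by the tests.

Everything here is written from the index definitions directly, without
touching the package implementation, so agreement is a genuine dual-route
check.
"""

import numpy as np
from scipy import stats


def shannon_oracle(x):
    p = x[x > 0] / x.sum()
    return -sum(pi * np.log(pi) for pi in p)


def chao1_oracle(x):
    s = int((x > 0).sum())
    f1 = int((x == 1).sum())
    f2 = int((x == 2).sum())
    return s + f1 * (f1 - 1) / (2 * (f2 + 1))


def inverse_simpson_oracle(x):
    p = x / x.sum()
    return 1.0 / sum(pi ** 2 for pi in p)


def gini_simpson_oracle(x):
    p = x / x.sum()
    return 1.0 - sum(pi ** 2 for pi in p)


def fisher_oracle(x):
    """Fisher alpha by bisection (independent of the brentq route)."""
    s, n = float((x > 0).sum()), float(x.sum())
    if s == 1:
        return 0.0
    lo, hi = 1e-10, 1e9
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if mid * np.log(1 + n / mid) < s:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def coverage_oracle(x, threshold=0.5):
    p = sorted(x / x.sum(), reverse=True)
    total, k = 0.0, 0
    for pi in p:
        total += pi
        k += 1
        if total >= threshold - 1e-12:
            return k
    return k


def camargo_oracle(x):
    p = x[x > 0] / x.sum()
    s = len(p)
    acc = 0.0
    for i in range(s):
        for j in range(i + 1, s):
            acc += abs(p[i] - p[j])
    return 1.0 - acc / s


def pielou_oracle(x):
    s = (x > 0).sum()
    return shannon_oracle(x) / np.log(s) if s > 1 else 0.0


def simpson_evenness_oracle(x):
    return inverse_simpson_oracle(x) / (x > 0).sum()


def evar_oracle(x):
    v = np.var(np.log(x[x > 0]))
    return 1.0 - (2.0 / np.pi) * np.arctan(v)


def bulla_oracle(x):
    p = x[x > 0] / x.sum()
    s = len(p)
    if s <= 1:
        return 0.0
    o = sum(min(pi, 1.0 / s) for pi in p)
    return (o - 1.0 / s) / (1.0 - 1.0 / s)


def berger_parker_oracle(x):
    return (x / x.sum()).max()


def dmn_oracle(x):
    p = sorted(x / x.sum(), reverse=True)
    return p[0] + (p[1] if len(p) > 1 else 0.0)


def gini_oracle(x):
    p = x / x.sum()
    s = len(p)
    acc = 0.0
    for i in range(s):
        for j in range(s):
            acc += abs(p[i] - p[j])
    return acc / (2.0 * s * s * (1.0 / s))


def core_abundance_oracle(x, core_mask):
    p = x / x.sum()
    return p[core_mask].sum()


def low_abundance_oracle(x, cutoff=0.002):
    p = x / x.sum()
    return p[p < cutoff].sum()


def log_modulo_skewness_oracle(x, n_bins=50):
    p = x[x > 0] / x.sum()
    if len(p) < 2 or p.max() == p.min():
        return 0.0
    hist, _ = np.histogram(p, bins=n_bins, range=(p.min(), p.max()))
    return np.log(abs(stats.skew(hist)) + 1.0)


def bh_oracle(pvalues):
    """Literal step-up from the definition: search the largest k with
    p(k) <= k*alpha/m for every alpha, i.e. adjusted p directly."""
    p = list(pvalues)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [None] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adjusted[i] = running
    return np.array(adjusted)


def ridge_oracle(X, y, lam):
    """(Z'Z + lam I)^-1 Z'y on standardized columns, unpenalized intercept."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    mean, sd = X.mean(axis=0), X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Z = (X - mean) / sd
    beta = np.linalg.inv(Z.T @ Z + lam * np.eye(X.shape[1])) @ Z.T @ (y - y.mean())
    coef = beta / sd
    return coef, y.mean() - coef @ mean
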