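"""Independent, deliberately unvectorized oracles used by the tests.

Each function re-derives a quantity from first principles (scalar loops,
rational arithmetic, brute-force enumeration) without touching the
library code it checks.
"""

from __future__ import annotations

import math
from fractions import Fraction


def tmm_factors_oracle(counts, lib_sizes, trim_m=0.3, trim_a=0.05):
    """Step-by-step TMM factors for a genes x samples list-of-lists.

    Returns a list of per-sample factors rescaled to geometric mean 1.
    Pure-Python loops; average-tie ranks computed by hand.
    """
    n_genes = len(counts)
    n_samples = len(counts[0])

    def quantile75(col):
        vals = sorted(counts[g][col] for g in range(n_genes))
        # linear interpolation (R type-7) at p = 0.75
        h = (len(vals) - 1) * 0.75
        lo = math.floor(h)
        hi = math.ceil(h)
        return (vals[lo] + (h - lo) * (vals[hi] - vals[lo])) / lib_sizes[col]

    f75 = [quantile75(k) for k in range(n_samples)]
    mean75 = sum(f75) / n_samples
    ref = min(range(n_samples), key=lambda k: abs(f75[k] - mean75))

    def avg_ranks(values):
        order = sorted(range(len(values)), key=lambda i: values[i])
        ranks = [0.0] * len(values)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
                j += 1
            avg = (i + j) / 2.0 + 1.0
            for t in range(i, j + 1):
                ranks[order[t]] = avg
            i = j + 1
        return ranks

    log2f = []
    for k in range(n_samples):
        if k == ref:
            log2f.append(0.0)
            continue
        m_vals, a_vals, w_vals = [], [], []
        for g in range(n_genes):
            yk, yr = counts[g][k], counts[g][ref]
            if yk > 0 and yr > 0:
                pk, pr = yk / lib_sizes[k], yr / lib_sizes[ref]
                m_vals.append(math.log2(pk / pr))
                a_vals.append(0.5 * math.log2(pk * pr))
                w_vals.append(
                    1.0
                    / (
                        (lib_sizes[k] - yk) / (lib_sizes[k] * yk)
                        + (lib_sizes[ref] - yr) / (lib_sizes[ref] * yr)
                    )
                )
        if not m_vals:
            log2f.append(0.0)
            continue
        if max(abs(m) for m in m_vals) < 1e-6:
            log2f.append(0.0)
            continue
        n = len(m_vals)
        lo_m = math.floor(n * trim_m) + 1
        hi_m = n + 1 - lo_m
        lo_a = math.floor(n * trim_a) + 1
        hi_a = n + 1 - lo_a
        rm = avg_ranks(m_vals)
        ra = avg_ranks(a_vals)
        num = den = 0.0
        for i in range(n):
            if lo_m <= rm[i] <= hi_m and lo_a <= ra[i] <= hi_a:
                num += w_vals[i] * m_vals[i]
                den += w_vals[i]
        log2f.append(num / den if den > 0 else 0.0)

    factors = [2.0 ** v for v in log2f]
    log_mean = sum(math.log(f) for f in factors) / n_samples
    geo = math.exp(log_mean)
    return [f / geo for f in factors]


def binomial_conditional_pvalue(a: int, b: int, n1: int, n2: int) -> float:
    """Exact two-sided conditional p at phi = 0 via rational enumeration.

    The conditional law of the first group sum given the total s is
    binomial(s, n1/(n1+n2)); the p-value sums P(a') over all splits with
    P(a') <= P(a), computed in exact rational arithmetic.
    """
    s = a + b
    if s == 0:
        return 1.0
    # P(a') proportional to C(s, a') * n1^a' * n2^(s - a') -- exact integers
    weights = [math.comb(s, k) * n1 ** k * n2 ** (s - k) for k in range(s + 1)]
    obs = weights[a]
    total = sum(weights)
    tail = sum(w for w in weights if w <= obs)
    return float(Fraction(tail, total))


def bh_stepup_oracle(pvalues):
    """Benjamini-Hochberg step-up by the textbook recursion."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvalues[i] * m / rank)
        q[i] = running
    return q


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), exact rationals."""
    total = math.comb(N, n)
    tail = sum(
        math.comb(K, i) * math.comb(N - K, n - i)
        for i in range(k, min(K, n) + 1)
    )
    return float(Fraction(tail, total))
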