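"""Independent brute-force oracles used only by the test suite.

Each oracle recomputes a quantity by direct enumeration or a step-by-step
textbook procedure, sharing no code with the implementation it checks.
"""

from __future__ import annotations

import math
from fractions import Fraction
from itertools import product

import numpy as np
from scipy.stats import nbinom


def hypergeom_upper_tail(overlap: int, universe: int, set_size: int,
                         query_size: int) -> float:
    """P(X >= overlap) for X ~ Hypergeometric, by exact rational tail sum.

    Numerators are summed as exact integers and divided once at the end, so
    the result is the correctly rounded float of the exact rational tail.
    """
    numerator = 0
    upper = min(set_size, query_size)
    for k in range(overlap, upper + 1):
        numerator += (math.comb(set_size, k)
                      * math.comb(universe - set_size, query_size - k))
    return float(Fraction(numerator, math.comb(universe, query_size)))


def wilcoxon_less_p(values) -> float:
    """One-sample one-sided (median < 0) signed-rank p by 2^n enumeration.

    Assumes no zeros and no tied absolute values. The observed statistic is
    W+ (rank sum of positive values); the p-value is the fraction of the 2^n
    equiprobable sign assignments with W+ <= observed.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    ranks = np.argsort(np.argsort(np.abs(values))) + 1
    w_obs = int(ranks[values > 0].sum())
    count = 0
    for signs in product((0, 1), repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if w <= w_obs:
            count += 1
    return count / 2.0 ** n


def signed_rank_less_cdf(n: int) -> np.ndarray:
    """Null CDF of W+ over all 2^n sign assignments, by full enumeration.

    ``cdf[w]`` is the one-sided (median < 0) p-value of an observed rank sum
    w for a sample of n distinct, non-zero values.
    """
    sums = np.zeros(1, dtype=np.int64)
    for rank in range(1, n + 1):
        sums = np.concatenate([sums, sums + rank])
    counts = np.bincount(sums, minlength=n * (n + 1) // 2 + 1)
    return np.cumsum(counts) / 2.0 ** n


def nb_exact_two_sided_p(a_sum: int, b_sum: int, n_a: int, n_b: int,
                         dispersion: float, mu: float = 10.0) -> float:
    """Conditional two-sided exact p by enumerating all splits of the total.

    Under the null both group sums are NB: the A-sum has size n_a/dispersion,
    the B-sum size n_b/dispersion, with a common mean per sample. The
    conditional probability of each split (k, t-k) of the total t is the
    product of the two unconditional pmfs, normalized over all splits; the
    mean parameter cancels in the normalization. The p-value doubles the
    smaller tail (observed value included), capped at 1.
    """
    t = a_sum + b_sum
    if t == 0:
        return 1.0
    r_a, r_b = n_a / dispersion, n_b / dispersion
    p_a = r_a / (r_a + n_a * mu)
    p_b = r_b / (r_b + n_b * mu)
    k = np.arange(t + 1)
    probs = nbinom.pmf(k, r_a, p_a) * nbinom.pmf(t - k, r_b, p_b)
    probs = probs / probs.sum()
    lower = probs[: a_sum + 1].sum()
    upper = probs[a_sum:].sum()
    return float(min(1.0, 2.0 * min(lower, upper)))


def tmm_factor_pair(obs, ref, logratio_trim=0.3, sum_trim=0.05):
    """Step-by-step trimmed weighted mean of M-values for one sample pair.

    Written deliberately as explicit Python lists with sorting-based trims;
    returns the unnormalized 2^f factor of ``obs`` against ``ref``.
    """
    n_obs = float(sum(obs))
    n_ref = float(sum(ref))
    records = []
    for y_o, y_r in zip(obs, ref):
        if y_o > 0 and y_r > 0:
            m = math.log2((y_o / n_obs) / (y_r / n_ref))
            a = 0.5 * math.log2((y_o / n_obs) * (y_r / n_ref))
            w = (n_obs - y_o) / (n_obs * y_o) + (n_ref - y_r) / (n_ref * y_r)
            records.append((m, a, w))
    if not records:
        return 1.0
    if max(abs(m) for m, _, _ in records) < 1e-6:
        return 1.0

    def average_ranks(values):
        order = sorted(range(len(values)), key=lambda i: values[i])
        ranks = [0.0] * len(values)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
                j += 1
            avg = (i + j) / 2.0 + 1.0
            for k in range(i, j + 1):
                ranks[order[k]] = avg
            i = j + 1
        return ranks

    n = len(records)
    m_ranks = average_ranks([m for m, _, _ in records])
    a_ranks = average_ranks([a for _, a, _ in records])
    lo_m = math.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = math.floor(n * sum_trim) + 1
    hi_a = n + 1 - lo_a
    num = den = 0.0
    for (m, _, w), rm, ra in zip(records, m_ranks, a_ranks):
        if lo_m <= rm <= hi_m and lo_a <= ra <= hi_a:
            num += m / w
            den += 1.0 / w
    if den == 0:
        return 1.0
    return 2.0 ** (num / den)


def tmm_factors_oracle(counts_df, logratio_trim=0.3, sum_trim=0.05):
    """Full TMM oracle: reference choice, pairwise factors, geometric rescale."""
    cols = list(counts_df.columns)
    mat = counts_df.to_numpy(dtype=float)
    lib = mat.sum(axis=0)
    f75 = [float(np.quantile(mat[:, j] / lib[j], 0.75)) for j in range(len(cols))]
    mean75 = sum(f75) / len(f75)
    ref = min(range(len(cols)), key=lambda j: abs(f75[j] - mean75))
    factors = []
    for j in range(len(cols)):
        if j == ref:
            factors.append(1.0)
        else:
            factors.append(tmm_factor_pair(mat[:, j], mat[:, ref],
                                           logratio_trim, sum_trim))
    log_mean = sum(math.log(f) for f in factors) / len(factors)
    return [f / math.exp(log_mean) for f in factors]
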