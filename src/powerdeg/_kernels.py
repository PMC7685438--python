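"""Compiled numerical kernels for the conditional negative-binomial exact test.

The two-group exact test used throughout the package conditions on the sum
``s`` of the two group totals.  When every sample has the same effective
library size and the per-sample dispersion is ``phi``, the group totals are
``NB(mean = n_A * mu, size = n_A / phi)`` and ``NB(mean = n_B * mu,
size = n_B / phi)`` under the null of a common per-sample mean ``mu``.  The
mean cancels out of the conditional distribution, which is exactly
Beta-Binomial(s, r_A, r_B) with ``r_A = n_A / phi`` and ``r_B = n_B / phi``
(Binomial(s, n_A / (n_A + n_B)) in the Poisson limit ``phi = 0``).

Two-sided extremeness follows the minimum-likelihood convention: the p-value
of an observed group-A total ``a`` is the null conditional probability of all
outcomes whose conditional probability does not exceed that of ``a``.

All kernels require ``r_A, r_B >= 1`` (equivalently ``phi <= min(n_A, n_B)``)
so the conditional pmf is log-concave and tail walks carry geometric error
bounds.
"""

import math

import numba
import numpy as np

_NEG_INF = -np.inf


@numba.njit(cache=True)
def _logpmf_bb_sym(a, s, r):
    """log pmf of BetaBinomial(s, r, r) at a (closed form)."""
    return (
        math.lgamma(s + 1.0)
        - math.lgamma(a + 1.0)
        - math.lgamma(s - a + 1.0)
        + math.lgamma(a + r)
        + math.lgamma(s - a + r)
        - math.lgamma(s + 2.0 * r)
        - 2.0 * math.lgamma(r)
        + math.lgamma(2.0 * r)
    )


@numba.njit(cache=True)
def _left_tail_sym(c, s, r, cap):
    """Upper bound on P(X <= c) for X ~ BetaBinomial(s, r, r), c < s/2.

    Sums the tail downward from ``c`` with the pmf ratio recurrence and stops
    once either the accumulated mass exceeds ``cap`` (the caller only needs
    the comparison) or the geometric bound on the remainder is negligible;
    the bound is added to the returned value so the comparison with ``cap``
    is conservative.
    """
    if c < 0:
        return 0.0
    term = math.exp(_logpmf_bb_sym(float(c), float(s), r))
    total = term
    a = float(c)
    while a > 0.0:
        ratio = a * (s - a + r) / ((a - 1.0 + r) * (s - a + 1.0))
        term *= ratio
        total += term
        a -= 1.0
        if total > cap:
            return total
        if ratio < 1.0:
            bound = term * ratio / (1.0 - ratio)
            if bound < 1e-10 * total and bound < 1e-10 * cap:
                return total + bound
    return total


@numba.njit(cache=True)
def _init_threshold(s, r, half):
    """Largest c with P(X <= c) <= half, X ~ BetaBinomial(s, r, r)."""
    sd = math.sqrt((s / 4.0) * (s + 2.0 * r) / (2.0 * r + 1.0))
    c = int(s / 2.0 - 4.0 * sd)
    cmax = (s - 1) // 2
    if c > cmax:
        c = cmax
    if c < -1:
        c = -1
    while c >= 0 and _left_tail_sym(c, s, r, half) > half:
        c -= 1
    while c < cmax and _left_tail_sym(c + 1, s, r, half) <= half:
        c += 1
    return c


@numba.njit(cache=True)
def rejection_thresholds(smin, smax, r, alpha):
    """Per-total rejection cutoffs of the symmetric two-sided exact test.

    For each grand total ``s`` in ``[smin, smax]`` returns the largest
    ``c(s) < s/2`` such that the doubled lower tail of
    BetaBinomial(s, r, r) at ``c(s)`` does not exceed ``alpha``; the test
    rejects iff the smaller group total is ``<= c(s)``.  ``c(s) = -1``
    marks totals where no outcome is extreme enough.
    """
    half = alpha / 2.0
    n_s = smax - smin + 1
    out = np.empty(n_s, dtype=np.int64)
    c = _init_threshold(smin, r, half)
    out[0] = c
    for i in range(1, n_s):
        s = smin + i
        cmax = (s - 1) // 2
        increased = False
        while c < cmax and _left_tail_sym(c + 1, s, r, half) <= half:
            c += 1
            increased = True
        if not increased:
            while c >= 0 and _left_tail_sym(c, s, r, half) > half:
                c -= 1
        out[i] = c
    return out


@numba.njit(cache=True)
def _cond_pvalue(aobs, s, rA, rB, poisson, log_nA, log_nB):
    """Minimum-likelihood two-sided p-value of the conditional exact test.

    ``aobs`` is the observed group-A total, ``s`` the grand total.  The null
    conditional law is BetaBinomial(s, rA, rB), or Binomial(s, nA/(nA+nB))
    when ``poisson`` is set.  Computed as 1 - P(outcomes strictly more
    likely than aobs), summing the unimodal pmf outward from its mode; ties
    with the observed probability count toward the p-value.
    """
    if s <= 0:
        return 1.0
    # unnormalized log pmf g(a); constants in a are dropped
    if poisson:
        g_obs = (
            -math.lgamma(aobs + 1.0)
            - math.lgamma(s - aobs + 1.0)
            + aobs * log_nA
            + (s - aobs) * log_nB
        )
    else:
        g_obs = (
            math.lgamma(aobs + rA)
            - math.lgamma(aobs + 1.0)
            + math.lgamma(s - aobs + rB)
            - math.lgamma(s - aobs + 1.0)
        )

    # locate the mode by a local climb from a moment-based guess
    if poisson:
        a0 = int(s * math.exp(log_nA) / (math.exp(log_nA) + math.exp(log_nB)))
    else:
        a0 = int(s * rA / (rA + rB))
    if a0 < 0:
        a0 = 0
    if a0 > s:
        a0 = s
    while a0 < s:
        if poisson:
            ratio = (s - a0) / (a0 + 1.0) * math.exp(log_nA - log_nB)
        else:
            ratio = (a0 + rA) * (s - a0) / ((a0 + 1.0) * (s - a0 - 1.0 + rB))
        if ratio > 1.0:
            a0 += 1
        else:
            break
    while a0 > 0:
        if poisson:
            ratio = (s - a0 + 1.0) / a0 * math.exp(log_nA - log_nB)
        else:
            ratio = (a0 - 1.0 + rA) * (s - a0 + 1.0) / (a0 * (s - a0 + rB))
        if ratio < 1.0:
            a0 -= 1
        else:
            break

    if poisson:
        g_max = (
            -math.lgamma(a0 + 1.0)
            - math.lgamma(s - a0 + 1.0)
            + a0 * log_nA
            + (s - a0) * log_nB
        )
    else:
        g_max = (
            math.lgamma(a0 + rA)
            - math.lgamma(a0 + 1.0)
            + math.lgamma(s - a0 + rB)
            - math.lgamma(s - a0 + 1.0)
        )

    t_obs = math.exp(g_obs - g_max)
    strict = t_obs * (1.0 + 1e-12)

    z_total = 1.0
    interior = 0.0 if strict >= 1.0 else 1.0

    # right side of the mode
    term = 1.0
    a = a0
    while a < s:
        if poisson:
            ratio = (s - a) / (a + 1.0) * math.exp(log_nA - log_nB)
        else:
            ratio = (a + rA) * (s - a) / ((a + 1.0) * (s - a - 1.0 + rB))
        term *= ratio
        a += 1
        if term < 1e-17:
            break
        z_total += term
        if term > strict:
            interior += term
    # left side of the mode
    term = 1.0
    a = a0
    while a > 0:
        if poisson:
            ratio = a / (s - a + 1.0) * math.exp(log_nB - log_nA)
        else:
            ratio = a * (s - a + rB) / ((a - 1.0 + rA) * (s - a + 1.0))
        term *= ratio
        a -= 1
        if term < 1e-17:
            break
        z_total += term
        if term > strict:
            interior += term

    p = 1.0 - interior / z_total
    if p < 1e-300:
        p = 1e-300
    if p > 1.0:
        p = 1.0
    return p


@numba.njit(cache=True)
def cond_pvalues(aobs, totals, nA, nB, phi):
    """Vectorized conditional exact-test p-values over genes.

    ``aobs[g]`` and ``totals[g]`` are the group-A and grand totals of gene
    ``g``; ``phi[g]`` its dispersion (0 selects the Poisson/binomial limit).
    """
    out = np.empty(aobs.shape[0])
    log_nA = math.log(nA)
    log_nB = math.log(nB)
    for g in range(aobs.shape[0]):
        if phi[g] <= 0.0:
            out[g] = _cond_pvalue(
                float(aobs[g]), float(totals[g]), 0.0, 0.0, True, log_nA, log_nB
            )
        else:
            out[g] = _cond_pvalue(
                float(aobs[g]),
                float(totals[g]),
                nA / phi[g],
                nB / phi[g],
                False,
                log_nA,
                log_nB,
            )
    return out
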