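"""Analytic power of the two-group negative-binomial exact test.

The design question addressed here: how many biological replicates, how much
sequencing depth, and how little biological variance does a case-control
RNA-seq experiment need before a gene with a *weak* fold change (1.05-1.5)
becomes detectable?  Per-sample counts in the reference group are modelled as
NB(mean = lambda0, dispersion = phi0) and in the other group as
NB(mean = w * rho * lambda0, dispersion = phi0), with variance
mu + phi * mu^2.  The test is the conditional exact test on the two group
totals (see :mod:`powerdeg._kernels`), and power is the exact sum of
alternative-model probabilities over the rejection region — no normal
approximation is involved.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from . import _kernels

__all__ = [
    "PowerPoint",
    "PowerGrid",
    "est_power",
    "mc_power",
    "traverse_grid",
    "bonferroni_cutoff",
    "default_axes",
]

#: truncation quantile for the group-total supports in the power sum;
#: the neglected probability mass is bounded by ~4e-12 per tail.
_TRUNC = 1e-12


def _validate_point(n, rho, lambda0, phi0, alpha, w):
    if not (isinstance(n, (int, np.integer)) or float(n).is_integer()):
        raise ValueError(f"sample size n must be an integer, got {n!r}")
    n = int(n)
    if n < 2:
        raise ValueError(f"sample size n must be >= 2, got {n}")
    for name, val in (("rho", rho), ("lambda0", lambda0), ("phi0", phi0), ("w", w)):
        if not (np.isfinite(val) and val > 0):
            raise ValueError(f"{name} must be a positive finite number, got {val!r}")
    if not (np.isfinite(alpha) and 0.0 < alpha < 1.0):
        raise ValueError(f"alpha must lie in (0, 1), got {alpha!r}")
    if n / phi0 < 1.0:
        raise ValueError(
            f"dispersion phi0={phi0} too large for n={n}: the conditional "
            "exact-test kernel requires phi0 <= n"
        )
    return n


@lru_cache(maxsize=16)
def _thresholds_cached(smin: int, smax: int, r: float, alpha: float) -> np.ndarray:
    out = _kernels.rejection_thresholds(smin, smax, r, alpha)
    # the power summation and the Monte-Carlo region lookup both rely on the
    # cutoff being non-decreasing in the grand total
    if np.any(np.diff(out) < 0):
        raise RuntimeError("rejection cutoff not monotone in the grand total")
    return out


def _total_support(mu: float, r: float) -> tuple[int, int]:
    dist = stats.nbinom(r, r / (r + mu))
    lo = int(dist.ppf(_TRUNC))
    hi = int(dist.isf(_TRUNC))
    return max(lo, 0), hi


def est_power(n, rho, lambda0, phi0, alpha, w=1.0):
    """Power of the two-sided NB exact test at one design point.

    Parameters
    ----------
    n : int
        Samples per group (>= 2).
    rho : float
        Fold change between the groups (> 0; 1 is the null).
    lambda0 : float
        Average read (fragment) count of the reference group.
    phi0 : float
        Dispersion, i.e. variance = mu + phi0 * mu^2 per sample.
    alpha : float
        Per-test significance level.
    w : float, optional
        Ratio of normalization factors between the groups (default 1).

    Returns
    -------
    float
        Probability that the exact test rejects at level ``alpha``.

    Notes
    -----
    Group totals are NB with mean ``n * (group mean)`` and dispersion
    ``phi0 / n``.  Conditional on the grand total ``s`` the null law of the
    group-A total is BetaBinomial(s, r, r) with ``r = n / phi0``; the test
    rejects when the smaller group total falls at or below the cutoff
    ``c(s)`` at which the doubled minimum-likelihood tail is ``<= alpha``.
    Power sums ``P_alt(A = a) * P_alt(B = b)`` over the rejection region,
    with the grand total truncated outside the ``1e-12`` quantiles.
    """
    n = _validate_point(n, rho, lambda0, phi0, alpha, w)
    r = n / phi0
    mu_a = n * lambda0
    mu_b = n * w * rho * lambda0

    a_lo, a_hi = _total_support(mu_a, r)
    b_lo, b_hi = _total_support(mu_b, r)
    smin, smax = a_lo + b_lo, a_hi + b_hi
    cutoff = _thresholds_cached(smin, smax, r, float(alpha))

    dist_a = stats.nbinom(r, r / (r + mu_a))
    dist_b = stats.nbinom(r, r / (r + mu_b))

    power = 0.0
    for dist_low, dist_other, lo, hi in (
        (dist_a, dist_b, a_lo, a_hi),
        (dist_b, dist_a, b_lo, b_hi),
    ):
        # low-tail rejection of this group: totals t <= c(s).  c is
        # non-decreasing, so {s : c(s) >= t} = {s >= v(t)} and the other
        # group's total must reach at least v(t) - t.
        t = np.arange(lo, min(hi, cutoff[-1]) + 1)
        if t.size == 0:
            continue
        v = smin + np.searchsorted(cutoff, t, side="left")
        need = v - t  # minimum for the other group's total
        power += float(np.sum(dist_low.pmf(t) * dist_other.sf(need - 1)))
    return min(power, 1.0)


def mc_power(n, rho, lambda0, phi0, alpha, w=1.0, n_sims=200_000, seed=0):
    """Monte Carlo rejection rate of the same exact test.

    Simulates ``n_sims`` gene instances from the stated NB model, applies
    the identical rejection rule (shared cutoff kernel) and returns the
    fraction rejected.  Serves as the stochastic cross-check of
    :func:`est_power`.
    """
    n = _validate_point(n, rho, lambda0, phi0, alpha, w)
    r = n / phi0
    mu_a = n * lambda0
    mu_b = n * w * rho * lambda0
    rng = np.random.default_rng(seed)
    a = rng.negative_binomial(r, r / (r + mu_a), size=n_sims)
    b = rng.negative_binomial(r, r / (r + mu_b), size=n_sims)
    s = a + b
    smin, smax = int(s.min()), int(s.max())
    cutoff = _thresholds_cached(smin, smax, r, float(alpha))
    c_s = cutoff[s - smin]
    return float(np.mean(np.minimum(a, b) <= c_s))


def bonferroni_cutoff(family_alpha, m_tests):
    """Per-test significance level after Bonferroni correction.

    ``bonferroni_cutoff(0.05, 15000)`` gives the 3.3e-6 cutoff used for the
    genome-wide power surfaces.
    """
    if not (0.0 < family_alpha < 1.0):
        raise ValueError(f"family_alpha must lie in (0, 1), got {family_alpha!r}")
    if not (isinstance(m_tests, (int, np.integer)) or float(m_tests).is_integer()):
        raise ValueError(f"m_tests must be an integer, got {m_tests!r}")
    m_tests = int(m_tests)
    if m_tests < 1:
        raise ValueError(f"m_tests must be >= 1, got {m_tests}")
    return family_alpha / m_tests


@dataclass(frozen=True)
class PowerPoint:
    """One design point of the power surface with its computed power."""

    n: int
    rho: float
    lambda0: float
    phi0: float
    alpha: float
    w: float
    power: float


@dataclass
class PowerGrid:
    """Cartesian power surface over (n, rho, lambda0, phi0)."""

    axes: dict = field(default_factory=dict)
    alpha: float = 3.3e-6
    w: float = 1.0
    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __len__(self):
        return len(self.table)

    def points(self):
        for row in self.table.itertuples(index=False):
            yield PowerPoint(
                int(row.n), row.rho, row.lambda0, row.phi0, self.alpha, self.w, row.power
            )


def default_axes():
    """Default design-parameter axes (configuration, not a fixed constant).

    Sample size 3..13, fold change 1.05..1.5 in steps of 0.05, mean read
    count in powers of two from 64 to 65,536 and dispersion in doublings
    from 0.0005 to 0.016.
    """
    return {
        "n": list(range(3, 14)),
        "rho": [round(1.05 + 0.05 * i, 2) for i in range(10)],
        "lambda0": [float(64 * 2**i) for i in range(11)],
        "phi0": [0.0005 * 2**i for i in range(6)],
    }


def traverse_grid(axes=None, alpha=3.3e-6, w=1.0, progress=False):
    """Compute power for every Cartesian combination of the axis values.

    Rows are emitted in lexicographic order of ``(n, rho, lambda0, phi0)``
    as given; the row count is the product of the axis lengths.
    """
    if axes is None:
        axes = default_axes()
    for key in ("n", "rho", "lambda0", "phi0"):
        if key not in axes or len(axes[key]) == 0:
            raise ValueError(f"axis {key!r} must be a non-empty list of values")
    combos = itertools.product(axes["n"], axes["rho"], axes["lambda0"], axes["phi0"])
    rows = []
    for n, rho, lambda0, phi0 in combos:
        p = est_power(n, rho, lambda0, phi0, alpha, w)
        rows.append((int(n), rho, lambda0, phi0, alpha, w, p))
        if progress:
            print(f"n={n} rho={rho} lambda0={lambda0} phi0={phi0} power={p:.6g}")
    table = pd.DataFrame(
        rows, columns=["n", "rho", "lambda0", "phi0", "alpha", "w", "power"]
    )
    return PowerGrid(axes=dict(axes), alpha=alpha, w=w, table=table)
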