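"""Sample-size subsampling, depth thinning and permutation nulls.

Three resampling procedures wrapped around the DE engine, each with
replicate bookkeeping:

* ``subsample_samples`` — draw N knockout and N wildtype samples without
  replacement and re-run differential expression, probing how DEG discovery
  grows with replication.
* ``thin_depth`` — retain each sequenced fragment independently with
  probability r (per-gene binomial thinning of counts, distributionally
  identical to subsampling the counted fragments), probing sequencing depth.
* ``permutation_null`` — genotype-balanced label shuffles: each pseudo-group
  receives half of the knockouts and half of the wildtypes, so any real
  knockout effect cancels and the replicate DEG counts estimate the false
  discovery behaviour of the whole pipeline.

Seeds: a master seed plus a counter-based spawn key (procedure-specific
design index, replicate index) deterministically derives each replicate's
child seed, so results are reproducible per replicate and independent of
execution order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import de
from .io import CountMatrix

__all__ = [
    "SubsamplingReport",
    "subsample_samples",
    "thin_counts",
    "thin_depth",
    "permutation_null",
    "balanced_split_sizes",
    "report_frame",
]


@dataclass
class SubsamplingReport:
    """One replicate of a resampling procedure."""

    procedure: str  # sample_size | depth | permutation
    design_value: object  # N, thinning ratio, or split spec
    replicate: int
    seed: int
    n_degs: int
    degs: de.DEGSet
    terms: frozenset | None = None

    def __post_init__(self):
        if self.n_degs != len(self.degs):
            raise ValueError("n_degs must equal |DEGSet|")


def report_frame(reports) -> pd.DataFrame:
    """Flatten replicate records into a tidy table."""
    return pd.DataFrame(
        {
            "procedure": [r.procedure for r in reports],
            "design_value": [r.design_value for r in reports],
            "replicate": [r.replicate for r in reports],
            "seed": [r.seed for r in reports],
            "n_degs": [r.n_degs for r in reports],
        }
    )


def _child_seed(master_seed, design_index, replicate):
    ss = np.random.SeedSequence(
        entropy=int(master_seed), spawn_key=(int(design_index), int(replicate))
    )
    return int(ss.generate_state(1, np.uint32)[0])


def subsample_samples(
    cm: CountMatrix,
    N,
    n_reps,
    seed,
    adj_p_threshold=0.05,
    fc_threshold=1.0,
    design_index=None,
    de_kwargs=None,
):
    """Re-run DE on ``n_reps`` random draws of N KO + N WT samples."""
    ko, wt = cm.samples_of("KO"), cm.samples_of("WT")
    N = int(N)
    if N < 2 or N > min(len(ko), len(wt)):
        raise ValueError(
            f"N={N} must lie in [2, min(#KO, #WT) = {min(len(ko), len(wt))}]"
        )
    de_kwargs = de_kwargs or {}
    if design_index is None:
        design_index = N
    reports = []
    for rep in range(n_reps):
        child = _child_seed(seed, design_index, rep)
        rng = np.random.default_rng(child)
        pick = list(rng.choice(ko, size=N, replace=False)) + list(
            rng.choice(wt, size=N, replace=False)
        )
        res = de.de_test(cm.subset_samples(pick), **de_kwargs)
        degs = de.call_degs(
            res, adj_p_threshold, fc_threshold, analysis_id=f"sample_size:N={N}:rep={rep}"
        )
        reports.append(
            SubsamplingReport("sample_size", N, rep, child, len(degs), degs)
        )
    return reports


def thin_counts(counts, ratio, rng):
    """Binomially thin an integer count array at retention probability ``ratio``.

    Each count ``k`` is replaced by Binomial(k, ratio) — distributionally the
    same as keeping each of the ``k`` fragments independently with
    probability ``ratio``.  Expectation ``ratio * counts``, variance
    ``ratio * (1 - ratio) * counts`` per cell.
    """
    ratio = float(ratio)
    if not (0.0 < ratio <= 1.0):
        raise ValueError(f"thinning ratio must lie in (0, 1], got {ratio}")
    counts = np.asarray(counts)
    return counts if ratio == 1.0 else rng.binomial(counts, ratio)


def thin_depth(
    cm: CountMatrix,
    ratio,
    n_reps,
    seed,
    adj_p_threshold=0.05,
    fc_threshold=1.0,
    design_index=None,
    de_kwargs=None,
):
    """Binomial thinning of every count at retention probability ``ratio``.

    Equivalent in distribution to keeping each sequenced fragment
    independently with probability ``ratio`` in every sample.
    """
    ratio = float(ratio)
    if not (0.0 < ratio <= 1.0):
        raise ValueError(f"thinning ratio must lie in (0, 1], got {ratio}")
    de_kwargs = de_kwargs or {}
    if design_index is None:
        design_index = int(round(ratio * 1000))
    mat = cm.counts.to_numpy()
    reports = []
    for rep in range(n_reps):
        child = _child_seed(seed, design_index, rep)
        rng = np.random.default_rng(child)
        thinned = thin_counts(mat, ratio, rng)
        res = de.de_test(cm.with_counts(thinned), **de_kwargs)
        degs = de.call_degs(
            res,
            adj_p_threshold,
            fc_threshold,
            analysis_id=f"depth:r={ratio}:rep={rep}",
        )
        reports.append(SubsamplingReport("depth", ratio, rep, child, len(degs), degs))
    return reports


def balanced_split_sizes(n_ko, n_wt):
    """Pseudo-group-1 sizes for the genotype-balanced permutation null.

    Half of each genotype (rounded down) goes to group 1 — e.g. 10+10 gives
    5 KO + 5 WT, 12+10 gives 6+5 and 12+14 gives 6+7 — so the two
    pseudo-groups are genotype-balanced and of (near-)equal size.
    """
    return n_ko // 2, n_wt // 2


def permutation_null(
    cm: CountMatrix,
    n_reps,
    seed,
    adj_p_threshold=0.05,
    fc_threshold=1.0,
    de_kwargs=None,
):
    """Genotype-balanced group-shuffle null for the whole DE pipeline.

    Each replicate relabels a random half of the knockouts plus a random
    half of the wildtypes as pseudo-group 1 (the rest as pseudo-group 2) and
    re-runs the DE analysis.  Returns the replicate reports plus a summary:
    the median replicate DEG count, the observed true-label DEG count and
    its empirical p-value under the replicate distribution, using the
    (r + 1) / (n + 1) convention.
    """
    ko, wt = cm.samples_of("KO"), cm.samples_of("WT")
    if len(ko) < 2 or len(wt) < 2:
        raise de.InvalidDesignError("need >= 2 samples per genotype to split")
    k1, w1 = balanced_split_sizes(len(ko), len(wt))
    if k1 < 1 or w1 < 1:
        raise de.InvalidDesignError("too few samples to build balanced pseudo-groups")
    de_kwargs = de_kwargs or {}

    obs_res = de.de_test(cm, **de_kwargs)
    obs_degs = de.call_degs(obs_res, adj_p_threshold, fc_threshold, analysis_id="observed")

    reports = []
    for rep in range(n_reps):
        child = _child_seed(seed, 0, rep)
        rng = np.random.default_rng(child)
        g1 = list(rng.choice(ko, size=k1, replace=False)) + list(
            rng.choice(wt, size=w1, replace=False)
        )
        g1set = set(g1)
        meta = cm.meta.copy()
        meta["genotype"] = ["KO" if s in g1set else "WT" for s in cm.samples]
        perm = CountMatrix(cm.counts, meta)
        res = de.de_test(perm, **de_kwargs)
        degs = de.call_degs(
            res, adj_p_threshold, fc_threshold, analysis_id=f"permutation:rep={rep}"
        )
        reports.append(
            SubsamplingReport(
                "permutation", f"{k1}KO+{w1}WT", rep, child, len(degs), degs
            )
        )
    null_counts = np.array([r.n_degs for r in reports])
    r_ge = int(np.sum(null_counts >= len(obs_degs)))
    summary = {
        "median_null_degs": float(np.median(null_counts)),
        "observed_degs": len(obs_degs),
        "empirical_p": (r_ge + 1) / (n_reps + 1),
        "group1_sizes": (k1, w1),
    }
    return reports, summary
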