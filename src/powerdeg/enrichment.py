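"""Bias-aware over-representation testing of DEG sets.

Long or highly expressed genes accumulate more fragments and are therefore
easier to call differentially expressed, which inflates naive enrichment
tests for categories of such genes.  Besides the plain one-sided
hypergeometric test, this module offers a Wallenius noncentral
hypergeometric variant: per-gene selection weights come from a monotone
(binned isotonic) fit of DEG probability against a bias covariate (gene
length or mean fragment count), a term's odds parameter is the mean weight
of its genes relative to the rest of the universe, and the one-sided tail
of the Wallenius distribution replaces the central one.  The testing
universe is always the set of *tested* (non-filtered) genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .de import DEGSet, bh_adjust
from .io import TermAnnotation

__all__ = ["EnrichmentResult", "enrich", "significant_terms", "selection_weights"]


@dataclass
class EnrichmentResult:
    """Per-term over-representation statistics."""

    table: pd.DataFrame  # index term; n_genes, n_degs, pvalue, padj
    method: str = "hypergeometric"
    skipped: list = field(default_factory=list)

    def __len__(self):
        return len(self.table)


def selection_weights(universe, deg_genes, bias, n_bins=20):
    """Monotone per-gene DEG-probability weights from a bias covariate.

    Genes are split into ``n_bins`` equal-occupancy bins of the covariate;
    the per-bin DEG fraction is smoothed by isotonic regression (weighted by
    bin occupancy, non-decreasing in the covariate) and floored at a small
    positive value.  Returns a pandas Series over the universe.
    """
    from sklearn.isotonic import IsotonicRegression

    universe = list(universe)
    x = np.array([float(bias[g]) for g in universe])
    y = np.array([1.0 if g in deg_genes else 0.0 for g in universe])
    order = np.argsort(x, kind="stable")
    n = len(universe)
    n_bins = max(1, min(n_bins, n))
    edges = np.linspace(0, n, n_bins + 1).astype(int)
    bx, by, bw = [], [], []
    for i in range(n_bins):
        sel = order[edges[i] : edges[i + 1]]
        if sel.size == 0:
            continue
        bx.append(np.mean(x[sel]))
        by.append(np.mean(y[sel]))
        bw.append(sel.size)
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    iso.fit(bx, by, sample_weight=bw)
    w = np.maximum(iso.predict(x), 1e-6)
    return pd.Series(w, index=universe)


def enrich(degs, universe, annotation: TermAnnotation, method="hypergeometric", n_bins=20):
    """One-sided over-representation p-values per term.

    Parameters
    ----------
    degs : DEGSet or set of gene ids
        Significant genes; must be a subset of ``universe``.
    universe : iterable of gene ids
        The tested (non-filtered) genes.
    annotation : TermAnnotation
        Term membership; only members inside the universe count.  Under
        ``wallenius`` the annotation's ``bias`` covariate must cover the
        universe.
    method : {"hypergeometric", "wallenius"}

    Returns
    -------
    EnrichmentResult
        With BH-adjusted p-values across the tested terms; terms with no
        gene in the universe are skipped and listed in ``skipped``.
    """
    deg_genes = degs.genes if isinstance(degs, DEGSet) else frozenset(degs)
    universe = set(universe)
    stray = deg_genes - universe
    if stray:
        raise ValueError(f"DEG {sorted(stray)[0]!r} is not in the tested universe")
    if method not in ("hypergeometric", "wallenius"):
        raise ValueError(f"unknown enrichment method {method!r}")
    M, n_deg = len(universe), len(deg_genes & universe)

    weights = None
    if method == "wallenius":
        missing = [g for g in universe if g not in annotation.bias]
        if missing:
            raise ValueError(
                f"bias covariate missing for gene {missing[0]!r} (wallenius)"
            )
        weights = selection_weights(sorted(universe), deg_genes, annotation.bias, n_bins)

    rows, skipped = [], []
    for term in sorted(annotation.terms):
        members = annotation.terms[term] & universe
        n_cat = len(members)
        if n_cat == 0:
            skipped.append(term)
            continue
        k = len(members & deg_genes)
        if n_deg == M or n_deg == 0:
            # every (or no) tested gene is a DEG: no enrichment information
            p = 1.0
        elif method == "hypergeometric":
            p = float(stats.hypergeom.sf(k - 1, M, n_cat, n_deg))
        else:
            inside = weights[list(members)].mean()
            outside = weights[list(universe - members)].mean() if n_cat < M else inside
            odds = float(inside / outside)
            p = float(
                stats.nchypergeom_wallenius.sf(k - 1, M, n_cat, n_deg, odds)
            )
        rows.append((term, n_cat, k, min(max(p, 0.0), 1.0)))

    table = pd.DataFrame(
        rows, columns=["term", "n_genes", "n_degs", "pvalue"]
    ).set_index("term")
    table["padj"] = bh_adjust(table["pvalue"].to_numpy())
    return EnrichmentResult(table=table, method=method, skipped=skipped)


def significant_terms(result: EnrichmentResult, threshold=0.05) -> frozenset:
    """Terms with BH-adjusted p at or below the threshold."""
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must lie in (0, 1]")
    if len(result.table) == 0:
        return frozenset()
    return frozenset(result.table.index[result.table["padj"] <= threshold])
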