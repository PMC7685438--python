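"""Over-representation testing: hypergeometric oracle and bias correction."""

import math

import numpy as np
import pytest

from powerdeg import enrich, significant_terms
from powerdeg.de import DEGSet
from powerdeg.enrichment import selection_weights
from powerdeg.io import TermAnnotation


def _hypergeom_tail(k, M, n_cat, n_deg):
    """P(X >= k) for X ~ Hypergeom(M, n_cat, n_deg) by direct enumeration."""
    total = math.comb(M, n_deg)
    return sum(
        math.comb(n_cat, j) * math.comb(M - n_cat, n_deg - j)
        for j in range(k, min(n_cat, n_deg) + 1)
    ) / total


def test_hypergeometric_matches_enumeration():
    universe = [f"g{i}" for i in range(20)]
    term = set(universe[:6])
    degs = set(universe[:4]) | {universe[10]}  # 4 of 5 DEGs inside the term
    ann = TermAnnotation(terms={"T": term})
    res = enrich(degs, universe, ann)
    k, M, n_cat, n_deg = 4, 20, 6, 5
    assert res.table.loc["T", "pvalue"] == pytest.approx(
        _hypergeom_tail(k, M, n_cat, n_deg), rel=1e-12
    )
    assert res.table.loc["T", "n_genes"] == n_cat
    assert res.table.loc["T", "n_degs"] == k


def test_only_universe_members_count():
    universe = ["g1", "g2", "g3", "g4"]
    ann = TermAnnotation(terms={"T": {"g1", "g2", "outside1", "outside2"}})
    res = enrich({"g1"}, universe, ann)
    assert res.table.loc["T", "n_genes"] == 2


def test_terms_with_no_tested_gene_are_skipped():
    ann = TermAnnotation(terms={"T1": {"g1"}, "T2": {"zzz"}})
    res = enrich({"g1"}, ["g1", "g2"], ann)
    assert res.skipped == ["T2"]
    assert list(res.table.index) == ["T1"]


def test_saturated_deg_sets_carry_no_information():
    universe = ["g1", "g2", "g3"]
    ann = TermAnnotation(terms={"T": {"g1", "g2"}})
    assert enrich(set(universe), universe, ann).table.loc["T", "pvalue"] == 1.0
    assert enrich(set(), universe, ann).table.loc["T", "pvalue"] == 1.0


def test_validation_errors():
    ann = TermAnnotation(terms={"T": {"g1"}})
    with pytest.raises(ValueError, match="not in the tested universe"):
        enrich({"g9"}, ["g1", "g2"], ann)
    with pytest.raises(ValueError, match="unknown enrichment method"):
        enrich({"g1"}, ["g1", "g2"], ann, method="fisher")
    with pytest.raises(ValueError, match="bias covariate missing"):
        enrich({"g1"}, ["g1", "g2"], ann, method="wallenius")


def test_degset_input_is_accepted():
    ann = TermAnnotation(terms={"T": {"g1", "g2"}})
    degs = DEGSet("x", frozenset({("g1", "up")}))
    res = enrich(degs, ["g1", "g2", "g3"], ann)
    assert res.table.loc["T", "n_degs"] == 1


def test_wallenius_reduces_to_hypergeometric_under_flat_bias():
    rng = np.random.default_rng(4)
    universe = [f"g{i}" for i in range(60)]
    degs = set(rng.choice(universe, size=12, replace=False))
    terms = {f"T{j}": set(rng.choice(universe, size=10, replace=False)) for j in range(5)}
    ann = TermAnnotation(terms=terms, bias={g: 7.0 for g in universe})
    p_h = enrich(degs, universe, ann, method="hypergeometric").table["pvalue"]
    p_w = enrich(degs, universe, ann, method="wallenius").table["pvalue"]
    np.testing.assert_allclose(p_w, p_h, atol=1e-6)


def test_wallenius_discounts_bias_driven_enrichment():
    # DEG probability rises with the bias covariate; a term made of
    # high-bias genes looks enriched to the central test but much less so
    # once selection weights absorb the bias.
    rng = np.random.default_rng(9)
    G = 400
    universe = [f"g{i}" for i in range(G)]
    bias = {g: float(i + 1) for i, g in enumerate(universe)}
    prob = np.linspace(0.02, 0.5, G)
    degs = {g for g, pr in zip(universe, prob) if rng.random() < pr}
    term = set(universe[-40:])  # the highest-bias genes
    ann = TermAnnotation(terms={"T": term}, bias=bias)
    p_h = enrich(degs, universe, ann, method="hypergeometric").table.loc["T", "pvalue"]
    p_w = enrich(degs, universe, ann, method="wallenius").table.loc["T", "pvalue"]
    assert p_h < 0.01
    assert p_w > 10.0 * p_h


def test_selection_weights_monotone_in_covariate():
    rng = np.random.default_rng(2)
    universe = [f"g{i}" for i in range(300)]
    bias = {g: float(i) for i, g in enumerate(universe)}
    degs = {g for i, g in enumerate(universe) if rng.random() < i / 300.0}
    w = selection_weights(universe, degs, bias)
    assert (w > 0).all()
    x = np.array([bias[g] for g in universe])
    order = np.argsort(x)
    assert np.all(np.diff(w.to_numpy()[order]) >= -1e-12)


def test_padj_is_bh_over_tested_terms():
    from powerdeg import bh_adjust

    rng = np.random.default_rng(6)
    universe = [f"g{i}" for i in range(50)]
    degs = set(rng.choice(universe, size=10, replace=False))
    terms = {f"T{j}": set(rng.choice(universe, size=8, replace=False)) for j in range(12)}
    res = enrich(degs, universe, TermAnnotation(terms=terms))
    np.testing.assert_allclose(
        res.table["padj"], bh_adjust(res.table["pvalue"].to_numpy()), rtol=1e-12
    )


def test_enrichment_null_calibration():
    # random DEG sets: significant-term fraction at p<=0.05 stays near level
    rng = np.random.default_rng(8)
    universe = [f"g{i}" for i in range(200)]
    terms = {f"T{j}": set(rng.choice(universe, size=20, replace=False)) for j in range(40)}
    hits = 0
    trials = 0
    for _ in range(25):
        degs = set(rng.choice(universe, size=30, replace=False))
        res = enrich(degs, universe, TermAnnotation(terms=terms))
        hits += int((res.table["pvalue"] <= 0.05).sum())
        trials += len(res.table)
    # discrete one-sided test is conservative; allow sampling slack upward
    assert hits / trials < 0.08


def test_significant_terms_edges():
    ann = TermAnnotation(terms={"T": {"g1", "g2"}})
    res = enrich({"g1", "g2"}, ["g1", "g2", "g3", "g4", "g5"], ann)
    assert significant_terms(res, threshold=1.0) == frozenset({"T"})
    assert significant_terms(res, threshold=0.01) == frozenset()
    with pytest.raises(ValueError):
        significant_terms(res, threshold=0.0)
    empty = enrich(set(), [], TermAnnotation(terms={}))
    assert significant_terms(empty) == frozenset()
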