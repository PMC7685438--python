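"""Differential-expression engine: normalization, dispersion, testing, FDR."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from powerdeg import (
    bh_adjust,
    call_degs,
    de_test,
    estimate_dispersions,
    est_power,
    generate,
    size_factors,
    wald_test,
)
from powerdeg.de import DEGSet, DegenerateInputError, InvalidDesignError
from powerdeg.io import CountMatrix


def _cm_from_array(arr, n_ko, n_wt):
    arr = np.asarray(arr)
    samples = [f"KO{i+1}" for i in range(n_ko)] + [f"WT{i+1}" for i in range(n_wt)]
    counts = pd.DataFrame(arr, index=[f"g{i+1}" for i in range(arr.shape[0])], columns=samples)
    meta = pd.DataFrame({"genotype": ["KO"] * n_ko + ["WT"] * n_wt}, index=samples)
    return CountMatrix(counts, meta)


# ---------------------------------------------------------------- size factors


def test_size_factors_identity_and_scaling():
    rng = np.random.default_rng(0)
    base = rng.poisson(100.0, size=(50, 4)) + 1
    # identical libraries: all factors exactly 1
    same = np.tile(base[:, :1], (1, 4))
    sf = size_factors(_cm_from_array(same, 2, 2).counts)
    np.testing.assert_allclose(sf, 1.0, atol=1e-12)

    # exact doubling of one library: replicate the matrix column-wise so the
    # per-gene ratios are noise-free, then the factor must be exactly 2
    tiled = np.hstack([base[:, :1] * 2, base[:, :1], base[:, :1], base[:, :1]])
    sf = size_factors(_cm_from_array(tiled, 2, 2).counts)
    assert sf.iloc[0] / sf.iloc[1] == pytest.approx(2.0, rel=1e-9)
    assert np.exp(np.mean(np.log(sf))) == pytest.approx(1.0)
    # doubling one noisy library moves its factor close to 2x the others
    doubled = base.copy()
    doubled[:, 0] *= 2
    sf = size_factors(_cm_from_array(doubled, 2, 2).counts)
    assert sf.iloc[0] / sf.iloc[1] == pytest.approx(2.0, rel=0.1)


def test_size_factors_median_of_ratios_brute_force():
    rng = np.random.default_rng(1)
    mat = rng.poisson(50.0, size=(60, 5)) + 1
    cm = _cm_from_array(mat, 2, 3)
    sf = size_factors(cm).to_numpy()
    logs = np.log(mat)
    ref = logs.mean(axis=1)
    expect = np.exp(np.median(logs - ref[:, None], axis=0))
    expect /= np.exp(np.mean(np.log(expect)))
    np.testing.assert_allclose(sf, expect, rtol=1e-12)


def test_size_factors_degenerate_inputs():
    with pytest.raises(DegenerateInputError):
        size_factors(_cm_from_array(np.zeros((5, 4), dtype=int), 2, 2).counts)
    single = pd.DataFrame({"s1": [3, 4, 5]})
    assert size_factors(single).tolist() == [1.0]


def test_size_factors_without_all_nonzero_genes():
    # every gene has at least one zero; the fallback reference still works
    mat = np.array([[10, 0, 12], [0, 20, 18], [5, 6, 0]])
    sf = size_factors(pd.DataFrame(mat, columns=["a", "b", "c"]))
    assert np.all(np.isfinite(sf)) and np.all(sf > 0)


# ----------------------------------------------------------------- dispersions


def test_dispersion_recovery_on_simulated_truth():
    cm, truth = generate(
        n_genes=1500,
        n_ko=10,
        n_wt=10,
        deg_fraction=0.0,
        mean_distribution=(np.log(500.0), 1.0),
        dispersion_scatter=0.3,
        seed=8,
    )
    disp = estimate_dispersions(cm)
    hi = truth["mu0"] > 100
    rel_err = np.abs(disp.loc[hi.values, "shrunk"].to_numpy() - truth.loc[hi, "phi"]) / truth.loc[hi, "phi"]
    assert np.median(rel_err) < 0.5
    rho = stats.spearmanr(disp.loc[hi.values, "shrunk"], truth.loc[hi, "phi"]).statistic
    assert rho > 0.6


def test_dispersion_trend_decreases_and_frame_shape(small_sim):
    cm, _ = small_sim
    disp = estimate_dispersions(cm)
    assert set(disp.columns) == {"mu", "raw", "trend", "shrunk"}
    assert (disp["shrunk"] > 0).all()
    pos = disp[disp["mu"] > 0]
    lo = pos["trend"][pos["mu"] < pos["mu"].median()]
    hi = pos["trend"][pos["mu"] >= pos["mu"].median()]
    assert lo.median() >= hi.median()


def test_dispersion_needs_two_samples_per_group():
    mat = np.random.default_rng(0).poisson(50.0, size=(20, 3))
    samples = ["KO1", "WT1", "WT2"]
    counts = pd.DataFrame(mat, index=[f"g{i}" for i in range(20)], columns=samples)
    meta = pd.DataFrame({"genotype": ["KO", "WT", "WT"]}, index=samples)
    with pytest.raises(InvalidDesignError):
        estimate_dispersions(CountMatrix(counts, meta))


# -------------------------------------------------------------------------- BH


def _bh_manual(p):
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def test_bh_matches_manual_step_up_on_random_vectors():
    rng = np.random.default_rng(3)
    for _ in range(20):
        p = rng.random(rng.integers(1, 200))
        np.testing.assert_allclose(bh_adjust(p), _bh_manual(p), rtol=1e-12)


def test_bh_nan_passthrough_and_validation():
    out = bh_adjust([0.01, np.nan, 0.5])
    assert np.isnan(out[1]) and not np.isnan(out[0])
    np.testing.assert_allclose(out[[0, 2]], _bh_manual(np.array([0.01, 0.5])))
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.2])
    assert bh_adjust([]).size == 0


# ------------------------------------------------------------------ wald & de


def test_auto_method_selection_by_size_factor_spread():
    cm_eq, _ = generate(n_genes=300, n_ko=4, n_wt=4, size_factor_spread=0.0, seed=2)
    assert de_test(cm_eq).attrs["method"] == "exact"
    cm_sp, _ = generate(n_genes=300, n_ko=4, n_wt=4, size_factor_spread=0.5, seed=2)
    assert de_test(cm_sp).attrs["method"] == "wald"


def test_wald_null_pvalues_roughly_uniform():
    cm, _ = generate(
        n_genes=2000, n_ko=8, n_wt=8, deg_fraction=0.0,
        mean_distribution=(np.log(500.0), 1.0), size_factor_spread=0.3, seed=4,
    )
    res = de_test(cm, method="wald")
    p = res.loc[res["status"] == "tested", "pvalue"].dropna()
    frac = float((p < 0.05).mean())
    assert 0.02 < frac < 0.10


def test_wald_recovers_fold_change():
    cm, truth = generate(
        n_genes=500, n_ko=10, n_wt=10, deg_fraction=0.2, fc_band=(2.0, 3.0),
        mean_distribution=(np.log(1000.0), 0.5), size_factor_spread=0.3, seed=6,
    )
    res = de_test(cm, method="wald")
    deg = truth["is_deg"].to_numpy()
    est = res["log2_fc"].to_numpy()[deg]
    true = np.log2(truth["fc"].to_numpy()[deg])
    assert np.corrcoef(est, true)[0, 1] > 0.95
    assert np.mean(np.sign(est) == np.sign(true)) > 0.95


def test_exact_and_wald_agree_on_equal_depth_data(small_sim):
    cm, _ = small_sim
    pe = de_test(cm, method="exact")["pvalue"]
    pw = de_test(cm, method="wald")["pvalue"]
    both = pe.notna() & pw.notna() & (pe > 1e-12)
    rho = stats.spearmanr(np.log(pe[both]), np.log(pw[both])).statistic
    assert rho > 0.95


def test_de_test_filters_low_expression(small_sim):
    cm, _ = small_sim
    res = de_test(cm)
    low = res["base_mean"] < 1.0
    assert (res.loc[low, "status"] == "filtered").all()
    assert res.loc[low, "pvalue"].isna().all()
    assert (res.loc[~low, "status"] == "tested").all()


def test_de_test_supplied_dispersions_and_validation(small_sim):
    cm, truth = small_sim
    res = de_test(cm, dispersions=truth["phi"].to_numpy())
    np.testing.assert_allclose(res["dispersion"], truth["phi"])
    with pytest.raises(ValueError):
        de_test(cm, dispersions=np.ones(3))
    with pytest.raises(ValueError):
        de_test(cm, method="bogus")


def test_empirical_power_matches_analytic_prediction():
    # All genes at one design point, true dispersions supplied, exact path:
    # the rejection rate at level alpha should match est_power.
    n, mu, phi, fc, alpha = 6, 200.0, 0.05, 2.0, 0.01
    rng = np.random.default_rng(12)
    r = 1.0 / phi
    G = 4000
    ko = rng.negative_binomial(r, r / (r + mu * fc), size=(G, n))
    wt = rng.negative_binomial(r, r / (r + mu), size=(G, n))
    cm = _cm_from_array(np.hstack([ko, wt]), n, n)
    res = de_test(cm, dispersions=np.full(G, phi), method="exact")
    frac = float((res["pvalue"] <= alpha).mean())
    expect = est_power(n, fc, mu, phi, alpha)
    se = np.sqrt(expect * (1 - expect) / G)
    assert abs(frac - expect) < 4 * se + 1e-9


def test_false_discovery_proportion_controlled_across_seeds():
    # Weak-effect study conditions; BH at 0.05 should keep the realized
    # false-discovery proportion at or below 0.10 in every run.
    fdps = []
    for seed in range(10):
        cm, truth = generate(
            n_genes=2000, n_ko=12, n_wt=14, deg_fraction=0.10,
            fc_band=(1.1, 1.5), mean_distribution=(np.log(300.0), 1.8), seed=seed,
        )
        degs = call_degs(de_test(cm), 0.05, 1.0, analysis_id=f"s{seed}")
        true = set(truth.index[truth["is_deg"]])
        fp = len(degs.genes - true)
        fdps.append(fp / max(len(degs), 1))
        assert len(degs) > 50  # sanity: the engine finds signal at all
    assert max(fdps) <= 0.10


# ------------------------------------------------------------------ call_degs


def test_call_degs_thresholds_and_directions(small_sim):
    cm, truth = small_sim
    res = de_test(cm)
    degs = call_degs(res, 0.05, 1.0, analysis_id="full")
    assert degs.analysis_id == "full"
    assert all(d in ("up", "down") for _, d in degs.members)
    for g, d in degs.members:
        lfc = res.loc[g, "log2_fc"]
        assert (d == "up") == (lfc > 0)
        assert res.loc[g, "padj"] <= 0.05
    stricter = call_degs(res, 0.01, 1.0)
    assert stricter.genes <= degs.genes
    with_fc = call_degs(res, 0.05, 1.5)
    assert with_fc.genes <= degs.genes
    assert all(abs(res.loc[g, "log2_fc"]) >= np.log2(1.5) for g in with_fc.genes)


def test_call_degs_validation(small_sim):
    res = de_test(small_sim[0])
    with pytest.raises(ValueError):
        call_degs(res, 0.0, 1.0)
    with pytest.raises(ValueError):
        call_degs(res, 0.05, 0.5)


def test_degset_rejects_gene_with_both_directions():
    with pytest.raises(ValueError):
        DEGSet("x", frozenset({("g1", "up"), ("g1", "down")}))
    d = DEGSet("x", frozenset({("g1", "up"), ("g2", "down")}))
    assert d.genes == {"g1", "g2"}
    assert d.directions == {"g1": "up", "g2": "down"}
    assert len(d) == 2
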