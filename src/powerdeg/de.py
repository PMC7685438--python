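"""Self-contained negative-binomial differential-expression testing.

A deliberately small two-group engine so the resampling studies run with no
external toolchain: median-of-ratios size factors, method-of-moments
dispersions shrunk toward a fitted ``a0 + a1/mu`` trend, the conditional
NB exact test for equal-depth designs (the same kernel the analytic power
module uses) with a per-gene Wald NB regression fallback when library sizes
are unequal, Benjamini-Hochberg adjustment over tested genes, and
threshold-based DEG calling.  Fold changes are always oriented KO over WT.

Not replicated on purpose: DESeq2's shrunken LFCs, Cook's-distance outlier
handling, adaptive independent filtering, edgeR's quantile-adjusted
conditional ML, and limma-voom weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from . import _kernels
from .io import CountMatrix

__all__ = [
    "DEGSet",
    "size_factors",
    "estimate_dispersions",
    "fit_dispersion_trend",
    "exact_test",
    "wald_test",
    "bh_adjust",
    "de_test",
    "call_degs",
]

#: genes whose mean normalized count falls below this are never tested
DEFAULT_MIN_MEAN = 1.0
#: floor for dispersion estimates
MIN_DISP = 1e-8
#: size-factor spread beyond which the exact test's equal-depth premise fails
EXACT_SF_TOLERANCE = 0.10
#: pseudo-count per group mean used for reported log2 fold changes
PRIOR_COUNT = 0.5


class DegenerateInputError(ValueError):
    pass


class InvalidDesignError(ValueError):
    pass


@dataclass(frozen=True)
class DEGSet:
    """Direction-signed set of significant genes from one analysis."""

    analysis_id: str
    members: frozenset = field(default_factory=frozenset)  # {(gene, "up"/"down")}
    rule: dict = field(default_factory=dict)

    def __post_init__(self):
        genes = [g for g, _ in self.members]
        if len(genes) != len(set(genes)):
            raise ValueError("a gene may not appear with both directions")

    def __len__(self):
        return len(self.members)

    @property
    def genes(self) -> frozenset:
        return frozenset(g for g, _ in self.members)

    @property
    def directions(self) -> dict:
        return {g: d for g, d in self.members}


def size_factors(counts) -> pd.Series:
    """Median-of-ratios normalization factors, geometric mean scaled to 1.

    The reference is the per-gene geometric mean over genes with all-nonzero
    counts; if no such gene exists the fallback uses genes with a nonzero
    geometric mean over the samples where they are observed.
    """
    if isinstance(counts, CountMatrix):
        counts = counts.counts
    mat = counts.to_numpy(dtype=float)
    if mat.size == 0 or not np.any(mat > 0):
        raise DegenerateInputError("all-zero count matrix has no size factors")
    if mat.shape[1] == 1:
        return pd.Series([1.0], index=counts.columns)
    with np.errstate(divide="ignore"):
        logs = np.log(mat)
    allpos = np.all(mat > 0, axis=1)
    if allpos.any():
        ref = np.mean(logs[allpos], axis=1)
        use = logs[allpos]
    else:
        # fallback: positive-part geometric means over observed samples
        anypos = np.any(mat > 0, axis=1)
        ref = np.array([np.mean(row[np.isfinite(row)]) for row in logs[anypos]])
        use = logs[anypos]
    log_sf = np.nanmedian(
        np.where(np.isfinite(use), use - ref[:, None], np.nan), axis=0
    )
    log_sf = log_sf - np.mean(log_sf)
    return pd.Series(np.exp(log_sf), index=counts.columns)


def fit_dispersion_trend(mu, disp, n_iter=8):
    """Fit ``phi_tr(mu) = a0 + a1 / mu`` by iteratively reweighted least squares.

    Gamma-style weights ``1 / fitted^2`` with one round of outlier exclusion
    (raw estimates more than 16-fold off the fit), mirroring the usual
    parametric mean-dispersion fits for bulk RNA-seq.
    """
    mu = np.asarray(mu, dtype=float)
    disp = np.asarray(disp, dtype=float)
    ok = (mu > 0) & (disp > MIN_DISP)
    if ok.sum() < 10:
        med = float(np.median(disp[disp > 0])) if np.any(disp > 0) else 0.01
        return max(med, MIN_DISP), 0.0
    x, y = 1.0 / mu[ok], disp[ok]
    a0, a1 = max(float(np.median(y)), MIN_DISP), 0.0
    keep = np.ones(y.size, dtype=bool)
    for it in range(n_iter):
        fitted = np.maximum(a0 + a1 * x, MIN_DISP)
        if it == n_iter // 2:
            ratio = y / fitted
            keep = (ratio < 16.0) & (ratio > 1.0 / 16.0)
            if keep.sum() < 10:
                keep[:] = True
        wgt = 1.0 / fitted[keep] ** 2
        X = np.column_stack([np.ones(keep.sum()), x[keep]])
        beta, *_ = np.linalg.lstsq(
            X * np.sqrt(wgt)[:, None], y[keep] * np.sqrt(wgt), rcond=None
        )
        a0, a1 = max(float(beta[0]), MIN_DISP), max(float(beta[1]), 0.0)
    return a0, a1


def estimate_dispersions(cm: CountMatrix, sf=None, prior_df=20.0):
    """Per-gene dispersions: within-group method of moments, trend-shrunk.

    Raw per-gene estimates come from the pooled within-genotype variance of
    normalized counts (so true fold changes do not inflate them); they are
    then shrunk toward the fitted ``a0 + a1/mu`` trend with precision-style
    linear weights (residual df against ``prior_df``) and floored at a small
    positive constant.

    Returns a DataFrame with columns ``mu`` (mean normalized count),
    ``raw``, ``trend`` and ``shrunk``.
    """
    if sf is None:
        sf = size_factors(cm)
    sf = np.asarray(sf, dtype=float)
    groups = [cm.samples_of(g) for g in ("KO", "WT")]
    for g, members in zip(("KO", "WT"), groups):
        if len(members) < 2:
            raise InvalidDesignError(f"genotype group {g} has < 2 samples")
    mat = cm.counts.to_numpy(dtype=float) / sf[None, :]
    mu = mat.mean(axis=1)
    cols = {s: i for i, s in enumerate(cm.samples)}
    ss, df = np.zeros(mat.shape[0]), 0
    inv_sf_sum = 0.0
    for members in groups:
        idx = [cols[s] for s in members]
        sub = mat[:, idx]
        ss += np.sum((sub - sub.mean(axis=1, keepdims=True)) ** 2, axis=1)
        df += len(idx) - 1
        inv_sf_sum += np.sum(1.0 / sf[idx])
    pooled_var = ss / df
    # E[var(K/sf)] = mu * mean(1/sf) + phi * mu^2
    shot = mu * inv_sf_sum / mat.shape[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(mu > 0, (pooled_var - shot) / mu**2, 0.0)
    raw = np.maximum(raw, 0.0)
    a0, a1 = fit_dispersion_trend(mu, raw)
    with np.errstate(divide="ignore"):
        trend = np.where(mu > 0, a0 + a1 / mu, np.inf)
    trend = np.minimum(trend, 1e6)
    shrunk = (df * raw + prior_df * trend) / (df + prior_df)
    raw = np.maximum(raw, MIN_DISP)
    shrunk = np.maximum(shrunk, MIN_DISP)
    # dispersion outliers: genes far above the trend keep their raw estimate
    # (shrinking them toward the trend would understate their variability
    # and inflate false discoveries)
    with np.errstate(divide="ignore", invalid="ignore"):
        resid = np.log(np.where(raw > MIN_DISP, raw, np.nan) / trend)
    finite = np.isfinite(resid)
    if finite.sum() >= 10:
        mad = 1.4826 * np.nanmedian(np.abs(resid[finite] - np.nanmedian(resid[finite])))
        outlier = finite & (resid > np.nanmedian(resid[finite]) + 2.0 * max(mad, 0.1))
        shrunk = np.where(outlier, raw, shrunk)
    return pd.DataFrame(
        {"mu": mu, "raw": raw, "trend": trend, "shrunk": shrunk}, index=cm.genes
    )


def exact_test(group_a, group_b, dispersion):
    """Two-sided conditional exact-test p-value for one gene.

    ``group_a`` and ``group_b`` are per-sample counts (equal effective
    library sizes assumed); ``dispersion`` is the per-sample NB dispersion
    (0 gives the Poisson/binomial conditional test).  Extremeness follows
    the minimum-likelihood convention; ties count toward the p-value.
    """
    a = np.asarray(group_a)
    b = np.asarray(group_b)
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("counts must be non-negative")
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    n_a, n_b = a.size, b.size
    phi = min(float(dispersion), float(min(n_a, n_b)))  # keeps the kernel log-concave
    ta, tb = float(a.sum()), float(b.sum())
    out = _kernels.cond_pvalues(
        np.array([ta]), np.array([ta + tb]), float(n_a), float(n_b), np.array([phi])
    )
    return float(out[0])


def _exact_pvalues(counts_ko, counts_wt, disp):
    n_a, n_b = counts_ko.shape[1], counts_wt.shape[1]
    ta = counts_ko.sum(axis=1).astype(np.float64)
    tb = counts_wt.sum(axis=1).astype(np.float64)
    phi = np.minimum(np.asarray(disp, dtype=float), float(min(n_a, n_b)))
    return _kernels.cond_pvalues(ta, ta + tb, float(n_a), float(n_b), phi)


def wald_test(cm: CountMatrix, dispersions, sf=None):
    """Per-gene NB regression Wald test on the genotype effect.

    Fits group means by Newton iterations on the per-group score equations
    (log link, size factors as offsets, dispersion fixed per gene), reports
    the KO/WT log2 fold change and a Wald p-value from the observed Fisher
    information.  Genes whose fit does not converge get ``p = NaN``.
    """
    if sf is None:
        sf = size_factors(cm)
    sf = np.asarray(sf, dtype=float)
    disp = np.asarray(dispersions, dtype=float)
    cols = {s: i for i, s in enumerate(cm.samples)}
    idx = {g: [cols[s] for s in cm.samples_of(g)] for g in ("KO", "WT")}
    mat = cm.counts.to_numpy(dtype=float)

    means, infos, converged = {}, {}, np.ones(mat.shape[0], dtype=bool)
    for g in ("KO", "WT"):
        y = mat[:, idx[g]]
        f = sf[idx[g]][None, :]
        m = np.maximum(y.mean(axis=1) / f.mean(), 1e-8)  # init: normalized mean
        ok = np.zeros(m.size, dtype=bool)
        for _ in range(50):
            mu = f * m[:, None]
            wden = 1.0 + disp[:, None] * mu
            score = np.sum((y - mu) / wden, axis=1)
            info = np.sum(mu / wden, axis=1)  # d(-score)/d(log m)... Fisher info
            step = score / np.maximum(info, 1e-12)
            step = np.clip(step, -3.0, 3.0)
            m = m * np.exp(step)
            newly = np.abs(step) < 1e-10
            ok |= newly
            if ok.all():
                break
        means[g], infos[g] = m, np.sum(f * m[:, None] / (1.0 + disp[:, None] * f * m[:, None]), axis=1)
        converged &= ok
    log2fc = np.log2(means["KO"] / means["WT"])
    var = 1.0 / np.maximum(infos["KO"], 1e-300) + 1.0 / np.maximum(infos["WT"], 1e-300)
    z = np.log(means["KO"] / means["WT"]) / np.sqrt(var)
    from scipy.stats import norm

    p = 2.0 * norm.sf(np.abs(z))
    p[~converged] = np.nan
    return log2fc, p


def bh_adjust(pvalues):
    """Benjamini-Hochberg step-up adjusted p-values (NaNs pass through)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if mask.any():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def de_test(
    cm: CountMatrix,
    min_mean=DEFAULT_MIN_MEAN,
    dispersions=None,
    method="auto",
    prior_df=20.0,
):
    """Two-group KO-vs-WT differential expression on a count matrix.

    Returns a DataFrame indexed by gene with columns ``base_mean``,
    ``log2_fc``, ``dispersion``, ``pvalue``, ``padj`` and ``status``
    (``tested``/``filtered``).  ``dispersions`` may supply known per-gene
    values (as in power-equivalence checks); otherwise they are estimated.
    ``method`` is ``auto`` (exact test unless size factors deviate more
    than 10% from equality), ``exact`` or ``wald``.
    """
    sf = size_factors(cm)
    sfv = sf.to_numpy()
    mat = cm.counts.to_numpy(dtype=float)
    norm_mat = mat / sfv[None, :]
    base_mean = norm_mat.mean(axis=1)
    tested = base_mean >= min_mean

    if dispersions is None:
        disp_all = estimate_dispersions(cm, sf=sf, prior_df=prior_df)["shrunk"].to_numpy()
    else:
        disp_all = np.asarray(dispersions, dtype=float)
        if disp_all.shape != (mat.shape[0],):
            raise ValueError("dispersions must provide one value per gene")

    ko = cm.samples_of("KO")
    wt = cm.samples_of("WT")
    if len(ko) < 2 or len(wt) < 2:
        raise InvalidDesignError("need >= 2 samples per genotype group")
    cols = {s: i for i, s in enumerate(cm.samples)}
    iko = [cols[s] for s in ko]
    iwt = [cols[s] for s in wt]

    mean_ko = norm_mat[:, iko].mean(axis=1)
    mean_wt = norm_mat[:, iwt].mean(axis=1)
    log2fc = np.log2((mean_ko + PRIOR_COUNT) / (mean_wt + PRIOR_COUNT))

    if method == "auto":
        spread = float(sfv.max() / sfv.min()) - 1.0
        method = "exact" if spread <= EXACT_SF_TOLERANCE else "wald"

    p = np.full(mat.shape[0], np.nan)
    if method == "exact":
        sub = tested
        p[sub] = _exact_pvalues(
            cm.counts.to_numpy()[np.ix_(sub, iko)],
            cm.counts.to_numpy()[np.ix_(sub, iwt)],
            disp_all[sub],
        )
    elif method == "wald":
        lfc_w, p_w = wald_test(cm, disp_all, sf=sfv)
        p[tested] = p_w[tested]
        log2fc = lfc_w
    else:
        raise ValueError(f"unknown method {method!r}")

    padj = np.full(mat.shape[0], np.nan)
    padj[tested] = bh_adjust(p[tested])
    res = pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2_fc": log2fc,
            "dispersion": disp_all,
            "pvalue": p,
            "padj": padj,
            "status": np.where(tested, "tested", "filtered"),
        },
        index=cm.genes,
    )
    res.attrs["method"] = method
    res.attrs["size_factors"] = sf
    return res


def call_degs(result: pd.DataFrame, adj_p_threshold=0.05, fc_threshold=1.0, analysis_id="de"):
    """Significant genes at the adjusted-p (and optional fold-change) rule.

    ``fc_threshold`` is interpreted symmetrically: keep fold changes
    ``>= t`` or ``<= 1/t``.  Direction comes from the sign of the KO/WT
    log2 fold change; filtered genes are never called.
    """
    if not (0.0 < adj_p_threshold <= 1.0):
        raise ValueError("adj_p_threshold must lie in (0, 1]")
    if fc_threshold < 1.0:
        raise ValueError("fc_threshold must be >= 1")
    ok = (
        (result["status"] == "tested")
        & result["padj"].notna()
        & (result["padj"] <= adj_p_threshold)
    )
    if fc_threshold > 1.0:
        lim = np.log2(fc_threshold)
        ok &= result["log2_fc"].abs() >= lim
    members = frozenset(
        (str(g), "up" if l > 0 else "down")
        for g, l in zip(result.index[ok], result.loc[ok, "log2_fc"])
        if l != 0
    )
    return DEGSet(
        analysis_id=analysis_id,
        members=members,
        rule={"adj_p": adj_p_threshold, "fc": fc_threshold},
    )
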