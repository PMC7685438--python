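"""Synthetic negative-binomial count matrices with known ground truth.

The generator emulates the statistical structure of deep case-control bulk
RNA-seq from a knockout line: per-gene means drawn from a long-tailed
log-normal (deep libraries, a small fraction of genes below the testing
filter), a dispersion-vs-mean trend ``phi(mu) = a0 + a1 / mu`` that
decreases with expression, spike-in differentially expressed genes with
weak fold changes (KO over WT), per-sample library-size factors, and an
optional sex-specific dispersion inflation that degrades power in the
affected stratum.  Counts for gene ``g`` in sample ``s`` are drawn

    NB(mean = sf_s * mu_g * fc_g^[s is KO],  dispersion = phi_g * infl_s)

with variance ``mu + phi * mu^2``.  Everything is reproducible from the
seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import CountMatrix

__all__ = ["generate", "default_mean_distribution"]

#: mean-count filter threshold the defaults are calibrated against
FILTER_THRESHOLD = 1.0


def default_mean_distribution(low_expression_fraction=0.02, sigma=2.0, mean_count=4400.0):
    """Log-normal over reference means, anchored on deep sequencing.

    ``mean_count`` is the expected fragment count per gene (about 66 million
    fragments over 15,000 genes at the default); ``low_expression_fraction``
    is the fraction of genes expected below the low-count filter, which sets
    the log-mean given ``sigma`` unless it would exceed the anchor.
    """
    from scipy.stats import norm

    meanlog_from_anchor = np.log(mean_count) - sigma**2 / 2.0
    meanlog_from_floor = (
        np.log(FILTER_THRESHOLD) - sigma * norm.ppf(low_expression_fraction)
    )
    return min(meanlog_from_anchor, meanlog_from_floor), sigma


def _draw_means(rng, n_genes, mean_distribution):
    if callable(mean_distribution):
        mu = np.asarray(mean_distribution(rng, n_genes), dtype=float)
    else:
        meanlog, sdlog = mean_distribution
        mu = rng.lognormal(meanlog, sdlog, size=n_genes)
    if mu.shape != (n_genes,) or np.any(mu <= 0):
        raise ValueError("mean distribution must yield n_genes positive values")
    return mu


def generate(
    n_genes=15000,
    n_ko=12,
    n_wt=14,
    deg_fraction=0.10,
    fc_band=(1.05, 1.5),
    mean_distribution=None,
    dispersion_trend=(0.008, 3.0),
    dispersion_scatter=0.2,
    size_factor_spread=0.0,
    dispersion_inflation=None,
    sexes=None,
    seed=None,
):
    """Generate a KO-vs-WT count matrix plus its ground-truth table.

    Parameters
    ----------
    n_genes, n_ko, n_wt : int
        Matrix dimensions (``n_ko, n_wt >= 2``).
    deg_fraction : float
        Fraction of genes spiked as true DEGs.
    fc_band : (float, float)
        Band of |fold change| for spiked DEGs; each DEG's magnitude is drawn
        log-uniformly in the band and half the DEGs (on average) are
        down-regulated (reciprocal fold change).  KO/WT orientation.
    mean_distribution : (meanlog, sdlog) or callable, optional
        Distribution of reference-group means; default
        :func:`default_mean_distribution`.
    dispersion_trend : (a0, a1) or callable
        ``phi(mu) = a0 + a1 / mu`` (decreasing in the mean), or a callable
        ``mu -> phi``.
    dispersion_scatter : float
        Log-normal sigma of gene-level scatter around the trend.
    size_factor_spread : float
        Log-normal sigma of per-sample library-size factors (0 = equal
        depth, the design assumption of the power model).
    dispersion_inflation : dict, optional
        Map sex label -> multiplicative dispersion inflation (e.g.
        ``{"F": 2.0}`` emulates the higher dispersion observed in female
        samples); requires ``sexes``.
    sexes : sequence of str, optional
        Sex label per sample (KO samples first, then WT); default ``NA``.
    seed : int
        Mandatory RNG seed.

    Returns
    -------
    (CountMatrix, pandas.DataFrame)
        The truth table has one row per gene: ``mu0``, ``fc``, ``phi``,
        ``is_deg``.
    """
    if seed is None:
        raise ValueError("a seed is required for reproducibility")
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if n_ko < 2 or n_wt < 2:
        raise ValueError("need at least 2 samples per genotype group")
    if not 0.0 <= deg_fraction <= 1.0:
        raise ValueError(f"deg_fraction must lie in [0, 1], got {deg_fraction}")
    lo, hi = fc_band
    if not (0 < lo <= hi):
        raise ValueError(f"impossible fold-change band {fc_band}")
    if lo < 1.0:
        raise ValueError("fc_band is a band of magnitudes; bounds must be >= 1")

    rng = np.random.default_rng(seed)
    n_samples = n_ko + n_wt
    samples = [f"KO{i + 1}" for i in range(n_ko)] + [f"WT{i + 1}" for i in range(n_wt)]
    genotype = np.array(["KO"] * n_ko + ["WT"] * n_wt)
    if sexes is None:
        sexes = ["NA"] * n_samples
    sexes = list(sexes)
    if len(sexes) != n_samples:
        raise ValueError("sexes must have one label per sample")
    if dispersion_inflation:
        infl = np.array([float(dispersion_inflation.get(s, 1.0)) for s in sexes])
        if np.any(infl <= 0):
            raise ValueError("dispersion inflation factors must be positive")
    else:
        infl = np.ones(n_samples)

    if mean_distribution is None:
        mean_distribution = default_mean_distribution()
    mu0 = _draw_means(rng, n_genes, mean_distribution)

    if callable(dispersion_trend):
        phi = np.asarray(dispersion_trend(mu0), dtype=float)
    else:
        a0, a1 = dispersion_trend
        phi = a0 + a1 / mu0
    if np.any(phi < 0):
        raise ValueError("dispersion trend must be non-negative")
    if dispersion_scatter > 0:
        phi = phi * rng.lognormal(0.0, dispersion_scatter, size=n_genes)

    fc = np.ones(n_genes)
    n_deg = int(round(deg_fraction * n_genes))
    deg_idx = rng.choice(n_genes, size=n_deg, replace=False)
    mag = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_deg))
    down = rng.random(n_deg) < 0.5
    mag[down] = 1.0 / mag[down]
    # a magnitude of exactly 1 (band lower edge) would not be a DEG
    fc[deg_idx] = np.where(mag == 1.0, 1.0 + 1e-9, mag)

    if size_factor_spread > 0:
        sf = rng.lognormal(0.0, size_factor_spread, size=n_samples)
        sf = sf / np.exp(np.mean(np.log(sf)))
    else:
        sf = np.ones(n_samples)

    mean_mat = mu0[:, None] * np.where(genotype == "KO", fc[:, None], 1.0) * sf[None, :]
    phi_mat = phi[:, None] * infl[None, :]
    poisson_cells = phi_mat <= 0
    safe_phi = np.where(poisson_cells, 1.0, phi_mat)
    size = 1.0 / safe_phi
    p = size / (size + mean_mat)
    counts = rng.negative_binomial(size, p)
    if poisson_cells.any():
        counts = np.where(poisson_cells, rng.poisson(mean_mat), counts)
    counts = counts.astype(np.int64)

    cm = CountMatrix(
        pd.DataFrame(counts, index=[f"g{i + 1}" for i in range(n_genes)], columns=samples),
        pd.DataFrame(
            {
                "genotype": genotype,
                "sex": sexes,
                "group": ["NA"] * n_samples,
                "size_factor": sf,
            },
            index=samples,
        ),
    )
    truth = pd.DataFrame(
        {"mu0": mu0, "fc": fc, "phi": phi, "is_deg": fc != 1.0},
        index=cm.genes,
    )
    return cm, truth
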