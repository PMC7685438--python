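# Methods

This note records the statistical model, the default parameter choices and
their rationale, what the synthetic-data generator does and does not emulate,
and the numerical conventions the implementation commits to.

## Model

All counts are modelled as negative binomial (NB) with the dispersion
parameterization used throughout bulk RNA-seq:

    K ~ NB(mean = mu, dispersion = phi),   Var(K) = mu + phi * mu^2

`phi = 0` is the Poisson limit. This convention is fixed package-wide: the
power module, the generator and the DE engine all mean the same `phi`.

### Conditional exact test

For two groups of `n_A` and `n_B` samples with equal effective library sizes
and common per-sample dispersion `phi`, the group totals are
`NB(n_A * mu, size = n_A / phi)` and `NB(n_B * mu, size = n_B / phi)` under
the null of a common per-sample mean `mu` (the NB family is closed under
summation at fixed per-sample dispersion). Conditioning on the grand total
`s` cancels `mu` exactly; the null conditional law of the group-A total is

    BetaBinomial(s, r_A, r_B),   r_A = n_A / phi,  r_B = n_B / phi

and `Binomial(s, n_A / (n_A + n_B))` in the Poisson limit. Two-sided
extremeness follows the **minimum-likelihood convention**: the p-value of an
observed group-A total `a` is the null conditional probability of all
outcomes whose conditional probability does not exceed that of `a`, ties
included. In the symmetric case (`n_A = n_B`) this reduces to the doubled
lower tail of the smaller total.

### Analytic power

`est_power(n, rho, lambda0, phi0, alpha, w)` computes the exact rejection
probability of that test when the reference group has per-sample mean
`lambda0` and the other group `w * rho * lambda0`, both with dispersion
`phi0` and `n` samples per group:

1. For each grand total `s`, the rejection cutoff `c(s)` is the largest
   `c < s/2` whose doubled BetaBinomial(s, r, r) lower tail is `<= alpha`
   (`r = n / phi0`). Cutoffs are computed by an incremental staircase walk
   over `s` with closed-form log-pmf evaluation; `c(s)` is non-decreasing in
   `s` (asserted at runtime).
2. Power is the exact double sum of alternative-model probabilities
   `P(A = a) P(B = b)` over the rejection region `{min(a, b) <= c(a + b)}`,
   assembled from the two tails (disjoint because `c(s) < s/2`).

`mc_power` simulates gene instances from the identical NB model and applies
the *same* cutoff kernel, so analytic/Monte-Carlo agreement checks the
summation, not a re-derivation.

## Parameter defaults and why

| Parameter | Default | Rationale |
|---|---|---|
| power grid axes | n 3–13; rho 1.05–1.5 step 0.05; lambda0 64–65,536 (powers of 2); phi0 0.0005–0.016 (doublings) | Spans the weak-effect regime from minimal pilot designs to deep, large experiments. The axes are configuration, not a constant: pass your own dict to `traverse_grid`. |
| grid `alpha` | 3.3e-6 | Bonferroni 0.05 over 15,000 tests — the genome-wide single-test level for a typical mammalian expressed-gene universe. |
| `generate` means | log-normal, sigma 2.0, mean ≈ 4,400 fragments/gene | Anchored on a deep library (~66M fragments over 15,000 genes) with a long right tail; at most ~2% of genes fall below the testing filter. |
| dispersion trend | `phi(mu) = 0.008 + 3.0/mu`, log-normal scatter 0.2 | Decreasing mean–dispersion trend with an asymptote of ~0.008, typical of genetically identical inbred animals (biological CV ~9%). |
| `deg_fraction` | 0.10, fold changes 1.05–1.5 | The weak-effect regime this package is about: many genes shifted, all of them slightly. |
| design size | 12 KO vs 14 WT | A deliberately large two-group design for a knockout study; also the shape used by the examples and acceptance suite (desk scale: 2,000 genes). |
| DE filter | mean normalized count >= 1 | Below one fragment per sample the exact test has essentially no resolution; filtering is applied before BH so it costs no multiplicity. |
| `prior_df` | 20 | Shrinkage weight of the fitted trend against the per-gene method-of-moments dispersion (residual df against prior df). Chosen for stability: with 12–24 residual df, raw NB dispersion estimates are noisy downward, and underestimated dispersions are exactly what inflates the realized false-discovery proportion. 20 keeps the FDP at BH ≤ 0.05 under 0.10 across seeds without measurable loss of true positives. |
| dispersion outlier rule | keep raw when log residual > median + 2·max(MAD, 0.1) | Genes far *above* the trend are plausibly genuinely variable; shrinking them down would manufacture false positives. |
| exact/Wald switch | size-factor spread ≤ 10% | The conditional test assumes equal effective depth. Within 10% the size-factor correction is second-order; beyond it the engine falls back to a per-gene NB Wald regression with size factors as offsets. |
| DEG rule | BH ≤ 0.05, no fold-change floor | Matches common practice; `fc_threshold` is symmetric (`>= t` or `<= 1/t`) when set. |
| permutation split | half of each genotype per pseudo-group | Genotype-balanced shuffles cancel the real effect in every replicate (12+14 → 6+7). Empirical p uses `(r + 1) / (n + 1)`. |
| enrichment universe | tested (non-filtered) genes | Filtered genes were never candidates; including them inflates enrichment. |
| Wallenius weights | 20 equal-occupancy bins + isotonic fit, floor 1e-6 | Monotone DEG-probability-vs-bias estimate without a parametric form; the odds parameter is the mean weight inside vs outside the term. |

## What the generator emulates — and does not

Emulated: NB marginals with a decreasing mean–dispersion trend and per-gene
scatter; log-normal expression means with a realistic low-expression tail;
spike-in DEGs with log-uniform weak fold changes in both directions;
per-sample library-size factors; optional sex-stratified dispersion
inflation (higher within-group variance in one stratum degrades power
there).

Not emulated: gene–gene correlation (counts are independent across genes
given the parameters), transcript-level effects and isoform switching, GC or
positional coverage bias, batch structure beyond a scalar size factor,
outlier samples, and count structure from UMI deduplication. Conclusions
that depend on between-gene correlation (e.g. joint behaviour of enrichment
p-values) are therefore optimistic on synthetic data.

## Numerical choices

- **Support truncation.** Power sums truncate each group-total support at
  the 1e-12 quantiles; the neglected mass is ~4e-12 per tail, far below any
  tolerance used.
- **Tail summation.** BetaBinomial tails are summed by the pmf ratio
  recurrence with a geometric remainder bound *added* to the partial sum, so
  threshold comparisons are conservative; log-pmfs come from `lgamma` closed
  forms.
- **Log-concavity guard.** The exact-test kernels require
  `r_A, r_B >= 1` (`phi <= min(n_A, n_B)`); the DE engine caps estimated
  dispersions at that boundary before testing. For the power module the
  constraint is validated (`phi0 <= n`).
- **Tie handling.** Outcomes with conditional probability equal to the
  observed one (within a 1e-12 relative tolerance) count toward the p-value;
  rejection thresholds treat `2 * cdf == alpha` as rejectable.
- **p-value floor/ceiling.** Exact-test p-values are clipped to
  `[1e-300, 1]`; series terms below 1e-17 relative to the mode are dropped.
- **Seeds.** Every stochastic routine takes a mandatory seed. Resampling
  replicates derive child seeds via `SeedSequence(master, spawn_key=(design
  index, replicate))`, so results are independent of execution order and
  reproducible per replicate.
- **BH.** Benjamini–Hochberg via `statsmodels` `multipletests`, applied over
  tested genes only; NaN p-values (non-converged Wald fits) pass through
  untested.

## Limitations

- The power model assumes equal per-sample library sizes within and across
  groups; `w` handles a *systematic* normalization ratio but not per-sample
  spread. The DE engine's Wald fallback covers unequal depth, at the cost of
  asymptotic (not exact) p-values.
- The analytic power's doubled-tail convention can differ from other
  software at boundary designs by ~1% absolute power; the Monte-Carlo oracle
  in the test suite, not agreement with any external package, is the
  correctness criterion.
- Method-of-moments dispersions with strong trend shrinkage are a stability
  choice, not a likelihood-optimal estimator; at very small group sizes
  (n = 2–3 per group after subsampling) dispersion estimates lean mostly on
  the trend.
- The permutation null requires at least 2 samples of each genotype per
  pseudo-group half; very small designs cannot be permuted in a balanced
  way.
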