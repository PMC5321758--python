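# Methods

This note records the models the package implements, the defaults it ships,
the numerical choices behind them, and what the synthetic benchmarks do and
do not demonstrate.

## Moderated differential expression

Each two-group contrast (mutant vs wild type, knockdown vs control) is a
per-gene comparison of means on log₂-scale expression. With n_a, n_b
samples per arm, the pooled residual variance s² has d = n_a + n_b − 2 df.
The empirical-Bayes layer assumes s² ~ s₀²·χ²_d/d with the prior itself
chi-square distributed (d₀ df), and estimates (d₀, s₀²) by moment matching
on z = log s²: the excess of Var(z − ψ(d/2) + log(d/2)) over the chi-square
noise ψ′(d/2) identifies d₀ through the trigamma inverse (Newton iteration,
relative tolerance 1e−10), and the mean identifies s₀². When the observed
spread of log-variances does not exceed chi-square noise — exactly what
happens under the homoscedastic synthetic generator — d₀ is infinite and
every gene shares s₀². The posterior variance s̃² = (d₀s₀² + d·s²)/(d₀+d)
gives the moderated t on d₀ + d df (normal in the infinite-d₀ limit).

The B statistic is the log posterior odds of differential expression under
a two-component model: a proportion p (default 0.01, exposed as
`p_prior`; the cohort data never pin it down, and it shifts B by a
constant) of genes carry a true effect with prior variance v₀ on the
coefficient scale. B = log(p/(1−p)) − ½log r + (1+df)/2 ·
log((t²+df)/(t²/r+df)) with r = (v+v₀)/v and v = 1/n_a + 1/n_b. v₀ is
estimated from the top 10% of genes by |t| via the moment identity
E[logFC²] = v₀ + v·σ² for a truly differential gene, averaging
max(0, logFC² − v·s̃²); the estimate is floored at v·median(s̃²) so the
prior stays proper when no gene shows excess spread. Selection rules are
strict inequalities, matching their published statements: candidates need
B > 0 **and** log₂FC > 1 in ≥ 2 systems; knockdown signatures need linear
FC < 0.5 (log₂FC < −1) and B > 0. Genes with zero residual variance in
both arms are floored at machine epsilon with a warning rather than
dropped; a matrix whose genes *all* have zero variance is a degenerate fit
and raises.

The expression floor filter drops a gene when *more than* the configured
fraction (default 0.5) of all samples sit below the floor (default 5 log₂
units; 4 for the knockdown-array configuration) — a gene low in exactly
half the samples is retained.

## Preranked GSEA and the recurrence filter

Lists are ranked by log₂FC descending with ties broken by ascending gene
symbol, so ranking is a pure function of the DE result. The enrichment
score is the signed extreme of P_hit(i) − P_miss(i), where hits contribute
|metric|^p/N_R (weight p default 1; p = 0 recovers the classical KS form)
and misses 1/(N − N_H). If every member's metric is zero the hit weights
fall back to equal weighting rather than dividing by zero. The extreme is
taken at the first index attaining the maximal |deviation|.

Because only a ranked list exists at this stage, significance uses a
gene-resampling null: random same-size sets drawn from the list. The
permutation code exploits the fact that the running-sum extreme occurs
immediately at a hit (positive side) or immediately before one (negative
side), so each permutation needs only 2·N_H candidate deviations; this is
vectorised across permutations and checked bit-for-bit against a full
running-sum evaluation in the tests. p = (1 + #{same-sign |ES_null| ≥
|ES|})/(1 + #same-sign nulls) — the +1 pseudo-count keeps p positive, and
conditioning on sign makes the minimum attainable p equal 1/(1 +
#same-sign nulls), roughly 2/(n_perm) rather than 1/(1+n_perm). NES
divides ES by the mean |ES| of same-sign nulls. n_perm defaults to 1000.

The leading edge is the set members at or before the running-sum peak
(positive ES) or at or after the trough (negative ES). The core signature
keeps genes present in strictly more than `recurrence_fraction` (default
0.5) of the per-cohort leading edges; with 4 cohorts that means ≥ 3
appearances. The orchestrator (`run_discovery`) halts with an explicit
status instead of raising when an intermediate set is empty
(`no cross-system candidates`, `no recurrent leading-edge genes`) or when
fewer systems than `min_systems` are supplied, so partial reports stay
usable.

## Signature scores, classifier, ROC

The geometric-mean score is 2^(mean log₂ expression) over the signature
genes — exactly the geometric mean of linear values. The z-sum score
standardizes each gene across samples (mean 0, sd 1, ddof 1) and sums over
the signature; zero-variance genes are excluded with a warning. Both
renormalize over the genes actually present when some are missing, down to
a minimum coverage fraction (default 0.75) below which scoring refuses.
The status classifier is a single-feature unregularized logistic
regression fit by IRLS (tolerance 1e−8 on the coefficient step, 100
iterations); complete separation is detected from a diverging slope
(|β| > 30 on the logit scale) and flagged on the returned fit rather than
raised, since separation is the *expected* outcome on strongly planted
synthetic cohorts. AUC uses the rank/Mann–Whitney formulation with ties
counting ½, which is exactly the concordant-pair count; ROC points come
from a threshold sweep.

## Survival

Kaplan–Meier estimation and Cox fitting delegate to lifelines (Efron tie
handling; without ties this agrees with a Breslow fit to 1e−6, verified by
cross-fitting scikit-survival). The Mantel–Cox log-rank statistic is
computed explicitly — expected events from the hypergeometric mean and
variance at each distinct event time, χ² = (ΣO − ΣE)²/ΣV on 1 df — because
the per-group observed/expected decomposition is part of the module
contract; it matches lifelines to 1e−9 and the one-binary-covariate Cox
score test in the suite. Cox results carry Wald CIs exp(β ± 1.96·se); a fit
with |β| > 20 or a failed likelihood maximization is returned flagged, not
raised. High/low stratification cuts at a configurable score quantile
(default the median — no published cutpoint exists, so the quantile is
explicit in every report), assigns threshold ties to *low*, and optionally
computes thresholds within each mutation-status stratum. "Worst curve"
comparisons in the drivers use restricted mean survival time to a fixed
horizon (the 80th percentile of follow-up), which is less noisy than a
single survival probability.

## Meta-analysis and enrichment

Per-study effects are Hedges' g: Cohen's d times J = 1 − 3/(4(n₁+n₂−2)−1),
with var(g) = J²[(n₁+n₂)/(n₁n₂) + d²/(2(n₁+n₂))] (Cohen's d available via
`correct=False`). Pooling is inverse-variance; the random-effects model
adds the DerSimonian–Laird τ² = max(0, (Q−df)/C) to every study variance.
Random effects is the CLI default since cross-platform cohorts are
heterogeneous; both CIs use the normal 1.96 quantile, so the random CI is
never narrower than the fixed one. Category enrichment is the inclusive
upper-tail hypergeometric P(X ≥ k) on categories intersected with the
universe, BH-adjusted; categories are taken as given (no ontology-graph
propagation).

## Drug synergy and assay metrics

The median-effect line log₁₀(fa/(1−fa)) = m·log₁₀D − m·log₁₀Dm is fit by
OLS; points with fa ∉ (0,1) are excluded (logit undefined) with a logged
count rather than clamped. Dx(fa) = Dm·(fa/(1−fa))^(1/m), and the
non-constant-ratio combination index is CI = d₁/Dx₁ + d₂/Dx₂ at the
observed combined effect — the assays this models combine fixed
concentration pairs, not constant-ratio dilutions. Calls use the strict
CI < 1 / = 1 / > 1 definitions with a ±0.05 reporting band around 1 for
"additive" on noisy data. CI is invariant to rescaling both drugs' dose
axes. Power for the two-sided two-sample t-test uses the noncentral t with
ncp = (Δ/σ)·√(n/2) on 2n−2 df; n is per group (the published 12/30%/0.25
design then yields 0.802, reproducing its stated 80%). Population doubling
time is hours·log 2/(log Nt − log N₀) — the conventional exponential-growth
formula; the formula as printed in the source protocol omits the division
by the doubling count and is not implementable as typeset. Tumour volume
is the ellipsoid π/6·L·W², with swapped dimensions corrected (warning)
rather than rejected.

## Synthetic data: what it emulates, and what it does not

`simulate_multi_cohort` plants the first `n_planted` genes with a uniform
+`planted_log2fc` shift in mutant samples over gene-specific baselines
(N(8, 1) log₂ units, far above the floor filter), with i.i.d. Gaussian
noise (sd 0.5) — matching the roughly Gaussian residuals of RMA-normalized
arrays. Defaults (2000 genes, 20 planted, log₂FC 1.5, 10 samples per arm,
3 systems, 4 cohorts) give the discovery rule high power while leaving the
recurrence filter non-trivial: validation cohorts attenuate the effect to
80% to emulate cross-dataset heterogeneity. Survival times are exponential
with hazard baseline·exp(β·(score − mean)) and independent exponential
censoring, so Cox recovery has a closed-form target. Dose-response curves
come from the median-effect equation with Gaussian noise on the logit,
clamped to (0.001, 0.999).

Deliberately absent: probe-level artifacts, batch effects, heavy-tailed or
gene-correlated noise, copy-number structure, non-proportional hazards and
Weibull baselines. Passing the recovery suites therefore shows the
*pipeline logic and statistics* are correct under their own model
assumptions — not that real cohorts would yield a 20/20 recovery or AUC
1.0; on real data the same stages face violated assumptions the generator
does not model.

## Problem sizes and determinism

All generators are pure functions of (params, seed); `run_discovery` with
a fixed seed is bit-reproducible (cohort k uses seed + k for its
permutations). The shipped benchmark sizes — 2000-gene simulations, 500
permutation/coverage replicates, 20 Cox replicates at n = 500, GSEA
calibration at 199 permutations on 200-gene lists — were chosen as the
smallest sizes at which the targeted effects are statistically
unambiguous, and run in seconds.

## Known limitations

Two-group contrasts only (no design matrices); gene identity is
case-folded symbol equality with an optional two-column mapping table, the
honest default given that cross-species ortholog mapping is unspecified
upstream; no FDR across multiple GSEA gene sets (single-set preranked use
only); the B statistic's p_prior is a reporting convention, so B
thresholds should be read jointly with it.
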