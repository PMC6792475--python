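# Methods

This note documents the statistical machinery, the numerical choices and
the known limitations of `cisel`.

## Conditional-independence tests

All selection decisions reduce to tests of ind(Y, X | Z): is feature X
independent of the target Y given the feature set Z?  Each test returns a
statistic, its degrees of freedom and the natural-log p-value `logp`.
Working on the log scale is not cosmetic: in n ≫ p problems p-values
routinely pass 1e-300, and comparing `logp < ln(α)` keeps every decision
exact where raw p-values would underflow to zero.  `log_pval_chisq`
evaluates ln P(χ²_df > stat) through `scipy`'s log-survival function and
switches to the asymptotic expansion of the upper incomplete gamma
function in the far tail (stat ≳ 1400), where the survival function
itself underflows.

**Continuous targets.**  The Fisher z-test on the partial correlation:
residualise y and the candidate column on [1, Z] (via one QR
factorisation per conditioning set), correlate the residuals, and refer
z = √(n − |Z| − 3) · |atanh r| to the standard normal (two-sided, on the
log scale).  The Spearman variant applies the same machinery to midranks
(computed once per matrix).  Exact collinearity (|r| = 1) is reported as
`logp = −inf` with a warning; a candidate lying in the span of Z carries
no additional information and is reported with r = 0.  Residualisation is
done one column at a time even when a whole batch shares a conditioning
set, so a replayed single test reproduces a batch result bit for bit.

**Regression families.**  For binary, nominal, count and survival targets
the likelihood-ratio test (LRT) compares nested fits Y ~ Z and
Y ~ Z ∪ {X}: stat = 2(ll₁ − ll₀), df = parameters added by X (1 for a
numeric column, L−1 dummies for an L-level categorical feature, times
C−1 for a C-class multinomial target).  Backends: logistic and Poisson
through `statsmodels` GLM, multinomial through `MNLogit`, negative
binomial (NB2) with its shape profiled by maximum likelihood, Cox partial
likelihood (Efron ties) and the Weibull accelerated-failure-time model
through `lifelines`.  Intercept-only null models use closed forms
(Gaussian, binomial, Poisson, multinomial) or the exact Efron null
partial likelihood −Σ groups Σ_{l<d} ln(m − l) for Cox, which matches
`lifelines`' internal likelihood-ratio test to machine precision.  Null
fits are cached per conditioning set.

**Quasi-Poisson.**  The dispersion φ is estimated by Pearson χ²/(n − k)
on the larger model and the scaled statistic (2Δll/df)/φ is referred to
F(df, n − k).  The quasi-Poisson literature offers several variants; this
one reduces to the LRT when φ = 1 and was verified to hold its size on
over-dispersed null data.

**Wald flavor.**  The coefficient block of X from the full fit gives
stat = b'V⁻¹b on df = |b|; for the correlation engine the Wald and LRT
flavors coincide (the z-test).  Wald and LRT agree asymptotically under
local alternatives; under fixed alternatives they may differ, which is
expected behaviour.

**Permutation flavor.**  The X column is permuted B times (target and Z
fixed), the base LRT-flavor statistic is recomputed each time, and
p = (1 + #{perm ≥ obs})/(B + 1) — the add-one estimator, so p > 0 always
and logp ≥ −ln(B + 1).  Default B = 999.  Permutation draws derive from
the configured seed and the query, so results are reproducible.
Correlation-family permutations are vectorised.

**Non-convergence.**  A fit that fails after a regularised/extended-
iteration retry yields logp = 0 with a warning: a failed fit is treated
as evidence of nothing, never as a selection.

**Degenerate inputs.**  Constant columns are excluded up front with a
warning; testing one raises.  Categorical features enter designs as
reference-cell dummies with the first sorted label as reference.

## Search algorithms

Significance everywhere means `logp < ln(threshold)` (default α = 0.05).
Ties in logp break by larger |stat|, then lower column index, making all
runs deterministic.

**MMPC.**  For every candidate the algorithm tracks its *weakest*
association — the maximum logp over all conditioning subsets tested so
far.  A candidate is dropped permanently once that maximum crosses ln α
(and the maximising subset is stored as its certificate of exclusion);
the next admission goes to the candidate whose weakest association is
strongest.  Tested subsets are those of size ≤ max_k drawn from the
selected set that contain the most recently admitted member, plus the
empty set — the classical restriction that bounds cost; across a run this
covers every subset (up to max_k) of the final selection for candidates
still alive when the subset became available.  With max_k = 0 the
algorithm reduces exactly to the marginal-significance filter.

**SES.**  After the MMPC run, each dropped feature x with excluding
subset Q is tried as a swap for every selected s ∈ Q: if
ind(Y, s | (Q \ {s}) ∪ {x}) also holds at the same threshold, x joins the
equivalence class of s.  Signatures are the Cartesian product of the
per-slot classes (row 0 = base selection), capped at `max_signatures`
(default 1000).  The single-subset swap rule is a design choice; an
alternative would re-validate against every subset, at higher cost.

**MMMB.**  MMPC on the target, then MMPC around each selected feature
(as a continuous target, Fisher or Spearman engine); a neighbour u of s
not already selected is admitted as a spouse when some tested subset
containing s re-establishes dependence of u with the target.

**IAMB / forward / backward.**  Textbook stepwise driven by the same
tests; IAMB's backward variant removes *all* currently non-significant
members per sweep.

**FBED.**  Each forward iteration tests every pool member conditional on
the current selection, drops all non-significant ones from the pool and
admits the best significant one.  When the pool empties the dropped set
is restored and the phase reruns, up to K extra times (K may be a
vector; `per_k_info` records (K, selected after pruning, cumulative
tests) per value).  A backward phase then prunes the selection.  The
reported per-feature statistic is the one from the test that admitted the
feature in the forward phase.  With `stop_rule="ebic"` admission/removal
uses the extended-BIC difference, eBIC = −2ll + d·ln n + 2γ·d·ln p with
γ ∈ [0, 1] (γ = 0 is plain BIC); the quasi-Poisson engine has no
likelihood and rejects this rule.

**Test accounting.**  `n_tests` counts conditional-independence test
evaluations, one per (feature, conditioning set) query; cached replays
count too.  This makes the counter identical with caching on or off, and
makes univariate-score reuse save exactly p tests — the two contracts the
counter exists to support.  (Counting model fits instead would make the
number cache-dependent and save p + 1 on reuse.)

**Caching and reuse.**  `TestCache` memoises results by (test, flavor,
feature, conditioning set); replay is bit-identical to recomputation, so
algorithm output is byte-identical with caching on or off.  `mmpc_path`
shares one cache across a (threshold, max_k) grid.  Univariate screens
(`univariate_screen`) transfer between MMPC, SES, FBED and forward
selection when the test name matches; mismatched names are recomputed.

## Generalised OMP

Classical OMP generalised by a per-family residual: raw residuals
(Gaussian), response residuals y − μ̂ (logistic, Poisson-family), the
per-class indicator-minus-probability matrix (multinomial; a feature's
score is the Euclidean norm of its per-class inner products), and
martingale residuals (Cox, Weibull).  Columns are centred and scaled to
unit standard deviation for the inner-product step; refits use the
original scale.  Stopping: a step must lower the deviance by at least
`tol` (default 3.84, the 0.95 quantile of χ²₁ — one significant
parameter's worth) or raise the adjusted R² by at least `tol`
(conventional 0.01; continuous targets only).  For quasi-Poisson the
deviance is scaled by the current model's Pearson dispersion, so
over-dispersed data pay more per step and fewer features enter — the
practical reason to prefer `testIndQPois` over `testIndPois` on counts
with variance above the mean.  A non-decreasing deviance step stops the
pursuit with a warning; when the selected features span the target the
path ends at deviance ≤ 1e-8 of the null.  The greedy order does not
depend on `tol`, so `gomp_path` computes the longest path once and
truncates — larger tolerances give exact prefixes.

## Synthetic data

`gen_glm` draws an n × p Gaussian design with exchangeable correlation ρ
(a single parameter is enough to stress collinearity), plants `n_active`
features with coefficients `beta` and draws the target from the chosen
family (Gaussian noise σ = 1 by default; NB2 dispersion such that
Var = μ + d·μ²; multinomial with 3 classes sharing the active set with
per-class random coefficient signs).  `gen_survival` draws Weibull
proportional-hazards times (shape 2) with independent exponential
censoring whose scale is calibrated by bisection to the requested
censoring fraction (realised within ±0.1 for n ≥ 200); status codes
1 = event.  `gen_equivalent` appends near-duplicates of an active column
(correlation 1/√(1 + sd²/var)).  Generators are deterministic under
their seed and never touch global random state.

What the generators do *not* emulate: heavy-tailed or non-linear
dependence, batch effects, measurement error, informative censoring and
realistic correlation structure beyond exchangeable.  Passing tests on
these data demonstrate algorithmic correctness and calibration under the
stated models, not performance on any particular real dataset.

## Study conditions used by the checks

Calibration uses 500 null replicates per test at n = 200; false-positive
behaviour 200 pure-noise replicates at n = 200, p = 50; recovery 50
replicates of a planted 5-feature regression at n = 500, p = 100,
β = 1, σ = 1; oracle comparisons 20 orthonormal 64 × 16 instances and
five 8-feature linear systems at n = 1000.  These sizes keep the full
check suite within a few minutes on one CPU while leaving the binomial
error of the measured rates well below the margins being tested.

## Known limitations

- On pure-noise data, threshold-based searches keep features that are
  marginally significant at α by chance; conditioning on other noise
  features barely moves such p-values, so the expected false-positive
  count scales like p·α for MMPC-style searches and p·α² for FBED.
  Tighten `threshold` (or use FBED with eBIC) when a near-zero
  false-positive count matters more than power.
- Wald tests can disagree with the LRT at small n or large effects;
  the permutation flavor is the safer choice at small n.
- Negative-binomial fits profile the shape parameter and can sit on the
  α → 0 boundary when data are not over-dispersed; the LRT is unaffected
  but Wald covariances there are unreliable (reported as non-convergent).
- Cross-validation selects and fits per training fold, but with very few
  events per fold survival metrics are noisy; stratification is applied
  to class labels only.
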