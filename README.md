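# cisel

Feature selection for biostatistics and epidemiological modelling, built
around conditional-independence (CI) tests that handle the outcome types
that actually occur in biomedical data: continuous measurements, binary
and nominal labels, counts, and censored time-to-event outcomes.

## Who this is for

Analysts facing a numeric feature matrix (rows = samples, columns =
features, often with n ≪ p, e.g. gene expression) who want the *minimal*
set of features that predicts an outcome — plus, when several feature sets
are statistically interchangeable, all of them.

## What it computes

Every algorithm decides "is feature X informative about target Y given
the already-selected set Z?" with a test of conditional independence
ind(Y, X | Z):

- continuous Y — Fisher z-test on the partial correlation
  (`testIndFisher`), or its Spearman rank variant (`testIndSpearman`);
- binary / nominal Y — logistic / multinomial regression
  (`testIndLogistic`, `testIndMultinom`);
- counts Y — Poisson, quasi-Poisson or negative binomial regression
  (`testIndPois`, `testIndQPois`, `testIndNB`);
- survival Y (time + 0/1 status, 1 = event observed) — Cox or Weibull
  regression (`censIndCR`, `censIndWR`).

Regression-based tests come in likelihood-ratio, Wald and permutation
flavors.  All p-values are reported and compared on the natural-log scale
(select iff log p < ln α), so nothing underflows even at p < 1e-300.

The search algorithms on top of the tests:

| function | algorithm |
|---|---|
| `mmpc` | max-min parents-and-children: forward search with max-min candidate scoring and permanent dropping of candidates rendered independent, with certificates of exclusion |
| `ses` | statistically equivalent signatures: MMPC plus enumeration of interchangeable feature sets |
| `mmmb` | max-min Markov blanket: MMPC plus spouse recovery |
| `forward_selection` / `backward_selection` | classical stepwise regression |
| `iamb` | incremental-association Markov blanket (forward phase, then sweeps removing all non-significant members) |
| `fbed` | forward-backward with early dropping; the dropped pool can be revisited K times; optional eBIC stopping |
| `gomp` | generalised orthogonal matching pursuit: residual-based greedy selection with deviance or adjusted-R² stopping |

Plus: test-result caching, univariate-score reuse across algorithms,
hyperparameter paths (`mmpc_path`, `gomp_path`), cross-validated
hyperparameter assessment (`cross_validate`; AUC / accuracy / F score,
MSE / MAE / proportion of variance explained, concordance index), and a
synthetic-data generator with planted ground truth (`gen_glm`,
`gen_survival`, `gen_equivalent`).

## Worked example

Select features for a censored survival outcome with forward-backward
early-dropping selection and the Cox likelihood-ratio test.  The data are
synthetic (295 samples, 70 features, ~21% censoring) with two planted
risk factors at columns 31 and 69:

```python
from cisel import AlgoConfig, fbed, gen_survival

ds = gen_survival(295, 70, n_active=2, beta=0.6, censor_rate=0.21, seed=42)
res = fbed(ds.target, ds.X, AlgoConfig(), test="censIndCR")
print(res.res_table());  print(res.info_table())
```

```
 sel      stat       pval
  31 67.930880 -36.314692
  69 77.477030 -41.151812
     Number of vars  Number of tests
K=0               2               80
```

Both planted features — and nothing else — are selected.  `stat` is the
chi-square likelihood-ratio statistic of the test that admitted each
feature and `pval` its natural-log p-value (−36.3 means p ≈ 1.7e-16);
the run fitted 80 conditional-independence tests in total.

The same run from the shell:

```bash
cisel simulate --n 295 --p 70 --family survival --n-active 2 --seed 42 --out surv
cisel fbed --data surv.csv --time time --status status --test censIndCR
```

## Limitations

Clustered/longitudinal targets (GLMM/GEE), ordinal, beta, zero-inflated,
Tobit and matched case-control regressions are out of scope, as are
out-of-core backends and plotting.  `gomp` accepts continuous features
only.  See `docs/methods.md` for the statistical details and design
choices.
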