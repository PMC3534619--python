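# riskbounds

Distribution-free upper bounds on the accuracy of genetic (or any
probabilistic) prediction of a binary trait, computed from just two
epidemiological parameters: the trait's average risk *k* (prevalence or
lifetime risk) and the proportion of phenotypic variance explained (PVE) by
the predictive factors — broad-sense heritability *H²* on the observed
binary scale when the factors are all genetic.

The package answers questions such as: *given that type 2 diabetes has
lifetime risk 13% and observed-scale heritability 26%, how accurate could a
genetic test ever be, no matter how many variants are discovered?*  It is
aimed at statistical geneticists and epidemiologists planning association
studies or evaluating proposed risk predictors.

## The model

The population's conditional risk distribution is a histogram on *b* + 1
equally spaced risk levels 0, 1/*b*, …, 1 with probabilities *p₀ … p_b*.
Two moment constraints pin the distribution family:

- mean risk:  k = Σᵢ (i/b) pᵢ   (law of total probability)
- PVE:  k(1−k)·PVE + k² = Σᵢ (i/b)² pᵢ

Bayes' rule gives the risk densities of future cases (Y) and non-cases (X),
and the AUC of the ideal risk-ranking predictor is the Mann–Whitney
probability P(X &lt; Y) + P(X = Y)/2.  After eliminating *p₀*, the AUC
numerator is the quadratic form *pᵀQp* + *b²k* with
Q[i,j] = −j(b+i)/2 for i ≥ j; Q is negative definite, so maximizing the AUC
over all feasible histograms is a concave quadratic program with a certified
global optimum.  At any decision threshold t/b, sensitivity and specificity
are linear in *p*, so the largest sensitivity compatible with a specificity
target is a linear program, maximized over all thresholds to give one point
of the best-case ROC envelope.  A moment-matched beta distribution
(shapes a = k(1/PVE−1), b = (1−k)(1/PVE−1)) serves as the baseline
corresponding to earlier smooth-liability approximations; it is one feasible
histogram, so it never beats the distribution-free bounds.

No external data are required; everything follows from (k, PVE, b).

## Worked example

Lifetime type 2 diabetes: average risk 13%, observed-scale heritability 26%.

```
$ riskbounds auc -k 0.13 --pve 0.26
k: 0.13
pve: 0.26
bins: 100
max_auc: 0.8882526687390059

$ riskbounds roc -k 0.13 --pve 0.26 --specificity 0.99
k: 0.13
pve: 0.26
bins: 1000
specificity: 0.99
max_sensitivity: 0.3553533099807843
threshold_bin: 90

$ riskbounds beta -k 0.13 --pve 0.26
k: 0.13
pve: 0.26
bins: 1000
a: 0.37
b_shape: 2.4761538461538457
beta_auc: 0.8697210182787319
```

Reading: no genetic test for this trait can exceed an AUC of 0.89, however
many variants are found; if a screening test must have 99% specificity, its
sensitivity cannot exceed 36% (achieved by declaring positive everyone with
risk ≥ 90/1000 = 0.09); and under the smooth beta-shaped risk assumption of
earlier approximations the ceiling would have been quoted lower, 0.87 —
the distribution-free bound is genuinely higher.  Note that each ROC point
may require a *different* risk distribution, so the envelope is not the ROC
of any single trait.

Liability-scale heritability estimates must be converted to the observed
binary scale first:

```
$ riskbounds convert --liability-h2 0.4 -k 0.13
binary_scale_h2: 0.15827173554075752
```

The same library API is available in Python:

```python
from riskbounds import DiseaseParams, max_auc
res = max_auc(DiseaseParams(k=0.13, pve=0.26), b=100)
res.max_auc        # 0.8882...
res.optimizer      # the risk distribution achieving it
```

Lookup tables over parameter grids (`riskbounds table-auc`,
`riskbounds table-sens`) and a bin-resolution convergence report
(`riskbounds convergence`) are written as CSV with a commented metadata
header.

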