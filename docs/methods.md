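# Methods

## Model

A binary trait with average risk *k* ∈ (0, 1) is predicted through each
individual's conditional risk (probability of the trait given their
measured factors).  On the population level these risks form a *risk
distribution*; we represent it non-parametrically as a categorical
distribution (histogram) on *b* + 1 equally spaced levels 0, 1/*b*, …, 1,
with bin probabilities *p₀ … p_b*.  Any risk distribution can be
approximated this way, which is the point: the bounds make no shape
assumption (no normal liability, no unimodality).

Two identities connect the histogram to the two inputs:

1. **Mean.** By the law of total probability the unconditional trait
   probability equals the mean of the risk distribution:
   k = Σ (i/b) pᵢ.
2. **Variance.** The proportion of phenotypic variance explained by the
   factors is PVE = 1 − E[risk(1−risk)] / (k(1−k)) — one minus the average
   within-risk-group Bernoulli variance over the total phenotypic variance
   — equivalently Var(risk)/(k(1−k)), i.e. the second moment satisfies
   E[risk²] = k(1−k)·PVE + k².  With all genetic factors, PVE is
   broad-sense heritability on the observed binary scale.

Both identities are implemented in `risk_model` in the residual-variance
form; the unit tests verify agreement with the second-moment form to 1e−12
on random distributions.

Conditioning by Bayes' rule yields the risk densities among future
non-cases (X) and cases (Y): P(X = i/b) = (b−i)pᵢ/(b(1−k)) and
P(Y = i/b) = i·pᵢ/(b·k).  The accuracy of the *ideal* predictor — one that
ranks individuals by their true risk — is then:

- **AUC** = P(X &lt; Y) + P(X = Y)/2 (the Mann–Whitney identity, ties
  counted half), evaluated by direct enumeration in `auc_oracle`;
- **sensitivity / specificity** at threshold "positive iff risk ≥ t/b":
  Se = Σ_{i≥t} i·pᵢ/(b·k), Sp = Σ_{i&lt;t} (b−i)pᵢ/(b(1−k)).

The enumeration routines are the oracle against which both optimizers are
verified (dominance and reproduction properties in the test suite).

## Maximal AUC: a concave quadratic program

Substituting p₀ = 1 − Σ_{i≥1} pᵢ makes the AUC numerator the quadratic form
pᵀQp + b²k on the reduced vector (p₁…p_b), with
Q[i,j] = −j(b+i)/2 for i ≥ j (symmetric).  Q is negative definite — checked
once per bin count by Cholesky factorization of −Q — so maximizing AUC over
the polytope {0 ≤ pᵢ ≤ 1, Σpᵢ ≤ 1, both moment equalities} is a concave QP
whose local optimum is global.

**Solver.**  The maximizer's support is empirically always a contiguous run
of bins, so `max_auc` uses an exact interval active-set method: solve the
equality-constrained KKT system on a candidate bin interval, shrink
interval ends whose probabilities go negative, extend ends where the
Lagrangian gradient of a zero bin is positive, and stop when the full KKT
conditions hold — which certifies the global optimum regardless of how the
interval was found.  For large *b* the interval is located on a 128-bin
grid first (support endpoints are stable as risk fractions) and refined at
full resolution; a b = 1000 solve takes ~0.1 s.  A general trust-region
constrained solver (scipy's trust-constr on the reduced Q-form) is retained
as a fallback for any case where the interval search fails, and as an
independent cross-check in the tests (agreement ~1e−8).  Returned
optimizers are validated post hoc: mean and PVE must be reproduced within
1e−6 and the reported bound must equal the enumeration AUC of the optimizer
within 1e−6, else the result is flagged `numerical_failure`.

**Degenerate corners.**  PVE = 1 forces all mass onto risks 0 and 1 (the
unique feasible histogram; AUC 1).  The grid minimum of variance at mean
*k* puts all mass on the two bins adjacent to k·b (PVE can only reach 0
when k·b is an integer); at that boundary the distribution is again unique
and is returned directly.  (k, PVE) pairs whose implied second moment falls
outside [grid minimum, k] are reported `infeasible` — a status, not an
exception, so grid sweeps can proceed.

**Relaxed second moment.**  `max_auc(..., relax_pve=True)` imposes
E[risk²] ≥ k(1−k)·PVE + k² instead of equality ("PVE at least this
large").  Because the maximal AUC is nondecreasing in PVE, this relaxation
is maximized at perfect separation (AUC → 1); the flag exists for contract
completeness and sanity checks, but the equality bound is the informative
quantity and is the default.

## Maximal ROC envelope: linear programs over thresholds

For fixed threshold t, Se and Sp are linear in *p*.  `max_sens_at_threshold`
maximizes Se subject to Sp ≥ target plus the moment equalities and simplex
bounds (scipy linprog, HiGHS); `max_roc_point` takes the best over all
t ∈ {0 … b+1}, recording the smallest optimal threshold on ties so output
is deterministic.  The specificity constraint is an inequality, not an
equality: the curve is an upper *envelope*, and "max Se at Sp ≥ s" is
feasible for every s up to the attainable maximum.  The
sensitivity-direction bound (`max_spec_at_sensitivity`) is its own LP with
the roles swapped, not a numerical inversion of the curve, so printed
values at extreme targets are exact.

Each envelope point may be achieved by a *different* risk distribution;
consequently the trapezoidal area under the envelope can exceed the
(single-distribution) maximal AUC, and the tests assert only the ≥
direction.  The defaults are b = 1000 for the LPs and b = 100 for the QP;
both are arguments.  A full threshold sweep at b = 1000 solves ~1000 LPs of
1001 variables in ~7 s.

## Beta baseline and conversions

The unique beta distribution with mean k and variance PVE·k(1−k) has shapes
a = k(1/PVE − 1), b = (1−k)(1/PVE − 1).  It stands in for earlier
approximations that assumed a smooth unimodal (liability-derived) risk
distribution.  We discretize it by cell probability — bin i receives the
CDF mass of [(i−½)/b, (i+½)/b] clipped to [0,1] — and renormalize; this
preserves total mass and converges in both moments at rate O(1/b) (the
exact discretization used by prior work is not specified; alternatives
differ in the third decimal at b = 1000).  Its enumeration AUC and
threshold ROC are compared against the QP/LP bounds in the tests: being one
feasible histogram, the beta baseline can never exceed them.

Conversions supplied for convenience: GWAS planning R² = r²H² (r the
correlation between estimated and true genetic risk); twin-correlation
heritability 2(r_MZ − r_DZ) on binary outcomes; and the Dempster–Lerner
mapping h²_obs = h²_liab·z²/(k(1−k)) with z the standard normal density at
the liability threshold for prevalence k.  The Dempster–Lerner formula is
taken from the standard quantitative-genetics literature.  Estimates pushed
outside [0, 1] by sampling noise are clamped with a warning rather than
rejected.

## Synthetic distributions and sampled cohorts

Property tests need arbitrary distributions with exact (k, PVE).
`random_feasible_distribution` draws Dirichlet weights on a random support,
fixes the mean by mixing with a point mass at risk 0 or 1, then fixes the
second moment by mixing with the minimum-variance (adjacent-bin) or
maximum-variance (risks 0 and 1) distribution of the same mean.  Every
stage is a convex combination of distributions, so feasibility is
guaranteed in one shot with moments exact to machine precision.  (A
least-squares projection onto the moment constraints was considered and
rejected: the unconstrained projection almost surely leaves small negative
mass on fine grids, and shrinking the noise cannot fix this because the
correction shrinks proportionally.)

`empirical_auc` simulates a cohort: risks sampled from the histogram,
outcomes Bernoulli in those risks, AUC as the rank statistic of risk
against outcome.  It emulates only the sampling noise of a finite study in
which true risks are known; it does not model genotyping, risk-estimation
error, or linkage structure — so passing tests show the bounds are
respected by ideal finite samples, not that any realizable genotype-based
predictor attains them (attainment is exactly what the bounds do not
promise).

## Numerical choices

- Probability sums and moment identities validated at 1e−9 (float
  accumulation over ≤1001 bins is orders of magnitude smaller).
- QP/LP constraint satisfaction required at 1e−8/1e−9; reported bounds are
  full precision, comparisons with whole-percent published values round to
  two decimals.
- Risk-distribution files must sit exactly on the i/b grid; re-binning is
  refused because the moment constraints are defined on the grid.
- Threshold convention: "positive" means risk ≥ t/b, t ∈ {0 … b+1} so both
  trivial ROC endpoints are included.
- Tie-break: smallest threshold achieving the LP optimum.

## Problem sizes used in the checks

The acceptance script solves the QP at b = 100 (and b = 10/1000 for the
resolution report, over 75 grid cells) and full LP threshold sweeps at
b = 1000; the whole run is well under a minute.  The test suite uses
b = 10–100 for property tests and the published-value checks at their
stated bin counts.

## Known limitations

- The bounds are *upper limits of an ideal risk-ranking predictor*; nothing
  here estimates what an actual predictor built from data would achieve.
- The bin-resolution report shows the AUC bound is insensitive to b away
  from feasibility corners (b = 100 vs 1000 agree to ~1e−5), but at coarse
  b with non-integer k·b and small PVE the feasible set itself is
  distorted and the bound can shift by >1 percentage point; use b ≥ 100
  near such corners.
- Heritability on the observed binary scale depends on prevalence; users
  comparing traits across populations should convert per population.
- The ROC envelope points are individually attainable but generally not
  jointly attainable by one trait.
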