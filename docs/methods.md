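# Methods

## Model and estimands

The analysis targets income-related inequality in a binary health-service
utilization outcome. Individuals are ranked within each survey wave by a
continuous living-standard variable — per-capita household consumption
expenditure minus health-care expenditure. Subtracting health spending
keeps catastrophic medical costs from inflating apparent living standards;
the difference may be negative and is retained, since the index only needs
the ordering.

**Fractional rank.** We use the weighted midpoint rank: after sorting
ascending, record *i* receives $(\sum_{j<i} w_j + w_i/2)/\sum_j w_j$, and a
block of records tied on the living standard shares the block's midpoint.
With equal weights and no ties this is $(i-\tfrac12)/N$ — a constant shift
of the textbook $i/N$. Because the concentration index is a covariance
with the rank, any constant shift is irrelevant, and the midpoint
convention extends cleanly to sampling weights and ties.

**Concentration index.** $C = (2/\mu)\,\mathrm{cov}_w(Y, R)$ with the
*population* weighted covariance (divisor = total weight). The population
divisor matters at small n: with the $n-1$ divisor a two-record dataset
with $y = (0, 1)$ would give $C = 1 > 1 - \mu$, violating the binary-outcome
bound; with the population divisor it gives exactly $0.5 = 1 - \mu$.

**Standard error.** The published analyses report 95% intervals without a
variance formula, so we use the standard "convenient regression"
delta-method: the WLS slope of $2\sigma^2_R\,(y_i/\mu)$ on $r_i$ equals $C$
algebraically, and its heteroskedasticity-robust (HC1) standard error is
the reported SE; bounds are $C \pm 1.96\,\mathrm{SE}$. This estimator
treats $\mu$ and the ranks as fixed, which is the usual first-order
approximation; exact replication of any particular published interval is
not attempted.

**Concentration curve.** Cumulative outcome share against cumulative
population share after sorting by living standard; one vertex per record
plus the origin. Twice the trapezoid area between the diagonal and the
curve equals the covariance formula up to an $O(1/n)$ discretization term;
the test suite enforces agreement within $2/n$, and this area route serves
as the independent oracle for the covariance implementation.

## Decomposition and horizontal inequity

Because the outcome is binary, the index is decomposed through a probit.
The probit is linearized with **average marginal effects**: for every
regressor, AME $= \overline{\phi(x'\hat b)}\,\hat b_j$, the sample mean of
the per-record derivative. The derivative form is used for dummy
regressors as well (not the discrete difference); "effects at means" were
rejected because the sample-averaged derivative is the standard choice for
the linear approximation the decomposition needs. The decomposition is

contribution$_j$ = elasticity$_j$ × $C_j$ = (AME$_j\bar x_j/\mu$) ×
$(2\,\mathrm{cov}_w(x_j, R)/\bar x_j)$,

in which $\bar x_j$ cancels, so contributions remain defined for
zero-mean regressors (elasticity and $C_j$ are reported as NaN there).

**Residual.** Reported as the exact remainder $C - \sum_j$ contribution$_j$,
which makes the additivity identity hold to machine precision by
construction. A direct computation of $GC_\varepsilon/\mu$ from the
residuals $\varepsilon = y - \sum_j \text{AME}_j x_j$ is provided as a
cross-check (`residual_generalized_ci`); by linearity of the covariance the
two coincide up to floating-point error, and a test asserts this.

**Horizontal inequity.** $HI = C - \sum_{j \in \text{need}}$
contribution$_j$. Need variables are sex, age group, disability and
chronic disease. Percent contributions are suppressed (NaN, with a
warning) when $|C| < 10^{-6}$, where the ratio is numerically meaningless.

**Economic status in the decomposition.** Default: within-wave tertile
dummies (medium, high; reference low), matching the tabulated reporting
convention. A log-expenditure alternative is available through the
pipeline's `decomposition_mode="log_expenditure"` (non-positive net
expenditures are excluded from that mode with a logged count); the package
takes no position on which a given published analysis used.

**Association model.** The odds-ratio table comes from a pooled
cross-section logit per residence stratum with survey-year dummies (plus
the region dummies already among the controls) — a two-way fixed-effect
structure in years and regions. Individual fixed effects are deliberately
not used: the covariate set contains time-invariant variables (sex, ...),
which a within-person estimator cannot identify.

## Tertiles

Within each wave, records are split by living standard into three groups
whose sizes differ by at most 2 before tie handling; the cut points are the
living-standard values at the group boundaries, and **every record tied at
a cut goes to the lower group** (deterministic; assignment depends only on
the ordering, so it is invariant to strictly increasing transforms — a
property test enforces this). Tertiles are wave-specific because economic
status is analyzed per wave.

## Synthetic panel generator

The generator emulates a 4-wave ageing panel of ~11,500 respondents aged
45+:

- **Marginals** (defaults): male 52.85%, junior-high-or-above education
  32.10%, married 89.76% (the dummy is "other marital status", 10.24%),
  insured 94.55%, smoker 39.07%, drinker 33.48%, disability 4.08%, chronic
  disease 67.09%, urban 17.74%; region west/central/east
  32.66/32.81/34.53%; age 45–50/51–60/61–70/71+ 22.96/39.39/27.15/10.50%.
- **Expenditure**: net per-capita expenditure is log-normal with mean
  5419.10 and SD 5472.43 currency units, redrawn each wave; health
  expenditure is an independent log-normal (mean 581, SD 900 — chosen once
  as a realistic order of magnitude) and total expenditure is their sum, so
  the net-expenditure construction can be exercised end to end.
- **Outcome**: $P(Y=1) = \Phi(\alpha_t + \sum_j c_j x_j + g\,R)$ with $R$
  the within-wave income fractional rank. The rank gradient $g$ defaults to
  0.05, putting the population concentration index near 0.01 — the order of
  magnitude typical of published estimates for this outcome. True
  coefficients $c_j$ follow the observed gradients (older age, education,
  insurance and chronic disease positive; smoking negative; all modest).
- **Intercept calibration**: $\alpha_t$ is solved per wave by root-finding
  so the population utilization rate matches per-wave targets
  (29.45/20.69/25.40/32.05% for 2011/2013/2015/2018). Calibration uses the
  first-wave age marginals; because the cohort ages across waves and older
  age carries positive coefficients, realized later-wave rates drift a few
  points above target — an intended consequence of panel ageing, not a bug.
- **Persistence**: covariates persist across waves; age advances with
  calendar time (a latent continuous age is drawn within bracket and
  re-bucketed each wave); expenditure is redrawn each wave from its
  conditional law given the persistent copula latents, so every wave has
  the configured cross-sectional marginals and correlations.
- **Correlation block**: a Gaussian copula over the binary covariates'
  latent normals and the log-expenditure latent. Its main use is routing
  the income gradient through a chosen covariate (e.g. chronic disease ×
  expenditure $\rho = 0.7$) to test the need/control logic of HI.
- **Step outcome**: `step_threshold=t` replaces the probit with
  $Y = 1\{R > t\}$, whose index is known in closed form:
  $C = (2/\mu)\int_t^1 (r - \tfrac12)\,dr = t = 1 - \mu$. With midpoint
  ranks the finite-sample index is exact (no Bernoulli noise), giving a
  sharp recovery check.

**What the generator does not emulate**: real attrition and refreshment,
informative missingness, survey design effects (clustering,
stratification), within-person outcome persistence, and the true joint
dependence structure of the covariates beyond the configured copula pairs.
Passing tests therefore validate the estimators under known data-generating
processes, not the substantive conclusions one would draw from any real
survey.

## The concentration-index oracle

For a configuration, the population index is computed by numeric
integration: $C = (2/\mu)\int_0^1 (r-\tfrac12)\,E[Y\mid r]\,dr$ on a
10,001-node trapezoid grid. $E[Y\mid r]$ is averaged **exactly** over the
covariate distribution: the rank-independent covariates' linear-index sum
is enumerated by discrete convolution (atoms collapsed by rounding at
1e-10), and covariates copula-linked to expenditure contribute
rank-dependent Bernoulli probabilities
$\Phi\big((\rho\,\Phi^{-1}(r) - \Phi^{-1}(1-p))/\sqrt{1-\rho^2}\big)$,
enumerated over their $2^d$ combinations. Only binary×expenditure
correlations are supported by the oracle (conditional independence given
the expenditure latent is what makes the enumeration exact);
binary×binary correlations raise `NotImplementedError` there even though
the generator accepts them. The oracle, the closed-form step case and
large-n simulation cross-validate each other in the test suite.

## Numerical choices and degenerate inputs

- Outcome mean 0 → the index is undefined and raises; constant outcome
  with positive mean → exactly 0.
- All-tied living standards → rank variance 0; the index is 0 and the SE
  is NaN.
- Probit/logit fits reject single-class outcomes, rank-deficient designs
  (naming constant/duplicated columns) and non-converged or exploding fits
  (|coef| > 100, the separation signature). The pipeline — not the core
  fitters — drops regressors that are constant *within a stratum* (e.g. the
  stratum dummy itself) and records them in the manifest.
- Stratum-level index estimates recompute ranks within the stratum;
  strata with n < 30 are flagged, not suppressed.
- Weights: duplicating a record is exactly equivalent to doubling its
  weight for the index value (a test enforces this); robust SEs differ
  slightly between the two representations, as they must.

## Problem sizes used in the test battery

Simulation-based checks run at n = 2,000–50,000 records (one 200,000-record
draw for the oracle cross-validation), 100–1,000 replicate datasets of
n = 200–500 for the bound and area-equivalence properties, and 200
replicates of n = 400 for the logit coverage check. These sizes put
Monte-Carlo error well below the asserted tolerances while keeping the full
suite around ten seconds on one core.

## Known limitations

- The delta-method SE ignores rank estimation noise and (for strata) any
  between-stratum dependence.
- Derivative-form AMEs on dummy regressors are a first-order
  approximation; the decomposition residual absorbs the gap (observed at a
  few percent of C in the single-channel configurations).
- The generator's later-wave utilization rates are calibrated through the
  first-wave age distribution (see above).
- No survey-design variance, no dominance tests, no normalized
  (Wagstaff/Erreygers) index variants.
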