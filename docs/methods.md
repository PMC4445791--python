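# Methods

This note documents the statistical machinery in `mlirt`: the model and its
estimation, the synthetic-data generator that defines the package's test
conditions, the assumption diagnostics, and the numerical and design choices
that were genuinely open.

## Model

### Measurement: graded response model

Ordinal responses $Y_{ik} \in \{0, \dots, C-1\}$ (higher = more difficulty =
worse health) follow a graded response model,

$$P(Y_{ik} \ge c \mid \theta_i) = F\big(a_k(\theta_i - \kappa_{k,c})\big),
\qquad c = 1, \dots, C-1,$$

with discrimination $a_k > 0$, strictly ordered thresholds $\kappa_{k,c}$,
and $F$ either the standard-normal or logistic CDF.  Category probabilities
are adjacent differences of the cumulative curves.  All items in one fit
must share $C$ (three after the survey's sparse top categories are
collapsed); heterogeneous category counts are rejected at fit time.
Probabilities are floored at 1e−300 before logs so a single impossible cell
cannot collapse a deviance trace to −∞ (a warning is raised instead).

The number of categories is fixed per fit, so the internal sampler works
with slope-scaled cutpoints $t_{kc} = a_k \kappa_{kc}$ — the natural scale
of the augmentation — and converts back to $\kappa$ for reporting.

### Structure: two-level latent regression

$\theta_{ij} = \mathbf{x}_{ij}'\boldsymbol\beta + \mathbf{w}_j'\boldsymbol\gamma
+ u_j + e_{ij}$ with dwelling effects $u_j \sim N(0, \tau^2)$ and person
residuals $e_{ij} \sim N(0, \sigma^2)$.  Dwelling-level covariates are
expanded to persons; the combined fixed-effect design must be full rank.
Covariates listed as *fixed* (error-free) — in the two-step analysis, the
step-1 biological-health score — enter as known columns of the design, i.e.
with their measurement error fixed to zero.

### Estimation

Under the probit link (default) the model admits fully conjugate Gibbs
sampling with data augmentation:

1. each observed cell gets a latent $Z_{ik} \sim N(a_k\theta_i, 1)$
   truncated to the interval its category defines;
2. slopes $a_k$ are conjugate (truncated) normal given $(Z, \theta)$;
   cutpoints have uniform order-constrained full conditionals
   (Albert–Chib); sides of a cutpoint with no observations fall back to the
   neighbouring cutpoint and a ±30 box, keeping the conditional proper;
3. abilities are normal, combining measurement information
   $\sum_k a_k Z_{ik}$ with the structural prediction; a person with no
   observed items draws from the structural prior alone, which is how
   missing responses (MCAR) are handled throughout;
4. regression coefficients are conjugate normal;
5. the variance pair $(\sigma^2, \tau^2)$ is updated by random-walk
   Metropolis on the *marginal* likelihood of the structural residuals with
   $u$ integrated out (cluster means $\bar r_j \sim N(0, \tau^2 +
   \sigma^2/n_j)$, within-cluster SS $\sim \sigma^2$), after which $u$ is
   redrawn from its exact conditional.  With ~1.13 persons per dwelling the
   textbook conditional-on-$u$ inverse-gamma updates confound the two
   variances and mix impractically slowly; the blocked update targets the
   same posterior and converges in hundreds of iterations.

Under the logit link steps 1–3 are replaced by random-walk
Metropolis-within-Gibbs on the item parameters and abilities; the
structural step is unchanged.  The logit option exists because applied
reports often quote GRM parameters "on the logit scale"; probit is the
estimation default and the two links agree to within 0.01 in probability
after the usual 1.7 rescaling of slopes.

**Identification.**  The latent scale is fixed by standardizing the sampled
ability vector to mean 0 / variance 1 in every iteration, with compensating
transforms $a \to as$, $t \to t - am$, $\beta_0 \to (\beta_0 - m)/s$,
$(\beta, \gamma, u) \to (\beta, \gamma, u)/s$, $(\sigma^2, \tau^2) \to
(\sigma^2, \tau^2)/s^2$.  The observed-data likelihood is invariant under
this transform (tested to 1e−8), and stored draws all live on the
identified scale.

**Priors.**  $a_k \sim N(1, 10)$ truncated positive; cutpoints flat with
the order constraint; $(\beta_0, \beta, \gamma) \sim N(0, 100 I)$; the
standard deviations $\sigma$ and $\tau$ each half-Cauchy(1).  The
half-Cauchy choice matters: with near-singleton clusters the variance split
is informed by only the ~13% of dwellings holding two or more people, and
an InverseGamma(0.001, 0.001) prior (density $\propto \tau^{-2}$) measurably
drags $\tau^2$ toward zero in that regime (mean ICC bias ≈ −0.08 at a true
ICC of 0.15 in recovery experiments; ≈ −0.03 after the switch).  The
inverse-gamma prior remains available via
`MCMCConfig(variance_prior="inverse_gamma")`.

**Initialization** (deterministic): unit slopes; cutpoints at
$\sqrt{2}\,\Phi^{-1}$ of the empirical exceedance proportions (the marginal
SD of $Z$ is $\sqrt{1+a^2} \approx \sqrt 2$ at the starting slope — using
SD 1 here biases short chains because cutpoints drift only $O(1/n)$ per
iteration); abilities at standardized rest-scores; structural coefficients
0; $\sigma^2 = \tau^2 = 0.5$.

**Run length.**  Library defaults are 5000 iterations with 1000 burn-in,
thinning 1, a single chain.  The package's own tests and acceptance runs
use 600–2500 iterations at their problem sizes (~500–4000 persons, 10–15
items), which the Geweke diagnostic and chain-length doubling checks show
to be converged for these posteriors; the structural-recovery study uses
1200 iterations per replicate.

**Summaries.**  Posterior mean, posterior SD and 95% HPD per parameter,
fixed effects in declaration order, then variance components, then item
parameters.  HPD intervals are Chen–Shao shortest windows of
$\lceil 0.95 n\rceil$ sorted draws (≥100 draws required).  Convergence is
single-chain Geweke (first 10% vs last 50%, long-run variances by
Bartlett-windowed autocovariance sums; |z| > 2 flags, constant chains are
"degenerate").  DIC uses the conditional (given $\theta$) measurement
deviance: $\mathrm{DIC} = \bar D + p_D$, $p_D = \bar D - D(\hat\theta,
\hat a, \hat\kappa)$ at posterior means; a negative $p_D$ is returned with
a warning.  Abilities are stored as running posterior means by default
(full traces optional) to bound memory.

## Two-step analysis

Step 1 fits the biological items with intercept + dwelling random effects
only and extracts posterior-mean scores.  Step 2 fits the lived items with
the step-1 score as an error-free person-level predictor alongside the
demographic/environmental blocks and the dwelling-level block.  Treating an
estimated score as error-free understates step-2 uncertainty slightly; the
one-step joint model that would avoid this is deliberately out of scope.

Derived quantities: ICC $= \tau^2_0/(\tau^2_0+\sigma^2_0)$ from the empty
lived-health model; variance explained per level by proportional reduction,
$(\sigma^2_0-\sigma^2_1)/\sigma^2_0$ and $(\tau^2_0-\tau^2_1)/\tau^2_0$
(negative values are reported as-is with a warning); and a DIC triple —
empty model, full model, and full model without the biological-health
control — whose ordering (full < no-control < empty on data with a strong
biological effect) is the model-comparison contract.  The empty model is
fitted on exactly the retained item set of the full model.

## Assumption diagnostics

* **Polychoric correlations**: two-step ML — thresholds from the univariate
  margins, then the latent correlation by bounded 1-D likelihood
  optimization over bivariate-normal rectangle probabilities; pairwise
  deletion for missing cells; items with a single observed category are
  excluded with a warning.
* **Unidimensionality**: minres extraction of 1 + G factors from the
  (smoothed) polychoric matrix, then an orthogonal gradient-projection
  rotation with the bi-quartimin criterion.  A domain is flagged when one
  group factor out-loads the general factor on a majority of the domain's
  items; singleton factors that absorb a single item's uniqueness (a routine
  over-extraction artifact) deliberately do not trigger the flag.  Flags
  warn and suggest a sensitivity re-fit; they never drop items
  automatically.
* **Local independence**: residuals of the polychoric matrix after a
  1-factor minres fit; $|r| > 0.25$ flags a pair; flagged pairs merge into
  subsets via connected components.  Heywood communalities are clipped with
  a warning.  (The 1-factor "confirmatory" model and a 1-factor exploratory
  fit coincide up to estimation method, so minres stands in for CFA here.)
* **Monotonicity**: persons binned by rest-score deciles (adjacent bins
  merged below 50 persons); an item fails when a decrease in binned mean
  score exceeds both 0.03 *and* twice its sampling standard error.  The SE
  guard is the automated analogue of judging a printed rest-score graph by
  eye — a dip within noise is not a violation; at survey scale (tens of
  thousands) it is inactive and the rule reduces to the plain 0.03
  tolerance.  Items with too few persons for two bins are "indeterminate".
* **Item retention**: monotonicity failures are dropped; within each
  local-dependence subset the item with the highest provisional
  discrimination is kept (the retention rule is a package decision — the
  convention in published applications is to keep one item per dependent
  subset without stating the rule).  When items are dropped, scores from
  fits with and without them are compared (robust if Pearson r ≥ 0.95 and
  mean |difference| ≤ 0.1).

## Synthetic-data generator

The generator emulates the structure of a national disability survey of
community dwellings and carries its ground truth for recovery tests.
Defaults are the package's study conditions:

* **Nesting**: 2000 dwellings (a desk-scale analogue of the real 15,263),
  cluster sizes $1 + \mathrm{Poisson}(0.134)$, matching the survey's 1.134
  persons/dwelling.
* **Items**: 15 per construct (analogue of the 42/31 survey questions),
  3 categories, discriminations $\sim U(0.9, 3.2)$ (the span of published
  survey estimates), first thresholds $\sim U(-1, 0.5)$ with gaps
  $\sim U(0.5, 1.5)$.  The range keeps all three categories populated at
  desk-scale n, unlike the survey's most extreme thresholds (≈ 4.5), which
  are only estimable at n ≈ 17,000.
* **Latent scores**: biological $\theta_B = u^B_j + e^B_i$ with ICC 0.15;
  lived $\theta_L$ from the structural equation with coefficients at
  published point estimates — biological health 0.902, male −0.172, age
  over 65 0.101, feeling discriminated −0.103, occupation change 0.269,
  work-relation change 0.148 — plus residual ICC 0.15 with
  $\sigma^2+\tau^2 = 0.25$.  The dwelling-level covariate (no environmental
  adaptation of the dwelling) defaults to a zero coefficient, matching its
  published null interval; "recovers all non-zero signs" therefore excludes
  it by construction.  Both scores are standardized empirically before
  response generation, and the stored truth (coefficients, variances,
  scores) is rescaled identically, so truth and estimates share the
  identified scale.
* **Covariates**: the biological-health covariate *is* the generated
  biological score (so family members share half of it through the dwelling
  effect, which is what lets person-level covariates explain dwelling-level
  variance, as observed in real data); binary gender/age/discrimination
  indicators at survey prevalences; one three-level work-change factor; one
  dwelling-level binary.  With these defaults the implied proportions of
  variance explained are ≈ 0.77 at the person level and ≈ 0.77 at the
  dwelling level, close to the published 77%/74%.
* **Observability**: every person has true lived responses, but only aid
  users' answers are observed (aid use per person × domain, logistic in
  $\theta_L$ with slope 1 and rate ≈ 0.5 — a modelling choice, as no
  prevalence is published); the equating step later copies biological
  responses for non-users, exactly as the survey handled them.  Item
  missingness is MCAR at 5%.

What the generator does **not** emulate: proxy interviews, the survey's
screening instrument, realistic Spanish demography beyond marginal
frequencies, informative (non-MCAR) missingness, or items whose lived and
biological difficulty genuinely diverge for non-aid users.  Passing
recovery tests therefore demonstrate correctness of the estimation
machinery under the model's own assumptions, not robustness to their
violation.

Because equated lived responses reflect the *biological* score for non-aid
users, the end-to-end pipeline recovers environmental coefficients with
attenuation toward zero (and the biological coefficient pushed up); signs
and orderings are preserved.  Recovery studies that quantify coverage and
bias therefore bypass equating and fit the fully observed lived matrix, as
a measurement-model study should.

## Known limitations

* Single-chain estimation; between-chain diagnostics (Gelman–Rubin) are out
  of scope.
* The conditional DIC is reported; marginal DIC is not.
* The two-step score treats step-1 estimates as error-free (see above).
* ICC recovery at the near-singleton design is noise-limited: with 2000
  dwellings only ~250 contain two or more persons, and even an oracle
  moment estimator given the true latent scores has an error SD of ≈ 0.06
  for a true ICC of 0.15.  Single-replicate ICC estimates at this scale
  should be read with that uncertainty in mind.
* Sampling weights enter descriptive tables only; model estimation is
  unweighted.
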