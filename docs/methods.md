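# Methods

## The problem

Family health history (FHH) is collected as *proxy reports*: an informant
describes the disease status of their relatives. When several members of the
same family each contribute a report set, the reports overlap — several
informants may describe the same relative, and they may disagree. `mifhh`
reconciles such multiple-informant FHH (MIFHH) tables into per-member disease
probabilities while modelling where report variation comes from: dyad-level
attributes (how far apart informant and member are in the pedigree, gender
homophily, the informant's perception of the member's health behaviours),
informant-level attributes (gender, obesity status), and residual noise.

## Model

The unit of analysis is the dyad $(i, j)$: informant $i$'s report $y_{ij}$ on
family member $j$.

$$
\begin{aligned}
y_{ij} &\sim \mathrm{Bernoulli}(\theta_{ij}), &
\operatorname{logit}(\theta_{ij}) &= \eta_{ij}
  = X_{ij}\beta + W_i b_{g(ij)} + \varepsilon_{ij},\\
\varepsilon_{ij} &\sim N(0, \sigma^2), &
b_c &\sim N_q(0, D),\\
\beta &\sim N_p(b, B^{-1}), &
\sigma^2 &\sim \mathrm{InvGamma}(\nu, \delta), \qquad
D \sim \mathrm{InvWishart}(\psi, \rho),\ \rho \ge q .
\end{aligned}
$$

$X_{ij}$ is the level-1 (dyadic) design with a leading intercept column —
the intercept is folded into $\beta$ so the whole fixed-effect block has one
conjugate update. $W_i$ is the level-2 design (leading 1 for a random
intercept, optionally informant attributes as random coefficients), and
$g(ij)$ maps the row to its cluster. Two clusterings are supported:
**informant level-2** (one $b_c$ per informant; within-informant covariance)
and **family level-2** (one $b_c$ per family; within- and between-informant
covariance). $\varepsilon_{ij}$ is a per-observation over-dispersion term on
the logit scale. The **null** baseline drops the hierarchy entirely:
an intercept-only logistic regression with constant $\theta$.

### Informative prevalence prior

Population prevalence enters through the intercept prior: prevalence $\pi$
maps to prior mean $\operatorname{logit}(\pi)$ with variance 100 (wide but
finite). The default $\pi = 0.12$ — a background rate appropriate for type 2
diabetes in the United States — gives prior mean $-1.99$. Non-intercept
effects get variance $10^6$: effectively flat on the logit scale while
keeping the conjugate normal update proper. Level-2 covariance priors default
to $\rho = q$, $\psi = q I_q$ (the vaguest proper inverse-Wishart at that
dimension), and $\nu = \delta = 0.001$ for $\sigma^2$.

### Over-dispersion is fixed to 1 by default

With a single Bernoulli trial per row, $\sigma^2$ is not identified by the
likelihood: each latent $\eta_{ij}$ can drift toward $\pm\infty$ to match its
own outcome, so under a vague prior the $\sigma^2$ chain wanders upward
(observed: $\sigma^2 \approx 545$ after 25,000 iterations at $N \approx
2{,}200$) and inflates the fixed-effect scale with it. The default therefore
fixes $\sigma^2 = 1$ — the standard practice for Bernoulli outcomes in this
model family — and `ModelSpec.estimate_sigma2=True` re-enables sampling for
binomial-like settings where it is identified.

## Sampling

A Metropolis-within-Gibbs scheme over $(\{\eta_{ij}\}, \beta, \{b_c\}, D,
\sigma^2)$:

1. **Latent logits** $\eta_{ij}$: independent random-walk Metropolis, one
   proposal standard deviation per observation, all observations updated in
   one vectorized sweep (valid because they are conditionally independent
   given the rest). The target is
   $p(\eta_{ij} \mid y_{ij}, \cdot) \propto
   \mathrm{Bern}(y_{ij}; \operatorname{expit}(\eta_{ij}))\,
   N(\eta_{ij}; X\beta + W b, \sigma^2)$.
2. **Conditional on $\eta$** the rest is an ordinary linear-Gaussian
   hierarchy with $\eta$ as response, so $\beta$, each $b_c$ (batched
   Cholesky solves across clusters), $D$ (inverse-Wishart via Bartlett
   decomposition) and $\sigma^2$ (inverse-gamma) are exact conjugate draws.

**Adaptation.** Proposal scales follow a Robbins–Monro recursion
$\log s_{ij} \mathrel{+}= t^{-0.55}(a_{ij} - 0.45)$ during burn-in only
($a_{ij}$ the 0/1 acceptance), frozen afterwards so the sampling-phase chain
is a valid fixed-kernel Markov chain. The realized sampling-phase acceptance
lands at ~45%.

**Run configuration.** Defaults: 5,000-iteration burn-in, 20,000 sampling
iterations, thin 2 — a retained sample of $S = 10{,}000$. Initialization is
deterministic and prior-consistent ($\beta$ at its prior mean, $b = 0$,
$D = \psi/\rho$, $\sigma^2 = 1$, $\varepsilon = 0$); a fixed seed gives
bitwise-identical draws. Single chain; convergence is monitored through the
acceptance-rate contract and the oracle-equivalence tests rather than
multi-chain diagnostics.

**Determinism and ordering.** `build_design` sorts rows canonically by
(family, member, informant) and codes clusters by first appearance, and the
sampler re-canonicalizes cluster codes internally. Consequently permuting
input rows, or relabelling clusters, leaves fixed-seed posteriors bitwise
unchanged (up to the matching permutation of the returned $b$ array).

## Posterior summaries

- **Dyad probabilities.** `theta` in the draws is
  $\operatorname{expit}(\eta_{ij})$ — conditioned on each row's own
  $\varepsilon$ draw. `dyad_marginal_scores` averages
  $\operatorname{expit}(X\beta + Wb)$ instead, excluding $\varepsilon$.
  The conditioned version partially memorizes the observed report, so
  model-comparison AUCs use the marginal score; risk aggregation uses the
  posterior-predictive `theta`, which is what carries the reports' evidence
  about the member.
- **Individual risk.** A member's risk is the equally weighted mean of their
  dyads' posterior probabilities (each informant's report counts once).
  Credible bounds: average theta across the member's rows *within* each
  draw, then take 2.5%/97.5% quantiles of that per-draw series. Because
  finite sums commute, the point estimate is identical under either
  averaging order.
- **DIC** $= \bar{D} + \tfrac12 \operatorname{Var}(D)$ over the retained
  deviance draws (sample variance, $S-1$ denominator); the variance term is
  the model-complexity penalty. Deviance is evaluated at the draw-level
  theta (fully conditioned likelihood); $\theta$ is clamped to
  $[10^{-12}, 1-10^{-12}]$ so the deviance stays finite in floating point.
- **Parameter count** reported as $p + Cq + q(q+1)/2 + \mathbf{1}\{\sigma^2
  \text{ estimated}\}$ — an explicit bookkeeping convention, not an
  effective-parameter estimate.
- **AUC** is the Mann–Whitney probability with ties counted ½ (trapezoidal
  area under the tie-grouped ROC); computed dyadically (scores vs observed
  reports), individually (aggregated risk vs a reference status), and
  stratified by family with single-class families skipped. AUC > 0.70 is
  flagged as clinically relevant — an annotation only. On synthetic data the
  individual-level reference label is the simulated true status; on real
  data the default reference is the member's self-report when available,
  else the majority vote of informant reports with ties resolved positive.

## Synthetic data generator

`simulate` emulates the structure of a multi-family MIFHH study: 45 families
by default; informants per family drawn from {2,…,5} with weights
(0.45, 0.35, 0.15, 0.05) — mean 2.8; 6–14 enumerated members per family;
every informant reports on every member of their family (self-reports with
degree 0, other degrees uniform on {1, 2}); binary covariates Bernoulli(0.5)
with member behaviours shared across that member's informants; background
prevalence 0.12.

- *model_faithful* mode draws reports exactly from the hierarchical model
  above (informant- or family-level $b$, selectable) and is the basis of the
  parameter-recovery checks. The dyadic model defines no member-level truth,
  so truth is defined as a Bernoulli draw from the member-level predictor
  (intercept + behaviour covariates); reports and truth are coupled only
  through those shared covariates.
- *misreporting* mode draws truth at the background prevalence and corrupts
  it per report with sensitivity/specificity (defaults 0.75/0.75, inside the
  53–87% range reported for self-reported diabetes FHH). Two reports on the
  same member then agree with probability
  $\pi(se^2 + (1-se)^2) + (1-\pi)(sp^2 + (1-sp)^2)$ — 0.625 at the defaults,
  matching the ~60% inter-informant congruence typical of such data.
  Missingness is $\text{base} + \text{degree} \times \text{increment}$,
  increasing with pedigree distance.

What the generator does **not** emulate: real pedigree topology (mating and
generation structure), informant-specific reporting biases correlated with
their own covariates, age-at-onset, non-random missingness beyond the degree
gradient, and within-family covariate correlation. Passing recovery and
ranking tests on this generator therefore demonstrates correctness of the
estimator under its own assumptions, not robustness to everything real MIFHH
data can do.

## Problem sizes used in the test suite

The validation suite runs at sizes chosen to make the checks sharp but
cheap: oracle equivalence at $N \le 8$ with the full retained sample of
10,000; the acceptance-rate contract on a ~2,000-dyad dataset at the full
default configuration; frequentist coverage over 100 replicate fits at
$N \approx 2{,}000$, $C = 45$ family clusters with shortened chains
(400 burn-in + 800 retained — quantile Monte-Carlo error at that length is
well inside the binomial tolerance band); model-ranking checks at 45
families with 1,000 + 3,000 iterations.

## Known limitations

- Single-informant families contribute to $\beta$ but leave their cluster
  effect prior-dominated; with $C = 1$ the level-2 covariance is weakly
  identified (the sampler warns).
- The latent-logit Metropolis step mixes slowly when $|\eta|$ is large
  (near-deterministic dyads); the adaptive scales compensate but extreme
  separation inflates autocorrelation.
- DIC on the fully conditioned likelihood penalizes latent-variable models
  heavily; comparisons across clusterings should also weigh AUC, as the
  intended workflow does.
- Equal-weight aggregation is deliberate: informant-reliability weighting is
  out of scope.
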