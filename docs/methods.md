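# Methods

`deerpop` implements a Bayesian hierarchical state-space model of
stage-structured ungulate population dynamics, fitted to annual
distance-sampling density estimates and sex/age classification counts
from a network of parks, together with the downstream machinery a
manager needs: goodness-of-fit checking, growth-rate eigenanalysis, and
posterior-predictive forecasting of culling and fertility-control
regimes.

## Process model

The population of park *i* is censused once per year, six months after
the birth pulse, in three stages: juveniles of both sexes (n1), adult
females (n2), and adult males (n3).  The deterministic skeleton is a
Lefkovitch projection

```
A(D) = [ 0          s2·f(D)   0  ]
       [ s1·m       s2        0  ]
       [ s1·(1−m)   0         s3 ]
```

where s1, s2, s3 are annual survival probabilities (harvest mortality
folded in, applied once per annual step), m is the juvenile sex ratio
(share of surviving juveniles recruiting as females), and f(D) is
density-dependent fecundity — fawns per doe surviving to census — as a
function of total deer density D (all stages summed over park area).

Two fecundity forms are supported (`fecundity_form` in all entry
points):

* `ricker_exp` (default): `f(D) = exp(r_f − (r_f/K_f)·D)`; equals 1 at
  D = K_f and exp(r_f) at zero density.
* `scaled`: `f(D) = r_f · exp(−(r_f/K_f)·D)`; r_f is itself the maximum
  number of fawns per doe.

Both are positive and strictly decreasing in density, and both have
log-fecundity linear in D, with the same scaled slope r_f/K_f but
intercepts r_f versus log r_f.  The forms are not reconcilable — under
the first, "maximum fecundity" is exp(r_f); under the second it is r_f
— and published parameter estimates for this system (maximum fecundity
≈ 0.86 fawns/doe, no-action growth rate ≈ 0.99) are on the scale of the
second.  We therefore fit with whichever form the configuration names,
record it in every output, and evaluate growth-rate linearizations at
maximum fecundity f₀ = r_f (see Eigenanalysis) so that λ is comparable
across forms.

Stochasticity enters as lognormal process noise: the true state is
`exp(z)` with `z ~ Normal(log(A·n_{t−1}), σ_p²·I)`, a single process
variance shared by all stages and parks.  Deterministic stage means are
floored at 10⁻⁶ before the log so that extreme culls cannot produce
log(0); the floor is orders of magnitude below one animal and has no
practical effect.

### Treatments

Model experiments add a fourth stage of sterilized/contracepted females
(n2s) that survive at s2 with zero fecundity.  The treatment event acts
immediately after census, before projection:

* **cull** removes the proportion p of *all* adult females (fertile and
  treated alike);
* **sterilize / contracept** transfer p of the currently fertile
  females into the treated stage (previously treated animals are
  assumed identifiable and are not re-handled).

One-year contraceptives revert fully after each year (surviving treated
does re-enter the fertile stage at rate s2); three-year-average
contraceptives revert geometrically with annual probability 1/3 (mean
effective duration 3 years); sterilization is absorbing.  Fawns and
males are never treated.  Fecundity in a treated year uses the
post-treatment density, since treatment precedes projection.  Treated
and fertile does are pooled in the classification proportions, because
field observers cannot distinguish them.

## Data model

Two observation streams per park-year:

* classification counts y_α = (juveniles, does, bucks) ~
  multinomial(y_N, π) with π the latent stage proportions ("unknown"
  classifications are excluded from both y_α and y_N);
* the density estimate y_d ~ Normal(Σ_j n_j / area, σ̂²), with σ̂ the
  standard error reported by the upstream distance-sampling analysis,
  treated as a known plug-in constant.

Initial conditions are parameters with an empirical year-1 prior: stage
proportions γ ~ Dirichlet(y_α,1 + 1), density d ~ Normal(y_d,1, σ̂₁²)
truncated below at zero, and n₁ = d·γ·area.  Because year-1 data build
this prior, the likelihood terms run over years 2..T only — using the
same observations in both places would count them twice.  The
posterior-predictive discrepancy sums run over the same likelihood
cells.  Missing park-years contribute nothing to the likelihood; the
latent process still propagates through them.

## Priors

* Park-level survivals s_ij ~ beta(a_j, b_j) per stage class j, with
  gamma hyperpriors on (a_j, b_j).  The hyperpriors are centred by
  moment matching on literature summaries of published annual survival
  (juvenile 0.67 ± 0.20, female 0.74 ± 0.14, male 0.39 ± 0.19) and have
  coefficient of variation `hyper_cv` = 0.25 by default.  Larger
  dispersions (0.5 and up) leave appreciable hyperprior mass near
  b_j = 0, where the beta density develops an unbounded spike at
  survival = 1; chains fall into that spike and report biologically
  absurd survival pinned at the boundary.  CV 0.25 keeps the hierarchy
  proper in practice while leaving the park-level distribution wide.
* Sex ratio m ~ beta(312, 312) — moment-matched to mean 0.5, SD 0.02 —
  encoding near-certain 1:1 recruitment (no preferential harvest in the
  first year).
* r_f ~ Normal(2·3.09·w^(−0.33), sd²) with w = 65 kg body mass: the
  allometric birth-rate scaling for Artiodactyla, doubled because the
  regression predicts offspring per individual.  The default prior SD
  is 2.5 (weakly informative).  The allometric regression's residual
  standard error, 0.1304, is exposed by `rf_prior()` and accepted via
  config, but it measures in-sample regression scatter, not honest
  prior uncertainty about the fecundity of a particular population with
  neonatal survival folded in; used as a prior SD it is sharp enough to
  override classification data that measure fawn:doe ratios directly.
* K_f ~ Uniform(1, 100) deer/km² and σ_p ~ Uniform(0, 2) on the
  log-scale SD: weakly informative over ecologically plausible ranges.

## Posterior sampling

An adaptive Metropolis-within-Gibbs sampler, fully vectorized across
parks:

* latent log-abundance 3-vectors update per park-year with Gaussian
  random-walk proposals on a checkerboard schedule over years (states
  interact only with temporal neighbours, so alternate-year blocks are
  conditionally independent and update in parallel);
* park survivals update in parallel across parks, one class at a time;
* (a_j, b_j) update jointly per class on the log scale;
* the global scalars move twice: coordinate-wise on transformed scales
  (logit for probabilities, log for r_f, scaled-logit for K_f and σ_p),
  and through a 7-dimensional joint Metropolis block over (m, r_f, K_f,
  σ_p, and one common logit-shift per survival class) whose proposal
  covariance is the running empirical covariance of those coordinates.
  Each survival-class shift re-centres the beta hyper-distribution —
  a_j, b_j move so their mean tracks the parks while the concentration
  stays fixed — so the hierarchical prior cannot veto coordinated
  moves.  r_f and K_f are the intercept and scaled slope of
  log-fecundity and are strongly correlated; this block is what lets
  chains traverse that ridge.
* initial conditions (d₁, γ₁) update jointly per park (log density +
  additive log-ratio proportions).

Proposal scales adapt by Robbins–Monro toward acceptance 0.44 (scalar)
or 0.30 (vector blocks) during burn-in only; the post-burn-in kernel is
fixed.  Default run lengths are 3 chains × 40,000 retained draws after
8,000 burn-in; the test-suite and acceptance runs use 3 × 2,000–3,000
after 1,000–1,500, which the simulation study below shows is enough for
R-hat ≤ 1.05 on the scalar parameters.  Convergence is summarized with
rank-normalized split R-hat and autocorrelation-based bulk ESS.
Identical seeds give bit-identical draws.

## Model checking

Posterior predictive checks use the squared-error discrepancy on
density: per retained draw, T_obs = Σ (y_d − μ)² with μ the draw's
predicted density, and T_rep the same statistic on replicated
observations y_rep ~ Normal(μ, σ̂²).  The Bayesian P-value
P_B = Pr(T_rep ≥ T_obs) flags lack of fit near 0 or 1.  On
well-specified synthetic data P_B falls in (0.05, 0.95) in ≥ 90% of
replicate fits; tripling all observed densities drives it below 0.05.

## Eigenanalysis

The asymptotic growth rate λ of a regime is the dominant eigenvalue of
the annual projection matrix linearized at zero density (maximum
fecundity, f₀ = r_f), computed per posterior draw from that draw's
across-park mean vital rates, so λ carries a full posterior.  Because
fecundity only declines with density, this λ upper-bounds realized
growth at any positive density.  Treatments fold into the annual matrix
as projection-after-treatment, `A₄ @ C`.  Sensitivities ∂λ/∂a_kl come
from the left/right eigenvectors (v_k w_l / ⟨v, w⟩); at the regional
point estimates the largest sensitivity involves adult female survival.

One structural caveat, documented rather than hidden: with a 3-stage
matrix in which culling scales only the female columns, the spectral
radius cannot fall below adult male survival s3 (~0.45), because males
persist regardless of female removal.  The decline rate of the
reproductive core under aggressive culling is therefore also reported
as the dominant eigenvalue of the juvenile/female submatrix (~0.19 for
a 90% annual cull at the default rates).

## Forecasting and decision metrics

Forecasts propagate every retained posterior draw forward from the
final-year latent state: treatment event, density-dependent projection
with that draw's park-level rates, lognormal process noise.  The
resulting ensemble is the posterior predictive process distribution.
Decision metrics:

* **objective probabilities** — fractions of draws whose pooled
  regional density (total abundance / total area; per-park evaluation
  available) falls below/within/above a management band, by default
  5–15 deer/km² evaluated 5 years out; boundaries count as within, and
  the three probabilities sum to one exactly;
* **net effect** — the ratio of the within-band probability under a
  treatment to that under no action;
* **treatment effort** — median cumulative number of does handled
  (culled does count fertile + previously treated; sterilization and
  contraception count newly treated fertile does only);
* **program cost** — effort times per-doe unit costs, defaulting to
  $370 (culling) and $750 (fertility control).

## Synthetic data

The generator emulates the regional survey: 8 parks (areas 2.5–50 km²)
observed 13 consecutive years; park survivals drawn around the class
means with between-park SD 0.05 (mirroring the fitted hierarchy); true
vital rates defaulting to the regional estimates s1 = 0.75, s2 = 0.67,
s3 = 0.45, m = 0.53, r_f = 0.86, K_f = 27.12, σ_p² = 0.50; initial
densities 30–70 deer/km² apportioned by the stable stage distribution;
density estimates with CV 10–20% (negatives resampled, a documented
truncation of the pure normal model); classification totals 100–500 per
park-year.  Under these defaults the simulated region declines gently
(median annual growth ≈ 0.93), matching the system the model was built
for.  What the generator does *not* emulate: distance-sampling
detection (only its plug-in summaries), immigration/emigration between
parks, age structure within the adult stages, and observer
misclassification.  Passing recovery tests therefore demonstrate that
the estimator inverts its own data-generating process at realistic
noise levels — not that the model is correct for any particular real
survey.

## Numerical choices and degenerate inputs

Stage means are floored at 10⁻⁶ before logs; proposals that underflow
onto a support boundary are rejected outright; an empty sterile stage
stays exactly empty under process noise (noise cannot create sterile
does); zero-total classification rows contribute zero log-likelihood;
boundary densities count as within the objective band (deterministic
tie-break of negligible measure); the net effect of a zero no-action
probability is reported as infinite with a warning rather than raising.
Dominant eigenvalues use the spectral radius (real for these
non-negative matrices); sensitivity computation refuses defective or
non-simple dominant eigenvalues.

## Known limitations

* The sampler is a random-walk scheme; posteriors with severe funnels
  (very small hyper_cv ceilings, or boundary-hugging survivals) mix
  slowly, and roughly one replicate in ten at the reduced test run
  lengths shows a scalar R-hat slightly above 1.05.
* σ̂ is a plug-in: uncertainty in the upstream density SEs is ignored.
* Male survival is weakly identified (males enter only through
  classification proportions), and its posterior leans on the
  literature-centred hyperprior.
* Forecast treated counts are expected values of the treatment operator
  (p·females), not binomial realizations; for large herds the
  difference is negligible.
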