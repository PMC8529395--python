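# Methods

## Task model

The simulator encodes a two-choice probabilistic learning task played for
three beneficiaries (Self, an unknown Other, No One). The default
configuration is 3 runs × 1 block per condition per run × 16 trials per
block (144 trials, 48 per condition), reward contingencies 0.75/0.25 with
point outcomes +1/−1, and a €0.25/point conversion clamped to [€1, €12]
for the paid conditions. Two modeling-relevant conventions are fixed here
because the design description leaves them open:

* **Reinforcement schedule.** Outcomes are i.i.d. Bernoulli(p) per trial,
  not an exact 12/16-per-block ratio — the simplest process consistent
  with stated probabilities. Realized per-block reward rates therefore
  vary binomially.
* **Counterbalancing.** Condition order within runs follows a seeded 3 × 3
  Latin square (cyclic shifts of a random permutation, rows shuffled);
  across agents the seed varies, which counterbalances order between
  participants in expectation.

Onset times (instruction 2 s; response window 2.5 s; selection frame
+0.5 s; fixation jitter U(1, 2) s before the outcome; outcome 1 s; ITI
jitter U(1, 8) s) exist only so event-file export is realistic; no
computation depends on them. Missed trials arise only from an explicit
per-agent miss probability (default 0), carry no choice, outcome, value
update, or trajectory row, and are excluded from every analysis
denominator.

## Learning model

Values are tracked per picture pair, initialized at q0 = 0 (the symmetric
midpoint of the ±1 outcome range) at every block start, never carried
across blocks or conditions. Only the chosen option updates:
`Q ← Q + α(R − Q)`. Choice probabilities are softmax with inverse
temperature β, computed with max-shifting so extreme β cannot overflow.
β may be negative (value-avoidant choice); β = 0 is random choice.

The two-learning-rate variant gates α on **outcome valence** (gain rate
after +1, loss rate after −1), not PE sign. With q ∈ [−1, 1] the two
conventions coincide except exactly at |q| = 1; fixing one makes the
variant well defined.

## Fitting

Each agent × condition is fitted independently by MAP. Priors:
Beta(1.2, 1.2) on every learning rate; Gaussian with location 0 and
**standard deviation** 10 on β (the scale parameter is interpreted as an
SD; weakly informative over the plausible β range). Optimization is
L-BFGS-B in natural parameter space with box bounds α ∈ (1e−6, 1−1e−6),
β ∈ (−100, 100), objective tolerance 1e−10, and 10 multi-starts (α starts
drawn from the prior, β starts from a dispersed anchor grid
{0, ±2, ±5, 1, 3, 10, ±20}). The best start wins; `converged` is False
only if every start fails. The sequential likelihood replay is compiled
with numba (a pure-Python fallback of the identical code runs if numba is
unavailable; tests assert agreement between the two and against an
independent trajectory replay).

With zero usable trials the fit returns the analytic prior modes
(α = 0.5, β = 0) and flags itself prior-only; BIC is then NaN.

**BIC** uses the log-likelihood evaluated at the MAP point with
n = number of non-missed trials — the common convention when the prior is
used only to regularize. At 48 trials the *unregularized* likelihood can
ridge toward extreme β with tiny α; this is precisely what the priors
suppress, and the test suite demonstrates both the ridge (flat-prior MAP
needs 480 trials to match an interior grid MLE) and the regularized
fit's agreement with an exhaustive 101 × 201 posterior grid. Ties in the
one- vs two-rate comparison go to the simpler model.

## Parameter recovery

The default recovery design mirrors the study's validation: one simulated
session per agent for 74 agents, with fitted (or sampled) per-condition
one-rate parameters as ground truth, refit with the same pipeline, and
Pearson/Spearman correlation, mean signed error, and RMSE per condition ×
parameter. A constant truth vector yields NaN correlations with a
warning, not an exception. Two known limits are documented by tests
rather than hidden: recovery sharpens with tenfold trial counts, and
under β = 0 truth α is unrecoverable (choices carry no value signal).

## Synthetic cohort

The generator emulates the *qualitative* behavioral effect structure of a
9–21-year-old cohort of 74; reported mixed-model coefficients on scaled
metrics do not pin down a generative model, so effect sizes are free
parameters in `CohortSpec`, set once:

* ages uniform on [9.03, 21.77]; z-age standardized by the uniform's own
  moments so an agent's parameters depend only on their age;
* learning rates on the log-odds scale,
  α = inv_logit(intercept + slope·z_age + N(0, 0.30)), with intercepts
  (Self −0.10, Other 0.70, No One 0.10) and slopes per SD of age
  (Self −0.30, Other −1.05, No One −0.04): mean α lowest for Self, the
  age decline steepest for Other and absent for No One;
* β = 4.0 + 0.6·z_age + N(0, 0.7): all agents value-driven, older ones
  more so;
* empathy on the 0–4 Likert-mean scale via a Gaussian copula with age
  (target r = 0.309, sample mean across replicate cohorts ≈ 0.29), plus
  an optional negative contribution of age-independent empathy variation
  to the Other-condition α (−0.35 logit units/SD; set
  `empathy_alpha_weight=0` to disable).

The intercept/slope choice is anchored to the simulated accuracy surface:
for 16-trial blocks at β ≈ 3–5, accuracy peaks near α ≈ 0.3–0.5 and falls
for higher α. Young agents in the Other condition start above that
optimum (α ≈ 0.85+), so the steeper Other α decline also produces the
larger age-related performance gain in that condition — the directional
interaction the cohort is meant to exhibit — while keeping every
condition's group performance well above chance.

What the generator does **not** emulate: real age distributions (uniform,
not the study's per-age counts), reaction times, IQ/sex structure,
quadratic age effects, within-agent parameter drift, or any neural
quantity. Passing tests therefore show that the pipeline recovers effects
of this kind and size from this task design — not that any specific
empirical coefficient is reproduced.

## Behavioral statistics

"Correct" is choosing the high-contingency picture, regardless of the
realized outcome. Learning curves average the correct indicator per trial
position across blocks within agent, then report mean and SEM across
agents. Above-chance tests are one-sample t-tests of per-agent accuracy
against 0.5 (df = n−1; zero-variance samples return ±∞ with a flag).
Partial Spearman correlations rank-transform all variables, residualize
the x- and y-ranks on covariate ranks by least squares, and correlate the
residuals; p-values use the t-approximation with df = n−2−(#covariates).
A variable perfectly explained by its covariates is returned as
(0, 1) with a warning. Mixed-model fits (GLMM/robust LMM) are left to
dedicated tools; this module produces the tidy tables they consume.

## Event files

Each non-missed trial yields two zero-duration events — decision
(modulator EV = the chosen option's pre-outcome value) and outcome
(modulator PE) — replayed under the agent's own fitted per-condition
parameters; missed trials yield one unmodulated row for a
regressor-of-no-interest. Files follow the BIDS events-TSV dialect
(onset/duration first, tab-separated, onsets at 4 decimals, `n/a` for
missing). Modulators are exported raw; per-run mean-centering is
available behind a flag since downstream GLM packages differ on it.

## Problem sizes and determinism

Every stochastic step is seeded (numpy Generator/SeedSequence; derived
seeds stay below 2³¹) and bit-reproducible. Suite-level simulation sizes
— 200 sessions for chance-level calibration, 10 agents for the grid
oracle, 74 agents for recovery and model comparison at 48
trials/condition, 12 agents × 4800 trials for the large-n two-rate
identifiability check, 20 replicate cohorts for the effect-structure
check — were chosen as the smallest designs that make the corresponding
property statistically unambiguous.
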