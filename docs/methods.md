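# Methods

## Densitometry normalization

Each autoradiograph carries four standards (15, 30, 45, 60 µg total
protein). An ordinary least-squares line of optical density on µg is
fitted per gel; the line's value at 30 µg defines one unit, and a sample
band's *relative amount* is its OD divided by that value. Using the fitted
value rather than the raw 30 µg band averages measurement error across all
four standards. The intercept is estimated by default — only linearity,
not proportionality, is assumed of film response — with a through-origin
option. Relative amounts are exactly invariant under multiplication of all
ODs on a gel by any positive constant (per-gel gain cancels). Gels whose
standard curve has r² below 0.95 (configurable) are excluded and logged.
Background subtraction and saturation correction are out of scope: ODs
arrive as numbers.

## Batch structure and standardization

Chicks are nested in hatch batches (up to three trained plus one untrained
control per batch). Batch effects are handled twice, in two different
roles:

* **Summaries and variance tests** use the *standardized relative amount*:
  each value minus (its batch mean − overall mean). Batch means are
  computed from all chicks in the batch by default (`batch_mean_scope:
  all`); the untrained rows of the output are therefore batch-adjusted
  like the trained ones. A `trained_only` scope is available.
* **The regression** is fitted to *raw* relative amounts with a random
  batch intercept. Fitting to pre-standardized values would remove part of
  the score effect through the batch means and attenuate the slope; in
  simulation this costs ~30% of the slope and drops interval coverage to
  ~0.73, whereas the raw-amount mixed fit is unbiased (coverage 0.944,
  type-I error 0.060 at nominal 0.05; see the acceptance tests for the
  exact Monte-Carlo settings).

Because standardization preserves the overall mean, the fixed effects of
the raw-amount fit and the standardized summaries live on the same scale
and are directly comparable.

## The mixed-effects fit

For each region × hemisphere × measure, trained chicks' amounts follow

    y_ij = α + β·score_ij + u_j + ε_ij,  u_j ~ N(0, σ_b²), ε_ij ~ N(0, σ²)

estimated by REML (ML optional). With one observation per chick the
chick-within-batch term is unidentifiable and is absorbed into the
residual; replicate rows (optional `replicate_id`) re-enable it as a
variance component, delegated to statsmodels' general mixed-model
machinery. The singleton model is fitted in-package by profiling the REML
criterion down to a 1-D search in λ = σ_b²/σ²: for fixed λ the GLS
estimates of (α, β) and σ² are closed-form, and the block structure makes
each evaluation O(n). The search uses a log-spaced grid (including exactly
λ = 0) refined by bounded minimization; variances pinned at the boundary
are reported as 0 with a log note. The fixed-effects covariance is the GLS
form (X'V⁻¹X)⁻¹ at the fitted components — the quantity classical
mixed-model software reports, and well-defined on the boundary. The fit
agrees with R's `nlme::lme` to ~1e-8 and with statsmodels MixedLM to ~1e-5
on test instances (both serve as independent cross-checks in the suite,
never as the implementation).

Numerical choices: data with exactly zero residual sum of squares
(noiseless synthetic fixtures) short-circuit to the exact line with all
variances and SEs zero; a single batch degenerates to OLS with σ_b² = 0.

### Degrees of freedom

Slope inference uses df = n_chicks − n_batches − 1 (10 for 21 chicks in 10
batches; 9 for 19 in 9), the denominator df convention of `nlme::lme` for
a within-batch fixed effect, and the same df is used for the residual
variance in the F test. With the approach covariates added the denominator
becomes n_chicks − n_batches − 3.

### Derived statistics

* correlation: r = sign(β̂)·√(t²/(t²+df)) with t = β̂/se(β̂) — a
  within-batch partial correlation whose p equals the slope's t-test p
  exactly, keeping every printed (r, df, p) triple internally consistent.
* predicted level at score s: α̂ + β̂s with
  se² = se_α² + s²·se_β² + 2s·cov(α̂, β̂); df as above.
* untrained group: mean, sem = sd/√n, df = n − 1 of the standardized
  values.

## Comparisons and variance tests

The predicted level at a score and the untrained mean are two estimates
with separate SEs and dfs, compared by a Welch two-sample t with
Satterthwaite df = (se_A²+se_B²)²/(se_A⁴/df_A + se_B⁴/df_B); the
fractional df always lies in [min(df_A, df_B), df_A+df_B]. The maximum
score defaults to the highest attained in the experiment (100 in the
study-sized presets); a fixed value is configurable.

The residual-variance criterion is one-tailed by design (only a
*reduction* below the untrained variance signals a predisposition):
p = P(F(df_untrained, df_residual) ≥ s²_untrained/s²_residual). The total
variance comparison (trained standardized amounts about their mean,
df = n−1, against untrained) is two-tailed. Tests are two-tailed at
α = 0.05 otherwise. No multiple-testing correction is applied across
measures (the output carries the per-measure test count, five, so users
can apply their own).

## Classification

Given a significant correlation: reduced residual variance with
homogeneous total variance ⇒ predisposition; non-reduced residual variance
with a displaced level at the maximum score ⇒ learning-dependent; a
displaced level at score 50 ⇒ training side-effect (assessable alongside a
learning verdict). All flags, including the side-effect, are gated on the
correlation; a non-significant correlation yields "no evidence", with
marginal findings (p < 0.1) reported in the notes, never as flags. In the
exactly-noiseless limit a perfect learning correlation is observationally
equivalent to a perfect predisposition (residual variance 0), and the
precedence rule classifies it as a predisposition; this degenerate
equivalence is inherent to the criteria, not to the implementation.

## Synthetic experiments

The generator reproduces the study design: 10 batches with (3,2,…,2)
trained chicks (21 total) plus one untrained control each for the 1 h
preset, 9 batches / 19 trained for the 24 h preset; baseline amount
μ0 = 1 relative unit; batch sd 0.10 and residual sd 0.10 (matching the
reported untrained SEMs of ~0.04–0.14 at n ≈ 10); preference scores
clamp(N(72, 22²), 0, 100), matching the reported group means of ~72 with
SEM ~4.9 at n = 21. Training and test approach distances are lognormal
with means near the reported 64 m and 13 m, and the two test approaches
are split exactly in the score's ratio, so every generated chick satisfies
the score-consistency invariant. Scenario effects: learning slope
β = 0.005 amount/score unit (sized so the amount–score correlation is
≈ 0.7 at the 1 h design); side-effect shift δ = 0.3; predisposition
aptitude sd 0.2 (twice the residual sd) with score gain 110 per aptitude
unit and score noise sd 5. Out-of-scenario effects are forced to zero
unless explicitly combined. Everything is deterministic given the seed.

What the generator does not emulate: non-Gaussian amount distributions,
saturating film response, unequal per-chick measurement precision,
correlations between measures within a chick (each run generates one
measure), and any mechanistic phosphorylation dynamics. Passing tests
therefore demonstrate the statistical machinery under the design's
idealized generative assumptions, not robustness to those violations.
Score clamping at 100 mildly attenuates tail effects; the floor applied to
keep generated amounts positive clips ~1e-5 of draws at default noise.

## Operating characteristics and problem sizes

`run_simulation_study` repeats generate → analyze → classify with child
seeds drawn from a master seed and reports flag rates with Monte-Carlo
standard errors √(p(1−p)/reps). The suite runs 2000 null replicates for
type-I error, 1000 learning replicates for slope recovery and interval
coverage, and 500 replicates per preset for classification rates — sizes
chosen to give binomial standard errors below ~0.011 while keeping the
full suite under a minute.

## Known limitations

The residual-variance criterion has intrinsically bounded power. With
aptitude-to-residual sd ratio k, the true untrained/residual variance
ratio is at most 1 + k², so at k = 2 the one-tailed F with dfs (9, 10) can
reject at most ~77% of the time even with perfect estimators — and batch
standardization with 3–4 chicks per batch shrinks the observed untrained
variance by roughly (1 − 1/m), lowering the realized rate to ~0.45 under
the default predisposition preset. Detecting predispositions reliably at
these sample sizes requires aptitude variation well above twice the
residual noise (the regime that strongly reduced ratios of ~0.1–0.2 correspond to). Runs in which the reduction is missed but the
extrapolated level at the maximum score is genuinely displaced are
classified learning-dependent: at small n the two hypotheses are only
partially separable. The framework also assumes the preference score is
measured without error attenuation and that batches are exchangeable; and
a pure side-effect (level shift with no correlation) is by construction
reported as "no evidence" rather than flagged, since all verdicts are
gated on a significant correlation.
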