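# Methods

This note documents the statistical procedure implemented in `keymood`, the
generative model behind its synthetic cohort, the numerical conventions, and
what the validation suite does and does not establish.

## Analysis model

Observations are subject-weeks. For each weekly clinician assessment at time
`t`, seven typing features are aggregated over the half-open window
`(t − 7 days, t]`:

| feature | definition | units |
|---|---|---|
| `avg_interkey_delay_s` | mean gap between consecutive within-session keypresses, pooled over sessions | s |
| `backspace_ratio` | backspace keypresses / keypresses | — |
| `autocorrect_rate` | autocorrect events / keypresses | — (may exceed 1; flagged, not clipped) |
| `circadian_similarity` | cosine between the week's 24-h keypress profile and the subject's whole-study profile | [0, 1] |
| `avg_accel_displacement` | mean of √(x²+y²+z²) over accelerometer samples in the window | m/s² |
| `avg_session_length_s` | mean of (last − first keypress time) per session | s |
| `session_count` | number of sessions in the window | — |

A *session* starts with a keypress at least 5 s after the previous keypress
and ends when 5 s elapse without one; the boundary rule is ≥, so a gap of
exactly 5 s splits. Autocorrect events are software events: they neither
start nor extend sessions and are excluded from all keypress denominators.
Interkey delays are computed within sessions only — the observed weekly mean
delay of well under a second is incompatible with including inter-session
gaps, and the session definition makes 5 s the natural censoring point.
Session length is last-minus-first keypress (no 5-s tail); a single-keypress
session has length 0. The circadian baseline pools the subject's entire
study period *including* the current week. Local clock hours use the UTC
offset recorded on each event; no daylight-saving normalization is applied.

Outcomes: raw HDRS-17 for depression; ln(YMRS + 1) for mania (raw YMRS is
right-skewed; the bias-corrected sample skewness statistic is provided to
check this on any cohort). Predictors are z-scaled by their pooled mean and
SD (ddof = 1) over the retained observations, so coefficients read as
outcome units per predictor SD. Missing feature values are handled by
pairwise deletion: a row is dropped only if the outcome or a predictor used
by that model is missing.

The primary model is a linear mixed model with a per-subject random
intercept, estimated by maximum likelihood (not REML):

    y_ij = β₀ + Σ_k β_k x_ijk + u_i + ε_ij,  u_i ~ N(0, σ_u²), ε_ij ~ N(0, σ_ε²)

ML is deliberate: the overall significance test is a likelihood-ratio test
against the intercept-plus-random-intercept null (models differing in fixed
effects are only comparable under ML), and the mixed-vs-OLS information
criterion comparison is only coherent when both likelihoods are full ML.
Parameter counts are explicit: k = (fixed coefficients incl. intercept) + 2
for the mixed model (two variance components), k = (fixed coefficients) + 1
for OLS; AIC = 2k − 2ℓ, BIC = k·ln n − 2ℓ.

Per-coefficient inference uses Wald chi-square tests ((β̂/SE)² on 1 df) and
symmetric normal intervals β̂ ± 1.96·SE for both model families. OLS
coefficient p-values use t-tests on n − p − 1 df. No multiple-testing
correction is applied to the seven coefficient tests; reports say so.

Variance explained for the mixed model follows the Nakagawa–Schielzeth
decomposition with σ_f² the *population* variance (divide by n) of the
fixed-effect linear predictor over the fitted observations:
marginal R² = σ_f²/(σ_f²+σ_u²+σ_ε²), conditional R² adds σ_u² to the
numerator. Always marginal ≤ conditional ≤ 1.

**Boundary fallback.** The ML estimate σ̂_u² can land exactly on the zero
boundary, where the mixed likelihood equals the OLS likelihood and AIC
penalizes the mixed model by exactly 2 for its unused parameter. The `auto`
model mode detects this (relative tolerance 1e-6 on the variance share) and
refits/report OLS, mirroring standard practice when the random effect
explains none of the variance. At truth σ_u² = 0 the boundary is hit for
roughly half of realizations (the MLE of a variance at the boundary behaves
as a half-normal); the equivalence is asserted on realizations that hit it.

**Fitting machinery.** statsmodels' `MixedLM` (ML) is the primary
optimizer, cross-checked in the test suite against R's lme4 on the same
data. Its Hessian-based variance step fails precisely at the σ̂_u² = 0
boundary; a closed-form fallback then takes over: for the single-ratio
random-intercept model, β and σ_ε² have closed-form GLS profiles given
λ = σ_u²/σ_ε² (per-group inverse I − λ/(1+λn_i)·J), leaving a 1-D profile
likelihood in λ that is maximized on a log grid with bounded refinement and
an explicit λ = 0 candidate. The two routes agree to ~1e-6 in log-likelihood
on interior optima.

## Synthetic cohort

The generator emulates the study design the analysis assumes: 9 subjects
followed for 8 weeks (defaults), ~10⁴ keypresses and ~10⁵ accelerometer
readings per subject-week, weekly HDRS-17 and YMRS ratings at the end of
each local week. A single global seed spawns one independent RNG substream
per subject, so adding subjects never perturbs existing streams and two runs
with the same seed are byte-identical.

Per subject-week, a latent mood deviation z ~ N(0,1) modulates the stream.
Each feature k is driven by its own component m_k = ρ·z + √(1−ρ²)·η_k
(η_k iid N(0,1), ρ = `mood_link_correlation`, default 0.5): with a single
shared z the seven weekly aggregates become numerically collinear (their
sampling noise is tiny at 10⁴ keypresses/week), which no real cohort
exhibits; ρ = 0.5 yields pairwise feature correlations around 0.2–0.5,
matching the moderate correlations implied by the study's separable
coefficient estimates.

Stream recipe: session count ~ Poisson(7 × sessions/day × e^(link·m));
session start hours sampled from a 24-bin circadian profile (default: quiet
overnight, midday plateau, evening peak), optionally mixed toward its 12-h
rotation in proportion to |m| to emulate diurnal disruption; keypresses per
session ~ 1 + Poisson(mean − 1); interkey delays lognormal (default mean
0.69 s) truncated below 5 s so generated sessions respect the session
definition by construction (delays are rounded to ms, so truncation is at
4.999 s); backspace and autocorrect probabilities logit-shifted by their m;
accelerometer magnitudes = gravity + link·m + N(0, σ_noise), directions
uniform on the sphere, sampled at 10 Hz over the union of the per-keystroke
5-s windows in a session (one physical sensor stream — per-keystroke
duplication would quintuple the weekly volume). A symmetric noise-SD change
would leave the weekly *mean* magnitude untouched, which is why the mood
link enters the accelerometer model as a mean shift.

Outcomes are generated **from the realized features**: the streams are run
through the production feature extractor, z-scaled across the cohort, and

    score = intercept + Σ β_k · x_k(scaled) + u_i + ε

on the modeling scale (raw for HDRS; ln(YMRS+1) back-transformed for the
YMRS stream), then rounded and clipped to the scale range — the clinical
instruments are discrete and floored, and the published cohort indeed
touches the HDRS floor. `discretize_scores=False` disables rounding for
exact-recovery diagnostics. Default generative coefficients follow the
published coefficient pattern; for HDRS they are rescaled by ~0.71 so that,
with near-independent unit-variance features, the implied decomposition
reproduces the published outcome SD (6.29) and marginal/conditional R²
(.41/.63) — the published betas arose under correlated features, so pattern
and variance structure cannot both be kept verbatim under an independent
design, and the variance structure is what the validation properties rest
on. The YMRS stream uses the published OLS coefficients directly with a
zero random-intercept SD (the study's own finding) and residual SD 0.66.

What the generator does *not* emulate: typed content and language, app
context, screen geometry, device sharing, adherence gaps (no missing weeks
by default; missingness handling is exercised with fixture-induced gaps in
tests), autocorrelated mood trajectories (weekly z is iid), and
heavy-tailed accelerometer artifacts. Passing recovery tests therefore
demonstrate that the pipeline estimates what it claims under its own
assumptions — not that those assumptions hold in any clinical population.

## Numerical conventions and edge cases

- Timestamps: ms resolution, ISO-8601 with mandatory explicit UTC offset;
  duplicate (subject, ms) collisions are kept in stable file order and
  flagged in the log.
- Windows: half-open `(t − 7 d, t]`; a keypress exactly 7 days before the
  assessment is excluded, one exactly at the assessment instant included.
- Features needing ≥ 1 keypress (or ≥ 1 within-session pair for the delay)
  are NaN, never 0, when undefined; `session_count` stays 0.
- Cosine similarity is NaN when either profile is all-zero; values are
  clipped into [−1, 1] against rounding.
- Zero-SD predictors make model-side scaling fail loudly (naming the
  predictor); generation-side scaling maps such a column to all-zeros so
  degenerate configurations (e.g. `backspace_prob=0`) still simulate.
- LRT statistics are clamped at 0; the paired fits must have identical
  observation counts and nested parameter counts.
- Spearman correlation is reported via the classical S = Σd² statistic on
  midranks; ρ uses 1 − 6S/(n(n²−1)) when untied, Pearson-on-midranks with
  ties.

## Validation suite sizes

Problem sizes used by the acceptance tests, chosen to make each check
statistically meaningful: sessionization oracle on 1,000 random streams of
up to 10³ keypresses; circadian-similarity laws on 10⁴ random profile
pairs; parameter recovery on 200 replicates of the full default cohort
(coverage band [.90, .99], |bias| < 0.1 SD-units); boundary equivalence
scanned over 12 seeded zero-variance cohorts; LRT calibration on 500
replicates at 9 subjects × 32 weeks with a reduced stream volume — the
check concerns the model layer's asymptotic calibration (at 64 observations
and 7 numerator df the ML LRT is intrinsically anticonservative by the
usual F-vs-χ² finite-sample gap, independent of implementation), and 32
weeks is where the χ² reference is accurate.

## Known limitations

- Only random intercepts: no random slopes, no autoregressive residuals.
- Pairwise deletion, not multiple imputation.
- The Wald intervals use ML standard errors, which are mildly
  anticonservative at 64 observations (coverage ≈ .93 rather than .95 in
  the recovery experiment's regime).
- The circadian feature is scale-free by construction and cannot separate
  "less activity" from "differently timed activity".
- `autocorrect_rate` > 1 is possible in principle (more software events
  than keypresses in a window); rows are flagged, not altered.
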