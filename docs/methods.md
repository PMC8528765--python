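# Methods

This note documents the models behind `otrack`, the choices made where the
published descriptions leave the design open, and what the synthetic-data
tests do and do not demonstrate.

## Instruments and cut-offs

Scales are declared in a versioned catalog (`otrack/data/catalog.yaml`):
item membership, reversed items, aggregation, and cut-offs. Two scoring
conventions follow from the printed cut-off values: ASC subscales are item
**sums** (cut-offs 23–39 exceed the 1–5 item range), ASQ subscales are item
**means** (cut-offs 1.70–2.29 lie inside it). The HSCL-11 total is scored
as the item **mean** (range 0–3) so partial batteries remain on a common
scale; no published rule dictates sum vs mean here. Reversal on the 1–5
scales is `v → 6 − v`, an involution with fixed midpoint. A scale score is
valid only when strictly more than 80% of its items are observed; missing
items are then imputed with the mean of the observed items, which leaves
the mean of observed responses untouched by construction.

The ASC/ASQ item-to-subscale assignment and the reversed-item sets are not
published at the item-number level; the catalog uses a block layout
(TA = 1–11, SS = 12–22, MO = 23–31, LE = 32–40; concealing = 1–8,
tolerating = 9–13, adjusting = 14–20) with all life-events and all
concealing items reversed. Analyses in this package depend only on the
catalog's consistency, not on matching any particular printed questionnaire
ordering.

**Risk/suicidality** combines the session-wise HSCL suicidal-ideation item
(designated item 11; cut-off ≥ 2) with OQ-30 items 5 and 18 (cut-off ≥ 3),
observed at battery sessions and carried forward in between. The default
risk predictor for regression is the **severity count** (0–3 items at/above
cut-off) — the simplest monotone score; a binary any-item flag is available
via `RiskAssessment.flag`. The HSCL item alone drives the immediate
("red-bar") alert, independent of track status.

## Expected treatment response and the failure boundary

The boundary machinery assumes an archival pool of complete session-wise
HSCL courses. Per archival patient, an OLS slope of impairment on
`ln(session)` is stored; "improving" means a negative coefficient (falling
impairment), and only improving patients are eligible neighbors. Neighbor
distance is the root-mean-square difference over the query's observed
sessions from intake to the current session — scaling by the number of
shared sessions keeps early and late queries on one scale; candidates
missing any required session are excluded, and ties break on archival id.

The expected model on the `k` selected neighbors is a linear mixed model
with fixed effects `{1, ln s, T, ln s·T}` and a random intercept per
neighbor (statsmodels `MixedLM`, REML). Degenerate cases degrade
explicitly: a single shared `T` drops the `T` terms; a zero intercept
variance or non-convergence falls back to pooled OLS, with warnings.

The failure boundary at session `s` is a **new-patient prediction bound**,
not a mean-only confidence band:

    u(s) = ŷ(s) + z₀.₉₅ · sqrt( x'V̂x + σ̂²_patient + σ̂²_resid ),

with `z₀.₉₅ = Φ⁻¹(0.95) ≈ 1.645` (the upper limit of a two-sided 90%
interval). A mean-only band would shrink with neighbor count and flag
nearly everyone. The boundary is recomputed at every session from 6 to 30,
re-selecting neighbors on the history up to that session. The
total-sessions covariate for the index patient is their own (planned) count
when known, else the pool median (configurable).

Key tunables: `k` (default 50 — at an archival pool of ~1200 this balances
neighbor-set homogeneity against estimation variance; the original
system's exact neighbor features are not published, so everything is
configuration), the one-sided coverage level (default 0.95), and the
session window (default 6–30).

## Track status and reliable change

"Surpasses the boundary" is a strict inequality; ties stay on track. The
first crossing's impairment level anchors the return rule: a patient
returns on track only when the observation is below the boundary *and* the
improvement since that anchor is reliable, RCI ≥ 1.96 with the
Jacobson–Truax standard error of the difference
`S_diff = SD·√2·√(1 − α)` built from the archival intake SD and the
instrument's internal consistency (default α = .87). RCI magnitude grows
with reliability (less measurement error makes a fixed change more
credible); α = 1 is rejected as degenerate. For group analyses a patient is
NOT if *any* session in the window was NOT ("ever-NOT"); patients with
fewer than six sessions are excluded. Repeated NOT→OT→NOT toggling is
allowed and logged; the first-crossing anchor is not reset.

## Alerting

Six domains: risk/suicidality, motivation (ASC-MO), therapeutic alliance
(ASC-TA), life events (ASC-LE), social support (ASC-SS), and emotion
regulation — the OR of the three ASQ subscale crossings (the aggregation is
not published; OR is monotone and errs toward alerting). Orange requires
NOT status *and* a domain crossing; tool access mirrors the orange flag
exactly, and critical items accompany it. The session-six group comparison
pairs the battery administered at session five with session-six track
status (batteries run at intake and every fifth session).

## Multilevel logistic regression

The per-session NOT indicator is modeled with nested random intercepts
(sessions in patients in therapists). No maximum-likelihood GLMM with a
proper marginal likelihood (hence comparable AIC/BIC) exists in the Python
scientific stack, so `otrack.glmm` implements one: Gauss–Hermite quadrature
(15 nodes per level by default; simulation studies use 9–11 for speed)
integrates the random effects out, and L-BFGS-B maximises the marginal
likelihood with analytic posterior-weighted score gradients. Fixed-effect
Wald SEs come from the β-block Hessian at the estimated variance
parameters — the convention `lme4::glmer` reports, against which the
implementation is cross-checked in the test suite (log-likelihood, AIC and
coefficients agree to ~1e-3 on a shared fixture). Variance parameters are
optimised on the SD scale with a zero lower bound; a boundary estimate of
zero is legal (therapist variance often is). The level-2 ICC uses the
logistic level-1 variance π²/3. Complete separation is flagged when
coefficients or SEs explode.

Model building mirrors the staged procedure: empty model (1) vs time-only
model (2) by AIC; per-domain screens (time + domain, grand-mean-centred) at
a liberal p ≤ .10; the retained domains form model 3, compared with the
step-1 winner by AIC. When AIC and BIC disagree, AIC decides. Battery
scores carry forward between batteries so every session row has predictor
values. No multiple-testing correction is applied anywhere, by design.

Chi-square tests are Pearson's without continuity correction — verified to
reproduce the published session-six statistics exactly, where corrected
values would not. Item comparisons use Student (pooled-variance) t-tests
with pairwise deletion, consistent with the pooled-SD Cohen's *d*.

## Synthetic cohorts

The generator defines the study conditions: 413 patients under 65
therapists, an archival pool of 1234, a latent not-on-track prevalence of
140/413, batteries at sessions {1, 5, 10, …}. Latent impairment follows

    y = β₀ + u_ther + u_pat + (β₁ + u_slope)·ln s + β₂T + β₃ T·ln s + ε,

with defaults β₀ = 1.65, β₁ = −0.50, β₂ = 0.005, β₃ = 0.006 (typical
courses fall from ≈1.8 toward ≈1.0), SDs 0.10 / 0.45 / 0.15 / 0.15
(therapist / patient / slope / residual) and AR(1) residuals (ρ = 0.6).
Three structural features matter for realism: session residuals are
**autocorrelated** (symptom states persist — with iid residuals the 25
repeated boundary looks behave independently and almost every patient
eventually crosses); patients have **heterogeneous recovery rates** (the
random slope keeps matched neighbor sets honestly spread, which is what
gives the prediction interval its width); and the archival pool passes
through the **same item-discretization measurement process** as the cohort,
so the neighbor model's residual variance matches the noise of the scores
it bounds. No published variance components exist for these quantities;
they are free parameters of the generator, documented here.

Deterioration is an additive bump (default 0.8 HSCL units ≈ 4 residual
SDs — large enough that detection failures indicate implementation faults,
not noise) from an onset drawn uniformly in sessions 4–20, clamped into the
patient's observable window. Total sessions are truncated-normal per latent
group (means 24.09 / 32.07, SD 14.2, giving a standardized difference of
≈0.56). Battery distributions are calibrated so the latent groups differ
the way the session-six comparisons expect: on-track crossing rates of
roughly 27% (risk), 4% (motivation), 2.6% (alliance), 5% (life events),
9% (social support) and ~35–40% (emotion regulation), with the
not-on-track group shifted upward on risk, life events and social support.
Item-level responses discretize latent Gaussians (so reversal, imputation
and item cut-offs are exercised); `discretize_items=False` yields exact
continuous trajectories for numerical tests.

What the generator does **not** emulate: real diagnosis mixtures, dropout
mechanisms beyond treatment length, item-level factor structure beyond a
single latent per scale, floor effects in severely ill patients, or the
original archival pool's case mix. Consequently, passing tests demonstrate
that the pipeline is correct and well-calibrated *under its stated model*,
not that the boundary's real-world flagging rate is reproduced: with the
default generator the ever-flagged fraction is larger than the roughly
one-third typically reported, because the matching resolution and interval
mechanics of the original system are not published at that level of
detail.

## Numerical and testing choices

Simulation studies are sized to run on one CPU in minutes: parameter
recovery uses 100 replicates of 400 patients × 10 sessions; screening
calibration and the retention-pattern study use 50 seeds of 150 patients ×
8 sessions; end-to-end determinism uses a 30-patient cohort against a
150-course pool. Every random draw descends deterministically from one
seed (`numpy` `SeedSequence` spawning), and report CSVs are written with a
fixed float format so identical runs are byte-identical. Quadrature
accuracy at 9–15 nodes was checked against 25-node fits and `glmer`
(nAGQ = 25). Degenerate inputs (single-class outcomes, zero variances,
singleton samples, zero margins) raise or degrade explicitly rather than
silently.

## Known limitations

* The exact neighbor features, `k`, and interval mechanics of the original
  feedback system are unpublished; all are configuration, and absolute
  flagging rates should not be compared against deployed systems.
* The GLMM supports nested random intercepts only (no random slopes,
  no crossed designs) — sufficient for the staged analysis it serves.
* The reliable-change anchor is the first boundary crossing ever; systems
  that re-anchor after each return on track will classify borderline
  relapse patterns differently.
* Item texts and reflection prompts are placeholders; the package models
  decision logic, not questionnaire content.
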