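# Methods

## Measurement model

Two observers measure the smoking status of the same cohort of baseline
current smokers around the 12-month follow-up mailing:

* the **survey** measures 6-month *prolonged* abstinence: a responder is
  not abstinent if they report (i) smoking in the past 30 days, (ii)
  smoking on seven consecutive days during the past 6 months, or (iii)
  smoking on two consecutive weekends.  All three "no" → prolonged
  abstinence.  Any "yes" dominates missing items; a no/missing mix with no
  "yes" is indeterminate and excluded (the source procedure does not state
  a missing-data rule; this choice is recorded in the report metadata);
* the **EHR** contributes health-factor labels mapped through a curated
  vocabulary to smoker / quitter / smokeless-only / unclassified.  Matching
  is exact on uppercase-trimmed strings; a curated-substring mode exists
  but is off by default because substrings invite false hits ("NON-SMOKER"
  contains "SMOKER").  Smokeless-only users count as cigarette-abstinent,
  since the outcome is cigarette smoking.  Unclassified labels are treated
  as absent.

The analysis HF is the temporally closest classifiable record within
±`window` days (default 120) of the mailing date, bounds inclusive, with
deterministic tie rules: equidistant pairs resolve to the pre-mailing
record (the survey's recall period lies before mailing); same-day status
conflicts resolve smoker > quitter > smokeless-only, i.e. conservatively
against overstating cessation, with a logged warning.  Neither rule is
specified by the source procedure; both are package decisions surfaced in
the run metadata.

## Agreement statistics

On the both-sources group, with the survey as rows and "quit" the positive
class (cells a, b / c, d; n = a+b+c+d):

* percent agreement (a+d)/n;
* **Cohen's κ** = (p_o − p_e)/(1 − p_e).  The SE uses the Fleiss–Cohen–
  Everitt large-sample variance (the "agreement-weighted" form used by
  mainstream statistical software).  This choice is empirical as well as
  conventional: it reproduces every published κ confidence interval that
  the reconstructed tables imply, whereas the simpler
  √(p_o(1−p_o))/((1−p_e)√n) form (available as `se_method="cohen"`)
  reproduces only the full-sample one;
* **sensitivity** a/(a+b), **specificity** d/(c+d), **PPV** a/(a+c),
  **NPV** d/(b+d), each with a first-order Taylor (delta-method) SE for a
  ratio of multinomial count sums.  For X a cell and Y ⊇ X a margin, the
  multinomial moments collapse the usual three-term expansion to
  Var(X/Y) ≈ p_x(p_y − p_x)/(n p_y³).  The first-order approximation
  carries an O(1/(n·p_margin)) deficit relative to the exact resampling SD
  (≈0.25% relative on the full-sample table); the resampling oracle in
  `agreement.multinomial_se_oracle` quantifies this;
* **McNemar** χ² = (b−c)²/(b+c), 1 df, no continuity correction (variant
  unstated in the source; recorded in metadata), with (0, p=1) when
  b+c = 0;
* CIs are Wald (±1.96·SE), truncated to [0, 100] on the percent scale and
  [−1, 1] for κ.  No multiplicity adjustment is applied anywhere.

**Reconstruction from printed marginals.**  Published rows report n, %quit
by survey, %quit by HF, and the concordant-quit %.  Nearest-integer
rounding of n·pct/100 recovers a, the quit-row and quit-column totals, and
hence the full table.  For every row used in the acceptance checks the
recovered table reproduces the printed statistics at printed precision,
with three caveats that the replication module flags rather than hides:
the ±60-day row is internally inconsistent (its marginals imply
sensitivity 50.0 and agreement 89.8 against printed 49.0/89.6); one site's
printed κ (0.59) reconstructs to 0.578; and one printed marginal (10.7% of
620) has no integer preimage.  Reconstructed-κ values inherit up to
~±0.005 from marginal rounding, so κ comparisons use one unit in the last
printed digit.

## Synthetic cohort generator

The generator's purpose is to emulate the *structure* of the validation
problem — quit-attempt cycling observed asynchronously by two imperfect
instruments — not to calibrate to external cessation literature.

**Trajectories.**  Day 0 (a Monday, so the weekend rule is deterministic)
is enrollment; every patient smokes at day 0.  While smoking, quit
attempts arrive as a Poisson process with rate λ(t) = base +
burst·exp(−t/τ): a constant background (0.1/person-year) plus an
enrollment burst (2.6/person-year at t=0, τ = 75 days) reflecting
front-loaded quit activity in a cessation-trial cohort.  Each attempt is
durable with probability 0.21 (abstinent through the horizon) or collapses
after 1 + Geometric days with mean 14 — most attempts fail within weeks.
These defaults put true 6-month prolonged abstinence at the day-365
mailing near 10–11%, the observed cohort-level quit prevalence.

**Survey observer.**  Response is Bernoulli(logit⁻¹(0.72 +
0.35·(age−57)/10 − 0.25·mental_illness)) — responders older and less
likely to have mental illness, overall ≈64% response.  Responders answer
the three items truthfully from their trajectory (item-level missingness
available, default 0).  Covariates (age ~ N(56, 12²) clipped to the trial
range [18, 80], mental illness 48%, respiratory disease 19%,
hospitalization 11%, 94% male, Charlson ~ Poisson(1.0)) echo the cohort's
baseline table and feed only the response model.

**EHR observer.**  Visits are Poisson per site (defaults 2.0–4.0/year);
each visit yields an HF with the site's recording probability (defaults
0.03–0.65, spanning the observed between-site availability extremes of
roughly 4% to 80%).  Recording imperfections:

* *carry-forward* (0.35): staff copy the status from the previous clinical
  contact instead of re-assessing — templated fields lag behind behavior;
* *false-smoker* (0.45): a truly abstinent patient is recorded with a
  smoker label.  This rate is taken directly from the validation data's
  own discordance structure, where 45.6% of survey-confirmed quitters
  carried a smoker HF;
* *false-quit* (0.04): mirrors the 5.8% of confirmed smokers with a
  quitter HF, net of what late quit attempts already produce;
* smokeless labels (0.02 of abstinent-recorded entries) and
  unclassifiable site-local labels (0.03) exercise the smokeless-only and
  unclassified pathways.

Every patient also carries one baseline smoker HF dated 0–90 days before
day 0, the screen that made them trial-eligible.

All randomness flows from one integer seed through a single
`numpy.random.Generator`; identical config + seed give byte-identical
output files.

**What passing simulator tests do and do not show.**  The generator
reproduces the qualitative finding — population quit rates that agree
within a fraction of a percentage point while individual-level κ stays
near 0.5, specificity high, and κ/sensitivity degrading as clinic contact
thins (the quit-cycling mechanism).  It does not model treatment arms,
seasonal visit patterns, within-patient correlation of recording errors,
dual-use misclassification dynamics, or informative visit timing
(hospitalization-triggered assessments), so real-data agreement may differ
in ways the tests cannot reveal.  Relapse kinetics are illustrative, not
literature-calibrated.

## Numerical and design notes

* Dates are calendar dates at day resolution; every offset is an integer
  day difference.  "Within the prior 3 months" for baseline eligibility is
  90 days inclusive.
* The 30-day recall window is the 30 days up to and including the mailing
  day; the 6-month window is 183 days.  A weekend counts as smoked if
  smoking occurred on at least one of its in-window days.
* Strata with fewer than 30 linked patients (configurable) are excluded
  from stratified agreement, flagged rather than dropped silently.
* Degenerate tables raise or report explicitly: κ is undefined when both
  sources report a single category (p_e = 1); a metric with an empty
  denominator is reported as None; McNemar with b+c=0 returns (0, 1).
* The simulation experiment (`experiments.quit_cycling_experiment`) uses
  20,000 patients, a three-point visit-rate sweep (×2.0, ×0.6, ×0.15 of
  the default site rates) averaged over 5 seeds — sizes chosen to keep the
  whole experiment around a minute while leaving the monotonicity signal
  several Monte-Carlo SDs wide.
* Published sensitivity/specificity CIs are roughly twice as wide as any
  standard closed form applied to the reconstructed tables (the exact
  interval method used at the source is underdetermined); point estimates,
  not those bounds, are the replication surface.  The κ CIs, by contrast,
  reproduce under the Fleiss-type SE.
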