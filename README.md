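# hfvalid

Validation of EHR tobacco **health factors** (HFs) — structured smoking-status
fields entered during routine clinical care — against survey-measured
**6-month prolonged smoking abstinence**, the conventional gold standard in
tobacco-cessation research.

## The problem

Large health systems record smoking status as queryable EHR fields
("CURRENT SMOKER", "NON TOBACCO USER - QUIT IN PAST YEAR", ...).  If those
fields tracked *change* in smoking status accurately, researchers could
measure cessation outcomes without costly follow-up surveys.  But an HF is
a point-prevalence snapshot taken whenever the patient happens to visit,
while the survey outcome is a sustained-abstinence definition over a
6-month recall window.  Quitters cycle in and out of attempts, so the two
measurements can disagree at the individual level even when both are
"right" at the moment they were taken.

`hfvalid` implements the full validation pipeline for a cohort of baseline
current smokers surveyed 12 months after enrollment:

1. **`hfvalid.records`** — typed ingest of the HF / survey / covariate CSVs
   with strict row accounting;
2. **`hfvalid.status`** — vocabulary-based mapping of HF labels to
   {smoker, quitter, smokeless-only, unclassified} and of the three survey
   items (past-30-day smoking, 7 consecutive days, two consecutive
   weekends) to prolonged abstinence;
3. **`hfvalid.linkage`** — selection of the temporally closest classifiable
   HF within ±`w` days of the survey mailing (default 120, inclusive
   bounds, deterministic tie rules) and the four-way source grouping
   {both, survey-only, HF-only, neither};
4. **`hfvalid.agreement`** — the 2×2 statistics, with the survey as the
   reference: percent agreement, Cohen's κ = (p_o − p_e)/(1 − p_e) with the
   Fleiss-type large-sample SE, sensitivity/specificity/PPV/NPV with
   first-order delta-method SEs for ratios of multinomial counts
   (Var(X/Y) ≈ p_x(p_y − p_x)/(n p_y³)), McNemar's (b−c)²/(b+c), and a
   reconstruction utility that recovers a 2×2 table from published
   marginals (n, %quit by each source, concordant-quit %) by
   nearest-integer rounding;
5. **`hfvalid.simulate`** — a synthetic cohort generator: quit-attempt
   renewal process with heavy early relapse, site-varying clinic visit and
   HF-recording rates, carry-forward and mislabeling noise, and
   covariate-dependent survey nonresponse;
6. **`hfvalid.pipeline` / `hfvalid.cli`** — orchestration, YAML config, and
   the `hfvalid` command (`simulate`, `analyze`, `replicate`,
   `show-config`).

## Worked example

Reconstruct the full-population agreement row from its published marginals
(n = 1713, 10.6% quit by survey, 10.9% by HF, 5.8% concordant quit) and
recompute every statistic:

```python
>>> from hfvalid import reconstruct_counts, agreement_summary
>>> table = reconstruct_counts(1713, 10.6, 10.9, 5.8)
>>> table.counts
(99, 83, 88, 1443)
>>> res = agreement_summary(table)
>>> round(100 * res.concordance, 1), round(res.kappa.estimate, 2)
(90.0, 0.48)
>>> round(res.kappa.ci_low, 2), round(res.kappa.ci_high, 2)
(0.41, 0.55)
>>> round(res.sensitivity.estimate, 1), round(res.specificity.estimate, 1)
(54.4, 94.3)
```

Read: 90% of patients get the same binary status from both sources, but
chance-corrected agreement is only moderate (κ 0.48) because only 54.4% of
survey-confirmed quitters carry a quitter HF, while ongoing smokers are
almost always labeled correctly (specificity 94.3%).

The same pattern emerges from a fully synthetic cohort:

```bash
hfvalid simulate --n 5000 --seed 1 --out data/
hfvalid analyze --hf data/hf.csv --survey data/survey.csv \
                --covariates data/covariates.csv --out out/
hfvalid replicate     # published-table reconstruction report
```

The analysis report (`out/report.json` and two CSV tables) contains
per-window (±120/90/60/30 day) and per-site agreement, subgroup results,
the four-way availability split, and every tie-break/SE decision in a
metadata block.

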