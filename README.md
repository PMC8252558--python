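# trauma-ehr

Rule-based identification of recorded **childhood sexual abuse (CSA)** in the
free text of electronic health records, and analysis of its demographic,
clinical and functional correlates in patients with **severe mental illness
(SMI)** — non-organic psychotic disorders (ICD-10 F20–F29) or bipolar disorder
(F30–F31).

The package is aimed at researchers in psychiatric epidemiology and clinical
NLP who want to prototype, validate and stress-test string-matching
phenotyping pipelines of this kind without access to a governed EHR platform:
it pairs the full analysis pipeline with a seeded synthetic-cohort generator
that emulates the statistical structure such a study assumes, so every stage
is runnable and testable end to end.

## What it does

1. **CSA detection** (`trauma_ehr.detector`). Notes are case-folded and
   whitespace-collapsed, then scanned against a phrase lexicon with three
   polarities: *include* phrases assert a recorded CSA history
   ("childhood sexual abuse", "sexually abused as a child", "csa",
   age-slot templates such as "sexually abused between the ages of X-Y");
   *exclude* phrases negate it or mark it as merely possible ("no CSA",
   "nil csa", "denied a childhood history of sexual abuse") and block any
   include phrase they overlap; *indeterminate* phrases ("historical sexual
   abuse") record abuse whose age cannot be confirmed. A patient is
   **exposed** when any effective include span has all extracted ages below
   the childhood cutoff (default 18 years); a patient whose only evidence is
   indeterminate is **removed** from the analytic cohort; everyone else is
   unexposed. Detector quality is audited the way a chart review would be:
   PPV on a random sample of flagged notes, with an exact Clopper–Pearson
   95% CI.
2. **Medication and dose extraction** (`trauma_ehr.meddose`). A gazetteer of
   generic and commercial antipsychotic names, `<number> mg` dose parsing
   with od/bd/tds frequency multipliers, percentage of the maximum
   recommended daily dose per mention (values above 200% excluded as entry
   errors), and the per-patient maximum percentage.
3. **Cohort features** (`trauma_ehr.features`). Eligibility filters (SMI
   diagnosis, first contact in 2009–2017 with ≥1 year follow-up, ≥1 HoNOS
   assessment), lifetime moderate–severe HoNOS item flags (item score ≥3 on
   any assessment), comorbidity flags (MDD F32–F33, PTSD F43.1, personality
   disorder F60–F61), and admission days per year on merged episode
   intervals.
4. **Statistics** (`trauma_ehr.stats`). Uncorrected Pearson chi-square on
   r×c tables (Unknown categories retained), odds ratios with Woolf 95% CIs,

   `OR = (d/c)/(b/a)`, `CI = exp(ln OR ± 1.96·√(1/a+1/b+1/c+1/d))`,

   and covariate-adjusted logistic regression (sex, age at first
   presentation, ethnicity), `adjusted OR = exp(β_exposure)` with Wald CIs.
5. **Synthetic cohorts** (`trauma_ehr.synthetic`). A seeded generator whose
   defaults emulate the published reference cohort: 7000 patients, 8.8% CSA
   prevalence, reference demographic marginals with exposure-tilted group
   profiles, outcomes drawn from logistic models with the reference odds
   ratios, and notes containing positive, negated, uncertain, adult-onset
   and indeterminate abuse mentions plus medication-with-dose sentences.

## Worked example

Simulate a 2000-patient cohort and run the whole study:

```text
$ trauma-ehr run --out report/ --seed 1 --n-patients 2000
analytic cohort 1996, exposed 173 (8.7%); report in report/
```

Four patients' only abuse mention was age-indeterminate, so they are removed
(1996 analytic patients); 173 of the rest (8.7%) have a detected CSA record,
close to the configured 8.8% prevalence. `report/summary.md` shows the
outcomes table (each row: percentage with the outcome among unexposed and
exposed patients, unadjusted OR from the 2×2 table, and the
covariate-adjusted OR from logistic regression):

```text
| outcome           |   pct_no_csa |   pct_csa |   or |   adj_or |
|:------------------|-------------:|----------:|-----:|---------:|
| admission         |         52.9 |      68.8 | 1.96 |     1.93 |
| antipsychotic     |         83.9 |      90.8 | 1.89 |     1.90 |
| days_above_median |         48.3 |      63.9 | 1.89 |     1.93 |
| dose_above_median |         49.1 |      55.8 | 1.31 |     1.32 |
```

Exposed patients are admitted more, stay longer than the cohort median of
inpatient days per year, and receive higher antipsychotic doses — the
directions the generator encodes; confidence intervals for every estimate
are in `report/estimates.json`. Audit the detector against generator truth:

```text
$ trauma-ehr ppv-audit --cohort report/cohort --n 100 --seed 2
{"n_flagged": 173, "sample_size": 100, "n_true_positive": 100,
 "ppv": 1.0, "ci_low": 0.9638, "ci_high": 1.0}
```

All 100 audited flagged notes are genuine childhood-abuse mentions
(PPV 100%, 95% CI 96.4–100%).

Replay mode re-tests the published summary counts shipped with the package
(`trauma-ehr replay`): every chi-square statistic recomputed from the
printed cross-tabulations matches the printed value to 2 dp (94.52, 64.92,
32.27, 9.99, 25.35), and the odds ratios recomputed from printed group
percentages match the printed ones to within rounding of the percentages
(1.94/1.31/2.49/1.71 vs printed 1.95/1.31/2.48/1.72).

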