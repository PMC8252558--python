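# Methods

This note documents the scientific model behind `trauma_ehr`: what each
stage computes, the parameters that matter, what the synthetic-data
generator does and does not emulate, and the design choices made where the
design was genuinely open.

## 1. Exposure ascertainment from free text

Detection is literal string matching after normalization (case folding,
whitespace-run collapse), not statistical NLP: the method's value lies in
being auditable phrase by phrase. The lexicon ships as a versioned,
user-extensible YAML file; every surface is matched at word boundaries, and
`{age}` slots match 1–2-digit integers (so 3-digit numbers can never be
read as ages). Range templates ("between the ages of X-Y") yield both
endpoints.

**Overlap precedence.** All candidate matches from all patterns are pooled
and selected greedily: blocking polarities (exclude, indeterminate) before
include, then longer matches, then earlier ones; a candidate overlapping an
already-selected span is suppressed. This single rule implements negation
("nil csa" blocks the embedded "csa") without general negation-scope
resolution, which is out of scope by design: phrases suggesting a merely
*possible* history are handled the same way, as blocking phrases.

**Patient classification.** A patient is *exposed* when at least one
effective include span has all extracted ages below the childhood cutoff.
The cutoff defaults to **18 years**, the convention of the meta-analytic
literature on childhood sexual abuse; it is a parameter, not a constant.
An include span carrying any adult age is demoted to non-evidence rather
than treated as blocking — abuse at 35 is not childhood abuse, but it also
does not negate a separate childhood mention. A patient with indeterminate
evidence only ("historical sexual abuse", no confirmable age) is *removed
from the analytic cohort entirely* rather than classified either way; the
pipeline reports these removals in its stage-by-stage accounting. A
deliberate consequence of "any effective include span dominates": a negated
mention in one note never overrides a positive mention in another note.
Whether the original ascertainment strategy behaved this way is not
documented; treating affirmative evidence as dominant is the conservative
reading for a lifetime exposure.

**Validation.** The PPV audit emulates a manual chart review: a uniform
random sample (without replacement) of flagged notes is compared against
ground truth; the interval is exact Clopper–Pearson. On synthetic corpora
ground truth is the generator's note-level label, so the audit measures the
rule set's precision against the distractors the generator plants.

## 2. Medication dose percentage

Antipsychotic receipt is ascertained from a gazetteer of generic and
commercial names; doses are parsed from `<number> mg` in the same sentence,
with od/bd/tds/qds multiplying to a daily dose and unstated frequency
defaulting to once daily (conservative and deterministic). Each dosed
mention becomes a percentage of that drug's maximum recommended daily dose;
the shipped maxima follow standard UK prescribing references for adult oral
use and are an editable config table, not a claimed reproduction of any
formulary. Records **above 200% of the maximum are excluded before any
aggregation** as probable data-entry or parsing errors; the per-patient
quantity is the maximum non-excluded percentage. Mentions without a
parseable dose (including depot formulations, which have no daily-dose
semantics) count toward receipt but never toward the percentage. Multiple
drugs are kept per-drug — percentages are never summed across drugs — and
the per-patient maximum is taken across all dosed mentions.

Median dichotomization (used for both dose percentage and admission days
per year) is the empirical median with strict ">" for "above", so ties sit
in the lower stratum and the split is well defined when many patients share
the median value.

## 3. Cohort filters and outcomes

Eligibility: ≥1 ICD-10 code in F20–F29/F30–F31, first contact inside the
2009-01-01–2017-12-31 study window with ≥365 days to the window end, and
≥1 HoNOS assessment. ICD-10 range checks operate on the 3-character
category (with 4th-character subdivision only where needed, e.g. PTSD =
F43.1). Patients with a missing first-contact date are removed with an
explicit count, since follow-up cannot be computed. The follow-up
denominator is first contact to window end — the only two dates the data
model guarantees per patient.

HoNOS items (0 = no problem … 4 = severe) are dichotomized to *lifetime
presence at moderate–severe level*: flag true iff any assessment scores the
item ≥ threshold. The threshold defaults to **3** ("moderately severe" on
the scale anchors) and is exposed as a parameter because both 2 and 3 are
used in this literature; the flag is monotone in the threshold by
construction. Admission days use the union of episode intervals (so
overlapping or split episodes never double-count), with a 1-day minimum per
merged episode so same-day admissions count one inpatient day.

## 4. Statistics

Group comparisons are uncorrected Pearson chi-square on r×c tables with
"Unknown" retained as an ordinary category (a switch drops it, mirroring
sensitivity analyses that re-test without unknowns); no Yates correction
and no multiple-testing adjustment are applied anywhere, matching the
analysis style this package replays. Odds ratios use the Woolf log-normal
interval with the standard 0.5 continuity add (with a warning) on zero
cells. Adjusted ORs come from maximum-likelihood logistic regression with
sex, age at first presentation and ethnicity as covariates; reference
levels are the largest groups (sex = M, ethnicity = White). Fitting uses
IRLS, which tolerates quasi-separation in sparse nuisance dummies; a
degenerate or non-converged exposure coefficient raises an explicit error
rather than returning numbers.

When only rounded percentages are available (replay mode), the OR point
estimate is computed exactly from the proportions and counts are
reconstructed as `round(p·n)` solely to attach a CI; percentages printed at
1 dp can shift a reconstructed OR by ±0.01–0.02, which is why replay output
reports both the recomputed and the published value. Two published
comorbidity chi-squares (PTSD, personality disorders) are excluded from the
shipped reference-counts file because their printed counts do not sum to
the stated group denominators and the printed statistics cannot be
reproduced from the printed counts by any uncorrected Pearson computation;
replaying them would assert numbers the source data cannot support.

## 5. The synthetic cohort generator

The generator's defaults are the study conditions the analyses assume:
7000 patients, CSA prevalence 0.088, demographic marginals equal to the
reference cohort's whole-cohort margins. Exposure-dependent demographics
use a tilt construction: the exposed group's category shares are the
marginal times `exp(shift)` (default shifts log-ratios of the reference
group columns), and the unexposed shares are the mixture complement, so
cohort marginals are preserved *exactly* while group differences reproduce
the reference directions (more female, more White, more single among
exposed). Binary outcomes are drawn independently per outcome from
`logit(p) = logit(baseline) + β·CSA`; admission and antipsychotic receipt
use the reference baselines (51.1%, 89.5%) and log-ORs (ln 1.95, ln 2.48),
comorbidities use baselines/ORs derived from the reference comorbidity
table, and the seven HoNOS items use package-chosen baselines (20–55%) with
β between 0.4 and 0.6, since the source figure prints no numbers. Admission
days per year are log-normal (median 10 days, log-sd 1.0, exposed shift
+0.28) split into non-overlapping episodes; dose intensity is a per-patient
fraction of maximum (mean 0.75, sd 0.35, exposed shift +0.12) quantized to
each drug's tablet grid, with a 1% rate of >200% entry errors so the
exclusion filter is exercised.

Notes are template-based. Every true-CSA patient receives exactly one
unqualified positive mention; unexposed patients' notes carry negated
(4%/note), uncertain (2%) and adult-onset (1.5%) distractor sentences; a
configurable fraction of unexposed patients (default 0.2%) carry only an
indeterminate mention and are therefore removed by the detector, exercising
the removal path at its observed real-world rate. Each note has exactly one
mention label, making the PPV audit's ground truth unambiguous. First
contact is sampled so ≥1 year of follow-up always holds — the eligibility
filter stays exercisable but non-destructive by default, with a separate
knob for missing first-contact dates.

**What the generator does not emulate** — and hence what green tests do not
show about real data: clinical language variability (spelling errors,
novel phrasings, negations outside the lexicon), correlation between
outcomes beyond their shared dependence on exposure (no joint distribution
is published, so none is invented), informative note volume (in real EHRs
sicker patients generate more notes and more chances of disclosure),
covariate-outcome confounding (outcomes depend on exposure only, so
adjusted ≈ unadjusted ORs by design), and under-recording of abuse — the
generator's detector-facing sensitivity is 1 by construction, whereas
recorded prevalence in real notes understates true prevalence. Measured
antipsychotic receipt also runs a few points below its generating baseline,
because receipt must be *observed* in a medication sentence and patients
with short follow-up have few notes — itself a realistic ascertainment
artifact. The detector's perfect PPV on synthetic text is an upper bound
that certifies the rule set's internal logic (negation blocking, age
handling), not its coverage of real clinical prose.

## 6. Numerical and scale choices

Seeded `numpy` Generators make every artifact byte-reproducible; the run
manifest records config, seed, lexicon version and input digests, and every
report table is reproducible from the manifest alone (the manifest
timestamp is provenance, not part of the determinism contract). Default
problem sizes were chosen so the whole pipeline at reference scale (7000
patients, ~77k notes) completes in well under a minute on one core:
scanning prefilters each note with a single combined alternation regex
before per-pattern matching. Tests run the pipeline at a few hundred
patients, which already exercises every code path; generator-recovery
checks (logistic β within ±0.1) use n = 50,000, where the Monte-Carlo
standard error of the recovered log-OR (~0.03) makes the band a ≥3σ test.

## 7. Known limitations

The lexicon covers the documented core phrases plus systematic inflectional
variants; site-specific phrasing requires extending the YAML file. The dose
parser reads one dose per drug per sentence and no start/stop or adherence
semantics. Logistic models use complete cases only (the synthetic data have
no missingness to impute). "Unknown" demographic categories are analysed as
categories, never imputed.
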