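# Published summary counts from a large UK severe-mental-illness EHR cohort
# (n = 7000; 619 with a recorded history of childhood sexual abuse), used by
# the replay analysis mode: each variable is a cross-tabulation of category
# counts against exposure (columns: no_csa, csa).
#
# The chi_square_2dp values are the statistics printed alongside those counts
# in the source report; replay mode recomputes uncorrected Pearson chi-square
# from the counts and compares.  Two comorbidity rows of the original report
# (PTSD, personality disorders) are omitted here because their printed counts
# do not sum to the group denominators and their printed statistics cannot be
# reproduced from the printed counts; see docs/methods.md.
cohort:
  n_total: 7000
  n_csa: 619
tables:
  sex:
    categories: [M, F]
    no_csa: [3609, 2772]
    csa: [224, 395]
    chi_square_2dp: 94.52
  ethnicity:
    categories: [White, Black, Asian, Mixed, Other, Unknown]
    no_csa: [3462, 1418, 485, 257, 465, 294]
    csa: [411, 108, 25, 43, 22, 10]
    chi_square_2dp: 64.92
  marital:
    categories: [Single, Married, Divorced, Widowed, Unknown]
    no_csa: [4244, 741, 680, 189, 527]
    csa: [476, 49, 58, 8, 28]
    chi_square_2dp: 32.27
  deprivation:
    categories: [Q1, Q2, Q3, Q4, Unknown]
    no_csa: [957, 1418, 1718, 1729, 559]
    csa: [83, 145, 174, 183, 34]
    chi_square_2dp: 9.99
  mdd:
    categories: ["No", "Yes"]
    no_csa: [5895, 486]
    csa: [536, 83]
    chi_square_2dp: 25.35
outcomes:
  # percentage with the outcome in each exposure group, and the unadjusted
  # odds ratio printed in the source report (2 dp)
  admission:        {pct_no_csa: 51.1, pct_csa: 67.0, printed_or: 1.95}
  days_above_median: {pct_no_csa: 50.1, pct_csa: 56.9, printed_or: 1.31}
  antipsychotic:    {pct_no_csa: 89.5, pct_csa: 95.5, printed_or: 2.48}
  dose_above_median: {pct_no_csa: 47.6, pct_csa: 60.9, printed_or: 1.72}
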