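# Default CSA string-matching lexicon, version 1.
#
# Surfaces are matched literally on normalized text (case-folded, whitespace
# collapsed) at word boundaries.  "{age}" marks a 1-2 digit age slot.
# Polarity:
#   include       - phrase asserting a recorded history of childhood sexual abuse
#   exclude       - phrase negating such a history, or flagging it as merely
#                   possible/uncertain; blocks any include phrase it overlaps
#   indeterminate - abuse recorded as historical but with no confirmable age at
#                   the time of abuse; triggers patient removal when it is the
#                   only evidence
#
# The list is deliberately user-extensible: point the detector at your own file
# to add site-specific phrasing.
version: 1
entries:
  # ---- inclusion phrases -------------------------------------------------
  - {pattern_id: inc_csa_abbrev,        surface: "csa",                                     polarity: include}
  - {pattern_id: inc_childhood_sa,      surface: "childhood sexual abuse",                  polarity: include}
  - {pattern_id: inc_hist_sa,           surface: "history of sexual abuse",                 polarity: include}
  - {pattern_id: inc_hx_sa,             surface: "hx of sexual abuse",                      polarity: include}
  - {pattern_id: inc_childhood_hx_sa,   surface: "childhood hx of sexual abuse",            polarity: include}
  - {pattern_id: inc_childhood_hist_sa, surface: "childhood history of sexual abuse",       polarity: include}
  - {pattern_id: inc_childhood_exp_sa,  surface: "childhood experiences of sexual abuse",   polarity: include}
  - {pattern_id: inc_childhood_exp1_sa, surface: "childhood experience of sexual abuse",    polarity: include}
  - {pattern_id: inc_abused_as_child,   surface: "sexually abused as a child",              polarity: include}
  - {pattern_id: inc_abuse_as_child,    surface: "sexual abuse as a child",                 polarity: include}
  - {pattern_id: inc_abused_in_childhood, surface: "sexually abused in childhood",          polarity: include}
  - {pattern_id: inc_sa_at_age,         surface: "sexual abuse at age {age}",               polarity: include}
  - {pattern_id: inc_abused_at_age,     surface: "sexually abused at age {age}",            polarity: include}
  - {pattern_id: inc_abused_at_the_age, surface: "sexually abused at the age of {age}",     polarity: include}
  - {pattern_id: inc_abused_aged,       surface: "sexually abused aged {age}",              polarity: include}
  - {pattern_id: inc_abused_when,       surface: "sexually abused when she was {age}",      polarity: include}
  - {pattern_id: inc_abused_when_m,     surface: "sexually abused when he was {age}",       polarity: include}
  - {pattern_id: inc_abused_between,    surface: "sexually abused between the ages of {age}-{age}", polarity: include}
  - {pattern_id: inc_abused_between_and, surface: "sexually abused between the ages of {age} and {age}", polarity: include}
  - {pattern_id: inc_sa_between,        surface: "sexual abuse between the ages of {age}-{age}", polarity: include}

  # ---- exclusion phrases: negated history --------------------------------
  - {pattern_id: exc_no_csa,            surface: "no csa",                                  polarity: exclude}
  - {pattern_id: exc_nil_csa,           surface: "nil csa",                                 polarity: exclude}
  - {pattern_id: exc_denies_csa,        surface: "denies csa",                              polarity: exclude}
  - {pattern_id: exc_denied_csa,        surface: "denied csa",                              polarity: exclude}
  - {pattern_id: exc_denied_childhood_hist, surface: "denied a childhood history of sexual abuse", polarity: exclude}
  - {pattern_id: exc_denies_childhood_hist, surface: "denies a childhood history of sexual abuse", polarity: exclude}
  - {pattern_id: exc_denied_any_hist,   surface: "denied any history of sexual abuse",      polarity: exclude}
  - {pattern_id: exc_denies_any_hist,   surface: "denies any history of sexual abuse",      polarity: exclude}
  - {pattern_id: exc_no_hist_sa,        surface: "no history of sexual abuse",              polarity: exclude}
  - {pattern_id: exc_no_hist_csa,       surface: "no history of childhood sexual abuse",    polarity: exclude}
  - {pattern_id: exc_no_childhood_sa,   surface: "no childhood sexual abuse",               polarity: exclude}

  # ---- exclusion phrases: merely possible/uncertain history ---------------
  - {pattern_id: exc_possible_csa,      surface: "possible csa",                            polarity: exclude}
  - {pattern_id: exc_query_csa,         surface: "query csa",                               polarity: exclude}
  - {pattern_id: exc_qmark_csa,         surface: "? csa",                                   polarity: exclude}
  - {pattern_id: exc_possible_hist,     surface: "possible history of sexual abuse",        polarity: exclude}
  - {pattern_id: exc_possible_childhood, surface: "possible childhood sexual abuse",        polarity: exclude}
  - {pattern_id: exc_unclear_whether,   surface: "unclear whether she was sexually abused", polarity: exclude}
  - {pattern_id: exc_unclear_whether_m, surface: "unclear whether he was sexually abused",  polarity: exclude}

  # ---- indeterminate age: recorded abuse, childhood status unconfirmable --
  - {pattern_id: ind_historical_sa,     surface: "historical sexual abuse",                 polarity: indeterminate}
  - {pattern_id: ind_hist_sa_age_unk,   surface: "sexual abuse in the past, age unknown",   polarity: indeterminate}
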