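# Antipsychotic gazetteer with maximum recommended daily doses (mg).
#
# Maxima follow the ranges published in standard UK prescribing references
# (BNF / Maudsley guidelines) for adult oral use; the table is a small,
# editable reference covering common agents, not an exhaustive formulary.
# Depot / long-acting injectable formulations are matched by name only and
# carry no daily-dose semantics (no max_daily_mg), so they contribute to
# "any antipsychotic" but never to the dose-percentage computation.
drugs:
  - {generic: olanzapine,     synonyms: [zyprexa],                max_daily_mg: 20}
  - {generic: risperidone,    synonyms: [risperdal],              max_daily_mg: 16}
  - {generic: quetiapine,     synonyms: [seroquel],               max_daily_mg: 750}
  - {generic: aripiprazole,   synonyms: [abilify],                max_daily_mg: 30}
  - {generic: haloperidol,    synonyms: [haldol, serenace],       max_daily_mg: 20}
  - {generic: clozapine,      synonyms: [clozaril, zaponex],      max_daily_mg: 900}
  - {generic: amisulpride,    synonyms: [solian],                 max_daily_mg: 1200}
  - {generic: chlorpromazine, synonyms: [largactil],              max_daily_mg: 1000}
  - {generic: flupentixol decanoate, synonyms: [depixol depot]}   # depot: name-only
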