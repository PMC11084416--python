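# Default point allocation for the Spanish Pharmacovigilance System (SEFV)
# causality algorithm (Karch-Lasagna derived): seven factors -- chronology,
# literature, withdrawal, rechallenge, alternative causes, contributing
# factors, complementary explorations. Positivity for validation purposes is
# a net score strictly greater than 6. The 'contradicted' literature level
# and the 'more_plausible' alternative level are reachable only through
# manual scoring, not from the structured record.
algorithm: sefv
positivity_threshold: 6
items:
  - id: chronology
    description: Latency from drug start to reaction onset, SEFV windows (1-7 days typical)
    levels:
      compatible: 2
      partially_compatible: 1
      incompatible: 0
      excluding: -1
  - id: literature
    description: Prior literature association (notoriety)
    levels:
      well_known: 2
      occasionally_reported: 1
      unknown: 0
      contradicted: -1
  - id: withdrawal
    description: Course after withdrawal (dechallenge)
    levels:
      improved: 2
      not_improved: -2
      not_withdrawn: 0
      unassessable: 0
  - id: rechallenge
    description: Reaction on re-exposure
    levels:
      positive: 3
      negative: -1
      not_done: 0
  - id: alternative_cause
    description: Alternative non-drug explanation for the reaction
    levels:
      more_plausible: -3
      plausible_alternative: -1
      no_information: 0
      excluded: 1
  - id: contributing_factors
    description: Predisposing conditions favouring the reaction
    levels:
      present: 1
      absent: 0
  - id: complementary_explorations
    description: Supportive complementary tests (LTT, patch test)
    levels:
      supportive: 1
      uninformative: 0
bands:
  - { name: unlikely, min_score: -8, max_score: 0 }
  - { name: conditional, min_score: 1, max_score: 3 }
  - { name: possible, min_score: 4, max_score: 5 }
  - { name: probable, min_score: 6, max_score: 7 }
  - { name: definite, min_score: 8, max_score: 12 }
binary:
  unlikely: unrelated
  conditional: unrelated
  possible: related
  probable: related
  definite: related
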