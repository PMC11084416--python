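# Default ALDRESS point allocation.
#
# This allocation is the package's own documented convention, constrained by
# the algorithm's published contract: positivity is a net score strictly
# greater than 7, and a textbook single-drug presentation (compatible
# chronology, improvement after withdrawal, well-known drug, alternative
# infectious causes excluded, immunology not done) must classify as related
# (3 + 2 + 2 + 1 = 8 > 7). Missing information is always score-neutral (0).
# Edit freely; the engine revalidates band coverage on load.
algorithm: aldress
positivity_threshold: 7
items:
  - id: chronology
    description: Latency from drug start to reaction onset, DRESS windows (2-8 weeks typical)
    levels:
      compatible: 3
      partially_compatible: 1
      incompatible: -3
      excluding: -4
  - id: dechallenge
    description: Clinical course after drug withdrawal
    levels:
      improved: 2
      not_improved: -2
      not_withdrawn: 0
      unassessable: 0
  - id: rechallenge
    description: Reaction on deliberate or accidental re-exposure
    levels:
      positive: 3
      negative: -2
      not_done: 0
  - id: notoriety
    description: Prior literature association of the drug with DRESS
    levels:
      well_known: 2
      occasionally_reported: 1
      unknown: 0
  - id: alternative_infection
    description: Microbiological screen for an alternative infectious cause
    levels:
      positive: -2
      screens_negative: 1
      not_recorded: 0
  - id: immunology
    description: LTT and epicutaneous patch test (combined, capped at +3)
    levels:
      ltt_positive: 3
      patch_positive: 2
      negative: -1
      not_done: 0
  - id: concomitant_suspect
    description: Another administered drug of equal or higher notoriety
    levels:
      penalty: -1
      none: 0
bands:
  - { name: unlikely, min_score: -12, max_score: 0 }
  - { name: possible, min_score: 1, max_score: 7 }
  - { name: probable, min_score: 8, max_score: 11 }
  - { name: definite, min_score: 12, max_score: 14 }
binary:
  unlikely: unrelated
  possible: unrelated
  probable: related
  definite: related
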