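# RegiSCAR DRESS validation score, per the published scoring system:
# fever absent/unknown -1; lymphadenopathy +1; eosinophilia moderate +1 /
# marked +2; atypical lymphocytes +1; skin extent > 50% +1; rash suggestive
# +1 (not suggestive -1); biopsy not suggestive -1; organ involvement one
# organ +1, two or more +2; resolution >= 15 days (else -1); >= 3 relevant
# alternative causes excluded +1.
#
# Category bands: <= +1 excluded, +2..+3 possible, +4 probable, >= +5
# definite. The inclusion gate for causality assessment is a total strictly
# greater than +2.
algorithm: regiscar
positivity_threshold: 2
items:
  - id: fever_ge_38_5
    description: Fever >= 38.5 C
    levels: { "yes": 0, no_or_unknown: -1 }
  - id: lymphadenopathy
    description: Enlarged lymph nodes (>= 2 sites, > 1 cm)
    levels: { "yes": 1, "no": 0, unknown: 0 }
  - id: eosinophilia
    description: Eosinophilia (moderate 0.7-1.499 x 10^9/L or 10-19.9%; marked above)
    levels: { none: 0, moderate: 1, marked: 2, unknown: 0 }
  - id: atypical_lymphocytes
    description: Atypical lymphocytes on blood smear
    levels: { "yes": 1, "no": 0, unknown: 0 }
  - id: skin_extent
    description: Rash extent > 50% body surface area
    levels: { gt50: 1, le50: 0, unknown: 0 }
  - id: rash_suggestive
    description: Rash morphology suggestive of DRESS
    levels: { "yes": 1, "no": -1, unknown: 0 }
  - id: biopsy
    description: Skin biopsy suggesting DRESS
    levels: { "yes": 0, "no": -1, not_done: 0 }
  - id: organ_involvement
    description: Number of internal organs involved
    levels: { none: 0, one: 1, two_or_more: 2 }
  - id: resolution
    description: Resolution in 15 days or more
    levels: { "yes": 0, no_or_unknown: -1 }
  - id: alternative_causes
    description: At least three relevant alternative causes excluded
    levels: { "yes": 1, "no": 0, unknown: 0 }
bands:
  - { name: excluded, min_score: -4, max_score: 1 }
  - { name: possible, min_score: 2, max_score: 3 }
  - { name: probable, min_score: 4, max_score: 4 }
  - { name: definite, min_score: 5, max_score: 9 }
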