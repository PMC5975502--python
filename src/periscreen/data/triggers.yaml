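# Trigger lexicon for the rule-based context engine (negation, temporality,
# experiencer, section titles). Patterns are case-insensitive regex fragments
# matched at word boundaries. Editable.
scope_window: 6

# Pre-mention negation triggers (NegEx-style), scoped to scope_window tokens
# before the mention; scope is broken by an adversative conjunction.
negation_pre:
  - denies
  - denied
  - denying
  - "no"
  - "not"
  - without
  - negative for
  - no evidence of
  - rules out
  - ruled out

# Scope-breaking conjunctions for pre-negation.
scope_breakers:
  - but
  - however
  - although
  - though
  - except

# Colon-structure negation: the mention is followed (on the same line, no
# sentence punctuation) by a colon and a negation word.
negation_post_colon_words:
  - none
  - denied
  - denies
  - "no"
  - negative
  - neg
  - absent
  - none reported

# Post-mention phrase negation.
negation_post:
  - was ruled out
  - is ruled out
  - has been ruled out

# Temporality: historical (document-time relation "before").
history_cues:
  - history of
  - hx of
  - h/o
  - in the past
  - years ago
  - prior
  - previous
  - remote
  - 'in (?:19|20)\d\d'
  - 'when (?:she|he|they) (?:was|were) \d+'
  - 'at age \d+'
  - 'as a (?:child|teenager|teen)'

# Temporality: hypothetical / conditional / future ("after").
hypothetical_cues:
  - if
  - would
  - will
  - in case
  - risk of
  - were to
  - should (?:she|he|they|symptoms)
  - in the event

# Temporality: started in the past and continuing ("before/overlap").
durative_cues:
  - since
  - ongoing
  - continues to
  - continued
  - still
  - chronic

# Experiencer: family members.
family_cues:
  - mom
  - mother
  - father
  - dad
  - sister
  - brother
  - grandmother
  - grandfather
  - aunt
  - uncle
  - cousin
  - son
  - daughter
  - husband
  - family history
  - fhx

# Experiencer: non-family third parties.
other_cues:
  - friend
  - roommate
  - neighbor
  - coworker
  - boyfriend
  - partner
  - classmate

# Experiencer: tokens that resolve the subject to the patient.
patient_cues:
  - patient
  - pt
  - she
  - he
  - they
  - her
  - his
  - woman

# Finite-verb cues: a line ending in ":" that contains one of these is a
# clause, not a section header.
section_verb_cues:
  - is
  - are
  - was
  - were
  - has
  - have
  - had
  - reports
  - states
  - denies
  - endorses
  - admits
  - feels
  - wants
  - describes
  - presents
  - appears
  - attempted
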