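# Term lexicon for the clinical-notes screen. Editable approximation covering
# suicide, suicidal ideation, suicide attempt, self-harm and overdose surface
# forms. Patterns are case-insensitive regular-expression fragments matched at
# word boundaries; concept_id is a flat local concept identifier standing in
# for a UMLS CUI.
pattern	concept_id	label
suicidal ideation	C-SB-001	suicidal ideation
suicidal behaviou?r	C-SB-002	suicidal behavior
suicide attempt	C-SB-003	suicide attempt
suicidal thoughts?	C-SB-004	suicidal thoughts
suicidality	C-SB-005	suicidality
suicidal	C-SB-006	suicidal (adjective)
suicide	C-SB-007	suicide
self[- ]harm	C-SB-008	self-harm
kill (?:her|him|them)self	C-SB-009	kill oneself
overdose	C-SB-010	overdose
SI	C-SB-011	suicidal ideation (abbreviation)
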