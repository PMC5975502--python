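# Diagnostic codes used to screen for suicidal behavior.
# Editable approximation: explicit ideation/attempt codes plus the poisoning
# categories (analgesics/antipyretics/antirheumatics; sedatives and hypnotics;
# psychotropic agents). LMR problem-list entries are local-vocabulary
# placeholders, to be replaced with site-specific values.
system	pattern	label
ICD9	E950-E958	suicide and self-inflicted injury
ICD9	V62.84	suicidal ideation
ICD9	965.*	poisoning by analgesics, antipyretics, antirheumatics
ICD9	967.*	poisoning by sedatives and hypnotics
ICD9	969.*	poisoning by psychotropic agents
ICD10	X60-X84	intentional self-harm
ICD10	R45.851	suicidal ideation
ICD10	T14.91	suicide attempt
ICD10	T39.*	poisoning by analgesics, antipyretics, antirheumatics
ICD10	T42.*	poisoning by sedatives and hypnotics
ICD10	T43.*	poisoning by psychotropic agents
LMR	SBH-IDEATION	suicidal ideation (problem list; placeholder)
LMR	SBH-ATTEMPT	suicide attempt (problem list; placeholder)
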