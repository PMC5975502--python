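# Psychiatric comorbidity code lists (editable approximation).
# columns: condition <TAB> system <TAB> pattern
condition	system	pattern
depression	ICD9	296.2.*
depression	ICD9	296.3.*
depression	ICD9	300.4
depression	ICD9	311
depression	ICD10	F32.*
depression	ICD10	F33.*
schizophrenia	ICD9	295.*
schizophrenia	ICD10	F20.*
bipolar	ICD9	296.0.*
bipolar	ICD9	296.1.*
bipolar	ICD9	296.4.*
bipolar	ICD9	296.5.*
bipolar	ICD9	296.6.*
bipolar	ICD9	296.7.*
bipolar	ICD9	296.8.*
bipolar	ICD10	F31.*
ptsd	ICD9	309.81
ptsd	ICD10	F43.1.*
substance_abuse	ICD9	303.*
substance_abuse	ICD9	304.*
substance_abuse	ICD9	305.*
substance_abuse	ICD10	F10-F19
anxiety	ICD9	300.0.*
anxiety	ICD10	F41.*
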