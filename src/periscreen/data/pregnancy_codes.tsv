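# Diagnostic codes identifying pregnancy or delivery encounters.
# Editable: columns are system <TAB> pattern <TAB> label.
# Pattern forms: exact code, trailing-wildcard ("V22.*"), numeric range ("640-679").
system	pattern	label
ICD10	Z3A.*	weeks of gestation
ICD10	O0.*-O9.*	obstetric chapter (pregnancy, childbirth, puerperium)
ICD9	640-679	complications of pregnancy, childbirth, puerperium
ICD9	V22.*	normal pregnancy
ICD9	V23.*	supervision of high-risk pregnancy
ICD9	V24.*	postpartum care and examination
ICD9	V27.*	outcome of delivery
ICD9	V28.*	antenatal screening
DRG	370-384	pregnancy/delivery diagnosis-related groups
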