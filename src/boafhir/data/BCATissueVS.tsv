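display	system	code	synonyms
muscle	local	tissue-muscle	muscle tissue
bone	local	tissue-bone	bone tissue
subcutaneous adipose tissue	local	tissue-sat	sat
visceral adipose tissue	local	tissue-vat	vat
intramuscular adipose tissue	local	tissue-imat	imat
epicardial adipose tissue	local	tissue-eat	eat
paracardial adipose tissue	local	tissue-pat	pat
total adipose tissue	local	tissue-tat	tat
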