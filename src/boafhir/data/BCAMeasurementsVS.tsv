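display	system	code	synonyms
measurement including extremities	local	measurement-with-extremities	with extremities|including extremities
measurement excluding extremities	local	measurement-without-extremities	without extremities|excluding extremities
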