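display	system	code	synonyms
abdominal cavity	sct	52731004	abdominal_cavity
thoracic cavity	sct	43799004	thoracic_cavity
mediastinum	sct	72410000	
pericardium	sct	76848001	
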