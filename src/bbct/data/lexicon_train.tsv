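isolate	8	train
infection	5	train
strain	5	train
attachment	3	train
adhesion	3	train
bacteremia	2	train
enrichment	2	train
growth	2	train
carriage	2	train
resistance	2	train
detection	1	train
bacteriophage	1	train
surveillance	1	train
isolation	1	train
elimination	1	train
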