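strain	21256	unlabeled
infection	12856	unlabeled
isolate	9555	unlabeled
prevalence	3300	unlabeled
growth	2868	unlabeled
detection	2621	unlabeled
resistance	2479	unlabeled
bacteria	1812	unlabeled
pathogen	1711	unlabeled
culture	1412	unlabeled
response	1358	unlabeled
survival	1275	unlabeled
abundance	1196	unlabeled
susceptibility	1161	unlabeled
colonization	1015	unlabeled
isolation	935	unlabeled
transmission	853	unlabeled
exposure	846	unlabeled
disease	818	unlabeled
adhesion	791	unlabeled
attachment	300	unlabeled-inferred
bacteremia	300	unlabeled-inferred
enrichment	300	unlabeled-inferred
carriage	300	unlabeled-inferred
bacteriophage	300	unlabeled-inferred
surveillance	300	unlabeled-inferred
elimination	300	unlabeled-inferred
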