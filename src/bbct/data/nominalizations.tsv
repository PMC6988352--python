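abound	abundance
adhere	adhesion
attach	attachment
carry	carriage
colonize	colonization
colonized	colonization
contaminate	contamination
contaminated	contamination
detect	detection
determine	determination
diagnose	diagnosis
eliminate	elimination
enrich	enrichment
evaluate	evaluation
expose	exposure
grow	growth
infect	infection
infected	infection
isolated	isolation
persist	persistence
present	presence
prevalent	prevalence
prevent	prevention
purify	purification
resist	resistance
resistant	resistance
respond	response
surveil	surveillance
survive	survival
susceptible	susceptibility
transmit	transmission
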