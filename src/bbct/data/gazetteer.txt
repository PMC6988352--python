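A. aquaeolei
Agrobacterium rhizogenes
C. burnetii
Campylobacter
Campylobacter jejuni
Chromatium
Ectothiorhodospira
Escherichia coli
Escherichia coli O157:H7
F. tularensis
F. tularensis LVS
Helicobacter pylori
K. kingae
Kingella kingae
M. agassizii
M. testudineum
MRSA
Methicillin-resistant Staphylococcus aureus
Mtb
Mycobacterium tuberculosis
Non-O1 Vibrio cholerae
P. aeruginosa
Pseudomonas aeruginosa
S. Paratyphi A
S. enterica
S. marcescens
S. marcescens MG1
Salmonella
Salmonella enterica
Staphylococcus
Staphylococcus aureus
Streptococcus pyogenes
V. cholerae
V. cholerae O:1
V. salmonicida
Vibrio cholerae
Vibrio salmonicida
salmonellae
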