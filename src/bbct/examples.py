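"""Curated miniature corpus of annotated documents with gold parses.

Each document reconstructs a characteristic configuration from the BioNLP-ST
2016 Bacteria Biotope event corpus (PubMed abstract snippets): intra-clause
patterns, trigger-mediated inference within and across sentences, propagation
through coordination and apposition, and hypothesis/negation scopes.  The
dependency analyses are hand-written Universal Dependencies parses; a few
sentences complete elided material with minimal neutral continuations.

Every document carries reference (gold) Lives_In events.  The gold layer
records what the corpus annotation scheme considers true, *not* what the
extractor finds: several documents deliberately preserve configurations the
rule set is known to miss or overpredict, so they double as regression
fixtures for documented error behavior.
"""

from __future__ import annotations

from bbct.docbuild import DocBuilder
from bbct.standoff import AnnotatedDocument

__all__ = ["load_curated_examples", "curated_example"]


def _kingae_pharyngeal() -> AnnotatedDocument:
    """Cross-sentence event through the context trigger "carriage"."""
    b = DocBuilder("kingae-pharyngeal")
    b.sentence([
        ("None", "none", "PRON", 6, "nsubj"),
        ("of", "of", "ADP", 5, "case"),
        ("the", "the", "DET", 5, "det"),
        ("colonized", "colonized", "ADJ", 5, "amod"),
        ("children", "child", "NOUN", 1, "nmod"),
        ("experienced", "experience", "VERB", 0, "root"),
        ("an", "a", "DET", 11, "det"),
        ("invasive", "invasive", "ADJ", 11, "amod"),
        ("K.", "K.", "PROPN", 10, "compound"),
        ("kingae", "kingae", "PROPN", 11, "compound"),
        ("infection", "infection", "NOUN", 6, "obj"),
        (".", ".", "PUNCT", 6, "punct"),
    ])
    b.sentence([
        ("The", "the", "DET", 2, "det"),
        ("prevalence", "prevalence", "NOUN", 10, "nsubj"),
        ("of", "of", "ADP", 5, "case"),
        ("pharyngeal", "pharyngeal", "ADJ", 5, "amod"),
        ("carriage", "carriage", "NOUN", 2, "nmod"),
        ("among", "among", "ADP", 8, "case"),
        ("surgical", "surgical", "ADJ", 8, "amod"),
        ("patients", "patient", "NOUN", 5, "nmod"),
        ("was", "be", "AUX", 10, "cop"),
        ("8.0%", "8.0%", "NUM", 0, "root"),
        (".", ".", "PUNCT", 10, "punct"),
    ])
    b.mention("T1", "Bacteria", (0, 8, 9))
    b.mention("T2", "Habitat", (1, 3, 3))
    b.event("T1", "T2")
    return b.build()


def _rhizogenes_tdna() -> AnnotatedDocument:
    """Trigger misdirection: "disease" yields a spurious cross-sentence location."""
    b = DocBuilder("rhizogenes-tdna")
    b.sentence([
        ("Agrobacterium", "Agrobacterium", "PROPN", 2, "compound"),
        ("rhizogenes", "rhizogenes", "PROPN", 3, "compound"),
        ("strains", "strain", "NOUN", 8, "nsubj"),
        ("of", "of", "ADP", 7, "case"),
        ("the", "the", "DET", 7, "det"),
        ("agropine", "agropine", "NOUN", 7, "compound"),
        ("type", "type", "NOUN", 3, "nmod"),
        ("harbor", "harbor", "VERB", 0, "root"),
        ("on", "on", "ADP", 11, "case"),
        ("their", "their", "PRON", 11, "nmod:poss"),
        ("Ri-plasmid", "Ri-plasmid", "PROPN", 8, "obl"),
        ("two", "two", "NUM", 13, "nummod"),
        ("T-DNAs", "T-DNA", "NOUN", 8, "obj"),
        (",", ",", "PUNCT", 13, "punct"),
        ("a", "a", "DET", 17, "det"),
        ("left", "left", "ADJ", 17, "amod"),
        ("TL-DNA", "TL-DNA", "NOUN", 13, "appos"),
        ("and", "and", "CCONJ", 21, "cc"),
        ("a", "a", "DET", 21, "det"),
        ("right", "right", "ADJ", 21, "amod"),
        ("TR-DNA", "TR-DNA", "NOUN", 17, "conj"),
        (".", ".", "PUNCT", 8, "punct"),
    ])
    b.sentence([
        ("The", "the", "DET", 3, "det"),
        ("rolB", "rolB", "PROPN", 3, "compound"),
        ("gene", "gene", "NOUN", 10, "nsubj"),
        ("of", "of", "ADP", 6, "case"),
        ("the", "the", "DET", 6, "det"),
        ("TL-DNA", "TL-DNA", "NOUN", 3, "nmod"),
        ("is", "be", "AUX", 10, "cop"),
        ("the", "the", "DET", 10, "det"),
        ("major", "major", "ADJ", 10, "amod"),
        ("factor", "factor", "NOUN", 0, "root"),
        ("in", "in", "ADP", 13, "case"),
        ("the", "the", "DET", 13, "det"),
        ("pathogenesis", "pathogenesis", "NOUN", 10, "nmod"),
        ("of", "of", "ADP", 17, "case"),
        ("the", "the", "DET", 17, "det"),
        ("hairy-root", "hairy-root", "NOUN", 17, "compound"),
        ("disease", "disease", "NOUN", 13, "nmod"),
        ("and", "and", "CCONJ", 22, "cc"),
        ("its", "its", "PRON", 21, "nmod:poss"),
        ("constitutive", "constitutive", "ADJ", 21, "amod"),
        ("expression", "expression", "NOUN", 22, "nsubj"),
        ("interfere", "interfere", "VERB", 10, "conj"),
        ("profoundly", "profoundly", "ADV", 22, "advmod"),
        ("with", "with", "ADP", 26, "case"),
        ("plant", "plant", "NOUN", 26, "compound"),
        ("morphogenesis", "morphogenesis", "NOUN", 22, "obl"),
        (".", ".", "PUNCT", 10, "punct"),
    ])
    b.mention("T1", "Bacteria", (0, 0, 1))
    b.mention("T2", "Habitat", (1, 15, 15))
    b.mention("T3", "Habitat", (1, 24, 24))
    b.event("T1", "T3")
    return b.build()


def _mrsa_correctional() -> AnnotatedDocument:
    """Long noun-phrase distances no pattern spans: both gold events are missed."""
    b = DocBuilder("mrsa-correctional")
    b.sentence([
        ("Finding", "find", "VERB", 17, "csubj"),
        ("MRSA-contaminated", "MRSA-contaminated", "ADJ", 3, "amod"),
        ("surfaces", "surface", "NOUN", 1, "obj"),
        ("on", "on", "ADP", 6, "case"),
        ("a", "a", "DET", 6, "det"),
        ("variety", "variety", "NOUN", 3, "nmod"),
        ("of", "of", "ADP", 9, "case"),
        ("environmental", "environmental", "ADJ", 9, "amod"),
        ("surfaces", "surface", "NOUN", 6, "nmod"),
        ("in", "in", "ADP", 12, "case"),
        ("the", "the", "DET", 12, "det"),
        ("absence", "absence", "NOUN", 1, "obl"),
        ("of", "of", "ADP", 16, "case"),
        ("an", "a", "DET", 16, "det"),
        ("overt", "overt", "ADJ", 16, "amod"),
        ("outbreak", "outbreak", "NOUN", 12, "nmod"),
        ("emphasizes", "emphasize", "VERB", 0, "root"),
        ("that", "that", "SCONJ", 22, "mark"),
        ("correctional", "correctional", "ADJ", 20, "amod"),
        ("facilities", "facility", "NOUN", 22, "nsubj"),
        ("should", "should", "AUX", 22, "aux"),
        ("have", "have", "VERB", 17, "ccomp"),
        ("protocols", "protocol", "NOUN", 22, "obj"),
        ("for", "for", "ADP", 26, "case"),
        ("environmental", "environmental", "ADJ", 26, "amod"),
        ("cleaning", "cleaning", "NOUN", 23, "nmod"),
        ("as", "as", "ADP", 29, "case"),
        ("a", "a", "DET", 29, "det"),
        ("component", "component", "NOUN", 22, "obl"),
        ("of", "of", "ADP", 32, "case"),
        ("MRSA", "MRSA", "PROPN", 32, "compound"),
        ("prevention", "prevention", "NOUN", 29, "nmod"),
        (".", ".", "PUNCT", 17, "punct"),
    ])
    b.mention("T1", "Bacteria", (0, 1, 1), char_slice=(0, 4))
    b.mention("T2", "Habitat", (0, 18, 19))
    b.mention("T3", "Bacteria", (0, 30, 30))
    b.event("T1", "T2")
    b.event("T3", "T2")
    return b.build()


def _tortoise_mycoplasma() -> AnnotatedDocument:
    """P2 plus coordination propagation; an if-clause shields the last location."""
    b = DocBuilder("tortoise-mycoplasma")
    b.sentence([
        ("Collectively", "collectively", "ADV", 5, "advmod"),
        (",", ",", "PUNCT", 5, "punct"),
        ("these", "this", "DET", 4, "det"),
        ("data", "data", "NOUN", 5, "nsubj"),
        ("indicate", "indicate", "VERB", 0, "root"),
        ("that", "that", "SCONJ", 14, "mark"),
        ("both", "both", "CCONJ", 9, "cc:preconj"),
        ("M.", "M.", "PROPN", 9, "compound"),
        ("agassizii", "agassizii", "PROPN", 14, "nsubj"),
        ("and", "and", "CCONJ", 12, "cc"),
        ("M.", "M.", "PROPN", 12, "compound"),
        ("testudineum", "testudineum", "PROPN", 9, "conj"),
        ("are", "be", "AUX", 14, "cop"),
        ("present", "present", "ADJ", 5, "ccomp"),
        ("in", "in", "ADP", 17, "case"),
        ("Georgia", "Georgia", "PROPN", 17, "compound"),
        ("populations", "population", "NOUN", 14, "obl"),
        ("of", "of", "ADP", 20, "case"),
        ("gopher", "gopher", "NOUN", 20, "compound"),
        ("tortoises", "tortoise", "NOUN", 17, "nmod"),
        ("and", "and", "CCONJ", 26, "cc"),
        ("that", "that", "SCONJ", 26, "mark"),
        ("clinical", "clinical", "ADJ", 24, "amod"),
        ("disease", "disease", "NOUN", 26, "nsubj"),
        ("is", "be", "AUX", 26, "cop"),
        ("apparent", "apparent", "ADJ", 14, "conj"),
        ("in", "in", "ADP", 28, "case"),
        ("populations", "population", "NOUN", 26, "obl"),
        ("where", "where", "ADV", 33, "advmod"),
        ("both", "both", "DET", 31, "det"),
        ("pathogens", "pathogen", "NOUN", 33, "nsubj"),
        ("are", "be", "AUX", 33, "cop"),
        ("present", "present", "ADJ", 28, "acl:relcl"),
        (".", ".", "PUNCT", 5, "punct"),
    ])
    b.sentence([
        ("Additional", "additional", "ADJ", 2, "amod"),
        ("research", "research", "NOUN", 4, "nsubj:pass"),
        ("is", "be", "AUX", 4, "aux:pass"),
        ("needed", "need", "VERB", 0, "root"),
        ("to", "to", "PART", 7, "mark"),
        ("better", "better", "ADV", 7, "advmod"),
        ("understand", "understand", "VERB", 4, "xcomp"),
        ("the", "the", "DET", 9, "det"),
        ("role", "role", "NOUN", 7, "obj"),
        ("of", "of", "ADP", 13, "case"),
        ("these", "this", "DET", 13, "det"),
        ("two", "two", "NUM", 13, "nummod"),
        ("pathogens", "pathogen", "NOUN", 9, "nmod"),
        (",", ",", "PUNCT", 18, "punct"),
        ("and", "and", "CCONJ", 18, "cc"),
        ("other", "other", "ADJ", 18, "amod"),
        ("potential", "potential", "ADJ", 18, "amod"),
        ("pathogens", "pathogen", "NOUN", 13, "conj"),
        (",", ",", "PUNCT", 13, "punct"),
        ("in", "in", "ADP", 23, "case"),
        ("the", "the", "DET", 23, "det"),
        ("overall", "overall", "ADJ", 23, "amod"),
        ("health", "health", "NOUN", 9, "nmod"),
        ("of", "of", "ADP", 26, "case"),
        ("tortoise", "tortoise", "NOUN", 26, "compound"),
        ("populations", "population", "NOUN", 23, "nmod"),
        (",", ",", "PUNCT", 4, "punct"),
        ("especially", "especially", "ADV", 33, "advmod"),
        ("if", "if", "SCONJ", 33, "mark"),
        ("future", "future", "ADJ", 32, "amod"),
        ("conservation", "conservation", "NOUN", 32, "compound"),
        ("efforts", "effort", "NOUN", 33, "nsubj"),
        ("involve", "involve", "VERB", 4, "advcl"),
        ("translocation", "translocation", "NOUN", 33, "obj"),
        ("of", "of", "ADP", 36, "case"),
        ("tortoises", "tortoise", "NOUN", 34, "nmod"),
        (".", ".", "PUNCT", 4, "punct"),
    ])
    b.mention("T1", "Bacteria", (0, 7, 8))
    b.mention("T2", "Bacteria", (0, 10, 11))
    b.mention("T3", "Habitat", (0, 15, 19))
    b.mention("T4", "Habitat", (1, 24, 25))
    b.mention("T5", "Habitat", (1, 35, 35))
    b.event("T1", "T3")
    b.event("T2", "T3")
    return b.build()


def _tularensis_goal() -> AnnotatedDocument:
    """A research-goal infinitive puts every mention in hypothesis scope."""
    b = DocBuilder("tularensis-goal")
    b.sentence([
        ("To", "to", "PART", 2, "mark"),
        ("evaluate", "evaluate", "VERB", 0, "root"),
        ("the", "the", "DET", 5, "det"),
        ("growth", "growth", "NOUN", 5, "compound"),
        ("potential", "potential", "NOUN", 2, "obj"),
        ("of", "of", "ADP", 10, "case"),
        ("F.", "F.", "PROPN", 8, "compound"),
        ("tularensis", "tularensis", "PROPN", 9, "compound"),
        ("LVS", "LVS", "PROPN", 10, "compound"),
        ("strain", "strain", "NOUN", 5, "nmod"),
        ("in", "in", "ADP", 14, "case"),
        ("macrophage-like", "macrophage-like", "ADJ", 14, "amod"),
        ("cell", "cell", "NOUN", 14, "compound"),
        ("line", "line", "NOUN", 10, "nmod"),
        ("J774", "J774", "PROPN", 14, "appos"),
        ("modulated", "modulate", "VERB", 14, "acl"),
        ("by", "by", "ADP", 18, "case"),
        ("cytokines", "cytokine", "NOUN", 16, "obl"),
        (".", ".", "PUNCT", 2, "punct"),
    ])
    b.mention("T1", "Bacteria", (0, 6, 8))
    b.mention("T2", "Habitat", (0, 11, 14))
    return b.build()


def _pyogenes_host_cell() -> AnnotatedDocument:
    """Negated predicate ("is not ... understood") shields its arguments."""
    b = DocBuilder("pyogenes-host-cell")
    b.sentence([
        ("The", "the", "DET", 2, "det"),
        ("interaction", "interaction", "NOUN", 14, "nsubj"),
        ("between", "between", "ADP", 5, "case"),
        ("Streptococcus", "Streptococcus", "PROPN", 5, "compound"),
        ("pyogenes", "pyogenes", "PROPN", 2, "nmod"),
        ("and", "and", "CCONJ", 10, "cc"),
        ("the", "the", "DET", 10, "det"),
        ("host", "host", "NOUN", 9, "compound"),
        ("cell", "cell", "NOUN", 10, "compound"),
        ("surface", "surface", "NOUN", 5, "conj"),
        ("is", "be", "AUX", 14, "aux:pass"),
        ("not", "not", "PART", 14, "advmod"),
        ("completely", "completely", "ADV", 14, "advmod"),
        ("understood", "understand", "VERB", 0, "root"),
        (".", ".", "PUNCT", 14, "punct"),
    ])
    b.mention("T1", "Bacteria", (0, 3, 4))
    b.mention("T2", "Habitat", (0, 7, 8))
    return b.build()


def _salmonicida_sediments() -> AnnotatedDocument:
    """Determiner negation ("No ...") blocks an otherwise clean P2 match."""
    b = DocBuilder("salmonicida-sediments")
    b.sentence([
        ("No", "no", "DET", 3, "det"),
        ("V.", "V.", "PROPN", 3, "compound"),
        ("salmonicida", "salmonicida", "PROPN", 6, "nsubj:pass"),
        ("could", "could", "AUX", 6, "aux"),
        ("be", "be", "AUX", 6, "aux:pass"),
        ("detected", "detect", "VERB", 0, "root"),
        ("in", "in", "ADP", 8, "case"),
        ("sediments", "sediment", "NOUN", 6, "obl"),
        (".", ".", "PUNCT", 6, "punct"),
    ])
    b.mention("T1", "Bacteria", (0, 1, 2))
    b.mention("T2", "Habitat", (0, 7, 7))
    return b.build()


def _kingae_colonized_children() -> AnnotatedDocument:
    """"None of the <location>" holds a true event the negation rule discards."""
    b = DocBuilder("kingae-colonized-children")
    b.sentence([
        ("None", "none", "PRON", 6, "nsubj"),
        ("of", "of", "ADP", 5, "case"),
        ("the", "the", "DET", 5, "det"),
        ("colonized", "colonized", "ADJ", 5, "amod"),
        ("children", "child", "NOUN", 1, "nmod"),
        ("experienced", "experience", "VERB", 0, "root"),
        ("an", "a", "DET", 11, "det"),
        ("invasive", "invasive", "ADJ", 11, "amod"),
        ("K.", "K.", "PROPN", 10, "compound"),
        ("kingae", "kingae", "PROPN", 11, "compound"),
        ("infection", "infection", "NOUN", 6, "obj"),
        (".", ".", "PUNCT", 6, "punct"),
    ])
    b.mention("T1", "Bacteria", (0, 8, 9))
    b.mention("T2", "Habitat", (0, 3, 4))
    b.event("T1", "T2")
    return b.build()


def _aquaeolei_subterranean() -> AnnotatedDocument:
    """Trigger linked to the nearest bacterium picks the wrong antecedent."""
    b = DocBuilder("aquaeolei-subterranean")
    b.sentence([
        ("Although", "although", "SCONJ", 7, "mark"),
        ("A.", "A.", "PROPN", 3, "compound"),
        ("aquaeolei", "aquaeolei", "PROPN", 7, "nsubj"),
        ("is", "be", "AUX", 7, "aux:pass"),
        ("most", "most", "ADV", 6, "advmod"),
        ("closely", "closely", "ADV", 7, "advmod"),
        ("related", "relate", "VERB", 25, "advcl"),
        ("to", "to", "ADP", 11, "case"),
        ("purple", "purple", "ADJ", 11, "amod"),
        ("sulfur", "sulfur", "NOUN", 11, "compound"),
        ("bacteria", "bacteria", "NOUN", 7, "obl"),
        ("(", "(", "PUNCT", 14, "punct"),
        ("the", "the", "DET", 14, "det"),
        ("genera", "genus", "NOUN", 11, "appos"),
        ("Ectothiorhodospira", "Ectothiorhodospira", "PROPN", 14, "appos"),
        ("and", "and", "CCONJ", 17, "cc"),
        ("Chromatium", "Chromatium", "PROPN", 15, "conj"),
        (")", ")", "PUNCT", 14, "punct"),
        (",", ",", "PUNCT", 25, "punct"),
        ("it", "it", "PRON", 25, "nsubj"),
        ("is", "be", "AUX", 25, "cop"),
        ("not", "not", "PART", 25, "advmod"),
        ("a", "a", "DET", 25, "det"),
        ("phototrophic", "phototrophic", "ADJ", 25, "amod"),
        ("microorganism", "microorganism", "NOUN", 0, "root"),
        (",", ",", "PUNCT", 29, "punct"),
        ("which", "which", "PRON", 29, "nsubj"),
        ("is", "be", "AUX", 29, "cop"),
        ("consistent", "consistent", "ADJ", 25, "acl:relcl"),
        ("with", "with", "ADP", 32, "case"),
        ("its", "its", "PRON", 32, "nmod:poss"),
        ("isolation", "isolation", "NOUN", 29, "obl"),
        ("from", "from", "ADP", 36, "case"),
        ("a", "a", "DET", 36, "det"),
        ("subterranean", "subterranean", "ADJ", 36, "amod"),
        ("environment", "environment", "NOUN", 32, "nmod"),
        (".", ".", "PUNCT", 25, "punct"),
    ])
    b.mention("T1", "Bacteria", (0, 1, 2))
    b.mention("T2", "Bacteria", (0, 8, 10))
    b.mention("T3", "Bacteria", (0, 14, 14))
    b.mention("T4", "Bacteria", (0, 16, 16))
    b.mention("T5", "Habitat", (0, 23, 24))
    b.mention("T6", "Habitat", (0, 34, 35))
    b.event("T1", "T6")
    return b.build()


def _aeruginosa_hcn() -> AnnotatedDocument:
    """Several triggers in one window; two correct events plus one documented extra."""
    b = DocBuilder("aeruginosa-hcn")
    b.sentence([
        ("We", "we", "PRON", 2, "nsubj"),
        ("present", "present", "VERB", 0, "root"),
        ("the", "the", "DET", 5, "det"),
        ("real-time", "real-time", "ADJ", 5, "amod"),
        ("monitoring", "monitoring", "NOUN", 2, "obj"),
        ("of", "of", "ADP", 12, "case"),
        ("hydrogen", "hydrogen", "NOUN", 8, "compound"),
        ("cyanide", "cyanide", "NOUN", 12, "compound"),
        ("(", "(", "PUNCT", 10, "punct"),
        ("HCN", "HCN", "PROPN", 8, "appos"),
        (")", ")", "PUNCT", 10, "punct"),
        ("production", "production", "NOUN", 5, "nmod"),
        ("from", "from", "ADP", 20, "case"),
        ("Pseudomonas", "Pseudomonas", "PROPN", 15, "compound"),
        ("aeruginosa", "aeruginosa", "PROPN", 20, "compound"),
        ("(", "(", "PUNCT", 18, "punct"),
        ("P.", "P.", "PROPN", 18, "compound"),
        ("aeruginosa", "aeruginosa", "PROPN", 15, "appos"),
        (")", ")", "PUNCT", 18, "punct"),
        ("strains", "strain", "NOUN", 12, "nmod"),
        ("in", "in", "ADP", 22, "case"),
        ("vitro", "vitro", "X", 20, "nmod"),
        (",", ",", "PUNCT", 2, "punct"),
        ("using", "use", "VERB", 2, "advcl"),
        ("laser-based", "laser-based", "ADJ", 27, "amod"),
        ("photoacoustic", "photoacoustic", "ADJ", 27, "amod"),
        ("spectroscopy", "spectroscopy", "NOUN", 24, "obj"),
        (".", ".", "PUNCT", 2, "punct"),
    ])
    b.sentence([
        ("Both", "both", "CCONJ", 3, "cc:preconj"),
        ("reference", "reference", "NOUN", 3, "compound"),
        ("strains", "strain", "NOUN", 12, "nsubj:pass"),
        ("and", "and", "CCONJ", 6, "cc"),
        ("clinical", "clinical", "ADJ", 6, "amod"),
        ("isolates", "isolate", "NOUN", 3, "conj"),
        ("of", "of", "ADP", 8, "case"),
        ("patients", "patient", "NOUN", 6, "nmod"),
        ("with", "with", "ADP", 10, "case"),
        ("CF", "CF", "PROPN", 8, "nmod"),
        ("were", "be", "AUX", 12, "aux:pass"),
        ("studied", "study", "VERB", 0, "root"),
        (",", ",", "PUNCT", 15, "punct"),
        ("and", "and", "CCONJ", 15, "cc"),
        ("compared", "compare", "VERB", 12, "conj"),
        ("to", "to", "ADP", 18, "case"),
        ("other", "other", "ADJ", 18, "amod"),
        ("pathogens", "pathogen", "NOUN", 15, "obl"),
        ("commonly", "commonly", "ADV", 20, "advmod"),
        ("present", "present", "ADJ", 18, "acl"),
        ("in", "in", "ADP", 22, "case"),
        ("lungs/airways", "lungs/airways", "NOUN", 20, "obl"),
        ("of", "of", "ADP", 25, "case"),
        ("CF", "CF", "PROPN", 25, "compound"),
        ("patients", "patient", "NOUN", 22, "nmod"),
        (".", ".", "PUNCT", 12, "punct"),
    ])
    b.mention("T1", "Bacteria", (0, 13, 14))
    b.mention("T2", "Habitat", (1, 4, 4))
    b.mention("T3", "Habitat", (1, 7, 9))
    b.mention("T4", "Habitat", (1, 21, 24))
    b.event("T1", "T2")
    b.event("T1", "T3")
    return b.build()


def _mrsa_snf() -> AnnotatedDocument:
    """Candidate restrictions keep a screening-sample location out of events."""
    b = DocBuilder("mrsa-snf")
    b.sentence([
        ("Prospective", "prospective", "ADJ", 4, "amod"),
        ("screening", "screening", "NOUN", 4, "compound"),
        ("culture", "culture", "NOUN", 4, "compound"),
        ("surveillance", "surveillance", "NOUN", 14, "nsubj:pass"),
        ("for", "for", "ADP", 6, "case"),
        ("MRSA", "MRSA", "PROPN", 4, "nmod"),
        ("among", "among", "ADP", 8, "case"),
        ("patients", "patient", "NOUN", 6, "nmod"),
        ("in", "in", "ADP", 12, "case"),
        ("a", "a", "DET", 12, "det"),
        ("community", "community", "NOUN", 12, "compound"),
        ("SNF", "SNF", "PROPN", 8, "nmod"),
        ("was", "be", "AUX", 14, "aux:pass"),
        ("performed", "perform", "VERB", 0, "root"),
        (".", ".", "PUNCT", 14, "punct"),
    ])
    b.sentence([
        ("Nares", "nares", "NOUN", 7, "nsubj:pass"),
        ("and", "and", "CCONJ", 5, "cc"),
        ("stool", "stool", "NOUN", 5, "compound"),
        ("swab", "swab", "NOUN", 5, "compound"),
        ("cultures", "culture", "NOUN", 1, "conj"),
        ("were", "be", "AUX", 7, "aux:pass"),
        ("obtained", "obtain", "VERB", 0, "root"),
        ("from", "from", "ADP", 11, "case"),
        ("newly", "newly", "ADV", 10, "advmod"),
        ("admitted", "admitted", "ADJ", 11, "amod"),
        ("patients", "patient", "NOUN", 7, "obl"),
        (".", ".", "PUNCT", 7, "punct"),
    ])
    b.sentence([
        ("MRSA", "MRSA", "PROPN", 3, "nsubj:pass"),
        ("were", "be", "AUX", 3, "aux:pass"),
        ("isolated", "isolate", "VERB", 0, "root"),
        ("by", "by", "ADP", 7, "case"),
        ("oxacillin", "oxacillin", "NOUN", 7, "compound"),
        ("screening", "screening", "NOUN", 7, "compound"),
        ("agar", "agar", "NOUN", 3, "obl"),
        (".", ".", "PUNCT", 3, "punct"),
    ])
    b.mention("T1", "Bacteria", (0, 5, 5))
    b.mention("T2", "Habitat", (0, 7, 7))
    b.mention("T3", "Habitat", (1, 0, 4))
    b.mention("T4", "Habitat", (1, 10, 10))
    b.mention("T5", "Bacteria", (2, 0, 0))
    b.mention("T6", "Habitat", (2, 4, 6))
    b.event("T1", "T2")
    b.event("T5", "T3")
    b.event("T5", "T6")
    return b.build()


def _marcescens_biofilm() -> AnnotatedDocument:
    """Hypothesis scopes are per-token: one "adhesion" is blocked, the other is not."""
    b = DocBuilder("marcescens-biofilm")
    b.sentence([
        ("In", "in", "ADP", 3, "case"),
        ("previous", "previous", "ADJ", 3, "amod"),
        ("studies", "study", "NOUN", 10, "obl"),
        ("of", "of", "ADP", 7, "case"),
        ("S.", "S.", "PROPN", 6, "compound"),
        ("marcescens", "marcescens", "PROPN", 7, "compound"),
        ("MG1", "MG1", "PROPN", 3, "nmod"),
        (",", ",", "PUNCT", 10, "punct"),
        ("we", "we", "PRON", 10, "nsubj"),
        ("showed", "show", "VERB", 0, "root"),
        ("that", "that", "SCONJ", 15, "mark"),
        ("biofilm", "biofilm", "NOUN", 13, "compound"),
        ("maturation", "maturation", "NOUN", 15, "nsubj:pass"),
        ("was", "be", "AUX", 15, "aux:pass"),
        ("regulated", "regulate", "VERB", 10, "ccomp"),
        (".", ".", "PUNCT", 10, "punct"),
    ])
    b.sentence([
        ("Because", "because", "ADP", 4, "case"),
        ("of", "of", "ADP", 4, "case"),
        ("the", "the", "DET", 4, "det"),
        ("importance", "importance", "NOUN", 20, "obl"),
        ("of", "of", "ADP", 6, "case"),
        ("adhesion", "adhesion", "NOUN", 4, "nmod"),
        ("in", "in", "SCONJ", 8, "mark"),
        ("initiating", "initiate", "VERB", 6, "acl"),
        ("biofilm", "biofilm", "NOUN", 10, "compound"),
        ("formation", "formation", "NOUN", 8, "obj"),
        ("and", "and", "CCONJ", 12, "cc"),
        ("infection", "infection", "NOUN", 10, "conj"),
        (",", ",", "PUNCT", 20, "punct"),
        ("the", "the", "DET", 16, "det"),
        ("primary", "primary", "ADJ", 16, "amod"),
        ("goal", "goal", "NOUN", 20, "nsubj"),
        ("of", "of", "ADP", 19, "case"),
        ("this", "this", "DET", 19, "det"),
        ("study", "study", "NOUN", 16, "nmod"),
        ("was", "be", "VERB", 0, "root"),
        ("to", "to", "PART", 22, "mark"),
        ("determine", "determine", "VERB", 20, "xcomp"),
        ("whether", "whether", "SCONJ", 26, "mark"),
        ("QS", "QS", "PROPN", 26, "nsubj"),
        ("is", "be", "AUX", 26, "cop"),
        ("important", "important", "ADJ", 22, "ccomp"),
        ("in", "in", "ADP", 28, "case"),
        ("adhesion", "adhesion", "NOUN", 26, "obl"),
        ("to", "to", "ADP", 34, "case"),
        ("both", "both", "CCONJ", 34, "cc:preconj"),
        ("abiotic", "abiotic", "ADJ", 34, "amod"),
        ("and", "and", "CCONJ", 33, "cc"),
        ("biotic", "biotic", "ADJ", 31, "conj"),
        ("surfaces", "surface", "NOUN", 28, "nmod"),
        (".", ".", "PUNCT", 20, "punct"),
    ])
    b.mention("T1", "Bacteria", (0, 4, 6))
    b.mention("T2", "Habitat", (0, 11, 11))
    b.mention("T3", "Habitat", (1, 8, 8))
    b.mention("T4", "Habitat", (1, 30, 33))
    b.event("T1", "T2")
    b.event("T1", "T3")
    return b.build()


_BUILDERS = {
    "kingae-pharyngeal": _kingae_pharyngeal,
    "rhizogenes-tdna": _rhizogenes_tdna,
    "mrsa-correctional": _mrsa_correctional,
    "tortoise-mycoplasma": _tortoise_mycoplasma,
    "tularensis-goal": _tularensis_goal,
    "pyogenes-host-cell": _pyogenes_host_cell,
    "salmonicida-sediments": _salmonicida_sediments,
    "kingae-colonized-children": _kingae_colonized_children,
    "aquaeolei-subterranean": _aquaeolei_subterranean,
    "aeruginosa-hcn": _aeruginosa_hcn,
    "mrsa-snf": _mrsa_snf,
    "marcescens-biofilm": _marcescens_biofilm,
}


def curated_example(doc_id: str) -> AnnotatedDocument:
    """One curated document by id (see :func:`load_curated_examples`)."""
    try:
        return _BUILDERS[doc_id]()
    except KeyError:
        raise KeyError(
            f"unknown curated example {doc_id!r}; available: {sorted(_BUILDERS)}"
        ) from None


def load_curated_examples() -> list[AnnotatedDocument]:
    """All curated documents, in a stable order."""
    return [build() for _, build in sorted(_BUILDERS.items())]
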