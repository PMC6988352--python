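"""Seeded synthetic corpora exercising each extraction mechanism in isolation.

Every template renders one miniature document (text, entities, gold events,
and a gold dependency parse) around a single mechanism: one of the trigger
patterns P1-P3, the noun-phrase configurations N1-N3, one propagation rule
R1-R5, a cross-sentence trigger inference, or a hypothesis scope that must
suppress all events.  Gold events record the relation the construction
expresses, so a correct extractor scores perfect precision and recall per
template; corpora are deterministic given the seed.

These corpora validate mechanics, not corpus-level accuracy: the sentences
are short, unambiguous, and parse-perfect by construction, so scores on them
say nothing about performance on natural abstracts.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Callable, Optional

from bbct.docbuild import DocBuilder, Tok, assemble
from bbct.examples import curated_example, load_curated_examples  # re-export  # noqa: F401
from bbct.standoff import AnnotatedDocument

BACTERIA_NAMES = [
    "Helicobacter pylori",
    "Escherichia coli",
    "Listeria monocytogenes",
    "Vibrio cholerae",
    "Borrelia burgdorferi",
    "Campylobacter jejuni",
    "Yersinia pestis",
    "Bacillus subtilis",
]

HABITAT_PHRASES = [
    "respiratory tract",
    "human gut",
    "chicken caecum",
    "marine sediment",
    "dairy cattle",
]

HABITAT_ADJECTIVES = ["pharyngeal", "intestinal", "nasal", "gastric"]

HOST_ADJECTIVES = ["fish", "plant", "human", "insect"]

MEDIA_PAIRS = [
    ("tryptic soy broth", "nutrient broth"),
    ("brain heart infusion", "nutrient agar"),
    ("potato dextrose agar", "blood agar"),
]

SURFACE_PAIRS = [("apple", "lettuce"), ("melon", "spinach"), ("tomato", "parsley")]

GEO_PAIRS = [
    ("Olmsted County", "Minnesota"),
    ("Harris County", "Texas"),
    ("Marin County", "California"),
]

TRAVELER_TRIPLES = [
    ("Israeli", "travelers", "Nepal"),
    ("German", "tourists", "India"),
    ("French", "hikers", "Peru"),
]

CROSS_TRIGGERS = ["carriage", "colonization"]

GOAL_VERBS = ["evaluate", "determine", "assess", "investigate"]


def _chain(name: str, head: int, deprel: str, pos: str = "PROPN") -> list[Tok]:
    """A multi-word name as a compound chain; the last token bears ``deprel``.

    Internal tokens attach to the chain's final token via negative relative
    heads, resolved against absolute positions by :func:`bbct.docbuild.assemble`.
    """
    parts = name.split()
    toks: list[Tok] = []
    for i, part in enumerate(parts):
        if i < len(parts) - 1:
            toks.append((part, part, pos, -(len(parts) - 1 - i), "compound"))
        else:
            toks.append((part, part.lower() if pos == "NOUN" else part, pos, head, deprel))
    return toks


def _noun_chain(phrase: str, head: int, deprel: str) -> list[Tok]:
    return _chain(phrase, head, deprel, pos="NOUN")


# ---------------------------------------------------------------------------
# Templates.  Token heads are 1-based sentence positions computed explicitly.


def _t_p1(rng: random.Random, doc_id: str) -> AnnotatedDocument:
    bact = rng.choice(BACTERIA_NAMES)
    hab = rng.choice(HABITAT_PHRASES)
    nb, nl = len(bact.split()), len(hab.split())
    root = 6 + nb + nl
    b = DocBuilder(doc_id)
    toks: list[Tok] = [
        ("Elimination", "elimination", "NOUN", root, "nsubj:pass"),
        ("of", "of", "ADP", 2 + nb, "case"),
    ]
    toks += _chain(bact, 1, "nmod")
    toks += [
        ("in", "in", "ADP", 4 + nb + nl, "case"),
        ("the", "the", "DET", 4 + nb + nl, "det"),
    ]
    toks += _noun_chain(hab, 1, "nmod")
    toks += [
        ("was", "be", "AUX", root, "aux:pass"),
        ("reported", "report", "VERB", 0, "root"),
        (".", ".", "PUNCT", root, "punct"),
    ]
    b.sentence(assemble(toks))
    b.mention("T1", "Bacteria", (0, 2, 1 + nb))
    b.mention("T2", "Habitat", (0, 4 + nb, 3 + nb + nl))
    b.event("T1", "T2")
    return b.build()


def _t_p2(rng: random.Random, doc_id: str) -> AnnotatedDocument:
    bact = rng.choice(BACTERIA_NAMES)
    hab = rng.choice(HABITAT_PHRASES)
    nb, nl = len(bact.split()), len(hab.split())
    pred = nb + nl + 5  # "common"
    b = DocBuilder(doc_id)
    toks = _chain(bact, nb + 1, "compound")
    toks += [
        ("bacteremia", "bacteremia", "NOUN", pred, "nsubj"),
        ("in", "in", "ADP", nb + 3 + nl, "case"),
        ("the", "the", "DET", nb + 3 + nl, "det"),
    ]
    toks += _noun_chain(hab, nb + 1, "nmod")
    toks += [
        ("was", "be", "AUX", pred, "cop"),
        ("common", "common", "ADJ", 0, "root"),
        (".", ".", "PUNCT", pred, "punct"),
    ]
    b.sentence(assemble(toks))
    b.mention("T1", "Bacteria", (0, 0, nb - 1))
    b.mention("T2", "Habitat", (0, nb + 3, nb + 2 + nl))
    b.event("T1", "T2")
    return b.build()


def _t_p3(rng: random.Random, doc_id: str) -> AnnotatedDocument:
    bact = rng.choice(BACTERIA_NAMES)
    adj = rng.choice(HABITAT_ADJECTIVES)
    trig = rng.choice(CROSS_TRIGGERS)
    nb = len(bact.split())
    pred = nb + 5  # "common"
    b = DocBuilder(doc_id)
    toks: list[Tok] = [
        (adj.capitalize(), adj, "ADJ", 2, "amod"),
        (trig, trig, "NOUN", pred, "nsubj"),
        ("of", "of", "ADP", 3 + nb, "case"),
    ]
    toks += _chain(bact, 2, "nmod")
    toks += [
        ("was", "be", "AUX", pred, "cop"),
        ("common", "common", "ADJ", 0, "root"),
        (".", ".", "PUNCT", pred, "punct"),
    ]
    b.sentence(assemble(toks))
    b.mention("T1", "Habitat", (0, 0, 0))
    b.mention("T2", "Bacteria", (0, 3, 2 + nb))
    b.event("T2", "T1")
    return b.build()


def _t_n1(rng: random.Random, doc_id: str) -> AnnotatedDocument:
    bact = rng.choice(BACTERIA_NAMES)
    host = rng.choice(HOST_ADJECTIVES)
    nb = len(bact.split())
    root = nb + 7  # "confirmed"
    b = DocBuilder(doc_id)
    toks: list[Tok] = [
        ("Presence", "presence", "NOUN", root, "nsubj:pass"),
        ("of", "of", "ADP", 5, "case"),
        ("the", "the", "DET", 5, "det"),
        (host, host, "NOUN", 5, "compound"),
        ("pathogen", "pathogen", "NOUN", 1, "nmod"),
    ]
    toks += _chain(bact, 5, "appos")
    toks += [
        ("was", "be", "AUX", root, "aux:pass"),
        ("confirmed", "confirm", "VERB", 0, "root"),
        (".", ".", "PUNCT", root, "punct"),
    ]
    b.sentence(assemble(toks))
    b.mention("T1", "Habitat", (0, 3, 3))
    b.mention("T2", "Bacteria", (0, 5, 4 + nb))
    b.event("T2", "T1")
    return b.build()


def _t_n2(rng: random.Random, doc_id: str) -> AnnotatedDocument:
    del rng  # fixed wording: the nested-token configuration needs this exact compound
    b = DocBuilder(doc_id)
    verb = "observed"
    b.sentence([
        ("Mtb-infected", "Mtb-infected", "ADJ", 4, "amod"),
        ("human", "human", "ADJ", 4, "amod"),
        ("blood", "blood", "NOUN", 4, "compound"),
        ("monocytes", "monocyte", "NOUN", 6, "nsubj:pass"),
        ("were", "be", "AUX", 6, "aux:pass"),
        (verb, "observe", "VERB", 0, "root"),
        (".", ".", "PUNCT", 6, "punct"),
    ])
    b.mention("T1", "Bacteria", (0, 0, 0), char_slice=(0, 3))
    b.mention("T2", "Habitat", (0, 0, 3))
    b.event("T1", "T2")
    return b.build()


def _t_n3(rng: random.Random, doc_id: str) -> AnnotatedDocument:
    bact = rng.choice(BACTERIA_NAMES)
    hab = rng.choice(HABITAT_PHRASES)
    nb, nl = len(bact.split()), len(hab.split())
    b = DocBuilder(doc_id)
    toks: list[Tok] = [
        ("Resistance", "resistance", "NOUN", 2, "nsubj"),
        ("emerged", "emerge", "VERB", 0, "root"),
        ("in", "in", "ADP", 3 + nb, "case"),
    ]
    toks += _chain(bact, 2, "obl")
    toks += [
        ("in", "in", "ADP", 5 + nb + nl, "case"),
        ("the", "the", "DET", 5 + nb + nl, "det"),
    ]
    toks += _noun_chain(hab, 3 + nb, "nmod")
    toks += [(".", ".", "PUNCT", 2, "punct")]
    b.sentence(assemble(toks))
    b.mention("T1", "Bacteria", (0, 3, 2 + nb))
    b.mention("T2", "Habitat", (0, 5 + nb, 4 + nb + nl))
    b.event("T1", "T2")
    return b.build()


def _t_r1(rng: random.Random, doc_id: str) -> AnnotatedDocument:
    bact = rng.choice(BACTERIA_NAMES)
    first, second = rng.choice(SURFACE_PAIRS)
    nb = len(bact.split())
    found = nb + 2
    surf = nb + 7
    b = DocBuilder(doc_id)
    toks = _chain(bact, found, "nsubj:pass")
    toks += [
        ("was", "be", "AUX", found, "aux:pass"),
        ("found", "find", "VERB", 0, "root"),
        ("on", "on", "ADP", surf, "case"),
        (first, first, "NOUN", surf, "compound"),
        ("and", "and", "CCONJ", nb + 6, "cc"),
        (second, second, "NOUN", nb + 4, "conj"),
        ("surfaces", "surface", "NOUN", found, "obl"),
        (".", ".", "PUNCT", found, "punct"),
    ]
    b.sentence(assemble(toks))
    b.mention("T1", "Bacteria", (0, 0, nb - 1))
    b.mention("T2", "Habitat", (0, nb + 3, nb + 6))  # "<first> and <second> surfaces"
    b.mention("T3", "Habitat", (0, nb + 3, nb + 3))  # "<first>"
    b.mention("T4", "Habitat", (0, nb + 5, nb + 5))  # "<second>"
    b.mention("T5", "Habitat", (0, nb + 3, nb + 3), (0, nb + 6, nb + 6))  # discontinuous
    b.mention("T6", "Habitat", (0, nb + 5, nb + 6))  # "<second> surfaces"
    for loc in ("T2", "T3", "T4", "T5", "T6"):
        b.event("T1", loc)
    return b.build()


def _t_r2(rng: random.Random, doc_id: str) -> AnnotatedDocument:
    bact = rng.choice(BACTERIA_NAMES)
    first, second = rng.choice(MEDIA_PAIRS)
    nb = len(bact.split())
    n1, n2 = len(first.split()), len(second.split())
    grew = nb + 1
    h1 = nb + 2 + n1  # head of the first medium phrase
    h2 = nb + 3 + n1 + n2  # head of the second
    b = DocBuilder(doc_id)
    toks = _chain(bact, grew, "nsubj")
    toks += [
        ("grew", "grow", "VERB", 0, "root"),
        ("in", "in", "ADP", h1, "case"),
    ]
    toks += _noun_chain(first, grew, "obl")
    toks += [("and", "and", "CCONJ", h2, "cc")]
    toks += _noun_chain(second, h1, "conj")
    toks += [(".", ".", "PUNCT", grew, "punct")]
    b.sentence(assemble(toks))
    b.mention("T1", "Bacteria", (0, 0, nb - 1))
    b.mention("T2", "Habitat", (0, nb + 2, nb + 1 + n1))
    b.mention("T3", "Habitat", (0, nb + 3 + n1, nb + 2 + n1 + n2))
    b.event("T1", "T2")
    b.event("T1", "T3")
    return b.build()


def _t_r3(rng: random.Random, doc_id: str) -> AnnotatedDocument:
    b = DocBuilder(doc_id)
    b.sentence([
        ("Methicillin-resistant", "Methicillin-resistant", "ADJ", 3, "amod"),
        ("Staphylococcus", "Staphylococcus", "PROPN", 3, "compound"),
        ("aureus", "aureus", "PROPN", 7, "compound"),
        ("(", "(", "PUNCT", 5, "punct"),
        ("MRSA", "MRSA", "PROPN", 3, "appos"),
        (")", ")", "PUNCT", 5, "punct"),
        ("colonization", "colonization", "NOUN", 17, "nsubj:pass"),
        ("in", "in", "ADP", 12, "case"),
        ("a", "a", "DET", 12, "det"),
        ("skilled", "skilled", "ADJ", 12, "amod"),
        ("nursing", "nursing", "NOUN", 12, "compound"),
        ("facility", "facility", "NOUN", 7, "nmod"),
        ("(", "(", "PUNCT", 14, "punct"),
        ("SNF", "SNF", "PROPN", 12, "appos"),
        (")", ")", "PUNCT", 14, "punct"),
        ("was", "be", "AUX", 17, "aux:pass"),
        ("reported", "report", "VERB", 0, "root"),
        (".", ".", "PUNCT", 17, "punct"),
    ])
    b.mention("T1", "Bacteria", (0, 0, 2))
    b.mention("T2", "Bacteria", (0, 4, 4))
    b.mention("T3", "Habitat", (0, 9, 11))
    b.mention("T4", "Habitat", (0, 13, 13))
    for bact in ("T1", "T2"):
        for loc in ("T3", "T4"):
            b.event(bact, loc)
    return b.build()


def _t_r4(rng: random.Random, doc_id: str) -> AnnotatedDocument:
    bact = rng.choice(BACTERIA_NAMES)
    county, state = rng.choice(GEO_PAIRS)
    nb = len(bact.split())
    nc = len(county.split())
    inf = nb + 1
    county_head = nb + 2 + nc
    root = nb + 6 + nc
    b = DocBuilder(doc_id)
    toks = _chain(bact, inf, "compound")
    toks += [
        ("infection", "infection", "NOUN", root, "nsubj:pass"),
        ("in", "in", "ADP", county_head, "case"),
    ]
    toks += _chain(county, inf, "nmod")
    toks += [
        (",", ",", "PUNCT", county_head, "punct"),
        (state, state, "PROPN", county_head, "nmod"),
        ("was", "be", "AUX", root, "aux:pass"),
        ("reported", "report", "VERB", 0, "root"),
        (".", ".", "PUNCT", root, "punct"),
    ]
    b.sentence(assemble(toks))
    b.mention("T1", "Bacteria", (0, 0, nb - 1))
    b.mention("T2", "Geographical", (0, nb + 2, nb + 1 + nc))
    b.mention("T3", "Geographical", (0, nb + 3 + nc, nb + 3 + nc))
    b.event("T1", "T2")
    b.event("T1", "T3")
    return b.build()


def _t_r5(rng: random.Random, doc_id: str) -> AnnotatedDocument:
    nationality, people, country = rng.choice(TRAVELER_TRIPLES)
    bact = rng.choice(BACTERIA_NAMES)
    nb = len(bact.split())
    bacteremia = nb + 1
    travelers = nb + 4
    root = nb + 9
    b = DocBuilder(doc_id)
    toks = _chain(bact, bacteremia, "compound")
    toks += [
        ("bacteremia", "bacteremia", "NOUN", root, "nsubj:pass"),
        ("in", "in", "ADP", travelers, "case"),
        (nationality, nationality, "ADJ", travelers, "amod"),
        (people, people, "NOUN", bacteremia, "nmod"),
        ("returning", "return", "VERB", travelers, "acl"),
        ("from", "from", "ADP", nb + 7, "case"),
        (country, country, "PROPN", nb + 5, "obl"),
        ("was", "be", "AUX", root, "aux:pass"),
        ("reported", "report", "VERB", 0, "root"),
        (".", ".", "PUNCT", root, "punct"),
    ]
    b.sentence(assemble(toks))
    b.mention("T1", "Bacteria", (0, 0, nb - 1))
    b.mention("T2", "Habitat", (0, nb + 2, nb + 3))
    b.mention("T3", "Geographical", (0, nb + 6, nb + 6))
    b.event("T1", "T2")
    b.event("T1", "T3")
    return b.build()


def _t_cross(rng: random.Random, doc_id: str) -> AnnotatedDocument:
    bact = rng.choice(BACTERIA_NAMES)
    adj = rng.choice(HABITAT_ADJECTIVES)
    trig = rng.choice(CROSS_TRIGGERS)
    nb = len(bact.split())
    inf = nb + 3
    b = DocBuilder(doc_id)
    toks: list[Tok] = [
        ("An", "a", "DET", inf, "det"),
        ("invasive", "invasive", "ADJ", inf, "amod"),
    ]
    toks += _chain(bact, inf, "compound")
    toks += [
        ("infection", "infection", "NOUN", inf + 2, "nsubj:pass"),
        ("was", "be", "AUX", inf + 2, "aux:pass"),
        ("reported", "report", "VERB", 0, "root"),
        (".", ".", "PUNCT", inf + 2, "punct"),
    ]
    b.sentence(assemble(toks))
    b.sentence([
        ("The", "the", "DET", 2, "det"),
        ("prevalence", "prevalence", "NOUN", 9, "nsubj"),
        ("of", "of", "ADP", 5, "case"),
        (adj, adj, "ADJ", 5, "amod"),
        (trig, trig, "NOUN", 2, "nmod"),
        ("among", "among", "ADP", 7, "case"),
        ("patients", "patient", "NOUN", 5, "nmod"),
        ("was", "be", "AUX", 9, "cop"),
        ("high", "high", "ADJ", 0, "root"),
        (".", ".", "PUNCT", 9, "punct"),
    ])
    b.mention("T1", "Bacteria", (0, 2, 1 + nb))
    b.mention("T2", "Habitat", (1, 3, 3))
    b.event("T1", "T2")
    return b.build()


def _t_modality(rng: random.Random, doc_id: str) -> AnnotatedDocument:
    bact = rng.choice(BACTERIA_NAMES)
    hab = rng.choice(HABITAT_PHRASES)
    verb = rng.choice(GOAL_VERBS)
    nb, nl = len(bact.split()), len(hab.split())
    collected = nb + nl + 11
    b = DocBuilder(doc_id)
    toks: list[Tok] = [
        ("To", "to", "PART", 2, "mark"),
        (verb, verb, "VERB", collected, "advcl"),
        ("the", "the", "DET", 4, "det"),
        ("elimination", "elimination", "NOUN", 2, "obj"),
        ("of", "of", "ADP", 5 + nb, "case"),
    ]
    toks += _chain(bact, 4, "nmod")
    toks += [
        ("in", "in", "ADP", 7 + nb + nl, "case"),
        ("the", "the", "DET", 7 + nb + nl, "det"),
    ]
    toks += _noun_chain(hab, 4, "nmod")
    toks += [
        (",", ",", "PUNCT", collected, "punct"),
        ("samples", "sample", "NOUN", collected, "nsubj:pass"),
        ("were", "be", "AUX", collected, "aux:pass"),
        ("collected", "collect", "VERB", 0, "root"),
        (".", ".", "PUNCT", collected, "punct"),
    ]
    b.sentence(assemble(toks))
    b.mention("T1", "Bacteria", (0, 5, 4 + nb))
    b.mention("T2", "Habitat", (0, 7 + nb, 6 + nb + nl))
    return b.build()


TEMPLATES: dict[str, Callable[[random.Random, str], AnnotatedDocument]] = {
    "p1-elimination": _t_p1,
    "p2-bacteremia": _t_p2,
    "p3-carriage": _t_p3,
    "n1-apposed-pathogen": _t_n1,
    "n2-nested-token": _t_n2,
    "n3-prep-link": _t_n3,
    "r1-nesting": _t_r1,
    "r2-coordination": _t_r2,
    "r3-apposition": _t_r3,
    "r4-geo-comma": _t_r4,
    "r5-participle": _t_r5,
    "cross-trigger": _t_cross,
    "modality-negative": _t_modality,
}


@dataclass
class FixtureConfig:
    """Deterministic synthetic-corpus recipe."""

    seed: int
    n_docs: int = 65
    templates: Optional[list[str]] = field(default=None)

    def active_templates(self) -> list[str]:
        names = self.templates if self.templates is not None else sorted(TEMPLATES)
        unknown = [n for n in names if n not in TEMPLATES]
        if unknown:
            raise ValueError(f"unknown templates: {unknown}; known: {sorted(TEMPLATES)}")
        return list(names)


def generate_corpus(config: FixtureConfig) -> list[AnnotatedDocument]:
    """Generate ``config.n_docs`` template documents, cycling through templates.

    Templates are visited round-robin (so every mechanism is represented) with
    seeded random vocabulary; the same config always yields the same corpus.
    """
    rng = random.Random(config.seed)
    names = config.active_templates()
    docs = []
    for i in range(config.n_docs):
        name = names[i % len(names)]
        docs.append(TEMPLATES[name](rng, f"{name}-{i:03d}"))
    return docs
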