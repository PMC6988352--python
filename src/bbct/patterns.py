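"""Dependency configurations shared by trigger mining and intra-clause extraction.

Three trigger patterns anchor on a bacteria mention (or, during inference, on a
context-trigger token standing in for one):

* P1  ``{noun} of [bacteria] loc_prep [location]`` — "elimination of
  Helicobacter pylori in the antrum"
* P2  ``[bacteria] {n/v/p} loc_prep [location]`` — "Non-O1 Vibrio cholerae
  bacteremia in patients with cirrhosis"
* P3  ``[location] {n/v/p} prep [bacteria]`` — "Respiratory carriage of
  Kingella kingae"

During lexicon mining the ``[location]`` slot is unconstrained: a locational
preposition alone is taken to imply a location, so plain unannotated text can
be mined.  During event extraction the slot must be an annotated location
mention.  Three further intra-clause patterns relate an anchor directly to a
location mention: noun-phrase co-nesting (N1), span nesting (N2), and a direct
prepositional link (N3).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from bbct.syntax import SentenceParse

#: locational prepositions the source patterns restrict P1/P2 to
LOC_PREPS = frozenset({"in", "on", "to", "from", "at"})
#: optional extended set (config flag), off by default
LOC_PREPS_EXTENDED = LOC_PREPS | frozenset({"within", "into", "onto"})

NOMINAL_POS = frozenset({"NOUN", "PROPN"})
#: {n/v/p}: noun, verb, or participle (participles surface as VERB or ADJ in UD)
ANCHOR_POS = frozenset({"NOUN", "PROPN", "VERB", "ADJ"})
#: relations internal to one noun phrase (for P3 modifiers and N1 co-nesting)
NP_RELATIONS = frozenset(
    {"amod", "compound", "flat", "nummod", "det", "appos", "nmod:poss"}
)
#: arc labels that do not count as a direct content link for P2
_NON_CONTENT = frozenset({"case", "punct", "cc", "mark", "det", "aux", "cop"})


@dataclass(frozen=True)
class PatternHit:
    pattern: str  # P1 | P2 | P3
    trigger_token: int  # the {noun} / {n/v/p} slot filler
    location_head: Optional[int]  # None when the location slot is unconstrained


def prep_objects(sent: SentenceParse, head: int) -> list[tuple[str, int]]:
    """(preposition lemma, object token) pairs governed by ``head`` via nmod/obl."""
    out = []
    for dep, label in sent.children(head):
        if label.split(":")[0] not in {"nmod", "obl"}:
            continue
        for case_tok, case_label in sent.children(dep):
            if case_label == "case" and sent.tokens[case_tok].pos == "ADP":
                out.append((sent.tokens[case_tok].lemma.lower(), dep))
    return out


def direct_arc(sent: SentenceParse, a: int, b: int) -> Optional[str]:
    """Label of the arc directly connecting tokens a and b, if any."""
    for head, dep, label in sent.arcs:
        if {head, dep} == {a, b}:
            return label
    return None


def np_connected(sent: SentenceParse, a: int, b: int) -> bool:
    """True when a and b sit in one noun phrase (path uses NP-internal arcs only)."""
    if a == b:
        return True
    return all(
        label.split(":")[0] in NP_RELATIONS or label in NP_RELATIONS
        for _, _, label in sent.path(a, b)
    )


def match_anchor_patterns(
    sent: SentenceParse,
    anchor_tokens: frozenset[int],
    anchor_head: int,
    location_heads: Optional[dict[int, str]] = None,
    loc_preps: frozenset[str] = LOC_PREPS,
) -> list[PatternHit]:
    """Match P1/P2/P3 around one anchor (a bacteria span or a trigger token).

    ``location_heads`` maps head-token index -> location mention id; when None
    the location slot is unconstrained (trigger-mining mode) and only the
    preposition is checked.
    """
    hits: list[PatternHit] = []

    def loc_ok(obj: int, preps_needed: frozenset[str], prep: str) -> bool:
        if prep not in preps_needed or obj in anchor_tokens:
            return False
        return location_heads is None or obj in location_heads

    # P1: {noun} of [anchor] loc_prep [location]
    for n_tok in range(len(sent.tokens)):
        if sent.tokens[n_tok].pos not in NOMINAL_POS or n_tok in anchor_tokens:
            continue
        if ("of", anchor_head) not in prep_objects(sent, n_tok):
            continue
        candidates = prep_objects(sent, n_tok) + prep_objects(sent, anchor_head)
        for prep, obj in candidates:
            if obj != anchor_head and loc_ok(obj, loc_preps, prep):
                hits.append(PatternHit("P1", n_tok, None if location_heads is None else obj))
                if location_heads is None:
                    break

    # P2: [anchor] {n/v/p} loc_prep [location]
    for a_tok in range(len(sent.tokens)):
        if sent.tokens[a_tok].pos not in ANCHOR_POS or a_tok in anchor_tokens:
            continue
        label = direct_arc(sent, a_tok, anchor_head)
        if label is None or label.split(":")[0] in _NON_CONTENT:
            continue
        for prep, obj in prep_objects(sent, a_tok):
            if obj != anchor_head and loc_ok(obj, loc_preps, prep):
                hits.append(PatternHit("P2", a_tok, None if location_heads is None else obj))
                if location_heads is None:
                    break

    # P3: [location] {n/v/p} prep [anchor]
    for a_tok in range(len(sent.tokens)):
        if sent.tokens[a_tok].pos not in ANCHOR_POS or a_tok in anchor_tokens:
            continue
        if not any(obj == anchor_head for _, obj in prep_objects(sent, a_tok)):
            continue
        if location_heads is None:
            hits.append(PatternHit("P3", a_tok, None))
            continue
        for l_head in location_heads:
            if l_head in anchor_tokens or l_head == a_tok:
                continue
            label = direct_arc(sent, a_tok, l_head)
            if label is not None and (
                label.split(":")[0] in NP_RELATIONS or label in NP_RELATIONS
            ):
                hits.append(PatternHit("P3", a_tok, l_head))

    return hits
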