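"""Trigger patterns P1-P3 and the shared dependency predicates.

`oracle_hits` is an independent re-derivation of the pattern definitions that
works directly off the raw arc list; the matcher must agree with it on every
sentence of the curated and synthetic fixture suites.
"""

from bbct.patterns import (
    ANCHOR_POS,
    LOC_PREPS,
    NOMINAL_POS,
    NP_RELATIONS,
    direct_arc,
    match_anchor_patterns,
    np_connected,
    prep_objects,
)


# ---------------------------------------------------------------------------
# brute-force oracle (arc-list scans only; no helpers from bbct.patterns)

_NON_CONTENT = {"case", "punct", "cc", "mark", "det", "aux", "cop"}


def _oracle_preps(sent, head):
    out = []
    for h, dep, label in sent.arcs:
        if h != head or label.split(":")[0] not in ("nmod", "obl"):
            continue
        for h2, d2, l2 in sent.arcs:
            if h2 == dep and l2 == "case" and sent.tokens[d2].pos == "ADP":
                out.append((sent.tokens[d2].lemma.lower(), dep))
    return out


def _oracle_arc_label(sent, a, b):
    for h, d, label in sent.arcs:
        if {h, d} == {a, b}:
            return label
    return None


def oracle_hits(sent, anchor_tokens, anchor_head, location_heads, loc_preps=LOC_PREPS):
    """All (pattern, trigger token, location head) triples, by direct definition."""
    hits = set()

    def slot_ok(obj, prep):
        return (
            prep in loc_preps
            and obj not in anchor_tokens
            and obj in location_heads
        )

    n = len(sent.tokens)
    # P1: nominal N (outside the anchor) with "of"-object == anchor head, and a
    # locational prep object (of N or of the anchor head) filling the slot
    for n_tok in range(n):
        if sent.tokens[n_tok].pos not in NOMINAL_POS or n_tok in anchor_tokens:
            continue
        if ("of", anchor_head) not in _oracle_preps(sent, n_tok):
            continue
        for prep, obj in _oracle_preps(sent, n_tok) + _oracle_preps(sent, anchor_head):
            if obj != anchor_head and slot_ok(obj, prep):
                hits.add(("P1", n_tok, obj))
    # P2: n/v/p token directly content-linked to the anchor head, with a
    # locational prep object
    for a_tok in range(n):
        if sent.tokens[a_tok].pos not in ANCHOR_POS or a_tok in anchor_tokens:
            continue
        label = _oracle_arc_label(sent, a_tok, anchor_head)
        if label is None or label.split(":")[0] in _NON_CONTENT:
            continue
        for prep, obj in _oracle_preps(sent, a_tok):
            if obj != anchor_head and slot_ok(obj, prep):
                hits.add(("P2", a_tok, obj))
    # P3: n/v/p token whose prep object is the anchor head; the location is a
    # direct NP-relation neighbour of that token
    for a_tok in range(n):
        if sent.tokens[a_tok].pos not in ANCHOR_POS or a_tok in anchor_tokens:
            continue
        if not any(obj == anchor_head for _, obj in _oracle_preps(sent, a_tok)):
            continue
        for l_head in location_heads:
            if l_head in anchor_tokens or l_head == a_tok:
                continue
            label = _oracle_arc_label(sent, a_tok, l_head)
            if label is not None and (
                label.split(":")[0] in NP_RELATIONS or label in NP_RELATIONS
            ):
                hits.add(("P3", a_tok, l_head))
    return hits


def _anchor_cases(pdoc):
    """(sent, anchor tokens, anchor head, location heads) for every bacterium."""
    cases = []
    for mention in pdoc.doc.bacteria:
        al = pdoc.alignment[mention.id]
        sent = pdoc.sentences[al.sentence_index]
        location_heads = {
            pdoc.alignment[m.id].head: m.id
            for m in pdoc.mentions_in_sentence(al.sentence_index)
            if m.is_location
        }
        cases.append((sent, frozenset(al.covered), al.head, location_heads))
    return cases


def test_matcher_agrees_with_oracle_on_curated(curated_parsed):
    checked = 0
    for pdoc in curated_parsed.values():
        for sent, anchor, head, loc_heads in _anchor_cases(pdoc):
            got = {
                (h.pattern, h.trigger_token, h.location_head)
                for h in match_anchor_patterns(sent, anchor, head, loc_heads)
            }
            assert got == oracle_hits(sent, anchor, head, loc_heads)
            checked += 1
    assert checked >= 12


def test_matcher_agrees_with_oracle_on_synthetic(synthetic_parsed):
    for pdoc in synthetic_parsed:
        for sent, anchor, head, loc_heads in _anchor_cases(pdoc):
            got = {
                (h.pattern, h.trigger_token, h.location_head)
                for h in match_anchor_patterns(sent, anchor, head, loc_heads)
            }
            assert got == oracle_hits(sent, anchor, head, loc_heads)


def test_mining_mode_leaves_location_unconstrained(curated_parsed):
    """With no location mentions supplied, hits carry location_head=None."""
    pdoc = curated_parsed["kingae-pharyngeal"]
    al = pdoc.alignment["T1"]
    sent = pdoc.sentences[al.sentence_index]
    hits = match_anchor_patterns(sent, frozenset(al.covered), al.head, None)
    assert all(h.location_head is None for h in hits)


def test_p1_p2_p3_each_fire_on_their_template(synthetic_parsed):
    seen = set()
    for pdoc in synthetic_parsed:
        doc_id = pdoc.doc.doc_id
        for sent, anchor, head, loc_heads in _anchor_cases(pdoc):
            for hit in match_anchor_patterns(sent, anchor, head, loc_heads):
                if doc_id.startswith("p1-"):
                    seen.add(("P1", hit.pattern))
                elif doc_id.startswith("p2-"):
                    seen.add(("P2", hit.pattern))
                elif doc_id.startswith("p3-"):
                    seen.add(("P3", hit.pattern))
    assert ("P1", "P1") in seen
    assert ("P2", "P2") in seen
    assert ("P3", "P3") in seen


def test_prep_objects(curated_parsed):
    pdoc = curated_parsed["salmonicida-sediments"]
    sent = pdoc.sentences[0]
    # detected (5) -obl-> sediments (7) with case "in"
    assert ("in", 7) in prep_objects(sent, 5)
    assert prep_objects(sent, 7) == []


def test_direct_arc_is_undirected(curated_parsed):
    pdoc = curated_parsed["salmonicida-sediments"]
    sent = pdoc.sentences[0]
    assert direct_arc(sent, 5, 7) == "obl"
    assert direct_arc(sent, 7, 5) == "obl"
    assert direct_arc(sent, 0, 7) is None


def test_np_connected(curated_parsed):
    pdoc = curated_parsed["kingae-pharyngeal"]
    sent = pdoc.sentences[0]
    # "invasive K. kingae infection": amod/compound links only
    assert np_connected(sent, 9, 10)
    assert np_connected(sent, 7, 10)
    # subject to object crosses the verb: not NP-internal
    assert not np_connected(sent, 4, 10)
    assert np_connected(sent, 3, 3)


def test_loc_prep_gate():
    """P2 must not fire when the preposition is outside the locational set."""
    from bbct.docbuild import DocBuilder
    from bbct.syntax import analyze

    b = DocBuilder("with-prep")
    b.sentence([
        ("Salmonella", "Salmonella", "PROPN", 2, "compound"),
        ("cultures", "culture", "NOUN", 7, "nsubj:pass"),
        ("with", "with", "ADP", 5, "case"),
        ("yolk", "yolk", "NOUN", 5, "compound"),
        ("sacs", "sac", "NOUN", 2, "nmod"),
        ("were", "be", "AUX", 7, "aux:pass"),
        ("spread", "spread", "VERB", 0, "root"),
        (".", ".", "PUNCT", 7, "punct"),
    ])
    b.mention("T1", "Bacteria", (0, 0, 0))
    b.mention("T2", "Habitat", (0, 3, 4))
    doc = b.build()
    pdoc = analyze(doc)
    al = pdoc.alignment["T1"]
    loc_heads = {pdoc.alignment["T2"].head: "T2"}
    sent = pdoc.sentences[0]
    default = match_anchor_patterns(sent, frozenset(al.covered), al.head, loc_heads)
    assert not any(h.pattern == "P2" for h in default)
    widened = match_anchor_patterns(
        sent, frozenset(al.covered), al.head, loc_heads,
        loc_preps=LOC_PREPS | {"with"},
    )
    assert any(h.pattern == "P2" for h in widened)
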