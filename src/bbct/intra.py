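"""Intra-sentence event extraction and event-label propagation.

Short-range (intra-clause) events come from the P1-P3 trigger patterns with the
location slot bound to an annotated mention, plus three tighter configurations:
N1 (bacteria and location co-nested in one noun phrase), N2 (one mention's
spans nested inside the other's), and N3 (a direct prepositional link).
Long-range (cross-clause) events are inferred through context triggers: a
trigger linked to a bacterium stands in for it as the pattern anchor, and a
trigger-location match yields the bacteria-location event by transitivity.
Finally, confirmed events are propagated to syntactically related same-type
mentions (nesting, coordination, apposition, geographical comma hierarchy,
participle/preposition links) until a fixpoint.
"""

from __future__ import annotations

import re
from typing import Iterable, Optional

from bbct.patterns import (
    LOC_PREPS,
    PatternHit,
    direct_arc,
    match_anchor_patterns,
    np_connected,
    prep_objects,
)
from bbct.standoff import EntityMention, LivesInEvent, dedupe_events
from bbct.syntax import ParsedDocument, trigger_word_distance
from bbct.triggers import TriggerMention

_PAREN_BETWEEN = re.compile(r"^\s*\(\s*$")
_COMMA_BETWEEN = re.compile(r"^\s*,\s*$")


def _locations_by_head(
    pdoc: ParsedDocument, sent_index: int, allowed: Optional[set[str]] = None
) -> dict[int, list[EntityMention]]:
    by_head: dict[int, list[EntityMention]] = {}
    for mention in pdoc.mentions_in_sentence(sent_index):
        if not mention.is_location:
            continue
        if allowed is not None and mention.id not in allowed:
            continue
        by_head.setdefault(pdoc.alignment[mention.id].head, []).append(mention)
    return by_head


def _anchor_location_links(
    pdoc: ParsedDocument,
    sent_index: int,
    anchor_tokens: frozenset[int],
    anchor_head: int,
    anchor_charset: Optional[frozenset[int]],
    loc_preps: frozenset[str],
    allowed_locations: Optional[set[str]] = None,
) -> list[tuple[str, str]]:
    """(location id, pattern label) pairs the anchor relates to intra-clause."""
    sent = pdoc.sentences[sent_index]
    by_head = _locations_by_head(pdoc, sent_index, allowed_locations)
    links: list[tuple[str, str]] = []
    seen: set[str] = set()

    def add(mention: EntityMention, pattern: str) -> None:
        if mention.id not in seen:
            seen.add(mention.id)
            links.append((mention.id, pattern))

    # P1-P3 with the location slot bound to annotated mentions
    hits: list[PatternHit] = match_anchor_patterns(
        sent,
        anchor_tokens,
        anchor_head,
        location_heads={h: "L" for h in by_head},
        loc_preps=loc_preps,
    )
    for hit in hits:
        assert hit.location_head is not None
        for mention in by_head[hit.location_head]:
            if anchor_charset is not None and (
                mention.charset() <= anchor_charset or anchor_charset <= mention.charset()
            ):
                continue  # nesting is N2's business
            add(mention, hit.pattern)

    for l_head, mentions in sorted(by_head.items()):
        for mention in mentions:
            l_charset = mention.charset()
            nested = anchor_charset is not None and (
                l_charset <= anchor_charset or anchor_charset <= l_charset
            )
            # N2: one mention nested within the other
            if nested:
                if l_charset != anchor_charset:
                    add(mention, "N2")
                continue
            if l_head in anchor_tokens:
                continue
            # N1: co-nested in one noun phrase
            if np_connected(sent, anchor_head, l_head):
                add(mention, "N1")
                continue
            # N3: direct prepositional link in either direction
            if any(obj == l_head for _, obj in prep_objects(sent, anchor_head)) or any(
                obj == anchor_head for _, obj in prep_objects(sent, l_head)
            ):
                add(mention, "N3")
    return links


def extract_intra_clause(
    pdoc: ParsedDocument,
    bacteria_ids: Optional[Iterable[str]] = None,
    loc_preps: frozenset[str] = LOC_PREPS,
    allowed_locations: Optional[set[str]] = None,
) -> list[LivesInEvent]:
    """Apply the intra-clause patterns to every (bacteria, location) pair."""
    if bacteria_ids is None:
        bacteria_ids = [m.id for m in pdoc.doc.bacteria if m.id in pdoc.alignment]
    events: list[LivesInEvent] = []
    for b_id in bacteria_ids:
        align = pdoc.alignment[b_id]
        links = _anchor_location_links(
            pdoc,
            align.sentence_index,
            frozenset(align.covered),
            align.head,
            pdoc.doc.entity(b_id).charset(),
            loc_preps,
            allowed_locations,
        )
        for l_id, pattern in links:
            events.append(LivesInEvent(b_id, l_id, provenance=pattern, sentence_span="intra"))
    return dedupe_events(events)


def trigger_location_links(
    pdoc: ParsedDocument,
    trigger: TriggerMention,
    loc_preps: frozenset[str] = LOC_PREPS,
    allowed_locations: Optional[set[str]] = None,
) -> list[tuple[str, str]]:
    """Locations an occurrence of a context trigger relates to, trigger as anchor."""
    return _anchor_location_links(
        pdoc,
        trigger.sentence_index,
        frozenset({trigger.token_index}),
        trigger.token_index,
        None,
        loc_preps,
        allowed_locations,
    )


def link_triggers(
    pdoc: ParsedDocument,
    triggers: Iterable[TriggerMention],
    bacteria_ids: Optional[Iterable[str]] = None,
    tiebreak: str = "preceding",
) -> list[TriggerMention]:
    """Link each trigger to the word-distance-nearest bacteria mention in its sentence.

    Equidistant ties go to the preceding mention in reading order (or the
    following one under ``tiebreak="following"``).  Triggers in sentences
    without a bacteria mention stay unlinked at this scope.
    """
    if bacteria_ids is None:
        bacteria_ids = [m.id for m in pdoc.doc.bacteria if m.id in pdoc.alignment]
    bacteria_ids = list(bacteria_ids)
    positions = pdoc.global_positions()
    linked: list[TriggerMention] = []
    for trig in triggers:
        candidates = [
            b_id
            for b_id in bacteria_ids
            if pdoc.alignment[b_id].sentence_index == trig.sentence_index
        ]
        if not candidates:
            linked.append(trig)
            continue
        trig_pos = positions[trig.at()]

        def sort_key(b_id: str) -> tuple:
            dist, _ = trigger_word_distance(
                pdoc, trig.sentence_index, trig.token_index, b_id
            )
            al = pdoc.alignment[b_id]
            b_pos = positions[(al.sentence_index, al.covered[0])]
            precedes = b_pos < trig_pos
            if tiebreak == "preceding":
                tie = 0 if precedes else 1
            else:
                tie = 1 if precedes else 0
            return (dist, tie, b_pos)

        best = min(candidates, key=sort_key)
        linked.append(
            TriggerMention(trig.lemma, trig.sentence_index, trig.token_index, best)
        )
    return linked


def infer_cross_clause(
    pdoc: ParsedDocument,
    linked_triggers: Iterable[TriggerMention],
    intra_events: Iterable[LivesInEvent],
    loc_preps: frozenset[str] = LOC_PREPS,
    allowed_locations: Optional[set[str]] = None,
) -> list[LivesInEvent]:
    """Transitivity B -> trigger -> location, for triggers linked within a sentence."""
    known = {e.pair for e in intra_events}
    events: list[LivesInEvent] = []
    for trig in linked_triggers:
        if trig.linked_bacteria is None:
            continue
        for l_id, pattern in trigger_location_links(
            pdoc, trig, loc_preps, allowed_locations=allowed_locations
        ):
            if (trig.linked_bacteria, l_id) in known:
                continue
            events.append(
                LivesInEvent(
                    trig.linked_bacteria,
                    l_id,
                    provenance=f"trigger:{trig.lemma}:{pattern}",
                    sentence_span="intra",
                )
            )
    return dedupe_events(events)


# ---------------------------------------------------------------------------
# Event-label propagation (five same-type syntactic relations)


def _related_pairs(
    pdoc: ParsedDocument,
) -> list[tuple[str, str, str]]:
    """Directed (from id, to id, rule) links between same-type mentions in one sentence."""
    text = pdoc.doc.text
    links: list[tuple[str, str, str]] = []
    for sent in pdoc.sentences:
        mentions = sorted(
            (m for m in pdoc.mentions_in_sentence(sent.index)),
            key=lambda m: (m.start, -(m.end)),
        )
        for i, m1 in enumerate(mentions):
            for m2 in mentions[i + 1 :]:
                if m1.etype != m2.etype and not (m1.is_location and m2.is_location):
                    continue
                h1 = pdoc.alignment[m1.id].head
                h2 = pdoc.alignment[m2.id].head
                # R1 nesting: events extend both ways between container and nested
                if m1.contains(m2) or m2.contains(m1):
                    links.append((m1.id, m2.id, "R1"))
                    links.append((m2.id, m1.id, "R1"))
                    continue
                # R2 coordination
                arc = direct_arc(sent, h1, h2)
                if arc is not None and arc.split(":")[0] == "conj":
                    links.append((m1.id, m2.id, "R2"))
                    links.append((m2.id, m1.id, "R2"))
                # R3 apposition (dependency appos or immediate parenthesis)
                is_appos = arc is not None and arc.split(":")[0] == "appos"
                paren = (
                    _PAREN_BETWEEN.match(text[m1.end : m2.start]) is not None
                    and text[m2.end : m2.end + 2].lstrip().startswith(")")
                )
                if is_appos or paren:
                    links.append((m1.id, m2.id, "R3"))
                    links.append((m2.id, m1.id, "R3"))
                # R4 comma-joined geographical hierarchy: smaller extends to larger
                if (
                    m1.etype == "Geographical"
                    and m2.etype == "Geographical"
                    and _COMMA_BETWEEN.match(text[m1.end : m2.start]) is not None
                    and not is_appos  # appos already propagates both ways
                ):
                    links.append((m1.id, m2.id, "R4"))
                # R5 participle-preposition / single-preposition location links
                if m1.is_location and m2.is_location:
                    single_prep = any(obj == h2 for _, obj in prep_objects(sent, h1))
                    participle = False
                    for child, label in sent.children(h1):
                        if label.split(":")[0] == "acl" and any(
                            obj == h2 for _, obj in prep_objects(sent, child)
                        ):
                            participle = True
                    if single_prep or participle:
                        links.append((m1.id, m2.id, "R5"))
    return links


def propagate(
    pdoc: ParsedDocument,
    events: Iterable[LivesInEvent],
    allowed_locations: Optional[set[str]] = None,
    allowed_bacteria: Optional[set[str]] = None,
    sentence_span: Optional[str] = None,
) -> list[LivesInEvent]:
    """Smallest superset of ``events`` closed under the five propagation rules.

    The closure is a unique fixpoint (rule application is monotone), bounded by
    |B| x |L| pairs.  Optional ``allowed_*`` sets restrict which mentions may
    *receive* propagated events (used by the cross-sentence sieve); seed events
    are never removed.
    """
    out: dict[tuple[str, str], LivesInEvent] = {}
    for event in events:
        out.setdefault(event.pair, event)
    by_source: dict[str, list[tuple[str, str]]] = {}
    for from_id, to_id, rule in _related_pairs(pdoc):
        by_source.setdefault(from_id, []).append((to_id, rule))

    frontier = list(out.keys())
    while frontier:
        next_frontier: list[tuple[str, str]] = []
        for b_id, l_id in frontier:
            base = out[(b_id, l_id)]
            for to_id, rule in sorted(by_source.get(l_id, [])):
                target = pdoc.doc.entity(to_id)
                if not target.is_location:
                    continue
                if allowed_locations is not None and to_id not in allowed_locations:
                    continue
                pair = (b_id, to_id)
                if pair not in out:
                    out[pair] = LivesInEvent(
                        b_id,
                        to_id,
                        provenance=rule,
                        sentence_span=sentence_span or base.sentence_span,
                    )
                    next_frontier.append(pair)
            for to_id, rule in sorted(by_source.get(b_id, [])):
                target = pdoc.doc.entity(to_id)
                if not target.is_bacteria:
                    continue
                if allowed_bacteria is not None and to_id not in allowed_bacteria:
                    continue
                pair = (to_id, l_id)
                if pair not in out:
                    out[pair] = LivesInEvent(
                        to_id,
                        l_id,
                        provenance=rule,
                        sentence_span=sentence_span or base.sentence_span,
                    )
                    next_frontier.append(pair)
        frontier = next_frontier
    return list(out.values())
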