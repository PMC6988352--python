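"""Cross-sentence event inference through context triggers.

Candidate selection follows three corpus observations: a bacterium whose
sentence has no location mention is a candidate; a bacterium that already has
an intra-sentence event is a candidate for further (cross-sentence) locations;
a location already in an intra-sentence event never takes part in a
cross-sentence one.  Each candidate bacterium gets a context window of up to
three sentences either side, truncated before any sentence holding a different
bacteria mention; triggers inside the window act as the bacterium's indirect
anaphors, and a trigger-location intra-clause match yields the cross-sentence
event by transitivity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from bbct.patterns import LOC_PREPS
from bbct.standoff import LivesInEvent, dedupe_events
from bbct.syntax import ParsedDocument, trigger_word_distance
from bbct.intra import propagate, trigger_location_links
from bbct.triggers import TriggerLexicon, TriggerMention

DEFAULT_WINDOW = 3


@dataclass(frozen=True)
class ContextWindow:
    """Sentence range [lo, hi] (inclusive) anchored on one bacteria mention."""

    bacteria_id: str
    lo: int
    hi: int

    def __contains__(self, sent_index: int) -> bool:
        return self.lo <= sent_index <= self.hi


def select_candidates(
    pdoc: ParsedDocument,
    intra_events: Iterable[LivesInEvent],
    eligible: Optional[set[str]] = None,
) -> tuple[set[str], set[str]]:
    """(candidate bacteria ids, candidate location ids) for cross-sentence events.

    ``eligible`` optionally restricts candidacy to those mention ids (mentions
    surviving the modality filter); ineligible mentions still count as context
    (window truncation, co-sentential location checks).
    """
    intra_pairs = {e.pair for e in intra_events}
    bacteria_with_event = {b for b, _ in intra_pairs}
    locations_with_event = {l for _, l in intra_pairs}

    candidate_bacteria: set[str] = set()
    for mention in pdoc.doc.bacteria:
        if eligible is not None and mention.id not in eligible:
            continue
        sent_index = pdoc.alignment[mention.id].sentence_index
        co_sentential_locations = [
            m
            for m in pdoc.mentions_in_sentence(sent_index)
            if m.is_location
        ]
        if not co_sentential_locations or mention.id in bacteria_with_event:
            candidate_bacteria.add(mention.id)

    candidate_locations = {
        m.id
        for m in pdoc.doc.locations
        if m.id not in locations_with_event
        and (eligible is None or m.id in eligible)
    }
    return candidate_bacteria, candidate_locations


def build_window(
    pdoc: ParsedDocument, bacteria_id: str, size: int = DEFAULT_WINDOW
) -> Optional[ContextWindow]:
    """Maximal +-size sentence range around the bacterium, truncated at other bacteria.

    Returns None when another bacteria mention shares the anchor's sentence
    (such bacteria get no cross-sentence inference at all).
    """
    anchor_sent = pdoc.alignment[bacteria_id].sentence_index
    bacteria_sentences: dict[int, set[str]] = {}
    for mention in pdoc.doc.bacteria:
        bacteria_sentences.setdefault(
            pdoc.alignment[mention.id].sentence_index, set()
        ).add(mention.id)
    if bacteria_sentences.get(anchor_sent, set()) - {bacteria_id}:
        return None
    lo = anchor_sent
    while lo > max(0, anchor_sent - size):
        if bacteria_sentences.get(lo - 1):
            break
        lo -= 1
    hi = anchor_sent
    last = len(pdoc.sentences) - 1
    while hi < min(last, anchor_sent + size):
        if bacteria_sentences.get(hi + 1):
            break
        hi += 1
    return ContextWindow(bacteria_id, lo, hi)


def _nearest_bacteria_in_window(
    pdoc: ParsedDocument,
    trig: TriggerMention,
    window_bacteria: list[str],
    tiebreak: str,
) -> Optional[str]:
    """Nearest bacterium by (sentence distance, word distance), ties to preceding."""
    if not window_bacteria:
        return None
    positions = pdoc.global_positions()
    trig_pos = positions[trig.at()]

    def sort_key(b_id: str) -> tuple:
        words, sents = trigger_word_distance(
            pdoc, trig.sentence_index, trig.token_index, b_id
        )
        al = pdoc.alignment[b_id]
        b_pos = positions[(al.sentence_index, al.covered[0])]
        precedes = b_pos < trig_pos
        tie = (0 if precedes else 1) if tiebreak == "preceding" else (1 if precedes else 0)
        return (sents, words, tie, b_pos)

    return min(window_bacteria, key=sort_key)


def infer_cross_sentence(
    pdoc: ParsedDocument,
    triggers: Iterable[TriggerMention],
    intra_events: Iterable[LivesInEvent],
    window_size: int = DEFAULT_WINDOW,
    loc_preps: frozenset[str] = LOC_PREPS,
    tiebreak: str = "preceding",
    eligible: Optional[set[str]] = None,
) -> list[LivesInEvent]:
    """Additional cross-sentence events, candidate bacteria processed top-to-bottom."""
    intra_events = list(intra_events)
    triggers = list(triggers)
    candidate_bacteria, candidate_locations = select_candidates(
        pdoc, intra_events, eligible
    )
    intra_pairs = {e.pair for e in intra_events}
    positions = pdoc.global_positions()

    ordered_bacteria = sorted(
        candidate_bacteria,
        key=lambda b: positions[
            (pdoc.alignment[b].sentence_index, pdoc.alignment[b].covered[0])
        ],
    )
    out: list[LivesInEvent] = []
    for b_id in ordered_bacteria:
        window = build_window(pdoc, b_id, window_size)
        if window is None:
            continue
        anchor_sent = pdoc.alignment[b_id].sentence_index
        window_triggers = [t for t in triggers if t.sentence_index in window]
        new_events: list[LivesInEvent] = []
        for trig in window_triggers:
            if trig.sentence_index == anchor_sent:
                continue  # same-sentence links are the intra sieve's job
            linked = _nearest_bacteria_in_window(pdoc, trig, [b_id], tiebreak)
            if linked != b_id:
                continue
            for l_id, pattern in trigger_location_links(
                pdoc, trig, loc_preps, allowed_locations=candidate_locations
            ):
                if pdoc.alignment[l_id].sentence_index == anchor_sent:
                    continue
                if (b_id, l_id) in intra_pairs:
                    continue
                new_events.append(
                    LivesInEvent(
                        b_id,
                        l_id,
                        provenance=f"x-trigger:{trig.lemma}:{pattern}",
                        sentence_span="cross",
                    )
                )
        if not new_events:
            continue
        # location-side propagation within the window, restricted to candidates
        window_locations = {
            l_id
            for l_id in candidate_locations
            if pdoc.alignment[l_id].sentence_index in window
            and pdoc.alignment[l_id].sentence_index != anchor_sent
        }
        closed = propagate(
            pdoc,
            new_events,
            allowed_locations=window_locations,
            allowed_bacteria=set(),
            sentence_span="cross",
        )
        out.extend(e for e in closed if e.pair not in intra_pairs)
    return dedupe_events(out)
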