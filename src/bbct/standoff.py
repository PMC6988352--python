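"""Reading and writing BioNLP-ST standoff documents (.txt / .a1 / .a2).

The BB-event subtask uses three entity types relevant to Lives_In relations:
``Bacteria`` mentions and two kinds of location mention, ``Habitat`` and
``Geographical``.  Entity annotations live in ``.a1`` files as tab-separated
lines with 0-based half-open character offsets (possibly discontinuous,
fragments separated by ``;``); binary relations and equivalence declarations
live in ``.a2`` files.  Annotation types outside the three event-relevant ones
(``Title``, ``Paragraph``, ...) are silently skipped on read.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import IO, Iterable, Optional, Union

BACTERIA = "Bacteria"
LOCATION_TYPES = frozenset({"Habitat", "Geographical"})
ENTITY_TYPES = frozenset({BACTERIA}) | LOCATION_TYPES

INTRA = "intra"
CROSS = "cross"


class StandoffParseError(ValueError):
    """A malformed .a1/.a2 line; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


class StandoffIntegrityError(ValueError):
    """Annotations that parse but contradict the document they annotate."""


@dataclass(frozen=True)
class EntityMention:
    """An entity annotation with one or more character spans.

    ``spans`` are 0-based half-open offsets into the raw document text, in
    strictly increasing order; ``surface`` is the covered text, fragments of a
    discontinuous mention joined by a single space.
    """

    id: str
    etype: str
    spans: tuple[tuple[int, int], ...]
    surface: str

    def __post_init__(self) -> None:
        if not self.spans:
            raise ValueError(f"{self.id}: mention needs at least one span")
        prev_end = -1
        prev_start = -1
        for start, end in self.spans:
            if start >= end:
                raise ValueError(f"{self.id}: empty or inverted span {start}..{end}")
            if start <= prev_start or start < prev_end:
                raise ValueError(f"{self.id}: spans overlap or are unordered")
            prev_start, prev_end = start, end

    @property
    def is_bacteria(self) -> bool:
        return self.etype == BACTERIA

    @property
    def is_location(self) -> bool:
        return self.etype in LOCATION_TYPES

    @property
    def start(self) -> int:
        return self.spans[0][0]

    @property
    def end(self) -> int:
        return self.spans[-1][1]

    def charset(self) -> frozenset[int]:
        """All character offsets covered by this mention."""
        covered: set[int] = set()
        for start, end in self.spans:
            covered.update(range(start, end))
        return frozenset(covered)

    def contains(self, other: "EntityMention") -> bool:
        """True when every character of ``other`` lies inside this mention."""
        return other is not self and other.charset() <= self.charset()


@dataclass(frozen=True)
class LivesInEvent:
    """A Lives_In relation between a bacteria and a location mention.

    ``provenance`` names the sieve/pattern that produced the event (``gold``
    for reference annotations); ``sentence_span`` is "intra" when both mentions
    share a sentence, "cross" otherwise, or None before alignment.
    """

    bacteria_id: str
    location_id: str
    provenance: str = "gold"
    sentence_span: Optional[str] = None

    @property
    def pair(self) -> tuple[str, str]:
        return (self.bacteria_id, self.location_id)


@dataclass(frozen=True)
class EquivalenceSet:
    """Entity ids declared mutually interchangeable for evaluation."""

    member_ids: frozenset[str]

    def __post_init__(self) -> None:
        if len(self.member_ids) < 2:
            raise ValueError("an equivalence set needs at least two members")


@dataclass
class AnnotatedDocument:
    doc_id: str
    text: str
    entities: list[EntityMention] = field(default_factory=list)
    equivalences: list[EquivalenceSet] = field(default_factory=list)
    gold_events: Optional[list[LivesInEvent]] = None
    #: optional gold dependency analysis (CoNLL-U text) for parser-free runs
    conllu: Optional[str] = None

    def __post_init__(self) -> None:
        self._by_id = {e.id: e for e in self.entities}
        for ent in self.entities:
            if ent.end > len(self.text):
                raise StandoffIntegrityError(
                    f"{self.doc_id}/{ent.id}: span {ent.spans} exceeds text length {len(self.text)}"
                )
        seen: set[str] = set()
        for eq in self.equivalences:
            if eq.member_ids & seen:
                raise StandoffIntegrityError(f"{self.doc_id}: overlapping Equiv sets")
            seen |= eq.member_ids

    def entity(self, entity_id: str) -> EntityMention:
        try:
            return self._by_id[entity_id]
        except KeyError:
            raise StandoffIntegrityError(
                f"{self.doc_id}: unknown entity id {entity_id!r}"
            ) from None

    def has_entity(self, entity_id: str) -> bool:
        return entity_id in self._by_id

    @property
    def bacteria(self) -> list[EntityMention]:
        return [e for e in self.entities if e.is_bacteria]

    @property
    def locations(self) -> list[EntityMention]:
        return [e for e in self.entities if e.is_location]


def _surface_at(text: str, spans: Iterable[tuple[int, int]]) -> str:
    return " ".join(text[s:e] for s, e in spans)


_A1_LINE = re.compile(
    r"^(?P<id>T\d+)\t(?P<type>\S+) (?P<offsets>\d+ \d+(?:;\d+ \d+)*)\t(?P<text>.*)$"
)
_A2_REL = re.compile(
    r"^(?P<id>R\d+)\tLives_In Bacteria:(?P<b>T\d+) Location:(?P<l>T\d+)\s*$"
)
_A2_EQUIV = re.compile(r"^\*\tEquiv (?P<ids>T\d+(?: T\d+)+)\s*$")


def _read_text(source: Union[str, IO[str]]) -> str:
    if hasattr(source, "read"):
        return source.read()
    return str(source)


def parse_a1(a1_text: str, text: str, doc_id: str = "?") -> list[EntityMention]:
    """Parse .a1 entity lines against the document text.

    Entities with types outside the three event-relevant ones are skipped.
    A surface/offset mismatch on a discontinuous mention is a warning (source
    files vary in how they render the text column); on a contiguous mention it
    is an integrity error.
    """
    entities: list[EntityMention] = []
    for lineno, line in enumerate(a1_text.splitlines(), start=1):
        if not line.strip():
            continue
        match = _A1_LINE.match(line)
        if match is None:
            if line.startswith("T"):
                raise StandoffParseError(f"malformed entity line {line!r}", lineno)
            continue  # non-entity standoff lines (e.g. normalizations) skipped
        etype = match.group("type")
        if etype not in ENTITY_TYPES:
            continue
        spans = tuple(
            (int(pair.split()[0]), int(pair.split()[1]))
            for pair in match.group("offsets").split(";")
        )
        try:
            mention = EntityMention(match.group("id"), etype, spans, match.group("text"))
        except ValueError as exc:
            raise StandoffParseError(str(exc), lineno) from exc
        if mention.end > len(text):
            raise StandoffIntegrityError(
                f"{doc_id}/{mention.id}: offsets {spans} outside text of length {len(text)}"
            )
        actual = _surface_at(text, spans)
        if actual != mention.surface:
            if len(spans) > 1:
                warnings.warn(
                    f"{doc_id}/{mention.id}: discontinuous surface {mention.surface!r} "
                    f"!= text {actual!r}; keeping text-derived surface",
                    stacklevel=2,
                )
                mention = EntityMention(mention.id, etype, spans, actual)
            else:
                raise StandoffIntegrityError(
                    f"{doc_id}/{mention.id}: surface {mention.surface!r} != text {actual!r}"
                )
        entities.append(mention)
    return entities


def parse_a2(
    a2_text: str, entities: list[EntityMention], doc_id: str = "?"
) -> tuple[list[LivesInEvent], list[EquivalenceSet]]:
    by_id = {e.id: e for e in entities}
    events: list[LivesInEvent] = []
    equivs: list[EquivalenceSet] = []
    for lineno, line in enumerate(a2_text.splitlines(), start=1):
        if not line.strip():
            continue
        rel = _A2_REL.match(line)
        if rel is not None:
            b_id, l_id = rel.group("b"), rel.group("l")
            for eid in (b_id, l_id):
                if eid not in by_id:
                    raise StandoffIntegrityError(
                        f"{doc_id}: relation references unknown entity {eid}"
                    )
            if not by_id[b_id].is_bacteria:
                raise StandoffIntegrityError(
                    f"{doc_id}: Bacteria role filled by {by_id[b_id].etype} mention {b_id}"
                )
            if not by_id[l_id].is_location:
                raise StandoffIntegrityError(
                    f"{doc_id}: Location role filled by {by_id[l_id].etype} mention {l_id}"
                )
            events.append(LivesInEvent(b_id, l_id, provenance="gold"))
            continue
        eq = _A2_EQUIV.match(line)
        if eq is not None:
            members = frozenset(eq.group("ids").split())
            missing = [m for m in members if m not in by_id]
            if missing:
                raise StandoffIntegrityError(
                    f"{doc_id}: Equiv references unknown entities {missing}"
                )
            equivs.append(EquivalenceSet(members))
            continue
        if line.startswith(("R", "*")):
            raise StandoffParseError(f"malformed relation line {line!r}", lineno)
        # other annotation kinds (events with E-ids etc.) are out of scope
    return events, equivs


def read_document(
    txt_source: Union[str, IO[str]],
    a1_source: Union[str, IO[str]],
    a2_source: Union[str, IO[str], None] = None,
    doc_id: str = "doc",
) -> AnnotatedDocument:
    """Load a standoff document from text/annotation streams (or strings)."""
    text = _read_text(txt_source)
    entities = parse_a1(_read_text(a1_source), text, doc_id)
    gold_events: Optional[list[LivesInEvent]] = None
    equivalences: list[EquivalenceSet] = []
    if a2_source is not None:
        gold_events, equivalences = parse_a2(_read_text(a2_source), entities, doc_id)
    return AnnotatedDocument(
        doc_id=doc_id,
        text=text,
        entities=entities,
        equivalences=equivalences,
        gold_events=gold_events,
    )


def write_predictions(doc: AnnotatedDocument, events: list[LivesInEvent]) -> str:
    """Render events as .a2 text, numbered R1.. in input order."""
    lines = []
    for k, event in enumerate(events, start=1):
        bacteria = doc.entity(event.bacteria_id)
        location = doc.entity(event.location_id)
        if not bacteria.is_bacteria:
            raise StandoffIntegrityError(
                f"{doc.doc_id}: {event.bacteria_id} is {bacteria.etype}, not Bacteria"
            )
        if not location.is_location:
            raise StandoffIntegrityError(
                f"{doc.doc_id}: {event.location_id} is {location.etype}, not a location"
            )
        lines.append(
            f"R{k}\tLives_In Bacteria:{event.bacteria_id} Location:{event.location_id}"
        )
    return "".join(line + "\n" for line in lines)


def write_a1(doc: AnnotatedDocument) -> str:
    """Render the document's entities as .a1 text (round-trip counterpart)."""
    lines = []
    for ent in doc.entities:
        offsets = ";".join(f"{s} {e}" for s, e in ent.spans)
        lines.append(f"{ent.id}\t{ent.etype} {offsets}\t{ent.surface}")
    return "".join(line + "\n" for line in lines)


def dedupe_events(events: Iterable[LivesInEvent]) -> list[LivesInEvent]:
    """Collapse duplicate (bacteria, location) pairs, keeping earliest provenance."""
    seen: dict[tuple[str, str], LivesInEvent] = {}
    for event in events:
        seen.setdefault(event.pair, event)
    return list(seen.values())
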