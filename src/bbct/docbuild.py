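"""Programmatic construction of annotated standoff documents with gold parses.

Fixture documents are defined as token lists carrying a hand-written Universal
Dependencies analysis; the builder detokenizes them into raw text, computes
character offsets mechanically, and renders both the standoff annotation
layers and the CoNLL-U analysis, so offsets can never drift out of sync with
the text.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from bbct.standoff import AnnotatedDocument, EntityMention, EquivalenceSet, LivesInEvent

#: (form, lemma, upos, head 1-based within sentence (0 = root), deprel)
Tok = tuple[str, str, str, int, str]

_NO_SPACE_BEFORE = {".", ",", ")", ";", ":", "?", "!", "%"}
_NO_SPACE_AFTER = {"("}


@dataclass
class DocBuilder:
    doc_id: str
    sentences: list[list[Tok]] = field(default_factory=list)
    _mentions: list[tuple[str, str, list[tuple[int, int, int]], Optional[tuple[int, int]]]] = field(
        default_factory=list
    )
    _events: list[tuple[str, str]] = field(default_factory=list)
    _equivs: list[Sequence[str]] = field(default_factory=list)

    def sentence(self, tokens: list[Tok]) -> int:
        """Add a sentence; returns its 0-based index."""
        self.sentences.append(tokens)
        return len(self.sentences) - 1

    def mention(
        self,
        mention_id: str,
        etype: str,
        *ranges: tuple[int, int, int],
        char_slice: Optional[tuple[int, int]] = None,
    ) -> str:
        """Annotate an entity over token ranges (sentence, first, last) inclusive.

        ``char_slice`` restricts the mention to a character window of the
        single covered token (for mentions nested inside one token, e.g. the
        bacteria inside "Mtb-infected").
        """
        self._mentions.append((mention_id, etype, list(ranges), char_slice))
        return mention_id

    def event(self, bacteria_id: str, location_id: str) -> None:
        self._events.append((bacteria_id, location_id))

    def equiv(self, *mention_ids: str) -> None:
        self._equivs.append(mention_ids)

    # -- rendering ---------------------------------------------------------

    def _detokenize(self) -> tuple[str, list[list[tuple[int, int]]]]:
        text_parts: list[str] = []
        offsets: list[list[tuple[int, int]]] = []
        cursor = 0
        for s_idx, tokens in enumerate(self.sentences):
            sent_offsets = []
            prev_form: Optional[str] = None
            for t_idx, (form, *_rest) in enumerate(tokens):
                first = s_idx == 0 and t_idx == 0
                space = not (
                    first
                    or form in _NO_SPACE_BEFORE
                    or (prev_form in _NO_SPACE_AFTER)
                )
                if space:
                    text_parts.append(" ")
                    cursor += 1
                text_parts.append(form)
                sent_offsets.append((cursor, cursor + len(form)))
                cursor += len(form)
                prev_form = form
            offsets.append(sent_offsets)
        return "".join(text_parts), offsets

    def to_conllu(self) -> str:
        blocks = []
        for tokens in self.sentences:
            lines = []
            for i, (form, lemma, upos, head, deprel) in enumerate(tokens, start=1):
                lines.append(
                    f"{i}\t{form}\t{lemma}\t{upos}\t_\t_\t{head}\t{deprel}\t_\t_"
                )
            blocks.append("\n".join(lines))
        return "\n\n".join(blocks) + "\n"

    def build(self) -> AnnotatedDocument:
        text, offsets = self._detokenize()
        entities = []
        for mention_id, etype, ranges, char_slice in self._mentions:
            spans = []
            for sent, first, last in ranges:
                start = offsets[sent][first][0]
                end = offsets[sent][last][1]
                spans.append((start, end))
            if char_slice is not None:
                (start, _end), = spans
                spans = [(start + char_slice[0], start + char_slice[1])]
            merged: list[tuple[int, int]] = []
            for span in sorted(spans):
                if merged and span[0] <= merged[-1][1] + 1 and text[merged[-1][1]:span[0]] in ("", " "):
                    pass  # keep fragments separate; standoff allows adjacency
                merged.append(span)
            surface = " ".join(text[s:e] for s, e in merged)
            entities.append(EntityMention(mention_id, etype, tuple(merged), surface))
        doc = AnnotatedDocument(
            doc_id=self.doc_id,
            text=text,
            entities=entities,
            equivalences=[EquivalenceSet(frozenset(ids)) for ids in self._equivs],
            gold_events=[LivesInEvent(b, l) for b, l in self._events],
        )
        doc.conllu = self.to_conllu()
        return doc


def np_chain(name: str, head_index: int, lemma_pos: str = "PROPN") -> list[Tok]:
    """Tokens of a multi-word name as a compound chain onto its last token.

    ``head_index`` is the 1-based sentence position the *last* token attaches
    to; callers must place these tokens so the chain's own positions
    immediately precede it.  Returns tokens whose heads assume the first token
    of the chain sits at position ``head_index - len(tokens)`` ... handled by
    the caller via :func:`renumber`.
    """
    parts = name.split()
    toks: list[Tok] = []
    for i, part in enumerate(parts):
        if i < len(parts) - 1:
            toks.append((part, part, lemma_pos, -(len(parts) - 1 - i), "compound"))
        else:
            toks.append((part, part, lemma_pos, head_index, "_EXTERNAL_"))
    return toks


def assemble(tokens: list[Tok]) -> list[Tok]:
    """Resolve relative heads (negative = offset to a later token in the chain)."""
    out: list[Tok] = []
    for pos, (form, lemma, upos, head, deprel) in enumerate(tokens, start=1):
        if head < 0:
            head = pos - head  # offset forward to the chain head
        out.append((form, lemma, upos, head, deprel))
    return out
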