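"""Hypothesis, research-goal, conditional, and negation filtering.

The BB-event corpus does not annotate working hypotheses as events, so
mentions and triggers inside such scopes must not take part in event
formation.  Three keyword-based rules approximate those scopes: (a) dependency
descendants of hypothesis keywords (research-purpose nouns and their verb
forms: determine, evaluate, study, ...); (b) tokens inside if- or
whether-clauses; (c) mentions directly modified by "no"/"none of", and
mentions governed by a predicate negated with "not".  Filtering is purely
subtractive and per-mention: other mentions in the same sentence stay
eligible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from bbct import resources
from bbct.syntax import ParsedDocument, SentenceParse
from bbct.triggers import TriggerMention

HYPOTHESIS = "hypothesis-keyword"
CONDITIONAL = "if-whether-clause"
NEGATION = "negation"


@dataclass
class ModalityBlock:
    """Blocked (sentence, token) positions, each with the reason that blocked it."""

    blocked: dict[tuple[int, int], str] = field(default_factory=dict)

    def is_blocked(self, sent_index: int, token_index: int) -> bool:
        return (sent_index, token_index) in self.blocked

    def reason(self, sent_index: int, token_index: int) -> Optional[str]:
        return self.blocked.get((sent_index, token_index))

    def add(self, sent_index: int, token_indices: Iterable[int], reason: str) -> None:
        for tok in token_indices:
            self.blocked.setdefault((sent_index, tok), reason)


def _negated_predicates(sent: SentenceParse) -> set[int]:
    """Predicates carrying a 'not' negation dependent."""
    negated = set()
    for head, dep, label in sent.arcs:
        if sent.tokens[dep].surface.lower() in {"not", "n't"} and label.split(":")[0] in {
            "advmod",
            "neg",
        }:
            if sent.tokens[head].pos in {"VERB", "AUX", "ADJ"}:
                negated.add(head)
    return negated


def find_blocked_mentions(
    pdoc: ParsedDocument,
    hypothesis_nouns: Optional[frozenset[str]] = None,
    hypothesis_verbs: Optional[frozenset[str]] = None,
) -> ModalityBlock:
    """Compute every token position excluded from event formation.

    Hypothesis keywords are matched part-of-speech-sensitively: the research
    nouns block only nominal uses and only the listed verb forms block verbal
    uses.  A noun keyword must not fire on its verb's past participle (e.g.
    the noun "study" vs. reported results phrased as "were studied"), which
    would discard legitimate events.
    """
    if hypothesis_nouns is None:
        hypothesis_nouns = resources.wordlist("hypothesis_nouns.txt")
    if hypothesis_verbs is None:
        hypothesis_verbs = resources.wordlist("hypothesis_verbs.txt")
    block = ModalityBlock()
    for sent in pdoc.sentences:
        # (a) descendants of hypothesis keywords
        for token in sent.tokens:
            lemma = token.lemma.lower()
            is_keyword = (token.pos in {"NOUN", "PROPN"} and lemma in hypothesis_nouns) or (
                token.pos == "VERB" and lemma in hypothesis_verbs
            )
            if is_keyword:
                block.add(sent.index, sent.subtree(token.index) - {token.index}, HYPOTHESIS)
        # (b) if-/whether-clauses: the clause head marked by if/whether + its subtree
        for head, dep, label in sent.arcs:
            if label == "mark" and sent.tokens[dep].surface.lower() in {"if", "whether"}:
                block.add(sent.index, sent.subtree(head), CONDITIONAL)
        # (c1) direct modification by no / none-of
        for head, dep, label in sent.arcs:
            surface = sent.tokens[dep].surface.lower()
            if surface == "no" and label.split(":")[0] == "det":
                block.add(sent.index, sent.subtree(head), NEGATION)
        for token in sent.tokens:
            if token.surface.lower() == "none":
                for prep, obj in _none_of_objects(sent, token.index):
                    if prep == "of":
                        block.add(sent.index, sent.subtree(obj), NEGATION)
        # (c2) arguments of predicates negated via not
        for pred in _negated_predicates(sent):
            block.add(sent.index, sent.subtree(pred) - {pred}, NEGATION)
    return block


def _none_of_objects(sent: SentenceParse, head: int) -> list[tuple[str, int]]:
    from bbct.patterns import prep_objects

    return prep_objects(sent, head)


def apply_filter(
    pdoc: ParsedDocument,
    mention_ids: Iterable[str],
    triggers: Iterable[TriggerMention],
    block: ModalityBlock,
) -> tuple[list[str], list[TriggerMention]]:
    """Remove mentions and triggers whose head token is blocked."""
    kept_mentions = []
    for mention_id in mention_ids:
        align = pdoc.alignment[mention_id]
        if not block.is_blocked(align.sentence_index, align.head):
            kept_mentions.append(mention_id)
    kept_triggers = [
        t for t in triggers if not block.is_blocked(t.sentence_index, t.token_index)
    ]
    return kept_mentions, kept_triggers
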