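"""Sentence/token/dependency layers and the tree predicates the sieves consume.

Dependency analyses follow Universal Dependencies labels.  The packaged parser
backend ("gold") reads CoNLL-U supplied alongside a document — either
hand-written gold parses for fixtures or the output of any external UD parser —
and aligns tokens to the raw standoff text by greedy character matching.  A
live statistical parser can be plugged in by registering another backend that
produces the same CoNLL-U surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional

from bbct.standoff import AnnotatedDocument, EntityMention

#: UD relations whose crossing places two tokens in different clauses.
CLAUSE_RELATIONS = frozenset(
    {"ccomp", "xcomp", "advcl", "acl", "acl:relcl", "csubj", "csubj:pass", "parataxis"}
)

VERB_POS = frozenset({"VERB", "AUX"})


class ParserBackendError(RuntimeError):
    """Requested parser backend is unavailable or its input is missing."""


@dataclass(frozen=True)
class Token:
    index: int
    surface: str
    lemma: str
    pos: str
    span: tuple[int, int]  # absolute character offsets in the document text


@dataclass
class SentenceParse:
    """One parsed sentence: tokens plus a single-rooted dependency tree."""

    index: int
    tokens: list[Token]
    arcs: list[tuple[int, int, str]]  # (head index, dependent index, relation)
    root: int

    def __post_init__(self) -> None:
        self._head: dict[int, tuple[int, str]] = {}
        self._children: dict[int, list[tuple[int, str]]] = {}
        for head, dep, label in self.arcs:
            if dep in self._head:
                raise ValueError(f"token {dep} has two heads")
            self._head[dep] = (head, label)
            self._children.setdefault(head, []).append((dep, label))
        n = len(self.tokens)
        if sorted([self.root, *self._head.keys()]) != list(range(n)):
            raise ValueError("arcs do not form a tree over all tokens")
        # reject cycles by walking every head chain
        for i in range(n):
            if self.root not in set(self.ancestors(i)) | {i}:
                raise ValueError("dependency arcs contain a cycle")

    def head_of(self, index: int) -> Optional[int]:
        entry = self._head.get(index)
        return entry[0] if entry else None

    def label_of(self, index: int) -> Optional[str]:
        entry = self._head.get(index)
        return entry[1] if entry else None

    def children(self, index: int) -> list[tuple[int, str]]:
        return list(self._children.get(index, []))

    def ancestors(self, index: int) -> list[int]:
        """Head chain from the token's head up to the root."""
        chain = []
        seen = {index}
        current = self._head.get(index)
        while current is not None:
            head = current[0]
            if head in seen:  # cycle guard during validation
                break
            chain.append(head)
            seen.add(head)
            current = self._head.get(head)
        return chain

    def subtree(self, index: int) -> set[int]:
        """The token and all its dependency descendants."""
        out = {index}
        stack = [index]
        while stack:
            for child, _ in self._children.get(stack.pop(), []):
                if child not in out:
                    out.add(child)
                    stack.append(child)
        return out

    def path(self, a: int, b: int) -> list[tuple[int, int, str]]:
        """Arcs on the unique tree path between tokens ``a`` and ``b``."""
        up_a = [a, *self.ancestors(a)]
        up_b = [b, *self.ancestors(b)]
        in_b = set(up_b)
        lca = next(node for node in up_a if node in in_b)
        arcs = []
        for node in up_a[: up_a.index(lca)]:
            head, label = self._head[node]
            arcs.append((head, node, label))
        for node in up_b[: up_b.index(lca)]:
            head, label = self._head[node]
            arcs.append((head, node, label))
        return arcs


@dataclass(frozen=True)
class Alignment:
    """Where one entity mention sits in the sentence/token layers."""

    sentence_index: int
    head: int
    covered: tuple[int, ...]


@dataclass
class ParsedDocument:
    doc: AnnotatedDocument
    sentences: list[SentenceParse]
    alignment: dict[str, Alignment] = field(default_factory=dict)

    def sentence_of(self, mention_id: str) -> SentenceParse:
        return self.sentences[self.alignment[mention_id].sentence_index]

    def mentions_in_sentence(self, sent_index: int) -> list[EntityMention]:
        return [
            self.doc.entity(mid)
            for mid, al in self.alignment.items()
            if al.sentence_index == sent_index
        ]

    def global_positions(self) -> dict[tuple[int, int], int]:
        """(sentence, token) -> position in document reading order."""
        positions = {}
        counter = 0
        for sent in self.sentences:
            for token in sent.tokens:
                positions[(sent.index, token.index)] = counter
                counter += 1
        return positions


# ---------------------------------------------------------------------------
# CoNLL-U reading


def read_conllu(conllu_text: str) -> list[list[dict]]:
    """Parse CoNLL-U into raw sentences of token dicts (id/form/lemma/upos/head/deprel)."""
    sentences: list[list[dict]] = []
    current: list[dict] = []
    for lineno, line in enumerate(conllu_text.splitlines(), start=1):
        line = line.rstrip("\n")
        if not line.strip():
            if current:
                sentences.append(current)
                current = []
            continue
        if line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 8:
            raise ValueError(f"conllu line {lineno}: expected >=8 columns")
        if "-" in cols[0] or "." in cols[0]:
            continue  # multiword-token ranges / empty nodes not used
        current.append(
            {
                "id": int(cols[0]),
                "form": cols[1],
                "lemma": cols[2],
                "upos": cols[3],
                "head": int(cols[6]),
                "deprel": cols[7],
            }
        )
    if current:
        sentences.append(current)
    return sentences


def _align_tokens(text: str, raw_sentences: list[list[dict]]) -> list[list[tuple[int, int]]]:
    """Greedily locate each token's character span in the raw text."""
    spans_per_sentence = []
    cursor = 0
    for raw in raw_sentences:
        spans = []
        for tok in raw:
            form = tok["form"]
            start = text.find(form, cursor)
            if start == -1:
                raise ValueError(
                    f"token {form!r} not found in text after offset {cursor}"
                )
            spans.append((start, start + len(form)))
            cursor = start + len(form)
        spans_per_sentence.append(spans)
    return spans_per_sentence


def _build_sentence(index: int, raw: list[dict], spans: list[tuple[int, int]]) -> SentenceParse:
    tokens = [
        Token(i, t["form"], t["lemma"], t["upos"], spans[i]) for i, t in enumerate(raw)
    ]
    arcs = []
    root = None
    for i, t in enumerate(raw):
        if t["head"] == 0:
            if root is None:
                root = i
            else:  # secondary roots re-attached to keep a single tree
                arcs.append((root, i, "parataxis"))
        else:
            arcs.append((t["head"] - 1, i, t["deprel"]))
    if root is None:
        raise ValueError("sentence has no root")
    return SentenceParse(index, tokens, arcs, root)


def _merge_sentences(a: SentenceParse, b: SentenceParse) -> SentenceParse:
    """Join two sentences split across a mention; b's tree hangs off a's root."""
    offset = len(a.tokens)
    tokens = list(a.tokens) + [
        Token(offset + t.index, t.surface, t.lemma, t.pos, t.span) for t in b.tokens
    ]
    arcs = list(a.arcs) + [(h + offset, d + offset, lab) for h, d, lab in b.arcs]
    arcs.append((a.root, b.root + offset, "parataxis"))
    return SentenceParse(a.index, tokens, arcs, a.root)


def _mention_alignment(
    doc: AnnotatedDocument, sentences: list[SentenceParse]
) -> dict[str, Alignment]:
    alignment = {}
    for mention in doc.entities:
        charset = mention.charset()
        covered_by_sentence: dict[int, list[int]] = {}
        for sent in sentences:
            for token in sent.tokens:
                if charset & set(range(*token.span)):
                    covered_by_sentence.setdefault(sent.index, []).append(token.index)
        if not covered_by_sentence:
            raise ValueError(f"{doc.doc_id}/{mention.id}: no token covers the mention")
        if len(covered_by_sentence) != 1:
            raise ValueError(
                f"{doc.doc_id}/{mention.id}: mention crosses sentence boundary"
            )
        (sent_index, covered), = covered_by_sentence.items()
        sent = sentences[sent_index]
        covered_set = set(covered)
        # head = token governed from outside the mention (fallback: last token)
        head = covered[-1]
        for idx in covered:
            head_idx = sent.head_of(idx)
            if head_idx is None or head_idx not in covered_set:
                head = idx
                break
        alignment[mention.id] = Alignment(sent_index, head, tuple(covered))
    return alignment


def _sentences_for_doc(doc: AnnotatedDocument) -> list[SentenceParse]:
    if not doc.conllu:
        raise ParserBackendError(
            f"{doc.doc_id}: gold backend needs a CoNLL-U analysis on the document"
        )
    raw = read_conllu(doc.conllu)
    spans = _align_tokens(doc.text, raw)
    sentences = [_build_sentence(i, r, s) for i, (r, s) in enumerate(zip(raw, spans))]
    # merge sentences wrongly split through an entity mention
    changed = True
    while changed:
        changed = False
        boundaries = [s.tokens[0].span[0] for s in sentences[1:]]
        for mention in doc.entities:
            for k, boundary in enumerate(boundaries):
                if mention.start < boundary <= mention.end - 1 or (
                    mention.start < boundary and mention.end > boundary
                ):
                    merged = _merge_sentences(sentences[k], sentences[k + 1])
                    sentences = sentences[:k] + [merged] + sentences[k + 2 :]
                    sentences = [
                        SentenceParse(i, s.tokens, s.arcs, s.root)
                        for i, s in enumerate(sentences)
                    ]
                    changed = True
                    break
            if changed:
                break
    return sentences


_BACKENDS: dict[str, Callable[[AnnotatedDocument], list[SentenceParse]]] = {
    "gold": _sentences_for_doc,
}


def register_backend(
    name: str, fn: Callable[[AnnotatedDocument], list[SentenceParse]]
) -> None:
    _BACKENDS[name] = fn


def analyze(doc: AnnotatedDocument, backend: str = "gold") -> ParsedDocument:
    """Produce the sentence/dependency layers and align every entity mention."""
    if backend not in _BACKENDS:
        raise ParserBackendError(
            f"unknown parser backend {backend!r}; available: {sorted(_BACKENDS)}"
        )
    sentences = _BACKENDS[backend](doc)
    alignment = _mention_alignment(doc, sentences)
    return ParsedDocument(doc=doc, sentences=sentences, alignment=alignment)


# ---------------------------------------------------------------------------
# Tree predicates


def is_descendant(sent: SentenceParse, node: int, ancestor: int) -> bool:
    """Proper dominance: ancestor lies on the head path from node to root."""
    return ancestor in sent.ancestors(node)


def _is_clause_boundary(sent: SentenceParse, head: int, dep: int, label: str) -> bool:
    base = label.split(":")[0]
    if label in CLAUSE_RELATIONS or base in {
        "ccomp",
        "xcomp",
        "advcl",
        "acl",
        "csubj",
        "parataxis",
    }:
        return True
    if base == "conj":
        return (
            sent.tokens[head].pos in VERB_POS and sent.tokens[dep].pos in VERB_POS
        )
    return False


def same_clause(sent: SentenceParse, a: int, b: int) -> bool:
    """True when the dependency path between a and b crosses no clause boundary."""
    if a == b:
        return True
    return not any(
        _is_clause_boundary(sent, head, dep, label)
        for head, dep, label in sent.path(a, b)
    )


def word_distance(
    pdoc: ParsedDocument, mention_a: str, mention_b: str
) -> tuple[int, int]:
    """(tokens strictly between the mentions in reading order, |sentence delta|)."""
    positions = pdoc.global_positions()
    al_a = pdoc.alignment[mention_a]
    al_b = pdoc.alignment[mention_b]
    pos_a = [positions[(al_a.sentence_index, t)] for t in al_a.covered]
    pos_b = [positions[(al_b.sentence_index, t)] for t in al_b.covered]
    if max(pos_a) < min(pos_b):
        between = min(pos_b) - max(pos_a) - 1
    elif max(pos_b) < min(pos_a):
        between = min(pos_a) - max(pos_b) - 1
    else:
        between = 0  # overlapping / nested mentions
    return between, abs(al_a.sentence_index - al_b.sentence_index)


def trigger_word_distance(
    pdoc: ParsedDocument, sent_index: int, token_index: int, mention_id: str
) -> tuple[int, int]:
    """Distance between one token (a trigger occurrence) and a mention."""
    positions = pdoc.global_positions()
    pos_t = positions[(sent_index, token_index)]
    al = pdoc.alignment[mention_id]
    pos_m = [positions[(al.sentence_index, t)] for t in al.covered]
    if pos_t < min(pos_m):
        between = min(pos_m) - pos_t - 1
    elif pos_t > max(pos_m):
        between = pos_t - max(pos_m) - 1
    else:
        between = 0
    return between, abs(sent_index - al.sentence_index)
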