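"""Sentence/dependency layer: CoNLL-U reading, alignment, tree predicates."""

import pytest

from bbct.docbuild import DocBuilder
from bbct.standoff import AnnotatedDocument, EntityMention
from bbct.syntax import (
    ParserBackendError,
    SentenceParse,
    Token,
    analyze,
    is_descendant,
    read_conllu,
    same_clause,
    trigger_word_distance,
    word_distance,
)


def _toy_sentence() -> SentenceParse:
    # "cats chase mice outside" ; chase is root
    tokens = [
        Token(0, "cats", "cat", "NOUN", (0, 4)),
        Token(1, "chase", "chase", "VERB", (5, 10)),
        Token(2, "mice", "mouse", "NOUN", (11, 15)),
        Token(3, "outside", "outside", "ADV", (16, 23)),
    ]
    arcs = [(1, 0, "nsubj"), (1, 2, "obj"), (1, 3, "advmod")]
    return SentenceParse(0, tokens, arcs, 1)


def test_sentence_accessors():
    sent = _toy_sentence()
    assert sent.head_of(0) == 1 and sent.head_of(1) is None
    assert sent.label_of(2) == "obj"
    assert {c for c, _ in sent.children(1)} == {0, 2, 3}
    assert sent.ancestors(0) == [1]
    assert sent.subtree(1) == {0, 1, 2, 3}
    assert sent.subtree(0) == {0}
    assert is_descendant(sent, 0, 1) and not is_descendant(sent, 1, 0)


def test_path_through_lowest_common_ancestor():
    sent = _toy_sentence()
    path = sent.path(0, 2)
    assert {(h, d) for h, d, _ in path} == {(1, 0), (1, 2)}
    assert sent.path(1, 1) == []


def test_sentence_validation_rejects_broken_trees():
    tokens = [
        Token(0, "a", "a", "DET", (0, 1)),
        Token(1, "b", "b", "NOUN", (2, 3)),
    ]
    with pytest.raises(ValueError):  # token with two heads
        SentenceParse(0, tokens, [(1, 0, "det"), (1, 0, "amod")], 1)
    with pytest.raises(ValueError):  # not covering all tokens
        SentenceParse(0, tokens + [Token(2, "c", "c", "NOUN", (4, 5))], [(1, 0, "det")], 1)
    with pytest.raises(ValueError):  # cycle
        SentenceParse(0, tokens, [(0, 1, "dep"), (1, 0, "dep")], 0)


def test_read_conllu_skips_comments_and_ranges():
    text = (
        "# sent_id = 1\n"
        "1\tthe\tthe\tDET\t_\t_\t2\tdet\t_\t_\n"
        "1-2\tthe gut\t_\t_\t_\t_\t_\t_\t_\t_\n"
        "2\tgut\tgut\tNOUN\t_\t_\t0\troot\t_\t_\n"
        "\n"
        "1\tYes\tyes\tINTJ\t_\t_\t0\troot\t_\t_\n"
    )
    sentences = read_conllu(text)
    assert len(sentences) == 2
    assert [t["form"] for t in sentences[0]] == ["the", "gut"]
    with pytest.raises(ValueError):
        read_conllu("1\ttoo\tfew\tcols\n")


def test_analyze_requires_conllu_for_gold_backend():
    doc = AnnotatedDocument("d", "Hello world.")
    with pytest.raises(ParserBackendError):
        analyze(doc)
    with pytest.raises(ParserBackendError):
        analyze(doc, backend="no-such-backend")


def test_alignment_heads_are_externally_governed(curated, curated_parsed):
    """The mention head is the covered token whose head lies outside the span."""
    pdoc = curated_parsed["kingae-pharyngeal"]
    al = pdoc.alignment["T1"]  # "K. kingae", kingae (index 9) attaches outside
    assert al.sentence_index == 0
    assert al.covered == (8, 9)
    assert al.head == 9
    for doc_id, pdoc in curated_parsed.items():
        doc = curated[doc_id]
        for mention in doc.entities:
            al = pdoc.alignment[mention.id]
            sent = pdoc.sentences[al.sentence_index]
            head_head = sent.head_of(al.head)
            assert head_head is None or head_head not in set(al.covered)


def test_alignment_of_token_internal_mention(curated_parsed):
    """A mention inside one token ("MRSA" in "MRSA-contaminated") aligns to it."""
    pdoc = curated_parsed["mrsa-correctional"]
    al = pdoc.alignment["T1"]
    assert al.covered == (1,)
    assert pdoc.sentences[0].tokens[1].surface == "MRSA-contaminated"


def test_sentences_split_through_a_mention_are_merged():
    b = DocBuilder("split")
    b.sentence([
        ("Listeria", "Listeria", "PROPN", 0, "root"),
    ])
    b.sentence([
        ("monocytogenes", "monocytogenes", "PROPN", 2, "compound"),
        ("grew", "grow", "VERB", 0, "root"),
        (".", ".", "PUNCT", 2, "punct"),
    ])
    b.mention("T1", "Bacteria", (0, 0, 0))
    doc = b.build()
    # rewrite the mention across the sentence boundary
    doc.entities = [
        EntityMention("T1", "Bacteria", ((0, 22),), doc.text[0:22])
    ]
    doc.__post_init__()
    pdoc = analyze(doc)
    assert len(pdoc.sentences) == 1
    assert pdoc.alignment["T1"].covered == (0, 1)


def test_same_clause_detects_clause_boundaries(curated_parsed):
    pdoc = curated_parsed["aquaeolei-subterranean"]
    sent = pdoc.sentences[0]
    aquaeolei = pdoc.alignment["T1"].head
    microorganism = 24  # root, main clause
    assert not same_clause(sent, aquaeolei, microorganism)  # crosses advcl
    sulfur_bact = pdoc.alignment["T2"].head
    assert same_clause(sent, aquaeolei, sulfur_bact)  # both in the advcl


def test_word_distance_counts_tokens_between(curated_parsed):
    pdoc = curated_parsed["kingae-pharyngeal"]
    # T1 covers tokens 8-9 of sentence 0; T2 covers token 3 of sentence 1
    between, sents = word_distance(pdoc, "T1", "T2")
    assert sents == 1
    assert between == 2 + 3  # "infection ." plus "The prevalence of"
    assert word_distance(pdoc, "T1", "T1") == (0, 0)


def test_trigger_word_distance(curated_parsed):
    pdoc = curated_parsed["kingae-pharyngeal"]
    # trigger "carriage" = sentence 1, token 4; T2 "pharyngeal" = token 3
    assert trigger_word_distance(pdoc, 1, 4, "T2") == (0, 0)
    assert trigger_word_distance(pdoc, 1, 4, "T1") == (6, 1)


def test_global_positions_monotone(curated_parsed):
    pdoc = curated_parsed["mrsa-snf"]
    positions = pdoc.global_positions()
    ordered = sorted(positions, key=lambda st: positions[st])
    assert ordered == sorted(positions)  # (sentence, token) lexicographic order
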