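"""Trigger lexicon: structure, mining, packaged lists, in-document detection."""

import warnings

import pytest

from bbct.fixtures import FixtureConfig, generate_corpus
from bbct.stem import porter_stem
from bbct.triggers import (
    Gazetteer,
    TriggerLexicon,
    TriggerMention,
    compile_lexicon,
    detect_triggers,
    filter_non_triggers,
    find_bacteria_mentions,
    load_packaged_lexicon,
    match_trigger_patterns,
    normalize_trigger,
    span_head,
)


# ---------------------------------------------------------------------------
# TriggerLexicon


def test_lexicon_validation():
    with pytest.raises(ValueError):
        TriggerLexicon(entries={"Carriage": (3, "x")})
    with pytest.raises(ValueError):
        TriggerLexicon(entries={"carriage": (0, "x")})


def test_lexicon_tsv_roundtrip():
    lex = TriggerLexicon(entries={"carriage": (12, "train"), "strain": (40, "train")})
    again = TriggerLexicon.from_tsv(lex.to_tsv())
    assert again.entries == lex.entries
    assert "carriage" in again and len(again) == 2
    assert again.frequency("strain") == 40
    with pytest.raises(ValueError):
        TriggerLexicon.from_tsv("nofrequency\n")


def test_stem_index_ties_keep_most_frequent():
    # "isolation" and "isolated" share the stem "isol"
    lex = TriggerLexicon(entries={"isolation": (10, "x"), "isolated": (90, "x")})
    index = lex.stem_index()
    assert index[porter_stem("isolation")] == "isolated"


# ---------------------------------------------------------------------------
# Gazetteer matching


def test_gazetteer_longest_match(curated_parsed):
    gaz = Gazetteer(["Staphylococcus", "Staphylococcus aureus",
                     "Methicillin-resistant Staphylococcus aureus", "MRSA"])
    # r3 snippet: "Methicillin-resistant Staphylococcus aureus ( MRSA ) ..."
    corpus = generate_corpus(FixtureConfig(seed=3, n_docs=13, templates=["r3-apposition"]))
    from bbct.syntax import analyze

    sent = analyze(corpus[0]).sentences[0]
    spans = find_bacteria_mentions(sent, gaz)
    assert (0, 3) in spans  # the full three-token name, not its nested parts
    assert (4, 5) in spans  # MRSA
    assert (1, 3) not in spans and (1, 2) not in spans


def test_gazetteer_requires_names():
    with pytest.raises(ValueError):
        Gazetteer(["", "  "])


def test_span_head_prefers_externally_governed_token(curated_parsed):
    pdoc = curated_parsed["kingae-pharyngeal"]
    sent = pdoc.sentences[0]
    assert span_head(sent, 8, 10) == 9  # "K. kingae": kingae governed from outside


# ---------------------------------------------------------------------------
# candidate normalization and filtering


def test_normalize_trigger_uses_nominalization_table(curated_parsed):
    pdoc = curated_parsed["mrsa-snf"]
    isolated = pdoc.sentences[2].tokens[2]  # "isolated", VERB
    assert isolated.surface == "isolated"
    assert normalize_trigger(isolated) == "isolation"
    carriage = curated_parsed["kingae-pharyngeal"].sentences[1].tokens[4]
    assert normalize_trigger(carriage) == "carriage"  # noun keeps its lemma


def test_filter_non_triggers_drops_method_and_amount_words():
    kept = filter_non_triggers({"carriage", "study", "number", "analysis", "strain"})
    assert kept == {"carriage", "strain"}


# ---------------------------------------------------------------------------
# mining


def test_match_trigger_patterns_mining_mode(curated_parsed):
    pdoc = curated_parsed["kingae-pharyngeal"]
    sent = pdoc.sentences[1]
    gaz = Gazetteer(["K. kingae"])
    # no gazetteer name in sentence 1, so anchor on a synthetic span is required:
    assert find_bacteria_mentions(sent, gaz) == []
    sent0 = pdoc.sentences[0]
    spans = find_bacteria_mentions(sent0, gaz)
    assert spans == [(8, 10)]
    with pytest.raises(ValueError):
        match_trigger_patterns(sent0, spans, require_location_entity=True)


def test_compile_lexicon_mines_template_triggers():
    corpus = generate_corpus(
        FixtureConfig(seed=5, n_docs=12, templates=["p1-elimination", "p3-carriage"])
    )
    gaz = Gazetteer([" ".join(doc.bacteria[0].surface.split()) for doc in corpus])
    lex = compile_lexicon(corpus, gaz, min_frequency=1)
    assert "elimination" in lex  # P1 slot noun
    assert {"carriage", "colonization"} & lex.lemmas()  # P3 slot nouns
    # threshold drops everything rarer than its frequency
    high = compile_lexicon(corpus, gaz, min_frequency=10 ** 6)
    assert len(high) == 0
    assert lex.metadata["min_frequency"] == 1


def test_compile_lexicon_warns_on_empty_corpus():
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        lex = compile_lexicon([], Gazetteer(["X y"]), min_frequency=1)
    assert len(lex) == 0
    assert any("empty corpus" in str(w.message) for w in caught)


# ---------------------------------------------------------------------------
# packaged lexicons


def test_packaged_train_lexicon():
    lex = load_packaged_lexicon("train")
    assert lex.frequency("isolate") == 8
    assert lex.metadata["original_total"] == 15
    assert len(lex) == 15


def test_packaged_unlabeled_lexicon_contains_train():
    train = load_packaged_lexicon("train")
    unlabeled = load_packaged_lexicon("unlabeled")
    assert train.lemmas() <= unlabeled.lemmas()
    assert unlabeled.frequency("strain") == 21256
    assert unlabeled.frequency("infection") == 12856
    assert unlabeled.frequency("isolate") == 9555
    with pytest.raises(ValueError):
        load_packaged_lexicon("nope")


# ---------------------------------------------------------------------------
# detection


def test_detect_triggers_stem_matches_and_skips_entities(curated_parsed):
    lex = load_packaged_lexicon("unlabeled")
    pdoc = curated_parsed["mrsa-snf"]
    found = detect_triggers(pdoc, lex)
    at = {(t.sentence_index, t.token_index): t.lemma for t in found}
    # "isolated" (sentence 2, token 2) stem-matches the nominal entry
    assert at[(2, 2)] in {"isolation", "isolate"}
    # "culture" in sentence 0 is free text: detected
    assert (0, 2) in at and at[(0, 2)] == "culture"
    # "cultures" in sentence 1 sits inside the T3 mention span: excluded
    assert (1, 4) not in at
    # detections are unlinked at this stage
    assert all(t.linked_bacteria is None for t in found)


def test_detect_triggers_matches_verbal_forms(curated_parsed):
    lex = load_packaged_lexicon("unlabeled")
    pdoc = curated_parsed["kingae-pharyngeal"]
    lemmas = {t.lemma for t in detect_triggers(pdoc, lex)}
    assert "carriage" in lemmas
    assert "infection" in lemmas


def test_trigger_mention_at():
    t = TriggerMention("carriage", 1, 4)
    assert t.at() == (1, 4)
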