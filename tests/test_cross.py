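"""Cross-sentence inference: candidate selection, context windows, transitivity."""

from bbct import cross, intra
from bbct.docbuild import DocBuilder
from bbct.standoff import LivesInEvent
from bbct.syntax import analyze
from bbct.triggers import TriggerMention, detect_triggers, load_packaged_lexicon


def test_select_candidates_corpus_observations(curated_parsed):
    pdoc = curated_parsed["mrsa-snf"]
    intra_events = [LivesInEvent("T1", "T2"), LivesInEvent("T5", "T6")]
    bacteria, locations = cross.select_candidates(pdoc, intra_events)
    # both bacteria already have an intra event -> candidates for more
    assert bacteria == {"T1", "T5"}
    # locations already in an intra event never join cross-sentence events
    assert "T2" not in locations and "T6" not in locations
    assert {"T3", "T4"} <= locations


def test_select_candidates_without_co_sentential_location(curated_parsed):
    pdoc = curated_parsed["kingae-pharyngeal"]
    bacteria, locations = cross.select_candidates(pdoc, [])
    assert bacteria == {"T1"}  # no location in T1's sentence
    assert locations == {"T2"}


def test_select_candidates_eligibility_restriction(curated_parsed):
    pdoc = curated_parsed["kingae-pharyngeal"]
    bacteria, locations = cross.select_candidates(pdoc, [], eligible={"T2"})
    assert bacteria == set() and locations == {"T2"}


def _chain_doc(bacteria_sentences, n_sentences):
    """One-sentence-per-line doc; listed sentences carry a bacteria mention."""
    b = DocBuilder("chain")
    for i in range(n_sentences):
        if i in bacteria_sentences:
            b.sentence([
                ("Salmonella", "Salmonella", "PROPN", 2, "nsubj"),
                ("grew", "grow", "VERB", 0, "root"),
                (".", ".", "PUNCT", 2, "punct"),
            ])
        else:
            b.sentence([
                ("Growth", "growth", "NOUN", 2, "nsubj"),
                ("continued", "continue", "VERB", 0, "root"),
                (".", ".", "PUNCT", 2, "punct"),
            ])
    for k, i in enumerate(sorted(bacteria_sentences), start=1):
        b.mention(f"T{k}", "Bacteria", (i, 0, 0))
    return analyze(b.build())


def test_build_window_extent_and_truncation():
    pdoc = _chain_doc({0, 4}, 8)
    w0 = cross.build_window(pdoc, "T1", size=3)
    assert (w0.lo, w0.hi) == (0, 3)  # truncated before the sentence holding T2
    w1 = cross.build_window(pdoc, "T2", size=3)
    assert (w1.lo, w1.hi) == (1, 7)
    assert 3 in w1 and 0 not in w1
    small = cross.build_window(pdoc, "T2", size=1)
    assert (small.lo, small.hi) == (3, 5)


def test_build_window_none_when_sharing_a_sentence(curated_parsed):
    pdoc = curated_parsed["aquaeolei-subterranean"]
    for b_id in ("T1", "T2", "T3", "T4"):
        assert cross.build_window(pdoc, b_id) is None


def test_windows_never_contain_other_bacteria(curated_parsed, synthetic_parsed):
    for pdoc in list(curated_parsed.values()) + list(synthetic_parsed):
        for mention in pdoc.doc.bacteria:
            window = cross.build_window(pdoc, mention.id)
            if window is None:
                continue
            for other in pdoc.doc.bacteria:
                if other.id == mention.id:
                    continue
                assert pdoc.alignment[other.id].sentence_index not in window


def test_infer_cross_sentence_worked_example(curated_parsed):
    pdoc = curated_parsed["kingae-pharyngeal"]
    triggers = detect_triggers(pdoc, load_packaged_lexicon("unlabeled"))
    events = cross.infer_cross_sentence(pdoc, triggers, intra_events=[])
    assert [(e.pair, e.sentence_span) for e in events] == [(("T1", "T2"), "cross")]
    assert events[0].provenance.startswith("x-trigger:carriage:")


def test_infer_cross_sentence_respects_window_size(curated_parsed):
    pdoc = curated_parsed["kingae-pharyngeal"]
    triggers = detect_triggers(pdoc, load_packaged_lexicon("unlabeled"))
    assert cross.infer_cross_sentence(pdoc, triggers, [], window_size=0) == []


def test_infer_cross_sentence_skips_ineligible_bacteria(curated_parsed):
    pdoc = curated_parsed["kingae-pharyngeal"]
    triggers = detect_triggers(pdoc, load_packaged_lexicon("unlabeled"))
    assert cross.infer_cross_sentence(pdoc, triggers, [], eligible={"T2"}) == []


def test_intra_locations_stay_out_of_cross_events(curated_parsed):
    """A location that already has an intra-sentence event is not re-used."""
    pdoc = curated_parsed["kingae-pharyngeal"]
    triggers = detect_triggers(pdoc, load_packaged_lexicon("unlabeled"))
    taken = [LivesInEvent("T1", "T2", sentence_span="intra")]
    assert cross.infer_cross_sentence(pdoc, triggers, taken) == []


def test_same_sentence_triggers_do_not_create_cross_events(curated_parsed):
    """Triggers in the anchor's own sentence belong to the intra sieve."""
    pdoc = curated_parsed["rhizogenes-tdna"]
    trig = TriggerMention("strain", 0, 2)  # same sentence as T1
    assert cross.infer_cross_sentence(pdoc, [trig], []) == []


def test_cross_events_propagate_only_within_window(curated_parsed):
    """aeruginosa-hcn: window triggers add T4 alongside the two correct events."""
    pdoc = curated_parsed["aeruginosa-hcn"]
    triggers = intra.link_triggers(
        pdoc, detect_triggers(pdoc, load_packaged_lexicon("unlabeled"))
    )
    events = cross.infer_cross_sentence(pdoc, triggers, [])
    assert {e.pair for e in events} == {("T1", "T2"), ("T1", "T3"), ("T1", "T4")}
    assert all(e.sentence_span == "cross" for e in events)
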