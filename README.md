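# bbct — context-trigger inference of bacteria–biotope events

`bbct` extracts **Lives_In** events — assertions that a bacterium lives in a
physical location — from biomedical text annotated in BioNLP-ST standoff
format (`.txt` raw text, `.a1` entity mentions, `.a2` relations). It targets
the Bacteria Biotope event setting, with `Bacteria` mentions on one side and
`Habitat`/`Geographical` mentions on the other.

## The problem

Most relation extractors only link mentions inside one sentence, but a large
share of true bacteria–location relations in abstracts cross sentence
boundaries: a bacterium is named once and then referred to indirectly
("…pharyngeal **carriage** among surgical patients…"). `bbct` implements an
unsupervised multi-pass sieve that recovers such events through **context
triggers** — words like *carriage*, *infection*, or *isolate* whose occurrence
implies the presence of a nearby-mentioned bacterium, so they act as indirect
anaphors that bridge clauses and sentences.

The sieves run in order of decreasing precision:

1. **Trigger detection** — stem-match document tokens against a trigger
   lexicon mined from corpora with dependency patterns anchored on
   gazetteer-matched bacteria names.
2. **Modality filtering** — withdraw mentions inside hypothesis/research-goal
   scopes ("To evaluate …"), *if/whether* clauses, and negation scopes
   ("No …", "none of …", "is not … understood"), which the annotation scheme
   does not count as events.
3. **Intra-clause patterns** — three dependency patterns (`{noun} of [B] in
   [L]`, `[B] {n/v/p} in [L]`, `[L] {n/v/p} of [B]`) plus noun-phrase
   co-nesting, span nesting, and direct prepositional links.
4. **Propagation** — extend confirmed events to syntactically related
   same-type mentions: nesting, coordination, apposition, comma-joined
   geographical hierarchies, and participle–preposition links, to a fixpoint.
5. **Cross-clause and cross-sentence inference** — a trigger linked to its
   nearest bacterium stands in for it as a pattern anchor; within a context
   window of up to ±3 sentences (truncated at other bacteria mentions) a
   trigger–location match yields the bacteria–location event by transitivity.

Evaluation uses the task's matching-similarity scoring: a predicted pair is
correct when it equals (or is `Equiv`-equivalent to) a reference pair, with
precision/recall/F1 reported separately for intra- and cross-sentence events.

## Worked example

```python
from bbct.examples import curated_example
from bbct import pipeline

doc = curated_example("kingae-pharyngeal")
print(doc.text)

result = pipeline.run_detailed(doc)
for event in result.events:
    b, l = doc.entity(event.bacteria_id), doc.entity(event.location_id)
    print(f"{event.bacteria_id} ({b.surface}) -> {event.location_id} ({l.surface})"
          f"  [{event.provenance}, {event.sentence_span}]")
print(result.to_a2())
```

Output:

```
None of the colonized children experienced an invasive K. kingae infection. The prevalence of pharyngeal carriage among surgical patients was 8.0%.
T1 (K. kingae) -> T2 (pharyngeal)  [x-trigger:carriage:N1, cross]
R1	Lives_In Bacteria:T1 Location:T2
```

No sentence states the relation directly: *K. kingae* sits in sentence one,
*pharyngeal* in sentence two. The trigger *carriage* in the second sentence is
linked back to the bacterium and forward (noun-phrase co-nesting, `N1`) to the
location, yielding the cross-sentence event.

## Command line

```
$ bbct make-fixtures --seed 11 --n-docs 13 --out fx
wrote 13 documents to fx
$ bbct extract --input fx --out out --mode M3
cross-trigger-000	events=1	intra=0	cross=1
...
total	intra=21	cross=1
$ bbct evaluate --gold fx --pred out
stratum	gold	predicted	correct	precision	recall	f1
Intra	21	21	21	100.0	100.0	100.0
Cross	1	1	1	100.0	100.0	100.0
All	22	22	22	100.0	100.0	100.0
```

`bbct collect-triggers --corpus DIR --out lexicon.tsv` mines a trigger lexicon
from any standoff corpus. `bbct extract` accepts a YAML `--config` mirroring
`PipelineConfig`, a `--lexicon` name (`train`/`unlabeled`) or TSV path,
`--no-modality`, `--window-size`, and `--external-intra DIR` to replace the
rule-based intra-sentence stage with another extractor's `.a2` output.

### Ablation modes

| mode | intra-sentence events | triggers | modality |
|------|----------------------|----------|----------|
| M1   | rule-based patterns + propagation | off | on |
| M2   | rule-based | training-data lexicon | on |
| M3   | rule-based | unlabeled-corpus lexicon | on |
| M4   | external `.a2` | unlabeled-corpus lexicon | on |
| M5   | external `.a2` | unlabeled-corpus lexicon | off |

On any fixed document the event sets nest: M1 ⊆ M2 ⊆ M3 (the training lexicon
is contained in the unlabeled one).

## Reproduction

```
python -m pytest -q tests/                          # full suite
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The acceptance script recomputes the package's headline quantities: the
evaluation arithmetic on published count triples, packaged-lexicon
frequencies, curated worked-example outcomes, and per-template
precision/recall on seeded synthetic corpora (all 100.0 for a correct build).
Everything is deterministic given the seed; there is no randomness anywhere in
extraction itself.

Corpus-level scores of the original task are **not** reproduced here: they
require the official hidden-label evaluation service, the full BB-event
corpus, a retrained supervised intra-sentence extractor, and a web-scale
PubMed/PMC crawl for trigger harvesting. See `docs/methods.md` for what the
packaged lexicons contain, what was reconstructed, and the known failure modes
the curated examples deliberately preserve.
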