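"""Sieve orchestration: triggers → modality → intra → propagation → cross.

The extractor is a multi-pass sieve ordered by decreasing precision.  Trigger
occurrences are detected first; the modality filter then withdraws mentions
and triggers inside hypothesis, conditional, or negation scopes; intra-clause
patterns extract the syntactically closest events and propagation closes them
over coordination, apposition, nesting, and geographical hierarchies; trigger
transitivity adds longer-range events inside the sentence and finally across
sentence boundaries within a context window.

Externally produced intra-sentence predictions (a standoff .a2 from any other
extractor) can replace the rule-based intra stage, with trigger-based
cross-sentence inference running on top.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

from bbct import cross, evaluation, intra, modality
from bbct.patterns import LOC_PREPS
from bbct.standoff import AnnotatedDocument, LivesInEvent, dedupe_events, write_predictions
from bbct.syntax import ParsedDocument, analyze
from bbct.triggers import TriggerLexicon, detect_triggers, load_packaged_lexicon

MODES = ("M1", "M2", "M3", "M4", "M5")


@dataclass
class PipelineConfig:
    """Which sieves run, with what lexicon, window, and parser backend.

    ``lexicon`` may be a packaged lexicon name ("train" or "unlabeled") or a
    :class:`~bbct.triggers.TriggerLexicon` instance.  With ``use_patterns``
    False, ``external_intra`` supplies the intra-sentence events instead of
    the rule-based patterns.
    """

    lexicon: object = "unlabeled"
    window_size: int = 3
    use_modality: bool = True
    use_patterns: bool = True
    use_triggers: bool = True
    use_propagation: bool = True
    use_cross_sentence: bool = True
    external_intra: Optional[Sequence[LivesInEvent]] = None
    backend: str = "gold"
    tiebreak: str = "preceding"
    loc_preps: frozenset[str] = field(default_factory=lambda: LOC_PREPS)

    @classmethod
    def for_mode(
        cls,
        mode: str,
        external_intra: Optional[Sequence[LivesInEvent]] = None,
        **overrides: object,
    ) -> "PipelineConfig":
        """Ablation presets M1-M5.

        M1: intra-clause patterns (with propagation) only.
        M2: M1 + trigger-based inference, training-data lexicon.
        M3: M1 + trigger-based inference, unlabeled-data lexicon.
        M4: externally supplied intra events + trigger-based inference (unlabeled).
        M5: M4 without modality filtering.
        """
        if mode not in MODES:
            raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
        cfg = cls()
        if mode == "M1":
            cfg = replace(cfg, use_triggers=False, use_cross_sentence=False)
        elif mode == "M2":
            cfg = replace(cfg, lexicon="train")
        elif mode in ("M4", "M5"):
            if external_intra is None:
                raise ValueError(f"mode {mode} needs external intra-sentence events")
            cfg = replace(
                cfg,
                use_patterns=False,
                external_intra=list(external_intra),
                use_modality=(mode == "M4"),
            )
        return replace(cfg, **overrides) if overrides else cfg

    def resolve_lexicon(self) -> Optional[TriggerLexicon]:
        if not (self.use_triggers or self.use_cross_sentence):
            return None
        if isinstance(self.lexicon, TriggerLexicon):
            return self.lexicon
        if isinstance(self.lexicon, str):
            return load_packaged_lexicon(self.lexicon)
        raise ValueError(
            f"lexicon must be a packaged name or TriggerLexicon, got {self.lexicon!r}"
        )

    def validate(self) -> None:
        if self.window_size < 0:
            raise ValueError("window_size must be >= 0")
        if self.tiebreak not in ("preceding", "following"):
            raise ValueError("tiebreak must be 'preceding' or 'following'")
        if not self.use_patterns and self.external_intra is None:
            raise ValueError("without patterns, external_intra events are required")
        self.resolve_lexicon()


@dataclass
class PipelineResult:
    """Final events plus every intermediate the sieves produced."""

    doc: AnnotatedDocument
    pdoc: ParsedDocument
    events: list[LivesInEvent]
    intra_events: list[LivesInEvent]
    cross_events: list[LivesInEvent]
    triggers: list
    blocked: modality.ModalityBlock

    def to_a2(self) -> str:
        return write_predictions(self.doc, self.events)

    def evaluate(self) -> evaluation.EvalReport:
        return evaluation.evaluate_documents([(self.pdoc, self.events)])


def _event_sort_key(event: LivesInEvent) -> tuple:
    def mention_key(mid: str) -> tuple:
        digits = "".join(ch for ch in mid if ch.isdigit())
        return (int(digits) if digits else 0, mid)

    return (mention_key(event.bacteria_id), mention_key(event.location_id))


def run_detailed(doc: AnnotatedDocument, cfg: Optional[PipelineConfig] = None) -> PipelineResult:
    """Run the sieve pipeline on one document, keeping intermediates."""
    cfg = cfg or PipelineConfig()
    cfg.validate()
    lexicon = cfg.resolve_lexicon()

    pdoc = analyze(doc, backend=cfg.backend)
    triggers = detect_triggers(pdoc, lexicon) if lexicon is not None else []

    aligned = [m.id for m in doc.entities if m.id in pdoc.alignment]
    if cfg.use_modality:
        blocked = modality.find_blocked_mentions(pdoc)
        kept_ids, triggers = modality.apply_filter(pdoc, aligned, triggers, blocked)
        eligible = set(kept_ids)
    else:
        blocked = modality.ModalityBlock()
        eligible = set(aligned)
    eligible_bacteria = [
        m.id for m in doc.bacteria if m.id in eligible and m.id in pdoc.alignment
    ]
    eligible_locations = {
        m.id for m in doc.locations if m.id in eligible and m.id in pdoc.alignment
    }

    # intra-clause patterns (or externally supplied intra events)
    if cfg.use_patterns:
        intra_events = intra.extract_intra_clause(
            pdoc,
            bacteria_ids=eligible_bacteria,
            loc_preps=cfg.loc_preps,
            allowed_locations=eligible_locations,
        )
    else:
        intra_events = [
            e
            for e in dedupe_events(list(cfg.external_intra or []))
            if e.bacteria_id in eligible and e.location_id in eligible
        ]

    # propagation closes pattern-level events over same-type syntactic relations;
    # trigger-inferred events are weaker evidence and are not propagated
    if cfg.use_propagation:
        intra_events = intra.propagate(
            pdoc,
            intra_events,
            allowed_locations=eligible_locations,
            allowed_bacteria=set(eligible_bacteria),
        )

    # trigger transitivity within the sentence
    if cfg.use_triggers:
        linked = intra.link_triggers(
            pdoc, triggers, bacteria_ids=eligible_bacteria, tiebreak=cfg.tiebreak
        )
        cross_clause = intra.infer_cross_clause(
            pdoc,
            linked,
            intra_events,
            loc_preps=cfg.loc_preps,
            allowed_locations=eligible_locations,
        )
        intra_events = dedupe_events([*intra_events, *cross_clause])

    # trigger transitivity across sentences
    cross_events: list[LivesInEvent] = []
    if cfg.use_cross_sentence:
        cross_events = cross.infer_cross_sentence(
            pdoc,
            triggers,
            intra_events,
            window_size=cfg.window_size,
            loc_preps=cfg.loc_preps,
            tiebreak=cfg.tiebreak,
            eligible=eligible,
        )

    events = sorted(
        dedupe_events([*intra_events, *cross_events]), key=_event_sort_key
    )
    return PipelineResult(
        doc=doc,
        pdoc=pdoc,
        events=events,
        intra_events=list(intra_events),
        cross_events=cross_events,
        triggers=list(triggers),
        blocked=blocked,
    )


def run(doc: AnnotatedDocument, cfg: Optional[PipelineConfig] = None) -> list[LivesInEvent]:
    """Extract Lives_In events from one annotated document."""
    return run_detailed(doc, cfg).events


def run_corpus(
    docs: Sequence[AnnotatedDocument], cfg: Optional[PipelineConfig] = None
) -> list[PipelineResult]:
    """Run the pipeline over a corpus, one result per document."""
    return [run_detailed(doc, cfg) for doc in docs]


def evaluate_corpus(results: Sequence[PipelineResult]) -> evaluation.EvalReport:
    """Pooled scores of pipeline results against each document's gold events."""
    return evaluation.evaluate_documents([(r.pdoc, r.events) for r in results])
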