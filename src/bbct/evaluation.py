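"""Matching-similarity precision/recall/F1 for Lives_In events.

A predicted event counts as correct when some reference event has the same (or
Equiv-equivalent) bacteria id and the same (or Equiv-equivalent) location id.
Scores are reported per stratum (intra-sentence, cross-sentence, all) to one
decimal, rounded half-up.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from typing import Iterable, Optional

from bbct.standoff import AnnotatedDocument, EquivalenceSet, LivesInEvent
from bbct.syntax import ParsedDocument


def _round1(value: Fraction) -> float:
    quantized = (
        Decimal(value.numerator) / Decimal(value.denominator)
    ).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
    return float(quantized)


def prf(gold: int, predicted: int, correct: int) -> tuple[float, float, float]:
    """(precision %, recall %, F1 %) at one decimal, half-up; 0 on empty denominators."""
    if min(gold, predicted, correct) < 0:
        raise ValueError("counts must be non-negative")
    if correct > min(gold, predicted):
        raise ValueError("correct cannot exceed gold or predicted")
    precision = Fraction(100 * correct, predicted) if predicted else Fraction(0)
    recall = Fraction(100 * correct, gold) if gold else Fraction(0)
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else Fraction(0)
    )
    return _round1(precision), _round1(recall), _round1(f1)


def _canonicalize(
    pairs: Iterable[tuple[str, str]], equivalences: Iterable[EquivalenceSet]
) -> set[tuple[str, str]]:
    representative: dict[str, str] = {}
    for eq in equivalences:
        rep = min(eq.member_ids)
        for member in eq.member_ids:
            representative[member] = rep
    return {
        (representative.get(b, b), representative.get(l, l)) for b, l in pairs
    }


def match_events(
    predicted: Iterable[LivesInEvent],
    reference: Iterable[LivesInEvent],
    equivalences: Iterable[EquivalenceSet] = (),
    doc: Optional[AnnotatedDocument] = None,
) -> int:
    """Number of distinct predicted pairs matching some reference pair under Equiv."""
    predicted = list(predicted)
    reference = list(reference)
    if doc is not None:
        for event in [*predicted, *reference]:
            doc.entity(event.bacteria_id)
            doc.entity(event.location_id)
    equivalences = list(equivalences)
    pred_pairs = _canonicalize((e.pair for e in predicted), equivalences)
    ref_pairs = _canonicalize((e.pair for e in reference), equivalences)
    return len(pred_pairs & ref_pairs)


def stratify(
    events: Iterable[LivesInEvent], pdoc: ParsedDocument
) -> dict[str, list[LivesInEvent]]:
    """Partition events into intra- and cross-sentence by mention alignment."""
    strata: dict[str, list[LivesInEvent]] = {"intra": [], "cross": []}
    for event in events:
        same = (
            pdoc.alignment[event.bacteria_id].sentence_index
            == pdoc.alignment[event.location_id].sentence_index
        )
        strata["intra" if same else "cross"].append(event)
    return strata


@dataclass(frozen=True)
class StratumScore:
    gold: int
    predicted: int
    correct: int
    precision: float
    recall: float
    f1: float


@dataclass
class EvalReport:
    """Gold/predicted/correct counts and P/R/F1 per stratum (intra, cross, all)."""

    strata: dict[str, StratumScore]

    def __getitem__(self, stratum: str) -> StratumScore:
        return self.strata[stratum]

    def to_tsv(self) -> str:
        lines = ["stratum\tgold\tpredicted\tcorrect\tprecision\trecall\tf1"]
        for name in ("intra", "cross", "all"):
            s = self.strata[name]
            lines.append(
                f"{name.capitalize()}\t{s.gold}\t{s.predicted}\t{s.correct}"
                f"\t{s.precision}\t{s.recall}\t{s.f1}"
            )
        return "".join(line + "\n" for line in lines)


def _score(gold: int, predicted: int, correct: int) -> StratumScore:
    p, r, f1 = prf(gold, predicted, correct)
    return StratumScore(gold, predicted, correct, p, r, f1)


def evaluate_documents(
    docs: list[tuple[ParsedDocument, list[LivesInEvent]]],
) -> EvalReport:
    """Score predictions against each document's gold events, pooled over documents."""
    totals = {name: [0, 0, 0] for name in ("intra", "cross", "all")}
    for pdoc, predicted in docs:
        doc = pdoc.doc
        gold = doc.gold_events or []
        gold_strata = stratify(gold, pdoc)
        pred_strata = stratify(predicted, pdoc)
        for name in ("intra", "cross"):
            g, p = gold_strata[name], pred_strata[name]
            correct = match_events(p, g, doc.equivalences, doc)
            totals[name][0] += len({e.pair for e in g})
            totals[name][1] += len({e.pair for e in p})
            totals[name][2] += correct
        totals["all"][0] += len({e.pair for e in gold})
        totals["all"][1] += len({e.pair for e in predicted})
        totals["all"][2] += match_events(predicted, gold, doc.equivalences, doc)
    return EvalReport(
        strata={name: _score(*counts) for name, counts in totals.items()}
    )
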