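"""Annotation agreement between predicted scaffolds and their partners.

For each type class: how many scaffolds carry any annotation at all
("known"), and how many of those share at least one term with at least one
partner ("matched"). The default partner scope is the witness partners —
the proteins the scaffold is predicted to recruit; ``all_partners`` widens
the scope to every direct interactor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from .model import AnnotationMap, Interactome, ScaffoldPrediction, partners

__all__ = ["SimilaritySummary", "partner_match_summary"]

TYPE_CLASSES = ("I", "II", "III")


@dataclass(frozen=True)
class SimilaritySummary:
    type_class: str
    n_total: int
    n_known: int
    n_matched: int

    @property
    def pct_known(self) -> Optional[float]:
        return self.n_known / self.n_total if self.n_total else None

    @property
    def pct_matched(self) -> Optional[float]:
        return self.n_matched / self.n_known if self.n_known else None


def _partner_scope(
    pred: ScaffoldPrediction, scope: str, interactome: Optional[Interactome]
) -> set[str]:
    if scope == "witness":
        return {p for w in pred.witnesses for p in (w.p1, w.p2)}
    if scope == "all_partners":
        if interactome is None:
            raise ValueError("scope='all_partners' needs the interactome")
        return partners(interactome, pred.scaffold)
    raise ValueError(f"unknown scope {scope!r}")


def partner_match_summary(
    predictions: Iterable[ScaffoldPrediction],
    annotations: AnnotationMap,
    scope: str = "witness",
    interactome: Optional[Interactome] = None,
) -> list[SimilaritySummary]:
    """Per-type-class counts of annotated scaffolds and of scaffolds sharing
    at least one term with at least one partner in scope."""
    predictions = list(predictions)
    if not predictions:
        raise ValueError("no predictions to summarize")
    out = []
    for tc in TYPE_CLASSES:
        preds = [p for p in predictions if p.type_class == tc]
        known = matched = 0
        for pred in preds:
            terms = annotations.terms(pred.scaffold)
            if not terms:
                continue
            known += 1
            scoped = _partner_scope(pred, scope, interactome)
            if any(terms & annotations.terms(p) for p in scoped):
                matched += 1
        out.append(
            SimilaritySummary(type_class=tc, n_total=len(preds), n_known=known, n_matched=matched)
        )
    return out
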