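"""Scoring predictions against gold-standard positive/negative lists.

The gold sets are curated accession lists (their construction is an
upstream, manual step). Proteins outside both gold sets are ignored, so the
confusion table lives entirely inside the gold universe.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional

from .model import ContingencyTable2x2

__all__ = ["MetricPanel", "confusion", "metric_panel", "format_pct"]


@dataclass(frozen=True)
class MetricPanel:
    """Confusion counts plus the derived rate panel.

    A rate whose denominator is zero is undefined and reported as ``None``,
    never as 0.
    """

    tp: int
    fp: int
    fn: int
    tn: int
    precision: Optional[float]
    sensitivity: Optional[float]
    specificity: Optional[float]
    accuracy: Optional[float]
    prevalence: Optional[float]
    miss_rate: Optional[float]
    fall_out: Optional[float]
    false_omission_rate: Optional[float]

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def confusion(predicted: set[str], gold_pos: set[str], gold_neg: set[str]) -> ContingencyTable2x2:
    """Build TP/FP/FN/TN counts from a predicted set and disjoint gold sets."""
    overlap = gold_pos & gold_neg
    if overlap:
        raise ValueError(f"gold sets overlap on {len(overlap)} protein(s)")
    return ContingencyTable2x2(
        a=len(predicted & gold_pos),
        b=len(predicted & gold_neg),
        c=len(gold_pos - predicted),
        d=len(gold_neg - predicted),
    )


def _ratio(num: int, den: int) -> Optional[float]:
    return num / den if den > 0 else None


def metric_panel(table: ContingencyTable2x2) -> MetricPanel:
    """Compute the full rate panel from a confusion table.

    With ``a=TP, b=FP, c=FN, d=TN``: precision a/(a+b), sensitivity a/(a+c),
    specificity d/(b+d), accuracy (a+d)/n, prevalence (a+c)/n, miss rate
    c/(a+c), fall-out b/(b+d), false omission rate c/(c+d).
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    return MetricPanel(
        tp=a,
        fp=b,
        fn=c,
        tn=d,
        precision=_ratio(a, a + b),
        sensitivity=_ratio(a, a + c),
        specificity=_ratio(d, b + d),
        accuracy=_ratio(a + d, table.n),
        prevalence=_ratio(a + c, table.n),
        miss_rate=_ratio(c, a + c),
        fall_out=_ratio(b, b + d),
        false_omission_rate=_ratio(c, c + d),
    )


def format_pct(fraction: Optional[float], decimals: int = 1) -> str:
    """Render a fraction as a percentage with round-half-up at ``decimals``
    places (matching conventional table formatting); ``None`` -> ``NA``."""
    if fraction is None:
        return "NA"
    q = Decimal(1).scaleb(-decimals)
    return str((Decimal(str(fraction)) * 100).quantize(q, rounding=ROUND_HALF_UP))
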