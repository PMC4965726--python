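"""2x2 association testing and native term enrichment.

Association tests (chi-square, risk ratio, odds ratio) quantify whether a
protein group (e.g. Type I scaffold candidates, or kinases) is enriched for
a trait (disease gene, drug target) relative to the proteome universe.
Orientation: rows = group membership, columns = trait status, so the risk
ratio compares trait prevalence inside vs outside the group.

Enrichment uses the hypergeometric upper tail (equivalently one-sided
Fisher) with Bonferroni or Benjamini-Hochberg correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .model import AnnotationMap, ContingencyTable2x2

__all__ = [
    "AssociationResult",
    "EnrichmentRow",
    "build_association_table",
    "association_test",
    "enrich",
    "adjust_pvalues",
]


@dataclass(frozen=True)
class AssociationResult:
    table: ContingencyTable2x2
    chi_square: float
    p_value: float
    risk_ratio: Optional[float]
    odds_ratio: Optional[float]

    def as_dict(self) -> dict:
        return {
            "table": [self.table.a, self.table.b, self.table.c, self.table.d],
            "chi_square": self.chi_square,
            "p_value": self.p_value,
            "risk_ratio": self.risk_ratio,
            "odds_ratio": self.odds_ratio,
        }


@dataclass(frozen=True)
class EnrichmentRow:
    """One annotation term scored against the foreground.

    k of n foreground proteins carry the term; K of N background proteins
    do. fold_enrichment = (k/n)/(K/N); p is the hypergeometric upper tail
    P[X >= k].
    """

    term: str
    k: int
    K: int
    n: int
    N: int
    fold_enrichment: float
    p_value: float
    adjusted_p: float
    significant: bool


def build_association_table(
    group: set[str],
    trait: Union[AnnotationMap, set],
    universe: set[str],
) -> ContingencyTable2x2:
    """Cross-tabulate group membership against trait status over a universe.

    ``trait`` may be an annotation map (any annotated protein counts) or a
    plain accession set; it is intersected with the universe first.
    """
    if not group <= universe:
        missing = sorted(group - universe)[:3]
        raise ValueError(f"group is not a subset of the universe (e.g. {missing})")
    trait_set = (trait.annotated() if isinstance(trait, AnnotationMap) else set(trait)) & universe
    return ContingencyTable2x2(
        a=len(group & trait_set),
        b=len(group - trait_set),
        c=len(trait_set - group),
        d=len(universe - (group | trait_set)),
    )


def association_test(
    table: ContingencyTable2x2, continuity_correction: bool = False
) -> AssociationResult:
    """Pearson chi-square (df=1), risk ratio and odds ratio for a 2x2 table.

    The statistic is uncorrected by default (``continuity_correction``
    enables Yates). All four marginals must be positive; with a zero cell
    the chi-square is still computed but RR/OR are reported absent.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if 0 in table.row_totals or 0 in table.col_totals:
        raise ValueError("chi-square requires all marginals > 0")
    chi2, p, _, _ = sps.chi2_contingency(
        [[a, b], [c, d]], correction=continuity_correction
    )
    risk_ratio = None
    if c + d > 0 and c > 0 and a + b > 0:
        risk_ratio = (a / (a + b)) / (c / (c + d))
    odds_ratio = (a * d) / (b * c) if b > 0 and c > 0 else None
    return AssociationResult(
        table=table,
        chi_square=float(chi2),
        p_value=float(p),
        risk_ratio=risk_ratio,
        odds_ratio=odds_ratio,
    )


def adjust_pvalues(pvals: Sequence[float], method: str = "bh") -> list[float]:
    """Multiple-testing adjustment preserving input order.

    ``bonferroni``: min(1, m*p). ``bh``: Benjamini-Hochberg step-up adjusted
    values (monotone in rank, capped at 1).
    """
    if method not in ("bonferroni", "bh"):
        raise ValueError(f"unknown correction method {method!r}")
    pvals = list(pvals)
    if not pvals:
        return []
    for p in pvals:
        if not (0 < p <= 1):
            raise ValueError(f"p-value out of (0, 1]: {p!r}")
    sm_method = "bonferroni" if method == "bonferroni" else "fdr_bh"
    _, adjusted, _, _ = multipletests(pvals, method=sm_method)
    return [float(q) for q in adjusted]


def _upper_tail_p(k: int, K: int, n: int, N: int, engine: str) -> float:
    if engine == "fisher":
        # identical one-sided p through the 2x2 table
        tab = [[k, n - k], [K - k, N - n - (K - k)]]
        return float(sps.fisher_exact(tab, alternative="greater")[1])
    return float(sps.hypergeom.sf(k - 1, N, K, n))


def enrich(
    foreground: set[str],
    background: set[str],
    annotations: AnnotationMap,
    correction: str = "bh",
    alpha: float = 0.05,
    engine: str = "hypergeometric",
) -> list[EnrichmentRow]:
    """Term enrichment of ``foreground`` against ``background``.

    For each term with at least one foreground hit, computes the
    hypergeometric upper-tail p (or the identical one-sided Fisher p with
    ``engine='fisher'``), the fold enrichment, and the corrected p. Rows are
    sorted by adjusted p, then term; rows with adjusted p <= alpha are
    flagged significant.
    """
    if not foreground <= background:
        raise ValueError("foreground must be a subset of the background")
    if engine not in ("hypergeometric", "fisher"):
        raise ValueError(f"unknown enrichment engine {engine!r}")
    N, n = len(background), len(foreground)
    hits: list[tuple[str, int, int]] = []
    for term in sorted(annotations.all_terms()):
        carriers = annotations.annotated(term) & background
        k = len(carriers & foreground)
        if k == 0:
            continue
        hits.append((term, k, len(carriers)))
    raw = [_upper_tail_p(k, K, n, N, engine) for _, k, K in hits]
    adjusted = adjust_pvalues(raw, method=correction)
    rows = [
        EnrichmentRow(
            term=term,
            k=k,
            K=K,
            n=n,
            N=N,
            fold_enrichment=(k / n) / (K / N),
            p_value=p,
            adjusted_p=q,
            significant=q <= alpha,
        )
        for (term, k, K), p, q in zip(hits, raw, adjusted)
    ]
    rows.sort(key=lambda r: (r.adjusted_p, r.term))
    return rows
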