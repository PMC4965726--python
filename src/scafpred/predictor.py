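"""The prediction engine: three structural criteria over an interactome.

A scaffold candidate must (1) directly interact with at least two other
proteins; and be supported by (2) domain-domain interactions placing the two
partners on *different* domain regions of the scaffold, and/or (3) triad
co-membership of scaffold and both partners in a known protein complex.
Criterion 2 is what separates scaffolds from hub proteins, whose partners
compete for one and the same binding region.

Candidates satisfying criterion 1 plus both 2 and 3 are Type I, plus 2 only
Type II, plus 3 only Type III; criterion-1-only proteins are not reported.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Optional

from .model import (
    ComplexCatalog,
    DDINetwork,
    DomainArchitecture,
    DomainInstance,
    Interactome,
    ScaffoldPrediction,
    WitnessPair,
    complexes_containing,
    partners,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PredictorConfig",
    "criterion1",
    "mediating_regions",
    "criterion2_witnesses",
    "criterion3_witnesses",
    "classify",
    "predict_all",
]


@dataclass(frozen=True)
class PredictorConfig:
    """Tunable interpretation points of the criteria.

    joint_witness
        Type I requires one partner *pair* satisfying criteria 2 and 3
        simultaneously (default); with ``False`` it suffices that each
        criterion holds for some (possibly different) pair.
    region_semantics
        ``instance``: two copies of one family are distinct physical
        regions (default); ``family``: the two partners must bind through
        different domain *families*.
    require_partner_domain_known
        With the default ``True`` a partner lacking domain data can never
        supply a criterion-2 witness. ``False`` is a lenient mode in which
        such a partner is assumed able to bind any scaffold region whose
        family occurs in the DDI network at all.
    """

    joint_witness: bool = True
    region_semantics: str = "instance"
    require_partner_domain_known: bool = True

    def __post_init__(self) -> None:
        if self.region_semantics not in ("instance", "family"):
            raise ValueError(f"unknown region semantics {self.region_semantics!r}")

    def regions_distinct(self, r1: DomainInstance, r2: DomainInstance) -> bool:
        if self.region_semantics == "family":
            return r1.family != r2.family
        return r1 != r2


def criterion1(interactome: Interactome) -> set[str]:
    """Proteins with at least two distinct non-self interaction partners."""
    return {p for p in interactome.proteins if len(partners(interactome, p)) >= 2}


def _architecture(
    architectures: Mapping[str, DomainArchitecture], protein: str
) -> DomainArchitecture:
    # absent from the domain table == empty architecture; incomplete domain
    # resources must not exclude a protein from complex-based evidence
    return architectures.get(protein, DomainArchitecture(protein=protein))


def mediating_regions(
    s: str,
    p: str,
    architectures: Mapping[str, DomainArchitecture],
    ddi: DDINetwork,
    config: Optional[PredictorConfig] = None,
) -> set[DomainInstance]:
    """Domain instances of scaffold ``s`` that can mediate the edge s-p.

    A region qualifies when its family forms a DDI pair with some family of
    ``p`` (homotypic pairs included). Empty when either architecture is
    empty or no family pair is in the DDI set.
    """
    config = config or PredictorConfig()
    s_arch = _architecture(architectures, s)
    p_arch = _architecture(architectures, p)
    if not config.require_partner_domain_known and len(p_arch) == 0:
        ddi_families = {fam for pair in ddi.pairs for fam in pair}
        return {inst for inst in s_arch if inst.family in ddi_families}
    p_families = p_arch.families
    return {
        inst
        for inst in s_arch
        if any(ddi.interacts(inst.family, pf) for pf in p_families)
    }


def _sorted_regions(regions: set[DomainInstance]) -> list[DomainInstance]:
    # deterministic representative order: lowest copy index, then family
    return sorted(regions, key=lambda r: (r.copy_index, r.family))


def criterion2_witnesses(
    s: str,
    interactome: Interactome,
    architectures: Mapping[str, DomainArchitecture],
    ddi: DDINetwork,
    config: Optional[PredictorConfig] = None,
) -> set[WitnessPair]:
    """All unordered partner pairs recruitable through *different* scaffold
    regions, one witness per pair with a deterministic representative
    region assignment. Hub-like proteins whose partners all compete for a
    single region produce no witness."""
    config = config or PredictorConfig()
    regs = {p: mediating_regions(s, p, architectures, ddi, config) for p in partners(interactome, s)}
    witnesses: set[WitnessPair] = set()
    for p1, p2 in combinations(sorted(regs), 2):
        assignment = None
        for r1 in _sorted_regions(regs[p1]):
            for r2 in _sorted_regions(regs[p2]):
                if config.regions_distinct(r1, r2):
                    assignment = (r1, r2)
                    break
            if assignment:
                break
        if assignment:
            witnesses.add(
                WitnessPair(p1=p1, p2=p2, region1=assignment[0], region2=assignment[1])
            )
    return witnesses


def criterion3_witnesses(
    s: str, interactome: Interactome, catalog: ComplexCatalog
) -> set[WitnessPair]:
    """All unordered partner pairs co-resident with ``s`` in some complex;
    the lexicographically smallest qualifying complex id is recorded.
    Both partners must directly interact with ``s``."""
    ps = sorted(partners(interactome, s))
    witnesses: set[WitnessPair] = set()
    for p1, p2 in combinations(ps, 2):
        hits = complexes_containing(catalog, {s, p1, p2})
        if hits:
            witnesses.add(WitnessPair(p1=p1, p2=p2, complex_id=min(hits)))
    return witnesses


def _merge(w2: WitnessPair, w3: WitnessPair) -> WitnessPair:
    return WitnessPair(
        p1=w2.p1, p2=w2.p2, region1=w2.region1, region2=w2.region2, complex_id=w3.complex_id
    )


def classify(
    s: str,
    c2: set[WitnessPair],
    c3: set[WitnessPair],
    config: Optional[PredictorConfig] = None,
) -> Optional[ScaffoldPrediction]:
    """Assign a type class from the criterion-2 and criterion-3 witness sets.

    Returns ``None`` when both sets are empty (criterion-1-only proteins are
    excluded from the reliable candidates).
    """
    config = config or PredictorConfig()
    if not c2 and not c3:
        return None
    by_pair3 = {w.pair: w for w in c3}
    if config.joint_witness:
        joint = [_merge(w, by_pair3[w.pair]) for w in sorted(c2, key=lambda w: w.pair) if w.pair in by_pair3]
        if joint:
            return ScaffoldPrediction(scaffold=s, type_class="I", witnesses=tuple(joint))
    elif c2 and c3:
        merged = {
            w.pair: (_merge(w, by_pair3[w.pair]) if w.pair in by_pair3 else w)
            for w in c2
        }
        for w in c3:
            merged.setdefault(w.pair, w)
        return ScaffoldPrediction(
            scaffold=s,
            type_class="I",
            witnesses=tuple(merged[k] for k in sorted(merged)),
        )
    if c2:
        return ScaffoldPrediction(
            scaffold=s, type_class="II", witnesses=tuple(sorted(c2, key=lambda w: w.pair))
        )
    return ScaffoldPrediction(
        scaffold=s, type_class="III", witnesses=tuple(sorted(c3, key=lambda w: w.pair))
    )


def predict_all(
    interactome: Interactome,
    architectures: Mapping[str, DomainArchitecture],
    ddi: DDINetwork,
    catalog: ComplexCatalog,
    config: Optional[PredictorConfig] = None,
) -> list[ScaffoldPrediction]:
    """Run the three criteria over every protein; deterministic order by
    scaffold accession. Per-criterion and per-type counts go to the log."""
    config = config or PredictorConfig()
    candidates = criterion1(interactome)
    predictions: list[ScaffoldPrediction] = []
    for s in sorted(candidates):
        c2 = criterion2_witnesses(s, interactome, architectures, ddi, config)
        c3 = criterion3_witnesses(s, interactome, catalog)
        pred = classify(s, c2, c3, config)
        if pred is not None:
            predictions.append(pred)
    counts = Counter(p.type_class for p in predictions)
    logger.info(
        "criterion 1: %d candidates; classified: Type I=%d, II=%d, III=%d",
        len(candidates),
        counts.get("I", 0),
        counts.get("II", 0),
        counts.get("III", 0),
    )
    return predictions
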