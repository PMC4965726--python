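"""Independent brute-force oracle for the prediction engine.

Enumerates every (scaffold, partner1, partner2) triple and every region
assignment directly from the raw containers, without reusing any predictor
code path. Used to cross-check ``predict_all`` on small random instances.
"""

from __future__ import annotations

import random
from itertools import combinations

from scafpred.model import (
    ComplexCatalog,
    DDINetwork,
    DomainArchitecture,
    DomainInstance,
    Interactome,
)


def _neighbors(net: Interactome, p: str) -> set[str]:
    return {q for q in net.graph.neighbors(p) if q != p}


def _regions_for(s, p, architectures, ddi):
    s_arch = architectures.get(s)
    p_arch = architectures.get(p)
    if s_arch is None or p_arch is None:
        return []
    out = []
    for inst in s_arch.instances:
        for pinst in p_arch.instances:
            if frozenset((inst.family, pinst.family)) in ddi.pairs:
                out.append(inst)
                break
    return out


def brute_force_classes(
    net: Interactome,
    architectures: dict,
    ddi: DDINetwork,
    catalog: ComplexCatalog,
    region_semantics: str = "instance",
    joint_witness: bool = True,
) -> dict[str, str]:
    """Map scaffold -> type class by exhaustive triple enumeration."""
    out: dict[str, str] = {}
    for s in net.proteins:
        ps = sorted(_neighbors(net, s))
        if len(ps) < 2:
            continue
        c2_pairs, c3_pairs = set(), set()
        for p1, p2 in combinations(ps, 2):
            # criterion 2: some assignment of distinct scaffold regions
            for r1 in _regions_for(s, p1, architectures, ddi):
                for r2 in _regions_for(s, p2, architectures, ddi):
                    distinct = (
                        r1.family != r2.family
                        if region_semantics == "family"
                        else r1 != r2
                    )
                    if distinct:
                        c2_pairs.add((p1, p2))
            # criterion 3: triad complex co-membership
            for cid, members in catalog.complexes.items():
                if {s, p1, p2} <= members:
                    c3_pairs.add((p1, p2))
        if not c2_pairs and not c3_pairs:
            continue
        if joint_witness:
            type1 = bool(c2_pairs & c3_pairs)
        else:
            type1 = bool(c2_pairs) and bool(c3_pairs)
        if type1:
            out[s] = "I"
        elif c2_pairs:
            out[s] = "II"
        else:
            out[s] = "III"
    return out


def random_instance(rng: random.Random, max_proteins: int = 30):
    """A small random prediction problem: random graph, random architectures
    over a shared family pool, random DDI pairs and random complexes."""
    n = rng.randint(4, max_proteins)
    proteins = [f"P{i:02d}" for i in range(n)]
    edge_prob = rng.uniform(0.05, 0.35)
    net = Interactome()
    for p in proteins:
        net.add_protein(p)
    for p, q in combinations(proteins, 2):
        if rng.random() < edge_prob:
            net.add_edge(p, q)
    if rng.random() < 0.3:  # occasional self-loops exercise the policy
        net.add_edge(proteins[0], proteins[0])

    families = [f"D{i}" for i in range(rng.randint(3, 8))]
    architectures = {}
    for p in proteins:
        k = rng.randint(0, 3)
        fams = [rng.choice(families) for _ in range(k)]
        counters: dict[str, int] = {}
        instances = []
        for fam in fams:
            counters[fam] = counters.get(fam, 0) + 1
            instances.append(
                DomainInstance(protein=p, family=fam, copy_index=counters[fam])
            )
        architectures[p] = DomainArchitecture(protein=p, instances=tuple(instances))

    n_ddi = rng.randint(0, 6)
    pairs = set()
    for _ in range(n_ddi):
        pairs.add(frozenset((rng.choice(families), rng.choice(families))))
    ddi = DDINetwork(frozenset(pairs))

    complexes = {}
    for i in range(rng.randint(0, 4)):
        size = rng.randint(3, min(5, n))
        complexes[f"C{i}"] = frozenset(rng.sample(proteins, size))
    catalog = ComplexCatalog(complexes)
    return net, architectures, ddi, catalog
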