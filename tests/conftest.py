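import pytest

from scafpred.model import (
    ComplexCatalog,
    DDINetwork,
    DomainArchitecture,
    DomainInstance,
    build_interactome,
)


def make_arch(protein, *families_with_coords):
    """families_with_coords: (family, start, end) or family string."""
    counters = {}
    instances = []
    for item in families_with_coords:
        if isinstance(item, str):
            fam, start, end = item, None, None
        else:
            fam, start, end = item
        counters[fam] = counters.get(fam, 0) + 1
        instances.append(
            DomainInstance(protein=protein, family=fam, copy_index=counters[fam], start=start, end=end)
        )
    return DomainArchitecture(protein=protein, instances=tuple(instances))


@pytest.fixture
def toy_problem():
    """One clean Type I scaffold S (partners A, B through different domains
    plus a triad complex) and one hub H whose four partners all compete for
    its single D5 region."""
    edges = [("S", "A"), ("S", "B")] + [("H", f"P{i}") for i in range(1, 5)]
    net = build_interactome(edges)
    architectures = {
        "S": make_arch("S", ("D1", 10, 80), ("D2", 120, 200)),
        "A": make_arch("A", ("D3", 1, 60)),
        "B": make_arch("B", ("D4", 1, 60)),
        "H": make_arch("H", ("D5", 10, 90)),
        **{f"P{i}": make_arch(f"P{i}", ("D6", 1, 50)) for i in range(1, 5)},
    }
    ddi = DDINetwork.from_pairs([("D1", "D3"), ("D2", "D4"), ("D5", "D6")])
    catalog = ComplexCatalog({"CPX1": frozenset({"S", "A", "B"})})
    return net, architectures, ddi, catalog
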