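"""In-memory data model for interactome-based scaffold prediction.

Proteins are opaque accession strings (UniProt-style tokens compared
case-sensitively). The physical interaction graph is held in a
:class:`networkx.Graph`; domain architectures, domain-family interaction
pairs, complex catalogs and annotation maps are thin validated containers
around plain sets and dicts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional

import networkx as nx

__all__ = [
    "DomainInstance",
    "DomainArchitecture",
    "Interactome",
    "DDINetwork",
    "ComplexCatalog",
    "AnnotationMap",
    "WitnessPair",
    "ScaffoldPrediction",
    "ContingencyTable2x2",
    "build_interactome",
    "partners",
    "complexes_containing",
]


def _check_accession(acc: str, what: str = "accession") -> str:
    if not isinstance(acc, str) or not acc or acc != acc.strip() or any(c.isspace() for c in acc):
        raise ValueError(f"invalid {what}: {acc!r} (non-empty, no whitespace)")
    return acc


@dataclass(frozen=True, order=True)
class DomainInstance:
    """One physical copy of a domain family on a protein.

    ``copy_index`` is the 1-based ordinal among same-family copies in the
    protein (by residue coordinate when coordinates exist, else by input
    order). ``start``/``end`` are 1-based inclusive residue coordinates.
    """

    protein: str
    family: str
    copy_index: int = 1
    start: Optional[int] = None
    end: Optional[int] = None

    def __post_init__(self) -> None:
        _check_accession(self.protein, "protein accession")
        _check_accession(self.family, "domain family accession")
        if self.copy_index < 1:
            raise ValueError(f"copy_index must be >= 1, got {self.copy_index}")
        if (self.start is None) != (self.end is None):
            raise ValueError("start and end must be given together")
        if self.start is not None:
            if self.start < 1 or self.end < 1:
                raise ValueError("residue coordinates are 1-based positive")
            if self.start > self.end:
                raise ValueError(f"start > end for {self.protein}/{self.family}")

    @property
    def region_label(self) -> str:
        """Stable textual label ``family.copy`` used in output files."""
        return f"{self.family}.{self.copy_index}"


@dataclass(frozen=True)
class DomainArchitecture:
    """Ordered domain instances of one protein (possibly empty)."""

    protein: str
    instances: tuple[DomainInstance, ...] = ()

    def __post_init__(self) -> None:
        _check_accession(self.protein, "protein accession")
        seen = set()
        per_family: dict[str, list[int]] = {}
        for inst in self.instances:
            if inst.protein != self.protein:
                raise ValueError(
                    f"instance protein {inst.protein!r} != architecture protein {self.protein!r}"
                )
            key = (inst.family, inst.copy_index)
            if key in seen:
                raise ValueError(f"duplicate domain instance {key} on {self.protein}")
            seen.add(key)
            per_family.setdefault(inst.family, []).append(inst.copy_index)
        for fam, idxs in per_family.items():
            if sorted(idxs) != list(range(1, len(idxs) + 1)):
                raise ValueError(f"copy indices for {self.protein}/{fam} are not 1..k")

    @property
    def families(self) -> frozenset[str]:
        return frozenset(inst.family for inst in self.instances)

    def __len__(self) -> int:
        return len(self.instances)

    def __iter__(self) -> Iterator[DomainInstance]:
        return iter(self.instances)


class Interactome:
    """Undirected PPI graph. Self-loops are stored but never counted as
    partners: a scaffold must recruit two *other* proteins."""

    def __init__(self) -> None:
        self._g = nx.Graph()

    @property
    def graph(self) -> nx.Graph:
        return self._g

    @property
    def proteins(self) -> set[str]:
        return set(self._g.nodes)

    @property
    def edges(self) -> set[frozenset[str]]:
        return {frozenset((u, v)) for u, v in self._g.edges}

    def add_protein(self, p: str) -> None:
        self._g.add_node(_check_accession(p))

    def add_edge(self, p: str, q: str) -> None:
        self._g.add_edge(_check_accession(p), _check_accession(q))

    def has_edge(self, p: str, q: str) -> bool:
        return self._g.has_edge(p, q)

    def __contains__(self, p: str) -> bool:
        return p in self._g

    def __len__(self) -> int:
        return self._g.number_of_nodes()

    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Interactome):
            return NotImplemented
        return self.proteins == other.proteins and self.edges == other.edges

    def __repr__(self) -> str:
        return f"Interactome({len(self)} proteins, {self.n_edges()} edges)"


@dataclass(frozen=True)
class DDINetwork:
    """Unordered interacting domain-family pairs; homotypic pairs allowed."""

    pairs: frozenset[frozenset[str]] = frozenset()

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "DDINetwork":
        out = set()
        for a, b in pairs:
            out.add(frozenset((_check_accession(a, "family"), _check_accession(b, "family"))))
        return cls(frozenset(out))

    def interacts(self, fam_a: str, fam_b: str) -> bool:
        return frozenset((fam_a, fam_b)) in self.pairs

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class ComplexCatalog:
    """Mapping complex-id -> member protein set (size >= 1)."""

    complexes: Mapping[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cid, members in self.complexes.items():
            _check_accession(cid, "complex id")
            if not members:
                raise ValueError(f"complex {cid!r} has no members")

    def __len__(self) -> int:
        return len(self.complexes)

    def __getitem__(self, cid: str) -> frozenset[str]:
        return self.complexes[cid]


@dataclass(frozen=True)
class AnnotationMap:
    """Protein -> set of term strings under one namespace (e.g.
    "localization", "pathway", "disease", "drug_target", "go_bp").
    Unmapped proteins are simply absent."""

    assignments: Mapping[str, frozenset[str]] = field(default_factory=dict)
    namespace: str = "annotation"

    def __post_init__(self) -> None:
        for p, terms in self.assignments.items():
            _check_accession(p, "protein accession")
            if not terms:
                raise ValueError(f"protein {p!r} mapped to an empty term set")

    def terms(self, p: str) -> frozenset[str]:
        return self.assignments.get(p, frozenset())

    def annotated(self, term: Optional[str] = None) -> set[str]:
        """Proteins carrying ``term``, or all annotated proteins."""
        if term is None:
            return set(self.assignments)
        return {p for p, ts in self.assignments.items() if term in ts}

    def all_terms(self) -> set[str]:
        out: set[str] = set()
        for ts in self.assignments.values():
            out |= ts
        return out

    def __contains__(self, p: str) -> bool:
        return p in self.assignments

    def __len__(self) -> int:
        return len(self.assignments)


@dataclass(frozen=True)
class WitnessPair:
    """The two recruited partners certifying a scaffold prediction.

    ``region1``/``region2`` are the scaffold's mediating domain instances for
    partner ``p1``/``p2`` (criterion 2 evidence); ``complex_id`` names a
    complex containing scaffold and both partners (criterion 3 evidence).
    """

    p1: str
    p2: str
    region1: Optional[DomainInstance] = None
    region2: Optional[DomainInstance] = None
    complex_id: Optional[str] = None

    def __post_init__(self) -> None:
        _check_accession(self.p1)
        _check_accession(self.p2)
        if self.p1 == self.p2:
            raise ValueError("witness partners must be distinct")
        if self.p1 > self.p2:
            raise ValueError("witness partners must satisfy p1 < p2 lexicographically")
        if (self.region1 is None) != (self.region2 is None):
            raise ValueError("regions must be given for both partners or neither")
        if self.region1 is not None and self.region1 == self.region2:
            raise ValueError("the two mediating regions must be distinct instances")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.p1, self.p2)

    @property
    def has_regions(self) -> bool:
        return self.region1 is not None


@dataclass(frozen=True)
class ScaffoldPrediction:
    scaffold: str
    type_class: str  # "I", "II" or "III"
    witnesses: tuple[WitnessPair, ...]

    def __post_init__(self) -> None:
        _check_accession(self.scaffold)
        if self.type_class not in ("I", "II", "III"):
            raise ValueError(f"unknown type class {self.type_class!r}")
        if not self.witnesses:
            raise ValueError("a prediction needs at least one witness pair")
        for w in self.witnesses:
            if self.scaffold in (w.p1, w.p2):
                raise ValueError("a witness partner cannot be the scaffold itself")
        if self.type_class == "I":
            # under the default joint-witness policy one witness carries
            # both kinds of evidence; the independent policy may split them
            if not any(w.has_regions for w in self.witnesses) or not any(
                w.complex_id is not None for w in self.witnesses
            ):
                raise ValueError("Type I requires region evidence and complex evidence")
        if self.type_class == "II":
            if not any(w.has_regions for w in self.witnesses):
                raise ValueError("Type II requires a domain-region witness")
            if any(w.complex_id is not None for w in self.witnesses):
                raise ValueError("Type II forbids complex witnesses")
        if self.type_class == "III":
            if not any(w.complex_id is not None for w in self.witnesses):
                raise ValueError("Type III requires a complex witness")
            if any(w.has_regions for w in self.witnesses):
                raise ValueError("Type III forbids two-region witnesses")

    @property
    def partner_pairs(self) -> set[tuple[str, str]]:
        return {w.pair for w in self.witnesses}


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 counts; row 1 = exposed / predicted-positive (a, b)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise ValueError(f"cell {name} must be a nonnegative integer, got {v!r}")
        if self.n == 0:
            raise ValueError("grand total must be >= 1")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def row_totals(self) -> tuple[int, int]:
        return (self.a + self.b, self.c + self.d)

    @property
    def col_totals(self) -> tuple[int, int]:
        return (self.a + self.c, self.b + self.d)

    def transposed(self) -> "ContingencyTable2x2":
        return ContingencyTable2x2(self.a, self.c, self.b, self.d)


def build_interactome(edge_list: Iterable[tuple[str, str]]) -> Interactome:
    """Build a symmetric, deduplicated interactome from accession pairs.

    Input order is irrelevant to the result; self-loops are stored (they
    never count as partners).
    """
    net = Interactome()
    for p, q in edge_list:
        net.add_edge(p, q)
    return net


def partners(interactome: Interactome, p: str) -> set[str]:
    """Direct interaction partners of ``p``, excluding ``p`` itself."""
    if p not in interactome:
        raise KeyError(f"unknown protein {p!r}")
    return set(interactome.graph.neighbors(p)) - {p}


def complexes_containing(catalog: ComplexCatalog, members: set[str]) -> set[str]:
    """Ids of complexes whose membership is a superset of ``members``."""
    if not members:
        raise ValueError("query member set must be non-empty")
    return {cid for cid, ms in catalog.complexes.items() if members <= ms}
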