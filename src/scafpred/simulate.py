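"""Seeded generator of complete synthetic datasets with planted truth.

Each planted motif follows the structural criteria directly:

* Type I — scaffold with two distinct domain families, two partners whose
  families are DDI-linked to *different* scaffold families, both edges
  present, plus a triad complex {scaffold, partner, partner};
* Type II — the same minus the complex;
* Type III — triad complex present but the scaffold carries at most one
  domain instance, so distinct-region recruitment is impossible;
* hub decoy — a single-domain protein with ``hub_degree`` partners all
  DDI-linked through that one domain (competitive binding) and no triad
  complex: passes the multi-partner criterion, fails the rest.

Background proteins carry fresh domain families that occur in no DDI pair
and are wired by an Erdős–Rényi rule. Dropout parameters delete planted DDI
pairs and complexes to emulate incomplete domain/complex resources.
Identical seed and config give byte-identical output files.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

from . import io as sio
from .model import (
    AnnotationMap,
    ComplexCatalog,
    DDINetwork,
    DomainArchitecture,
    DomainInstance,
    Interactome,
)
from .predictor import PredictorConfig, predict_all

__all__ = ["SimConfig", "GroundTruth", "SyntheticDataset", "generate", "write_dataset"]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic dataset."""

    n_type1: int = 5
    n_type2: int = 7
    n_type3: int = 3
    n_hub_decoys: int = 4
    n_background_proteins: int = 50
    hub_degree: int = 4
    background_edge_prob: float = 0.02
    ddi_dropout: float = 0.0
    complex_dropout: float = 0.0
    annotation_match_rate: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_type1", "n_type2", "n_type3", "n_hub_decoys", "n_background_proteins"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.hub_degree < 2:
            raise ValueError("hub_degree must be >= 2 (a hub needs multiple partners)")
        for name in ("background_edge_prob", "ddi_dropout", "complex_dropout", "annotation_match_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass(frozen=True)
class GroundTruth:
    """Planted role of every generated protein: I, II, III, hub or
    background (partners and wiring filler are background)."""

    labels: dict[str, str] = field(default_factory=dict)

    def of_class(self, label: str) -> set[str]:
        return {p for p, l in self.labels.items() if l == label}


@dataclass(frozen=True)
class SyntheticDataset:
    interactome: Interactome
    architectures: dict[str, DomainArchitecture]
    ddi: DDINetwork
    complexes: ComplexCatalog
    localization: AnnotationMap
    pathways: AnnotationMap
    gold_positive: set[str]
    gold_negative: set[str]
    truth: GroundTruth


def _instance(protein: str, family: str, start: int, end: int, copy: int = 1) -> DomainInstance:
    return DomainInstance(protein=protein, family=family, copy_index=copy, start=start, end=end)


def generate(config: Optional[SimConfig] = None, seed: Optional[int] = None) -> SyntheticDataset:
    """Generate one full dataset. ``seed`` overrides ``config.seed``."""
    config = config or SimConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    rng = random.Random(config.seed)

    edges: list[tuple[str, str]] = []
    arch: dict[str, DomainArchitecture] = {}
    ddi_pairs: list[tuple[str, str]] = []
    complexes: dict[str, frozenset[str]] = {}
    labels: dict[str, str] = {}
    # scaffold -> (witness partners) for annotation planting
    scaffold_partners: dict[str, tuple[str, str]] = {}

    def add_arch(protein: str, *instances: DomainInstance) -> None:
        arch[protein] = DomainArchitecture(protein=protein, instances=instances)

    for i in range(config.n_type1):
        s, a, b = f"T1S{i:04d}", f"T1A{i:04d}", f"T1B{i:04d}"
        fs1, fs2, fa, fb = (f"F1S{i:04d}A", f"F1S{i:04d}B", f"F1A{i:04d}", f"F1B{i:04d}")
        add_arch(s, _instance(s, fs1, 10, 80), _instance(s, fs2, 120, 200))
        add_arch(a, _instance(a, fa, 5, 70))
        add_arch(b, _instance(b, fb, 5, 70))
        ddi_pairs += [(fs1, fa), (fs2, fb)]
        edges += [(s, a), (s, b)]
        complexes[f"CPX1{i:04d}"] = frozenset({s, a, b})
        labels.update({s: "I", a: "background", b: "background"})
        scaffold_partners[s] = (a, b)

    for i in range(config.n_type2):
        s, a, b = f"T2S{i:04d}", f"T2A{i:04d}", f"T2B{i:04d}"
        fs1, fs2, fa, fb = (f"F2S{i:04d}A", f"F2S{i:04d}B", f"F2A{i:04d}", f"F2B{i:04d}")
        add_arch(s, _instance(s, fs1, 10, 80), _instance(s, fs2, 120, 200))
        add_arch(a, _instance(a, fa, 5, 70))
        add_arch(b, _instance(b, fb, 5, 70))
        ddi_pairs += [(fs1, fa), (fs2, fb)]
        edges += [(s, a), (s, b)]
        labels.update({s: "II", a: "background", b: "background"})
        scaffold_partners[s] = (a, b)

    for i in range(config.n_type3):
        s, a, b = f"T3S{i:04d}", f"T3A{i:04d}", f"T3B{i:04d}"
        # single domain instance, family absent from the DDI set
        add_arch(s, _instance(s, f"F3S{i:04d}", 10, 80))
        add_arch(a, _instance(a, f"F3A{i:04d}", 5, 70))
        add_arch(b, _instance(b, f"F3B{i:04d}", 5, 70))
        edges += [(s, a), (s, b)]
        complexes[f"CPX3{i:04d}"] = frozenset({s, a, b})
        labels.update({s: "III", a: "background", b: "background"})
        scaffold_partners[s] = (a, b)

    for i in range(config.n_hub_decoys):
        h = f"HUB{i:04d}"
        fh, fp = f"FH{i:04d}", f"FHP{i:04d}"
        add_arch(h, _instance(h, fh, 10, 80))
        ddi_pairs.append((fh, fp))
        for j in range(config.hub_degree):
            p = f"HUB{i:04d}P{j:02d}"
            add_arch(p, _instance(p, fp, 5, 70))
            edges.append((h, p))
            labels[p] = "background"
        labels[h] = "hub"

    background = [f"BG{i:04d}" for i in range(config.n_background_proteins)]
    for i, p in enumerate(background):
        add_arch(p, _instance(p, f"FBG{i:04d}", 5, 60))
        labels[p] = "background"
    # Erdős–Rényi wiring over pairs touching at least one background protein
    others = sorted(set(labels) - set(background))
    for i, p in enumerate(background):
        for q in background[i + 1 :]:
            if rng.random() < config.background_edge_prob:
                edges.append((p, q))
        for q in others:
            if rng.random() < config.background_edge_prob:
                edges.append((p, q))

    # incomplete-resource noise
    ddi_pairs = [pair for pair in ddi_pairs if rng.random() >= config.ddi_dropout]
    complexes = {
        cid: members for cid, members in complexes.items() if rng.random() >= config.complex_dropout
    }

    net = Interactome()
    for p in sorted(labels):
        net.add_protein(p)
    for p, q in edges:
        net.add_edge(p, q)
    ddi = DDINetwork.from_pairs(ddi_pairs)
    catalog = ComplexCatalog(complexes)

    localization = _plant_annotations(rng, "loc", scaffold_partners, labels, config)
    pathways = _plant_annotations(rng, "pwy", scaffold_partners, labels, config)

    gold_positive = set(scaffold_partners)
    gold_negative = {p for p, l in labels.items() if l == "hub"} | set(background)

    # consistency pass: any non-scaffold protein that genuinely satisfies the
    # criteria on the final dataset is relabeled with its earned class
    for pred in predict_all(net, arch, ddi, catalog, PredictorConfig()):
        if labels.get(pred.scaffold) in ("hub", "background"):
            labels[pred.scaffold] = pred.type_class
            gold_negative.discard(pred.scaffold)

    return SyntheticDataset(
        interactome=net,
        architectures=arch,
        ddi=ddi,
        complexes=catalog,
        localization=localization,
        pathways=pathways,
        gold_positive=gold_positive,
        gold_negative=gold_negative,
        truth=GroundTruth(labels=labels),
    )


def _plant_annotations(
    rng: random.Random,
    prefix: str,
    scaffold_partners: dict[str, tuple[str, str]],
    labels: dict[str, str],
    config: SimConfig,
) -> AnnotationMap:
    """Annotate every protein; scaffold-partner term agreement is planted at
    ``annotation_match_rate`` (per scaffold, at least one witness partner
    shares a term when the coin lands heads)."""
    assign: dict[str, set[str]] = {}
    for idx, (s, (a, b)) in enumerate(sorted(scaffold_partners.items())):
        term = f"{prefix}:motif{idx:04d}"
        assign.setdefault(s, set()).add(term)
        if rng.random() < config.annotation_match_rate:
            assign.setdefault(a, set()).add(term)
            assign.setdefault(b, set()).add(f"{prefix}:other{idx:04d}")
        else:
            assign.setdefault(a, set()).add(f"{prefix}:offA{idx:04d}")
            assign.setdefault(b, set()).add(f"{prefix}:offB{idx:04d}")
    for j, p in enumerate(sorted(set(labels) - set(assign))):
        assign[p] = {f"{prefix}:misc{j:04d}"}
    return AnnotationMap(
        {p: frozenset(ts) for p, ts in assign.items()}, namespace=prefix
    )


DATASET_FILES = {
    "ppi": "ppi.tsv",
    "domains": "domains.tsv",
    "ddi": "ddi.tsv",
    "complexes": "complexes.gmt",
    "localization": "localization.gmt",
    "pathways": "pathways.gmt",
    "gold_positive": "gold_positive.txt",
    "gold_negative": "gold_negative.txt",
    "truth": "truth_labels.tsv",
}


def write_dataset(dataset: SyntheticDataset, outdir) -> dict[str, Path]:
    """Write every pipeline input format plus truth_labels.tsv; returns the
    mapping of logical name to path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {k: outdir / v for k, v in DATASET_FILES.items()}
    sio.write_ppi(dataset.interactome, paths["ppi"])
    sio.write_architectures(dataset.architectures, paths["domains"])
    sio.write_pairs(dataset.ddi, paths["ddi"])
    sio.write_gmt(
        {cid: ms for cid, ms in dataset.complexes.complexes.items()}, paths["complexes"]
    )
    sio.write_annotation_gmt(dataset.localization, paths["localization"])
    sio.write_annotation_gmt(dataset.pathways, paths["pathways"])
    sio.write_protein_list(dataset.gold_positive, paths["gold_positive"])
    sio.write_protein_list(dataset.gold_negative, paths["gold_negative"])
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        fh.write("#protein\tlabel\n")
        for p in sorted(dataset.truth.labels):
            fh.write(f"{p}\t{dataset.truth.labels[p]}\n")
    return paths
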