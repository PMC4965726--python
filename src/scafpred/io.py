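"""Readers and writers for every on-disk format the pipeline touches.

All files are UTF-8 text; ``#``-prefixed comment lines and blank lines are
ignored everywhere. Readers are deterministic functions of file bytes;
malformed lines are counted and logged, and become fatal only when no line
parses at all. Every writer's output is re-readable by its paired reader.

Formats
-------
* two-column TSV edge list (``tsv2``) and a PSI-MI TAB 2.5 subset
  (``mitab``: interactor ids from columns 1-2, ``uniprotkb:`` prefix
  stripped; detection method text from column 7);
* Pfam-scan-like domain TSV: protein, family, optional start/end;
* two-column TSV of domain-family pairs;
* GMT gene sets (set-id, description, members...) for complexes and
  annotations;
* prediction TSV (one row per witness);
* one-accession-per-line protein lists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

from .model import (
    AnnotationMap,
    ComplexCatalog,
    DDINetwork,
    DomainArchitecture,
    DomainInstance,
    Interactome,
    ScaffoldPrediction,
    WitnessPair,
    build_interactome,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


class FormatError(ValueError):
    """Raised when a file yields no valid record at all."""


@dataclass(frozen=True)
class EvidenceFilterConfig:
    """Evidence-based record filters mirroring typical interactome curation.

    ``require_experimental_ppi`` keeps only MITAB rows whose detection-method
    column matches ``allowed_evidence_codes``; an empty allowed set means
    "any non-empty method". ``require_structural_ddi`` is accepted for DDI
    inputs whose rows carry an evidence column (third column, optional).
    Records lacking a recognizable evidence column are dropped, not passed
    through, when a require flag is set.
    """

    require_experimental_ppi: bool = False
    require_structural_ddi: bool = False
    allowed_evidence_codes: frozenset[str] = frozenset()

    def method_ok(self, method_text: Optional[str]) -> bool:
        if not self.require_experimental_ppi:
            return True
        if not method_text or method_text.strip() in ("", "-"):
            return False
        if not self.allowed_evidence_codes:
            return True
        return any(code in method_text for code in self.allowed_evidence_codes)


def _data_lines(path: PathLike):
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line


def _strip_db_prefix(token: str) -> str:
    # "uniprotkb:P12345" -> "P12345"; bare accessions pass through
    if ":" in token:
        return token.split(":", 1)[1]
    return token


def _strip_isoform(acc: str) -> str:
    head, sep, tail = acc.rpartition("-")
    if sep and tail.isdigit():
        return head
    return acc


def read_ppi(
    path: PathLike,
    format: str = "tsv2",
    filter: Optional[EvidenceFilterConfig] = None,
    strip_isoforms: bool = False,
) -> Interactome:
    """Read an interaction edge list into a deduplicated symmetric graph.

    ``format`` is ``tsv2`` (two tab-separated accession columns) or
    ``mitab`` (PSI-MI TAB 2.5; only columns 1, 2 and 7 are consulted).
    ``strip_isoforms`` removes a trailing ``-<digits>`` isoform suffix; off
    by default because accessions are otherwise treated opaquely.
    """
    if format not in ("tsv2", "mitab"):
        raise ValueError(f"unknown PPI format {format!r}")
    filt = filter or EvidenceFilterConfig()
    edges: list[tuple[str, str]] = []
    n_bad = n_filtered = n_lines = 0
    for lineno, line in _data_lines(path):
        n_lines += 1
        cols = line.split("\t")
        try:
            if format == "tsv2":
                if len(cols) < 2:
                    raise ValueError("need two columns")
                a, b = cols[0].strip(), cols[1].strip()
                method = None
            else:
                if len(cols) < 2:
                    raise ValueError("need at least two MITAB columns")
                a = _strip_db_prefix(cols[0].strip())
                b = _strip_db_prefix(cols[1].strip())
                method = cols[6] if len(cols) >= 7 else None
            if not a or not b:
                raise ValueError("empty accession")
        except ValueError as exc:
            n_bad += 1
            logger.warning("%s:%d: skipping malformed line (%s)", path, lineno, exc)
            continue
        if format == "mitab" and not filt.method_ok(method):
            n_filtered += 1
            continue
        if strip_isoforms:
            a, b = _strip_isoform(a), _strip_isoform(b)
        edges.append((a, b))
    if n_lines == 0 or (n_bad == n_lines):
        raise FormatError(f"{path}: no valid interaction records")
    if n_bad:
        logger.warning("%s: %d malformed line(s) skipped", path, n_bad)
    if n_filtered:
        logger.info("%s: %d record(s) removed by evidence filter", path, n_filtered)
    net = build_interactome(edges)
    logger.info("%s: %d proteins, %d edges", path, len(net), net.n_edges())
    return net


def read_architectures(path: PathLike) -> dict[str, DomainArchitecture]:
    """Read a domain TSV (protein, family[, start, end]) into per-protein
    architectures. Copy indices are assigned per (protein, family) in
    coordinate order when coordinates exist, else in file order."""
    rows: dict[str, list[tuple[str, Optional[int], Optional[int]]]] = {}
    n_bad = n_lines = 0
    for lineno, line in _data_lines(path):
        n_lines += 1
        cols = [c.strip() for c in line.split("\t")]
        try:
            if len(cols) < 2 or not cols[0] or not cols[1]:
                raise ValueError("need protein and family columns")
            start = end = None
            if len(cols) >= 4 and cols[2] and cols[3]:
                start, end = int(cols[2]), int(cols[3])
                if start < 1 or start > end:
                    raise ValueError(f"bad coordinates {start}..{end}")
        except ValueError as exc:
            n_bad += 1
            logger.warning("%s:%d: skipping domain row (%s)", path, lineno, exc)
            continue
        rows.setdefault(cols[0], []).append((cols[1], start, end))
    if n_lines and n_bad == n_lines:
        raise FormatError(f"{path}: no valid domain records")
    if n_bad:
        logger.warning("%s: %d malformed domain row(s) skipped", path, n_bad)

    out: dict[str, DomainArchitecture] = {}
    for protein, items in rows.items():
        # order instances by start coordinate when every row has one,
        # otherwise keep file order (stable sort keeps ties in file order)
        if all(s is not None for _, s, _ in items):
            items = sorted(items, key=lambda t: t[1])
        counters: dict[str, int] = {}
        instances = []
        for fam, start, end in items:
            counters[fam] = counters.get(fam, 0) + 1
            instances.append(
                DomainInstance(protein=protein, family=fam, copy_index=counters[fam], start=start, end=end)
            )
        out[protein] = DomainArchitecture(protein=protein, instances=tuple(instances))
    return out


def read_pairs(path: PathLike) -> DDINetwork:
    """Read a two-column TSV of domain-family pairs into a symmetric,
    deduplicated DDI set; homotypic pairs are kept."""
    pairs: list[tuple[str, str]] = []
    n_bad = n_lines = 0
    for lineno, line in _data_lines(path):
        n_lines += 1
        cols = [c.strip() for c in line.split("\t")]
        if len(cols) < 2 or not cols[0] or not cols[1]:
            n_bad += 1
            logger.warning("%s:%d: skipping malformed DDI line", path, lineno)
            continue
        pairs.append((cols[0], cols[1]))
    if n_lines == 0 or n_bad == n_lines:
        raise FormatError(f"{path}: no valid DDI records")
    if n_bad:
        logger.warning("%s: %d malformed DDI line(s) skipped", path, n_bad)
    return DDINetwork.from_pairs(pairs)


def _read_gmt(path: PathLike) -> dict[str, tuple[str, tuple[str, ...]]]:
    sets: dict[str, tuple[str, tuple[str, ...]]] = {}
    for lineno, line in _data_lines(path):
        cols = line.split("\t")
        if len(cols) < 2:
            logger.warning("%s:%d: skipping malformed GMT line", path, lineno)
            continue
        set_id, desc = cols[0].strip(), cols[1].strip()
        members = tuple(dict.fromkeys(c.strip() for c in cols[2:] if c.strip()))
        if set_id in sets:
            raise FormatError(f"{path}:{lineno}: duplicate set id {set_id!r}")
        if not members:
            logger.warning("%s:%d: dropping empty set %r", path, lineno, set_id)
            continue
        sets[set_id] = (desc, members)
    return sets


def read_complexes(path: PathLike) -> ComplexCatalog:
    """Read a GMT file as a complex catalog (set-id -> member proteins)."""
    sets = _read_gmt(path)
    return ComplexCatalog({cid: frozenset(members) for cid, (_, members) in sets.items()})


def read_annotations(path: PathLike, namespace: str = "annotation") -> AnnotationMap:
    """Read a GMT file as an annotation map, inverted to protein -> terms."""
    sets = _read_gmt(path)
    inv: dict[str, set[str]] = {}
    for term, (_, members) in sets.items():
        for p in members:
            inv.setdefault(p, set()).add(term)
    return AnnotationMap({p: frozenset(ts) for p, ts in inv.items()}, namespace=namespace)


def read_gene_sets(path: PathLike, as_annotation: bool = False, namespace: str = "annotation"):
    """GMT reader dispatching to a complex catalog or an annotation map."""
    if as_annotation:
        return read_annotations(path, namespace=namespace)
    return read_complexes(path)


def read_protein_list(path: PathLike) -> set[str]:
    """One accession per line (first tab-separated column is used)."""
    out: set[str] = set()
    for _, line in _data_lines(path):
        acc = line.split("\t")[0].strip()
        if acc:
            out.add(acc)
    return out


PRED_COLUMNS = (
    "scaffold",
    "type_class",
    "n_witnesses",
    "p1",
    "p2",
    "region1",
    "region2",
    "complex_id",
)


def _region_str(inst) -> str:
    return inst.region_label if inst is not None else "."


def write_predictions(predictions: Iterable[ScaffoldPrediction], path: PathLike) -> None:
    """Write predictions as a TSV, one row per witness pair, ordered by
    (scaffold, p1, p2). Missing fields are printed as ``.``."""
    preds = sorted(predictions, key=lambda pr: pr.scaffold)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#" + "\t".join(PRED_COLUMNS) + "\n")
        for pred in preds:
            for w in sorted(pred.witnesses, key=lambda w: (w.p1, w.p2)):
                fh.write(
                    "\t".join(
                        (
                            pred.scaffold,
                            pred.type_class,
                            str(len(pred.witnesses)),
                            w.p1,
                            w.p2,
                            _region_str(w.region1),
                            _region_str(w.region2),
                            w.complex_id if w.complex_id is not None else ".",
                        )
                    )
                    + "\n"
                )


def _parse_region(scaffold: str, text: str) -> Optional[DomainInstance]:
    if text == ".":
        return None
    family, _, copy = text.rpartition(".")
    return DomainInstance(protein=scaffold, family=family, copy_index=int(copy))


def read_predictions(path: PathLike) -> list[ScaffoldPrediction]:
    """Parse the prediction TSV back into prediction objects.

    Regions are reconstructed from their ``family.copy`` labels, so residue
    coordinates (display-only in the table) are not restored.
    """
    rows: dict[str, tuple[str, list[WitnessPair]]] = {}
    for lineno, line in _data_lines(path):
        cols = line.split("\t")
        if len(cols) != len(PRED_COLUMNS):
            raise FormatError(f"{path}:{lineno}: expected {len(PRED_COLUMNS)} columns")
        scaffold, type_class, _, p1, p2, r1, r2, cid = cols
        witness = WitnessPair(
            p1=p1,
            p2=p2,
            region1=_parse_region(scaffold, r1),
            region2=_parse_region(scaffold, r2),
            complex_id=None if cid == "." else cid,
        )
        rows.setdefault(scaffold, (type_class, []))[1].append(witness)
    out = []
    for scaffold, (type_class, witnesses) in sorted(rows.items()):
        out.append(
            ScaffoldPrediction(scaffold=scaffold, type_class=type_class, witnesses=tuple(witnesses))
        )
    return out


# --- writers used by the synthetic-data generator -------------------------


def write_ppi(net: Interactome, path: PathLike) -> None:
    """Serialize the edge set (isolated proteins have no edge rows and are
    not preserved; round-trip identity is on the edge set)."""
    lines = sorted(tuple(sorted(e)) if len(e) == 2 else (next(iter(e)),) * 2 for e in net.edges)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#protein_a\tprotein_b\n")
        for a, b in lines:
            fh.write(f"{a}\t{b}\n")


def write_architectures(architectures: dict[str, DomainArchitecture], path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#protein\tfamily\tstart\tend\n")
        for protein in sorted(architectures):
            for inst in architectures[protein]:
                start = str(inst.start) if inst.start is not None else ""
                end = str(inst.end) if inst.end is not None else ""
                fh.write(f"{protein}\t{inst.family}\t{start}\t{end}\n")


def write_pairs(ddi: DDINetwork, path: PathLike) -> None:
    rows = sorted(tuple(sorted(p)) if len(p) == 2 else (next(iter(p)),) * 2 for p in ddi.pairs)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#family_a\tfamily_b\n")
        for a, b in rows:
            fh.write(f"{a}\t{b}\n")


def write_gmt(sets: dict[str, Iterable[str]], path: PathLike, description: str = "na") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for set_id in sorted(sets):
            members = sorted(sets[set_id])
            fh.write("\t".join([set_id, description, *members]) + "\n")


def write_annotation_gmt(annotations: AnnotationMap, path: PathLike) -> None:
    by_term: dict[str, set[str]] = {}
    for p in sorted(annotations.assignments):
        for t in annotations.assignments[p]:
            by_term.setdefault(t, set()).add(p)
    write_gmt(by_term, path, description=annotations.namespace)


def write_protein_list(proteins: Iterable[str], path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for p in sorted(proteins):
            fh.write(p + "\n")
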