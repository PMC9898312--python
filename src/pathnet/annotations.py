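"""Pathway annotation handling: reading, size filtering, and restriction.

A pathway collection is a flat list of named gene sets (GO terms or any other
functional annotation).  The ontology DAG is deliberately not traversed:
annotated sets are used as-is, pooled across namespaces.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from ._util import logger, normalize_gene_id

NAMESPACES = (
    "biological_process",
    "cellular_component",
    "molecular_function",
    "unassigned",
)

# GAF column 8 ("Aspect") codes
_GAF_ASPECT = {
    "P": "biological_process",
    "F": "molecular_function",
    "C": "cellular_component",
}


@dataclass(frozen=True)
class Pathway:
    """One named gene set."""

    pathway_id: str
    name: str
    namespace: str = "unassigned"
    genes: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        if self.namespace not in NAMESPACES:
            raise ValueError(f"unknown namespace {self.namespace!r}")
        if not self.genes:
            raise ValueError(f"pathway {self.pathway_id!r} has an empty gene set")

    @property
    def size(self) -> int:
        return len(self.genes)


class PathwayCollection:
    """An ordered collection of pathways with unique identifiers."""

    def __init__(self, pathways: Iterable[Pathway]):
        self.pathways: list[Pathway] = list(pathways)
        seen: set[str] = set()
        for p in self.pathways:
            if p.pathway_id in seen:
                raise ValueError(f"duplicate pathway id {p.pathway_id!r}")
            seen.add(p.pathway_id)
        self._by_id = {p.pathway_id: p for p in self.pathways}

    def __len__(self) -> int:
        return len(self.pathways)

    def __iter__(self) -> Iterator[Pathway]:
        return iter(self.pathways)

    def __contains__(self, pathway_id: str) -> bool:
        return pathway_id in self._by_id

    def get(self, pathway_id: str) -> Pathway:
        return self._by_id[pathway_id]

    @property
    def ids(self) -> list[str]:
        return [p.pathway_id for p in self.pathways]

    def sizes(self) -> dict[str, int]:
        return {p.pathway_id: p.size for p in self.pathways}

    def gene_universe(self) -> frozenset[str]:
        """Union of all member genes."""
        out: set[str] = set()
        for p in self.pathways:
            out |= p.genes
        return frozenset(out)


@dataclass
class CandidateGeneList:
    """A prioritised candidate-gene list (gene id, priority score).

    The score is the upstream prioritisation score; entries below an optional
    cutoff (the study design used 42) are dropped at construction.
    """

    entries: list[tuple[str, float]]
    score_cutoff: float | None = None

    def __post_init__(self):
        entries = [(normalize_gene_id(g), float(s)) for g, s in self.entries]
        if self.score_cutoff is not None:
            entries = [(g, s) for g, s in entries if s >= self.score_cutoff]
        ids = [g for g, _ in entries]
        if len(ids) != len(set(ids)):
            dup = sorted({g for g in ids if ids.count(g) > 1})
            raise ValueError(f"duplicate candidate gene ids: {dup[:5]}")
        self.entries = entries

    @property
    def gene_ids(self) -> frozenset[str]:
        return frozenset(g for g, _ in self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def from_tsv(cls, path, gene_col: str = "gene_id",
                 score_col: str = "priority_score",
                 score_cutoff: float | None = None) -> "CandidateGeneList":
        import pandas as pd

        frame = pd.read_csv(path, sep="\t")
        for col in (gene_col, score_col):
            if col not in frame.columns:
                raise ValueError(f"{path}: missing column {col!r}")
        return cls(list(zip(frame[gene_col].astype(str), frame[score_col])),
                   score_cutoff=score_cutoff)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("gene_id\tpriority_score\n")
            for g, s in self.entries:
                fh.write(f"{g}\t{s:.6g}\n")


def _parse_gmt(path) -> list[Pathway]:
    pathways = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT row needs >=3 tab-separated fields")
            set_id, desc, *genes = fields
            genes = frozenset(normalize_gene_id(g) for g in genes if g.strip())
            if not genes:
                raise ValueError(f"{path}:{lineno}: gene set {set_id!r} is empty")
            pathways.append(Pathway(set_id, desc, "unassigned", genes))
    return pathways


def _parse_gaf(path) -> list[Pathway]:
    term_genes: dict[str, set[str]] = {}
    term_ns: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("!"):
                continue
            fields = line.split("\t")
            if len(fields) < 15:
                raise ValueError(
                    f"{path}:{lineno}: GAF 2.x row needs >=15 tab-separated "
                    f"columns, got {len(fields)}")
            gene = normalize_gene_id(fields[1])
            term = fields[4].strip()
            aspect = fields[8].strip()
            if not gene or not term:
                raise ValueError(f"{path}:{lineno}: empty gene or term id")
            term_genes.setdefault(term, set()).add(gene)
            term_ns.setdefault(term, _GAF_ASPECT.get(aspect, "unassigned"))
    return [
        Pathway(term, term, term_ns[term], frozenset(genes))
        for term, genes in term_genes.items()
    ]


def read_gene_sets(path, format: str = "gmt") -> PathwayCollection:
    """Read pathway annotations from a GMT or GAF 2.x file.

    GAF input is inverted into term -> gene sets; ``!`` comment lines and
    empty lines are skipped; duplicate gene memberships collapse.
    """
    path = Path(path)
    if format == "gmt":
        pathways = _parse_gmt(path)
    elif format == "gaf":
        pathways = _parse_gaf(path)
    else:
        raise ValueError(f"unknown annotation format {format!r}")
    if not pathways:
        raise ValueError(f"{path}: zero parsed sets")
    return PathwayCollection(pathways)


def write_gmt(collection: PathwayCollection, path) -> None:
    with open(path, "w") as fh:
        for p in collection:
            genes = "\t".join(sorted(p.genes))
            fh.write(f"{p.pathway_id}\t{p.name}\t{genes}\n")


def filter_by_size(collection: PathwayCollection, min_size: int = 6,
                   max_size: int = 1500) -> PathwayCollection:
    """Retain pathways with min_size <= |genes| <= max_size (inclusive).

    The defaults drop under-annotated sets (< 6 genes) and catch-all sets
    (> 1500 genes), which carry little discriminating information.
    """
    if not (1 <= min_size <= max_size):
        raise ValueError(f"need 1 <= min_size <= max_size, got "
                         f"({min_size}, {max_size})")
    kept = [p for p in collection if min_size <= p.size <= max_size]
    if not kept:
        logger.warning("size filter [%d, %d] removed every pathway",
                       min_size, max_size)
    return PathwayCollection(kept)


def restrict_to_candidates(collection: PathwayCollection,
                           candidates: CandidateGeneList) -> PathwayCollection:
    """Keep pathways containing at least one candidate gene."""
    ids = candidates.gene_ids
    return PathwayCollection(p for p in collection if p.genes & ids)


def restrict_to_universe(collection: PathwayCollection,
                         universe: Iterable[str]) -> PathwayCollection:
    """Intersect each pathway with the measured-gene universe.

    Pathways emptied by the intersection are dropped, so downstream counts
    (L, S, M) all refer to the same measured population.
    """
    universe = frozenset(normalize_gene_id(g) for g in universe)
    if not universe:
        raise ValueError("empty universe")
    kept = []
    for p in collection:
        genes = p.genes & universe
        if genes:
            kept.append(Pathway(p.pathway_id, p.name, p.namespace, genes))
    return PathwayCollection(kept)
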