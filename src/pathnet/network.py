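"""Functional gene networks: construction, degree analysis, key-gene selection.

Nodes are genes with a role label (``candidate`` for the prioritised list,
``intermediate`` for recruited connector genes); edges carry a positive
functional-interaction weight (log-likelihood scale).  Degree — the
unweighted count of incident edges — is the sole centrality measure: dense
modules are extracted as degree bands (default 20-30) and key genes are the
candidate genes inside at least one band.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

from ._util import logger, normalize_gene_id

ROLES = ("candidate", "intermediate", "group")


class GeneNetwork:
    """Weighted undirected gene graph wrapping a :class:`networkx.Graph`.

    Node attribute ``role`` in {candidate, intermediate, group}; edge
    attribute ``weight`` (positive real).  No self-loops; duplicate edges are
    resolved when reading (maximum weight wins).
    """

    def __init__(self, graph: nx.Graph | None = None):
        self.graph = graph if graph is not None else nx.Graph()
        loops = list(nx.selfloop_edges(self.graph))
        if loops:
            raise ValueError(f"self-loops not allowed: {loops[:3]}")
        #: candidate genes requested but absent from the reference network
        self.missing_seeds: frozenset[str] = frozenset()

    # -- basic accessors --------------------------------------------------

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def role(self, gene: str) -> str:
        return self.graph.nodes[gene].get("role", "intermediate")

    def genes_with_role(self, role: str) -> frozenset[str]:
        return frozenset(n for n, d in self.graph.nodes(data=True)
                         if d.get("role") == role)

    def degrees(self) -> dict[str, int]:
        return dict(self.graph.degree())

    def __contains__(self, gene: str) -> bool:
        return gene in self.graph


@dataclass
class SubnetworkSelection:
    """Genes whose parent-network degree lies in a band."""

    member_genes: frozenset[str]
    degree_band: tuple[int, int]
    mean_degree: float | None
    label: str = ""
    #: parent-network degrees of the members, for reporting
    degrees: dict[str, int] = field(default_factory=dict)


def read_edge_list(path) -> GeneNetwork:
    """Read a weighted TSV edge list (gene_a, gene_b, weight).

    Self-loop rows are skipped with a warning; duplicate edges keep the
    maximum weight; gene ids are case-normalised.  A header row starting
    with non-numeric weight text is tolerated.
    """
    g = nx.Graph()
    n_dup = n_loop = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: need 3 tab-separated fields")
            a, b = normalize_gene_id(fields[0]), normalize_gene_id(fields[1])
            try:
                w = float(fields[2])
            except ValueError:
                if lineno == 1:  # header
                    continue
                raise ValueError(
                    f"{path}:{lineno}: non-numeric weight {fields[2]!r}")
            if a == b:
                n_loop += 1
                continue
            if g.has_edge(a, b):
                n_dup += 1
                w = max(w, g.edges[a, b]["weight"])
            g.add_edge(a, b, weight=w)
    if n_loop:
        logger.warning("%s: skipped %d self-loop rows", path, n_loop)
    if n_dup:
        logger.warning("%s: %d duplicate edges resolved by max weight",
                       path, n_dup)
    return GeneNetwork(g)


def build_seeded_network(reference: GeneNetwork, seeds, min_seed_links: int = 2
                         ) -> GeneNetwork:
    """Induce the analysis network from seed (candidate) genes.

    Retains the seeds present in the reference plus every non-seed node
    adjacent to at least ``min_seed_links`` seeds (recruited as
    ``intermediate`` connector genes), with all reference edges among the
    retained nodes.  Seeds absent from the reference are recorded on the
    returned network's ``missing_seeds``.
    """
    if min_seed_links < 1:
        raise ValueError("min_seed_links must be >= 1")
    seeds = frozenset(normalize_gene_id(s) for s in seeds)
    present = seeds & set(reference.graph.nodes)
    missing = seeds - present
    intermediates = set()
    for node in reference.graph.nodes:
        if node in seeds:
            continue
        n_links = sum(1 for nb in reference.graph.neighbors(node)
                      if nb in present)
        if n_links >= min_seed_links:
            intermediates.add(node)
    keep = present | intermediates
    sub = nx.Graph(reference.graph.subgraph(keep))
    sub.add_nodes_from(present)  # keep isolated seeds
    for node in sub.nodes:
        sub.nodes[node]["role"] = ("candidate" if node in seeds
                                   else "intermediate")
    net = GeneNetwork(sub)
    net.missing_seeds = frozenset(missing)
    if missing:
        logger.info("%d seed genes absent from reference network",
                    len(missing))
    return net


def node_degrees(network: GeneNetwork) -> dict[str, int]:
    """Per-node incident-edge counts, with a logged min/max/mean summary."""
    deg = network.degrees()
    if deg:
        vals = list(deg.values())
        logger.info("degrees: n=%d min=%d max=%d mean=%.2f", len(vals),
                    min(vals), max(vals), sum(vals) / len(vals))
    return deg


def extract_degree_band(network: GeneNetwork, low: int = 20, high: int = 30,
                        label: str = "") -> SubnetworkSelection:
    """Select nodes whose degree in the parent network lies in [low, high].

    Degrees come from the parent network, not from the induced subgraph.
    An empty band yields mean_degree None.
    """
    if low > high:
        raise ValueError("need low <= high")
    deg = network.degrees()
    members = {g: d for g, d in deg.items() if low <= d <= high}
    mean = (sum(members.values()) / len(members)) if members else None
    return SubnetworkSelection(frozenset(members), (low, high), mean,
                               label=label, degrees=members)


def collapse_low_degree(network: GeneNetwork, max_degree: int = 2,
                        group_label: str = "Group0_2") -> GeneNetwork:
    """Replace all nodes of degree <= max_degree by one meta-node.

    The meta-node (role ``group``) carries the sorted member list; edges from
    members to retained nodes merge, keeping the maximum weight and recording
    the multiplicity.  The meta-node never enters key-gene selection.
    """
    if max_degree < 0:
        raise ValueError("max_degree must be >= 0")
    deg = network.degrees()
    low = {g for g, d in deg.items() if d <= max_degree}
    if not low:
        return network
    g = nx.Graph()
    keep = [n for n in network.graph.nodes if n not in low]
    for node in keep:
        g.add_node(node, **network.graph.nodes[node])
    g.add_node(group_label, role="group",
               members=",".join(sorted(low)), n_members=len(low))
    for a, b, data in network.graph.edges(data=True):
        a_low, b_low = a in low, b in low
        if a_low and b_low:
            continue
        if not a_low and not b_low:
            g.add_edge(a, b, **data)
            continue
        kept, w = (b, data["weight"]) if a_low else (a, data["weight"])
        if g.has_edge(group_label, kept):
            e = g.edges[group_label, kept]
            e["weight"] = max(e["weight"], w)
            e["multiplicity"] += 1
        else:
            g.add_edge(group_label, kept, weight=w, multiplicity=1)
    return GeneNetwork(g)


def select_key_genes(selections, candidates) -> tuple[frozenset[str],
                                                      dict[str, list[str]]]:
    """Union over degree-band selections of their candidate members.

    Returns the key-gene set and a provenance map gene -> contributing
    selection labels.  Intermediate genes never become key genes.
    """
    selections = list(selections)
    if not selections:
        raise ValueError("need at least one selection")
    cand_ids = (candidates.gene_ids if hasattr(candidates, "gene_ids")
                else frozenset(normalize_gene_id(g) for g in candidates))
    provenance: dict[str, list[str]] = {}
    for i, sel in enumerate(selections):
        label = sel.label or f"selection_{i}"
        for gene in sorted(sel.member_genes & cand_ids):
            provenance.setdefault(gene, []).append(label)
    return frozenset(provenance), provenance


def export_network(network: GeneNetwork, path, format: str = "sif") -> None:
    """Write the network as SIF (``a interacts b`` lines) or GraphML."""
    path = Path(path)
    if format == "sif":
        with open(path, "w") as fh:
            isolated = [n for n in sorted(network.graph.nodes)
                        if network.graph.degree(n) == 0]
            for a, b in sorted(map(sorted, network.graph.edges)):
                fh.write(f"{a} interacts {b}\n")
            for n in isolated:
                fh.write(f"{n}\n")
    elif format == "graphml":
        g = nx.Graph()
        for n, d in network.graph.nodes(data=True):
            g.add_node(n, role=d.get("role", "intermediate"),
                       degree=network.graph.degree(n),
                       **({"members": d["members"]} if "members" in d else {}))
        for a, b, d in network.graph.edges(data=True):
            g.add_edge(a, b, weight=float(d.get("weight", 1.0)))
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown export format {format!r}")


def read_exported_network(path, format: str = "sif") -> GeneNetwork:
    """Read back an exported network (for round-trip checks)."""
    if format == "sif":
        g = nx.Graph()
        with open(path) as fh:
            for line in fh:
                parts = line.split()
                if len(parts) == 1:
                    g.add_node(parts[0])
                elif len(parts) == 3:
                    g.add_edge(parts[0], parts[2], weight=1.0)
                elif parts:
                    raise ValueError(f"malformed SIF line: {line!r}")
        return GeneNetwork(g)
    if format == "graphml":
        return GeneNetwork(nx.read_graphml(path))
    raise ValueError(f"unknown export format {format!r}")
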