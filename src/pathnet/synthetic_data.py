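"""Synthetic study generator with known ground truth.

Emulates the statistical structure the pipeline assumes on real data:

* a pathway collection with log-uniform sizes over the analysis-ready range,
  natural overlap arising from independent membership sampling;
* per-condition gene p-values — Uniform(0,1) background, with members of
  planted enriched pathways drawn Beta(a, 1), a < 1 (stochastically smaller
  than uniform, so -log10 scores are shifted upward and right-skewness grows
  as a shrinks);
* a candidate list seeded into the planted pathways so the competitive test
  has recoverable signal, topped up with background genes;
* a hub-structured interaction network: truncated preferential-attachment
  background (mean degree ~ 7, degree cap below the analysis band) plus
  planted candidate hubs wired to a target degree inside the 20-30 band.

Every generator is a pure function of (parameters, seed); independent
deterministic streams are derived per component so outputs do not depend on
call order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from itertools import combinations
from pathlib import Path

import numpy as np

from ._util import logger
from .annotations import CandidateGeneList, Pathway, PathwayCollection, write_gmt
from .gene_scores import GeneScoreTable
from .network import GeneNetwork
from .sampling import sample_index_subsets

_STREAMS = {"annotations": 1, "candidates": 2, "scores": 3, "network": 4}

DEFAULT_CONDITIONS = ("3h", "6h", "12h", "24h")


@dataclass
class SyntheticTruth:
    """Ground truth and parameters for one simulated study.

    The planted sets (``enriched_pathway_ids``, ``candidate_ids``,
    ``planted_hub_ids``) start empty and are filled by the generators;
    pre-filling them pins the choice.
    """

    seed: int = 0
    universe_size: int = 5000
    n_pathways: int = 200
    size_range: tuple[int, int] = (6, 300)
    n_enriched: int = 10
    enrichment_effect: float = 0.1     # Beta(a, 1) shape for planted members
    planted_size_window: tuple[int, int] = (20, 80)
    n_candidates: int = 144
    candidates_per_enriched: int = 12
    candidate_score_cutoff: float = 42.0
    n_hubs: int = 5
    n_network_nodes: int = 300
    network_mean_links: int = 3        # truncated-PA attachments per node
    background_degree_cap: int = 15
    hub_degree_range: tuple[int, int] = (20, 28)
    min_seed_links: int = 2
    candidate_network_frac: float = 0.75
    condition_labels: tuple[str, ...] = DEFAULT_CONDITIONS
    late_onset_ids: frozenset[str] = frozenset()  # enriched only after 1st cond.
    skewness_target: float | None = None  # informational; not enforced per draw
    enriched_pathway_ids: frozenset[str] = frozenset()
    candidate_ids: frozenset[str] = frozenset()
    planted_hub_ids: frozenset[str] = frozenset()

    def __post_init__(self):
        lo, hi = self.size_range
        if not (1 <= lo <= hi <= self.universe_size):
            raise ValueError(f"size_range {self.size_range} infeasible for "
                             f"universe of {self.universe_size}")
        if not (0 < self.enrichment_effect <= 1):
            raise ValueError("enrichment_effect must lie in (0, 1]")
        if self.n_pathways < 1:
            raise ValueError("n_pathways must be >= 1")

    def rng(self, component: str, extra: tuple[int, ...] = ()) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence(
            entropy=self.seed, spawn_key=(_STREAMS[component],) + extra))

    def gene_ids(self) -> list[str]:
        return [f"g{i:05d}" for i in range(self.universe_size)]

    # -- manifest ---------------------------------------------------------

    def to_manifest(self, path) -> None:
        data = asdict(self)
        for key in ("enriched_pathway_ids", "candidate_ids",
                    "planted_hub_ids", "late_onset_ids"):
            data[key] = sorted(data[key])
        for key in ("size_range", "planted_size_window", "hub_degree_range",
                    "condition_labels"):
            data[key] = list(data[key])
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_manifest(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            data = json.load(fh)
        for key in ("enriched_pathway_ids", "candidate_ids",
                    "planted_hub_ids", "late_onset_ids"):
            data[key] = frozenset(data[key])
        for key in ("size_range", "planted_size_window", "hub_degree_range",
                    "condition_labels"):
            data[key] = tuple(data[key])
        return cls(**data)


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

def simulate_annotations(truth: SyntheticTruth) -> PathwayCollection:
    """Generate the pathway collection and choose the planted pathways.

    Sizes are log-uniform over ``size_range`` so small sets do not vanish
    against the 6-1500 span; memberships are sampled independently without
    replacement, letting overlap arise naturally.  If ``n_enriched`` > 0 and
    no planted ids were pre-set, planted pathways are drawn among those whose
    size falls in ``planted_size_window`` (moderate sizes keep the candidate
    overlap per pathway feasible).
    """
    rng = truth.rng("annotations")
    lo, hi = truth.size_range
    sizes = np.floor(np.exp(rng.uniform(np.log(lo), np.log(hi + 1),
                                        truth.n_pathways))).astype(int)
    sizes = np.clip(sizes, lo, hi)
    genes = truth.gene_ids()
    namespaces = ("biological_process", "cellular_component",
                  "molecular_function")
    pathways = []
    for i, size in enumerate(sizes):
        members = rng.choice(truth.universe_size, size=size, replace=False)
        pathways.append(Pathway(
            f"PW:{i:04d}", f"synthetic pathway {i}",
            namespaces[i % 3], frozenset(genes[j] for j in members)))
    collection = PathwayCollection(pathways)
    if truth.n_enriched > 0 and not truth.enriched_pathway_ids:
        w_lo, w_hi = truth.planted_size_window
        eligible = [p.pathway_id for p in pathways if w_lo <= p.size <= w_hi]
        if len(eligible) < truth.n_enriched:
            logger.warning("only %d pathways in planted size window; "
                           "relaxing to all", len(eligible))
            eligible = [p.pathway_id for p in pathways]
        chosen = rng.choice(len(eligible), size=truth.n_enriched,
                            replace=False)
        truth.enriched_pathway_ids = frozenset(eligible[j] for j in chosen)
    return collection


# ---------------------------------------------------------------------------
# candidates
# ---------------------------------------------------------------------------

def simulate_candidates(truth: SyntheticTruth,
                        collection: PathwayCollection) -> CandidateGeneList:
    """Build the prioritised candidate list.

    Each planted pathway contributes up to ``candidates_per_enriched``
    members; the list is topped up with background genes to ``n_candidates``.
    Priority scores are uniform above the cutoff (the list is already the
    retained tail of an upstream prioritisation).  Planted hubs are chosen
    among the planted candidates (falling back to any candidate).
    """
    rng = truth.rng("candidates")
    planted: list[str] = []
    seen: set[str] = set()
    for pid in sorted(truth.enriched_pathway_ids):
        members = sorted(collection.get(pid).genes - seen)
        take = min(len(members), truth.candidates_per_enriched)
        if take:
            picked = rng.choice(len(members), size=take, replace=False)
            chosen = [members[j] for j in picked]
            planted.extend(chosen)
            seen.update(chosen)
    n_total = max(truth.n_candidates, len(planted))
    if n_total > truth.n_candidates:
        logger.warning("planted candidates (%d) exceed n_candidates (%d); "
                       "growing the list", len(planted), truth.n_candidates)
    pool = sorted(set(truth.gene_ids()) - seen)
    extra = rng.choice(len(pool), size=n_total - len(planted), replace=False)
    gene_list = planted + [pool[j] for j in sorted(extra)]
    scores = rng.uniform(truth.candidate_score_cutoff,
                         truth.candidate_score_cutoff + 60, size=len(gene_list))
    truth.candidate_ids = frozenset(gene_list)
    if truth.n_hubs > 0 and not truth.planted_hub_ids:
        hub_pool = sorted(planted) if planted else sorted(gene_list)
        idx = rng.choice(len(hub_pool), size=min(truth.n_hubs, len(hub_pool)),
                         replace=False)
        truth.planted_hub_ids = frozenset(hub_pool[j] for j in idx)
    return CandidateGeneList(list(zip(gene_list, scores)),
                             score_cutoff=truth.candidate_score_cutoff)


# ---------------------------------------------------------------------------
# scores
# ---------------------------------------------------------------------------

def simulate_scores(truth: SyntheticTruth, collection: PathwayCollection,
                    condition_labels=None) -> list[GeneScoreTable]:
    """Per-condition p-value tables with planted enrichment.

    Background genes draw p ~ Uniform(0,1); members of enriched pathways draw
    p ~ Beta(a, 1) with a = ``enrichment_effect`` in every condition
    (pathways listed in ``late_onset_ids`` stay null in the first condition,
    mimicking responses that switch on only at later time points).
    """
    labels = tuple(condition_labels or truth.condition_labels)
    missing = truth.enriched_pathway_ids - set(collection.ids)
    if missing:
        raise ValueError(f"enriched pathways absent from collection: "
                         f"{sorted(missing)[:5]}")
    genes = truth.gene_ids()
    pos = {g: i for i, g in enumerate(genes)}
    tables = []
    for c, label in enumerate(labels):
        rng = truth.rng("scores", (c,))
        p = rng.uniform(size=truth.universe_size)
        active = set(truth.enriched_pathway_ids)
        if c == 0:
            active -= set(truth.late_onset_ids)
        member_idx = sorted({pos[g] for pid in sorted(active)
                             for g in collection.get(pid).genes})
        if member_idx:
            p[member_idx] = rng.beta(truth.enrichment_effect, 1.0,
                                     size=len(member_idx))
        p = np.clip(p, 1e-300, 1.0)
        tables.append(GeneScoreTable(label, genes, p))
    return tables


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------

def _truncated_pa_edges(rng, n, m, cap):
    """Preferential attachment with a hard degree cap.

    Attachment probability ~ degree + 1 among nodes below the cap, so the
    background stays hub-y in shape but no background node can reach the
    analysis degree band.
    """
    deg = np.zeros(n, dtype=int)
    edges: set[tuple[int, int]] = set()

    def add(a, b):
        e = (a, b) if a < b else (b, a)
        if e not in edges:
            edges.add(e)
            deg[a] += 1
            deg[b] += 1

    for a, b in combinations(range(m + 1), 2):
        add(a, b)
    for v in range(m + 1, n):
        elig = np.flatnonzero(deg[:v] < cap)
        w = deg[elig] + 1.0
        k = min(m, elig.size)
        targets = rng.choice(elig, size=k, replace=False, p=w / w.sum())
        for t in targets:
            add(v, int(t))
    return edges, deg


def simulate_network(truth: SyntheticTruth) -> GeneNetwork:
    """Hub-structured reference interactome over candidates and background.

    A fraction of the candidate list (always including the planted hubs) is
    placed into a truncated-preferential-attachment background of
    ``n_network_nodes`` genes; each planted hub is then wired up to a target
    degree inside ``hub_degree_range``, with at least ``min_seed_links``
    candidate neighbours, and every recruited non-candidate neighbour is
    guaranteed a second candidate link so seeding recovers it.  Non-hub
    candidates are pinned to low-degree positions, so only planted hubs can
    occupy the analysis band among candidates.
    """
    import networkx as nx

    if not truth.candidate_ids:
        raise ValueError("simulate_candidates must run first (candidate_ids "
                         "empty)")
    if not truth.planted_hub_ids <= truth.candidate_ids:
        raise ValueError("planted hubs must be candidates")
    lo_hub, hi_hub = truth.hub_degree_range
    n = truth.n_network_nodes
    if hi_hub >= n:
        raise ValueError("hub degree range exceeds node count")
    rng = truth.rng("network")

    edges, deg = _truncated_pa_edges(rng, n, truth.network_mean_links,
                                     truth.background_degree_cap)

    # choose which candidates join the network
    cands = sorted(truth.candidate_ids)
    hubs = sorted(truth.planted_hub_ids)
    non_hub = [g for g in cands if g not in set(hubs)]
    n_in = max(len(hubs),
               int(round(truth.candidate_network_frac * len(cands))))
    n_extra = min(len(non_hub), n_in - len(hubs))
    picked = rng.choice(len(non_hub), size=n_extra, replace=False)
    in_net = hubs + [non_hub[j] for j in sorted(picked)]
    if len(in_net) + 1 > n:
        raise ValueError("network too small for the candidate list")

    # assign candidates (hubs first) to low-degree node slots
    order = np.argsort(deg, kind="stable")
    low_slots = [int(i) for i in order if deg[i] <= 8]
    if len(low_slots) < len(in_net):
        low_slots = [int(i) for i in order]  # fall back: lowest degrees first
    slot_idx = rng.choice(len(low_slots), size=len(in_net), replace=False)
    node_gene: dict[int, str] = {}
    cand_slots: dict[str, int] = {}
    for g, j in zip(in_net, sorted(slot_idx)):
        node = low_slots[j]
        node_gene[node] = g
        cand_slots[g] = node
    hub_nodes = {cand_slots[g] for g in hubs}
    cand_nodes = set(cand_slots.values())

    # name remaining nodes with background genes not in the candidate list
    bg_pool = sorted(set(truth.gene_ids()) - truth.candidate_ids)
    bg_take = rng.choice(len(bg_pool), size=n - len(in_net), replace=False)
    bg_iter = iter(bg_pool[j] for j in sorted(bg_take))
    for node in range(n):
        if node not in node_gene:
            node_gene[node] = next(bg_iter)

    adj: dict[int, set[int]] = {i: set() for i in range(n)}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)

    def wire(a, b):
        if b not in adj[a]:
            edges.add((a, b) if a < b else (b, a))
            adj[a].add(b)
            adj[b].add(a)
            deg[a] += 1
            deg[b] += 1

    non_hub_cand_nodes = sorted(cand_nodes - hub_nodes)
    for hub_gene in hubs:
        h = cand_slots[hub_gene]
        target = int(rng.integers(lo_hub, hi_hub + 1))
        # candidate neighbours first
        pool = [u for u in non_hub_cand_nodes
                if u not in adj[h] and deg[u] < truth.background_degree_cap]
        for u in list(rng.permutation(pool))[:truth.min_seed_links]:
            wire(h, int(u))
        # then background neighbours, each guaranteed a 2nd candidate link
        bg_nodes = [u for u in range(n)
                    if u not in cand_nodes and u != h]
        rng.shuffle(bg_nodes)
        for u in bg_nodes:
            if deg[h] >= target:
                break
            if u in adj[h] or deg[u] >= truth.background_degree_cap + 2:
                continue
            wire(h, u)
            cand_nb = sum(1 for v in adj[u] if v in cand_nodes)
            if cand_nb < truth.min_seed_links:
                helpers = [v for v in non_hub_cand_nodes
                           if v not in adj[u] and deg[v] < 13]
                if helpers:
                    wire(u, int(rng.choice(helpers)))

    g = nx.Graph()
    for node in range(n):
        role = "candidate" if node in cand_nodes else "intermediate"
        g.add_node(node_gene[node], role=role)
    weights = np.round(rng.gamma(2.0, 1.5, size=len(edges)) + 0.1, 3)
    for (a, b), w in zip(sorted(edges), weights):
        g.add_edge(node_gene[a], node_gene[b], weight=float(w))
    net = GeneNetwork(g)
    net.missing_seeds = frozenset(truth.candidate_ids -
                                  {node_gene[i] for i in cand_nodes})
    # construction guarantees: hubs inside the band, other candidates below it
    dd = net.degrees()
    assert all(lo_hub <= dd[h] <= hi_hub + 2 for h in hubs)
    assert all(dd[node_gene[u]] < lo_hub for u in non_hub_cand_nodes)
    return net


# ---------------------------------------------------------------------------
# fixture bundle
# ---------------------------------------------------------------------------

def write_fixture_bundle(truth: SyntheticTruth, outdir) -> dict[str, Path]:
    """Generate everything and write it in the pipeline's input formats.

    Writes ``annotations.gmt``, one ``scores_<condition>.tsv`` per condition,
    ``candidates.tsv``, ``network_edges.tsv`` and a machine-readable
    ``truth.json`` manifest; returns the path map.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    collection = simulate_annotations(truth)
    candidates = simulate_candidates(truth, collection)
    tables = simulate_scores(truth, collection)
    net = simulate_network(truth)

    paths: dict[str, Path] = {"annotations": outdir / "annotations.gmt"}
    write_gmt(collection, paths["annotations"])
    for table in tables:
        key = f"scores_{table.condition_label}"
        paths[key] = outdir / f"{key}.tsv"
        table.to_tsv(paths[key])
    paths["candidates"] = outdir / "candidates.tsv"
    candidates.to_tsv(paths["candidates"])
    paths["edges"] = outdir / "network_edges.tsv"
    with open(paths["edges"], "w") as fh:
        fh.write("gene_a\tgene_b\tweight\n")
        for a, b in sorted(map(sorted, net.graph.edges)):
            fh.write(f"{a}\t{b}\t{net.graph.edges[a, b]['weight']:.3f}\n")
    paths["truth"] = outdir / "truth.json"
    truth.to_manifest(paths["truth"])
    return paths
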