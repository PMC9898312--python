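"""End-to-end orchestration: annotations -> scores -> enrichment -> networks
-> key genes -> group comparisons, with a reproducible run manifest.

Every analysis threshold is a :class:`PipelineConfig` field; nothing is
hard-coded, and the manifest written alongside the outputs (config, seed,
stage row counts, resolved L/M per condition) suffices to reproduce a run
byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from ._util import logger
from . import annotations as ann
from . import enrichment as enr
from . import gene_scores as gsc
from . import group_compare as grp
from . import network as nwk

__version__ = "0.1.0"


@dataclass
class PipelineConfig:
    """Inputs and analysis settings for one run."""

    annotations: str = ""
    annotations_format: str = "gmt"
    score_tables: dict[str, str] = field(default_factory=dict)  # label -> path
    candidates: str = ""
    candidate_score_cutoff: float | None = None
    edge_list: str = ""
    output_dir: str = "pathnet_run"

    min_size: int = 6
    max_size: int = 1500
    significance_threshold: float = 1e-4
    fdr_level: float = 0.05
    permutations: int = 10_000
    seed: int = 0
    methods: tuple[str, ...] = ("hypergeometric", "sumstat", "sumsq")
    require_all_conditions: bool = True
    degree_band: tuple[int, int] = (20, 30)
    low_degree_collapse: int = 2
    min_seed_links: int = 2
    single_gene_threshold: float = 3.0
    group_test_resamples: int = 10_000

    def __post_init__(self):
        if self.min_size > self.max_size:
            raise ValueError("min_size must be <= max_size")
        lo, hi = self.degree_band
        if lo > hi:
            raise ValueError("degree band low must be <= high")
        for name in ("significance_threshold", "fdr_level",
                     "single_gene_threshold"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be positive")
        unknown = set(self.methods) - set(enr.METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        for key in ("methods", "degree_band"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["methods"] = list(self.methods)
        data["degree_band"] = list(self.degree_band)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    def resolve(self, base) -> "PipelineConfig":
        """Resolve relative input paths against a base directory."""
        base = Path(base)
        out = PipelineConfig(**{**asdict(self)})
        out.methods = tuple(self.methods)
        out.degree_band = tuple(self.degree_band)
        out.annotations = str(base / self.annotations)
        out.candidates = str(base / self.candidates)
        out.edge_list = str(base / self.edge_list)
        out.score_tables = {k: str(base / v)
                            for k, v in self.score_tables.items()}
        return out


@dataclass
class PipelineResult:
    collection: ann.PathwayCollection
    tables: list[gsc.GeneScoreTable]
    enrichment: list[enr.EnrichmentResults]
    consensus: enr.ConsensusResult
    networks: dict[str, nwk.GeneNetwork]
    selections: dict[str, nwk.SubnetworkSelection]
    key_genes: frozenset[str]
    key_provenance: dict[str, list[str]]
    comparisons: pd.DataFrame
    zscores: pd.DataFrame
    manifest: dict
    output_dir: Path


def _network_seed_sets(candidates: ann.CandidateGeneList,
                       collection: ann.PathwayCollection,
                       consensus: enr.ConsensusResult,
                       methods) -> dict[str, frozenset[str]]:
    """Seed-gene subsets mirroring the method-specific gene networks."""
    cand = candidates.gene_ids
    sets = {"all_candidates": cand}
    available = {p.pathway_id: p for p in collection}

    def genes_of(pids):
        out: set[str] = set()
        for pid in pids:
            if pid in available:
                out |= available[pid].genes
        return frozenset(out) & cand

    for method in methods:
        ids = consensus.per_method.get(method, [])
        if ids:
            sets[method] = genes_of(ids)
    pair = "hypergeometric&sumstat"
    if pair in consensus.intersections and consensus.intersections[pair]:
        sets[pair] = genes_of(consensus.intersections[pair])
    return {k: v for k, v in sets.items() if v}


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full workflow and write all outputs under ``output_dir``."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "version": __version__,
                      "stages": {}}

    # Step 1: annotations
    collection = ann.read_gene_sets(config.annotations,
                                    config.annotations_format)
    manifest["stages"]["annotations_read"] = len(collection)
    collection = ann.filter_by_size(collection, config.min_size,
                                    config.max_size)
    manifest["stages"]["annotations_size_filtered"] = len(collection)
    candidates = ann.CandidateGeneList.from_tsv(
        config.candidates, score_cutoff=config.candidate_score_cutoff)
    collection = ann.restrict_to_candidates(collection, candidates)
    manifest["stages"]["annotations_with_candidates"] = len(collection)
    ann.write_gmt(collection, outdir / "filtered_annotations.gmt")

    # Step 2: gene scores
    tables = [gsc.read_score_table(path, condition_label=label)
              for label, path in sorted(config.score_tables.items())]
    for table in tables:
        table.to_tsv(outdir / f"scores_{table.condition_label}.tsv",
                     significance_threshold=config.single_gene_threshold)
        manifest["stages"][f"genes_{table.condition_label}"] = len(table)

    # Step 3: enrichment per condition and method
    pconfig = enr.PermutationConfig(B=config.permutations, seed=config.seed)
    results: list[enr.EnrichmentResults] = []
    backgrounds = {}
    for table in tables:
        restricted = ann.restrict_to_universe(collection, table.universe)
        cache = enr.PermutationNullCache(table, pconfig)
        for method in config.methods:
            if method == "hypergeometric":
                res = enr.CompetitiveEnrichment(
                    table, restricted, candidates,
                    config.significance_threshold).fit()
            else:
                res = enr.SelfContainedEnrichment(
                    table, restricted, method, pconfig, candidates,
                    config.significance_threshold, null_cache=cache).fit()
            res.to_tsv(outdir /
                       f"enrichment_{method}_{table.condition_label}.tsv")
            results.append(res)
        backgrounds[table.condition_label] = {
            "L": results[-1].universe_size, "M": results[-1].n_candidates}
    manifest["backgrounds"] = backgrounds

    # Step 4: consensus
    consensus = enr.consensus_pathways(results, config.significance_threshold,
                                       config.require_all_conditions)
    consensus.to_frame().to_csv(outdir / "consensus.tsv", sep="\t",
                                index=False)
    manifest["stages"]["consensus_per_method"] = {
        m: len(ids) for m, ids in sorted(consensus.per_method.items())}

    # Step 5: networks and key genes
    reference = nwk.read_edge_list(config.edge_list)
    networks: dict[str, nwk.GeneNetwork] = {}
    selections: dict[str, nwk.SubnetworkSelection] = {}
    lo, hi = config.degree_band
    for label, seeds in _network_seed_sets(candidates, collection, consensus,
                                           config.methods).items():
        net = nwk.build_seeded_network(reference, seeds,
                                       config.min_seed_links)
        networks[label] = net
        selections[label] = nwk.extract_degree_band(net, lo, hi, label=label)
        nwk.export_network(net, outdir / f"network_{label}.sif", "sif")
        collapsed = nwk.collapse_low_degree(
            net, config.low_degree_collapse,
            f"Group0_{config.low_degree_collapse}")
        nwk.export_network(collapsed, outdir / f"network_{label}.graphml",
                           "graphml")
        deg = net.degrees()
        report = pd.DataFrame(
            [(g, net.role(g), deg[g], lo <= deg[g] <= hi)
             for g in sorted(net.nodes)],
            columns=["gene_id", "role", "degree", "in_band"])
        report.to_csv(outdir / f"network_{label}_nodes.tsv", sep="\t",
                      index=False)
        manifest["stages"][f"network_{label}"] = {
            "nodes": net.n_nodes, "edges": net.n_edges,
            "missing_seeds": len(net.missing_seeds),
            "in_band": len(selections[label].member_genes)}
    key_genes, provenance = nwk.select_key_genes(
        list(selections.values()), candidates)
    key_frame = pd.DataFrame(
        [(g, ";".join(provenance[g])) for g in sorted(key_genes)],
        columns=["gene_id", "selections"])
    key_frame.to_csv(outdir / "key_genes.tsv", sep="\t", index=False)
    manifest["stages"]["key_genes"] = len(key_genes)

    # Step 5b: group comparisons on scores
    intermediates = (networks["all_candidates"].genes_with_role("intermediate")
                     if "all_candidates" in networks else frozenset())
    comp_rows = []
    pairs = [("key", "candidate"), ("key", "intermediate"),
             ("key", "remaining"), ("candidate", "intermediate"),
             ("candidate", "remaining"), ("intermediate", "remaining")]
    for table in tables:
        groups = grp.stratify_genes(table, key_genes, candidates.gene_ids,
                                    intermediates)
        for a, b in pairs:
            if len(groups[a]) < 2 or len(groups[b]) < 2:
                continue
            res = grp.compare_group_means(
                table.scores_for(groups[a]), table.scores_for(groups[b]),
                n_resamples=config.group_test_resamples, seed=config.seed,
                labels=(a, b), condition_label=table.condition_label)
            comp_rows.append(asdict(res))
    comparisons = pd.DataFrame(comp_rows)
    comparisons.to_csv(outdir / "group_comparisons.tsv", sep="\t",
                       index=False, float_format="%.6g")

    # per-gene two-proportion z: conditions passing the single-gene flag
    # vs the genome-wide background proportion
    flags = {t.condition_label: gsc.flag_single_gene_significance(
        t, config.single_gene_threshold) for t in tables}
    n_cond = len(tables)
    common = set.intersection(*(set(f) for f in flags.values())) \
        if flags else set()
    total_flags = sum(sum(f[g] for g in common) for f in flags.values())
    total_n = n_cond * len(common)
    z_rows = []
    for gene in sorted(candidates.gene_ids & common):
        x1 = sum(flags[c][gene] for c in flags)
        z = grp.two_proportion_z(x1, n_cond, total_flags, total_n) \
            if total_n else 0.0
        z_rows.append((gene, x1, n_cond, round(z, 4)))
    zscores = pd.DataFrame(z_rows, columns=["gene_id", "n_significant",
                                            "n_conditions", "z_score"])
    zscores.to_csv(outdir / "candidate_zscores.tsv", sep="\t", index=False)

    with open(outdir / "run_manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    logger.info("pipeline complete: %d key genes, outputs in %s",
                len(key_genes), outdir)
    return PipelineResult(collection, tables, results, consensus, networks,
                          selections, key_genes, provenance, comparisons,
                          zscores, manifest, outdir)
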