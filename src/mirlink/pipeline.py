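"""End-to-end orchestration: filter -> normalise -> DE -> cluster -> target ->
link -> enrich -> network.

Every stage writes its table under the run directory and logs one structured
line with record counts in/out. Given the same configuration (including the
seed) the run directory is byte-identical across reruns; anything
time-dependent goes to the log stream only.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd
import yaml

from . import clustering, enrichment, expression, integration, ioformats, targeting

log = logging.getLogger("mirlink")


@dataclass
class PipelineConfig:
    """All thresholds of the analysis, at their published defaults."""

    mirna_counts: str = "mirna_counts.tsv"
    mirna_samples: str = "mirna_samples.tsv"
    mrna_counts: str = "mrna_counts.tsv"
    mrna_samples: str = "mrna_samples.tsv"
    mirna_fasta: str = "mirna.fasta"
    transcripts_fasta: str = "transcripts.fasta"
    annotation: str = "annotation.tsv"
    pathways_gmt: str = "pathways.gmt"
    outdir: str = "run"

    min_max_depth: int = 10
    mirna_padj: float = 0.05
    mirna_min_abs_log2fc: float = 0.0
    mrna_padj: float = 0.05
    mrna_min_abs_log2fc: float = 0.5
    n_clusters: int = 5
    linkage: str = "complete"
    distance: str = "euclidean"
    fuzzifier: float = 2.0
    dispersion_mode: str = "pooled"
    top_fraction: float = 0.20
    select_before_de_intersect: bool = True
    r_link_max: float = -0.5
    enrich_padj_max: float = 0.05
    within_cluster_bh: bool = True
    network_top_fraction_per_pathway: float = 0.50
    network_r_max: float = -0.8
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("top_fraction", "network_top_fraction_per_pathway"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        for name in ("r_link_max", "network_r_max"):
            v = getattr(self, name)
            if not -1 <= v <= 0:
                raise ValueError(f"{name} must be in [-1, 0]")

    @classmethod
    def from_yaml(cls, path: Path | str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: Path | str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def correlation_to_hex(r: float, lo: float = -1.0, hi: float = -0.8) -> str:
    """Map a correlation in [lo, hi] (clamped) to dark grey .. white."""
    if math.isnan(r):
        r = hi
    t = (min(max(r, lo), hi) - lo) / (hi - lo)      # 0 at lo (strongest), 1 at hi
    dark, white = 64, 255
    v = int(round(dark + t * (white - dark)))
    return f"#{v:02x}{v:02x}{v:02x}"


def build_network(links: pd.DataFrame, enrich_results: pd.DataFrame,
                  config: PipelineConfig) -> nx.DiGraph:
    """Display subgraph of the linked pairs for the enriched pathways.

    Per enriched (cluster, pathway) row: that cluster's links into the
    pathway are reduced to the top-half by composite score (ceil rounding,
    deterministic ties) AND strict anti-correlation r < network_r_max. Gene
    nodes carry the strongest (most negative) correlation of their incoming
    edges and a grey-scale hex colour over [-1, -0.8]; edges carry the score,
    the correlation and the pathway ids that recruited them.
    """
    G = nx.DiGraph()
    if links.empty or enrich_results.empty:
        return G
    gene_hits = {}
    for row in enrich_results.itertuples(index=False):
        hits = set(row.gene_hits.split(","))
        sub = links[(links["cluster"] == row.cluster)
                    & (links["gene_id"].isin(hits))]
        if sub.empty:
            continue
        sub = sub[sub["pearson_r"] < config.network_r_max]    # strict bound
        if sub.empty:
            continue
        n_keep = math.ceil(config.network_top_fraction_per_pathway * len(sub))
        sub = sub.sort_values(["score", "mirna_id", "gene_id"],
                              ascending=[False, True, True], kind="mergesort")
        sub = sub.head(n_keep)
        for link in sub.itertuples(index=False):
            key = (link.mirna_id, link.gene_id)
            if G.has_edge(*key):
                paths = set(G.edges[key]["pathways"].split(";"))
                paths.add(row.pathway_id)
                G.edges[key]["pathways"] = ";".join(sorted(paths))
            else:
                G.add_node(link.mirna_id, kind="mirna",
                           cluster=int(link.cluster))
                if not G.has_node(link.gene_id):
                    G.add_node(link.gene_id, kind="gene")
                G.add_edge(link.mirna_id, link.gene_id,
                           score=float(link.score),
                           pearson_r=float(link.pearson_r),
                           pathways=row.pathway_id)
            prev = gene_hits.get(link.gene_id)
            if prev is None or link.pearson_r < prev:
                gene_hits[link.gene_id] = float(link.pearson_r)
    for gid, r in gene_hits.items():
        G.nodes[gid]["pearson_r"] = r
        G.nodes[gid]["color"] = correlation_to_hex(r)
    return G


def _stage_log(stage: str, n_in: int, n_out: int, **extra) -> None:
    kv = " ".join(f"{k}={v}" for k, v in extra.items())
    log.info("stage=%s in=%d out=%d %s", stage, n_in, n_out, kv)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full analysis; returns the run directory."""
    cfg = config
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.yaml")
    summary: dict[str, object] = {}

    # --- load ------------------------------------------------------------
    mirna_cm = ioformats.read_counts(cfg.mirna_counts, cfg.mirna_samples)
    mrna_cm = ioformats.read_counts(cfg.mrna_counts, cfg.mrna_samples)
    mirna_seqs = ioformats.read_fasta(cfg.mirna_fasta)
    tx_seqs = ioformats.read_fasta(cfg.transcripts_fasta)
    annotations = ioformats.read_annotation(cfg.annotation)
    pathways = ioformats.read_gmt(cfg.pathways_gmt)

    # --- low-count filter ------------------------------------------------
    mirna_f = expression.low_count_filter(mirna_cm, cfg.min_max_depth)
    mrna_f = expression.low_count_filter(mrna_cm, cfg.min_max_depth)
    _stage_log("filter_mirna", mirna_cm.n_features, mirna_f.n_features,
               min_max_depth=cfg.min_max_depth)
    _stage_log("filter_mrna", mrna_cm.n_features, mrna_f.n_features,
               min_max_depth=cfg.min_max_depth)
    summary["n_mirna_filtered"] = mirna_f.n_features
    summary["n_mrna_filtered"] = mrna_f.n_features

    # --- normalise -------------------------------------------------------
    sf_mi = expression.size_factors(mirna_f)
    sf_mr = expression.size_factors(mrna_f)
    norm_mi = expression.normalize_log(mirna_f, sf_mi)
    norm_mr = expression.normalize_log(mrna_f, sf_mr)
    norm_mi.normalized_log.to_csv(out / "mirna_normalized_log.tsv", sep="\t")
    norm_mr.normalized_log.to_csv(out / "mrna_normalized_log.tsv", sep="\t")

    # --- differential expression ------------------------------------------
    stage_order = [s for s in ioformats.STAGES
                   if s in set(mirna_f.stages)]
    mi_contrasts = expression.pairwise_contrasts(mirna_f, sf_mi, stage_order,
                                                 cfg.dispersion_mode)
    mr_contrasts = expression.pairwise_contrasts(mrna_f, sf_mr, stage_order,
                                                 cfg.dispersion_mode)
    for name, res in mi_contrasts.items():
        res.to_csv(out / f"de_mirna_{name}.tsv", sep="\t")
    for name, res in mr_contrasts.items():
        res.to_csv(out / f"de_mrna_{name}.tsv", sep="\t")
    de_mirnas = expression.differentially_expressed(
        mi_contrasts, cfg.mirna_padj, cfg.mirna_min_abs_log2fc)
    de_genes = expression.differentially_expressed(
        mr_contrasts, cfg.mrna_padj, cfg.mrna_min_abs_log2fc)
    _stage_log("de_mirna", mirna_f.n_features, len(de_mirnas),
               padj=cfg.mirna_padj, min_abs_lfc=cfg.mirna_min_abs_log2fc)
    _stage_log("de_mrna", mrna_f.n_features, len(de_genes),
               padj=cfg.mrna_padj, min_abs_lfc=cfg.mrna_min_abs_log2fc)
    summary["n_de_mirna"] = len(de_mirnas)
    summary["n_de_mrna"] = len(de_genes)

    # --- cluster DE miRNAs -------------------------------------------------
    if len(de_mirnas) >= cfg.n_clusters:
        de_profiles = norm_mi.normalized_log.loc[sorted(de_mirnas)]
        sd = de_profiles.std(axis=1, ddof=0)
        de_profiles = de_profiles[sd > 0]
        zprof = clustering.standardize_profiles(de_profiles)
        assign = clustering.hierarchical_clusters(zprof, cfg.n_clusters,
                                                  cfg.linkage, cfg.distance)
        memberships, _ = clustering.fuzzy_profiles(
            zprof, cfg.n_clusters, cfg.fuzzifier, rng_seed=cfg.rng_seed)
        assign.memberships = memberships
        pd.DataFrame({"cluster": assign.labels}).to_csv(
            out / "mirna_clusters.tsv", sep="\t")
        assign.cluster_profiles.to_csv(out / "cluster_profiles.tsv", sep="\t")
        memberships.to_csv(out / "fuzzy_memberships.tsv", sep="\t")
        with open(out / "mirna_dendrogram.nwk", "w") as fh:
            fh.write(assign.tree_newick + "\n")
        clusters = assign.labels
    else:
        clusters = pd.Series({m: 1 for m in sorted(de_mirnas)}, dtype=int)
        pd.DataFrame({"cluster": clusters}).to_csv(
            out / "mirna_clusters.tsv", sep="\t")
    _stage_log("cluster", len(de_mirnas), int(clusters.nunique()) if len(clusters) else 0,
               k=cfg.n_clusters)

    # --- 3'-UTR extraction -------------------------------------------------
    by_tx: dict[str, list[ioformats.UTRRecord]] = {}
    for ann in annotations:
        if ann.transcript_id not in tx_seqs:
            raise KeyError(f"annotation references unknown transcript "
                           f"{ann.transcript_id!r}")
        rec = ioformats.extract_3utr(tx_seqs[ann.transcript_id], ann)
        by_tx.setdefault(ann.transcript_id, []).append(rec)
    utrs: dict[str, tuple[str, str]] = {}
    for tid in sorted(by_tx):
        rec = ioformats.choose_longest_utr(by_tx[tid])
        if rec.length > 0:
            utrs[tid] = (rec.gene_id, rec.sequence)
    _stage_log("utr_extraction", len(annotations), len(utrs))
    summary["n_utrs"] = len(utrs)

    # --- target prediction for DE miRNAs -----------------------------------
    de_mirna_seqs = {m: mirna_seqs[m] for m in sorted(de_mirnas)
                     if m in mirna_seqs}
    missing = sorted(set(de_mirnas) - set(mirna_seqs))
    if missing:
        raise KeyError(f"no mature sequence for DE miRNAs: {missing[:5]}")
    predictions = targeting.predict_targets(de_mirna_seqs, utrs)
    scored = targeting.score_predictions(predictions)
    if cfg.select_before_de_intersect:
        retained = targeting.select_top_fraction(scored, cfg.top_fraction)
    else:
        subset = scored[scored["gene_id"].isin(de_genes)]
        retained = targeting.select_top_fraction(subset, cfg.top_fraction)
    scored_out = scored.copy()
    key = pd.MultiIndex.from_frame(retained[["mirna_id", "transcript_id"]])
    scored_key = pd.MultiIndex.from_frame(scored_out[["mirna_id", "transcript_id"]])
    scored_out["retained"] = scored_key.isin(key)
    scored_out.to_csv(out / "target_predictions.tsv", sep="\t", index=False)
    _stage_log("targeting", len(scored), len(retained),
               top_fraction=cfg.top_fraction)
    summary["n_predictions"] = len(scored)
    summary["n_retained"] = len(retained)

    # --- stage profiles and pair links --------------------------------------
    mi_prof = integration.stage_average(norm_mi.normalized_log, mirna_f.stages,
                                        stage_order)
    mr_prof = integration.stage_average(norm_mr.normalized_log, mrna_f.stages,
                                        stage_order)
    mi_prof.to_csv(out / "mirna_stage_profiles.tsv", sep="\t")
    mr_prof.to_csv(out / "mrna_stage_profiles.tsv", sep="\t")
    links = integration.link_pairs(retained, clusters, de_genes,
                                   mi_prof, mr_prof, cfg.r_link_max)
    links.to_csv(out / "pair_links.tsv", sep="\t", index=False)
    _stage_log("link", len(retained), len(links), r_max=cfg.r_link_max)
    summary["n_links"] = len(links)

    # --- enrichment ----------------------------------------------------------
    covered = pathways.all_genes()
    universe = set(mrna_f.counts.index) & covered
    links_in_universe = links[links["gene_id"].isin(universe)]
    enriched = enrichment.enrich_clusters(links_in_universe, pathways, universe,
                                          cfg.enrich_padj_max,
                                          cfg.within_cluster_bh)
    enriched.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    _stage_log("enrich", len(links_in_universe), len(enriched),
               padj=cfg.enrich_padj_max, universe=len(universe))
    summary["n_enriched"] = len(enriched)

    # --- network -------------------------------------------------------------
    graph = build_network(links, enriched, cfg)
    ioformats.write_network(graph, out / "network.graphml",
                            out / "network_edges.tsv")
    _stage_log("network", len(links), graph.number_of_edges(),
               r_max=cfg.network_r_max,
               top_fraction=cfg.network_top_fraction_per_pathway)
    summary["n_network_edges"] = graph.number_of_edges()
    summary["n_network_nodes"] = graph.number_of_nodes()

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out
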