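"""Cluster-wise pathway over-representation of anti-correlated target genes.

For each miRNA cluster, the query is the set of genes its pair links point
at; each pathway with at least one overlapping gene is tested with the exact
hypergeometric upper tail P(X >= k), and Benjamini-Hochberg correction is
applied across the pathways tested within that cluster (optionally across all
cluster x pathway tests). A cluster whose targets hit no pathway beyond
chance legitimately produces zero rows.
"""

from __future__ import annotations

import pandas as pd
from scipy import stats

from .expression import bh_adjust
from .ioformats import GeneSetCollection


def hypergeom_upper(k: int, K: int, n: int, N: int) -> float:
    """Exact upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    N: universe size, K: pathway genes in the universe, n: query-set size,
    k: overlap. Inconsistent counts are rejected.
    """
    if not (0 <= k <= min(n, K)):
        raise ValueError(f"k={k} outside [0, min(n={n}, K={K})]")
    if N < max(n, K) or n < 0 or K < 0:
        raise ValueError(f"inconsistent counts: k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich_clusters(links: pd.DataFrame, pathways: GeneSetCollection,
                    universe: set[str], padj_max: float = 0.05,
                    within_cluster_bh: bool = True) -> pd.DataFrame:
    """Hypergeometric over-representation per cluster, BH-corrected.

    ``links`` must carry columns cluster, gene_id. Every query gene must lie
    inside ``universe`` (the caller restricts queries to pathway-covered genes
    first). Pathways are intersected with the universe; only pathways with
    k >= 1 are tested. Rows with padj <= padj_max are returned, with the dot
    plot quantities (row percentage k/K*100) attached.
    """
    cols = ["cluster", "pathway_id", "pathway_name", "k", "n", "K", "N",
            "p", "padj", "row_pct", "gene_hits"]
    if links.empty:
        return pd.DataFrame(columns=cols)
    N = len(universe)
    path_sets = {pid: pathways.genes(pid) & universe for pid in pathways}
    path_sets = {pid: s for pid, s in path_sets.items() if s}

    all_rows: list[dict] = []
    for cluster, grp in links.groupby("cluster", sort=True):
        query = set(grp["gene_id"])
        outside = sorted(query - universe)
        if outside:
            raise ValueError(
                f"cluster {cluster}: query genes outside universe: {outside[:5]}")
        n = len(query)
        rows = []
        for pid in sorted(path_sets):
            genes = path_sets[pid]
            hits = sorted(query & genes)
            k = len(hits)
            if k == 0:
                continue
            K = len(genes)
            rows.append({
                "cluster": cluster,
                "pathway_id": pid,
                "pathway_name": pathways.names.get(pid, pid),
                "k": k, "n": n, "K": K, "N": N,
                "p": hypergeom_upper(k, K, n, N),
                "row_pct": 100.0 * k / K,
                "gene_hits": ",".join(hits),
            })
        if within_cluster_bh and rows:
            padj = bh_adjust([r["p"] for r in rows])
            for r, q in zip(rows, padj):
                r["padj"] = float(q)
        all_rows.extend(rows)

    if not within_cluster_bh and all_rows:
        padj = bh_adjust([r["p"] for r in all_rows])
        for r, q in zip(all_rows, padj):
            r["padj"] = float(q)

    df = pd.DataFrame(all_rows, columns=cols)
    if df.empty:
        return df
    df = df[df["padj"] <= padj_max].reset_index(drop=True)
    return df[cols]
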