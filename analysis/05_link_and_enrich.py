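#!/usr/bin/env python
"""Refine predictions into anti-correlated pair links; enrich per cluster.

Keeps retained predictions whose gene is DE and whose stage profiles
anti-correlate with the miRNA at Pearson r <= -0.5, then tests each
cluster's target genes for pathway over-representation (hypergeometric,
BH within cluster). Reports precision/recall against the planted pairs.
"""

from pathlib import Path

import pandas as pd

from mirlink import enrichment as en
from mirlink import expression as ex
from mirlink import integration as it
from mirlink import ioformats as io

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "links"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    norm_mi = pd.read_csv(ROOT / "results/de/mirna_normalized_log.tsv",
                          sep="\t", index_col=0)
    norm_mr = pd.read_csv(ROOT / "results/de/mrna_normalized_log.tsv",
                          sep="\t", index_col=0)
    stages = pd.read_csv(ROOT / "results/sim/mirna_samples.tsv", sep="\t") \
        .set_index("sample_id")["stage"]
    mi_prof = it.stage_average(norm_mi, stages)
    mr_prof = it.stage_average(norm_mr, stages)

    preds = pd.read_csv(ROOT / "results/targets/target_predictions.tsv",
                        sep="\t")
    retained = preds[preds["retained"]]
    de_genes = set(pd.read_csv(ROOT / "results/de/mrna_de_features.tsv",
                               sep="\t")["feature_id"])
    clusters = pd.read_csv(ROOT / "results/clusters/mirna_clusters.tsv",
                           sep="\t", index_col=0)["cluster"]
    links = it.link_pairs(retained, clusters, de_genes, mi_prof, mr_prof,
                          r_max=-0.5)
    links.to_csv(OUT / "pair_links.tsv", sep="\t", index=False)

    truth = pd.read_csv(ROOT / "results/sim/truth_pairs.tsv", sep="\t")
    t = set(map(tuple, truth[["mirna_id", "gene_id"]].values))
    f = set(map(tuple, links[["mirna_id", "gene_id"]].values))
    tp = len(t & f)
    print(f"{len(f)} anti-correlated links; planted-pair precision "
          f"{tp / max(len(f), 1):.3f}, recall {tp / len(t):.3f}")

    pathways = io.read_gmt(ROOT / "results/sim/pathways.gmt")
    universe = set(norm_mr.index) & pathways.all_genes()
    enriched = en.enrich_clusters(links[links["gene_id"].isin(universe)],
                                  pathways, universe)
    enriched.to_csv(OUT / "enrichment.tsv", sep="\t", index=False)
    if enriched.empty:
        print("no pathway enrichment in any cluster")
    for row in enriched.itertuples(index=False):
        print(f"cluster {row.cluster}: {row.pathway_id} k={row.k}/{row.K} "
              f"padj={row.padj:.2e}")


if __name__ == "__main__":
    main()
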