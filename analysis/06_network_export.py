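#!/usr/bin/env python
"""Export the display network of enriched pathways and their targeted genes.

Within each enriched pathway, edges need strict anti-correlation
(r < -0.8) and a top-half composite score; gene nodes are shaded dark grey
to white over the correlation range [-1, -0.8]. GraphML (for a network
viewer) plus a flat edge TSV and the enrichment dot plot are written.
"""

from pathlib import Path

import pandas as pd

from mirlink import ioformats as io
from mirlink.pipeline import PipelineConfig, build_network
from mirlink.plots import enrichment_dotplot, profile_plot

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "network"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    links = pd.read_csv(ROOT / "results/links/pair_links.tsv", sep="\t")
    enriched = pd.read_csv(ROOT / "results/links/enrichment.tsv", sep="\t")
    graph = build_network(links, enriched, PipelineConfig())
    io.write_network(graph, OUT / "network.graphml", OUT / "network_edges.tsv")
    print(f"network: {graph.number_of_nodes()} nodes, "
          f"{graph.number_of_edges()} edges "
          f"({len(links)} links before display filtering)")

    made = enrichment_dotplot(ROOT / "results/links/enrichment.tsv",
                              OUT / "enrichment_dotplot.png")
    if made:
        print(f"wrote {made}")
    print("wrote", profile_plot(ROOT / "results/clusters/cluster_profiles.tsv",
                                OUT / "cluster_profiles.png"))


if __name__ == "__main__":
    main()
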