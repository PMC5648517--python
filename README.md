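# mirlink

Integrative miRNA–mRNA analysis of staged expression data, built around the
question of which miRNAs repress which transcripts during testis maturation
(immature → prepubertal → pubertal, three replicates per stage). The package
implements the full analysis chain as a reusable, tested library:

1. **Differential expression** — low-count filtering (max count across
   libraries ≥ 10), median-of-ratios size factors, shifted-log normalisation
   `log2(count/sf + 0.5)`, and a negative-binomial Wald test
   (variance `μ + αμ²`, method-of-moments dispersion) over all pairwise stage
   contrasts with Benjamini–Hochberg correction. miRNAs pass at
   `padj ≤ 0.05`; mRNAs additionally need `|log2FC| ≥ 0.5`.
2. **Profile clustering** — hierarchical clustering (Euclidean, complete
   linkage) of standardised DE-miRNA profiles into `k = 5` stage clusters,
   with fuzzy c-means memberships for profile plots.
3. **Target prediction** — canonical seed-site scanning of 3′-UTRs
   (6mer, 7mer-A1, 7mer-m8, 8mer; Watson–Crick only in the seed), with a
   composite score combining site class, nearest-neighbour duplex ΔG
   (Turner-style stack table), flank AU content, and a binomial site
   over-representation probability. The top 20% of predictions per miRNA are
   retained. 3′-UTRs are the sequence from CDS end to transcript end,
   longest UTR per transcript.
4. **Anti-correlation refinement** — stage-mean expression profiles; a
   retained prediction becomes a pair link only if the gene is DE and
   miRNA/gene profiles have Pearson `r ≤ −0.5`.
5. **Pathway enrichment** — per miRNA cluster, exact hypergeometric
   over-representation of linked genes in GMT gene sets, BH within cluster,
   reported at `padj ≤ 0.05`.
6. **Network export** — per enriched pathway, edges with strict `r < −0.8`
   and top-half composite score, written as GraphML + edge TSV with node
   colours interpolating dark grey → white over `r ∈ [−1, −0.8]`.

Because the original tissue data are not needed to validate the machinery, a
first-class synthetic-data module generates negative-binomial count matrices
with five planted stage archetypes, planted repressive miRNA→mRNA pairs
(seed sites written into target UTRs, mirror-image expression profiles), and
a planted-enriched pathway, so that every stage of the analysis is testable
end to end against known truth.

## Worked example

Run the numbered drivers in order (or equivalently `mirlink simulate` /
`mirlink run` / `mirlink report` from the CLI):

```bash
python analysis/01_simulate.py
python analysis/02_differential_expression.py
python analysis/03_cluster_profiles.py
python analysis/04_target_prediction.py
python analysis/05_link_and_enrich.py
python analysis/06_network_export.py
```

Output (seed 1 defaults — 200 miRNAs, 2000 mRNAs, 50 planted pairs):

```
mirna: 200 features -> 200 after filter -> 28 differentially expressed (padj<=0.05, |lfc|>=0.0)
mrna: 2000 features -> 2000 after filter -> 57 differentially expressed (padj<=0.05, |lfc|>=0.5)
cluster sizes: {1: 6, 2: 5, 3: 7, 4: 5, 5: 5}
adjusted Rand index vs planted archetypes (25 planted miRNAs): 1.000
extracted 2000 3'-UTRs (mean length 303 nt)
4569 predictions for 28 DE miRNAs; 927 retained in the top 20% per miRNA
50 anti-correlated links; planted-pair precision 1.000, recall 1.000
cluster 1: PATH-TRUE k=10/30 padj=1.72e-16
network: 8 nodes, 5 edges (50 links before display filtering)
```

Reading this: the DE stage recovers all 25 planted miRNAs (plus 3 false
positives, as expected at a 5% FDR) and all 50 planted target genes (plus 7
extra); clustering reproduces the five planted archetypes exactly; the
anti-correlation refinement reduces 927 retained predictions to exactly the
50 planted repressive pairs; and the planted pathway is the only enrichment,
in the cluster that carries its targeting miRNAs. Clusters whose targets hit
only background genes correctly yield no enrichment. The display network is
sparse because its `r < −0.8` bound and top-half score cut are deliberately
stricter than the linking thresholds.

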