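# Methods

This note documents the statistical models, the defaults and why they are
set where they are, what the synthetic data do and do not emulate, and the
numerical conventions. Nothing here states a result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Count model and differential expression

Counts are modelled as negative binomial in the mean/dispersion
parameterisation, `Var = μ + αμ²`; the simulator draws gamma–Poisson
mixtures with exactly these moments, so the generator and the test agree on
the parameterisation by construction.

**Size factors.** Median-of-ratios over the features positive in every
sample, rescaled so the factors' geometric mean is exactly 1. The rescaling
makes factors comparable across runs and gives the documented
`(1/√2, √2)` result when one sample is a doubled copy of the other.

**Normalisation.** A regularised log transform is not re-derivable from a
tool name alone, so the pipeline uses the shifted log
`log2(count/sf + 0.5)`. It preserves the orderings and profile shapes that
clustering and correlation consume; it does not shrink low-count variance
the way a ridge-penalised rlog does, which mainly costs a little noise in
the profiles of weakly expressed features.

**DE test.** Per feature, a Wald contrast on `log2` of normalised group
means, with delta-method variance
`(m·s + αm²)/n` per group (`s` = mean reciprocal size factor). Dispersion
is method-of-moments within groups, floored at `1e-8`, with two modes:

* `per_feature` — each feature keeps its own estimate. Because that
  estimate rests on `n_a + n_b − 2` residual degrees of freedom, the Wald
  statistic is referred to a *t* distribution with that df. On the null
  simulation (2000 features, 3 vs 3, dispersion 0.1) the p ≤ 0.05 fraction
  is ≈ 0.05, which the acceptance suite checks against the [0.03, 0.07]
  band.
* `pooled` — one dispersion for the panel, the cross-feature **mean of the
  raw (signed) moment estimates**. The raw estimator is unbiased but very
  noisy at n = 3; averaging before flooring avoids the downward bias that
  flooring-then-averaging (or taking a median) introduces, and the
  resulting test is calibrated under a normal reference. The pipeline
  defaults to this mode: with three replicates per group, per-feature
  dispersion is too noisy to give any power after multiple-testing
  correction, and borrowing strength across the panel is the standard
  remedy in NB differential expression.

No empirical-Bayes shrinkage, independent filtering or outlier handling is
applied; the test is deliberately desk-scale and fully specified. BH
adjustment is applied per contrast; a feature is "differentially expressed"
if it passes in any pairwise stage contrast. Thresholds are inclusive:
`padj ≤ 0.05`, and for mRNAs `|log2FC| ≥ 0.5`.

## Clustering

Hierarchical clustering uses Euclidean distance and complete linkage on
per-feature standardised (z-scored) 9-sample profiles, cut into `k = 5`
groups. Neither the distance, the linkage nor an automatic choice of k is
prescribed by the analysis this reproduces; 5 is the number of stage
archetypes the design expects, and both distance and linkage are
configurable. Features are processed in sorted-id order and labels
renumbered by first appearance, so results are invariant to input row
order. Fuzzy c-means (fuzzifier m = 2, tolerance 1e-6, ≤ 200 iterations,
seeded random initial memberships) provides soft memberships for profile
plots; its objective is non-increasing per iteration by construction of the
alternating updates.

## Target prediction

Seed patterns are the reverse complements of miRNA nt 2–7 (6mer) and 2–8
(7mer-m8), optionally with a 3′ `A` in the UTR opposite nt 1 (7mer-A1,
8mer). Matching is Watson–Crick only; G:U wobble is accepted in the
thermodynamic feature but never in site definition. Every UTR start
position is scanned and reported with its most specific class; a match
nested inside a strictly more specific overlapping match is the same
physical site and is reported once. An independent brute-force scanner in
the test suite must agree exactly on randomised inputs.

Features per (miRNA, transcript) prediction aggregate over sites: best site
class, summed nearest-neighbour duplex ΔG of the seed-paired core (Turner
2004-style stack free energies embedded as a parameter table; the unpaired
A1 position is excluded), mean flank AU fraction (30 nt each side,
truncated at UTR ends), and the binomial over-representation probability of
the 6mer core count, `P(X ≥ k)` with `X ~ Bin(L − l + 1, Π f_base)`. The
binomial treats windows as independent — exact for single-base patterns
(verified by enumeration) and a standard approximation otherwise.

The composite score is a weighted sum of min–max-normalised features
(weights: site class 1.0, −ΔG 1.0, AU flank 0.5, −log10 p_over 1.0;
normalisation bounds taken over the prediction batch). With non-negative
weights and fixed bounds the score is monotone in every feature. Per miRNA
the `ceil(0.20·n)` best predictions are retained, ties broken
lexicographically by gene then transcript id. The 20% cut is applied before
intersecting with DE mRNAs (a config switch reverses the order).

## Integration and enrichment

Stage profiles are arithmetic means of normalised log expression per stage,
in fixed immature → prepubertal → pubertal order. Pair links require the
gene to be DE and plain Pearson `r ≤ −0.5` between the two 3-point
profiles; a constant profile yields NaN, which fails every correlation
filter. With three points |r| ≥ 0.5 is weak evidence; the bound reproduces
the analysis design rather than endorsing its strength. Transcript-level
predictions collapse to the gene's best-scoring retained transcript.

Enrichment per cluster is the exact hypergeometric upper tail
`P(X ≥ k)` for each pathway with at least one overlapping gene, BH-adjusted
within the cluster (a flag switches to across-cluster adjustment), reported
at `padj ≤ 0.05` with the dot-plot row percentage `k/K·100`. The universe
defaults to filtered genes that appear in at least one pathway, and the
pipeline intersects each cluster's query with that universe before testing
— the convention of standard over-representation tools. A cluster with no
passing pathway legitimately returns zero rows.

The display network applies, within each enriched pathway, first the strict
anti-correlation bound `r < −0.8`, then the top `ceil(50%)` by composite
score. Gene node colour interpolates linearly from dark grey (`r = −1`) to
white (`r = −0.8`), clamped.

## Synthetic data: what it emulates, what it does not

The generator mirrors the study design: 3 stages × 3 replicates, NB counts
with per-sample size factors `U(0.7, 1.4)`, base means log-uniform on
[50, 500], dispersion 0.1 (typical of bulk RNA-seq), 200 miRNAs and 2000
mRNAs (desk scale), 50 planted repressive pairs spread over 25 DE miRNAs.
The five stage archetypes are encoded as per-stage mean multipliers: unit
vectors spaced 72° apart in the centered 3-point profile plane, amplitude
1.6 log2 units, realising the qualitative shapes high-high-low,
high-low-low, high-dip-high, low-high-high and low-low-high. The equiangular
placement is an identifiability choice made at design time: no two distinct
archetypes correlate above r ≈ 0.31, so cluster recovery and
anti-correlation linking are well-posed, while mirror profiles (planted
targets use the reciprocal multipliers) correlate at exactly −1.

Planted target UTRs carry two non-overlapping 8mer sites for their miRNA;
miRNA 5′ octamers are kept unique so planted sites are specific. All UTRs
(and decoys) are drawn from the same AU-rich mononucleotide composition
(A/U 0.30, C/G 0.20), so composition features cannot trivially separate
planted from decoy targets. UTR lengths are uniform on [150, 450] nt —
shorter than typical vertebrate 3′-UTRs, chosen to keep the all-vs-all scan
fast at desk scale; chance seed matches still occur at realistic per-site
rates. One pathway collects the archetype-I planted targets plus 20 random
genes; 20 background pathways (30–80 genes) are drawn from non-planted
genes, so background clusters form a clean enrichment null.

Not emulated: read-level artefacts (mapping, multi-mapping, adapter
effects), isoform structure beyond one transcript per gene (multiple
annotations per transcript are exercised in unit tests only), GC/length
biases, correlated replicates, conservation signal, and non-seed (3′
compensatory) miRNA binding. Passing tests therefore demonstrate the
machinery is correct and calibrated under its own model, not that the
biological findings of any particular tissue would be reproduced.

## Numerical conventions and edge cases

* Annotation coordinates are 1-based inclusive; internal slices half-open
  0-based. `cds_end == transcript_length` yields a retained empty UTR.
* Sequences are normalised to uppercase RNA (T→U) at load.
* Longest-UTR ties keep the first record in annotation order; top-fraction
  and network ties break lexicographically; hierarchical clustering sorts
  features by id first. All outputs are byte-identical across reruns of the
  same configuration and seed (verified by digest comparison).
* Degenerate inputs fail loudly: non-integer counts, duplicate FASTA ids,
  malformed GMT lines (with line number), constant profiles reaching
  standardisation, groups overlapping in the DE test, query genes outside
  the enrichment universe.
* The acceptance script runs the default-size study end to end twice plus a
  2000-feature null and a 100-miRNA archetype recovery; everything fits in
  well under a minute on one CPU.

## Known limitations

* The composite target score is a documented surrogate with the same
  feature families as thermodynamics-aware target predictors, not a
  re-implementation of any published weight set; only the ranking semantics
  (top 20% per miRNA) are load-bearing downstream.
* The DE test trades DESeq2's empirical-Bayes machinery for a fully
  specified moment-based test; at n = 3 its power depends on the pooled
  dispersion mode.
* Correlation on 3 stage means cannot distinguish direct repression from
  shared regulation; the planted-pair recovery numbers quantify behaviour
  under the generator's assumptions only.
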