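"""Synthetic testis-maturation datasets with planted regulatory structure.

The generator emulates the statistical shape of a 3-stage (immature,
prepubertal, pubertal) x 3-replicate small-RNA / mRNA sequencing experiment:

* negative-binomial counts (variance mu + dispersion * mu^2) with per-sample
  size factors;
* a subset of miRNAs differentially expressed along five stage-profile
  archetypes (high-high-low, high-low-low, high-dip-high, low-high-high,
  low-low-high), encoded as per-stage mean multipliers;
* planted repressive miRNA -> mRNA pairs: each target carries exact seed
  sites for its miRNA in its 3'-UTR and follows the exact mirror (reciprocal
  multiplier) stage profile, so the pair's log-scale stage means correlate at
  r = -1 before noise;
* decoy UTRs drawn from the same mononucleotide composition as planted UTRs,
  so sequence-composition features cannot trivially separate the classes;
* one "true" pathway collecting the planted targets of the first archetype
  plus random extras, and background pathways of random non-planted genes.

Everything is driven by a single integer seed; identical configuration gives
byte-identical serialised output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import targeting
from .ioformats import (STAGES, CountMatrix, GeneSetCollection, write_fasta,
                        write_gmt)

# The five archetypes as per-stage mean multipliers. They realise the five
# qualitative stage shapes as unit vectors spaced 72 degrees apart in the
# centered 3-point profile plane (amplitude 1.6 log2 units), so no two
# distinct archetypes have |r| above ~0.31 and mirror profiles are exactly
# anti-correlated.
_ARCHETYPE_LOG2 = [
    (0.137, 1.057, -1.194),    # I   high-high-low
    (1.278, -0.404, -0.874),   # II  high-low-low
    (0.653, -1.306, 0.653),    # III high-dip-high
    (-1.194, 1.057, 0.137),    # IV  low-high-high
    (-0.874, -0.404, 1.278),   # V   low-low-high
]
DEFAULT_ARCHETYPES = [tuple(2.0 ** v for v in row) for row in _ARCHETYPE_LOG2]

#: nucleotide frequencies used for every UTR (3'-UTRs lean AU-rich)
_UTR_COMPOSITION = {"A": 0.30, "C": 0.20, "G": 0.20, "U": 0.30}


@dataclass
class SimConfig:
    n_stages: int = 3
    n_reps_per_stage: int = 3
    n_mirna: int = 200
    n_mrna: int = 2000
    n_true_pairs: int = 50
    targets_per_de_mirna: int = 2
    profile_archetypes: list[tuple[float, ...]] = field(
        default_factory=lambda: [tuple(a) for a in DEFAULT_ARCHETYPES])
    base_mean_range: tuple[float, float] = (50.0, 500.0)
    dispersion: float = 0.1
    size_factor_range: tuple[float, float] = (0.7, 1.4)
    utr_length_range: tuple[int, int] = (150, 450)
    cds_length_range: tuple[int, int] = (300, 900)
    sites_per_true_target: int = 2
    site_type: str = "8mer"
    mirna_length: int = 22
    n_background_pathways: int = 20
    background_pathway_size_range: tuple[int, int] = (30, 80)
    true_pathway_extra_genes: int = 20
    rng_seed: int = 1

    def __post_init__(self) -> None:
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.n_true_pairs > self.n_mirna * self.n_mrna:
            raise ValueError("more true pairs than miRNA x mRNA combinations")
        if self.n_true_pairs > self.n_mrna:
            raise ValueError("planted targets are distinct genes; "
                             "n_true_pairs cannot exceed n_mrna")
        for name in ("base_mean_range", "size_factor_range", "utr_length_range",
                     "cds_length_range", "background_pathway_size_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name}: low {lo} > high {hi}")
            if lo <= 0:
                raise ValueError(f"{name}: bounds must be positive")
        if self.site_type not in targeting.SITE_TYPES:
            raise ValueError(f"unknown site_type {self.site_type!r}")
        if not self.profile_archetypes:
            raise ValueError("need at least one archetype")
        for arch in self.profile_archetypes:
            if len(arch) != self.n_stages:
                raise ValueError("archetype length must equal n_stages")
            if any(v <= 0 for v in arch):
                raise ValueError("archetype multipliers must be positive")

    @property
    def n_de_mirna(self) -> int:
        return math.ceil(self.n_true_pairs / self.targets_per_de_mirna)


@dataclass
class SyntheticDataset:
    config: SimConfig
    mirna_counts: CountMatrix
    mrna_counts: CountMatrix
    mirna_seqs: dict[str, str]
    transcript_seqs: dict[str, str]          # DNA-convention written; RNA here
    utr_seqs: dict[str, str]                 # transcript_id -> true UTR
    annotation: pd.DataFrame                 # transcript_id, gene_id, cds_end, transcript_length
    pathways: GeneSetCollection
    truth_pairs: pd.DataFrame                # mirna_id, gene_id, archetype, n_sites, site_type
    truth_de: pd.DataFrame                   # feature_id, kind, archetype (-1 = flat)
    true_pathway_id: str

    def write(self, outdir: Path | str) -> Path:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.mirna_counts.write(out / "mirna_counts.tsv", out / "mirna_samples.tsv")
        self.mrna_counts.write(out / "mrna_counts.tsv", out / "mrna_samples.tsv")
        write_fasta(self.mirna_seqs, out / "mirna.fasta")
        write_fasta(self.transcript_seqs, out / "transcripts.fasta", alphabet="dna")
        ann = self.annotation.copy()
        ann.to_csv(out / "annotation.tsv", sep="\t", index=False)
        write_gmt(self.pathways, out / "pathways.gmt")
        self.truth_pairs.to_csv(out / "truth_pairs.tsv", sep="\t", index=False)
        self.truth_de.to_csv(out / "truth_de.tsv", sep="\t", index=False)
        with open(out / "true_pathway.txt", "w") as fh:
            fh.write(self.true_pathway_id + "\n")
        return out


def simulate_counts(mean_matrix: np.ndarray, dispersion: float,
                    size_factors: np.ndarray, rng_seed: int) -> np.ndarray:
    """Draw NB(mean = mu * sf, dispersion) counts, gamma-Poisson mixture.

    Variance is mu_sf + dispersion * mu_sf^2; a zero mean is degenerate at 0.
    Identical seeds give identical matrices.
    """
    mu = np.asarray(mean_matrix, dtype=float)
    sf = np.asarray(size_factors, dtype=float)
    if not np.isfinite(mu).all() or (mu < 0).any():
        raise ValueError("mean_matrix must be finite and non-negative")
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    if (sf <= 0).any():
        raise ValueError("size factors must be positive")
    if sf.shape[0] != mu.shape[1]:
        raise ValueError("one size factor per sample required")
    rng = np.random.default_rng(rng_seed)
    scaled = mu * sf[None, :]
    lam = rng.gamma(shape=1.0 / dispersion, scale=scaled * dispersion)
    return rng.poisson(lam).astype("int64")


def plant_seed_sites(utr_sequence: str, mirna_sequence: str, n_sites: int,
                     site_type: str, rng_seed: int) -> str:
    """Overwrite the UTR with n non-overlapping seed sites of the given class.

    The UTR is divided into n equal blocks and one site is written at a
    random offset inside each block, so sites never overlap. The result is
    verifiable with ``targeting.find_seed_sites``.
    """
    if site_type not in targeting.SITE_TYPES:
        raise ValueError(f"unknown site_type {site_type!r}")
    if n_sites == 0:
        return utr_sequence
    pattern = targeting.seed_patterns(mirna_sequence)[site_type]
    L, l = len(utr_sequence), len(pattern)
    block = L // n_sites
    if block < l:
        raise ValueError(
            f"UTR of length {L} cannot host {n_sites} non-overlapping "
            f"{site_type} sites ({l} nt each)")
    rng = np.random.default_rng(rng_seed)
    seq = list(utr_sequence)
    for i in range(n_sites):
        start = i * block + int(rng.integers(0, block - l + 1))
        seq[start:start + l] = pattern
    return "".join(seq)


def _random_seq(rng: np.random.Generator, length: int,
                composition: dict[str, float] | None = None) -> str:
    if composition is None:
        bases, probs = list("ACGU"), None
    else:
        bases = list(composition)
        probs = np.array([composition[b] for b in bases])
        probs = probs / probs.sum()
    return "".join(rng.choice(bases, size=length, p=probs))


def _sample_names(cfg: SimConfig) -> tuple[list[str], list[str]]:
    stages = list(STAGES[: cfg.n_stages])
    names, labels = [], []
    for st in stages:
        for r in range(1, cfg.n_reps_per_stage + 1):
            names.append(f"{st[:3]}_{r}")
            labels.append(st)
    return names, labels


def generate_experiment(config: SimConfig) -> SyntheticDataset:
    """Build a complete synthetic dataset satisfying the planted invariants."""
    cfg = config
    rng = np.random.default_rng(cfg.rng_seed)
    n_arch = len(cfg.profile_archetypes)
    arch_log2 = [np.log2(np.asarray(a, dtype=float)) for a in cfg.profile_archetypes]

    # ---- identities -----------------------------------------------------
    mirna_ids = [f"mir-{i + 1:04d}" for i in range(cfg.n_mirna)]
    gene_ids = [f"gene-{i + 1:05d}" for i in range(cfg.n_mrna)]
    tx_ids = [f"tx-{i + 1:05d}" for i in range(cfg.n_mrna)]

    # mature miRNA sequences with unique 5' octamers, so planted sites are
    # specific to their miRNA
    mirna_seqs: dict[str, str] = {}
    seen_heads: set[str] = set()
    for mid in mirna_ids:
        while True:
            seq = _random_seq(rng, cfg.mirna_length)
            if seq[:8] not in seen_heads:
                seen_heads.add(seq[:8])
                mirna_seqs[mid] = seq
                break

    # ---- planted regulatory structure ----------------------------------
    n_de = cfg.n_de_mirna
    de_mirnas = mirna_ids[:n_de]
    mirna_arch = {mid: i % n_arch for i, mid in enumerate(de_mirnas)}

    target_pool = list(rng.permutation(gene_ids))
    pair_rows = []
    gi = 0
    for mid in de_mirnas:
        for _ in range(cfg.targets_per_de_mirna):
            if len(pair_rows) == cfg.n_true_pairs:
                break
            pair_rows.append({"mirna_id": mid, "gene_id": target_pool[gi],
                              "archetype": mirna_arch[mid],
                              "n_sites": cfg.sites_per_true_target,
                              "site_type": cfg.site_type})
            gi += 1
    truth_pairs = pd.DataFrame(
        pair_rows,
        columns=["mirna_id", "gene_id", "archetype", "n_sites", "site_type"])
    gene_arch = {r.gene_id: r.archetype for r in truth_pairs.itertuples()}
    gene_mirna = {r.gene_id: r.mirna_id for r in truth_pairs.itertuples()}
    planted_genes = set(gene_arch)

    # ---- sequences ------------------------------------------------------
    utr_lo, utr_hi = cfg.utr_length_range
    cds_lo, cds_hi = cfg.cds_length_range
    transcript_seqs: dict[str, str] = {}
    utr_seqs: dict[str, str] = {}
    ann_rows = []
    for gid, tid in zip(gene_ids, tx_ids):
        utr_len = int(rng.integers(utr_lo, utr_hi + 1))
        cds_len = int(rng.integers(cds_lo, cds_hi + 1))
        utr = _random_seq(rng, utr_len, _UTR_COMPOSITION)
        if gid in planted_genes:
            site_seed = int(rng.integers(0, 2**31 - 1))
            utr = plant_seed_sites(utr, mirna_seqs[gene_mirna[gid]],
                                   cfg.sites_per_true_target, cfg.site_type,
                                   site_seed)
        cds = _random_seq(rng, cds_len, _UTR_COMPOSITION)
        transcript_seqs[tid] = cds + utr
        utr_seqs[tid] = utr
        ann_rows.append({"transcript_id": tid, "gene_id": gid,
                         "cds_end": cds_len,
                         "transcript_length": cds_len + utr_len})
    annotation = pd.DataFrame(ann_rows)

    # ---- expression means ----------------------------------------------
    samples, labels = _sample_names(cfg)
    n_samples = len(samples)
    stage_idx = np.array([STAGES.index(s) for s in labels])

    def build_means(ids: list[str], arch_of: dict[str, int],
                    mirror: bool) -> np.ndarray:
        lo, hi = np.log(cfg.base_mean_range[0]), np.log(cfg.base_mean_range[1])
        base = np.exp(rng.uniform(lo, hi, size=len(ids)))
        mat = np.tile(base[:, None], (1, n_samples))
        for i, fid in enumerate(ids):
            if fid in arch_of:
                prof = arch_log2[arch_of[fid]]
                sign = -1.0 if mirror else 1.0
                mat[i] = base[i] * 2.0 ** (sign * prof[stage_idx])
        return mat

    mirna_means = build_means(mirna_ids, mirna_arch, mirror=False)
    mrna_means = build_means(gene_ids, gene_arch, mirror=True)

    sf_lo, sf_hi = cfg.size_factor_range
    sf_mirna = rng.uniform(sf_lo, sf_hi, size=n_samples)
    sf_mrna = rng.uniform(sf_lo, sf_hi, size=n_samples)

    seed_a = int(rng.integers(0, 2**31 - 1))
    seed_b = int(rng.integers(0, 2**31 - 1))
    mirna_mat = simulate_counts(mirna_means, cfg.dispersion, sf_mirna, seed_a)
    mrna_mat = simulate_counts(mrna_means, cfg.dispersion, sf_mrna, seed_b)

    stages_s = pd.Series(labels, index=samples)
    mirna_counts = CountMatrix(
        pd.DataFrame(mirna_mat, index=mirna_ids, columns=samples), stages_s)
    mrna_counts = CountMatrix(
        pd.DataFrame(mrna_mat, index=gene_ids, columns=samples), stages_s)

    # ---- pathways -------------------------------------------------------
    coll = GeneSetCollection()
    true_targets = sorted(truth_pairs.loc[truth_pairs["archetype"] == 0, "gene_id"])
    non_planted = [g for g in gene_ids if g not in planted_genes]
    n_extra = min(cfg.true_pathway_extra_genes, len(non_planted))
    extra = list(rng.choice(non_planted, size=n_extra, replace=False))
    true_pid = "PATH-TRUE"
    coll.names[true_pid] = "planted_target_pathway"
    coll.sets[true_pid] = frozenset(true_targets + extra)
    bg_lo, bg_hi = cfg.background_pathway_size_range
    for b in range(cfg.n_background_pathways):
        size = min(int(rng.integers(bg_lo, bg_hi + 1)), len(non_planted))
        genes = rng.choice(non_planted, size=size, replace=False)
        pid = f"PATH-BG{b + 1:03d}"
        coll.names[pid] = f"background_pathway_{b + 1}"
        coll.sets[pid] = frozenset(genes.tolist())

    # ---- truth table ----------------------------------------------------
    de_rows = [{"feature_id": mid, "kind": "mirna",
                "archetype": mirna_arch.get(mid, -1)} for mid in mirna_ids]
    de_rows += [{"feature_id": gid, "kind": "mrna",
                 "archetype": gene_arch.get(gid, -1)} for gid in gene_ids]
    truth_de = pd.DataFrame(de_rows)

    return SyntheticDataset(
        config=cfg,
        mirna_counts=mirna_counts,
        mrna_counts=mrna_counts,
        mirna_seqs=mirna_seqs,
        transcript_seqs=transcript_seqs,
        utr_seqs=utr_seqs,
        annotation=annotation,
        pathways=coll,
        truth_pairs=truth_pairs,
        truth_de=truth_de,
        true_pathway_id=true_pid,
    )


def with_seed(config: SimConfig, rng_seed: int) -> SimConfig:
    return replace(config, rng_seed=rng_seed)
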