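"""Seed-match target prediction and composite scoring.

A miRNA recognises a transcript mainly through Watson-Crick pairing between
its seed (nucleotides 2-7, optionally extended to 8) and the 3'-UTR. The four
canonical site classes are, in decreasing specificity:

    8mer      complement of miRNA nt 2-8, with an A in the UTR opposite nt 1
    7mer-m8   complement of miRNA nt 2-8
    7mer-A1   complement of miRNA nt 2-7 plus an A opposite nt 1
    6mer      complement of miRNA nt 2-7

Each prediction aggregates its sites into feature values — best site class,
summed nearest-neighbour duplex free energy, AU content of the site flanks,
and a binomial over-representation probability — which a weighted, min-max
normalised composite score combines. Per miRNA, the top-scoring fraction
(default 20%) of predictions is retained.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

_RNA = frozenset("ACGU")
_COMPLEMENT = {"A": "U", "C": "G", "G": "C", "U": "A"}

SITE_TYPES = ("6mer", "7mer-A1", "7mer-m8", "8mer")
#: precedence for reporting; also the default per-class weight contribution
SITE_RANK = {"6mer": 0, "7mer-A1": 1, "7mer-m8": 2, "8mer": 3}

# Nearest-neighbour helix stacking free energies (kcal/mol at 37 C), Turner-style
# parameters.  Key "XY/ZW" reads: top strand 5'-XY-3' over bottom strand 3'-ZW-5',
# i.e. base pairs X:Z and Y:W.  Symmetric stacks are stored once; lookup tries the
# 180-degree rotation.  Wobble G:U pairs are accepted in stacking (not in seed
# matching).
NN_STACKS: dict[str, float] = {
    # Watson-Crick / Watson-Crick
    "AA/UU": -0.93, "AU/UA": -1.10, "UA/AU": -1.33,
    "CU/GA": -2.08, "CA/GU": -2.11, "GU/CA": -2.24, "GA/CU": -2.35,
    "CG/GC": -2.36, "GG/CC": -3.26, "GC/CG": -3.42,
    # G:U wobble containing
    "AG/UU": -0.55, "AU/UG": -1.36, "CG/GU": -1.41, "CU/GG": -2.11,
    "GG/CU": -1.53, "GU/CG": -2.51, "UG/AU": -1.27, "UU/AG": -1.36,
    "GU/UG": +0.47, "UG/GU": +0.30, "GG/UU": -0.74, "UU/GG": -0.74,
    "AG/UC": -2.08, "GA/UU": -1.27,
}

_VALID_PAIRS = frozenset({("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"),
                          ("G", "U"), ("U", "G")})


def _check_rna(seq: str, what: str) -> None:
    bad = set(seq) - _RNA
    if bad:
        raise ValueError(f"{what} contains non-RNA characters {sorted(bad)}")


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


@dataclass(frozen=True)
class SeedSite:
    """One seed match on a UTR; ``utr_position`` is the 0-based start."""

    utr_position: int
    site_type: str
    site_sequence: str


@dataclass
class TargetPrediction:
    """One miRNA -> transcript relation with its scoring features."""

    mirna_id: str
    transcript_id: str
    gene_id: str
    sites: list[SeedSite]
    delta_g: float          # summed stack free energy over sites, kcal/mol (<= 0)
    au_flank: float         # mean A/U fraction of site flanks, in [0, 1]
    p_over: float           # P(>= observed site count by chance), in [0, 1]
    composite_score: float = float("nan")

    @property
    def best_site_type(self) -> str:
        return max(self.sites, key=lambda s: SITE_RANK[s.site_type]).site_type

    @property
    def n_sites(self) -> int:
        return len(self.sites)


def seed_patterns(mirna_seq: str) -> dict[str, str]:
    """UTR-strand match patterns (5'->3') for each canonical site class."""
    _check_rna(mirna_seq, "miRNA")
    if len(mirna_seq) < 8:
        raise ValueError("miRNA shorter than 8 nt")
    core6 = reverse_complement(mirna_seq[1:7])   # complement of nt 2-7
    core7 = reverse_complement(mirna_seq[1:8])   # complement of nt 2-8
    return {
        "6mer": core6,
        "7mer-A1": core6 + "A",
        "7mer-m8": core7,
        "8mer": core7 + "A",
    }


def find_seed_sites(mirna_seq: str, utr_seq: str) -> list[SeedSite]:
    """Scan every UTR start position and report the most specific matching class.

    Precedence at a position is 8mer > 7mer-m8 > 7mer-A1 > 6mer, so each start
    position appears at most once; a match whose span lies entirely inside a
    strictly more specific overlapping match (the 7mer/6mer cores nested in an
    8mer) is the same physical site and is not reported again.
    """
    _check_rna(utr_seq, "UTR")
    patterns = seed_patterns(mirna_seq)
    ordered = ["8mer", "7mer-m8", "7mer-A1", "6mer"]
    raw: list[SeedSite] = []
    L = len(utr_seq)
    for pos in range(L):
        for st in ordered:
            pat = patterns[st]
            if pos + len(pat) <= L and utr_seq.startswith(pat, pos):
                raw.append(SeedSite(pos, st, utr_seq[pos:pos + len(pat)]))
                break
    sites = [
        s for s in raw
        if not any(
            SITE_RANK[o.site_type] > SITE_RANK[s.site_type]
            and o.utr_position <= s.utr_position
            and s.utr_position + len(s.site_sequence)
            <= o.utr_position + len(o.site_sequence)
            for o in raw if o is not s
        )
    ]
    return sites


def _stack_energy(top: str, bottom_rev: str) -> float:
    """Energy of one stack; ``bottom_rev`` is the bottom dinucleotide 3'->5'."""
    key = f"{top}/{bottom_rev}"
    if key in NN_STACKS:
        return NN_STACKS[key]
    rot = f"{bottom_rev[::-1]}/{top[::-1]}"   # 180-degree rotation of the stack
    if rot in NN_STACKS:
        return NN_STACKS[rot]
    raise KeyError(f"no stacking parameters for {key}")


def duplex_delta_g(mirna_subseq: str, site_seq: str) -> float:
    """Nearest-neighbour free energy of a fully paired duplex window.

    ``mirna_subseq`` and ``site_seq`` are both 5'->3' and antiparallel: base i
    of the miRNA pairs with base (L-1-i) of the site. Energy is the sum of
    stack terms over consecutive pairs; a single pair has no stack and scores
    0. A non-pairing (non-WC, non-wobble) position is an error — this routine
    is only ever called on matched seed windows.
    """
    _check_rna(mirna_subseq, "miRNA window")
    _check_rna(site_seq, "site")
    if len(mirna_subseq) != len(site_seq):
        raise ValueError("duplex strands differ in length")
    L = len(mirna_subseq)
    pairs = [(mirna_subseq[i], site_seq[L - 1 - i]) for i in range(L)]
    for i, p in enumerate(pairs):
        if p not in _VALID_PAIRS:
            raise ValueError(f"mismatched pair {p[0]}:{p[1]} at duplex position {i}")
    total = 0.0
    for i in range(L - 1):
        top = mirna_subseq[i] + mirna_subseq[i + 1]
        bottom_rev = site_seq[L - 1 - i] + site_seq[L - 2 - i]
        total += _stack_energy(top, bottom_rev)
    return total


def site_delta_g(mirna_seq: str, site: SeedSite) -> float:
    """Duplex energy of the seed-paired core of a site (the A1 position, when
    present, is unpaired by convention and excluded)."""
    core_len = 7 if site.site_type in ("7mer-m8", "8mer") else 6
    mir_window = mirna_seq[1:1 + core_len]
    site_core = site.site_sequence[:core_len]
    return duplex_delta_g(mir_window, site_core)


def au_flank_content(utr_seq: str, site: SeedSite, flank: int = 30) -> float:
    """A/U fraction of up to ``flank`` nt on each side of a site, truncated at
    the UTR ends; a site flush against both ends has no flank and scores 0."""
    lo = max(0, site.utr_position - flank)
    hi = min(len(utr_seq), site.utr_position + len(site.site_sequence) + flank)
    flanks = utr_seq[lo:site.utr_position] + \
        utr_seq[site.utr_position + len(site.site_sequence):hi]
    if not flanks:
        return 0.0
    return sum(1 for b in flanks if b in "AU") / len(flanks)


def p_over(utr_seq: str, pattern: str, observed_sites: int,
           base_freqs: Mapping[str, float] | None = None) -> float:
    """Probability of observing at least ``observed_sites`` matches by chance.

    Site count is modelled as Binomial(n = L - l + 1, p), with the
    per-position match probability p the product of mononucleotide
    frequencies over the pattern's bases — taken from the UTR itself unless
    ``base_freqs`` overrides them. A UTR shorter than the pattern has no
    positions: P(X >= 0) = 1, P(X >= k > 0) = 0. The binomial treats window
    matches as independent; it is exact for single-base patterns and a
    standard approximation for longer ones.
    """
    if observed_sites < 0:
        raise ValueError("observed_sites must be >= 0")
    if observed_sites == 0:
        return 1.0
    L, l = len(utr_seq), len(pattern)
    n = L - l + 1
    if n <= 0:
        return 0.0
    if base_freqs is None:
        base_freqs = {b: utr_seq.count(b) / L for b in "ACGU"}
    p = 1.0
    for b in pattern:
        p *= base_freqs[b]
    return float(stats.binom.sf(observed_sites - 1, n, p))


def predict_targets(mirna_seqs: Mapping[str, str],
                    utrs: Mapping[str, tuple[str, str]],
                    flank: int = 30) -> list[TargetPrediction]:
    """Scan every (miRNA, UTR) combination and build per-pair predictions.

    ``utrs`` maps transcript_id -> (gene_id, UTR sequence). Features aggregate
    over a pair's sites: best (most specific) site class, summed duplex
    energy, mean flank AU content, and the over-representation probability of
    the 6mer core count.
    """
    out: list[TargetPrediction] = []
    for mid in sorted(mirna_seqs):
        mseq = mirna_seqs[mid]
        core6 = seed_patterns(mseq)["6mer"]
        for tid in sorted(utrs):
            gid, useq = utrs[tid]
            sites = find_seed_sites(mseq, useq)
            if not sites:
                continue
            dg = sum(site_delta_g(mseq, s) for s in sites)
            au = float(np.mean([au_flank_content(useq, s, flank) for s in sites]))
            # every canonical site contains the 6mer core, so the core count is
            # the natural over-representation statistic
            n_core = sum(1 for i in range(len(useq)) if useq.startswith(core6, i))
            po = p_over(useq, core6, n_core)
            out.append(TargetPrediction(mid, tid, gid, sites, dg, au, po))
    return out


#: default composite weights per feature family
DEFAULT_WEIGHTS = {"site_type": 1.0, "delta_g": 1.0, "au_flank": 0.5, "p_over": 1.0}


def feature_table(predictions: Sequence[TargetPrediction]) -> pd.DataFrame:
    rows = []
    for p in predictions:
        rows.append({
            "mirna_id": p.mirna_id,
            "transcript_id": p.transcript_id,
            "gene_id": p.gene_id,
            "n_sites": p.n_sites,
            "best_type": p.best_site_type,
            "site_type": float(SITE_RANK[p.best_site_type]),
            "delta_g": -p.delta_g,                       # more negative dG -> larger
            "au_flank": p.au_flank,
            "p_over": -math.log10(max(p.p_over, 1e-300)),
        })
    return pd.DataFrame(rows)


def composite_score(features: Mapping[str, float],
                    bounds: Mapping[str, tuple[float, float]],
                    weights: Mapping[str, float] = DEFAULT_WEIGHTS) -> float:
    """Weighted sum of min-max normalised features against fixed bounds.

    With non-negative weights and fixed bounds the score is monotone
    non-decreasing in every feature. Degenerate bounds (lo == hi) contribute a
    constant 0.5.
    """
    total = 0.0
    for name, w in weights.items():
        lo, hi = bounds[name]
        x = features[name]
        if hi > lo:
            z = min(1.0, max(0.0, (x - lo) / (hi - lo)))
        else:
            z = 0.5
        total += w * z
    return total


def score_predictions(predictions: Sequence[TargetPrediction],
                      weights: Mapping[str, float] = DEFAULT_WEIGHTS) -> pd.DataFrame:
    """Attach composite scores; normalisation bounds are taken over the batch."""
    if not predictions:
        return pd.DataFrame(columns=["mirna_id", "transcript_id", "gene_id", "n_sites",
                                     "best_type", "delta_g", "au_flank", "p_over",
                                     "score"])
    tab = feature_table(predictions)
    bounds = {name: (float(tab[name].min()), float(tab[name].max()))
              for name in weights}
    scores = [
        composite_score(row, bounds, weights)
        for row in tab[list(weights)].to_dict("records")
    ]
    tab["score"] = scores
    for p, s in zip(predictions, scores):
        p.composite_score = s
    return tab


def select_top_fraction(scored: pd.DataFrame, fraction: float = 0.20) -> pd.DataFrame:
    """Per miRNA, keep the ceil(fraction * n) highest-scoring predictions.

    Ties resolve lexicographically by (gene_id, transcript_id) so the output
    is deterministic.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if scored.empty:
        return scored.copy()
    kept = []
    for _, grp in scored.groupby("mirna_id", sort=True):
        n_keep = math.ceil(fraction * len(grp))
        ordered = grp.sort_values(
            ["score", "gene_id", "transcript_id"],
            ascending=[False, True, True],
            kind="mergesort",
        )
        kept.append(ordered.head(n_keep))
    return pd.concat(kept, axis=0).reset_index(drop=True)
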