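"""Normalisation, low-count filtering and differential expression.

Counts are modelled as negative binomial with variance mu + alpha * mu**2
(mean/dispersion parameterisation). Library depth is removed with
median-of-ratios size factors, rescaled to geometric mean 1; expression is
compared on a shifted-log scale, log2(count / sf + pseudocount) — a
variance-stabilising stand-in for a regularised log transform that preserves
the orderings downstream clustering and correlation rely on.

The two-group test is a Wald contrast on log2 group means of normalised
counts. Per-feature dispersion is estimated by method of moments within
groups (floored at 1e-8, no shrinkage); because the variance is estimated
from 4 residual degrees of freedom, the Wald statistic is referred to a
t(n_a + n_b - 2) distribution rather than the normal. Multiple testing uses
Benjamini-Hochberg.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .ioformats import CountMatrix

DISPERSION_FLOOR = 1e-8


@dataclass
class NormalizationModel:
    size_factors: pd.Series          # per sample, geometric mean 1
    pseudocount: float
    normalized_log: pd.DataFrame     # feature x sample, log2 scale


def low_count_filter(cm: CountMatrix, min_max_depth: int = 10) -> CountMatrix:
    """Drop features whose maximum count across samples is below the threshold.

    A feature survives iff max_j(count_ij) >= min_max_depth.
    """
    keep = cm.counts.max(axis=1) >= min_max_depth
    return CountMatrix(cm.counts.loc[keep], cm.stages)


def size_factors(cm: CountMatrix) -> pd.Series:
    """Median-of-ratios depth factors, rescaled to geometric mean 1.

    For features positive in every sample, each sample's factor is the median
    ratio of its count to the feature's geometric mean across samples.
    """
    counts = cm.counts.to_numpy(dtype=float)
    all_pos = (counts > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError(
            "no feature has positive counts in every sample; "
            "add a pseudocount or filter samples"
        )
    ref = counts[all_pos]
    log_geo = np.log(ref).mean(axis=1, keepdims=True)
    ratios = ref / np.exp(log_geo)
    sf = np.median(ratios, axis=0)
    sf = sf / np.exp(np.mean(np.log(sf)))     # rescale: geometric mean exactly 1
    return pd.Series(sf, index=cm.counts.columns, name="size_factor")


def normalize_log(cm: CountMatrix, sf: pd.Series,
                  pseudocount: float = 0.5) -> NormalizationModel:
    """Shifted-log normalisation: log2(count / size_factor + pseudocount)."""
    if (sf <= 0).any():
        raise ValueError("size factors must be positive")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    norm = np.log2(cm.counts / sf.loc[cm.counts.columns] + pseudocount)
    return NormalizationModel(sf, pseudocount, norm)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up, sort-cummin definition)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _group_moments(q: np.ndarray, inv_sf: np.ndarray):
    """Mean, sample variance and mean(1/sf) of normalised counts per feature."""
    m = q.mean(axis=1)
    v = q.var(axis=1, ddof=1)
    s = float(np.mean(inv_sf))
    return m, v, s


def de_test(cm: CountMatrix, sf: pd.Series, group_a: Sequence[str],
            group_b: Sequence[str], dispersion_mode: str = "per_feature",
            pseudocount: float = 0.5) -> pd.DataFrame:
    """Two-group NB Wald contrast; log2 fold change is group B over group A.

    Returns a frame with feature_id, log2fc, p, padj. ``dispersion_mode``:
    ``per_feature`` (method of moments within groups, floored) or ``pooled``
    (each feature uses the across-feature median dispersion — more stable for
    very small panels).
    """
    group_a, group_b = list(group_a), list(group_b)
    overlap = set(group_a) & set(group_b)
    if overlap:
        raise ValueError(f"groups overlap: {sorted(overlap)}")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 samples")
    if dispersion_mode not in ("per_feature", "pooled"):
        raise ValueError(f"unknown dispersion_mode {dispersion_mode!r}")

    counts = cm.counts
    sfa = sf.loc[group_a].to_numpy()
    sfb = sf.loc[group_b].to_numpy()
    qa = counts[group_a].to_numpy(dtype=float) / sfa
    qb = counts[group_b].to_numpy(dtype=float) / sfb
    na, nb = len(group_a), len(group_b)

    ma, va, sa = _group_moments(qa, 1.0 / sfa)
    mb, vb, sb = _group_moments(qb, 1.0 / sfb)

    # method-of-moments dispersion: Var(q) = mu * mean(1/sf) + alpha * mu^2
    with np.errstate(divide="ignore", invalid="ignore"):
        aa = (va - ma * sa) / np.square(ma)
        ab = (vb - mb * sb) / np.square(mb)
    alpha_raw = np.nanmean(np.stack([aa, ab]), axis=0)
    alpha_raw = np.where(np.isfinite(alpha_raw), alpha_raw, 0.0)
    if dispersion_mode == "pooled":
        # average the raw (signed) moment estimates across the panel: the
        # per-feature estimator is unbiased but noisy, so its cross-feature
        # mean recovers a common dispersion without the floor-induced bias
        expressed = (ma > 0) & (mb > 0)
        pooled = float(np.mean(alpha_raw[expressed])) if expressed.any() else 0.0
        alpha = np.full_like(alpha_raw, max(pooled, DISPERSION_FLOOR))
    else:
        alpha = np.maximum(alpha_raw, DISPERSION_FLOOR)

    var_mean_a = (ma * sa + alpha * np.square(ma)) / na
    var_mean_b = (mb * sb + alpha * np.square(mb)) / nb

    lfc = np.log2(mb + pseudocount) - np.log2(ma + pseudocount)
    ln2sq = np.log(2.0) ** 2
    var_lfc = (var_mean_a / np.square(ma + pseudocount)
               + var_mean_b / np.square(mb + pseudocount)) / ln2sq
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = lfc / np.sqrt(var_lfc)
    wald = np.where(var_lfc > 0, wald, 0.0)
    if dispersion_mode == "per_feature":
        # variance rests on (na + nb - 2) residual df -> t reference
        p = 2.0 * stats.t.sf(np.abs(wald), na + nb - 2)
    else:
        # pooled dispersion borrows strength across the whole panel, so the
        # variance is effectively known and the normal reference applies
        p = 2.0 * stats.norm.sf(np.abs(wald))

    out = pd.DataFrame({
        "feature_id": counts.index,
        "log2fc": lfc,
        "p": p,
        "padj": bh_adjust(p),
    }).set_index("feature_id")
    return out


def apply_thresholds(results: pd.DataFrame, padj_max: float = 0.05,
                     min_abs_log2fc: float = 0.0) -> set[str]:
    """Features passing both bounds, inclusively: padj <= padj_max and
    |log2fc| >= min_abs_log2fc. With min_abs_log2fc = 0 the adjusted p alone
    decides (the miRNA mode); 0.5 is the mRNA mode."""
    ok = (results["padj"] <= padj_max) & (results["log2fc"].abs() >= min_abs_log2fc)
    return set(results.index[ok])


def pairwise_contrasts(cm: CountMatrix, sf: pd.Series,
                       stage_order: Sequence[str],
                       dispersion_mode: str = "per_feature") -> dict[str, pd.DataFrame]:
    """All pairwise stage contrasts (later vs earlier), each with its own BH."""
    out: dict[str, pd.DataFrame] = {}
    for i in range(len(stage_order)):
        for j in range(i + 1, len(stage_order)):
            a, b = stage_order[i], stage_order[j]
            ga = [s for s in cm.samples if cm.stages[s] == a]
            gb = [s for s in cm.samples if cm.stages[s] == b]
            out[f"{b}_vs_{a}"] = de_test(cm, sf, ga, gb, dispersion_mode)
    return out


def differentially_expressed(contrasts: dict[str, pd.DataFrame],
                             padj_max: float = 0.05,
                             min_abs_log2fc: float = 0.0) -> set[str]:
    """A feature is differentially expressed if it passes in any contrast."""
    hits: set[str] = set()
    for res in contrasts.values():
        hits |= apply_thresholds(res, padj_max, min_abs_log2fc)
    return hits
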