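"""Stage-averaged profiles and anti-correlation refinement of predictions.

A retained target prediction becomes a pair link only when the miRNA and the
gene show inverted expression across development: the Pearson correlation of
their stage-mean profiles must fall at or below ``r_max`` (default -0.5).
With three stages the profile has only three points, so the correlation is a
coarse screen rather than strong statistical evidence; it reproduces the
refinement rule this analysis is built around.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ioformats import STAGES


def stage_average(normalized_log: pd.DataFrame, stage_labels: pd.Series,
                  stage_order: Sequence[str] = STAGES) -> pd.DataFrame:
    """Arithmetic mean of each feature's normalised values per stage.

    Columns follow ``stage_order``; an unknown stage label is an error.
    """
    known = set(stage_order)
    bad = sorted(set(stage_labels.unique()) - known)
    if bad:
        raise ValueError(f"unknown stage labels: {bad}")
    cols = {}
    for stage in stage_order:
        samples = stage_labels.index[stage_labels == stage]
        if len(samples) == 0:
            raise ValueError(f"stage {stage!r} has no samples")
        cols[stage] = normalized_log[list(samples)].mean(axis=1)
    return pd.DataFrame(cols)[list(stage_order)]


def pearson_r(a: Sequence[float], b: Sequence[float]) -> float:
    """Pearson product-moment correlation of two equal-length profiles.

    A constant profile leaves the correlation undefined; NaN is returned,
    which fails every <=/< comparison and therefore every correlation filter.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.shape != y.shape:
        raise ValueError("profiles differ in length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt(float(xc @ xc) * float(yc @ yc))
    if denom == 0.0:
        return float("nan")
    return float(xc @ yc) / denom


def link_pairs(retained: pd.DataFrame,
               mirna_clusters: pd.Series,
               de_genes: set[str],
               mirna_profiles: pd.DataFrame,
               mrna_profiles: pd.DataFrame,
               r_max: float = -0.5) -> pd.DataFrame:
    """Refine retained predictions into anti-correlated miRNA -> gene links.

    ``retained`` is the top-fraction prediction table (one row per miRNA x
    transcript). Transcript-level predictions collapse to gene level by best
    composite score. A link survives when the gene is differentially
    expressed and the miRNA/gene stage profiles have Pearson r <= r_max; the
    miRNA's cluster label is attached.
    """
    cols = ["mirna_id", "gene_id", "cluster", "score", "pearson_r"]
    if retained.empty:
        return pd.DataFrame(columns=cols)
    cand = retained[retained["gene_id"].isin(de_genes)]
    if cand.empty:
        return pd.DataFrame(columns=cols)
    # best transcript per (miRNA, gene); deterministic tie-break on transcript id
    cand = cand.sort_values(["mirna_id", "gene_id", "score", "transcript_id"],
                            ascending=[True, True, False, True], kind="mergesort")
    cand = cand.drop_duplicates(subset=["mirna_id", "gene_id"], keep="first")

    rows = []
    for rec in cand.itertuples(index=False):
        if rec.mirna_id not in mirna_profiles.index:
            raise KeyError(f"no stage profile for miRNA {rec.mirna_id!r}")
        if rec.gene_id not in mrna_profiles.index:
            raise KeyError(f"no stage profile for gene {rec.gene_id!r}")
        r = pearson_r(mirna_profiles.loc[rec.mirna_id].to_numpy(),
                      mrna_profiles.loc[rec.gene_id].to_numpy())
        if r <= r_max:              # NaN (constant profile) never passes
            rows.append({
                "mirna_id": rec.mirna_id,
                "gene_id": rec.gene_id,
                "cluster": mirna_clusters.get(rec.mirna_id),
                "score": rec.score,
                "pearson_r": r,
            })
    return pd.DataFrame(rows, columns=cols)
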