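#!/usr/bin/env python
"""Filter, normalise and test both count matrices for stage-wise DE.

Applies the max-count >= 10 filter, median-of-ratios size factors and the
shifted-log transform, then runs all three pairwise stage contrasts with the
pooled-dispersion NB Wald test. miRNAs pass on adjusted p <= 0.05; mRNAs
additionally need |log2FC| >= 0.5.
"""

from pathlib import Path

import pandas as pd

from mirlink import expression as ex
from mirlink import ioformats as io

ROOT = Path(__file__).resolve().parents[1]
SIM = ROOT / "results" / "sim"
OUT = ROOT / "results" / "de"


def analyse(tag: str, padj_max: float, min_lfc: float) -> set[str]:
    cm = io.read_counts(SIM / f"{tag}_counts.tsv", SIM / f"{tag}_samples.tsv")
    filt = ex.low_count_filter(cm, 10)
    sf = ex.size_factors(filt)
    norm = ex.normalize_log(filt, sf)
    norm.normalized_log.to_csv(OUT / f"{tag}_normalized_log.tsv", sep="\t")
    contrasts = ex.pairwise_contrasts(filt, sf, io.STAGES,
                                      dispersion_mode="pooled")
    for name, res in contrasts.items():
        res.to_csv(OUT / f"{tag}_de_{name}.tsv", sep="\t")
    de = ex.differentially_expressed(contrasts, padj_max, min_lfc)
    pd.Series(sorted(de), name="feature_id").to_csv(
        OUT / f"{tag}_de_features.tsv", sep="\t", index=False)
    print(f"{tag}: {cm.n_features} features -> {filt.n_features} after "
          f"filter -> {len(de)} differentially expressed "
          f"(padj<={padj_max}, |lfc|>={min_lfc})")
    return de


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    analyse("mirna", 0.05, 0.0)
    analyse("mrna", 0.05, 0.5)


if __name__ == "__main__":
    main()
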