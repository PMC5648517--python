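#!/usr/bin/env python
"""Predict 3'-UTR targets of the DE miRNAs and keep the top 20% per miRNA.

Extracts each transcript's 3'-UTR (CDS end to transcript end, longest per
transcript), scans for canonical seed sites (6mer/7mer-A1/7mer-m8/8mer),
computes the duplex energy, flank AU content and site over-representation
features, and ranks predictions by the weighted composite score.
"""

from pathlib import Path

import pandas as pd

from mirlink import ioformats as io
from mirlink import targeting as tg

ROOT = Path(__file__).resolve().parents[1]
SIM = ROOT / "results" / "sim"
OUT = ROOT / "results" / "targets"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    tx_seqs = io.read_fasta(SIM / "transcripts.fasta")
    annotations = io.read_annotation(SIM / "annotation.tsv")
    by_tx: dict[str, list[io.UTRRecord]] = {}
    for ann in annotations:
        rec = io.extract_3utr(tx_seqs[ann.transcript_id], ann)
        by_tx.setdefault(ann.transcript_id, []).append(rec)
    utrs = {}
    for tid in sorted(by_tx):
        rec = io.choose_longest_utr(by_tx[tid])
        if rec.length > 0:
            utrs[tid] = (rec.gene_id, rec.sequence)
    print(f"extracted {len(utrs)} 3'-UTRs "
          f"(mean length {sum(len(s) for _, s in utrs.values()) / len(utrs):.0f} nt)")

    mirna_seqs = io.read_fasta(SIM / "mirna.fasta")
    de = pd.read_csv(ROOT / "results/de/mirna_de_features.tsv",
                     sep="\t")["feature_id"].tolist()
    de_seqs = {m: mirna_seqs[m] for m in de}
    predictions = tg.predict_targets(de_seqs, utrs)
    scored = tg.score_predictions(predictions)
    retained = tg.select_top_fraction(scored, fraction=0.20)
    key = pd.MultiIndex.from_frame(retained[["mirna_id", "transcript_id"]])
    scored["retained"] = pd.MultiIndex.from_frame(
        scored[["mirna_id", "transcript_id"]]).isin(key)
    scored.to_csv(OUT / "target_predictions.tsv", sep="\t", index=False)
    print(f"{len(scored)} predictions for {len(de_seqs)} DE miRNAs; "
          f"{len(retained)} retained in the top 20% per miRNA")
    print("site-class spectrum of retained predictions:",
          dict(retained["best_type"].value_counts()))


if __name__ == "__main__":
    main()
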