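#!/usr/bin/env python
"""Generate the default synthetic study and write it under results/sim.

Emulates a 3-stage x 3-replicate testis maturation experiment: 200 miRNAs
(25 of them differentially expressed along 5 stage archetypes), 2000 mRNAs,
and 50 planted repressive miRNA->mRNA pairs whose targets carry seed sites
and mirror-image expression profiles.
"""

from pathlib import Path

from mirlink import simdata as sd

ROOT = Path(__file__).resolve().parents[1]
SEED = 1


def main() -> None:
    cfg = sd.SimConfig(rng_seed=SEED)
    ds = sd.generate_experiment(cfg)
    out = ds.write(ROOT / "results" / "sim")
    print(f"wrote dataset to {out}")
    print(f"  miRNA matrix : {ds.mirna_counts.counts.shape[0]} x "
          f"{ds.mirna_counts.counts.shape[1]} (features x samples)")
    print(f"  mRNA matrix  : {ds.mrna_counts.counts.shape[0]} x "
          f"{ds.mrna_counts.counts.shape[1]}")
    print(f"  planted DE miRNAs : {cfg.n_de_mirna} across "
          f"{len(cfg.profile_archetypes)} archetypes")
    print(f"  planted pairs     : {len(ds.truth_pairs)} "
          f"({cfg.sites_per_true_target} x {cfg.site_type} sites each)")
    print(f"  pathways          : {len(ds.pathways)} "
          f"(true pathway: {ds.true_pathway_id})")


if __name__ == "__main__":
    main()
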