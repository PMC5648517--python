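"""Readers and writers for every on-disk format the pipeline touches.

Counts travel as TSV (features x samples) with a companion sample sheet
mapping sample id to developmental stage; sequences as FASTA; pathway gene
sets as GMT; the final regulatory network as GraphML plus a flat edge list.

Coordinate convention: transcript annotation is 1-based inclusive (``cds_end``
is the last coding base); internal slicing is half-open 0-based. Sequences are
normalised to the RNA alphabet (uppercase, T -> U) as they are loaded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd
from Bio import SeqIO

STAGES = ("immature", "prepubertal", "pubertal")

_RNA_ALPHABET = frozenset("ACGU")


def normalize_rna(seq: str) -> str:
    """Uppercase a nucleotide string and convert T to U."""
    return seq.upper().replace("T", "U")


@dataclass
class CountMatrix:
    """Integer feature x sample count table with per-sample stage labels."""

    counts: pd.DataFrame            # features x samples, integer dtype
    stages: pd.Series               # sample id -> stage label

    def __post_init__(self) -> None:
        missing = [s for s in self.counts.columns if s not in self.stages.index]
        if missing:
            raise ValueError(f"samples missing from sample sheet: {missing}")
        self.stages = self.stages.loc[list(self.counts.columns)]

    @property
    def n_features(self) -> int:
        return self.counts.shape[0]

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def subset(self, feature_ids: Iterable[str]) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(feature_ids)], self.stages)

    def write(self, counts_path: Path | str, sample_sheet_path: Path | str) -> None:
        df = self.counts.copy()
        df.index.name = "feature_id"
        df.to_csv(counts_path, sep="\t")
        sheet = pd.DataFrame({"sample_id": self.stages.index, "stage": self.stages.values})
        sheet.to_csv(sample_sheet_path, sep="\t", index=False)


@dataclass(frozen=True)
class TranscriptAnnotation:
    """One transcript's coordinates: where its coding sequence ends."""

    transcript_id: str
    gene_id: str
    cds_end: int              # 1-based inclusive position of the last CDS base
    transcript_length: int

    def __post_init__(self) -> None:
        if not (1 <= self.cds_end <= self.transcript_length):
            raise ValueError(
                f"{self.transcript_id}: cds_end {self.cds_end} outside "
                f"[1, {self.transcript_length}]"
            )


@dataclass(frozen=True)
class UTRRecord:
    """A transcript's 3'-UTR in the RNA alphabet."""

    transcript_id: str
    gene_id: str
    sequence: str

    def __post_init__(self) -> None:
        bad = set(self.sequence) - _RNA_ALPHABET
        if bad:
            raise ValueError(f"{self.transcript_id}: non-RNA characters {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class GeneSetCollection:
    """Pathway id -> (display name, member gene ids)."""

    names: dict[str, str] = field(default_factory=dict)
    sets: dict[str, frozenset[str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def genes(self, pathway_id: str) -> frozenset[str]:
        return self.sets[pathway_id]

    def all_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for s in self.sets.values():
            out |= s
        return frozenset(out)


def read_counts(counts_path: Path | str, sample_sheet_path: Path | str) -> CountMatrix:
    """Load a count TSV and its sample sheet into a validated CountMatrix.

    Rejects non-integer cells, duplicated feature ids and samples absent from
    the sheet, naming the offender in the error message.
    """
    df = pd.read_csv(counts_path, sep="\t", index_col=0)
    dup = df.index[df.index.duplicated()].unique().tolist()
    if dup:
        raise ValueError(f"duplicate feature ids in {counts_path}: {dup}")
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            bad = df.index[vals.isna()][0]
            raise ValueError(f"non-numeric count at feature {bad!r}, sample {col!r}")
        if not (vals == vals.round()).all():
            bad = df.index[vals != vals.round()][0]
            raise ValueError(f"non-integer count at feature {bad!r}, sample {col!r}")
        if (vals < 0).any():
            bad = df.index[vals < 0][0]
            raise ValueError(f"negative count at feature {bad!r}, sample {col!r}")
    df = df.astype("int64")

    sheet = pd.read_csv(sample_sheet_path, sep="\t")
    for needed in ("sample_id", "stage"):
        if needed not in sheet.columns:
            raise ValueError(f"sample sheet missing column {needed!r}")
    stages = pd.Series(sheet["stage"].values, index=sheet["sample_id"].astype(str))
    missing = [s for s in df.columns if s not in stages.index]
    if missing:
        raise ValueError(f"samples in counts but not in sample sheet: {missing}")
    return CountMatrix(df, stages)


def extract_3utr(transcript_sequence: str, annotation: TranscriptAnnotation) -> UTRRecord:
    """Return the sequence from the end of the CDS to the end of the transcript.

    ``cds_end`` is 1-based inclusive, so the UTR is positions ``cds_end + 1``
    through ``transcript_length``; an annotation ending at the last base yields
    a zero-length record, which is retained.
    """
    seq = normalize_rna(transcript_sequence)
    if len(seq) != annotation.transcript_length:
        raise ValueError(
            f"{annotation.transcript_id}: sequence length {len(seq)} != annotated "
            f"transcript_length {annotation.transcript_length}"
        )
    utr = seq[annotation.cds_end:]            # half-open 0-based slice
    return UTRRecord(annotation.transcript_id, annotation.gene_id, utr)


def choose_longest_utr(records: list[UTRRecord]) -> UTRRecord:
    """Among alternative annotations of one transcript, keep the longest UTR.

    Ties resolve to the earliest record in input order.
    """
    if not records:
        raise ValueError("no UTR records to choose from")
    ids = {r.transcript_id for r in records}
    if len(ids) > 1:
        raise ValueError(f"records span multiple transcripts: {sorted(ids)}")
    return max(records, key=lambda r: r.length)   # max keeps the first maximum


def read_annotation(path: Path | str) -> list[TranscriptAnnotation]:
    """Load a transcript annotation TSV (transcript_id, gene_id, cds_end, transcript_length)."""
    df = pd.read_csv(path, sep="\t")
    needed = {"transcript_id", "gene_id", "cds_end", "transcript_length"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"annotation missing columns: {sorted(missing)}")
    return [
        TranscriptAnnotation(str(r.transcript_id), str(r.gene_id), int(r.cds_end),
                             int(r.transcript_length))
        for r in df.itertuples(index=False)
    ]


def read_fasta(path: Path | str) -> dict[str, str]:
    """Load a FASTA file into an id -> RNA sequence map; duplicate ids are an error."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        out[rec.id] = normalize_rna(str(rec.seq))
    return out


def write_fasta(seqs: Mapping[str, str], path: Path | str, alphabet: str = "rna") -> None:
    """Write sequences in a stable order; ``alphabet='dna'`` converts U back to T."""
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            if alphabet == "dna":
                seq = seq.upper().replace("U", "T")
            fh.write(f">{name}\n{seq}\n")


def read_gmt(path: Path | str) -> GeneSetCollection:
    """Load gene sets from GMT (pathway id, name, then member genes, tab-separated)."""
    coll = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            pid, name, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            if pid in coll.sets:
                raise ValueError(f"{path}:{lineno}: duplicate pathway id {pid!r}")
            if not genes:
                raise ValueError(f"{path}:{lineno}: pathway {pid!r} has no genes")
            coll.names[pid] = name
            coll.sets[pid] = frozenset(genes)
    return coll


def write_gmt(coll: GeneSetCollection, path: Path | str) -> None:
    with open(path, "w") as fh:
        for pid in sorted(coll.sets):
            genes = "\t".join(sorted(coll.sets[pid]))
            fh.write(f"{pid}\t{coll.names.get(pid, pid)}\t{genes}\n")


def write_network(graph: nx.DiGraph, graphml_path: Path | str,
                  edges_tsv_path: Path | str) -> None:
    """Serialise the miRNA -> gene network as GraphML plus a flat edge table.

    GraphML carries every node and edge attribute (for import into a network
    viewer); the TSV duplicates the edges for spreadsheet inspection.
    """
    nx.write_graphml(graph, str(graphml_path), named_key_ids=True)
    rows = []
    for u, v, attrs in sorted(graph.edges(data=True)):
        row = {"source": u, "target": v}
        row.update({k: attrs[k] for k in sorted(attrs)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(edges_tsv_path, sep="\t", index=False)


def read_network(graphml_path: Path | str) -> nx.DiGraph:
    return nx.read_graphml(str(graphml_path))
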