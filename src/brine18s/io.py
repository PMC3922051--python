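"""Readers and writers for the pipeline's file formats.

Sequence files go through Biopython; tables are TSV with a single header
line beginning ``#``.  All coordinates are 0-based half-open and sequences
are handled uppercase.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


@dataclasses.dataclass
class Read:
    """A single amplicon read with per-base Phred quality.

    ``sample_id`` and ``template_id`` are provenance fields filled by
    demultiplexing and (for synthetic reads) by the generator.
    """

    id: str
    seq: str
    qual: list[int]
    sample_id: str | None = None

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.qual):
            raise ValueError(
                f"read {self.id}: sequence length {len(self.seq)} != "
                f"quality length {len(self.qual)}"
            )

    def __len__(self) -> int:
        return len(self.seq)

    def trim_prefix(self, n: int) -> "Read":
        return Read(self.id, self.seq[n:], self.qual[n:], self.sample_id)


def write_fastq(reads: Iterable[Read], path: str | Path) -> Path:
    path = Path(path)
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.seq), id=r.id, description="")
        rec.letter_annotations["phred_quality"] = list(r.qual)
        records.append(rec)
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fastq")
    return path


def read_fastq(path: str | Path) -> list[Read]:
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        reads.append(
            Read(rec.id, str(rec.seq).upper(), list(rec.letter_annotations["phred_quality"]))
        )
    return reads


def write_fasta(entries: Iterable[tuple[str, str]], path: str | Path) -> Path:
    path = Path(path)
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in entries]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")
    return path


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_mapping(mapping: dict[str, str], path: str | Path) -> Path:
    """Write a sample->barcode mapping as TSV with a ``#sample_id`` header."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("#sample_id\tbarcode\n")
        for sample, barcode in mapping.items():
            fh.write(f"{sample}\t{barcode}\n")
    return path


def read_mapping(path: str | Path) -> dict[str, str]:
    mapping: dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValueError(f"mapping file {path} lacks a '#'-prefixed header line")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            sample, barcode = line.split("\t")
            mapping[sample] = barcode.upper()
    return mapping


def write_table(df: pd.DataFrame, path: str | Path, index_label: str = "id") -> Path:
    """Write a DataFrame as TSV whose header line starts with ``#``."""
    path = Path(path)
    out = df.copy()
    out.insert(0, index_label, df.index)
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(str(c) for c in out.columns) + "\n")
        out.to_csv(fh, sep="\t", header=False, index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValueError(f"table {path} lacks a '#'-prefixed header line")
        columns = header[1:].rstrip("\n").split("\t")
        df = pd.read_csv(fh, sep="\t", header=None, names=columns)
    return df.set_index(columns[0])
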